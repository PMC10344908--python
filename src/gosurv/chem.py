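"""Drug featurization and the rare-drug support filter.

Drugs enter the model as fixed-length Morgan (circular substructure)
fingerprint bit vectors computed from SMILES with RDKit. The default length
is 2048 bits at radius 2 (ECFP4-equivalent), both configurable.

The support filter removes drugs with too few supporting (patient, drug)
data points in the training partition. Rarely seen drugs invite the
memorization failure mode: the network reproduces the one training label it
saw for that fingerprint instead of generalizing, so held-out predictions
for such drugs collapse onto a memorized value. Support is counted on data
points, not distinct patients, and only on the training partition;
validation pairs whose drug is removed are dropped as well.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = ["DrugRecord", "smiles_to_fingerprint", "filter_rare_drugs",
           "load_drug_library", "DEFAULT_N_BITS", "DEFAULT_RADIUS"]

DEFAULT_N_BITS = 2048
DEFAULT_RADIUS = 2


@dataclass(frozen=True)
class DrugRecord:
    """A named compound with its SMILES and fingerprint bit vector."""

    name: str
    smiles: str
    fingerprint: np.ndarray  # uint8 0/1, length n_bits

    def __post_init__(self):
        fp = self.fingerprint
        if not np.isin(fp, (0, 1)).all():
            raise ValueError(f"fingerprint of {self.name!r} is not binary")


def smiles_to_fingerprint(smiles: str, n_bits: int = DEFAULT_N_BITS,
                          radius: int = DEFAULT_RADIUS,
                          name: str | None = None) -> np.ndarray:
    """Fold a molecule's circular fingerprint into an `n_bits` 0/1 vector.

    Deterministic in (smiles, n_bits, radius). Raises ValueError for an
    unparseable SMILES (naming the drug if `name` is given) or n_bits <= 0.
    """
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be nonnegative, got {radius}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = name or smiles
        raise ValueError(f"unparseable SMILES for drug {label!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    return np.asarray(gen.GetFingerprint(mol), dtype=np.uint8)


def load_drug_library(path: str, n_bits: int = DEFAULT_N_BITS,
                      radius: int = DEFAULT_RADIUS) -> dict[str, DrugRecord]:
    """Read a drug TSV (columns: name, smiles) into fingerprinted records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "smiles"} <= set(df.columns):
        raise ValueError("drug library needs 'name' and 'smiles' columns")
    lib: dict[str, DrugRecord] = {}
    for row in df.itertuples(index=False):
        lib[row.name] = DrugRecord(
            row.name, row.smiles,
            smiles_to_fingerprint(row.smiles, n_bits, radius, name=row.name))
    return lib


def filter_rare_drugs(
    train_pairs: Sequence[tuple[Hashable, str]],
    min_support: int = 5,
    val_pairs: Sequence[tuple[Hashable, str]] | None = None,
) -> tuple[list, list, pd.DataFrame]:
    """Drop drugs with training support below `min_support`.

    Parameters
    ----------
    train_pairs, val_pairs : sequences of (patient, drug_name) data points.
        Support is counted on `train_pairs` only; a drug is kept iff its
        training support >= min_support. Pairs from both partitions whose
        drug is removed are dropped.

    Returns
    -------
    (kept_train, kept_val, removed) where `removed` is a DataFrame with
    columns name, support for every eliminated drug. `kept_val` is [] when
    `val_pairs` is None. Idempotent and order-independent.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    support = Counter(drug for _, drug in train_pairs)
    removed = sorted((d, n) for d, n in support.items() if n < min_support)
    removed_set = {d for d, _ in removed}
    # validation-only drugs have zero training support and must also go
    if val_pairs:
        for _, drug in val_pairs:
            if drug not in support and drug not in removed_set:
                removed.append((drug, 0))
                removed_set.add(drug)
    kept_train = [p for p in train_pairs if p[1] not in removed_set]
    kept_val = [p for p in (val_pairs or []) if p[1] not in removed_set]
    if removed:
        logger.info("rare-drug filter removed %d drug(s): %s", len(removed),
                    ", ".join(f"{d} (n={n})" for d, n in removed))
    report = pd.DataFrame(sorted(removed), columns=["name", "support"])
    return kept_train, kept_val, report
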