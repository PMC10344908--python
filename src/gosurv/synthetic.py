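"""Ground-truth-bearing synthetic inputs for the whole pipeline.

The generator emulates the statistical structure the model assumes — a
transcriptome and a prescribed drug jointly determining survival — with a
planted, recoverable mechanism:

* a random rooted ontology DAG whose leaf terms act as "pathways";
* genes partitioned across pathways, with within-pathway expression
  correlation induced by a shared latent factor per (pathway, patient);
* true log months-to-death that is linear in the standardized pathway mean
  expressions plus an additive per-drug effect and Gaussian noise:
  ``log_months = mu + sum_p w_p * m_p + beta_drug + N(0, noise_sd)``
  where ``m_p`` is the mean standardized expression of pathway p's genes;
* right-censoring: with probability ``censoring_rate`` a patient is marked
  alive with a follow-up drawn uniformly on (0, death time) — the lower
  bound semantics the stage-1 labels rely on.

Because the planted survival is exactly linear in observable pathway means,
a noiseless configuration is solvable in closed form by ordinary least
squares, which gives the recovery tests an oracle that never touches the
neural network. The ground truth (pathway weights, drug effects, baseline)
is returned with every cohort.

Drug SMILES come from a packaged panel of 20 valid small molecules;
``rare_drug_injection`` appends drugs with exactly the listed patient
supports to reproduce the rare-drug memorization setting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cohort import (DAYS_PER_MONTH, ClinicalRecord, ExpressionMatrix,
                     VitalStatus, standardize_expression)
from .ontology import OntologyDAG, _assemble

__all__ = ["GeneratorConfig", "GroundTruth", "SMILES_PANEL",
           "generate_toy_ontology", "generate_cohort", "write_inputs"]

#: 20 valid small-molecule SMILES used as the synthetic drug library
SMILES_PANEL: tuple[str, ...] = (
    "CC(=O)OC1=CC=CC=C1C(=O)O",            # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",        # caffeine
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)NC1=CC=C(O)C=C1",               # paracetamol
    "CN(C)CCOC(C1=CC=CC=C1)C1=CC=CC=C1",   # diphenhydramine
    "CN1CCC[C@H]1C1=CN=CC=C1",             # nicotine
    "NC1=CC=C(C=C1)S(N)(=O)=O",            # sulfanilamide
    "OC1=CC=CC=C1C(=O)O",                  # salicylic acid
    "C1=CC=C2C(=C1)C(=CN2)CCN",            # tryptamine
    "CC(N)CC1=CC=CC=C1",                   # amphetamine
    "OCC1OC(O)C(O)C(O)C1O",                # glucose
    "C1=CC=C(C=C1)C(=O)O",                 # benzoic acid
    "NC(=O)C1=CC=CC=C1",                   # benzamide
    "CC1=CC=C(C=C1)S(=O)(=O)N",            # p-toluenesulfonamide
    "C1=CC=C(C=C1)NC(=O)C2=CC=C(C=C2)Cl",  # 4-chlorobenzanilide
    "C1CCC(CC1)N",                         # cyclohexylamine
    "C1=CC=C2C=CC=CC2=C1",                 # naphthalene
    "O=C(O)CCC(=O)O",                      # succinic acid
    "COC1=CC=CC=C1OC",                     # veratrole
    "CN1CCN(C)CC1",                        # N,N'-dimethylpiperazine
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_internal_terms: int = 30
    max_depth: int = 4
    branching: int = 3
    n_genes: int = 300
    n_patients: int = 2000
    n_drugs: int = 12
    censoring_rate: float = 0.3
    noise_sd: float = 0.3
    drug_effect_sd: float = 0.3
    pathway_effect_sd: float = 0.5
    zero_weight_fraction: float = 0.5
    gene_noise_sd: float = 0.3
    baseline_log_months: float = 3.3      # median survival ~ 27 months
    tandem_fraction: float = 0.05         # patients with two drugs
    multi_parent_prob: float = 0.15
    rare_drug_injection: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_internal_terms, self.n_genes, self.n_patients,
               self.n_drugs, self.branching, self.max_depth) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0,1]")
        if self.n_drugs + len(self.rare_drug_injection) > len(SMILES_PANEL):
            raise ValueError("drug count exceeds the packaged SMILES panel")


@dataclass
class GroundTruth:
    """The planted generating mechanism, kept for recovery tests."""

    baseline: float                       # mu
    pathway_weights: dict[str, float]     # leaf term -> w_p
    pathway_genes: dict[str, list[str]]   # leaf term -> member genes
    drug_effects: dict[str, float]        # drug name -> beta_d
    noise_sd: float
    log_months: dict[str, float] = dc_field(default_factory=dict)


def generate_toy_ontology(config: GeneratorConfig,
                          ) -> tuple[OntologyDAG, pd.DataFrame]:
    """Random rooted DAG plus a gene->term annotation table.

    Terms attach to a uniformly chosen existing parent of depth
    < max_depth (so depth is bounded); with probability
    ``multi_parent_prob`` a term gains a second parent. Genes are
    partitioned across the childless ("leaf") terms, every leaf getting at
    least one gene, so every term has an annotated descendant.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_internal_terms
    width = len(str(max(n - 1, 1)))
    term_ids = [f"T:{i:0{width}d}" for i in range(n)]
    root = term_ids[0]
    depth = {root: 0}
    child_edges: dict[str, list[str]] = {}
    n_children: dict[str, int] = {root: 0}
    for t in term_ids[1:]:
        candidates = [p for p in depth
                      if depth[p] < config.max_depth
                      and n_children[p] < config.branching]
        if not candidates:
            raise ValueError("infeasible generator config: branching "
                             f"{config.branching} x depth {config.max_depth} "
                             f"cannot host {n} terms")
        parent = candidates[rng.integers(len(candidates))]
        child_edges.setdefault(parent, []).append(t)
        n_children[parent] += 1
        n_children[t] = 0
        depth[t] = depth[parent] + 1
        if rng.random() < config.multi_parent_prob:
            others = [p for p in depth
                      if p not in (t, parent) and depth[p] < config.max_depth
                      and t not in child_edges.get(p, [])]
            if others:
                second = others[rng.integers(len(others))]
                child_edges.setdefault(second, []).append(t)

    leaves = [t for t in term_ids if not child_edges.get(t)]
    if config.n_genes < len(leaves):
        raise ValueError(f"n_genes ({config.n_genes}) must be >= number of "
                         f"leaf terms ({len(leaves)})")
    gwidth = len(str(config.n_genes - 1))
    genes = [f"G{i:0{gwidth}d}" for i in range(config.n_genes)]
    assignment = rng.integers(len(leaves), size=config.n_genes)
    # guarantee every leaf at least one gene
    for i, _ in enumerate(leaves):
        if not (assignment == i).any():
            assignment[rng.integers(config.n_genes)] = i
    # re-check (a reassignment could empty another leaf); loop until stable
    while True:
        empty = [i for i in range(len(leaves)) if not (assignment == i).any()]
        if not empty:
            break
        for i in empty:
            assignment[rng.integers(config.n_genes)] = i
    rows = [(g, leaves[a]) for g, a in zip(genes, assignment)]
    annotations = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    dag = _assemble(set(term_ids), child_edges,
                    {t: sorted(g for g, tt in rows if tt == t)
                     for t in leaves})
    return dag, annotations


def generate_cohort(dag: OntologyDAG, config: GeneratorConfig,
                    ) -> tuple[ExpressionMatrix, list[ClinicalRecord],
                               pd.DataFrame, GroundTruth]:
    """Generate expression, clinical records, a drug library and the truth.

    Returns the *raw* (unstandardized, FPKM-like nonnegative) expression
    matrix; the planted survival uses the standardized pathway means, so
    downstream standardization reproduces exactly the signal that was
    planted.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7_919]))
    pathways = {t: list(g) for t, g in dag.gene_annotations.items() if g}
    pathway_names = sorted(pathways)
    genes = dag.genes()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_pat, n_genes = config.n_patients, len(genes)
    pwidth = len(str(n_pat - 1))
    patients = [f"P{i:0{pwidth}d}" for i in range(n_pat)]

    # ---- expression: shared latent factor per (pathway, patient) ---------
    values = np.zeros((n_genes, n_pat))
    base = rng.uniform(2.0, 8.0, size=n_genes)        # FPKM-like offsets
    loading = rng.uniform(0.5, 1.5, size=n_genes)
    latent = {p: rng.normal(size=n_pat) for p in pathway_names}
    for p in pathway_names:
        for g in pathways[p]:
            i = gene_pos[g]
            values[i] = base[i] + loading[i] * (
                latent[p] + rng.normal(scale=config.gene_noise_sd,
                                       size=n_pat))
    values = np.maximum(values, 0.0)
    expr = ExpressionMatrix(genes, patients, values)

    # ---- planted survival ------------------------------------------------
    z = standardize_expression(expr)
    pathway_means = {p: z.values[[gene_pos[g] for g in pathways[p]], :]
                     .mean(axis=0) for p in pathway_names}
    w = rng.normal(scale=config.pathway_effect_sd, size=len(pathway_names))
    n_zero = int(round(config.zero_weight_fraction * len(pathway_names)))
    zero_idx = rng.choice(len(pathway_names), size=n_zero, replace=False)
    w[zero_idx] = 0.0
    pathway_weights = dict(zip(pathway_names, w))

    drug_names = [f"drug_{i:02d}" for i in range(config.n_drugs)]
    beta = dict(zip(drug_names,
                    rng.normal(scale=config.drug_effect_sd,
                               size=config.n_drugs)))
    drug_probs = rng.dirichlet(np.full(config.n_drugs, 5.0))
    assigned = [
        [drug_names[j]] for j in rng.choice(config.n_drugs, size=n_pat,
                                            p=drug_probs)]
    for i in range(n_pat):                       # tandem prescriptions
        if rng.random() < config.tandem_fraction:
            extra = drug_names[rng.integers(config.n_drugs)]
            if extra not in assigned[i]:
                assigned[i].append(extra)

    # injected rare drugs replace the prescriptions of `support` patients
    injected = []
    taken: set[int] = set()
    for j, support in enumerate(config.rare_drug_injection):
        name = f"rare_{j:02d}"
        injected.append(name)
        beta[name] = float(rng.normal(scale=config.drug_effect_sd))
        free = [i for i in range(n_pat) if i not in taken]
        chosen = rng.choice(free, size=support, replace=False)
        for i in chosen:
            assigned[i] = [name]
            taken.add(int(i))

    signal = np.full(n_pat, config.baseline_log_months)
    for p in pathway_names:
        signal += pathway_weights[p] * pathway_means[p]
    drug_term = np.array([np.mean([beta[d] for d in ds]) for ds in assigned])
    log_months = signal + drug_term + rng.normal(scale=config.noise_sd,
                                                 size=n_pat)

    # ---- censoring and clinical records ----------------------------------
    death_days = np.exp(log_months) * DAYS_PER_MONTH
    records: list[ClinicalRecord] = []
    for i, pid in enumerate(patients):
        if rng.random() < config.censoring_rate:
            followup = rng.uniform(0.0, death_days[i])
            records.append(ClinicalRecord(
                pid, VitalStatus.ALIVE_OR_CENSORED,
                days_to_last_followup=float(followup),
                drugs=tuple(assigned[i])))
        else:
            records.append(ClinicalRecord(
                pid, VitalStatus.DECEASED,
                days_to_death=float(death_days[i]),
                drugs=tuple(assigned[i])))

    all_drugs = drug_names + injected
    library = pd.DataFrame({"name": all_drugs,
                            "smiles": list(SMILES_PANEL[:len(all_drugs)])})
    truth = GroundTruth(
        baseline=config.baseline_log_months,
        pathway_weights=pathway_weights,
        pathway_genes={p: list(pathways[p]) for p in pathway_names},
        drug_effects=beta, noise_sd=config.noise_sd,
        log_months=dict(zip(patients, log_months.tolist())),
    )
    return expr, records, library, truth


# ---------------------------------------------------------------------------
# file emission (round-trips through the pipeline's readers)

def write_obo(dag: OntologyDAG, path: str) -> None:
    parents = dag.parents()
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for t in sorted(dag.terms):
            fh.write(f"[Term]\nid: {t}\nname: synthetic term {t}\n")
            for p in parents[t]:
                fh.write(f"is_a: {p} ! synthetic term {p}\n")
            fh.write("\n")


def write_inputs(outdir: str, dag: OntologyDAG, annotations: pd.DataFrame,
                 expr: ExpressionMatrix, records: list[ClinicalRecord],
                 library: pd.DataFrame) -> dict[str, str]:
    """Emit the five input files the pipeline consumes; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "obo": "ontology.obo", "annotations": "annotations.tsv",
        "expression": "expression.tsv", "clinical": "clinical.tsv",
        "drugs": "drugs.tsv"}.items()}
    write_obo(dag, paths["obo"])
    annotations.to_csv(paths["annotations"], sep="\t", header=False,
                       index=False)
    pd.DataFrame(expr.values, index=expr.gene_ids,
                 columns=expr.sample_ids).to_csv(paths["expression"],
                                                 sep="\t")
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "vital_status": r.vital_status.value,
            "days_to_death": "" if r.days_to_death is None
            else f"{r.days_to_death:.6f}",
            "days_to_last_followup": "" if r.days_to_last_followup is None
            else f"{r.days_to_last_followup:.6f}",
            "drugs": ";".join(r.drugs),
        })
    pd.DataFrame(rows).to_csv(paths["clinical"], sep="\t", index=False)
    library.to_csv(paths["drugs"], sep="\t", index=False)
    return paths
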