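import numpy as np
import pandas as pd
import pytest

from gosurv.chem import DrugRecord, smiles_to_fingerprint
from gosurv.cohort import (ClinicalRecord, ExpressionMatrix, VitalStatus,
                           standardize_expression)
from gosurv.ontology import OntologyDAG, annotate_and_prune, parse_obo
from gosurv.vnn import VNNConfig, build_model

TOY_OBO = """format-version: 1.2

[Term]
id: T:R
name: root

[Term]
id: T:A
name: alpha
is_a: T:R ! root

[Term]
id: T:B
name: beta
is_a: T:R ! root

[Term]
id: T:C
name: gamma
is_a: T:A ! alpha
is_a: T:B ! beta
"""


@pytest.fixture
def toy_obo(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return str(p)


@pytest.fixture
def toy_dag(toy_obo):
    """4 terms (root, two mid, one multi-parent leaf), 4 genes."""
    dag = parse_obo(toy_obo)
    ann = pd.DataFrame({"gene_id": ["g1", "g2", "g3", "g4"],
                        "term_id": ["T:A", "T:C", "T:C", "T:B"]})
    return annotate_and_prune(dag, ann, ["g1", "g2", "g3", "g4"])


@pytest.fixture
def tiny_model(toy_dag):
    """Small but fully real model over the toy DAG."""
    cfg = VNNConfig(k_term_neurons=3, drug_layer_sizes=(8, 4, 2),
                    n_bits=64, head_hidden=5, seed=7)
    return build_model(toy_dag, cfg, stage="stage2")


@pytest.fixture
def tiny_library():
    smiles = {"apixol": "CCO", "benzem": "c1ccccc1", "cyclor": "C1CCCCC1"}
    return {n: DrugRecord(n, s, smiles_to_fingerprint(s, n_bits=64))
            for n, s in smiles.items()}


@pytest.fixture
def small_expression():
    rng = np.random.default_rng(11)
    genes = ["g1", "g2", "g3", "g4"]
    samples = [f"P{i}" for i in range(6)]
    m = ExpressionMatrix(genes, samples,
                         rng.uniform(1.0, 9.0, size=(4, 6)))
    return standardize_expression(m)


def make_record(pid, status="deceased", death=None, follow=None, drugs=()):
    return ClinicalRecord(
        patient_id=pid,
        vital_status=VitalStatus(status),
        days_to_death=death,
        days_to_last_followup=follow,
        drugs=tuple(drugs),
    )
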