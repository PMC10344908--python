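"""In-silico optimal drug selection: score every retained library drug
for each held-out patient and summarize the predicted improvement.

The optimal drug D* is the argmax of predicted months over the library;
a patient has a "better alternative" when D* differs from the actual
prescription and its predicted survival exceeds the observed one.
"""

from gosurv.experiments import default_recovery_run
from gosurv.interpret import nearest_patients
from gosurv.synthetic import GeneratorConfig
from gosurv.train import TrainConfig

run = default_recovery_run(
    seed=7,
    gen=GeneratorConfig(n_internal_terms=15, n_genes=100, n_patients=600,
                        n_drugs=6, seed=7),
    tcfg=TrainConfig(max_epochs=30, patience=8, seed=7))

s = run["selection_summary"]
print(f"scanned {s.n_patients} held-out patients x "
      f"{len(run['library'])} drugs")
print(f"better alternative for {100 * s.fraction_with_better_alternative:.1f}%")
print(f"median months: observed {s.median_observed_months:.1f} -> "
      f"optimal {s.median_optimal_months:.1f}")
print(f">=5% relative improvement: "
      f"{100 * s.fraction_relative_improvement_ge_threshold:.1f}% of patients")
print(f"largest predicted fold change: {s.max_fold_change:.2f}x")

best = max(run["selection_results"],
           key=lambda r: r.relative_improvement or 0)
print(f"\ncase study — patient {best.patient_id}: prescribed "
      f"{best.prescribed_drug} (observed {best.observed_months:.1f} mo), "
      f"scan suggests {best.optimal_drug} "
      f"({best.predicted_optimal_months:.1f} mo predicted)")
# Patients with similar transcriptomes are where one would look for
# observational support of the suggested switch:
from gosurv.cohort import ExpressionMatrix  # noqa: E402
import numpy as np  # noqa: E402

val = {e.patient_id: e for e in run["stages"]["stage2"]["val"]}
ids = sorted(val)
expr = ExpressionMatrix(
    [f"g{i}" for i in range(len(val[ids[0]].expression))], ids,
    np.stack([val[p].expression for p in ids], axis=1))
peers = nearest_patients(expr, best.patient_id, n=5)
print("five most similar held-out patients (cosine similarity):")
print(peers.to_string(index=False))
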