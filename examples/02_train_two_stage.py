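"""Two-stage training with knowledge transfer on a small synthetic cohort.

Stage 1 pretrains a binary long-/short-lived classifier (censored
patients join through their follow-up lower bound); stage 2 re-uses the
pretrained encoders and fits exact log months-to-death on deceased
patients. Runs in about a minute.
"""

from gosurv.experiments import default_recovery_run
from gosurv.synthetic import GeneratorConfig
from gosurv.train import TrainConfig

run = default_recovery_run(
    seed=7,
    gen=GeneratorConfig(n_internal_terms=15, n_genes=100, n_patients=600,
                        n_drugs=6, seed=7),
    tcfg=TrainConfig(max_epochs=30, patience=8, seed=7))

s1, s2 = run["stage1"], run["stage2"]
print(f"stage 1: best validation accuracy {s1.best_metric:.3f} "
      f"at epoch {s1.best_epoch} of {len(s1.history)}")
print(f"stage 2: best held-out Pearson r {s2.best_metric:.3f} "
      f"at epoch {s2.best_epoch} of {len(s2.history)}")
# Accuracy near 0.9 and r near 0.9 mean the encoder recovered the planted
# pathway signal; the transfer means stage 2 started from the stage-1
# encoder weights rather than from scratch.
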