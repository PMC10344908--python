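# gosurv

Ontology-structured neural survival prediction from tumor transcriptomes
and prescribed drugs — with attention-based interpretation of the pathway
hierarchy and in-silico optimal-drug selection.

## The problem

Patients with the same cancer diagnosis respond very differently to the
same drug. Given a patient's transcriptome **T** and a prescribed drug's
chemical structure **D**, `gosurv` learns to predict the survival outcome
**S** from (T, D) pairs, so that, once trained, every library drug can be
scored *in silico* for a new patient and the one with the longest
predicted survival selected. The package is aimed at computational
biologists who want a fully synthetic, reproducible testbed for this
class of "visible" neural network: every input — ontology, annotations,
expression, clinical table, drug library — can be generated with planted
ground truth, so each architectural and statistical claim is testable
without any external download.

## The model

The expression encoder is a visible neural network wired like a Gene
Ontology DAG: genes are leaf inputs, each GO term is a block that takes
the concatenation of its children's states — scaled by softmax attention
weights `α_c` with `Σ_c α_c = 1` per parent — through a linear layer,
batch normalization and tanh into a k = 6 neuron state. The root state is
the expression embedding. A drug encoder (MLP, 2048 → 64 → 32 → 4) embeds
the Morgan fingerprint of the drug, and a head on the concatenated
embeddings (6 + 4 = 10) predicts either the binary long-/short-lived
status (stage 1) or log months-to-death (stage 2).

Training is two-stage with knowledge transfer: stage 1 pretrains on the
data-rich binary task — censored patients join through their follow-up
lower bound (alive after > 1200 days ⇒ long-lived; died within < 1000
days ⇒ short-lived) — and stage 2 initializes the encoders from the best
stage-1 checkpoint, then fine-tunes a fresh regression head on deceased
patients' exact log months-to-death. Drugs with fewer than five
supporting training pairs are removed (the rare-drug filter): a network
can only memorize, not generalize, a fingerprint it saw once or twice.
Attention weights above depth-banded cutoffs (> 0.05 near the root,
> 0.1 at depth 2, > 0.2 below) flag each patient's most discriminating
GO terms. Details: [docs/methods.md](docs/methods.md).

## Worked example

```python
from gosurv.synthetic import GeneratorConfig, generate_toy_ontology, generate_cohort
from gosurv.experiments import default_recovery_run
from gosurv.interpret import aggregate_attention, flag_discriminating_terms
from gosurv.vnn import forward_encoder

run = default_recovery_run(seed=1)   # generate, prepare, train both stages
print(f"stage-1 validation accuracy: {run['stage1_val_accuracy']:.3f}")
print(f"stage-2 held-out Pearson r:  {run['stage2_val_pearson_r']:.3f}")
s = run["selection_summary"]
print(f"better alternative drug for {100 * s.fraction_with_better_alternative:.1f}% "
      f"of {s.n_patients} held-out patients")
print(f"median months: observed {s.median_observed_months:.1f} -> "
      f"optimal {s.median_optimal_months:.1f}")
```

prints (seed 1, under a minute on one CPU core):

```
stage-1 validation accuracy: 0.911
stage-2 held-out Pearson r:  0.945
better alternative drug for 27.1% of 284 held-out patients
median months: observed 25.0 -> optimal 25.2
```

The first two numbers say the planted expression→survival signal was
recovered: 91% of held-out patients are correctly classified long- vs
short-lived, and predicted log months correlate 0.94 with the truth. The
last two summarize the in-silico drug scan of the held-out cohort: for
about a quarter of patients some library drug is predicted to beat the
prescription, which lifts the cohort's median survival when each patient
keeps the better of prescription and scanned optimum.

The same pipeline is scriptable from a shell:

```sh
gosurv simulate -c config.json   # write synthetic inputs
gosurv prepare  -c config.json   # cohorts, pairs, rare-drug filter
gosurv train    -c config.json   # stage-1 + stage-2 checkpoints
gosurv interpret -c config.json  # attention TSVs, discriminating terms
gosurv select   -c config.json   # per-patient drug scan + summary JSON
gosurv report   -c config.json   # one markdown summary
```

`examples/` holds short narrative scripts, one per capability.

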