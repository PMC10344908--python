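"""Generate a complete synthetic input set and inspect its structure.

Builds a random ontology DAG with planted pathways, a cohort whose
survival is a linear function of pathway mean expressions plus a drug
effect, and writes the five input files the pipeline consumes.
"""

from gosurv.cohort import VitalStatus
from gosurv.synthetic import (GeneratorConfig, generate_cohort,
                              generate_toy_ontology, write_inputs)

cfg = GeneratorConfig(n_internal_terms=12, n_genes=60, n_patients=300,
                      n_drugs=5, seed=7)
dag, annotations = generate_toy_ontology(cfg)
expr, records, library, truth = generate_cohort(dag, cfg)
paths = write_inputs("scratch/example_inputs", dag, annotations, expr,
                     records, library)

n_dead = sum(r.vital_status is VitalStatus.DECEASED for r in records)
active = {p: round(float(w), 3)
          for p, w in truth.pathway_weights.items() if w != 0}
print(f"ontology: {len(dag.terms)} terms, root {dag.root}, "
      f"{len(dag.genes())} annotated genes")
print(f"cohort:   {len(records)} patients, {n_dead} deceased "
      f"({1 - n_dead / len(records):.0%} censored), "
      f"{len(library)} drugs")
print(f"planted:  {len(active)} pathways with nonzero survival weight, "
      f"e.g. {next(iter(active.items()))}")
print("files:   ", ", ".join(sorted(paths.values())))
# The nonzero pathway weights are what a trained encoder must rediscover:
# genes under those terms carry the survival signal, the rest are noise.
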