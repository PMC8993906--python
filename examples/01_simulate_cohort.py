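"""Generate a synthetic SV cohort with known ground truth.

Per patient and 1 Mb bin, SV event counts follow a negative-binomial
log-linear model on eight genomic covariates; events are realized as
DEL/DUP/INV/BND calls with log-uniform sizes. The printed numbers are
the cohort size, the per-patient call burden, and the SV type mix —
the raw material every later stage consumes.
"""

from collections import Counter

import numpy as np

from svselect import GenomeDef, MESpec, SimParams, simulate_cohort

genome = GenomeDef.uniform(4, 50_000_000)
params = SimParams(
    genome=genome,
    n_patients=40,
    me=MESpec(mean_per_patient=20),
    seed=7,
)
cohort, truth = simulate_cohort(params)

per_patient = [len(cohort.calls[p]) for p in cohort.patients]
types = Counter(c.svtype for c in cohort.all_calls())
print(f"patients: {cohort.n_patients}, total SV calls: {cohort.n_calls}")
print(
    "calls per patient: median "
    f"{np.median(per_patient):.0f} (range {min(per_patient)}-{max(per_patient)})"
)
print("SV type mix:", dict(sorted(types.items())))
print(f"ME insertions simulated: {sum(len(v) for v in truth.insertions.values())}")
print(
    "Every call pairs two breakends; the type mix reflects the configured "
    "DEL/DUP/INV/BND proportions plus ME companion junctions (BND)."
)
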