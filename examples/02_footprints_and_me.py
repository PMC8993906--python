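"""Cluster SVs into footprints and annotate mobile-element junctions.

Two SVs of one tumour merge into a footprint when their nearest
breakend distance is below d* = -ln(alpha) G / (2 N); footprints are
simple (one SV), complex (several), or ME when they contain breakend
junctions coinciding with LINE-1 insertion sites.
"""

from collections import Counter

from svselect import (
    GenomeDef,
    MESpec,
    SimParams,
    annotate_me,
    classify_clusters,
    cluster_cohort,
    filter_polya,
    simulate_cohort,
    summarize_me,
)

genome = GenomeDef.uniform(4, 50_000_000)
params = SimParams(
    genome=genome, n_patients=40, me=MESpec(mean_per_patient=20), seed=7
)
cohort, truth = simulate_cohort(params)

insertions = {p: filter_polya(v) for p, v in truth.insertions.items()}
for pid in cohort.patients:
    annotate_me(cohort.calls[pid], insertions[pid])

clusters = cluster_cohort(cohort, genome, alpha=0.05)
for pid, cls in clusters.items():
    classify_clusters(cls, {c.call_id: c for c in cohort.calls[pid]})

classes = Counter(c.cls for per in clusters.values() for c in per)
print("footprint classes:", dict(sorted(classes.items())))

summary = summarize_me(insertions)
print(
    f"ME inserts per tumour: median {summary['median']:.0f} "
    f"(IQR {summary['iqr'][0]:.0f}-{summary['iqr'][1]:.0f})"
)
print("class shares:", summary["class_pct"])
print(
    "Simple footprints are isolated rearrangements; complex ones are "
    "clusters; ME footprints are set aside as retrotransposition, not "
    "rearrangement, before signature analysis."
)
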