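"""Count driver recurrence with and without SVs and test the increase.

A gene is SV-hit when the interval between a call's breakpoints
overlaps at least one exon of its canonical transcript. Adding SV hits
to prior SNV/indel/CN alterations raises recurrence; the one-sided
continuity-corrected two-proportion z-test asks whether significantly.
"""

import numpy as np
import pandas as pd

from svselect import (
    DriverSpec,
    GeneModel,
    GenomeDef,
    SimParams,
    format_percent,
    gene_hits,
    recurrence_test,
    simulate_cohort,
)
from svselect.drivers import spans_for_cohort, tally_recurrence

genome = GenomeDef.uniform(2, 50_000_000)
tsg = GeneModel(
    "TSG1", "T1", "chr1", "+",
    exons=[(10_000_000, 10_000_500), (10_100_000, 10_100_300)],
    cancer_gene=True,
)
cohort, truth = simulate_cohort(
    SimParams(
        genome=genome, n_patients=100, seed=5,
        drivers=[DriverSpec(gene=tsg, fraction=0.3)],
    )
)

hits = gene_hits(spans_for_cohort(cohort), [tsg])
rng = np.random.default_rng(5)
prior = pd.DataFrame(
    {"TSG1": rng.random(100) < 0.15}, index=cohort.patients
)  # SNV/indel/CN alterations from upstream callers

tallies = tally_recurrence(prior, hits, cohort.n_patients)
result = recurrence_test(tallies).iloc[0]
print(
    f"TSG1 recurrence: {format_percent(result['without_sv'], 100)} without SVs "
    f"-> {format_percent(result['with_sv'], 100)} with SVs "
    f"(z = {result['z']:.2f}, one-sided p = {result['p']:.2e})"
)
print(
    "The implanted exon-overlapping deletions (30% of patients) push "
    "recurrence well past the prior-alteration rate; a small p-value "
    "says the increase is larger than sampling noise allows."
)
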