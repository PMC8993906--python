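# Methods

This note documents the models, parameter choices, numerical details
and known limitations of svselect. It is the package's own account;
every empirical statement here is one the test suite or
`scripts/acceptance.py` computes at run time.

## Data model and conventions

Breakend positions and interval endpoints are 1-based closed
throughout the library; BED/BEDPE files are read and written as
0-based half-open at the boundary. Genomic bins are 0-based half-open
because the fixed-width/fixed-step tiling arithmetic is cleanest
there. Breakend orientation `+` means the segment to the left of the
junction is retained (the MANTA/BEDPE strand convention); on one
chromosome the orientation pair (+,−) is a deletion-type junction,
(−,+) duplication-type, (+,+)/(−,−) inversion-type, and any
inter-chromosomal junction is a BND. Intra-chromosomal calls are
normalized so the lower-position breakend comes first, with the
orientation pair ordered `+` before `-` at equal positions so
classification is invariant under swapping the input breakends.

Bin tiling: full-width bins start at every multiple of the step while
they fit; one truncated final bin is appended only when the chromosome
end would otherwise be uncovered, and a chromosome shorter than the
width becomes the single bin [0, L). This is the unique rule under
which every base is covered at least once and, with width = 2·step,
interior bases exactly twice, without emitting bins wholly contained
in their predecessor.

Callset equivalence (panel-of-normals filtering and precision/recall
matching) requires identical SV type and both breakends within the
window (default 300 bp), applied per breakend rather than to the
summed distance; matching is greedy by ascending summed distance with
ties broken by call id, which makes it deterministic.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline is built
to detect, not sequence-level realism (no nucleotides, no reads, no
empirical SV-type spectra).

* **Count layer.** Per patient and per non-overlapping 1 Mb tile, the
  number of SV events anchored in the tile is NB(μ_b, θ) with
  μ_b = exp(β·x_b) × hotspot multiplier and Var = μ + μ²/θ. The
  default dispersion θ = 2 gives visible overdispersion; the default
  β has intercept −4 (≈ 0.02 events/patient/Mb before covariates)
  with slopes between log 1.2 and log 2 — the order of magnitude of
  published genomic-context effects on breakpoint rates.
* **Covariates.** Two Bernoulli flags (fragile sites, prevalence 0.05;
  copy-number aberration, 0.10) and six continuous tracks built as
  logistic transforms of per-chromosome AR(1) standard-normal series
  (autocorrelation 0.8), so each lies in [0, 1], is smooth along the
  chromosome, and has generative mean 0.5.
* **Realization.** Each event's first breakend is uniform in its tile;
  the mate is placed by type — log-uniform size in [1 kb, 10 Mb] for
  intra-chromosomal calls (all catalogue size channels populated),
  uniform on another chromosome for BND. Mate breakends therefore
  spill into neighbouring tiles: the realized per-tile breakend counts
  are a locally smeared version of the count layer. Recovery studies
  that ask whether the NB regression recovers β therefore fit the
  count layer itself (the estimand is exact there); the realized-
  breakend path is exercised by the binning and hotspot tests.
* **Implants.** Driver specs deterministically alter the first
  ⌊fraction·n⌋ patients with an exon-overlapping call, so expected
  counts are exact in tests. ME insertions per patient are NB(60, 0.6)
  by default — median tens with an IQR spanning two orders of
  magnitude, as in real tumour cohorts — with class mix
  (solo, partnered, orphan) = (0.81, 0.07, 0.12), poly-A probability
  0.95, and a configurable fraction of insertions spawning a companion
  BND that shares the insertion site (transductions point at their
  source element).
* **Determinism.** One seeded generator stream in a fixed order;
  identical parameters give byte-identical BEDPE/TSV output.

What passing tests on this generator do **not** show: robustness to
caller artifacts (imprecise breakpoints, missed mates), to real
covariate collinearity, or to the fragile-site/amplicon bins whose
removal the artifact filters exist for — the generator contains no
such class unless implanted.

## Footprint clustering

Footprints are built by a simplified agglomeration in the spirit of
breakpoint-proximity clusterers used in cancer genomics: the nearest
inter-SV breakend distance is compared with
d\* = −ln(α)·G/(2N) — the lower-α quantile of the exponential
nearest-neighbour gap under uniform placement of the patient's N
breakends on a genome of length G — and merging is transitive
(union–find), so footprints partition the callset. α defaults to 0.05
and is configurable; lowering α shrinks d\* and can only split, never
merge. ME labelling follows the "contains" reading: a footprint with
at least one ME-annotated BND member is an ME footprint
(`me_rule="all"` is available), and ME takes precedence over the
simple/complex split because ME footprints are set aside before it.
The ME annotation window defaults to 0 bp (direct overlap) and is
configurable because insertion breakpoint resolution varies between
callers. IQRs are 25th/75th percentiles with linear interpolation.

## Signature extraction

NMF is authored in-package as Lee–Seung multiplicative updates on the
Frobenius objective (the objective is non-increasing per iteration and
asserted so in tests; scikit-learn's `mu` solver serves as an
independent cross-check of the attained objective, never as the
implementation). Defaults: 1000 iterations, 30 restarts per rank
(pipeline defaults are smaller), seeded per (k, restart) so runs are
reproducible. Rank selection combines two stability scores by mean
rank, ties to the smaller k:

* cophenetic correlation of the restart consensus matrix
  (co-assignment of patients to their dominant signature);
* silhouette of the exposure-argmax patient clustering measured in the
  32-channel catalogue-proportion space. The silhouette is computed in
  this k-independent frame deliberately: measured in each rank's own
  exposure space it is biased toward small k, because the rank-k
  projection makes merged clusters look tight.

W is returned column-stochastic with H rescaled. Reference matching is
greedy cosine without replacement, which is permutation-equivariant.
"Presence" of a signature in a tumour (the response of the feature
regressions) is exposure proportion ≥ 0.05, configurable — the
threshold is a package decision, as presence has no canonical
definition.

Feature associations: predictors are log(x+1)-transformed and
standardized; univariate logistic fits at p < 0.05 seed a multivariate
logistic model refined by bidirectional stepwise AIC from the full
candidate set, with BH q-values on the final coefficients. Complete
separation is detected before fitting (non-overlapping ranges) and
reported as a flag rather than a divergent estimate. Hold-out
validation refits the selected model on 80/60/40% training fractions
and reports per-coefficient sign consistency. Group comparisons use
the two-sided Wilcoxon rank-sum test, exact when the combined sample
is ≤ 50 without ties, normal approximation with tie correction
otherwise.

## Hotspot detection

The context model regresses per-bin recurrence (or total counts) on
the eight covariates as an NB2 GLM with MLE dispersion. Significance
follows the ≥ 2 SD rule on standardized Pearson residuals; residual
type and threshold are package choices where the source convention
names only "residuals". Numerical care: an NB2 fit whose dispersion
collapses to the boundary can report NaN confidence intervals while
claiming convergence — such fits are treated as failures, retried with
BFGS and Nelder–Mead, and finally replaced by a Poisson GLM with a
fallback flag on the fit record (appropriate, since boundary cases are
the near-equidispersed ones).

The focal scan removes fragile-flagged and high-density bins
(high-density = density above the 0.975 quantile, configurable; the
threshold is an artifact-filter choice, not a published constant),
then applies three methods to the retained bins: intercept-only NB
outliers genome-wide, the same per chromosome (chromosomes with < 5
retained bins are skipped and reported), and the rank-sum method —
per-patient ascending ranks with ties averaged, summed per bin, split
by 1-D k-means (k = 2, k-means++, fixed seed), higher-centroid cluster
flagged. Because a 2-means split of a unimodal rank-sum distribution
is degenerate, the method abstains when the higher cluster exceeds 20%
of bins; the guard applies only from 20 bins upward so that tiny
worked examples (where a single top bin is legitimately 25% of four)
behave as expected. The consensus requires ≥ 2 methods.

**Known limitation — the focal scan's false-flag floor.** The
genome-wide and per-chromosome NB methods are near-duplicate tests of
the same counts. Each flags the ≥ 2 SD upper tail of standardized
residuals, whose mass cannot fall below ≈ 2.3% even for perfectly
normal residuals (and is larger under NB right-skew); since the two
methods agree almost everywhere, the 2-of-3 consensus inherits a
null-bin flag rate of a few percent, which the validation study
measures (the rank-sum guard keeps the third method silent under the
null). Detection of implanted 10× bins is essentially certain at the
study's cohort sizes; the cost of the simple ≥ 2 SD rule is this
false-flag floor, and merged candidate regions should be read
accordingly — as candidates for inspection, not calibrated
discoveries. Enabling the high-density filter in the validation would
remove the implanted hotspot itself (it is, by construction, the
densest bin), so the studies run with the filter disabled; on real
data the filter targets fragile-site and amplicon artifact bins, a
class the generator does not produce.

## Driver recurrence

SV spans are the closed interval between the two breakpoints
(intra-chromosomal) or a ± window around each breakend (BND; default
0 bp, i.e. point loci, configurable for imprecise calls). Overlap is
any-overlap (≥ 1 bp) against canonical-transcript exons, matching the
exon-overlap counting rule; interval trees give the same answer as the
per-base membership oracle, which is asserted over hundreds of random
toys. The two-proportion z-test uses pooled variance with Yates
continuity correction (matching R's `prop.test`, verified against a
frozen value from it), one-sided "greater", then BH across genes. The
permutation overlap test places each query region uniformly at random
on its own chromosome, length preserved, and reports
p = (1 + #{perm ≥ obs}) / (n_perm + 1), so p is bounded below by
1/(n_perm + 1); uniform placement (rather than circular rotation) was
chosen as the null and is documented here as a package decision.

## Validation studies and their problem sizes

The studies behind `scripts/acceptance.py` use desk-scale conditions
chosen once: coefficient recovery at 2000 bins × 200 patients × 100
replicates on the generator's count layer; hotspot detection at 200
bins × 60 patients × 100 replicate pairs (null and 10×-implanted)
through the full realized-call path; signature recovery over 20
planted catalogues of 60 patients; calibration at 1000 null replicates
(two binomial proportions at n = 383; a logistic null at n = 400).
Each study reports exactly what it computes — coverage, sensitivity,
null flag rate, mean matched cosine, type-I rates — and the rank
selected on the first planted instance is reported informationally:
stability-based rank selection at these sizes occasionally prefers
k = 2 on a rank-3 catalogue, a genuine property of the procedure, not
of one seed.
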