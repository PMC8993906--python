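"""Breakpoint hotspot detection.

Per-bin breakpoint statistics (recurrence = patients with >= 1
breakpoint, density = mean breakpoints per patient), a negative-binomial
log-linear background model on genomic covariates whose standardized
Pearson-residual outliers (>= 2 SD) mark significantly recurrent bins,
and a three-method focal consensus on the artifact-filtered bins:
genome-wide NB outliers, per-chromosome NB outliers, and a per-patient
rank-sum statistic split by 1-D k-means. Bins found by at least two
methods form the focal consensus; adjacent flagged bins merge into
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import Bin, Cohort, Interval


@dataclass
class BinTable:
    """Per-bin per-patient breakpoint counts plus covariates and flags."""

    bins: list[Bin]
    patients: list[str]
    counts: np.ndarray  # bins x patients
    covariates: Optional[pd.DataFrame] = None
    fragile: np.ndarray = field(default=None)  # type: ignore[assignment]
    high_density: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.counts.shape != (n, len(self.patients)):
            raise ValueError("counts must be bins x patients")
        if self.fragile is None:
            self.fragile = np.zeros(n, dtype=bool)
        if self.high_density is None:
            self.high_density = np.zeros(n, dtype=bool)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def recurrence(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=1)

    @property
    def density(self) -> np.ndarray:
        return self.total / self.n_patients

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin": [b.index for b in self.bins],
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "total": self.total,
                "recurrence": self.recurrence,
                "density": self.density,
                "fragile": self.fragile,
                "high_density": self.high_density,
            }
        )
        return df.set_index("bin")


def bin_breakpoint_stats(
    cohort: Cohort,
    bins: Sequence[Bin],
    covariates: Optional[pd.DataFrame] = None,
    fragile_regions: Sequence[Interval] = (),
    density_quantile: float = 0.975,
    include_blacklisted: bool = False,
) -> BinTable:
    """Count every breakend of every (non-blacklisted) SV into its bins.

    A breakpoint is a single breakend position; with overlapping bins a
    position contributes to every bin containing it, but once per bin.
    Bins overlapping ``fragile_regions`` are flagged fragile; bins above
    the ``density_quantile`` of breakpoint density are flagged
    high-density (quantile 1.0 disables the flag).
    """
    bins = list(bins)
    n = len(bins)
    pidx = {p: i for i, p in enumerate(cohort.patients)}
    row = {b.index: i for i, b in enumerate(bins)}
    counts = np.zeros((n, len(cohort.patients)), dtype=np.int64)
    by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    starts = {c: np.array([b.start for b in bs]) for c, bs in by_chrom.items()}
    widths = {c: max(b.width for b in bs) for c, bs in by_chrom.items()}
    for call in cohort.all_calls():
        if call.blacklisted and not include_blacklisted:
            continue
        p = pidx[call.patient]
        for be in call.breakends():
            bs = by_chrom.get(be.chrom)
            if bs is None:
                continue
            st = starts[be.chrom]
            # candidate bins: start in (pos - width, pos]; check each
            lo = int(np.searchsorted(st, be.pos - widths[be.chrom], side="left"))
            hi = int(np.searchsorted(st, be.pos, side="left"))
            for b in bs[lo:hi]:
                if b.contains(be.pos):
                    counts[row[b.index], p] += 1
    fragile = np.array(
        [any(b.overlaps_interval(r) for r in fragile_regions if r.chrom == b.chrom)
         for b in bins]
    )
    table = BinTable(
        bins=bins,
        patients=list(cohort.patients),
        counts=counts,
        covariates=covariates,
        fragile=fragile,
    )
    if density_quantile < 1.0:
        dens = table.density
        cut = np.quantile(dens, density_quantile)
        table.high_density = dens > cut
    return table


# ---------------------------------------------------------------------------
# Negative-binomial fits


@dataclass
class NBFit:
    """A fitted NB (or fallback Poisson) background model for bin counts."""

    params: pd.Series
    alpha: float  # NB2 dispersion (Var = mu + alpha mu^2); 0 under Poisson
    fitted: np.ndarray
    resid_std: np.ndarray  # standardized Pearson residuals
    flags: np.ndarray  # resid_std >= threshold
    threshold: float
    converged: bool
    poisson_fallback: bool
    conf_int: Optional[pd.DataFrame] = None


def _fit_nb(y: np.ndarray, X: pd.DataFrame) -> tuple:
    """NB2 regression with MLE dispersion; Poisson fallback on failure."""
    import statsmodels.api as sm

    exog = sm.add_constant(X, has_constant="add")
    try:
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, exog)
            for kwargs in (
                {"method": "newton"},
                {"method": "bfgs", "maxiter": 500},
                {"method": "nm", "maxiter": 5000},
            ):
                try:
                    trial = model.fit(disp=0, **kwargs)
                    ok = (
                        trial.mle_retvals.get("converged", False)
                        and np.all(np.isfinite(trial.params))
                        and np.all(np.isfinite(trial.conf_int()))
                    )
                except Exception:
                    continue
                if ok:
                    res = trial
                    break
        if res is None:
            raise RuntimeError("NB fit did not converge")
        alpha = max(float(res.params["alpha"]), 0.0)
        params = res.params.drop("alpha")
        mu = np.exp(exog.to_numpy() @ params.to_numpy())
        ci = res.conf_int().drop(index="alpha")
        ci.columns = ["lo", "hi"]
        return params, alpha, mu, ci, True, False
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
        params = res.params
        mu = np.asarray(res.fittedvalues)
        ci = res.conf_int()
        ci.columns = ["lo", "hi"]
        return params, 0.0, mu, ci, True, True


def _residual_flags(
    y: np.ndarray, mu: np.ndarray, alpha: float, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    var = mu + alpha * mu**2
    var = np.maximum(var, 1e-12)
    pearson = (y - mu) / np.sqrt(var)
    sd = pearson.std(ddof=0)
    if sd < 1e-12:
        return np.zeros_like(pearson), np.zeros(len(pearson), dtype=bool)
    z = (pearson - pearson.mean()) / sd
    return z, z >= threshold


def fit_context_model(
    bintable: BinTable,
    response: str = "recurrence",
    threshold: float = 2.0,
    min_bins: int = 50,
) -> NBFit:
    """NB regression of per-bin breakpoint burden on genomic covariates.

    Response is recurrence (default) or total breakpoint count; the
    model is a log-link NB2 with MLE dispersion. Bins whose standardized
    Pearson residual is >= ``threshold`` SD above the residual mean are
    flagged as significantly recurrent. Falls back to Poisson (recorded
    on the fit) when the NB likelihood fails to converge.
    """
    if bintable.covariates is None:
        raise ValueError("context model requires per-bin covariates")
    if len(bintable.bins) < min_bins:
        raise ValueError(f"context model requires >= {min_bins} bins")
    y = getattr(bintable, response).astype(float)
    X = bintable.covariates
    params, alpha, mu, ci, converged, fallback = _fit_nb(y, X)
    z, flags = _residual_flags(y, mu, alpha, threshold)
    return NBFit(
        params=params,
        alpha=alpha,
        fitted=mu,
        resid_std=z,
        flags=flags,
        threshold=threshold,
        converged=converged,
        poisson_fallback=fallback,
        conf_int=ci,
    )


def _intercept_outliers(y: np.ndarray, threshold: float) -> np.ndarray:
    """Intercept-only NB outlier flags on a count vector."""
    if len(y) == 0 or y.min() == y.max():
        return np.zeros(len(y), dtype=bool)
    X = pd.DataFrame(index=range(len(y)))
    _, alpha, mu, _, _, _ = _fit_nb(y, X)
    _, flags = _residual_flags(y, mu, alpha, threshold)
    return flags


def ranksum_kmeans(
    per_patient_counts: np.ndarray,
    seed: int = 0,
    guard_frac: float = 0.2,
    guard_min_bins: int = 20,
) -> np.ndarray:
    """Rank-sum hotspot flags: rank bins within each patient, sum, split.

    Counts are ranked ascending within each patient (average ranks for
    ties), summed across patients per bin, and the rank sums split by
    1-D k-means with k = 2 (k-means++, fixed seed); bins in the
    higher-centroid cluster are flagged. When all rank sums coincide no
    bin is flagged; when the bin set is large (>= ``guard_min_bins``)
    and the higher cluster holds more than ``guard_frac`` of bins the
    split is considered degenerate and nothing is flagged.
    """
    from sklearn.cluster import KMeans

    counts = np.asarray(per_patient_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a bins x patients matrix with >= 2 bins")
    ranks = np.apply_along_axis(rankdata, 0, counts)
    rank_sums = ranks.sum(axis=1)
    if np.allclose(rank_sums, rank_sums[0]):
        return np.zeros(len(rank_sums), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tied rank sums duplicate points
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(
            rank_sums.reshape(-1, 1)
        )
    hi_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    flags = km.labels_ == hi_cluster
    if len(rank_sums) >= guard_min_bins and flags.mean() > guard_frac:
        return np.zeros(len(rank_sums), dtype=bool)
    return flags


def focal_hotspots(
    bintable: BinTable,
    threshold: float = 2.0,
    min_bins_per_chrom: int = 5,
    seed: int = 0,
    guard_frac: float = 0.2,
    guard_min_bins: int = 20,
) -> pd.DataFrame:
    """Three-method focal hotspot consensus on artifact-filtered bins.

    Fragile and high-density bins are removed first. On the retained
    bins: (1) intercept-only NB on total counts genome-wide, outliers at
    >= ``threshold`` SD standardized Pearson residual; (2) the same fit
    per chromosome (chromosomes with < ``min_bins_per_chrom`` retained
    bins are skipped and reported); (3) the per-patient rank-sum k-means
    method. A bin enters the focal consensus when flagged by >= 2
    methods. Returns one row per retained bin with per-method flags.
    """
    keep = ~(bintable.fragile | bintable.high_density)
    kept = np.flatnonzero(keep)
    bins = [bintable.bins[i] for i in kept]
    total = bintable.total[kept]
    counts = bintable.counts[kept]
    m_genome = _intercept_outliers(total, threshold)
    m_chrom = np.zeros(len(kept), dtype=bool)
    skipped: list[str] = []
    chroms = np.array([b.chrom for b in bins])
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) < min_bins_per_chrom:
            skipped.append(chrom)
            continue
        m_chrom[sel] = _intercept_outliers(total[sel], threshold)
    if len(bins) >= 2:
        m_rank = ranksum_kmeans(
            counts, seed=seed, guard_frac=guard_frac, guard_min_bins=guard_min_bins
        )
    else:
        m_rank = np.zeros(len(bins), dtype=bool)
    votes = m_genome.astype(int) + m_chrom.astype(int) + m_rank.astype(int)
    df = pd.DataFrame(
        {
            "bin": [b.index for b in bins],
            "chrom": chroms,
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "total": total,
            "genomewide": m_genome,
            "perchrom": m_chrom,
            "ranksum": m_rank,
            "consensus": votes >= 2,
        }
    ).set_index("bin")
    df.attrs["skipped_chromosomes"] = skipped
    return df


def merge_bins_to_regions(flagged_bins: Sequence[Bin]) -> list[Interval]:
    """Merge overlapping or bookended flagged bins into regions.

    Returns 1-based closed region intervals named region1, region2, ...
    in (chromosome, start) order.
    """
    by_chrom: dict[str, list[Bin]] = {}
    for b in flagged_bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    regions: list[Interval] = []
    rid = 0
    for chrom in sorted(by_chrom):
        bs = sorted(by_chrom[chrom], key=lambda b: b.start)
        cur_s, cur_e = bs[0].start, bs[0].end
        for b in bs[1:]:
            if b.start <= cur_e:  # overlap or bookended (half-open)
                cur_e = max(cur_e, b.end)
            else:
                rid += 1
                regions.append(Interval(chrom, cur_s + 1, cur_e, f"region{rid}"))
                cur_s, cur_e = b.start, b.end
        rid += 1
        regions.append(Interval(chrom, cur_s + 1, cur_e, f"region{rid}"))
    return regions
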