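"""Driver-gene recurrence from SV spans and region overlap analyses.

An SV's genomic span is the interval between its two breakpoints
(intra-chromosomal) or a window at each breakend (inter-chromosomal); a
patient "hits" a gene when any span intersects at least one exon of the
gene's canonical transcript. Recurrence with SVs added is compared to
recurrence from SNV/indel/copy-number alone by a one-sided
continuity-corrected two-proportion z-test with Benjamini-Hochberg
correction across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import norm

from .core import Cohort, FootprintCluster, GeneModel, GenomeDef, Interval, SVCall


@dataclass(frozen=True)
class SVSpan:
    """Genomic footprint of one SV: one interval, or two for BNDs."""

    call_id: str
    intervals: tuple[Interval, ...]


def sv_spans(call: SVCall, bnd_window_bp: int = 0) -> SVSpan:
    """The genomic region(s) between/around a call's breakpoints.

    Intra-chromosomal: the single closed interval from the lower to the
    higher breakend. BND: one interval of +/- ``bnd_window_bp`` around
    each breakend (a 1-bp point interval when the window is 0).
    """
    if call.is_intra:
        return SVSpan(
            call.call_id,
            (Interval(call.a.chrom, call.a.pos, call.b.pos, call.call_id),),
        )
    ivs = tuple(
        Interval(be.chrom, max(1, be.pos - bnd_window_bp), be.pos + bnd_window_bp,
                 call.call_id)
        for be in call.breakends()
    )
    return SVSpan(call.call_id, ivs)


def _exon_trees(gene_models: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        t = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            t.addi(s, e + 1, g.symbol)  # closed -> half-open
    return trees


def gene_hits(
    spans_by_patient: dict[str, Sequence[SVSpan]],
    gene_models: Sequence[GeneModel],
) -> pd.DataFrame:
    """Patient x gene boolean table: does any span intersect >= 1 exon?"""
    trees = _exon_trees(gene_models)
    patients = list(spans_by_patient)
    genes = [g.symbol for g in gene_models]
    hits = pd.DataFrame(False, index=patients, columns=genes)
    for pid, spans in spans_by_patient.items():
        for span in spans:
            for iv in span.intervals:
                t = trees.get(iv.chrom)
                if t is None:
                    continue
                for hit in t.overlap(iv.start, iv.end + 1):
                    hits.loc[pid, hit.data] = True
    return hits


def spans_for_cohort(
    cohort: Cohort, bnd_window_bp: int = 0, svtypes: Optional[set[str]] = None
) -> dict[str, list[SVSpan]]:
    """Per-patient spans for all (optionally type-filtered) calls."""
    out: dict[str, list[SVSpan]] = {}
    for pid in cohort.patients:
        out[pid] = [
            sv_spans(c, bnd_window_bp)
            for c in cohort.calls[pid]
            if not c.blacklisted and (svtypes is None or c.svtype in svtypes)
        ]
    return out


# ---------------------------------------------------------------------------
# Recurrence testing


def two_proportion_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alternative: str = "greater",
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-proportion z-test (pooled variance, optional Yates correction).

    Tests H1: p1 > p2 (``greater``), p1 < p2 (``less``) or p1 != p2
    (``two-sided``); matches R's prop.test conventions. Returns (z, p).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0 if alternative != "two-sided" else 1.0
    diff = p1 - p2
    cc = min(0.5 * (1 / n1 + 1 / n2), abs(diff)) if continuity else 0.0
    if alternative == "greater":
        z = (diff - cc) / se
        p = float(norm.sf(z))
    elif alternative == "less":
        z = (diff + cc) / se
        p = float(norm.cdf(z))
    elif alternative == "two-sided":
        z = (abs(diff) - cc) / se
        p = float(2 * norm.sf(abs(z)))
        p = min(p, 1.0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return z, p


@dataclass
class DriverTally:
    """Per-gene patient recurrence with and without SVs."""

    gene: str
    without_sv: int
    with_sv: int
    cohort_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.without_sv <= self.with_sv <= self.cohort_size:
            raise ValueError(
                f"{self.gene}: need 0 <= without <= with <= cohort size"
            )


def tally_recurrence(
    prior_alterations: pd.DataFrame,
    hits: pd.DataFrame,
    cohort_size: int,
) -> list[DriverTally]:
    """Combine a prior alteration table (patient x gene, truthy = altered
    by SNV/indel/CN) with SV exon hits into per-gene tallies."""
    tallies = []
    for gene in prior_alterations.columns:
        prior = prior_alterations[gene].astype(bool)
        sv = hits[gene].reindex(prior.index, fill_value=False).astype(bool) \
            if gene in hits.columns else pd.Series(False, index=prior.index)
        tallies.append(
            DriverTally(
                gene=gene,
                without_sv=int(prior.sum()),
                with_sv=int((prior | sv).sum()),
                cohort_size=cohort_size,
            )
        )
    return tallies


def recurrence_test(
    tallies: Sequence[DriverTally], continuity: bool = True
) -> pd.DataFrame:
    """One-sided (greater) two-proportion test per gene, BH across genes."""
    from statsmodels.stats.multitest import multipletests

    if not tallies:
        return pd.DataFrame(
            columns=["gene", "without_sv", "with_sv", "cohort_size", "z", "p", "q"]
        )
    rows = []
    for t in tallies:
        if t.cohort_size == 0:
            raise ValueError("cohort size must be positive")
        z, p = two_proportion_test(
            t.with_sv, t.cohort_size, t.without_sv, t.cohort_size,
            alternative="greater", continuity=continuity,
        )
        rows.append(
            dict(
                gene=t.gene,
                without_sv=t.without_sv,
                with_sv=t.with_sv,
                cohort_size=t.cohort_size,
                z=z,
                p=p,
            )
        )
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Candidate driver narrowing and locus analyses


def candidate_driver_filter(
    regions: Sequence[Interval],
    gene_models: Sequence[GeneModel],
    fragile_sites: Sequence[Interval],
    spans_by_patient: dict[str, Sequence[SVSpan]],
) -> list[str]:
    """Narrow hotspot regions to cancer-gene candidates hit by SVs.

    Keeps genes whose exons intersect a region, that carry the
    cancer-gene flag, that do not overlap a fragile site, and that are
    actually hit (exon-overlapping span in >= 1 patient) — a hotspot may
    contain a cancer gene that no SV directly touches.
    """
    in_region = []
    for g in gene_models:
        if not g.cancer_gene:
            continue
        if any(g.span().overlaps(f) for f in fragile_sites):
            continue
        exon_ivs = [Interval(g.chrom, s, e) for s, e in g.exons]
        if any(iv.overlaps(r) for iv in exon_ivs for r in regions):
            in_region.append(g)
    if not in_region:
        return []
    hits = gene_hits(spans_by_patient, in_region)
    return [g.symbol for g in in_region if hits[g.symbol].any()]


def gene_sv_profile(
    gene: GeneModel,
    cohort: Cohort,
    clusters_by_patient: dict[str, list[FootprintCluster]],
    bnd_window_bp: int = 0,
) -> pd.DataFrame:
    """Per-patient tallies of exon-overlapping SVs by footprint class and type.

    Rows are (patient, class, svtype) with the count of that patient's
    exon-overlapping calls in footprints of that class; patients with no
    overlap contribute no rows.
    """
    class_by_call: dict[tuple[str, str], str] = {}
    for pid, clusters in clusters_by_patient.items():
        for cl in clusters:
            for mid in cl.member_ids:
                class_by_call[(pid, mid)] = cl.cls or "simple"
    exon_ivs = [Interval(gene.chrom, s, e) for s, e in gene.exons]
    rows: dict[tuple[str, str, str], int] = {}
    for call in cohort.all_calls():
        if call.blacklisted:
            continue
        span = sv_spans(call, bnd_window_bp)
        if not any(iv.overlaps(ex) for iv in span.intervals for ex in exon_ivs):
            continue
        cls = class_by_call.get((call.patient, call.call_id), "simple")
        key = (call.patient, cls, call.svtype)
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [
            {"patient": p, "cls": c, "svtype": t, "n": n}
            for (p, c, t), n in sorted(rows.items())
        ],
        columns=["patient", "cls", "svtype", "n"],
    )


def rs_group_bin_enrichment(
    bintable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_diff: float = 0.15,
) -> pd.DataFrame:
    """Bins hit more frequently in one signature group than another.

    Per non-fragile bin, freq = fraction of the group's patients with
    >= 1 breakpoint; bins with freq_a - freq_b >= ``min_diff`` are
    returned with both frequencies.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both patient groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("patient groups must be disjoint")
    pidx = {p: i for i, p in enumerate(bintable.patients)}
    ia = [pidx[p] for p in group_a]
    ib = [pidx[p] for p in group_b]
    hit = bintable.counts > 0
    freq_a = hit[:, ia].mean(axis=1)
    freq_b = hit[:, ib].mean(axis=1)
    diff = freq_a - freq_b
    sel = (diff >= min_diff) & ~bintable.fragile
    rows = [
        dict(
            bin=b.index,
            chrom=b.chrom,
            start=b.start,
            end=b.end,
            freq_a=freq_a[i],
            freq_b=freq_b[i],
            diff=diff[i],
        )
        for i, b in enumerate(bintable.bins)
        if sel[i]
    ]
    return pd.DataFrame(
        rows, columns=["bin", "chrom", "start", "end", "freq_a", "freq_b", "diff"]
    )


def locus_feature_overlap(
    deletion_spans_by_patient: dict[str, Sequence[SVSpan]],
    locus_features: Sequence[Interval],
) -> pd.DataFrame:
    """Distinct-patient counts per named locus feature.

    A patient counts toward a feature when any deletion span intersects
    it; a patient may count toward several features.
    """
    rows = []
    for feat in locus_features:
        patients = set()
        for pid, spans in deletion_spans_by_patient.items():
            if any(iv.overlaps(feat) for span in spans for iv in span.intervals):
                patients.add(pid)
        rows.append(dict(feature=feat.name, n_patients=len(patients)))
    return pd.DataFrame(rows, columns=["feature", "n_patients"])


# ---------------------------------------------------------------------------
# Region permutation test


def _merged_target_arrays(
    targets: Sequence[Interval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[Interval]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda v: v.start)
        merged = [[ivs[0].start, ivs[0].end]]
        for v in ivs[1:]:
            if v.start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], v.end)
            else:
                merged.append([v.start, v.end])
        arr = np.array(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def _overlaps_any(
    starts: np.ndarray, ends: np.ndarray, q_start, q_end
) -> np.ndarray:
    """Vectorized: does [q_start, q_end] overlap any sorted merged target?"""
    idx = np.searchsorted(starts, np.atleast_1d(q_end), side="right")
    ok = idx > 0
    prev_end = np.where(ok, ends[np.maximum(idx - 1, 0)], 0)
    return ok & (prev_end >= np.atleast_1d(q_start))


def permutation_overlap_test(
    query_regions: Sequence[Interval],
    target_regions: Sequence[Interval],
    genome: GenomeDef,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Empirical enrichment of query regions in target regions.

    Statistic: number of query regions overlapping >= 1 target. Null:
    each query region independently re-placed uniformly (length
    preserved) on its own chromosome. p = (1 + #{perm >= observed}) /
    (n_perm + 1); also reports the observed and null-expected overlap
    counts.
    """
    for q in query_regions:
        if q.length > genome.lengths[q.chrom]:
            raise ValueError(f"region {q} longer than its chromosome")
    tgt = _merged_target_arrays(target_regions)
    rng = np.random.default_rng(seed)

    def count_hits(starts_ends: Sequence[tuple[str, int, int]]) -> int:
        hits = 0
        for chrom, s, e in starts_ends:
            if chrom in tgt and bool(_overlaps_any(*tgt[chrom], s, e)[0]):
                hits += 1
        return hits

    observed = count_hits([(q.chrom, q.start, q.end) for q in query_regions])
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    for q in query_regions:
        L = genome.lengths[q.chrom]
        qlen = q.length
        starts = rng.integers(1, L - qlen + 2, size=n_perm)
        if q.chrom in tgt:
            hit = _overlaps_any(*tgt[q.chrom], starts, starts + qlen - 1)
            # note: _overlaps_any broadcasts on the query side
            perm_counts += hit.astype(np.int64)
    p = float((1 + int((perm_counts >= observed).sum())) / (n_perm + 1))
    return {
        "observed": observed,
        "expected": float(perm_counts.mean()),
        "p": p,
        "n_perm": n_perm,
    }
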