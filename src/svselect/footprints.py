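"""SV footprint clustering and mobile-element annotation.

Each tumour's SVs are agglomerated into footprints: two SVs merge when
their nearest same-chromosome breakend distance is smaller than
expected under uniform breakpoint placement, d* = -ln(alpha) * G /
(2 * N_bp), where G is the genome length and N_bp the patient's total
breakend count. Merging is transitive, so footprints partition the
callset. Singleton footprints are "simple", multi-member ones
"complex"; footprints containing breakend junctions that coincide with
mobile-element insertions are set aside as "ME".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import (
    Cohort,
    FootprintCluster,
    GenomeDef,
    Interval,
    MEInsertion,
    SVCall,
)
from .report import format_percent


def _sv_distance(a: SVCall, b: SVCall) -> float:
    """Nearest same-chromosome breakend distance between two SVs."""
    best = math.inf
    for x in a.breakends():
        for y in b.breakends():
            if x.chrom == y.chrom:
                best = min(best, abs(x.pos - y.pos))
    return best


def merge_threshold(genome_length: int, n_breakends: int, alpha: float) -> float:
    """Distance below which a nearest-neighbour gap is unexpectedly small.

    Under uniform placement of N_bp breakends on a genome of length G the
    nearest inter-SV gap is ~exponential with mean G / N_bp; a gap in its
    lower alpha tail, relative to the two-sided neighbour rate, is
    d* = -ln(alpha) * G / (2 * N_bp).
    """
    if n_breakends <= 0:
        return 0.0
    return -math.log(alpha) * genome_length / (2 * n_breakends)


def cluster_footprints(
    patient_calls: Sequence[SVCall],
    genome: GenomeDef,
    alpha: float = 0.05,
) -> list[FootprintCluster]:
    """Partition one patient's SVs into footprints by transitive merging."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    calls = list(patient_calls)
    if not calls:
        return []
    patients = {c.patient for c in calls}
    if len(patients) > 1:
        raise ValueError("cluster_footprints operates on one patient at a time")
    n_bp = 2 * len(calls)
    d_star = merge_threshold(genome.total_length, n_bp, alpha)

    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if _sv_distance(calls[i], calls[j]) < d_star:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(i)

    clusters: list[FootprintCluster] = []
    patient = calls[0].patient
    for cid, (_, members) in enumerate(sorted(groups.items()), start=1):
        spans: dict[str, tuple[int, int]] = {}
        type_counts: dict[str, int] = {}
        for i in members:
            c = calls[i]
            c.cluster_id = cid
            type_counts[c.svtype] = type_counts.get(c.svtype, 0) + 1
            for be in c.breakends():
                lo, hi = spans.get(be.chrom, (be.pos, be.pos))
                spans[be.chrom] = (min(lo, be.pos), max(hi, be.pos))
        clusters.append(
            FootprintCluster(
                patient=patient,
                cluster_id=cid,
                member_ids=[calls[i].call_id for i in members],
                spans=spans,
                svtype_counts=type_counts,
            )
        )
    return clusters


def cluster_cohort(
    cohort: Cohort, genome: GenomeDef, alpha: float = 0.05
) -> dict[str, list[FootprintCluster]]:
    """Footprint-cluster every patient; keeps calls' cluster ids in sync."""
    return {
        pid: cluster_footprints(cohort.calls[pid], genome, alpha)
        for pid in cohort.patients
    }


def classify_clusters(
    clusters: Sequence[FootprintCluster],
    calls_by_id: dict[str, SVCall],
    me_rule: str = "any",
) -> list[FootprintCluster]:
    """Set each cluster's class: ME, else simple (1 member) / complex (>= 2).

    A cluster is an ME-transduction footprint when it contains
    ME-annotated BNDs — with ``me_rule="any"`` one such member suffices;
    ``"all"`` requires every member to be an ME-annotated BND. ME takes
    precedence: those footprints are set aside before the simple/complex
    split.
    """
    if me_rule not in ("any", "all"):
        raise ValueError("me_rule must be 'any' or 'all'")
    for cl in clusters:
        members = [calls_by_id[i] for i in cl.member_ids]
        me_bnd = [m.svtype == "BND" and m.me_flag for m in members]
        if (me_rule == "any" and any(me_bnd)) or (
            me_rule == "all" and members and all(me_bnd)
        ):
            cl.cls = "ME"
        elif len(members) == 1:
            cl.cls = "simple"
        else:
            cl.cls = "complex"
    return list(clusters)


# ---------------------------------------------------------------------------
# ME annotation


def _build_point_tree(
    insertions: Iterable[MEInsertion], window_bp: int
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for ins in insertions:
        trees.setdefault(ins.chrom, IntervalTree()).addi(
            ins.pos - window_bp, ins.pos + window_bp + 1
        )
    return trees


def _build_region_tree(regions: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1)
    return trees


def _hits(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    t = trees.get(chrom)
    return bool(t and t.overlaps_point(pos))


def annotate_me(
    calls: Sequence[SVCall],
    insertions: Sequence[MEInsertion],
    transduction_regions: Sequence[Interval] = (),
    window_bp: int = 0,
) -> list[SVCall]:
    """Flag BNDs whose breakends coincide with ME insertions.

    A BND is flagged iff either breakend lies within ``window_bp`` of an
    insertion site or inside a known LINE-1 transduction source region.
    Non-BND calls are never flagged. Insertions should already be
    poly-A filtered (see :func:`svselect.simulate.filter_polya`).
    Idempotent and independent of list order.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    ins_trees = _build_point_tree(insertions, window_bp)
    src_trees = _build_region_tree(transduction_regions)
    for c in calls:
        if c.svtype != "BND":
            c.me_flag = False
            continue
        c.me_flag = any(
            _hits(ins_trees, be.chrom, be.pos) or _hits(src_trees, be.chrom, be.pos)
            for be in c.breakends()
        )
    return list(calls)


@dataclass(frozen=True)
class MEOverlap:
    """Cluster/ME overlap tallies for one signature group's footprints."""

    n_clusters: int
    n_insertion_overlap: int
    n_source_only: int
    frac_insertion: Optional[float]
    frac_source_only: Optional[float]


def me_cluster_overlap(
    clusters: Sequence[FootprintCluster],
    calls_by_id: dict[str, SVCall],
    insertions: Sequence[MEInsertion],
    transduction_regions: Sequence[Interval] = (),
    window_bp: int = 0,
) -> MEOverlap:
    """Count clusters whose breakends touch ME insertions or source regions.

    Each cluster counts once; direct insertion overlap takes precedence
    over source-region-only overlap. Fractions are None (not 0) for an
    empty cluster set.
    """
    ins_trees = _build_point_tree(insertions, window_bp)
    src_trees = _build_region_tree(transduction_regions)
    n_ins = 0
    n_src = 0
    for cl in clusters:
        hit_ins = False
        hit_src = False
        for mid in cl.member_ids:
            for be in calls_by_id[mid].breakends():
                if _hits(ins_trees, be.chrom, be.pos):
                    hit_ins = True
                    break
                if _hits(src_trees, be.chrom, be.pos):
                    hit_src = True
            if hit_ins:
                break
        if hit_ins:
            n_ins += 1
        elif hit_src:
            n_src += 1
    n = len(clusters)
    return MEOverlap(
        n_clusters=n,
        n_insertion_overlap=n_ins,
        n_source_only=n_src,
        frac_insertion=n_ins / n if n else None,
        frac_source_only=n_src / n if n else None,
    )


def summarize_me(
    insertions_by_patient: dict[str, list[MEInsertion]]
) -> dict:
    """Per-tumour burden and class/source composition of ME insertions.

    Returns the median and IQR (25th/75th percentiles, linear
    interpolation) of per-patient insert counts, plus class and source
    tallies with shares rendered as printed percentages of the grand
    total.
    """
    counts = np.array([len(v) for v in insertions_by_patient.values()])
    result: dict = {"n_patients": len(counts)}
    if len(counts):
        result["median"] = float(np.median(counts))
        result["iqr"] = (
            float(np.percentile(counts, 25)),
            float(np.percentile(counts, 75)),
        )
    else:
        result["median"] = None
        result["iqr"] = None
    all_ins = [i for v in insertions_by_patient.values() for i in v]
    total = len(all_ins)
    result["total"] = total
    class_counts = {c: 0 for c in ("solo", "partnered", "orphan")}
    source_counts = {s: 0 for s in ("germline", "somatic", "unknown")}
    for i in all_ins:
        class_counts[i.me_class] += 1
        source_counts[i.source] += 1
    result["class_counts"] = class_counts
    result["source_counts"] = source_counts
    if total:
        result["class_pct"] = {
            c: format_percent(n, total) for c, n in class_counts.items()
        }
        result["source_pct"] = {
            s: format_percent(n, total) for s, n in source_counts.items()
        }
    return result
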