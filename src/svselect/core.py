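"""Core genomic data model shared by every pipeline stage.

Coordinate conventions: breakend positions and interval endpoints are
1-based and closed everywhere inside the package; 0-based half-open
coordinates appear only at the BED/BEDPE file boundary. Genomic bins are
the one exception — they are stored 0-based half-open because the tiling
arithmetic (fixed width and step) is cleanest in that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

SV_TYPES = ("DEL", "DUP", "INV", "BND")

#: breakend orientation: "+" means the segment to the left of the junction
#: is the one retained (MANTA/BEDPE strand convention).
ORIENTATIONS = ("+", "-")


@dataclass(frozen=True)
class Interval:
    """A 1-based closed genomic interval, optionally named."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeDef:
    """Reference frame: ordered chromosomes, lengths, optional excluded regions.

    Excluded regions (typically centromeres/telomeres) are 1-based closed
    intervals that must lie within their chromosome.
    """

    names: list[str]
    lengths: dict[str, int]
    excluded: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        for name in self.names:
            if name not in self.lengths:
                raise ValueError(f"no length given for chromosome {name}")
            if self.lengths[name] <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for iv in self.excluded:
            if iv.chrom not in self.lengths:
                raise ValueError(f"excluded region on unknown chromosome {iv.chrom}")
            if iv.start < 1 or iv.end > self.lengths[iv.chrom]:
                raise ValueError(
                    f"excluded region {iv} outside chromosome {iv.chrom}"
                )

    @property
    def total_length(self) -> int:
        return sum(self.lengths[c] for c in self.names)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.lengths

    def is_excluded(self, chrom: str, pos: int) -> bool:
        return any(iv.contains_point(chrom, pos) for iv in self.excluded)

    @classmethod
    def uniform(
        cls, n_chroms: int, length: int, prefix: str = "chr"
    ) -> "GenomeDef":
        names = [f"{prefix}{i + 1}" for i in range(n_chroms)]
        return cls(names=names, lengths={n: length for n in names})


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    orient: str

    def __post_init__(self) -> None:
        if self.orient not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.pos < 1:
            raise ValueError("breakend position must be >= 1")


def classify_sv_type(a: Breakend, b: Breakend) -> str:
    """Classify a junction by the simplest rearrangement generating it.

    Different chromosomes -> BND (translocation-type junction). On one
    chromosome, with the breakends ordered by position: (+,-) is a
    deletion-type junction, (-,+) a tandem-duplication-type junction, and
    (+,+)/(-,-) inversion-type.
    """
    if a.chrom != b.chrom:
        return "BND"
    if (a.pos, a.orient) > (b.pos, b.orient):  # "+" sorts before "-"
        a, b = b, a
    key = (a.orient, b.orient)
    if key == ("+", "-"):
        return "DEL"
    if key == ("-", "+"):
        return "DUP"
    return "INV"


@dataclass
class SVCall:
    """One structural variant: a pair of breakends with a type and owner.

    Intra-chromosomal calls are normalized so breakend A is the one with
    the smaller position; ``svtype`` is BND iff the chromosomes differ.
    """

    call_id: str
    patient: str
    a: Breakend
    b: Breakend
    svtype: str
    blacklisted: bool = False
    me_flag: bool = False
    cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.a.chrom == self.b.chrom and (self.a.pos, self.a.orient) > (
            self.b.pos,
            self.b.orient,
        ):
            self.a, self.b = self.b, self.a
        inter = self.a.chrom != self.b.chrom
        if inter != (self.svtype == "BND"):
            raise ValueError(
                f"svtype {self.svtype} inconsistent with chromosomes "
                f"{self.a.chrom}/{self.b.chrom} for call {self.call_id}"
            )

    @property
    def is_intra(self) -> bool:
        return self.a.chrom == self.b.chrom

    @property
    def span_length(self) -> Optional[int]:
        """Span in bp for intra-chromosomal calls, None for BND."""
        if not self.is_intra:
            return None
        return self.b.pos - self.a.pos

    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.a, self.b)

    @classmethod
    def make(
        cls,
        call_id: str,
        patient: str,
        a: Breakend,
        b: Breakend,
        svtype: Optional[str] = None,
    ) -> "SVCall":
        if svtype is None:
            svtype = classify_sv_type(a, b)
        return cls(call_id=call_id, patient=patient, a=a, b=b, svtype=svtype)


@dataclass
class Cohort:
    """Per-patient SV callsets for a tumour cohort."""

    patients: list[str]
    calls: dict[str, list[SVCall]]

    def __post_init__(self) -> None:
        known = set(self.patients)
        for pid, pcalls in self.calls.items():
            if pid not in known:
                raise ValueError(f"calls for unknown patient {pid}")
            ids = [c.call_id for c in pcalls]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate call ids for patient {pid}")
        for pid in self.patients:
            self.calls.setdefault(pid, [])

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def all_calls(self) -> Iterator[SVCall]:
        for pid in self.patients:
            yield from self.calls[pid]

    @property
    def n_calls(self) -> int:
        return sum(len(self.calls[p]) for p in self.patients)

    @classmethod
    def from_calls(cls, calls: Iterable[SVCall]) -> "Cohort":
        by_patient: dict[str, list[SVCall]] = {}
        for c in calls:
            by_patient.setdefault(c.patient, []).append(c)
        return cls(patients=sorted(by_patient), calls=by_patient)


@dataclass
class GeneModel:
    """A gene with the exons of its canonical transcript.

    Exons are 1-based closed intervals, normalized to be sorted and
    non-overlapping (touching or overlapping input exons are merged).
    """

    symbol: str
    transcript: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cancer_gene: bool = False

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        merged: list[tuple[int, int]] = []
        for s, e in exons:
            if s > e:
                raise ValueError(f"exon start {s} > end {e} in {self.symbol}")
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.exons = merged

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.symbol)


@dataclass(frozen=True)
class Bin:
    """A genomic bin, 0-based half-open, with a globally unique index."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bin end must exceed start")
        if self.end - self.start > 1_000_000:
            raise ValueError("bin width must be <= 1 Mb")

    def contains(self, pos: int) -> bool:
        """Whether a 1-based position falls in this half-open bin."""
        return self.start < pos <= self.end

    def overlaps_interval(self, iv: Interval) -> bool:
        """Overlap with a 1-based closed interval."""
        return iv.chrom == self.chrom and iv.start <= self.end and iv.end > self.start

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class MEInsertion:
    """A somatic LINE-1 mobile-element insertion call.

    ``me_class``: solo (LINE-1 sequence only), partnered (LINE-1 plus
    transduced 3' flank) or orphan (transduced flank only). Transductions
    carry the source-element locus; solo insertions do not.
    """

    chrom: str
    pos: int
    me_class: str
    source: str = "unknown"  # germline / somatic / unknown
    polya: bool = True
    source_locus: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.me_class not in ("solo", "partnered", "orphan"):
            raise ValueError(f"unknown ME class {self.me_class!r}")
        if self.me_class == "solo" and self.source_locus is not None:
            raise ValueError("solo insertions carry no source locus")
        if self.me_class in ("partnered", "orphan") and self.source_locus is None:
            raise ValueError(f"{self.me_class} transduction requires a source locus")


@dataclass
class FootprintCluster:
    """A footprint: SVs of one tumour closer together than chance expects."""

    patient: str
    cluster_id: int
    member_ids: list[str]
    cls: Optional[str] = None  # simple / complex / ME
    spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    svtype_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def log_uniform(rng, lo: float, hi: float, size=None):
    """Log-uniform draw in [lo, hi]; the default SV size distribution."""
    import numpy as np

    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))
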