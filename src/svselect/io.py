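"""Readers, writers and interval plumbing for every external format touched.

BEDPE and BED are parsed as 0-based half-open and converted to the
package's internal 1-based conventions at this boundary; all tabular
output is TSV with a stable column order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import (
    Bin,
    Breakend,
    Cohort,
    GeneModel,
    GenomeDef,
    Interval,
    SVCall,
    classify_sv_type,
)


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


# ---------------------------------------------------------------------------
# BEDPE


def read_sv_bedpe(path, genome: Optional[GenomeDef] = None) -> list[SVCall]:
    """Read SV calls from BEDPE.

    Expected columns: chrom1 start1 end1 chrom2 start2 end2 name score
    strand1 strand2 [patient] [svtype]. Breakend positions are taken as
    start+1 (the 1-based base of the half-open interval start). When the
    svtype column is absent the type is derived from the junction
    geometry. Records on chromosomes missing from ``genome`` are rejected
    and reported via a warning, never silently dropped.
    """
    calls: list[SVCall] = []
    rejected: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 10 BEDPE columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom1, start1 = fields[0], int(fields[1])
                chrom2, start2 = fields[3], int(fields[4])
                name = fields[6]
                strand1, strand2 = fields[8], fields[9]
                a = Breakend(chrom1, start1 + 1, _norm_strand(strand1))
                b = Breakend(chrom2, start2 + 1, _norm_strand(strand2))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            patient = fields[10] if len(fields) > 10 else "unknown"
            svtype = fields[11] if len(fields) > 11 and fields[11] != "." else None
            if genome is not None and not (
                genome.has_chrom(chrom1) and genome.has_chrom(chrom2)
            ):
                rejected.append(f"line {lineno}: unknown chromosome in {name}")
                continue
            if name == ".":
                name = f"sv{lineno}"
            try:
                calls.append(SVCall.make(name, patient, a, b, svtype))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} record(s): " + "; ".join(rejected),
            stacklevel=2,
        )
    return calls


def _norm_strand(s: str) -> str:
    # tolerate the unicode minus that sneaks into hand-written tables
    return "-" if s in ("-", "−") else s


def write_sv_bedpe(calls: Iterable[SVCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.a.chrom,
                        str(c.a.pos - 1),
                        str(c.a.pos),
                        c.b.chrom,
                        str(c.b.pos - 1),
                        str(c.b.pos),
                        c.call_id,
                        ".",
                        c.a.orient,
                        c.b.orient,
                        c.patient,
                        c.svtype,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Panel-of-normals filtering and callset matching


def _breakend_close(x: Breakend, y: Breakend, window_bp: int) -> bool:
    return x.chrom == y.chrom and abs(x.pos - y.pos) <= window_bp


def _pair_close(a: SVCall, b: SVCall, window_bp: int) -> Optional[int]:
    """Summed breakend distance if both breakends match within the window."""
    if a.svtype != b.svtype:
        return None
    for (x1, x2) in ((b.a, b.b), (b.b, b.a)):
        if _breakend_close(a.a, x1, window_bp) and _breakend_close(a.b, x2, window_bp):
            return abs(a.a.pos - x1.pos) + abs(a.b.pos - x2.pos)
    return None


def filter_panel(
    calls: Sequence[SVCall], panel_calls: Sequence[SVCall], window_bp: int = 300
) -> list[SVCall]:
    """Flag calls that match a panel-of-normals record.

    A call is blacklisted iff some panel record shares its svtype and
    chromosome pair with both breakends within ``window_bp``. Flags are
    set in place; the call list is returned for chaining.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_key: dict[tuple, list[SVCall]] = {}
    for p in panel_calls:
        key = (p.svtype, tuple(sorted((p.a.chrom, p.b.chrom))))
        by_key.setdefault(key, []).append(p)
    for c in calls:
        key = (c.svtype, tuple(sorted((c.a.chrom, c.b.chrom))))
        c.blacklisted = any(
            _pair_close(c, p, window_bp) is not None for p in by_key.get(key, [])
        )
    return list(calls)


@dataclass(frozen=True)
class MatchResult:
    precision: float
    sensitivity: float
    f1: float
    n_matched: int


def match_callsets(
    calls_a: Sequence[SVCall], calls_b: Sequence[SVCall], window_bp: int = 300
) -> MatchResult:
    """Greedy one-to-one matching of two callsets from the same genome.

    Candidate pairs share svtype and have both breakends within
    ``window_bp``; pairs are consumed by ascending summed breakend
    distance (ties broken by call id), each call matched at most once.
    precision = matched/|A|, sensitivity = matched/|B|. Two empty sets
    are perfect agreement by convention: all three metrics are 1.0.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if not calls_a and not calls_b:
        return MatchResult(1.0, 1.0, 1.0, 0)
    candidates = []
    for i, a in enumerate(calls_a):
        for j, b in enumerate(calls_b):
            d = _pair_close(a, b, window_bp)
            if d is not None:
                candidates.append((d, a.call_id, b.call_id, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched += 1
    precision = matched / len(calls_a) if calls_a else 1.0
    sensitivity = matched / len(calls_b) if calls_b else 1.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    return MatchResult(precision, sensitivity, f1, matched)


# ---------------------------------------------------------------------------
# Binning


def make_bins(
    genome: GenomeDef, width: int = 1_000_000, step: int = 500_000
) -> list[Bin]:
    """Tile every chromosome with overlapping bins of fixed width and step.

    Full-width bins start at 0, step, 2*step, ...; when the chromosome end
    would otherwise be uncovered one final truncated bin is appended. A
    chromosome shorter than ``width`` gets the single bin [0, L).
    Indices are globally unique and ordered (chromosome, start).
    """
    if step <= 0 or width < step:
        raise ValueError("need width >= step > 0")
    bins: list[Bin] = []
    idx = 0
    for chrom in genome.names:
        L = genome.lengths[chrom]
        if L <= width:
            starts = [0]
        else:
            starts = list(range(0, L - width + 1, step))
            if starts[-1] + width < L:
                starts.append(starts[-1] + step)
        for s in starts:
            bins.append(Bin(chrom, s, min(s + width, L), idx))
            idx += 1
    return bins


def flag_bins(bins: Sequence[Bin], regions: Sequence[Interval]) -> list[bool]:
    """Per-bin flag: does the bin overlap any of the given regions?"""
    by_chrom: dict[str, list[Interval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    return [
        any(b.overlaps_interval(r) for r in by_chrom.get(b.chrom, ())) for b in bins
    ]


# ---------------------------------------------------------------------------
# BED / BED12 / TSV


def read_regions(path, genome: Optional[GenomeDef] = None) -> list[Interval]:
    """Read a BED3+ file into 1-based closed intervals."""
    out: list[Interval] = []
    rejected: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else ""
            if genome is not None:
                if not genome.has_chrom(chrom) or end > genome.lengths[chrom]:
                    rejected.append(f"line {lineno}: outside genome ({chrom}:{end})")
                    continue
            out.append(Interval(chrom, start + 1, end, name))
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} region(s): " + "; ".join(rejected),
            stacklevel=2,
        )
    return out


def write_regions(regions: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.chrom, str(r.start - 1), str(r.end)]
            if r.name:
                cols.append(r.name)
            fh.write("\t".join(cols) + "\n")


def read_gene_models(
    path, cancer_genes: Optional[set[str]] = None
) -> list[GeneModel]:
    """Read gene models from BED12 (one canonical transcript per gene).

    The name column is ``SYMBOL`` or ``SYMBOL:TRANSCRIPT``; blocks become
    exons (1-based closed). Genes in ``cancer_genes`` are flagged.
    """
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 BED12 columns")
            try:
                chrom, chrom_start = fields[0], int(fields[1])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(
                    f"{path}: line {lineno}: block count disagrees with block lists"
                )
            symbol, _, transcript = name.partition(":")
            exons = [
                (chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(offsets, sizes)
            ]
            out.append(
                GeneModel(
                    symbol=symbol,
                    transcript=transcript,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cancer_gene=bool(cancer_genes and symbol in cancer_genes),
                )
            )
    return out


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            chrom_start = g.start - 1
            sizes = ",".join(str(e - s + 1) for s, e in g.exons)
            offsets = ",".join(str(s - 1 - chrom_start) for s, _ in g.exons)
            name = f"{g.symbol}:{g.transcript}" if g.transcript else g.symbol
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(chrom_start),
                        str(g.end),
                        name,
                        "0",
                        g.strand,
                        str(chrom_start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_matrix(path) -> pd.DataFrame:
    """Read a labelled numeric TSV (first column = row labels)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gene_list(path) -> set[str]:
    """Read a one-per-line (or first-TSV-column) gene symbol list."""
    out = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.add(line.split()[0])
    return out


# ---------------------------------------------------------------------------
# Minimal breakend-style VCF reader (MANTA-like records)

_BND_ALT = re.compile(
    r"^(?P<lead>[ACGTNacgtn]*)"
    r"(?P<open>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<trail>[ACGTNacgtn]*)$"
)

_SYMBOLIC = {"<DEL>": "DEL", "<DUP>": "DUP", "<DUP:TANDEM>": "DUP", "<INV>": "INV"}


def read_sv_vcf(path, patient: Optional[str] = None) -> list[SVCall]:
    """Read simple SV records from a breakend-style VCF.

    Handles symbolic <DEL>/<DUP>/<INV> records (via INFO END) and paired
    BND records linked by MATEID with bracket ALT notation. Complex or
    unpaired records are rejected with a warning naming the record; the
    full VCF breakend grammar (inserted sequence, single breakends) is
    out of scope.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if patient is None:
        patient = vcf.samples[0] if vcf.samples else "unknown"
    calls: list[SVCall] = []
    bnd_records: dict[str, dict] = {}
    rejected: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            rejected.append(f"{rec.ID or rec.POS}: multi-allelic record")
            continue
        alt = rec.ALT[0]
        if alt in _SYMBOLIC:
            end = rec.INFO.get("END")
            if end is None:
                rejected.append(f"{rec.ID or rec.POS}: symbolic ALT without END")
                continue
            svtype = _SYMBOLIC[alt]
            orients = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+")}[svtype]
            calls.append(
                SVCall(
                    call_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    patient=patient,
                    a=Breakend(rec.CHROM, rec.POS, orients[0]),
                    b=Breakend(rec.CHROM, int(end), orients[1]),
                    svtype=svtype,
                )
            )
            continue
        m = _BND_ALT.match(alt)
        if m:
            mate = rec.INFO.get("MATEID")
            if mate is None or rec.ID is None:
                rejected.append(f"{rec.ID or rec.POS}: BND without MATEID")
                continue
            bnd_records[rec.ID] = {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                # t[p[ / t]p] keep the left side; ]p]t / [p[t keep the right
                "orient": "+" if m.group("lead") else "-",
                "mate": mate,
            }
            continue
        rejected.append(f"{rec.ID or rec.POS}: unsupported ALT {alt!r}")
    seen: set[str] = set()
    for rid, rec in bnd_records.items():
        if rid in seen:
            continue
        mate = bnd_records.get(rec["mate"])
        if mate is None:
            rejected.append(f"{rid}: mate {rec['mate']} not found")
            continue
        seen.add(rid)
        seen.add(rec["mate"])
        a = Breakend(rec["chrom"], rec["pos"], rec["orient"])
        b = Breakend(mate["chrom"], mate["pos"], mate["orient"])
        calls.append(SVCall.make(rid.rsplit(":", 1)[0], patient, a, b))
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} record(s): " + "; ".join(rejected),
            stacklevel=2,
        )
    return calls


def drop_excluded(calls: Sequence[SVCall], genome: GenomeDef) -> list[SVCall]:
    """Drop calls with any breakend inside an excluded (centromere/telomere) region."""
    return [
        c
        for c in calls
        if not (
            genome.is_excluded(c.a.chrom, c.a.pos)
            or genome.is_excluded(c.b.chrom, c.b.pos)
        )
    ]
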