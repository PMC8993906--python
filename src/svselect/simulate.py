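"""Synthetic tumour cohorts with known ground truth.

The generator emulates the statistical structure the downstream stages
are built for: per-bin SV event counts follow a negative-binomial
log-linear model on eight genomic covariates, optionally multiplied up
in implanted hotspot bins; events are realized as SV calls with a
configurable type mix and log-uniform sizes; driver deletions are
implanted over gene exons in a fixed fraction of patients; LINE-1
mobile-element insertions carry solo/partnered/orphan class labels,
poly-A flags and transduction source loci, with companion BND calls.

Everything is driven by one seeded generator stream: identical
parameters (including the seed) give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Bin,
    Breakend,
    Cohort,
    GeneModel,
    GenomeDef,
    MEInsertion,
    SVCall,
)
from .io import make_bins

COVARIATE_NAMES = [
    "fragile",
    "cna",
    "gc",
    "reptime",
    "h3k36me3",
    "h3k27ac",
    "dnase",
    "alu",
]

#: Default log-scale covariate effects (intercept first). The intercept
#: of -4 gives a background of ~0.02 anchored events per patient per
#: 1 Mb bin, a desk-scale stand-in for a heavily rearranged cohort; the
#: slopes are of the order log(1.2)-log(2), the effect sizes reported
#: for genomic-context models of breakpoint rates.
DEFAULT_BETA = np.array([-4.0, 0.4, 0.3, 0.7, 0.5, 0.2, 0.2, 0.3, 0.3])

DEFAULT_TYPE_MIX = {"DEL": 0.40, "DUP": 0.25, "INV": 0.15, "BND": 0.20}


@dataclass
class DriverSpec:
    """Implant exon-overlapping SVs of one gene in a patient fraction."""

    gene: GeneModel
    fraction: float
    svtype: str = "DEL"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("driver fraction must be in [0, 1]")


@dataclass
class MESpec:
    """Mobile-element insertion model.

    ``class_mix`` is (solo, partnered, orphan) and must sum to 1. The
    per-patient insert count is NB(mean, dispersion); a small dispersion
    reproduces the heavy spread seen in real tumours (median ~60,
    IQR spanning two orders of magnitude).
    """

    mean_per_patient: float = 60.0
    dispersion: float = 0.6
    class_mix: tuple[float, float, float] = (0.81, 0.07, 0.12)
    polya_prob: float = 0.95
    bnd_prob: float = 0.25
    germline_frac: float = 0.72
    n_sources: int = 20
    sources: Optional[list[tuple[str, int]]] = None

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("ME class mix must sum to 1")


@dataclass
class SimParams:
    genome: GenomeDef
    n_patients: int = 50
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    dispersion: float = 2.0
    rate_scale: float = 1.0
    hotspots: dict[int, float] = field(default_factory=dict)
    drivers: list[DriverSpec] = field(default_factory=list)
    me: Optional[MESpec] = None
    sv_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )
    size_range: tuple[float, float] = (1e3, 1e7)
    bin_width: int = 1_000_000
    bin_step: int = 1_000_000
    fragile_prev: float = 0.05
    cna_prev: float = 0.10
    autocorr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (1 + len(COVARIATE_NAMES),):
            raise ValueError(
                f"beta must have {1 + len(COVARIATE_NAMES)} entries "
                "(intercept + one per covariate)"
            )
        for mult in self.hotspots.values():
            if mult <= 1.0:
                raise ValueError("hotspot multipliers must be > 1")
        if self.bin_width != self.bin_step:
            raise ValueError(
                "generator tiles must be non-overlapping (bin_width == bin_step); "
                "overlapping bins are an analysis-side construct"
            )


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated cohort."""

    bins: list[Bin]
    covariates: pd.DataFrame
    beta: np.ndarray
    mu: np.ndarray  # per-bin expected anchored events per patient
    counts: np.ndarray  # bins x patients anchored NB event counts
    patients: list[str]
    hotspot_bins: list[int]
    driver_patients: dict[str, list[str]]
    insertions: dict[str, list[MEInsertion]]


# ---------------------------------------------------------------------------


def gen_covariates(
    bins: Sequence[Bin],
    seed: int,
    fragile_prev: float = 0.05,
    cna_prev: float = 0.10,
    autocorr: float = 0.8,
) -> pd.DataFrame:
    """Per-bin genomic covariates: two binary flags, six smooth tracks.

    The binary fragile-site and copy-number-aberration flags are iid
    Bernoulli with the given prevalences. The six continuous tracks (GC,
    replication timing, H3K36me3, H3K27ac, DNase, ALU density) are
    logistic transforms of per-chromosome AR(1) standard-normal series,
    so each lies in [0, 1], is spatially autocorrelated along the
    chromosome, and has generative mean 0.5 by symmetry.
    """
    rng = np.random.default_rng(seed)
    n = len(bins)
    data = {
        "fragile": (rng.random(n) < fragile_prev).astype(float),
        "cna": (rng.random(n) < cna_prev).astype(float),
    }
    chroms = np.array([b.chrom for b in bins])
    for name in COVARIATE_NAMES[2:]:
        z = np.empty(n)
        for chrom in pd.unique(chroms):
            idx = np.flatnonzero(chroms == chrom)
            eps = rng.standard_normal(len(idx))
            zc = np.empty(len(idx))
            zc[0] = eps[0]
            a = autocorr
            for i in range(1, len(idx)):
                zc[i] = a * zc[i - 1] + math.sqrt(1 - a * a) * eps[i]
            z[idx] = zc
        data[name] = 1.0 / (1.0 + np.exp(-z))
    df = pd.DataFrame(data, index=[b.index for b in bins])
    df.index.name = "bin"
    return df


def expected_rates(
    params: SimParams, covariates: pd.DataFrame
) -> np.ndarray:
    """Per-bin expected anchored events per patient, hotspots applied."""
    X = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy() for c in COVARIATE_NAMES]
    )
    mu = params.rate_scale * np.exp(X @ params.beta)
    for bin_id, mult in params.hotspots.items():
        mu[bin_id] *= mult
    return mu


def simulate_bin_counts(
    params: SimParams, covariates: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the NB count layer: anchored SV events per (bin, patient).

    counts[b, p] ~ NB(mean = mu_b, dispersion theta) with
    Var = mu + mu^2/theta.
    """
    mu = expected_rates(params, covariates)
    theta = params.dispersion
    n_bins = len(mu)
    if np.all(mu == 0):
        return np.zeros((n_bins, params.n_patients), dtype=np.int64), mu
    p = theta / (theta + mu)
    counts = rng.negative_binomial(
        theta, p[:, None], size=(n_bins, params.n_patients)
    )
    return counts.astype(np.int64), mu


# ---------------------------------------------------------------------------


def _draw_sv(
    rng: np.random.Generator,
    genome: GenomeDef,
    chrom: str,
    pos: int,
    svtype: str,
    size_range: tuple[float, float],
) -> tuple[Breakend, Breakend, str]:
    L = genome.lengths[chrom]
    if svtype == "BND":
        others = [c for c in genome.names if c != chrom]
        mate_chrom = others[rng.integers(len(others))]
        mate_pos = int(rng.integers(1, genome.lengths[mate_chrom] + 1))
        o1, o2 = rng.choice(["+", "-"], size=2)
        return (
            Breakend(chrom, pos, str(o1)),
            Breakend(mate_chrom, mate_pos, str(o2)),
            "BND",
        )
    size = int(
        np.exp(rng.uniform(math.log(size_range[0]), math.log(size_range[1])))
    )
    size = max(size, 1)
    if rng.random() < 0.5:
        pos2 = pos + size
        if pos2 > L:
            pos2 = max(1, pos - size)
    else:
        pos2 = pos - size
        if pos2 < 1:
            pos2 = min(L, pos + size)
    if pos2 == pos:
        pos2 = pos + 1 if pos < L else pos - 1
    lo, hi = (pos, pos2) if pos < pos2 else (pos2, pos)
    if svtype == "DEL":
        orients = ("+", "-")
    elif svtype == "DUP":
        orients = ("-", "+")
    else:
        s = "+" if rng.random() < 0.5 else "-"
        orients = (s, s)
    return (
        Breakend(chrom, lo, orients[0]),
        Breakend(chrom, hi, orients[1]),
        svtype,
    )


def _type_mix_for(genome: GenomeDef, mix: dict[str, float]) -> tuple[list, np.ndarray]:
    mix = dict(mix)
    if len(genome.names) < 2:
        mix.pop("BND", None)
    types = sorted(mix)
    probs = np.array([mix[t] for t in types], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("SV type mix must have positive mass")
    return types, probs / probs.sum()


def simulate_cohort(params: SimParams) -> tuple[Cohort, SimTruth]:
    """Generate a full cohort plus its ground truth.

    Per (patient, bin) the number of SV events anchored in the bin is
    NB(exp(beta . x_bin) * hotspot multiplier, dispersion); each event's
    first breakend is uniform in its bin and the mate is placed by type
    (log-uniform size for intra-chromosomal calls, uniform on another
    chromosome for BND). Driver specs add exon-overlapping calls to the
    first floor(fraction * n) patients; the ME spec adds insertions and
    their companion BND calls.
    """
    rng = np.random.default_rng(params.seed)
    bins = make_bins(params.genome, params.bin_width, params.bin_step)
    for bin_id in params.hotspots:
        if not 0 <= bin_id < len(bins):
            raise ValueError(f"hotspot bin id {bin_id} outside the genome tiling")
    covariates = gen_covariates(
        bins,
        seed=int(rng.integers(2**31)),
        fragile_prev=params.fragile_prev,
        cna_prev=params.cna_prev,
        autocorr=params.autocorr,
    )
    counts, mu = simulate_bin_counts(params, covariates, rng)

    patients = [f"P{i + 1:03d}" for i in range(params.n_patients)]
    types, probs = _type_mix_for(params.genome, params.sv_type_mix)
    calls: dict[str, list[SVCall]] = {p: [] for p in patients}
    for p_idx, pid in enumerate(patients):
        k = 0
        for b in bins:
            c = counts[b.index, p_idx]
            for _ in range(int(c)):
                pos = int(rng.integers(b.start + 1, b.end + 1))
                svtype = types[rng.choice(len(types), p=probs)]
                be_a, be_b, svtype = _draw_sv(
                    rng, params.genome, b.chrom, pos, svtype, params.size_range
                )
                k += 1
                calls[pid].append(
                    SVCall(f"{pid}_sv{k}", pid, be_a, be_b, svtype)
                )

    driver_patients: dict[str, list[str]] = {}
    for spec in params.drivers:
        gene = spec.gene
        if not params.genome.has_chrom(gene.chrom):
            raise ValueError(f"driver gene {gene.symbol} not on the genome")
        n_aff = int(spec.fraction * params.n_patients)
        affected = patients[:n_aff]
        driver_patients[gene.symbol] = affected
        L = params.genome.lengths[gene.chrom]
        for pid in affected:
            margin_lo = int(rng.integers(100, 5000))
            margin_hi = int(rng.integers(100, 5000))
            ex_s, ex_e = gene.exons[int(rng.integers(len(gene.exons)))]
            lo = max(1, ex_s - margin_lo)
            hi = min(L, ex_e + margin_hi)
            orients = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+")}[
                spec.svtype
            ]
            calls[pid].append(
                SVCall(
                    f"{pid}_drv_{gene.symbol}",
                    pid,
                    Breakend(gene.chrom, lo, orients[0]),
                    Breakend(gene.chrom, hi, orients[1]),
                    spec.svtype,
                )
            )

    insertions: dict[str, list[MEInsertion]] = {p: [] for p in patients}
    if params.me is not None:
        insertions, companions = gen_me_insertions(
            params.genome, params.me, patients, rng
        )
        for sv in companions:
            calls[sv.patient].append(sv)

    cohort = Cohort(patients=patients, calls=calls)
    truth = SimTruth(
        bins=bins,
        covariates=covariates,
        beta=params.beta.copy(),
        mu=mu,
        counts=counts,
        patients=patients,
        hotspot_bins=sorted(params.hotspots),
        driver_patients=driver_patients,
        insertions=insertions,
    )
    return cohort, truth


# ---------------------------------------------------------------------------


def gen_me_insertions(
    genome: GenomeDef,
    spec: MESpec,
    patients: Sequence[str],
    rng: np.random.Generator,
) -> tuple[dict[str, list[MEInsertion]], list[SVCall]]:
    """Draw ME insertions per patient plus companion BND calls.

    Each insertion gets a class from ``class_mix``, a poly-A flag, and —
    for transductions — a source locus drawn from the simulated source
    elements, labelled germline or somatic. With probability
    ``bnd_prob`` an insertion spawns a companion BND sharing its site as
    one breakend (transductions point at their source element).
    """
    sources = spec.sources
    if sources is None:
        sources = []
        for _ in range(spec.n_sources):
            chrom = genome.names[int(rng.integers(len(genome.names)))]
            sources.append((chrom, int(rng.integers(1, genome.lengths[chrom] + 1))))
    classes = ("solo", "partnered", "orphan")
    mix = np.asarray(spec.class_mix, dtype=float)
    theta = spec.dispersion
    p_nb = theta / (theta + spec.mean_per_patient)
    insertions: dict[str, list[MEInsertion]] = {}
    companions: list[SVCall] = []
    multi_chrom = len(genome.names) > 1
    for pid in patients:
        n_ins = int(rng.negative_binomial(theta, p_nb))
        plist: list[MEInsertion] = []
        for i in range(n_ins):
            chrom = genome.names[int(rng.integers(len(genome.names)))]
            pos = int(rng.integers(1, genome.lengths[chrom] + 1))
            me_class = classes[rng.choice(3, p=mix)]
            polya = bool(rng.random() < spec.polya_prob)
            if me_class == "solo":
                source_locus = None
                source = "unknown"
            else:
                source_locus = sources[int(rng.integers(len(sources)))]
                source = (
                    "germline" if rng.random() < spec.germline_frac else "somatic"
                )
            ins = MEInsertion(
                chrom=chrom,
                pos=pos,
                me_class=me_class,
                source=source,
                polya=polya,
                source_locus=source_locus,
            )
            plist.append(ins)
            if multi_chrom and rng.random() < spec.bnd_prob:
                if source_locus is not None and source_locus[0] != chrom:
                    mate_chrom, mate_pos = source_locus
                else:
                    others = [c for c in genome.names if c != chrom]
                    mate_chrom = others[int(rng.integers(len(others)))]
                    mate_pos = int(rng.integers(1, genome.lengths[mate_chrom] + 1))
                o1, o2 = rng.choice(["+", "-"], size=2)
                companions.append(
                    SVCall(
                        f"{pid}_me{i + 1}",
                        pid,
                        Breakend(chrom, pos, str(o1)),
                        Breakend(mate_chrom, mate_pos, str(o2)),
                        "BND",
                    )
                )
        insertions[pid] = plist
    return insertions, companions


def filter_polya(insertions: Sequence[MEInsertion]) -> list[MEInsertion]:
    """Discard inserts lacking the expected poly-A tail."""
    return [i for i in insertions if i.polya]
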