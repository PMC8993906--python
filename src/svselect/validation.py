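"""Validation studies: the package's own end-to-end checks on synthetic
cohorts with known ground truth.

Each study generates its inputs from the synthetic-cohort model,
runs the corresponding pipeline stage, and measures recovery or
calibration. Problem sizes are desk-scale by design (a few hundred
bins, tens of patients, tens to hundreds of replicates); the methods
note documents what these studies do and do not show about real
cohorts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import GenomeDef
from .hotspots import BinTable, bin_breakpoint_stats, fit_context_model, focal_hotspots
from .io import make_bins
from .report import percent_value
from .signatures import (
    CHANNELS,
    Catalogue,
    associate_features,
    extract_signatures,
    match_reference,
)
from .simulate import SimParams, gen_covariates, simulate_bin_counts, simulate_cohort

#: Worked printed-ratio examples: cohort tallies reported as rounded
#: percentages. Each entry is (name, numerator, denominator, decimals).
PRINTED_RATIOS = [
    ("runx1_recurrence_pct", 92, 383, 0),
    ("solo_insert_pct", 37_475, 37_475 + 8_517, 0),
    ("rs4_cluster_me_overlap_pct", 1622, 2751, 0),
    ("amplicon_oncogene_pct", 295, 507, 1),
    ("amplicon_driver_patient_pct", 136, 383, 1),
    ("germline_source_pct", 6109, 45_992, 0),
    ("orphan_transduction_pct", 5322, 45_992, 0),
]


def printed_ratios() -> dict[str, dict]:
    """Render each worked tally through the percent-formatting chain."""
    return {
        name: {"value": percent_value(num, den, decimals), "n": den}
        for name, num, den, decimals in PRINTED_RATIOS
    }


# ---------------------------------------------------------------------------
# NB context-model coefficient recovery


def nb_coefficient_recovery(
    seed: int,
    n_reps: int = 100,
    n_bins: int = 2000,
    n_patients: int = 200,
    beta_gc: float = math.log(2),
) -> dict:
    """95% CI coverage of a planted GC effect in the NB context model.

    Per replicate, per-bin per-patient counts are drawn from the
    generator's NB count layer (log-linear in the eight covariates with
    the GC coefficient set to ``beta_gc``); the context model is refit
    on the per-bin totals and the GC coefficient's 95% CI is checked
    against the truth.
    """
    chrom_mb = 200
    n_chroms = max(1, n_bins * 1_000_000 // (chrom_mb * 1_000_000))
    genome = GenomeDef.uniform(n_chroms, chrom_mb * 1_000_000)
    bins = make_bins(genome, 1_000_000, 1_000_000)[:n_bins]
    beta = np.array([-4.0, 0.4, 0.3, beta_gc, 0.5, 0.2, 0.2, 0.3, 0.3])
    patients = [f"P{i}" for i in range(n_patients)]
    rng = np.random.default_rng(seed)
    covered = 0
    fallbacks = 0
    for rep in range(n_reps):
        params = SimParams(
            genome=genome, n_patients=n_patients, beta=beta,
            seed=int(rng.integers(2**31)),
        )
        cov = gen_covariates(bins, seed=int(rng.integers(2**31)))
        counts, _ = simulate_bin_counts(params, cov, rng)
        table = BinTable(bins=bins, patients=patients, counts=counts, covariates=cov)
        fit = fit_context_model(table, response="total")
        fallbacks += fit.poisson_fallback
        lo, hi = fit.conf_int.loc["gc"]
        covered += bool(lo <= beta_gc <= hi)
    return {
        "coverage": covered / n_reps,
        "n_reps": n_reps,
        "n_bins": n_bins,
        "n_patients": n_patients,
        "poisson_fallbacks": fallbacks,
    }


# ---------------------------------------------------------------------------
# Focal hotspot consensus: implant detection and null false-flag rate


def hotspot_consensus_study(
    seed: int,
    n_reps: int = 100,
    n_patients: int = 60,
    multiplier: float = 10.0,
    hotspot_bin: int = 125,
) -> dict:
    """Sensitivity to an implanted hotspot and null-bin consensus rate.

    Genome: 4 chromosomes x 50 Mb tiled in 200 non-overlapping 1 Mb
    bins. Per replicate a null cohort (covariate-driven background
    only) and a matched cohort with one bin's rate multiplied are
    simulated through the full path (SV calls realized, breakends
    re-binned); the focal consensus runs with the artifact filters
    disabled, since the synthetic cohorts contain no fragile-site or
    amplicon artifact class for them to remove.
    """
    genome = GenomeDef.uniform(4, 50_000_000)
    rng = np.random.default_rng(seed)
    null_flags = 0
    null_bins = 0
    detected = 0
    for rep in range(n_reps):
        s_null = int(rng.integers(2**31))
        s_hot = int(rng.integers(2**31))
        cohort, truth = simulate_cohort(
            SimParams(genome=genome, n_patients=n_patients, seed=s_null)
        )
        table = bin_breakpoint_stats(
            cohort, truth.bins, covariates=truth.covariates, density_quantile=1.0
        )
        focal = focal_hotspots(table, seed=0)
        null_flags += int(focal["consensus"].sum())
        null_bins += len(focal)
        cohort, truth = simulate_cohort(
            SimParams(
                genome=genome,
                n_patients=n_patients,
                seed=s_hot,
                hotspots={hotspot_bin: multiplier},
            )
        )
        table = bin_breakpoint_stats(
            cohort, truth.bins, covariates=truth.covariates, density_quantile=1.0
        )
        focal = focal_hotspots(table, seed=0)
        detected += bool(focal.loc[hotspot_bin, "consensus"])
    return {
        "sensitivity": detected / n_reps,
        "null_flag_rate": null_flags / null_bins,
        "n_reps": n_reps,
        "n_bins": null_bins // n_reps,
    }


# ---------------------------------------------------------------------------
# Planted-signature recovery


def planted_signature_catalogue(
    seed: int, n_patients: int = 60, k: int = 3
) -> tuple[pd.DataFrame, Catalogue]:
    """A catalogue of Poisson counts around W0 @ H0 with ``k`` block
    signatures and strongly dominated patients ("well-separated").

    Returns (W0 as a channel x k DataFrame, the catalogue).
    """
    rng = np.random.default_rng(seed)
    W0 = np.zeros((len(CHANNELS), k))
    edges = np.linspace(0, len(CHANNELS), k + 1).astype(int)
    for j in range(k):
        block = list(range(edges[j], edges[j + 1]))
        W0[block, j] = rng.dirichlet(np.ones(len(block)) * 2.0)
    H0 = rng.gamma(1.5, 8.0, size=(k, n_patients))
    dominant = rng.integers(0, k, n_patients)
    for i, d in enumerate(dominant):
        H0[d, i] = rng.gamma(4.0, 40.0)
    V = rng.poisson(W0 @ H0)
    ref = pd.DataFrame(W0, index=CHANNELS, columns=[f"T{j + 1}" for j in range(k)])
    cat = Catalogue(
        counts=pd.DataFrame(
            V, index=CHANNELS, columns=[f"P{i + 1}" for i in range(n_patients)]
        )
    )
    return ref, cat


def signature_recovery_study(
    seed: int,
    n_seeds: int = 20,
    iters: int = 500,
    replicates: int = 10,
) -> dict:
    """Mean matched cosine of planted 3-signature recovery over seeds,
    plus the stability-selected rank on the first instance (scan 2..5)."""
    rng = np.random.default_rng(seed)
    cosines = []
    chosen_k = None
    for i in range(n_seeds):
        s = int(rng.integers(2**31))
        ref, cat = planted_signature_catalogue(s)
        if i == 0:
            scan = extract_signatures(
                cat, kmin=2, kmax=5, iters=iters, replicates=replicates, seed=s
            )
            chosen_k = scan.k
        model = extract_signatures(
            cat, kmin=3, kmax=3, iters=iters, replicates=replicates, seed=s
        )
        assignment = match_reference(model.W, ref)
        cosines.append(float(assignment["cosine"].mean()))
    return {
        "mean_cosine": float(np.mean(cosines)),
        "min_cosine": float(np.min(cosines)),
        "chosen_k": chosen_k,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Type-I calibration


def recurrence_test_calibration(
    seed: int, n_reps: int = 1000, n: int = 383, p: float = 0.3
) -> dict:
    """Rejection rate of the one-sided two-proportion test at alpha=0.05
    under equal true proportions."""
    from .drivers import two_proportion_test

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x1 = int(rng.binomial(n, p))
        x2 = int(rng.binomial(n, p))
        _, pval = two_proportion_test(x1, n, x2, n, alternative="greater")
        rejections += pval < 0.05
    return {"type1": rejections / n_reps, "n_reps": n_reps, "n": n}


def logistic_calibration(
    seed: int, n_reps: int = 1000, n: int = 400, prevalence: float = 0.4
) -> dict:
    """Univariate type-I rate of the feature-association regression at
    alpha=0.05 with a feature independent of the response."""
    rng = np.random.default_rng(seed)
    rejections = 0
    pvals = []
    for _ in range(n_reps):
        y = rng.random(n) < prevalence
        x = np.exp(rng.standard_normal(n))  # positive, log1p-transformed inside
        uni, _ = associate_features(
            pd.DataFrame({"RS": y}), pd.DataFrame({"feature": x})
        )
        pval = float(uni["p"].iloc[0])
        pvals.append(pval)
        rejections += pval < 0.05
    return {
        "type1": rejections / n_reps,
        "n_reps": n_reps,
        "n": n,
        "p_mean": float(np.mean(pvals)),
    }
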