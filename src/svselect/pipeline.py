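"""Pipeline orchestration: filter -> footprints/ME -> signatures ->
hotspots -> drivers, with per-stage TSV outputs and a run manifest.

Outputs are deterministic for a fixed config and seed: floating-point
columns are printed at fixed precision and every table has a stable
column order, so re-running a config reproduces the TSVs byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Cohort, GenomeDef, Interval
from .drivers import (
    recurrence_test,
    spans_for_cohort,
    tally_recurrence,
    gene_hits,
)
from .footprints import annotate_me, classify_clusters, cluster_cohort
from .hotspots import bin_breakpoint_stats, focal_hotspots, fit_context_model, \
    merge_bins_to_regions
from .io import (
    drop_excluded,
    filter_panel,
    make_bins,
    read_gene_list,
    read_gene_models,
    read_matrix,
    read_regions,
    read_sv_bedpe,
    write_sv_bedpe,
)
from .signatures import (
    build_catalogue,
    consensus_group,
    extract_signatures,
    match_reference,
)
from .simulate import SimParams, filter_polya, simulate_cohort

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Either ``simulate`` is set (synthetic cohort; no input paths needed)
    or ``sv_calls`` points at a BEDPE. All optional inputs simply skip
    their stage when absent.
    """

    outdir: Path
    genome: GenomeDef
    simulate: Optional[SimParams] = None
    sv_calls: Optional[Path] = None
    panel: Optional[Path] = None
    gene_models: Optional[Path] = None
    cancer_genes: Optional[Path] = None
    fragile_sites: Optional[Path] = None
    reference_signatures: Optional[Path] = None
    prior_alterations: Optional[Path] = None
    bin_width: int = 1_000_000
    bin_step: int = 500_000
    cluster_alpha: float = 0.05
    panel_window_bp: int = 300
    density_quantile: float = 0.975
    residual_threshold: float = 2.0
    kmin: int = 2
    kmax: int = 6
    nmf_iters: int = 500
    nmf_replicates: int = 10
    consensus_resamples: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and self.sv_calls is None:
            raise ValueError("config needs either a simulate block or sv_calls")
        for name in (
            "sv_calls",
            "panel",
            "gene_models",
            "cancer_genes",
            "fragile_sites",
            "reference_signatures",
            "prior_alterations",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p} does not exist")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages in order; returns the run manifest.

    With ``resume=True`` a stage whose outputs already exist is skipped.
    Stage row counts and wall-clock are recorded in
    ``<outdir>/manifest.json``.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "bin_width": config.bin_width,
            "bin_step": config.bin_step,
            "cluster_alpha": config.cluster_alpha,
            "panel_window_bp": config.panel_window_bp,
            "density_quantile": config.density_quantile,
            "residual_threshold": config.residual_threshold,
            "kmin": config.kmin,
            "kmax": config.kmax,
        },
        "stages": {},
    }

    def stage(name: str, outputs: list[Path], fn):
        t0 = time.perf_counter()
        if resume and outputs and all(p.exists() for p in outputs):
            manifest["stages"][name] = {"skipped": True}
            return None
        result = fn()
        manifest["stages"][name] = {
            "skipped": False,
            "seconds": round(time.perf_counter() - t0, 3),
            "rows": result if isinstance(result, int) else None,
        }
        return result

    # ---- input / simulation
    insertions: dict = {}
    if config.simulate is not None:
        cohort, truth = simulate_cohort(config.simulate)
        insertions = {p: filter_polya(v) for p, v in truth.insertions.items()}
        write_sv_bedpe(cohort.all_calls(), out / "calls.bedpe")
    else:
        calls = read_sv_bedpe(config.sv_calls, genome=config.genome)
        cohort = Cohort.from_calls(calls)
        truth = None
    manifest["stages"]["input"] = {"patients": cohort.n_patients,
                                   "calls": cohort.n_calls}

    # ---- filtering
    if config.panel is not None:
        panel = read_sv_bedpe(config.panel)
        for pid in cohort.patients:
            filter_panel(cohort.calls[pid], panel, config.panel_window_bp)
    for pid in cohort.patients:
        cohort.calls[pid] = drop_excluded(
            [c for c in cohort.calls[pid] if not c.blacklisted], config.genome
        )
    manifest["stages"]["filter"] = {"calls": cohort.n_calls}

    # ---- footprints + ME annotation
    all_ins = [i for v in insertions.values() for i in v]
    for pid in cohort.patients:
        annotate_me(cohort.calls[pid], insertions.get(pid, []))
    clusters = cluster_cohort(cohort, config.genome, config.cluster_alpha)
    calls_by_id = {
        (c.patient, c.call_id): c for c in cohort.all_calls()
    }
    for pid, cls in clusters.items():
        classify_clusters(
            cls, {cid: calls_by_id[(pid, cid)] for cid in
                  [m for cl in cls for m in cl.member_ids]}
        )
    cluster_rows = [
        {
            "patient": cl.patient,
            "cluster_id": cl.cluster_id,
            "cls": cl.cls,
            "n_members": cl.n_members,
            "members": ",".join(cl.member_ids),
        }
        for pid in cohort.patients
        for cl in clusters[pid]
    ]
    cluster_df = pd.DataFrame(
        cluster_rows, columns=["patient", "cluster_id", "cls", "n_members", "members"]
    ).set_index(["patient", "cluster_id"])
    _write(cluster_df, out / "clusters.tsv")
    manifest["stages"]["footprints"] = {"clusters": len(cluster_df),
                                        "me_insertions": len(all_ins)}

    # ---- catalogue + signatures
    catalogue = build_catalogue(cohort, clusters)
    _write(catalogue.counts, out / "catalogue.tsv")
    sig_manifest = {"catalogue_channels": len(catalogue.counts)}
    if catalogue.counts.to_numpy().any() and cohort.n_patients >= config.kmax:
        model = extract_signatures(
            catalogue,
            kmin=config.kmin,
            kmax=config.kmax,
            iters=config.nmf_iters,
            replicates=config.nmf_replicates,
            seed=config.seed,
        )
        _write(model.W, out / "signatures.tsv")
        _write(model.H, out / "exposures.tsv")
        _write(model.scores, out / "signature_scores.tsv")
        sig_manifest["k"] = model.k
        if config.reference_signatures is not None:
            ref = read_matrix(config.reference_signatures)
            assignment = match_reference(model.W, ref)
            _write(assignment.set_index("signature"), out / "signature_match.tsv")
        groups = consensus_group(
            model.H,
            Kmax=min(config.kmax, cohort.n_patients - 1),
            resamples=config.consensus_resamples,
            seed=config.seed,
        )
        gdf = pd.DataFrame(
            {"patient": list(groups.labels), "group": list(groups.labels.values())}
        ).set_index("patient")
        _write(gdf, out / "patient_groups.tsv")
        sig_manifest["K"] = groups.K
    manifest["stages"]["signatures"] = sig_manifest

    # ---- bins + hotspots
    bins = make_bins(config.genome, config.bin_width, config.bin_step)
    fragile = (
        read_regions(config.fragile_sites) if config.fragile_sites else []
    )
    bintable = bin_breakpoint_stats(
        cohort,
        bins,
        covariates=truth.covariates if truth is not None and
        config.bin_width == config.bin_step else None,
        fragile_regions=fragile,
        density_quantile=config.density_quantile,
    )
    _write(bintable.frame(), out / "bintable.tsv")
    if bintable.covariates is not None and len(bins) >= 50:
        ctx = fit_context_model(bintable, threshold=config.residual_threshold)
        ctx_df = bintable.frame()
        ctx_df["resid_std"] = ctx.resid_std
        ctx_df["context_flag"] = ctx.flags
        _write(ctx_df, out / "context_model.tsv")
    focal = focal_hotspots(
        bintable, threshold=config.residual_threshold, seed=config.seed
    )
    _write(focal, out / "hotspot_calls.tsv")
    flagged = [bintable.bins[i] for i, b in enumerate(bintable.bins)
               if b.index in set(focal.index[focal["consensus"]])]
    regions = merge_bins_to_regions(flagged)
    rdf = pd.DataFrame(
        [
            {"region": r.name, "chrom": r.chrom, "start": r.start, "end": r.end}
            for r in regions
        ],
        columns=["region", "chrom", "start", "end"],
    ).set_index("region")
    _write(rdf, out / "regions.tsv")
    manifest["stages"]["hotspots"] = {
        "bins": len(bins),
        "consensus_bins": int(focal["consensus"].sum()),
        "regions": len(regions),
    }

    # ---- drivers
    if config.gene_models is not None:
        cancer = (
            read_gene_list(config.cancer_genes) if config.cancer_genes else set()
        )
        genes = read_gene_models(config.gene_models, cancer_genes=cancer)
        spans = spans_for_cohort(cohort)
        hits = gene_hits(spans, genes)
        _write(hits, out / "gene_hits.tsv")
        drv_manifest = {"genes": len(genes), "hit_genes": int(hits.any().sum())}
        if config.prior_alterations is not None:
            prior = read_matrix(config.prior_alterations)
            tallies = tally_recurrence(prior, hits, cohort.n_patients)
            test = recurrence_test(tallies)
            _write(test.set_index("gene"), out / "driver_recurrence.tsv")
            drv_manifest["tested_genes"] = len(test)
        manifest["stages"]["drivers"] = drv_manifest

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# Config file loading (flat YAML key-value)


def load_config(path, outdir: Optional[Path] = None) -> PipelineConfig:
    """Load a flat YAML config; see PipelineConfig for recognized keys.

    The genome is given as ``chromosomes: {name: length}`` plus an
    optional ``excluded`` BED path; a ``simulate`` mapping is forwarded
    to SimParams (gene/ME specs are library-level constructs and are
    configured in code).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    chroms = raw.pop("chromosomes", None)
    if not chroms:
        raise ValueError("config must define chromosomes: {name: length}")
    names = list(chroms)
    excluded = []
    excl_path = raw.pop("excluded", None)
    genome = GenomeDef(names=names, lengths={k: int(v) for k, v in chroms.items()},
                       excluded=excluded)
    if excl_path:
        genome.excluded.extend(read_regions(excl_path, genome=genome))
    sim_raw = raw.pop("simulate", None)
    sim = None
    if sim_raw:
        sim = SimParams(genome=genome, **sim_raw)
    path_keys = (
        "sv_calls", "panel", "gene_models", "cancer_genes", "fragile_sites",
        "reference_signatures", "prior_alterations",
    )
    kwargs = {}
    for k, v in raw.items():
        kwargs[k] = Path(v) if k in path_keys and v is not None else v
    out = Path(outdir) if outdir is not None else Path(kwargs.pop("outdir", "results"))
    kwargs.pop("outdir", None)
    return PipelineConfig(outdir=out, genome=genome, simulate=sim, **kwargs)
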