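"""SV spans, exon-hit counting, recurrence testing and overlap analyses."""

import numpy as np
import pandas as pd
import pytest

from svselect import (
    Breakend,
    Cohort,
    DriverTally,
    GeneModel,
    GenomeDef,
    Interval,
    SVCall,
    candidate_driver_filter,
    gene_hits,
    gene_sv_profile,
    locus_feature_overlap,
    permutation_overlap_test,
    recurrence_test,
    rs_group_bin_enrichment,
    sv_spans,
    two_proportion_test,
)
from svselect.core import FootprintCluster
from svselect.drivers import SVSpan
from svselect.hotspots import BinTable
from svselect.io import make_bins


def _del(cid, lo, hi, patient="P1", chrom="chr1"):
    return SVCall.make(
        cid, patient, Breakend(chrom, lo, "+"), Breakend(chrom, hi, "-")
    )


class TestSpans:
    def test_intra_span_is_breakpoint_interval(self):
        s = sv_spans(_del("a", 1000, 5000))
        assert s.intervals == (Interval("chr1", 1000, 5000, "a"),)

    def test_bnd_zero_window_two_point_intervals(self):
        c = SVCall.make("a", "P1", Breakend("chr1", 100, "+"), Breakend("chr2", 200, "-"))
        s = sv_spans(c, bnd_window_bp=0)
        assert len(s.intervals) == 2
        assert all(iv.length == 1 for iv in s.intervals)

    def test_swapped_breakends_same_interval(self):
        c1 = SVCall.make("a", "P1", Breakend("chr1", 5000, "+"), Breakend("chr1", 100, "+"))
        c2 = SVCall.make("a", "P1", Breakend("chr1", 100, "+"), Breakend("chr1", 5000, "+"))
        assert sv_spans(c1).intervals == sv_spans(c2).intervals


def _brute_force_hits(spans_by_patient, genes):
    """Per-base membership oracle."""
    hits = set()
    for pid, spans in spans_by_patient.items():
        for g in genes:
            for span in spans:
                for iv in span.intervals:
                    if iv.chrom != g.chrom:
                        continue
                    bases = set(range(iv.start, iv.end + 1))
                    for s, e in g.exons:
                        if bases & set(range(s, e + 1)):
                            hits.add((pid, g.symbol))
    return hits


class TestGeneHits:
    def test_span_covering_gene_hits(self, toy_gene):
        hits = gene_hits({"P1": [sv_spans(_del("a", 50_000, 400_000))]}, [toy_gene])
        assert bool(hits.loc["P1", "TSG1"])

    def test_intronic_span_no_hit(self, toy_gene):
        # entirely between exon 1 (ends 100,500) and exon 2 (starts 200,000)
        hits = gene_hits({"P1": [sv_spans(_del("a", 120_000, 150_000))]}, [toy_gene])
        assert not hits.loc["P1", "TSG1"]

    def test_matches_per_base_oracle_on_random_toys(self, rng):
        for _ in range(30):
            genes = []
            for gi in range(4):
                start = int(rng.integers(1, 5000))
                exons = []
                pos = start
                for _e in range(int(rng.integers(1, 4))):
                    w = int(rng.integers(1, 200))
                    exons.append((pos, pos + w))
                    pos += w + int(rng.integers(50, 400))
                genes.append(
                    GeneModel(f"G{gi}", "T", "chr1", "+", exons, cancer_gene=True)
                )
            spans = {}
            for pid in ("P1", "P2", "P3"):
                spans[pid] = []
                for si in range(int(rng.integers(0, 5))):
                    lo = int(rng.integers(1, 6000))
                    spans[pid].append(
                        SVSpan(f"{pid}s{si}",
                               (Interval("chr1", lo, lo + int(rng.integers(1, 500))),))
                    )
            table = gene_hits(spans, genes)
            got = {
                (p, g) for p in table.index for g in table.columns if table.loc[p, g]
            }
            assert got == _brute_force_hits(spans, genes)


class TestRecurrenceTest:
    def test_no_enrichment_large_p(self):
        df = recurrence_test([DriverTally("G", 100, 100, 383)])
        assert df["p"].iloc[0] >= 0.5

    def test_matches_r_prop_test(self):
        # frozen from R: prop.test(c(165, 96), c(383, 383),
        # alternative="greater") -> p = 1.086415899e-07
        _, p = two_proportion_test(165, 383, 96, 383, alternative="greater")
        assert p == pytest.approx(1.086415899e-07, rel=1e-8)
        _, p_nocc = two_proportion_test(
            165, 383, 96, 383, alternative="greater", continuity=False
        )
        assert p_nocc == pytest.approx(7.197179252e-08, rel=1e-8)

    def test_bh_q_dominates_p_and_monotone(self, rng):
        tallies = []
        for i in range(48):
            without = int(rng.integers(5, 120))
            extra = int(rng.integers(0, 40))
            tallies.append(DriverTally(f"G{i}", without, without + extra, 383))
        df = recurrence_test(tallies)
        assert (df["q"] >= df["p"] - 1e-12).all()
        srt = df.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_invalid_tally_rejected(self):
        with pytest.raises(ValueError):
            DriverTally("G", 10, 5, 383)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 0, 0, 0)


class TestCandidateFilter:
    def _setup(self, toy_gene):
        region = [Interval("chr1", 50_000, 400_000, "region1")]
        spans = {"P1": [sv_spans(_del("a", 99_000, 101_000))]}
        return region, spans

    def test_hit_cancer_gene_returned(self, toy_gene):
        region, spans = self._setup(toy_gene)
        out = candidate_driver_filter(region, [toy_gene], [], spans)
        assert out == ["TSG1"]

    def test_gene_without_exon_hit_excluded(self, toy_gene):
        region, _ = self._setup(toy_gene)
        spans = {"P1": [sv_spans(_del("a", 120_000, 150_000))]}  # intronic
        assert candidate_driver_filter(region, [toy_gene], [], spans) == []

    def test_fragile_site_gene_excluded(self, toy_gene):
        region, spans = self._setup(toy_gene)
        fragile = [Interval("chr1", 1, 1_000_000)]
        assert candidate_driver_filter(region, [toy_gene], fragile, spans) == []

    def test_non_cancer_gene_excluded(self, toy_gene):
        region, spans = self._setup(toy_gene)
        toy_gene.cancer_gene = False
        assert candidate_driver_filter(region, [toy_gene], [], spans) == []

    def test_output_subset_of_flagged_genes_in_regions(self, toy_gene):
        region, spans = self._setup(toy_gene)
        out = candidate_driver_filter(region, [toy_gene], [], spans)
        assert set(out) <= {g.symbol for g in [toy_gene] if g.cancer_gene}


class TestGeneProfile:
    def test_simple_del_counted(self, toy_gene):
        call = _del("a", 99_000, 101_000)
        cohort = Cohort.from_calls([call])
        clusters = {
            "P1": [FootprintCluster("P1", 1, ["a"], "simple")]
        }
        prof = gene_sv_profile(toy_gene, cohort, clusters)
        assert prof.to_dict("records") == [
            {"patient": "P1", "cls": "simple", "svtype": "DEL", "n": 1}
        ]

    def test_complex_cluster_members_counted_individually(self, toy_gene):
        calls = [
            _del("a", 99_000, 101_000),
            _del("b", 199_000, 201_000),
            _del("c", 900_000, 950_000),  # no exon overlap
        ]
        cohort = Cohort.from_calls(calls)
        clusters = {"P1": [FootprintCluster("P1", 1, ["a", "b", "c"], "complex")]}
        prof = gene_sv_profile(toy_gene, cohort, clusters)
        assert prof["n"].sum() == 2
        assert (prof["cls"] == "complex").all()

    def test_no_overlap_empty(self, toy_gene):
        cohort = Cohort.from_calls([_del("a", 900_000, 950_000)])
        clusters = {"P1": [FootprintCluster("P1", 1, ["a"], "simple")]}
        assert gene_sv_profile(toy_gene, cohort, clusters).empty


class TestGroupEnrichment:
    def _table(self, counts):
        g = GenomeDef.uniform(1, len(counts) * 1_000_000)
        bins = make_bins(g, 1_000_000, 1_000_000)
        return BinTable(
            bins=bins,
            patients=[f"P{i}" for i in range(counts.shape[1])],
            counts=counts,
        )

    def test_identical_groups_nothing_enriched(self):
        counts = np.tile([[1, 1, 1, 1]], (5, 1))
        t = self._table(np.array(counts))
        out = rs_group_bin_enrichment(t, ["P0", "P1"], ["P2", "P3"])
        assert out.empty

    def test_differential_bin_returned(self):
        counts = np.zeros((5, 20), dtype=int)
        counts[2, :4] = 1  # 40% of group A (P0..P9), none of B
        counts[2, 1] = 1
        t = self._table(counts)
        a = [f"P{i}" for i in range(10)]
        b = [f"P{i}" for i in range(10, 20)]
        out = rs_group_bin_enrichment(t, a, b, min_diff=0.15)
        assert list(out["bin"]) == [2]
        assert out["freq_a"].iloc[0] == pytest.approx(0.4)
        assert out["freq_b"].iloc[0] == pytest.approx(0.0)

    def test_fragile_bins_excluded(self):
        counts = np.zeros((5, 4), dtype=int)
        counts[1, :2] = 1
        t = self._table(counts)
        t.fragile[1] = True
        out = rs_group_bin_enrichment(t, ["P0", "P1"], ["P2", "P3"])
        assert out.empty

    def test_empty_group_rejected(self):
        t = self._table(np.zeros((5, 2), dtype=int))
        with pytest.raises(ValueError):
            rs_group_bin_enrichment(t, [], ["P0"])


class TestLocusFeatures:
    FEATURES = [
        Interval("chr1", 1000, 2000, "enhancer"),
        Interval("chr1", 5000, 5600, "runt_exons"),
        Interval("chr1", 9000, 9100, "promoter2"),
    ]

    def test_deletion_covering_all_counts_everywhere(self):
        spans = {"P1": [sv_spans(_del("a", 500, 10_000))]}
        out = locus_feature_overlap(spans, self.FEATURES)
        assert list(out["n_patients"]) == [1, 1, 1]

    def test_deletion_between_features_counts_nowhere(self):
        spans = {"P1": [sv_spans(_del("a", 2500, 4500))]}
        out = locus_feature_overlap(spans, self.FEATURES)
        assert list(out["n_patients"]) == [0, 0, 0]

    def test_matches_brute_force_matrix(self, rng):
        for _ in range(20):
            spans = {}
            for pid in [f"P{i}" for i in range(5)]:
                spans[pid] = []
                for si in range(int(rng.integers(0, 4))):
                    lo = int(rng.integers(1, 12_000))
                    spans[pid].append(
                        SVSpan(f"{pid}s{si}",
                               (Interval("chr1", lo, lo + int(rng.integers(1, 3000))),))
                    )
            out = locus_feature_overlap(spans, self.FEATURES)
            for _, row in out.iterrows():
                feat = [f for f in self.FEATURES if f.name == row["feature"]][0]
                brute = sum(
                    any(
                        set(range(iv.start, iv.end + 1))
                        & set(range(feat.start, feat.end + 1))
                        for sp in spans[pid]
                        for iv in sp.intervals
                    )
                    for pid in spans
                )
                assert row["n_patients"] == brute


class TestPermutationOverlap:
    GENOME = GenomeDef(names=["chr1"], lengths={"chr1": 4_000_000})

    def test_empty_targets_p_one(self):
        out = permutation_overlap_test(
            [Interval("chr1", 100, 200)], [], self.GENOME, n_perm=100, seed=1
        )
        assert out["observed"] == 0 and out["p"] == 1.0

    def test_full_coverage_targets_p_one(self):
        out = permutation_overlap_test(
            [Interval("chr1", 100, 200)],
            [Interval("chr1", 1, 4_000_000)],
            self.GENOME,
            n_perm=200,
            seed=1,
        )
        assert out["observed"] == 1 and out["p"] == 1.0

    def test_p_converges_to_placement_probability(self):
        # single 1 bp query, target [1M+1, 2M]: placement probability 1/4
        target = [Interval("chr1", 1_000_001, 2_000_000)]
        query = [Interval("chr1", 1_500_000, 1_500_000)]
        out = permutation_overlap_test(query, target, self.GENOME, n_perm=20_000, seed=3)
        assert out["observed"] == 1
        assert out["p"] == pytest.approx(0.25, abs=0.02)
        assert out["expected"] == pytest.approx(0.25, abs=0.02)

    def test_min_p_bound_and_halving(self):
        target = [Interval("chr1", 3_999_999, 4_000_000)]
        query = [Interval("chr1", 3_999_999, 4_000_000)]
        for n_perm in (500, 1000):
            out = permutation_overlap_test(query, target, self.GENOME, n_perm=n_perm,
                                           seed=5)
            assert out["p"] >= 1 / (n_perm + 1)

    def test_oversized_region_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            permutation_overlap_test(
                [Interval("chr1", 1, 4_000_001)], [], self.GENOME
            )
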