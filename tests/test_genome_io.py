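"""Data model, format round trips, binning, panel filtering and matching."""

import warnings

import pytest
from hypothesis import given
from hypothesis import strategies as st

from svselect import (
    Breakend,
    GenomeDef,
    Interval,
    SVCall,
    classify_sv_type,
    filter_panel,
    make_bins,
    match_callsets,
    read_gene_models,
    read_regions,
    read_sv_bedpe,
    read_sv_vcf,
    write_sv_bedpe,
)
from svselect.io import ParseError, write_gene_models, write_regions


def _call(cid, c1, p1, o1, c2, p2, o2, svtype=None, patient="P1"):
    return SVCall.make(cid, patient, Breakend(c1, p1, o1), Breakend(c2, p2, o2), svtype)


class TestClassify:
    @pytest.mark.parametrize(
        "o1,o2,expected",
        [("+", "-", "DEL"), ("-", "+", "DUP"), ("+", "+", "INV"), ("-", "-", "INV")],
    )
    def test_intra_orientations(self, o1, o2, expected):
        assert classify_sv_type(
            Breakend("chr1", 100, o1), Breakend("chr1", 5100, o2)
        ) == expected

    def test_interchromosomal_is_bnd(self):
        assert classify_sv_type(
            Breakend("chr1", 100, "+"), Breakend("chr2", 200, "-")
        ) == "BND"

    @given(
        p1=st.integers(1, 10**6),
        p2=st.integers(1, 10**6),
        o1=st.sampled_from("+-"),
        o2=st.sampled_from("+-"),
    )
    def test_swap_invariance(self, p1, p2, o1, o2):
        a, b = Breakend("chr1", p1, o1), Breakend("chr1", p2, o2)
        assert classify_sv_type(a, b) == classify_sv_type(b, a)


class TestSVCall:
    def test_normalization_orders_intra_breakends(self):
        c = _call("s1", "chr1", 5000, "-", "chr1", 1000, "+")
        assert (c.a.pos, c.b.pos) == (1000, 5000)
        assert c.svtype == "DEL"
        assert c.span_length == 4000

    def test_bnd_iff_different_chromosomes(self):
        with pytest.raises(ValueError):
            SVCall("x", "P1", Breakend("chr1", 1, "+"), Breakend("chr2", 2, "-"), "DEL")
        with pytest.raises(ValueError):
            SVCall("x", "P1", Breakend("chr1", 1, "+"), Breakend("chr1", 2, "-"), "BND")

    def test_span_undefined_for_bnd(self):
        c = _call("s1", "chr1", 100, "+", "chr2", 200, "-")
        assert c.svtype == "BND" and c.span_length is None


class TestBedpe:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bedpe"
        p.write_text("")
        assert read_sv_bedpe(p) == []

    def test_single_record_coordinates_and_span(self, tmp_path):
        p = tmp_path / "one.bedpe"
        p.write_text("chr1\t99\t100\tchr1\t5099\t5100\tsv1\t.\t+\t-\tP1\tDEL\n")
        (call,) = read_sv_bedpe(p)
        assert (call.a.pos, call.b.pos) == (100, 5100)
        assert call.svtype == "DEL"
        assert call.span_length == 5000
        assert call.patient == "P1"

    def test_three_records_one_bnd(self, tmp_path):
        p = tmp_path / "three.bedpe"
        p.write_text(
            "chr1\t99\t100\tchr1\t5099\t5100\tsv1\t.\t+\t-\tP1\tDEL\n"
            "chr2\t199\t200\tchr2\t999\t1000\tsv2\t.\t-\t+\tP1\tDUP\n"
            "chr1\t299\t300\tchr2\t399\t400\tsv3\t.\t+\t-\tP1\t.\n"
        )
        calls = read_sv_bedpe(p)
        assert len(calls) == 3
        assert sum(c.svtype == "BND" for c in calls) == 1
        # field-by-field check of the derived-type record
        bnd = [c for c in calls if c.svtype == "BND"][0]
        assert (bnd.a.chrom, bnd.a.pos, bnd.b.chrom, bnd.b.pos) == (
            "chr1", 300, "chr2", 400,
        )

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text(
            "chr1\t99\t100\tchr1\t5099\t5100\tsv1\t.\t+\t-\tP1\tDEL\n"
            "chr1\tnotanint\t100\tchr1\t1\t2\tsv2\t.\t+\t-\tP1\tDEL\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_sv_bedpe(p)

    def test_unknown_chromosome_reported_not_dropped_silently(self, tmp_path):
        genome = GenomeDef.uniform(1, 10_000_000)
        p = tmp_path / "unk.bedpe"
        p.write_text("chrZ\t99\t100\tchrZ\t5099\t5100\tsv1\t.\t+\t-\tP1\tDEL\n")
        with pytest.warns(UserWarning, match="rejected 1"):
            calls = read_sv_bedpe(p, genome=genome)
        assert calls == []

    def test_round_trip_identity(self, tmp_path):
        calls = [
            _call("a", "chr1", 100, "+", "chr1", 5100, "-"),
            _call("b", "chr1", 10, "-", "chr2", 99, "+"),
            _call("c", "chr3", 7, "-", "chr3", 9000, "+"),
        ]
        p = tmp_path / "rt.bedpe"
        write_sv_bedpe(calls, p)
        back = read_sv_bedpe(p)
        assert [
            (c.call_id, c.a.chrom, c.a.pos, c.a.orient, c.b.chrom, c.b.pos,
             c.b.orient, c.svtype)
            for c in back
        ] == [
            (c.call_id, c.a.chrom, c.a.pos, c.a.orient, c.b.chrom, c.b.pos,
             c.b.orient, c.svtype)
            for c in calls
        ]


class TestPanelFilter:
    def test_empty_panel_no_flags(self):
        calls = [_call("a", "chr1", 1000, "+", "chr1", 2000, "-")]
        filter_panel(calls, [])
        assert not calls[0].blacklisted

    def test_both_breakends_within_window_flags(self):
        calls = [_call("a", "chr1", 1000, "+", "chr1", 2000, "-")]
        panel = [_call("p", "chr1", 1250, "+", "chr1", 2100, "-", patient="N")]
        filter_panel(calls, panel, window_bp=300)
        assert calls[0].blacklisted

    def test_offset_beyond_window_not_flagged(self):
        calls = [_call("a", "chr1", 1000, "+", "chr1", 2000, "-")]
        panel = [_call("p", "chr1", 1250, "+", "chr1", 2100, "-", patient="N")]
        filter_panel(calls, panel, window_bp=100)
        assert not calls[0].blacklisted

    def test_type_mismatch_never_flags(self):
        calls = [_call("a", "chr1", 1000, "+", "chr1", 2000, "-")]  # DEL
        panel = [_call("p", "chr1", 1000, "-", "chr1", 2000, "+", patient="N")]  # DUP
        filter_panel(calls, panel, window_bp=300)
        assert not calls[0].blacklisted

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            filter_panel([], [], window_bp=-1)

    @given(
        offsets=st.lists(
            st.tuples(st.integers(-400, 400), st.integers(-400, 400)),
            min_size=1,
            max_size=8,
        ),
        w_small=st.integers(0, 300),
        w_extra=st.integers(0, 300),
    )
    def test_flags_monotone_in_window(self, offsets, w_small, w_extra):
        calls = [
            _call(f"a{i}", "chr1", 10_000 + d1, "+", "chr1", 20_000 + d2, "-")
            for i, (d1, d2) in enumerate(offsets)
        ]
        panel = [_call("p", "chr1", 10_000, "+", "chr1", 20_000, "-", patient="N")]
        filter_panel(calls, panel, window_bp=w_small)
        small = [c.blacklisted for c in calls]
        filter_panel(calls, panel, window_bp=w_small + w_extra)
        large = [c.blacklisted for c in calls]
        assert all(l or not s for s, l in zip(small, large))


class TestMatchCallsets:
    def _five(self, jitter=0):
        return [
            _call(f"b{i}", "chr1", 1000 * i + 10 + jitter, "+",
                  "chr1", 1000 * i + 500 + jitter, "-")
            for i in range(1, 6)
        ]

    def test_identical_sets_perfect(self):
        b = self._five()
        r = match_callsets(b, b, window_bp=300)
        assert (r.precision, r.sensitivity, r.f1) == (1.0, 1.0, 1.0)

    def test_four_of_five_plus_spurious(self):
        b = self._five()
        a = b[:4] + [_call("x", "chr2", 77, "+", "chr2", 999, "-")]
        r = match_callsets(a, b, window_bp=300)
        assert r.precision == pytest.approx(0.8)
        assert r.sensitivity == pytest.approx(0.8)

    def test_zero_window_with_jitter_matches_nothing(self):
        r = match_callsets(self._five(), self._five(jitter=1), window_bp=0)
        assert r.n_matched == 0

    def test_both_empty_is_perfect_by_convention(self):
        r = match_callsets([], [], window_bp=300)
        assert (r.precision, r.sensitivity, r.f1) == (1.0, 1.0, 1.0)

    @given(w=st.integers(0, 1000))
    def test_self_match_perfect_for_any_window(self, w):
        b = self._five()
        r = match_callsets(b, b, window_bp=w)
        assert (r.precision, r.sensitivity, r.f1) == (1.0, 1.0, 1.0)


class TestMakeBins:
    def test_single_bin_for_width_sized_chromosome(self):
        g = GenomeDef(names=["c"], lengths={"c": 1_000_000})
        bins = make_bins(g)
        assert [(b.start, b.end) for b in bins] == [(0, 1_000_000)]

    def test_two_chromosomes_counts_and_unique_indices(self):
        g = GenomeDef(names=["c1", "c2"], lengths={"c1": 3_000_000, "c2": 2_000_000})
        bins = make_bins(g)
        per = {"c1": 0, "c2": 0}
        for b in bins:
            per[b.chrom] += 1
        assert per == {"c1": 5, "c2": 3}
        assert sorted(b.index for b in bins) == list(range(8))

    def test_truncated_final_bin_covers_chromosome_end(self):
        g = GenomeDef(names=["c"], lengths={"c": 1_200_000})
        bins = make_bins(g)
        assert bins[-1].end == 1_200_000
        assert max(b.end for b in bins) == 1_200_000

    def test_step_larger_than_width_rejected(self):
        g = GenomeDef(names=["c"], lengths={"c": 3_000_000})
        with pytest.raises(ValueError):
            make_bins(g, width=1_000_000, step=2_000_000)

    def test_coverage_once_everywhere_twice_interior(self):
        g = GenomeDef(names=["c"], lengths={"c": 3_000_000})
        bins = make_bins(g)  # width = 2 * step
        probe = list(range(1, 3_000_001, 9973))
        for pos in probe:
            n = sum(b.contains(pos) for b in bins)
            if 500_000 < pos <= 2_500_000:
                assert n == 2, pos
            else:
                assert n == 1, pos


class TestRegionsAndGenes:
    def test_bed_line_converted_to_one_based_closed(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t0\t100\n")
        (iv,) = read_regions(p)
        assert (iv.start, iv.end) == (1, 100)

    def test_empty_bed(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert read_regions(p) == []

    def test_region_round_trip(self, tmp_path):
        regs = [Interval("chr1", 1, 100, "a"), Interval("chr2", 501, 900, "b")]
        p = tmp_path / "rt.bed"
        write_regions(regs, p)
        assert read_regions(p) == regs

    def test_bed12_three_blocks_to_three_exons(self, tmp_path):
        p = tmp_path / "g.bed"
        # blocks at offsets 0, 500, 1400 with sizes 100, 200, 100
        p.write_text(
            "chr1\t1000\t2500\tGENE1:TX1\t0\t+\t1000\t2500\t0\t3\t"
            "100,200,100\t0,500,1400\n"
        )
        (g,) = read_gene_models(p, cancer_genes={"GENE1"})
        assert g.symbol == "GENE1" and g.transcript == "TX1" and g.cancer_gene
        assert g.exons == [(1001, 1100), (1501, 1700), (2401, 2500)]

    def test_gene_model_round_trip(self, tmp_path, toy_gene):
        p = tmp_path / "g.bed"
        write_gene_models([toy_gene], p)
        (back,) = read_gene_models(p, cancer_genes={"TSG1"})
        assert back.exons == toy_gene.exons
        assert back.symbol == toy_gene.symbol

    def test_out_of_genome_region_reported(self, tmp_path):
        g = GenomeDef.uniform(1, 1000)
        p = tmp_path / "r.bed"
        p.write_text("chr1\t0\t100\nchr1\t500\t5000\n")
        with pytest.warns(UserWarning, match="rejected 1"):
            regs = read_regions(p, genome=g)
        assert len(regs) == 1


class TestVcf:
    def _write_vcf(self, path, body):
        header = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n'
            '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate">\n'
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type">\n'
            "##contig=<ID=chr1,length=10000000>\n"
            "##contig=<ID=chr2,length=10000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        path.write_text(header + body)

    def test_symbolic_del_and_bnd_pair(self, tmp_path):
        p = tmp_path / "sv.vcf"
        self._write_vcf(
            p,
            "chr1\t1000\tdel1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=5000\n"
            "chr1\t2000\tbnd1:0\tN\tN[chr2:3000[\t.\tPASS\tSVTYPE=BND;MATEID=bnd1:1\n"
            "chr2\t3000\tbnd1:1\tN\t]chr1:2000]N\t.\tPASS\tSVTYPE=BND;MATEID=bnd1:0\n",
        )
        calls = read_sv_vcf(p, patient="P1")
        assert sorted(c.svtype for c in calls) == ["BND", "DEL"]
        bnd = [c for c in calls if c.svtype == "BND"][0]
        assert {be.chrom for be in bnd.breakends()} == {"chr1", "chr2"}
        assert {be.orient for be in bnd.breakends()} == {"+", "-"}

    def test_complex_record_rejected_with_report(self, tmp_path):
        p = tmp_path / "sv.vcf"
        self._write_vcf(
            p,
            "chr1\t2000\tlone:0\tN\tN[chr2:3000[\t.\tPASS\tSVTYPE=BND;MATEID=lone:1\n",
        )
        with pytest.warns(UserWarning, match="rejected"):
            calls = read_sv_vcf(p, patient="P1")
        assert calls == []
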