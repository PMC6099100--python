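import numpy as np
import pytest
from hypothesis import given, strategies as st

from coreskew.genome_model import reverse_complement
from coreskew.skew_terminus import (
    SkewCurve,
    base_skew_cumulative,
    base_skew_cumulative_cds3,
    coding_density_cumulative,
    combined_skew,
    detect_terminal_region,
    locate_terminus,
    strand_bias_row,
    terminus_locus_listing,
    assign_replichores,
    TerminusCall,
)
from conftest import cds, make_genome


class TestBaseSkew:
    def test_symmetric_sequence_returns_to_zero(self):
        c = base_skew_cumulative("GGGCCC", "GC", stride=1)
        assert list(c.values) == [1, 2, 3, 2, 1, 0]

    def test_pure_g_run(self):
        c = base_skew_cumulative("GGGG", "GC", stride=1)
        assert c.values[-1] == 4

    def test_ta_alternation(self):
        c = base_skew_cumulative("TATA", "TA", stride=1)
        assert list(c.values) == [1, 0, 1, 0]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            base_skew_cumulative("", "GC")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_telescoping_final_value(self, seq):
        gc = base_skew_cumulative(seq, "GC", stride=50)
        ta = base_skew_cumulative(seq, "TA", stride=50)
        assert gc.values[-1] == seq.count("G") - seq.count("C")
        assert ta.values[-1] == seq.count("T") - seq.count("A")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_reverse_complement_negates_final_skew(self, seq):
        for pair in ("GC", "TA"):
            fwd = base_skew_cumulative(seq, pair, stride=1).values[-1]
            rev = base_skew_cumulative(reverse_complement(seq), pair, stride=1).values[-1]
            assert fwd == -rev

    def test_stride_subsamples_but_keeps_final(self):
        seq = "G" * 2500
        c = base_skew_cumulative(seq, "GC", stride=1000)
        assert list(c.positions) == [1000, 2000, 2500]
        assert c.values[-1] == 2500

    def test_cds3_counts_only_third_positions(self):
        # one forward CDS of 2 codons: third positions are G (pos 2), C (pos 5)
        genome = make_genome("AAGAAC" + "GGGG", [cds("g1", 0, 6, +1)])
        c = base_skew_cumulative_cds3(genome, "GC", stride=1)
        assert c.values[-1] == 0  # +1 for G, -1 for C; trailing Gs masked


class TestCodingDensity:
    def test_mixed_strands(self):
        genes = [cds(f"g{i}", i * 10, i * 10 + 8, s) for i, s in enumerate([+1, +1, -1, +1])]
        c = coding_density_cumulative(genes)
        assert list(c.values) == [1, 2, 1, 2]

    def test_all_forward(self):
        genes = [cds(f"g{i}", i * 10, i * 10 + 8, +1) for i in range(10)]
        assert coding_density_cumulative(genes).values[-1] == 10

    def test_alternating_cancels(self):
        genes = [cds(f"g{i}", i * 10, i * 10 + 8, +1 if i % 2 else -1) for i in range(6)]
        assert coding_density_cumulative(genes).values[-1] == 0

    def test_unsorted_input_rejected(self):
        genes = [cds("g1", 20, 28), cds("g2", 0, 8)]
        with pytest.raises(ValueError, match="sorted"):
            coding_density_cumulative(genes)


class TestCombinedSkew:
    def test_single_curve_is_rescaled_copy(self):
        c = SkewCurve(np.array([1, 2, 3]), np.array([0.0, 5.0, 10.0]), "GC")
        out = combined_skew([c])
        assert np.allclose(out.values, [-1, 0, 1])

    def test_identical_curves_share_extremum(self):
        pos = np.arange(1, 101)
        vals = np.concatenate([np.arange(60), np.arange(60 - 2, 60 - 2 - 40, -1)]).astype(float)
        c1 = SkewCurve(pos, vals, "GC")
        c2 = SkewCurve(pos, vals, "TA")
        out = combined_skew([c1, c2])
        assert out.positions[np.argmax(out.values)] == pos[np.argmax(vals)]

    def test_flat_plus_peaked_keeps_peak_location(self):
        # flat GC contributes nothing; TA has a tent peak at x=70
        pos = np.arange(1, 101, dtype=float)
        flat = SkewCurve(pos, np.zeros(100), "GC")
        tent = SkewCurve(pos, -np.abs(pos - 70), "TA")
        out = combined_skew([flat, tent])
        assert out.positions[np.argmax(out.values)] == 70

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combined_skew([])


class TestLocateTerminus:
    def test_v_minimum_is_terminus(self):
        pos = np.arange(1000, 2_001_000, 1000, dtype=float)
        vals = np.abs(pos - 1_200_000)
        call = locate_terminus(SkewCurve(pos, vals, "combined"))
        assert call.terminus_bp == 1_200_000

    def test_lambda_maximum_is_terminus(self):
        pos = np.arange(1000, 2_001_000, 1000, dtype=float)
        vals = -np.abs(pos - 900_000)
        call = locate_terminus(SkewCurve(pos, vals, "combined"))
        assert call.terminus_bp == 900_000

    def test_constant_curve_is_no_signal(self):
        with pytest.raises(ValueError, match="no skew signal"):
            locate_terminus(SkewCurve(np.arange(1, 5.0), np.ones(4), "combined"))

    def test_tie_breaks_to_smallest_coordinate(self):
        pos = np.arange(1, 6, dtype=float)
        vals = np.array([0.0, 5.0, 0.0, 5.0, 0.0])
        call = locate_terminus(SkewCurve(pos, vals, "combined"))
        assert call.terminus_bp == 2  # first of the two equal maxima


class TestTerminalRegion:
    def _sharp_setup(self):
        """Sharp tent curve + deterministic strand flip at the apex."""
        L, ter = 200_000, 110_000
        pos = np.arange(1000, L + 1000, 1000, dtype=float)
        vals = -np.abs(pos - ter)
        curve = SkewCurve(pos, vals, "combined")
        genes = [
            cds(f"g{i:04d}", i * 500, i * 500 + 400, +1 if i * 500 + 200 < ter else -1)
            for i in range(L // 500)
        ]
        return curve, genes

    def test_sharp_terminus_stays_point(self):
        curve, genes = self._sharp_setup()
        call = detect_terminal_region(curve, genes)
        assert not call.is_region
        assert call.region[1] - call.region[0] < 10_000

    def test_epsilon_zero_collapses_to_extremum(self):
        curve, genes = self._sharp_setup()
        call = detect_terminal_region(curve, genes, epsilon=0.0)
        assert call.region[0] == call.region[1] == call.terminus_bp

    def test_plateau_reported_as_region(self):
        # tent with a flat 60 kb top and unbiased genes across it
        L, ter, half = 400_000, 210_000, 30_000
        pos = np.arange(1000, L + 1000, 1000, dtype=float)
        vals = -np.maximum(np.abs(pos - ter) - half, 0.0)
        curve = SkewCurve(pos, vals, "combined")
        rng = np.random.default_rng(0)
        genes = []
        for i in range(L // 500):
            mid = i * 500 + 200
            if abs(mid - ter) <= half:
                strand = +1 if rng.random() < 0.5 else -1
            else:
                strand = +1 if mid < ter else -1
            genes.append(cds(f"g{i:04d}", i * 500, i * 500 + 400, strand))
        call = detect_terminal_region(curve, genes)
        width = call.region[1] - call.region[0]
        assert call.is_region
        assert 0.7 * 2 * half <= width <= 1.3 * 2 * half


class TestAssignReplichores:
    def _genome(self, gene_mid, strand, L=1000):
        g = cds("g1", gene_mid - 5, gene_mid + 5, strand)
        return make_genome("A" * L, [g])

    @pytest.mark.parametrize(
        "mid,strand,expected",
        [(250, +1, "right_fwd"), (250, -1, "right_rev"), (750, +1, "left_fwd"), (750, -1, "left_rev")],
    )
    def test_classes(self, mid, strand, expected):
        genome = self._genome(mid, strand)
        call = TerminusCall(terminus_bp=500, origin_bp=0)
        assert assign_replichores(genome, call) == {"g1": expected}

    def test_midpoint_at_terminus_goes_left_with_warning(self):
        genome = self._genome(500, +1)
        call = TerminusCall(terminus_bp=500, origin_bp=0)
        with pytest.warns(UserWarning, match="terminus"):
            out = assign_replichores(genome, call)
        assert out["g1"] == "left_fwd"

    def test_short_right_replichore_warns(self):
        genome = self._genome(100, +1)
        call = TerminusCall(terminus_bp=200, origin_bp=0)
        with pytest.warns(UserWarning, match="right replichore"):
            assign_replichores(genome, call)


class TestStrandBiasRow:
    def test_published_amylovorus_row(self):
        row = strand_bias_row(
            "Lam", {"right_fwd": 766, "right_rev": 247, "left_rev": 185, "left_fwd": 498}
        )
        assert row["total_coding_genes"] == 1696
        assert row["forward"] == 1264 and row["forward_pct"] == 74.5
        assert row["reverse"] == 432 and row["reverse_pct"] == 25.5

    def test_single_gene_is_all_forward(self):
        row = strand_bias_row("x", {"right_fwd": 1, "right_rev": 0, "left_rev": 0, "left_fwd": 0})
        assert row["forward_pct"] == 100.0

    @given(
        st.tuples(*[st.integers(0, 2000)] * 4).filter(lambda t: sum(t) > 0)
    )
    def test_percentages_sum_to_about_hundred(self, counts):
        rf, rr, lr, lf = counts
        row = strand_bias_row(
            "x", {"right_fwd": rf, "right_rev": rr, "left_rev": lr, "left_fwd": lf}
        )
        assert rf + rr + lr + lf == row["total_coding_genes"]
        assert row["forward"] + row["reverse"] == row["total_coding_genes"]
        assert 99.9 <= row["forward_pct"] + row["reverse_pct"] <= 100.1


class TestTerminusLocusListing:
    def _genome(self, n=10):
        genes = [cds(f"g{i}", i * 100, i * 100 + 90, +1, f"product {i}") for i in range(n)]
        return make_genome("A" * (100 * n), genes)

    def test_flanks_around_intergenic_terminus(self):
        genome = self._genome()
        call = TerminusCall(terminus_bp=495, origin_bp=0)  # between g4 and g5
        out = terminus_locus_listing(genome, call, flank_genes=2)
        assert [d["gene_id"] for d in out] == ["g3", "g4", "g5", "g6"]

    def test_flank_larger_than_gene_count_lists_all_once(self):
        genome = self._genome(4)
        call = TerminusCall(terminus_bp=250, origin_bp=0)
        out = terminus_locus_listing(genome, call, flank_genes=10)
        assert sorted(d["gene_id"] for d in out) == ["g0", "g1", "g2", "g3"]

    def test_gene_containing_terminus_listed_on_midpoint_side(self):
        genome = self._genome()
        call = TerminusCall(terminus_bp=460, origin_bp=0)  # inside g4, mid 445 < 460
        out = terminus_locus_listing(genome, call, flank_genes=1)
        sides = {d["gene_id"]: d["side"] for d in out}
        assert sides == {"g4": "before", "g5": "after"}
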