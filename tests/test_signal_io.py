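import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sumoscape.genome_model import GenomicInterval
from sumoscape.signal_io import (
    build_coverage,
    count_reads,
    normalize_depth,
    read_bed,
    rpkm,
    signal_matrix,
    window_signal,
    write_bed,
)

from .conftest import make_readset, uniform_coverage

SIZES = {"chr1": 10_000}


def iv(s, e, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, s, e, strand)


class TestBedIO:
    def test_three_column_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        [x] = read_bed(p)
        assert (x.chrom, x.start, x.end, x.strand) == ("chr1", 0, 100, ".")

    def test_roundtrip_random_intervals(self, tmp_path):
        rng = np.random.default_rng(0)
        ivs = [
            iv(int(s), int(s) + int(l) + 1, "-" if d else "+")
            for s, l, d in zip(
                rng.integers(0, 5_000, 1000), rng.integers(0, 300, 1000), rng.integers(0, 2, 1000)
            )
        ]
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        assert read_bed(p) == ivs

    def test_invalid_coordinates_report_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\t200\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)


class TestBuildCoverage:
    def test_fragment_mode_distributes_one_tag(self):
        rs = make_readset([iv(0, 200)])
        cov = build_coverage(rs, SIZES, bin_size=50, mode="fragment")
        assert np.allclose(cov.counts["chr1"]["+"][:4], 0.25)
        assert cov.counts["chr1"]["+"].sum() == pytest.approx(1.0)

    def test_5prime_mode_single_bin(self):
        rs = make_readset([iv(100, 130)])
        cov = build_coverage(rs, SIZES, bin_size=50, mode="5prime")
        assert cov.counts["chr1"]["+"][2] == 1.0
        assert cov.counts["chr1"]["+"].sum() == 1.0

    def test_5prime_minus_strand_uses_read_end(self):
        rs = make_readset([iv(100, 130, "-")])
        cov = build_coverage(rs, SIZES, bin_size=50, mode="5prime")
        assert cov.counts["chr1"]["-"][2] == 1.0  # 5' of a minus read = end-1

    def test_linearity(self):
        rs = make_readset([iv(70, 230)] * 7)
        cov1 = build_coverage(make_readset([iv(70, 230)]), SIZES, 50)
        cov7 = build_coverage(rs, SIZES, 50)
        assert np.allclose(cov7.counts["chr1"]["+"], 7 * cov1.counts["chr1"]["+"])

    def test_tag_conservation_both_modes(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 9_000, 500)
        ivs = [iv(int(s), int(s) + 120) for s in starts]
        for mode in ("fragment", "5prime"):
            cov = build_coverage(make_readset(ivs), SIZES, 50, mode)
            total = sum(a.sum() for d in cov.counts.values() for a in d.values())
            assert total == pytest.approx(500)

    def test_out_of_bounds_reads_warn(self):
        rs = make_readset([iv(9_990, 10_050)])
        with pytest.warns(UserWarning, match="clipped"):
            build_coverage(rs, SIZES, 50)


class TestNormalizeDepth:
    def test_scale_factor(self):
        cov = uniform_coverage({"chr1": 1000}, 1.0, total_reads=2e7)
        out = normalize_depth(cov)
        assert out.scale == pytest.approx(0.5)

    def test_identity_at_target_depth(self):
        cov = uniform_coverage({"chr1": 1000}, 1.0, total_reads=1e7)
        out = normalize_depth(cov)
        assert np.allclose(out.counts["chr1"]["+"], cov.counts["chr1"]["+"])

    def test_scaled_total_hits_target(self):
        rng = np.random.default_rng(2)
        ivs = [iv(int(s), int(s) + 30) for s in rng.integers(0, 9_000, 1234)]
        cov = build_coverage(make_readset(ivs), SIZES, 50, "5prime")
        out = normalize_depth(cov, 1e7)
        total = sum(a.sum() for d in out.counts.values() for a in d.values())
        assert total == pytest.approx(1e7, abs=1e-3)

    def test_zero_depth_errors(self):
        cov = uniform_coverage({"chr1": 1000}, 0.0, total_reads=0)
        with pytest.raises(ValueError):
            normalize_depth(cov)


class TestWindowSignal:
    def test_uniform_window(self):
        cov = uniform_coverage({"chr1": 1000}, 1.0)
        assert window_signal(cov, iv(100, 200)) == pytest.approx(100)

    def test_outside_region_zero(self):
        cov = uniform_coverage({"chr1": 1000}, 1.0)
        assert window_signal(cov, iv(10, 20, chrom="chrX")) == 0.0

    def test_partial_bin_prorating_matches_per_base_oracle(self):
        """Pro-rated bin fractions equal a per-base (bin_size=1) computation."""
        rng = np.random.default_rng(3)
        ivs = [iv(int(s), int(s) + 40) for s in rng.integers(0, 900, 300)]
        cov50 = build_coverage(make_readset(ivs), {"chr1": 1000}, 50, "5prime")
        cov1 = build_coverage(make_readset(ivs), {"chr1": 1000}, 1, "5prime")
        w_full = window_signal(cov50, iv(100, 150))
        w_half = window_signal(cov50, iv(100, 125))
        # uniform-within-bin assumption: half the bin carries half its tags
        assert w_half == pytest.approx(w_full / 2)
        # and full-bin-aligned windows agree exactly with the per-base oracle
        assert w_full == pytest.approx(window_signal(cov1, iv(100, 150)))

    def test_additivity_over_disjoint_windows(self):
        rng = np.random.default_rng(4)
        ivs = [iv(int(s), int(s) + 70) for s in rng.integers(0, 9_000, 400)]
        cov = build_coverage(make_readset(ivs), SIZES, 50)
        whole = window_signal(cov, iv(1_000, 4_000))
        parts = sum(window_signal(cov, iv(s, s + 500)) for s in range(1_000, 4_000, 500))
        assert parts == pytest.approx(whole)

    def test_sense_antisense_selection(self):
        cov = uniform_coverage({"chr1": 1000}, 1.0, strands=("+",))
        assert window_signal(cov, iv(0, 100, "-"), "sense") == 0.0
        assert window_signal(cov, iv(0, 100, "-"), "antisense") == pytest.approx(100)


class TestRpkm:
    def test_worked_example(self):
        assert rpkm(100, 2000, 1e7) == pytest.approx(5.0)

    def test_zero_count(self):
        assert rpkm(0, 2000, 1e7) == 0.0

    def test_depth_scaling_law(self):
        assert rpkm(100, 2000, 2e7) == pytest.approx(rpkm(100, 2000, 1e7) / 2)

    @pytest.mark.parametrize("length,total", [(0, 1e7), (100, 0)])
    def test_degenerate_inputs_error(self, length, total):
        with pytest.raises(ValueError):
            rpkm(10, length, total)


class TestSignalMatrix:
    def test_flat_row_on_uniform_coverage(self):
        cov = uniform_coverage({"chr1": 100_000}, 2.0)
        mat, prof, edge = signal_matrix([iv(50_000, 50_001)], cov, flank=500, bin=25)
        assert np.allclose(mat, 50.0)
        assert not edge.any()

    def test_planted_peak_profile_maximal_at_center(self):
        rng = np.random.default_rng(5)
        centers = rng.integers(20_000, 80_000, 30)
        reads = []
        for c in centers:
            offs = rng.normal(0, 80, 200).astype(int)
            reads += [iv(int(c + o) - 50, int(c + o) + 50) for o in offs]
        cov = build_coverage(make_readset(reads), {"chr1": 100_000}, 25)
        cents = [iv(int(c), int(c) + 1) for c in centers]
        _, prof, _ = signal_matrix(cents, cov, flank=500, bin=25)
        assert abs(int(np.argmax(prof)) - len(prof) // 2) <= 1

    def test_minus_strand_rows_are_flipped(self):
        """A signal asymmetric around the center flips for minus-strand rows."""
        reads = [iv(5_100 + i, 5_130 + i) for i in range(0, 200, 10)]  # right of center
        cov = build_coverage(make_readset(reads), SIZES, 25)
        mp, _, _ = signal_matrix([iv(5_000, 5_001, "+")], cov, 500, 25)
        mm, _, _ = signal_matrix([iv(5_000, 5_001, "-")], cov, 500, 25)
        assert np.allclose(mm[0], mp[0][::-1])

    def test_row_sum_equals_window_signal(self):
        rng = np.random.default_rng(6)
        ivs = [iv(int(s), int(s) + 60) for s in rng.integers(0, 9_000, 500)]
        cov = build_coverage(make_readset(ivs), SIZES, 25)
        center = iv(5_000, 5_001)
        mat, _, _ = signal_matrix([center], cov, flank=500, bin=25)
        assert mat[0].sum() == pytest.approx(window_signal(cov, iv(4_500, 5_500)))

    def test_edge_rows_flagged_and_padded(self):
        cov = uniform_coverage({"chr1": 1_000}, 1.0)
        mat, _, edge = signal_matrix([iv(100, 101)], cov, flank=500, bin=25)
        assert edge[0] and mat[0][0] == 0.0


class TestCountReads:
    @given(hst.integers(0, 900), hst.integers(1, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_naive_scan(self, start, width):
        rng = np.random.default_rng(9)
        ivs = [iv(int(s), int(s) + 25) for s in rng.integers(0, 975, 200)]
        rs = make_readset(ivs)
        q = iv(start, start + width)
        naive = sum(1 for r in ivs if r.start < q.end and q.start < r.end)
        assert count_reads(rs, q) == naive
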