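"""Track reading, normalization, algebra and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remodelscan.genomic_signal import (GenomicInterval, SignalTrack,
                                        TrackParseError, add_tracks,
                                        gaussian_kernel, gaussian_smooth,
                                        read_intervals, read_track,
                                        subtract_tracks, write_bedgraph,
                                        zscore_normalize)
from conftest import make_track


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadTrack:
    @pytest.mark.parametrize("record,expected", [
        ("chr1\t0\t30\t2.0", [2.0, 2.0, 2.0]),          # constant record
        ("chr1\t0\t15\t2.0", [2.0, 1.0]),               # half-covered 2nd bin
        ("chr1\t5\t15\t2.0", [1.0, 1.0]),               # straddling a boundary
    ])
    def test_bedgraph_rebinning(self, tmp_path, record, expected):
        path = write_lines(tmp_path / "t.bedGraph", [record])
        track = read_track(path, "bedGraph", bin_size=10)
        np.testing.assert_allclose(track.chrom_values["chr1"], expected)

    def test_fixedstep_identity_rebin(self, tmp_path):
        path = write_lines(tmp_path / "t.wig", [
            "fixedStep chrom=chr2 start=1 step=10 span=10",
            "1", "2", "3", "4", "5"])
        track = read_track(path, "wiggle", bin_size=10)
        np.testing.assert_allclose(track.chrom_values["chr2"], [1, 2, 3, 4, 5])

    def test_variablestep_and_coarse_replication(self, tmp_path):
        # span 20 coarser than 10-bp bins: value replicated over both bins
        path = write_lines(tmp_path / "t.wig", [
            "variableStep chrom=chr1 span=20", "1\t3.0"])
        track = read_track(path, "wiggle", bin_size=10)
        np.testing.assert_allclose(track.chrom_values["chr1"], [3.0, 3.0])

    def test_fine_steps_averaged(self, tmp_path):
        path = write_lines(tmp_path / "t.bedGraph", [
            "chr1\t0\t5\t2.0", "chr1\t5\t10\t4.0"])
        track = read_track(path, "bedGraph", bin_size=10)
        np.testing.assert_allclose(track.chrom_values["chr1"], [3.0])

    def test_overlapping_records_rejected(self, tmp_path):
        path = write_lines(tmp_path / "t.bedGraph", [
            "chr1\t0\t20\t1.0", "chr1\t10\t30\t1.0"])
        with pytest.raises(TrackParseError, match="overlap"):
            read_track(path, "bedGraph", bin_size=10)

    def test_malformed_record_reports_line(self, tmp_path):
        path = write_lines(tmp_path / "t.bedGraph", [
            "chr1\t0\t10\t1.0", "chr1\tnot_a_number\t20\t1.0"])
        with pytest.raises(TrackParseError, match="line 2"):
            read_track(path, "bedGraph", bin_size=10)

    def test_bedgraph_roundtrip(self, tmp_path, rng):
        track = make_track(rng.normal(size=200).round(4))
        write_bedgraph(track, tmp_path / "rt.bedGraph")
        back = read_track(tmp_path / "rt.bedGraph", "bedGraph", bin_size=10)
        np.testing.assert_allclose(back.chrom_values["chr1"],
                                   track.chrom_values["chr1"], atol=1e-6)

    def test_bigwig_roundtrip(self, tmp_path, rng):
        from remodelscan.genomic_signal import write_bigwig
        track = make_track(rng.normal(size=100))
        write_bigwig(track, tmp_path / "rt.bw")
        back = read_track(tmp_path / "rt.bw", "bigWig", bin_size=10)
        np.testing.assert_allclose(back.chrom_values["chr1"],
                                   track.chrom_values["chr1"], atol=1e-6)


class TestZscore:
    def test_three_bins_forced_values(self):
        out = zscore_normalize(make_track([2, 4, 6]))
        np.testing.assert_allclose(out.chrom_values["chr1"],
                                   [-1.224745, 0.0, 1.224745], atol=1e-6)
        assert out.normalized

    def test_idempotent(self, rng):
        once = zscore_normalize(make_track(rng.normal(2, 5, 500)))
        twice = zscore_normalize(once)
        np.testing.assert_allclose(twice.chrom_values["chr1"],
                                   once.chrom_values["chr1"], atol=1e-9)

    def test_constant_track_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_normalize(make_track([3.0, 3.0, 3.0]))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 2000))
    def test_global_moments(self, seed, n):
        values = np.random.default_rng(seed).normal(3, 7, n)
        if np.std(values) == 0:  # pragma: no cover - essentially impossible
            return
        out = zscore_normalize(make_track(values)).all_values()
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1) < 1e-9


class TestAlgebra:
    def test_self_subtraction_is_zero(self, rng):
        t = make_track(rng.normal(size=50), normalized=True)
        delta = subtract_tracks(t, t)
        assert not delta.normalized
        np.testing.assert_array_equal(delta.chrom_values["chr1"], 0.0)

    def test_subtract_values_and_zero_fill(self):
        a = SignalTrack({"chr1": np.array([1.0, 2.0]),
                         "chr2": np.array([5.0])}, 10, normalized=True)
        b = SignalTrack({"chr1": np.array([0.5, 0.5])}, 10, normalized=True)
        d = subtract_tracks(a, b)
        np.testing.assert_allclose(d.chrom_values["chr1"], [0.5, 1.5])
        np.testing.assert_allclose(d.chrom_values["chr2"], [5.0])

    def test_bin_size_mismatch(self):
        with pytest.raises(ValueError, match="bin_size"):
            subtract_tracks(make_track([1.0, 2], bin_size=10),
                            make_track([1.0, 2], bin_size=20))

    def test_sum_linearity_and_inverse(self, rng):
        t = make_track(rng.normal(size=40))
        neg = make_track(-t.chrom_values["chr1"])
        np.testing.assert_allclose(
            add_tracks([t, t, t]).chrom_values["chr1"],
            3 * t.chrom_values["chr1"], atol=1e-9)
        np.testing.assert_allclose(
            add_tracks([t, neg]).chrom_values["chr1"], 0.0, atol=1e-12)

    def test_sum_of_three_deltas(self):
        tracks = [make_track(v) for v in ([1, 0], [0, 1], [-1, -1])]
        np.testing.assert_array_equal(
            add_tracks(tracks).chrom_values["chr1"], [0.0, 0.0])

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_add_commutative_associative(self, seed):
        g = np.random.default_rng(seed)
        a, b, c = (make_track(g.normal(size=30)) for _ in range(3))
        left = add_tracks([add_tracks([a, b]), c]).chrom_values["chr1"]
        right = add_tracks([a, add_tracks([c, b])]).chrom_values["chr1"]
        np.testing.assert_allclose(left, right, atol=1e-9)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        t = make_track(np.full(300, 2.5))
        out = gaussian_smooth(t, sd_bp=20)
        interior = out.chrom_values["chr1"][20:-20]
        np.testing.assert_allclose(interior, 2.5, atol=1e-9)

    def test_mass_conserved_for_interior_impulse(self):
        values = np.zeros(500)
        values[250] = 1.0  # mass 10 signal*bp at bin 10
        out = gaussian_smooth(make_track(values), sd_bp=20)
        assert abs(out.chrom_values["chr1"].sum() * 10 - 10) < 1e-6

    def test_impulse_center_equals_kernel_weight(self):
        values = np.zeros(100)
        values[50] = 1.0
        out = gaussian_smooth(make_track(values), sd_bp=20)
        kernel = gaussian_kernel(20 / 10)
        assert abs(out.chrom_values["chr1"][50] - kernel[kernel.size // 2]) < 1e-12

    def test_sd_below_bin_resolution_rejected(self):
        with pytest.raises(ValueError, match="sd_bp"):
            gaussian_smooth(make_track([1.0, 2.0]), sd_bp=2)


class TestIntervals:
    def test_narrowpeak_summit_offset(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t200\tpk1\t50\t.\t4.2\t-1\t-1\t25\n")
        iv, = read_intervals(path)
        assert iv.summit == 125 and iv.anchor == 125

    def test_bed6_midpoint_fallback(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t100\t200\tpk1\t50\t+\n")
        iv, = read_intervals(path)
        assert iv.summit is None and iv.anchor == 150

    def test_negative_start_rejected(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t-5\t200\tpk1\t0\t+\n")
        with pytest.raises(TrackParseError, match="line 1"):
            read_intervals(path)

    def test_start_not_before_end_rejected(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t200\t200\tpk1\t0\t+\n")
        with pytest.raises(TrackParseError, match="line 1"):
            read_intervals(path)

    def test_summit_offset_minus_one_falls_back(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t200\tpk1\t50\t.\t4.2\t-1\t-1\t-1\n")
        iv, = read_intervals(path)
        assert iv.summit is None and iv.anchor == 150
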