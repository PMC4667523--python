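"""Segment calling and four-mode classification of delta profiles."""

import numpy as np
import pytest

from remodelscan.genomic_signal import smooth_profile
from remodelscan.mode_classifier import (ClassifierParams, MODES,
                                         assign_modes, call_segments,
                                         classify_profile, profile_features)
from remodelscan.remodeling_cluster import kmeans_cluster
from remodelscan.synthetic_fixtures import (CohortConfig, simulate_cohort)
from remodelscan.profile_matrix import build_matrix
from conftest import anchor, make_track

BIN, HW = 10, 1500
NBINS = 2 * HW // BIN


def profile_with(blocks, noise=0.0, seed=0):
    """Profile from (start_offset, end_offset, value) blocks."""
    rng = np.random.default_rng(seed)
    p = rng.normal(0, noise, NBINS) if noise else np.zeros(NBINS)
    for start, end, value in blocks:
        p[(start + HW) // BIN:(end + HW) // BIN] += value
    return p


def classify(profile, fp=150, params=ClassifierParams()):
    segments = call_segments(profile, BIN, HW, params.threshold_z,
                             params.min_segment_length, params.merge_gap)
    smoothed = smooth_profile(profile, params.smooth_sd_bp, BIN)
    return classify_profile(segments, fp, smoothed, BIN, HW, params)


class TestCallSegments:
    def test_empty_on_zero_profile(self):
        assert call_segments(np.zeros(NBINS), BIN, HW) == []

    def test_planted_loss_run_recovered_exactly(self):
        p = profile_with([(-100, 100, -1.0)])
        (seg,) = call_segments(p, BIN, HW, threshold_z=0.3, min_len=100)
        assert (seg.start_offset, seg.end_offset) == (-100, 100)
        assert seg.sign == "loss" and seg.mean_delta == pytest.approx(-1.0)

    def test_nearby_same_sign_runs_merged(self):
        p = profile_with([(-200, -100, -1.0), (-80, 100, -1.0)])  # 20-bp gap
        (seg,) = call_segments(p, BIN, HW, merge_gap=30)
        assert (seg.start_offset, seg.end_offset) == (-200, 100)

    def test_distant_runs_not_merged(self):
        p = profile_with([(-300, -150, -1.0), (100, 250, -1.0)])
        segs = call_segments(p, BIN, HW, merge_gap=30)
        assert len(segs) == 2

    def test_opposite_signs_never_merge(self):
        p = profile_with([(-200, -100, -1.0), (-90, 100, 1.0)])
        segs = call_segments(p, BIN, HW, merge_gap=30)
        assert [s.sign for s in segs] == ["loss", "gain"]

    def test_short_runs_discarded(self):
        p = profile_with([(0, 50, -1.0)])
        assert call_segments(p, BIN, HW, min_len=100) == []


class TestClassifyProfile:
    def test_central_loss_over_footprint(self):
        assert classify(profile_with([(-150, 150, -1.0)])) == "central"

    def test_loss_outside_footprint_is_noncentral(self):
        assert classify(profile_with([(400, 600, -1.0)])) == "non_central"

    def test_alternating_flanks_with_central_loss_is_phased(self):
        blocks = [(-150, 150, -1.0)]
        for side in (-1, 1):
            for center, value in ((200, 0.8), (380, -0.8), (560, 0.8)):
                start = side * center - 40
                blocks.append((min(start, start + 80), max(start, start + 80),
                               value))
        assert classify(profile_with(blocks)) == "phased"

    def test_no_segments_is_minimal(self):
        assert classify(np.zeros(NBINS)) == "minimal"

    def test_gain_only_profile_is_minimal(self):
        assert classify(profile_with([(-150, 150, 1.0)])) == "minimal"

    @pytest.mark.parametrize("blocks,expected", [
        ([(-150, 150, -1.0)], "central"),
        ([], "minimal"),
    ])
    def test_mirror_invariance_symmetric_modes(self, blocks, expected):
        p = profile_with(blocks, noise=0.05, seed=4)
        assert classify(p) == expected
        assert classify(p[::-1].copy()) == expected

    def test_mirror_flips_side_but_keeps_noncentral(self):
        p = profile_with([(400, 600, -1.0)], noise=0.05, seed=5)
        assert classify(p) == "non_central"
        assert classify(p[::-1].copy()) == "non_central"
        _, _, flanks, _ = profile_features(p, BIN, HW, 150)
        _, _, flanks_m, _ = profile_features(p[::-1].copy(), BIN, HW, 150)
        assert flanks == flanks_m[::-1]

    @pytest.mark.parametrize("blocks", [
        [(-150, 150, -0.5)],
        [(400, 600, -0.5)],
        [(-150, 150, -0.35), (300, 500, 0.35), (550, 700, -0.35)],
        [],
    ])
    def test_raising_threshold_never_unmutes_minimal(self, blocks):
        p = profile_with(blocks, noise=0.08, seed=6)
        thresholds = [0.3, 0.4, 0.6, 1.0, 2.0]
        calls = [classify(p, params=ClassifierParams(threshold_z=t))
                 for t in thresholds]
        for lo, hi in zip(calls, calls[1:]):
            assert not (lo == "minimal" and hi != "minimal")


@pytest.fixture(scope="module")
def classified_cohort():
    cohort = simulate_cohort(CohortConfig(n_sites=400, seed=21))
    from remodelscan.genomic_signal import (add_tracks, subtract_tracks,
                                            zscore_normalize)
    deltas = [subtract_tracks(zscore_normalize(cohort.tracks[(m, "after")]),
                              zscore_normalize(cohort.tracks[(m, "before")]))
              for m in ("H3K4me1", "H3K4me2", "H3K4me3")]
    matrix = build_matrix(add_tracks(deltas), cohort.gr_peaks)
    clusters = kmeans_cluster(matrix, k=27, restarts=5, seed=21)
    calls = assign_modes(matrix, clusters, [p for p in cohort.gr_peaks])
    return cohort, matrix, clusters, calls


class TestAssignModes:
    def test_modes_partition_the_site_set(self, classified_cohort):
        _, matrix, _, calls = classified_cohort
        counts = {m: sum(1 for c in calls if c.mode == m) for m in MODES}
        assert sum(counts.values()) == matrix.n_sites

    def test_sites_inherit_cluster_mode(self, classified_cohort):
        _, _, _, calls = classified_cohort
        by_cluster = {}
        for c in calls:
            by_cluster.setdefault(c.cluster, set()).add(c.mode)
        assert all(len(modes) == 1 for modes in by_cluster.values())

    def test_planted_modes_recovered(self, classified_cohort):
        cohort, _, _, calls = classified_cohort
        truth = dict(zip(cohort.truth.site, cohort.truth.planted_mode))
        hits = sum(1 for c in calls if c.mode == truth[c.site])
        assert hits / len(calls) >= 0.90

    def test_single_site_cluster_gets_own_classification(self):
        cohort = simulate_cohort(CohortConfig(n_sites=40, seed=3))
        from remodelscan.genomic_signal import (add_tracks, subtract_tracks,
                                                zscore_normalize)
        deltas = [subtract_tracks(zscore_normalize(cohort.tracks[(m, "after")]),
                                  zscore_normalize(cohort.tracks[(m, "before")]))
                  for m in ("H3K4me1", "H3K4me2", "H3K4me3")]
        matrix = build_matrix(add_tracks(deltas), cohort.gr_peaks)
        clusters = kmeans_cluster(matrix, k=35, restarts=3, seed=3)
        calls = assign_modes(matrix, clusters, list(cohort.gr_peaks))
        sizes = clusters.cluster_sizes()
        singletons = [c for c in calls if sizes[c.cluster] == 1]
        assert singletons  # k close to n forces singleton clusters
        for call in singletons:
            i = [a.name for a in matrix.anchors].index(call.site)
            params = ClassifierParams()
            segs, _, _, _ = (profile_features(
                matrix.values[i], matrix.bin_size, matrix.half_width, 150,
                params))
            smoothed = smooth_profile(matrix.values[i], params.smooth_sd_bp,
                                      matrix.bin_size)
            own = classify_profile(segs, 150, smoothed, matrix.bin_size,
                                   matrix.half_width, params)
            assert call.mode == own
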