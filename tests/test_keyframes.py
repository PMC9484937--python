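"""Histogram intersection, leader clustering, and key-frame refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rppgkit.keyframes import (ColorHistogram, build_histogram, cluster_frames,
                               pair_distance, refine_keyframes,
                               select_keyframes, similarity)


def _solid(color, h=8, w=8):
    frame = np.empty((h, w, 3))
    frame[:] = color
    return frame


def _norm_hist(values):
    return ColorHistogram(np.asarray(values, float) / np.sum(values))


class TestBuildHistogram:
    def test_uniform_frame_has_all_mass_in_one_cell(self):
        hist = build_histogram(_solid((200, 30, 30)))
        assert hist.bins.max() == pytest.approx(1.0)
        assert (hist.bins > 0).sum() == 1

    def test_spatial_invariance_under_mirroring(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 255, size=(12, 16, 3))
        assert np.array_equal(build_histogram(frame).bins,
                              build_histogram(frame[:, ::-1]).bins)

    def test_four_pixel_frame_hand_count(self):
        # 3 red pixels and 1 green pixel -> masses 0.75 / 0.25
        frame = np.array([[[255, 0, 0], [255, 0, 0]],
                          [[255, 0, 0], [0, 255, 0]]], dtype=float)
        hist = build_histogram(frame, n_bins=2, m_bins=2)
        assert sorted(hist.bins.ravel()[hist.bins.ravel() > 0]) == [0.25, 0.75]

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_histogram(np.empty((0, 0, 3)))


class TestSimilarity:
    def test_self_similarity_is_one(self):
        h = _norm_hist([[0.5, 0.25], [0.25, 0.0]])
        assert similarity(h, h) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert similarity(_norm_hist([1, 0]), _norm_hist([0, 1])) == 0.0

    def test_worked_intersection(self):
        # sum of minima: min(.5,.25) + min(.5,.75) = 0.75
        assert similarity(_norm_hist([0.5, 0.5]),
                          _norm_hist([0.25, 0.75])) == pytest.approx(0.75)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            similarity(_norm_hist([1, 0]), _norm_hist([[1, 0], [0, 0]]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 10), min_size=4, max_size=4),
           st.lists(st.floats(0.01, 10), min_size=4, max_size=4))
    def test_symmetric_bounded_and_maximal_at_equality(self, a, b):
        ha, hb = _norm_hist(a), _norm_hist(b)
        s = similarity(ha, hb)
        assert s == pytest.approx(similarity(hb, ha))
        assert 0.0 <= s <= 1.0 + 1e-12
        assert s <= similarity(ha, ha) + 1e-12


class TestClusterFrames:
    def test_identical_frames_form_one_cluster(self):
        frames = [_solid((100, 100, 100))] * 6
        assert len(cluster_frames(frames, T=0.5)) == 1

    def test_alternating_dissimilar_colors_form_two_clusters(self):
        # leader pass: frame 0 opens cluster A, frame 1 (similarity 0 <= T)
        # opens B, later frames rejoin their color's cluster
        frames = [_solid((255, 0, 0)) if i % 2 == 0 else _solid((0, 0, 255))
                  for i in range(8)]
        clusters = cluster_frames(frames, T=0.5)
        assert len(clusters) == 2
        assert clusters.clusters[0].members == [0, 2, 4, 6]
        assert clusters.clusters[1].members == [1, 3, 5, 7]

    def test_threshold_near_one_isolates_noisy_frames(self, rng):
        frames = [rng.uniform(0, 255, size=(6, 6, 3)) for _ in range(5)]
        clusters = cluster_frames(frames, T=0.999999)
        assert len(clusters) == 5

    def test_partition_property(self, rng):
        frames = [rng.uniform(0, 255, size=(6, 6, 3)) for _ in range(12)]
        clusters = cluster_frames(frames, T=0.6)
        members = sorted(i for c in clusters.clusters for i in c.members)
        assert members == list(range(12))

    @pytest.mark.parametrize("T", [0.0, 1.0, -0.2])
    def test_threshold_domain(self, T):
        with pytest.raises(ValueError, match="T"):
            cluster_frames([_solid((1, 1, 1))], T=T)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            cluster_frames([], T=0.5)


class TestSelectKeyframes:
    def test_singleton_cluster_returns_its_member(self):
        kset = select_keyframes(cluster_frames([_solid((9, 9, 9))], T=0.5))
        assert kset.indices == [0]

    def test_tie_breaks_to_smallest_index(self):
        kset = select_keyframes(cluster_frames([_solid((9, 9, 9))] * 4, T=0.5))
        assert kset.indices == [0]

    def test_matches_brute_force_argmax(self, rng):
        base = rng.uniform(0, 255, size=(6, 6, 3))
        frames = [base + rng.normal(0, 20, base.shape) for _ in range(3)]
        clusters = cluster_frames(frames, T=0.01)
        assert len(clusters) == 1
        c = clusters.clusters[0]
        sims = [similarity(clusters.histograms[i], c.centroid) for i in c.members]
        expected = c.members[int(np.argmax(sims))]
        assert select_keyframes(clusters).indices == [expected]


class TestRefinement:
    def test_identical_key_frames_give_distance_equal_to_region_count(self):
        regions = [_norm_hist([0.3, 0.7]), _norm_hist([0.5, 0.5]),
                   _norm_hist([0.1, 0.9])]
        assert pair_distance(regions, regions) == pytest.approx(3.0)

    def test_disjoint_regions_give_zero(self):
        a = [_norm_hist([1, 0]), _norm_hist([1, 0])]
        b = [_norm_hist([0, 1]), _norm_hist([0, 1])]
        assert pair_distance(a, b) == 0.0

    def test_worked_two_region_example(self):
        # squared intersections 0.6^2 + 0.8^2 = 1.0
        a = [_norm_hist([0.6, 0.4]), _norm_hist([0.8, 0.2])]
        b = [_norm_hist([1.0, 0.0]), _norm_hist([1.0, 0.0])]
        assert pair_distance(a, b) == pytest.approx(0.6 ** 2 + 0.8 ** 2)

    def test_relabeling_invariance(self, rng):
        from rppgkit.keyframes import KeyFrameSet

        parts = []
        for _ in range(3):
            parts.append([_norm_hist(rng.uniform(0.1, 1, 4)) for _ in range(4)])
        kset = KeyFrameSet([0, 5, 9], [0, 1, 2])
        d1, _ = refine_keyframes(kset, parts)
        perm = [2, 0, 3, 1]
        permuted = [[p[j] for j in perm] for p in parts]
        d2, _ = refine_keyframes(kset, permuted)
        assert np.allclose(d1, d2)

    def test_mismatched_region_counts_rejected(self):
        from rppgkit.keyframes import KeyFrameSet

        kset = KeyFrameSet([0, 1], [0, 1])
        parts = [[_norm_hist([1, 0])], [_norm_hist([1, 0]), _norm_hist([0, 1])]]
        with pytest.raises(ValueError, match="region counts"):
            refine_keyframes(kset, parts)

    def test_retention_senses(self):
        from rppgkit.keyframes import KeyFrameSet

        kset = KeyFrameSet([0, 4, 8], [0, 1, 2])
        near = [_norm_hist([0.5, 0.5])]
        far = [_norm_hist([1.0, 0.0])]
        parts = [near, near, far]  # distances: 1.0 then 0.25
        _, kept_dissimilar = refine_keyframes(kset, parts, threshold=0.5,
                                              keep="dissimilar")
        _, kept_similar = refine_keyframes(kset, parts, threshold=0.5,
                                           keep="similar")
        assert kept_dissimilar == [0, 8]
        assert kept_similar == [0, 4]
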