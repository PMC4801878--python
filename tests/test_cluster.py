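"""Spatio-temporal clustering, permutation testing, response summaries."""

from collections import deque

import numpy as np
import pytest
from scipy import stats

from nirsdot.cluster import (
    Cluster,
    cluster_strength,
    cluster_timecourse,
    compute_tmap,
    decimate_time,
    downsample_for_clustering,
    form_clusters,
    permutation_test,
    summarize_cohort,
    summarize_response,
    trace_support,
)


def _tmap_from_mask(mask, tvals=None):
    from nirsdot.cluster import TMap

    t = np.where(mask, 3.0, 0.0) if tvals is None else tvals
    return TMap(t=t, n_events=10, alpha=0.05, sig_mask=mask)


def _flood_fill_components(mask):
    """Independent BFS oracle under 6-connectivity in space + time adjacency."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    dims = mask.shape
    neigh = []
    for ax in range(4):
        for d in (-1, 1):
            step = [0, 0, 0, 0]
            step[ax] = d
            neigh.append(tuple(step))
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = []
        qd = deque([start])
        seen[start] = True
        while qd:
            p = qd.popleft()
            comp.append(p)
            for st in neigh:
                q = tuple(p[i] + st[i] for i in range(4))
                if all(0 <= q[i] < dims[i] for i in range(4)) and mask[q] and not seen[q]:
                    seen[q] = True
                    qd.append(q)
        comps.append(frozenset(comp))
    return set(comps)


class TestDownsample:
    def test_identity_at_target_resolution(self, rng):
        x = rng.normal(size=(2, 4, 4, 2, 10))
        out, mm, fs = downsample_for_clustering(x, 2.0, 2.0)
        np.testing.assert_array_equal(out, x)
        assert (mm, fs) == (2.0, 2.0)

    def test_constant_stays_constant(self):
        x = np.full((6, 6, 4, 40), 3.5)
        out, _, _ = downsample_for_clustering(x, 1.0, 20.0)
        np.testing.assert_allclose(out, 3.5)

    def test_block_means_match_direct_oracle(self, rng):
        x = rng.normal(size=(4, 4, 2, 40))
        out, mm, fs = downsample_for_clustering(x, 1.0, 20.0)
        assert out.shape == (2, 2, 1, 4)
        direct = x[:2, :2, :2, :10].mean(axis=(0, 1, 2))
        np.testing.assert_allclose(out[0, 0, 0, 0], direct[0] if False else x[:2, :2, :2, :10].mean())
        # full oracle over every block
        for i in range(2):
            for j in range(2):
                for t in range(4):
                    blk = x[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, :, 10 * t : 10 * t + 10]
                    assert out[i, j, 0, t] == pytest.approx(blk.mean())

    def test_decimate_time_blocks(self, rng):
        x = rng.normal(size=(3, 40))
        out, fs = decimate_time(x, 20.0, 2.0)
        assert out.shape == (3, 4) and fs == 2.0
        np.testing.assert_allclose(out[:, 0], x[:, :10].mean(axis=1))


class TestComputeTmap:
    def test_alternating_signs_not_significant(self):
        data = np.array([1.0, -1.0, 1.0, -1.0])[:, None, None, None, None]
        tm = compute_tmap(data)
        assert tm.t[0, 0, 0, 0] == 0.0
        assert not tm.sig_mask.any()

    def test_textbook_t_recomputation(self, rng):
        vals = 2.0 + np.array([0.1, -0.1, 0.1, -0.1, 0.0])
        data = vals[:, None, None, None, None]
        tm = compute_tmap(data)
        expected = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        assert tm.t[0, 0, 0, 0] == pytest.approx(expected)
        assert tm.sig_mask[0, 0, 0, 0]

    def test_null_significant_fraction_near_alpha(self, rng):
        data = rng.normal(size=(20, 8, 8, 2, 30))
        tm = compute_tmap(data, alpha=0.05)
        n = tm.sig_mask.size
        frac = tm.sig_mask.mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_zero_variance_points_excluded(self):
        data = np.ones((5, 2, 1, 1, 3))
        tm = compute_tmap(data)
        assert not tm.sig_mask.any()
        assert tm.excluded is not None and tm.excluded.all()

    def test_too_few_events_raise(self):
        with pytest.raises(ValueError, match="3 events"):
            compute_tmap(np.zeros((2, 1, 1, 1, 1)))


class TestFormClusters:
    def test_spatial_diagonals_split(self):
        mask = np.zeros((3, 3, 1, 1), bool)
        mask[0, 0, 0, 0] = mask[1, 1, 0, 0] = True
        assert len(form_clusters(_tmap_from_mask(mask))) == 2

    def test_temporal_chain_single_cluster(self):
        mask = np.zeros((2, 2, 1, 6), bool)
        mask[0, 0, 0, 2:5] = True
        cl = form_clusters(_tmap_from_mask(mask))
        assert len(cl) == 1 and cl[0].size == 3
        assert cl[0].time_extent() == (2, 4)

    def test_spacetime_diagonal_split(self):
        mask = np.zeros((2, 1, 1, 2), bool)
        mask[0, 0, 0, 0] = mask[1, 0, 0, 1] = True
        assert len(form_clusters(_tmap_from_mask(mask))) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_flood_fill_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((6, 5, 4, 8)) < 0.3
        clusters = form_clusters(_tmap_from_mask(mask))
        got = {frozenset(zip(*c.members)) for c in clusters}
        assert got == _flood_fill_components(mask)


class TestClusterStrength:
    def test_sum_of_absolute_t(self):
        t = np.zeros((3, 1, 1, 1))
        t[0, 0, 0, 0], t[1, 0, 0, 0], t[2, 0, 0, 0] = 2.5, -3.0, 4.0
        mask = t != 0
        clusters = form_clusters(_tmap_from_mask(mask, t))
        assert sum(c.strength for c in clusters) == pytest.approx(9.5)

    def test_singleton_absolute_value(self):
        t = np.full((1, 1, 1, 1), -2.1)
        clusters = form_clusters(_tmap_from_mask(t != 0, t))
        assert clusters[0].strength == pytest.approx(2.1)

    def test_strength_recomputation_audit(self, rng):
        t = rng.normal(size=(5, 5, 2, 6)) * 3
        mask = np.abs(t) > 2
        tm = _tmap_from_mask(mask, t)
        for c in form_clusters(tm):
            assert c.strength == pytest.approx(cluster_strength(c, tm))

    def test_disjoint_union_additivity(self):
        t = np.zeros((5, 1, 1, 1))
        t[0, 0, 0, 0], t[3, 0, 0, 0] = 2.0, 3.0  # not adjacent
        clusters = form_clusters(_tmap_from_mask(t != 0, t))
        assert len(clusters) == 2
        assert sum(c.strength for c in clusters) == pytest.approx(5.0)


class TestPermutationTest:
    def _images(self, rng, n, shape=(4, 4, 1, 10), effect=0.0):
        x = rng.normal(size=(n, *shape))
        x[:, 1:3, 1:3, :, 3:7] += effect
        return x

    def test_p_values_valid_and_reproducible(self, rng):
        ied = self._images(rng, 12, effect=1.2)
        ctl = self._images(rng, 12)
        a, null_a = permutation_test(ied, ctl, n_perm=150, seed=7)
        b, null_b = permutation_test(ied, ctl, n_perm=150, seed=7)
        np.testing.assert_array_equal(null_a, null_b)
        for c in a:
            assert 1 / 151 <= c.p_perm <= 1.0
        assert [c.p_perm for c in a] == [c.p_perm for c in b]

    def test_strong_effect_detected(self, rng):
        ied = self._images(rng, 15, effect=2.5)
        ctl = self._images(rng, 15)
        clusters, _ = permutation_test(ied, ctl, n_perm=300, seed=1)
        assert clusters[0].p_perm <= 0.05

    def test_identical_sets_nothing_beyond_chance(self, rng):
        x = self._images(rng, 10, effect=2.0)
        clusters, _ = permutation_test(x, x.copy(), n_perm=200, seed=3)
        # pooled set is two copies: permuted pseudo-IED maps match the
        # observed map in distribution, so no cluster can look extreme
        assert all(c.p_perm > 0.05 for c in clusters)

    def test_low_n_perm_warns(self, rng):
        ied, ctl = self._images(rng, 5), self._images(rng, 5)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(ied, ctl, n_perm=50, seed=0)

    def test_flat_and_dense_inputs_agree(self, rng):
        ied = self._images(rng, 8, effect=1.5)
        ctl = self._images(rng, 8)
        a, null_a = permutation_test(ied, ctl, n_perm=100, seed=11)
        fov = np.argwhere(np.ones(ied.shape[1:4], bool))
        flat_i = ied.reshape(8, -1, ied.shape[-1])
        flat_c = ctl.reshape(8, -1, ied.shape[-1])
        b, null_b = permutation_test(
            flat_i, flat_c, n_perm=100, seed=11, fov_voxels=fov, grid_shape=ied.shape[1:4]
        )
        np.testing.assert_allclose(null_a, null_b)
        assert [c.strength for c in a] == pytest.approx([c.strength for c in b])


class TestTimecourse:
    def test_single_voxel_cluster_equals_event_mean(self, rng):
        images = rng.normal(size=(6, 3, 3, 1, 8))
        c = Cluster(members=(np.array([1]), np.array([1]), np.array([0]), np.array([4])), strength=1.0)
        mean, se = cluster_timecourse(c, images)
        np.testing.assert_allclose(mean, images[:, 1, 1, 0, :].mean(axis=0))

    def test_identical_events_zero_se(self):
        one = np.arange(24.0).reshape(2, 2, 1, 6)
        images = np.stack([one] * 5)
        c = Cluster(members=(np.array([0]), np.array([0]), np.array([0]), np.array([0])), strength=1.0)
        _, se = cluster_timecourse(c, images)
        np.testing.assert_allclose(se, 0.0)

    def test_two_stage_averaging_oracle(self, rng):
        images = rng.normal(size=(7, 4, 4, 2, 9))
        c = Cluster(
            members=(np.array([0, 1]), np.array([0, 0]), np.array([1, 1]), np.array([2, 2])),
            strength=1.0,
        )
        mean, se = cluster_timecourse(c, images)
        per_event = images[:, [0, 1], [0, 0], [1, 1], :].mean(axis=1)
        np.testing.assert_allclose(mean, per_event.mean(axis=0))
        np.testing.assert_allclose(se, per_event.std(axis=0, ddof=1) / np.sqrt(7))


class TestSummaries:
    def test_single_interval_forced_fields(self):
        ts = np.linspace(-20, 40, 121)
        trace = np.exp(-((ts - 3.8) ** 2) / 8)
        s = summarize_response(trace, ts, [(0.0, 15.0)])
        assert s.onset_s == 0.0 and s.end_s == 15.0 and s.duration_s == 15.0
        assert s.peak_s == pytest.approx(3.8, abs=0.5)
        assert s.polarity == ["HbO up"]

    def test_two_intervals_span(self):
        ts = np.linspace(-20, 40, 121)
        trace = np.ones_like(ts)
        s = summarize_response(trace, ts, [(12.0, 17.0), (-5.0, 10.0)])
        assert (s.onset_s, s.end_s, s.duration_s) == (-5.0, 17.0, 22.0)

    def test_no_interval_empty_summary(self):
        s = summarize_response(np.zeros(10), np.arange(10.0), [])
        assert s.empty

    def test_cohort_single_record(self):
        s = summarize_cohort([4.2])
        assert s["mean"] == 4.2 and np.isnan(s["se"])

    def test_cohort_matches_textbook(self, rng):
        x = rng.normal(size=11)
        s = summarize_cohort(x)
        assert s["mean"] == pytest.approx(x.mean())
        assert s["se"] == pytest.approx(x.std(ddof=1) / np.sqrt(11))
        assert s["median"] == pytest.approx(np.median(x))

    def test_trace_support_walks_from_peak(self):
        ts = np.linspace(-20, 40, 1201)
        from nirsdot.simulate import HRSpec, hr_waveform

        w = hr_waveform(HRSpec(), ts)[0]
        on, pk, end = trace_support(w, ts)
        assert on == pytest.approx(-5.0, abs=0.1)
        assert pk == pytest.approx(3.0, abs=0.1)
        assert end == pytest.approx(17.0, abs=0.1)
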