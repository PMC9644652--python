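"""Paired t maps, cluster permutation engine, FDR and RMS time courses."""

import itertools

import numpy as np
import pytest

from betalat import (
    Adjacency,
    InvalidParameterError,
    SensorEpochs,
    SourceStatMap,
    cluster_permutation_test,
    fallback_threshold,
    paired_t_map,
    pointwise_fdr_test,
    rms_timecourse,
)
from betalat.inference import grid_adjacency, knn_adjacency, _cluster_labels


def line_adjacency(n):
    return Adjacency(n_elem=n, edges=np.column_stack([np.arange(n - 1),
                                                      np.arange(1, n)]))


class TestPairedT:
    def test_identical_conditions_give_zero(self):
        x = np.random.default_rng(0).standard_normal((10, 4))
        assert np.allclose(paired_t_map(x, x), 0.0)

    def test_textbook_value(self):
        """Differences with mean 1 and sd 1 over n = 100: t = 10."""
        rng = np.random.default_rng(1)
        d = rng.standard_normal(100)
        d = (d - d.mean()) / d.std(ddof=1) + 1.0
        base = d[:, None]
        act = np.zeros_like(base)
        assert paired_t_map(act, base)[0] == pytest.approx(10.0, abs=1e-9)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(2)
        act = rng.standard_normal((20, 5))
        base = rng.standard_normal((20, 5))
        t = paired_t_map(act, base)
        for v in range(5):
            d = base[:, v] - act[:, v]
            expected = d.mean() / (d.std(ddof=1) / np.sqrt(20))
            assert t[v] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_infinite(self):
        base = np.ones((5, 2))
        act = np.zeros((5, 2))
        act[:, 1] = 1.0  # zero mean, zero variance
        t = paired_t_map(act, base)
        assert np.isposinf(t[0]) and t[1] == 0.0


class TestClusterPermutation:
    def test_planted_cluster_survives(self):
        """A contiguous d = 1.5 effect over 8 voxels with 60 trials is
        detected in virtually every seed."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n_vox = 40
            base = rng.standard_normal((60, n_vox))
            act = rng.standard_normal((60, n_vox))
            act[:, 10:18] -= 1.5
            res = cluster_permutation_test(act, base, line_adjacency(n_vox),
                                           n_perm=500, seed=seed)
            detected = res.surviving[10:18].all()
            hits += detected
        assert hits >= 9

    def test_no_suprathreshold_reports_no_cluster(self):
        x = np.zeros((10, 5))
        res = cluster_permutation_test(x + 0.001, x, line_adjacency(5),
                                       n_perm=100, seed=0)
        assert res.status == "no-cluster"
        assert not res.surviving.any()

    def test_min_p_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((30, 10)) + 3.0
        act = rng.standard_normal((30, 10))
        res = cluster_permutation_test(act, base, line_adjacency(10),
                                       n_perm=200, seed=1)
        assert min(c["p"] for c in res.clusters) == pytest.approx(1 / 201)

    def test_trial_order_exchangeability(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((25, 12))
        act = rng.standard_normal((25, 12))
        perm = rng.permutation(25)
        r1 = cluster_permutation_test(act, base, line_adjacency(12),
                                      n_perm=200, seed=7)
        r2 = cluster_permutation_test(act[perm], base[perm], line_adjacency(12),
                                      n_perm=200, seed=7)
        assert np.allclose(r1.tvals, r2.tvals, atol=1e-12)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((20, 8)) + 0.5
        act = rng.standard_normal((20, 8))
        r1 = cluster_permutation_test(act, base, line_adjacency(8), n_perm=300, seed=9)
        r2 = cluster_permutation_test(act, base, line_adjacency(8), n_perm=300, seed=9)
        assert [c["p"] for c in r1.clusters] == [c["p"] for c in r2.clusters]
        assert np.array_equal(r1.surviving, r2.surviving)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """n = 8 trials: the Monte Carlo cluster p agrees with the exactly
        enumerated 2^8 sign-flip distribution within 2/sqrt(n_perm)."""
        rng = np.random.default_rng(6)
        n_trials, n_vox = 8, 6
        base = rng.standard_normal((n_trials, n_vox)) + 1.2
        act = rng.standard_normal((n_trials, n_vox))
        adj = line_adjacency(n_vox)
        n_perm = 4000
        res = cluster_permutation_test(act, base, adj, n_perm=n_perm,
                                       t_crit=1.65, seed=11)
        d = base - act

        def max_mass(dd):
            m = dd.mean(axis=0)
            sd = dd.std(axis=0, ddof=1)
            with np.errstate(divide="ignore"):
                t = np.where(sd > 0, m / (sd / np.sqrt(n_trials)), 0.0)
            mask = t > 1.65
            if not mask.any():
                return 0.0
            labels = _cluster_labels(mask, adj.edges)
            return max(t[labels == c].sum() for c in range(labels.max() + 1))

        null = [max_mass(d * np.array(s)[:, None])
                for s in itertools.product([-1, 1], repeat=n_trials)]
        null = np.asarray(null)
        for c in res.clusters:
            exact_p = np.mean(null >= c["mass"] - 1e-12)
            assert abs(c["p"] - exact_p) <= 2 / np.sqrt(n_perm)

    def test_rejects_tiny_permutation_counts(self):
        x = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(InvalidParameterError):
            cluster_permutation_test(x, x + 1, line_adjacency(3), n_perm=10)


class TestFallbackThreshold:
    def test_threshold_rule_and_metadata(self, anatomy):
        _, grid = anatomy
        values = np.zeros(grid.n_grid)
        mask = grid.inside_mask.copy()
        inside = grid.inside_indices
        values[inside[0]] = 2.0
        values[inside[1]] = 1.9
        tmap = SourceStatMap(values=values, mask=mask, grid=grid)
        out = fallback_threshold(tmap, 1.97)
        assert out.values[inside[0]] == 2.0
        assert out.values[inside[1]] == 0.0
        assert out.info["corrected"] is False

    def test_all_null_map_stays_empty_but_marked(self, anatomy):
        _, grid = anatomy
        tmap = SourceStatMap(values=np.zeros(grid.n_grid),
                             mask=grid.inside_mask.copy(), grid=grid)
        out = fallback_threshold(tmap, 1.97)
        assert not np.any(out.values)
        assert out.info["rule"] == "uncorrected"


class TestRMSTimecourse:
    @staticmethod
    def _epochs(data, sfreq=100.0):
        t = np.arange(data.shape[2]) / sfreq - 0.5
        return SensorEpochs(data=data, times=t, sfreq=sfreq)

    def test_single_channel_is_absolute_z(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((20, 1, 100))
        ep = self._epochs(data)
        rms = rms_timecourse(ep, [0])
        evoked = data.mean(axis=0)[0]
        pre = ep.times < 0
        z = (evoked - evoked[pre].mean()) / evoked[pre].std()
        assert np.allclose(rms, np.abs(z), atol=1e-12)

    def test_duplicated_channel_changes_nothing(self):
        rng = np.random.default_rng(1)
        one = rng.standard_normal((10, 1, 80))
        two = np.concatenate([one, one], axis=1)
        assert np.allclose(rms_timecourse(self._epochs(one), [0]),
                           rms_timecourse(self._epochs(two), [0, 1]), atol=1e-12)

    def test_three_channel_hand_computation(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((15, 3, 60))
        ep = self._epochs(data)
        rms = rms_timecourse(ep, [0, 1, 2])
        evoked = data.mean(axis=0)
        pre = ep.times < 0
        z = (evoked - evoked[:, pre].mean(1, keepdims=True)) / \
            evoked[:, pre].std(1, keepdims=True)
        assert np.allclose(rms, np.sqrt((z**2).mean(axis=0)), atol=1e-12)

    def test_empty_sensor_set_rejected(self):
        ep = self._epochs(np.zeros((2, 2, 50)))
        with pytest.raises(InvalidParameterError):
            rms_timecourse(ep, [])


class TestPointwiseFDR:
    def test_identical_hemispheres_stay_null(self):
        empty = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            left = rng.standard_normal((12, 30))
            right = rng.standard_normal((12, 30))
            mask, _ = pointwise_fdr_test(left, right, n_perm=500, q=0.05, seed=seed)
            empty += not mask.any()
        assert empty >= 9

    def test_strong_interval_detected(self):
        rng = np.random.default_rng(3)
        left = rng.standard_normal((15, 40))
        right = rng.standard_normal((15, 40))
        left[:, 10:20] += 2.0
        mask, p = pointwise_fdr_test(left, right, n_perm=1000, q=0.05, seed=1)
        assert mask[10:20].mean() > 0.8
        assert mask[25:].mean() < 0.2

    def test_bh_stepup_hand_example(self):
        """BH at q = 0.05 on p = (0.001, 0.02, 0.30) keeps the first two."""
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests([0.001, 0.02, 0.30], alpha=0.05, method="fdr_bh")
        assert list(reject) == [True, True, False]

    def test_lowering_q_never_adds_detections(self):
        rng = np.random.default_rng(4)
        left = rng.standard_normal((10, 25))
        right = rng.standard_normal((10, 25)) - 0.4
        m_strict, _ = pointwise_fdr_test(left, right, n_perm=400, q=0.01, seed=2)
        m_loose, _ = pointwise_fdr_test(left, right, n_perm=400, q=0.10, seed=2)
        assert np.all(m_loose[m_strict])


class TestAdjacency:
    def test_grid_adjacency_face_neighbours(self, anatomy):
        _, grid = anatomy
        idx = grid.inside_indices
        adj = grid_adjacency(grid, idx, 6)
        pos = grid.positions[idx]
        d = np.linalg.norm(pos[adj.edges[:, 0]] - pos[adj.edges[:, 1]], axis=1)
        assert np.allclose(d, grid.spacing)

    def test_no_self_loops_and_symmetry_canonical(self):
        adj = Adjacency(n_elem=4, edges=np.array([[1, 0], [0, 1], [2, 3]]))
        assert adj.edges.shape == (2, 2)
        assert np.all(adj.edges[:, 0] < adj.edges[:, 1])

    def test_knn_is_connected_for_sensor_ring(self, anatomy):
        head, _ = anatomy
        adj = knn_adjacency(head.sensor_positions, k=4)
        labels = _cluster_labels(np.ones(adj.n_elem, bool), adj.edges)
        assert labels.max() == 0  # one component
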