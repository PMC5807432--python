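"""Cluster-mass permutation machinery against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import meglock as mg
from meglock.cluster_stats import gaussian_kernel

from .oracles import brute_force_clusters, exhaustive_max_masses, one_sample_t


class TestPairedT:
    def test_equal_maps_give_zero_t(self):
        a = np.random.default_rng(0).standard_normal((5, 3, 4))
        sm = mg.paired_t_map(a, a.copy())
        assert np.allclose(sm.t_values, 0.0)
        assert sm.df == 4

    def test_toy_differences_match_hand_computation(self):
        diffs = np.array([1.0, 2.0, 3.0, 2.0]).reshape(4, 1)
        sm = mg.paired_t_map(diffs, np.zeros((4, 1)))
        # mean 2, sd sqrt(2/3), t = 2 / (sd/2) = 4.898979...
        assert sm.t_values[0] == pytest.approx(2 / (np.sqrt(2 / 3) / 2))
        assert sm.t_values[0] == pytest.approx(4.898979, abs=1e-5)

    def test_misaligned_axes_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            mg.paired_t_map(np.zeros((4, 3)), np.zeros((4, 5)))


class TestClusterFormingThreshold:
    def test_df59_two_tailed(self):
        assert mg.cluster_forming_threshold(0.05, 59) == pytest.approx(2.0010, abs=5e-4)

    def test_normal_limit(self):
        assert mg.cluster_forming_threshold(0.05, 10 ** 7) == pytest.approx(1.9600, abs=1e-3)

    def test_alpha_one_degenerate(self):
        assert mg.cluster_forming_threshold(1.0, 10) == 0.0


class TestSmoothMap:
    def test_constant_map_unchanged(self):
        out = mg.smooth_map(np.full((8, 9), 3.5))
        assert np.allclose(out, 3.5)

    def test_interior_impulse_reproduces_kernel(self):
        m = np.zeros((11, 11))
        m[5, 5] = 1.0
        out = mg.smooth_map(m, kernel_size=5, sigma=2.0)
        assert np.allclose(out[3:8, 3:8], gaussian_kernel(5, 2.0))
        assert out.sum() == pytest.approx(1.0)

    def test_interior_support_preserves_total(self):
        rng = np.random.default_rng(0)
        m = np.zeros((20, 20))
        m[5:15, 5:15] = rng.standard_normal((10, 10))
        assert mg.smooth_map(m).sum() == pytest.approx(m.sum())

    def test_map_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            mg.smooth_map(np.zeros((3, 10)))


class TestFindClusters:
    def test_subthreshold_map_yields_nothing(self):
        assert mg.find_clusters(np.array([0.5, -1.0, 1.5]), 2.0) == []

    def test_1d_example_masses(self):
        cls = mg.find_clusters(np.array([0.0, 3.0, 3.0, 0.0, -3.0, 0.0]), 2.0)
        masses = sorted(c.mass for c in cls)
        assert masses == [-3.0, 6.0]
        pos = next(c for c in cls if c.sign == 1)
        assert list(pos.indices[0]) == [1, 2]

    def test_diagonal_touch_depends_on_connectivity(self):
        m = np.zeros((4, 4))
        m[1, 1] = m[2, 2] = 5.0
        assert len(mg.find_clusters(m, 2.0, connectivity="4")) == 2
        assert len(mg.find_clusters(m, 2.0, connectivity="8")) == 1

    @pytest.mark.parametrize("ndim", [1, 2])
    def test_agrees_with_flood_fill_oracle_on_random_maps(self, ndim):
        rng = np.random.default_rng(42 + ndim)
        for _ in range(100):
            shape = (rng.integers(2, 9), rng.integers(2, 9)) if ndim == 2 \
                else (rng.integers(3, 40),)
            t_map = rng.standard_normal(shape) * 2
            got = mg.find_clusters(t_map, 1.5)
            want = brute_force_clusters(t_map, 1.5)
            got_set = {(c.sign, frozenset(zip(*c.indices)) if ndim == 2
                        else frozenset(c.indices[0].tolist()), round(c.mass, 9))
                       for c in got}
            want_set = {(s, m, round(mass, 9)) for s, m, mass in want}
            assert got_set == want_set


class TestMonteCarloP:
    def test_fraction_strictly_larger(self):
        null = np.concatenate([np.full(250, 10.0), np.full(4750, 1.0)])
        assert mg.monte_carlo_p(5.0, null) == 0.05

    def test_extremes(self):
        assert mg.monte_carlo_p(9.0, np.ones(100)) == 0.0
        assert mg.monte_carlo_p(0.5, np.ones(100)) == 1.0

    def test_plus_one_variant(self):
        assert mg.monte_carlo_p(9.0, np.ones(99), plus_one=True) == pytest.approx(0.01)


class TestPermutationTests:
    def test_all_zero_contrasts_give_no_clusters(self):
        cfg = mg.PermutationConfig(n_permutations=20, seed=0)
        assert mg.permutation_test_time(np.zeros((6, 50)), cfg) == []

    def test_exhaustive_monte_carlo_equals_exact_permutation_p(self):
        rng = np.random.default_rng(3)
        diffs = rng.standard_normal((5, 6, 8)) + 0.8
        cfg = mg.PermutationConfig(exhaustive=True, seed=0)
        clusters = mg.permutation_test_tf(diffs, np.zeros_like(diffs), cfg, smooth=False)
        thr = mg.cluster_forming_threshold(0.05, 4)
        null = exhaustive_max_masses(diffs, thr)
        assert len(null) == 32
        for cl in clusters:
            assert cl.p == pytest.approx(mg.monte_carlo_p(cl.mass, null))

    def test_strong_deflection_recovered(self):
        rng = np.random.default_rng(4)
        n_samples, window = 200, slice(80, 110)
        contrasts = 0.5 * rng.standard_normal((5, n_samples))
        contrasts[:, window] += 5 * 0.5
        cfg = mg.PermutationConfig(n_permutations=500, seed=1)
        sig = mg.significant(mg.permutation_test_time(contrasts, cfg), 0.05)
        assert sig, "expected a significant cluster"
        covered = set(sig[0].indices[0].tolist()) & set(range(80, 110))
        assert sig[0].sign == 1 and len(covered) >= 0.8 * 30

    def test_label_swap_equals_sign_flip_permutation_for_permutation(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((6, 7, 9)) + 0.5
        b = rng.standard_normal((6, 7, 9))
        cfg = mg.PermutationConfig(n_permutations=64, seed=11)
        clusters = mg.permutation_test_tf(a, b, cfg, smooth=False)
        # independent route: literally swap each subject's (A, B) pair
        signs = np.random.default_rng(cfg.seed).choice([1.0, -1.0], size=(64, 6))
        thr = mg.cluster_forming_threshold(0.05, 5)
        null = []
        for s in signs:
            swap = s < 0
            aa = np.where(swap[:, None, None], b, a)
            bb = np.where(swap[:, None, None], a, b)
            t = one_sample_t(aa - bb)
            masses = [abs(m) for _, _, m in brute_force_clusters(t, thr)]
            null.append(max(masses, default=0.0))
        null = np.array(null)
        for cl in clusters:
            assert cl.p == pytest.approx(mg.monte_carlo_p(cl.mass, null))

    def test_min_p_nonincreasing_along_effect_ladder(self):
        rng = np.random.default_rng(6)
        noise = rng.standard_normal((8, 5, 30))
        template = np.zeros((5, 30))
        template[2:4, 10:18] = 1.0
        cfg = mg.PermutationConfig(n_permutations=200, seed=2)
        min_ps = []
        for scale in (0.0, 2.0, 4.0, 8.0):
            cls = mg.permutation_test_tf(noise + scale * template, np.zeros_like(noise),
                                         cfg, smooth=False)
            min_ps.append(min((c.p for c in cls), default=1.0))
        assert all(b <= a for a, b in zip(min_ps, min_ps[1:]))

    def test_p_values_within_unit_interval(self):
        rng = np.random.default_rng(7)
        cls = mg.permutation_test_time(rng.standard_normal((6, 40)),
                                       mg.PermutationConfig(n_permutations=100, seed=3))
        assert all(0.0 <= c.p <= 1.0 for c in cls)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            mg.permutation_test_time(np.zeros((1, 10)),
                                     mg.PermutationConfig(n_permutations=10))
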