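"""Voxel-pair t-tests, envelopes, Monte-Carlo FWER thresholds, split halves."""

import numpy as np
import pytest
from scipy import stats as sps

from rfnclust.connectivity import CCMatrix, threshold_cc
from rfnclust.stats import (
    FWERCurve,
    SignificanceConfig,
    _smin_from_max_sizes,
    analytic_envelope,
    cluster_size_threshold,
    fwer_curve,
    is_significant,
    lower_envelope,
    moments,
    null_cc_tail,
    pair_t_test,
    split_half,
)
from rfnclust.synthetic import generate_box_mask


class TestPairTTest:
    def test_hand_computed_t(self):
        """(0.1, 0.2, 0.3, 0.4): mean 0.25, sd 0.1291 -> t = 3.873."""
        t, p = pair_t_test(np.array([0.1, 0.2, 0.3, 0.4]))
        expect = 0.25 / (np.std([0.1, 0.2, 0.3, 0.4], ddof=1) / 2.0)
        assert t[0] == pytest.approx(expect, abs=1e-9)
        assert t[0] == pytest.approx(3.8729833462, abs=1e-9)
        assert p[0] == pytest.approx(2 * sps.t.sf(expect, df=3), abs=1e-12)

    def test_symmetric_values_give_zero(self):
        t, _ = pair_t_test(np.array([-0.3, -0.1, 0.1, 0.3]))
        assert t[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_gives_t0_p1(self):
        t, p = pair_t_test(np.zeros(5))
        assert t[0] == 0.0 and p[0] == 1.0

    def test_zero_variance_nonzero_mean_flagged_infinite(self):
        t, p = pair_t_test(np.full(5, 0.4))
        assert np.isinf(t[0]) and p[0] == 0.0

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            pair_t_test(np.array([0.1, 0.2]))


class TestMoments:
    def test_symmetric_sample_zero_skew(self):
        s, _ = moments(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_near_zero_excess_kurtosis(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        _, k = moments(x)
        assert abs(k[0]) < 0.1

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            moments(np.ones(5))


class TestLowerEnvelope:
    def test_single_bin(self):
        env = lower_envelope(np.array([5.0, 3.0, 4.0]), np.array([0.2, 0.201, 0.202]),
                             bin_width=0.05, df=9)
        assert len(env.t_min) == 1
        assert env.t_min[0] == 3.0

    def test_linear_construction_recovered(self):
        """t = 20*cc exactly: the envelope returns 20*cc at bin centers."""
        cc = np.linspace(0.05, 0.5, 200)
        env = lower_envelope(20 * cc, cc, bin_width=0.05, df=9)
        # per-bin minimum of 20*cc is 20*(bin lower edge): within one bin width
        np.testing.assert_allclose(env.t_min, 20 * (env.cc_centers - 0.025), atol=0.5)

    def test_p_nonincreasing_in_cc(self):
        rng = np.random.default_rng(1)
        cc = rng.uniform(0, 0.6, 500)
        t = 15 * cc + rng.normal(0, 1, 500)
        env = lower_envelope(t, cc, bin_width=0.02, df=19)
        assert np.all(np.diff(env.p) <= 1e-18)
        assert env.p_at(0.1) >= env.p_at(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lower_envelope(np.array([]), np.array([]), 0.01, df=3)


class TestClusterSizeThreshold:
    def test_tiny_voxel_p_no_smoothing_gives_one(self):
        """Expected supra-threshold count 1000 * 1e-8 << alpha: S_min = 1."""
        mask = generate_box_mask((10, 10, 10), voxel_size_mm=(3, 3, 3))
        cfg = SignificanceConfig(alpha_fwer=0.01, n_iterations=500, seed=3)
        assert cluster_size_threshold(mask, 1e-8, 0.0, cfg) == 1

    def test_alpha_out_of_range_rejected(self):
        # the config invariant demands alpha in (0, 1); the degenerate
        # "every cluster passes" limit lives in the tail estimator itself
        mask = generate_box_mask((5, 5, 4))
        cfg = SignificanceConfig(alpha_fwer=0.5, n_iterations=100, seed=0)
        cfg.alpha_fwer = 1.0
        with pytest.raises(ValueError):
            cluster_size_threshold(mask, 0.01, 0.0, cfg)

    def test_monotone_in_fwhm_and_voxel_p(self):
        """Paired seeds: smoothing enlarges null clusters; laxer voxel p too."""
        mask = generate_box_mask((12, 12, 6), voxel_size_mm=(3, 3, 3))
        cfg = SignificanceConfig(alpha_fwer=0.05, n_iterations=400, seed=11)
        s_smooth = cluster_size_threshold(mask, 0.01, 6.0, cfg)
        s_flat = cluster_size_threshold(mask, 0.01, 0.0, cfg)
        assert s_smooth >= s_flat
        s_lax = cluster_size_threshold(mask, 0.05, 0.0, cfg)
        assert s_lax >= s_flat

    def test_smin_estimator_unit(self):
        # 10% of iterations reach max size 5; at alpha=0.05, S_min must exceed 5
        sizes = np.array([5] * 10 + [1] * 90)
        assert _smin_from_max_sizes(sizes, 0.05) == 6
        assert _smin_from_max_sizes(sizes, 0.15) == 2
        assert _smin_from_max_sizes(sizes, 1.0) == 1


class TestFWERCurve:
    def make_env(self):
        grid = np.arange(0.05, 0.51, 0.05)
        return analytic_envelope(0.3, 120, 10, grid), grid

    def test_single_point_curve_matches_threshold(self):
        mask = generate_box_mask((8, 8, 4), voxel_size_mm=(3, 3, 3))
        cfg = SignificanceConfig(alpha_fwer=0.05, n_iterations=300, seed=5)
        env, _ = self.make_env()
        grid = np.array([0.1])
        curve = fwer_curve(mask, env, 0.0, cfg, grid)
        direct = cluster_size_threshold(mask, env.p_at(0.1), 0.0, cfg)
        assert curve.s_min[0] == direct

    def test_curve_nonincreasing(self):
        mask = generate_box_mask((8, 8, 4), voxel_size_mm=(3, 3, 3))
        cfg = SignificanceConfig(alpha_fwer=0.05, n_iterations=300, seed=6)
        env, grid = self.make_env()
        curve = fwer_curve(mask, env, 4.0, cfg, grid)
        assert np.all(np.diff(curve.s_min) <= 0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            FWERCurve(min_cc=np.array([0.2, 0.1]), s_min=np.array([5, 3]))


class TestIsSignificant:
    def curve(self):
        return FWERCurve(min_cc=np.array([0.1, 0.2, 0.3]), s_min=np.array([40, 10, 5]))

    def test_floor_dominates(self):
        cfg = SignificanceConfig(size_floor=12)
        assert is_significant((12, 0.25), self.curve(), cfg) is True
        assert is_significant((11, 0.25), self.curve(), cfg) is False

    def test_below_curve_value_false(self):
        cfg = SignificanceConfig(size_floor=12)
        assert is_significant((20, 0.12), self.curve(), cfg) is False  # needs 40
        assert is_significant((45, 0.12), self.curve(), cfg) is True

    def test_uncovered_cc_false(self):
        cfg = SignificanceConfig(size_floor=12)
        assert is_significant((100, 0.05), self.curve(), cfg) is False
        assert is_significant((100, float("nan")), self.curve(), cfg) is False


class TestSplitHalf:
    def make_ccs(self, n, rng):
        out = []
        for _ in range(n):
            vals = rng.uniform(0, 1, 10).astype(np.float32)
            out.append(threshold_cc(CCMatrix(values=vals, n_voxels=5), 0.3))
        return out

    def test_halves_have_equal_size(self, rng):
        a, b = split_half(self.make_ccs(8, rng), seed=4)
        assert a.n_subjects == b.n_subjects == 4

    def test_same_seed_same_split(self, rng):
        ccs = self.make_ccs(10, rng)
        a1, b1 = split_half(ccs, seed=9)
        a2, b2 = split_half(ccs, seed=9)
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(b1.values, b2.values)

    def test_union_is_full_set(self, rng):
        ccs = self.make_ccs(6, rng)
        a, b = split_half(ccs, seed=2)
        total = np.stack([c.values for c in ccs]).mean(axis=0)
        np.testing.assert_allclose((a.values + b.values) / 2, total, atol=1e-6)

    def test_odd_count_rejected(self, rng):
        with pytest.raises(ValueError):
            split_half(self.make_ccs(7, rng), seed=0)


def test_null_cc_tail_matches_beta_form():
    """Cross-check the t-transform tail against the exact beta distribution of
    r^2 under the null."""
    for tau, n in [(0.3, 290), (0.15, 60), (0.5, 20)]:
        df = n - 2
        # r has density prop. to (1-r^2)^((df-2)/2); P(r >= tau) via betainc
        exact = sps.beta.sf(tau**2, 0.5, df / 2) / 2
        assert null_cc_tail(tau, n) == pytest.approx(exact, rel=1e-10)
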