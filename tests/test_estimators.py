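import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsuite import estimators as est
from mrsuite.instruments import HarmonizedPair
from mrsuite.simulate import SimConfig, harmonize_simulated, simulate_summary_stats

from conftest import make_harmonized, random_harmonized


def brute_force_weighted_median(ratios, weights):
    """Independent oracle: dense scan of the cumulative-weight function."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    running = 0.0
    prev_cum = prev_r = None
    for rj, wj in zip(r, w):
        cum = running + wj / 2.0
        if cum >= 0.5:
            if prev_cum is None:
                return float(rj)
            return float(prev_r + (rj - prev_r) * (0.5 - prev_cum) / (cum - prev_cum))
        running += wj
        prev_cum, prev_r = cum, rj
    return float(r[-1])


class TestWaldRatio:
    def test_arithmetic(self):
        p = HarmonizedPair("rs1", beta_exp=0.1, se_exp=0.01, beta_out=0.2, se_out=0.05)
        r = est.wald_ratio(p)
        assert r.ratio == pytest.approx(2.0)
        assert r.ratio_se == pytest.approx(0.5)
        assert r.weight == pytest.approx(4.0)

    def test_null_outcome(self):
        p = HarmonizedPair("rs1", 0.1, 0.01, 0.0, 0.05)
        assert est.wald_ratio(p).ratio == 0.0

    def test_orientation_sensitivity(self):
        p = HarmonizedPair("rs1", -0.1, 0.01, 0.2, 0.05)
        r = est.wald_ratio(p)
        assert r.ratio == pytest.approx(-2.0)
        assert r.ratio_se == pytest.approx(0.5)  # SE uses |gamma|

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(est.DegenerateInstrumentError):
            est.wald_ratio(HarmonizedPair("rs1", 0.0, 0.01, 0.2, 0.05))


class TestIvw:
    def test_perfect_homogeneity(self):
        data = make_harmonized([0.1, 0.2], [0.01, 0.01], [0.2, 0.4], [0.05, 0.05])
        e, het = est.ivw(data)
        assert e.b == pytest.approx(2.0)
        assert het.q == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        # independent closed-form WLS through the origin:
        # b = sum(w g G)/sum(w g^2) with equal weights
        data = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3,
                               [0.05, 0.04, 0.09], [0.01] * 3)
        e, _ = est.ivw(data)
        assert e.b == pytest.approx(0.04 / 0.14, abs=1e-12)

    def test_single_snp_equals_wald_ratio(self):
        data = make_harmonized([0.1], [0.01], [0.2], [0.05])
        e, het = est.ivw(data)
        r = est.wald_ratio(data.pairs[0])
        assert e.b == r.ratio and e.se == r.ratio_se
        assert het is None

    def test_fixed_and_re_share_point_estimate(self, rng):
        data = random_harmonized(rng, 12)
        ef, _ = est.ivw(data, model="fixed")
        er, _ = est.ivw(data, model="multiplicative_re")
        assert ef.b == er.b
        assert er.se >= ef.se

    def test_q_invariant_to_order_and_flips(self, rng):
        data = random_harmonized(rng, 8)
        _, het = est.ivw(data)
        flipped = make_harmonized(
            *[np.array(a) * s for a, s in zip(
                (np.array([p.beta_exp for p in data.pairs]),
                 np.array([p.se_exp for p in data.pairs]),
                 np.array([p.beta_out for p in data.pairs]),
                 np.array([p.se_out for p in data.pairs])),
                (-1, 1, -1, 1))]
        )
        _, het_f = est.ivw(flipped)
        assert het_f.q == pytest.approx(het.q, rel=1e-12)
        perm = data.subset(np.array([3, 1, 0, 2, 7, 6, 5, 4]))
        _, het_p = est.ivw(perm)
        assert het_p.q == pytest.approx(het.q, rel=1e-12)

    @given(c=st.floats(min_value=-3, max_value=3).filter(lambda v: abs(v) > 1e-3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scaling_outcome_scales_estimate(self, c):
        rng = np.random.default_rng(11)
        data = random_harmonized(rng, 6)
        bx, sx, by, sy = data.arrays()
        scaled = make_harmonized(bx, sx, c * by, sy)
        e0, _ = est.ivw(data)
        e1, _ = est.ivw(scaled)
        assert e1.b == pytest.approx(c * e0.b, rel=1e-9)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.01 + 0.5 * bx
        data = make_harmonized(bx, [0.01] * 4, by, [0.01] * 4)
        res = est.egger(data)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.slope.b == pytest.approx(0.5, abs=1e-12)

    def test_collinear_through_origin_matches_ivw(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        data = make_harmonized(bx, [0.01] * 4, 0.7 * bx, [0.01] * 4)
        res = est.egger(data)
        e, _ = est.ivw(data)
        assert abs(res.intercept) < 1e-10
        assert res.slope.b == pytest.approx(e.b, abs=1e-10)

    def test_i2_floored_at_zero_when_no_spread(self):
        data = make_harmonized([0.1] * 4, [0.02] * 4, [0.05, 0.06, 0.04, 0.05],
                               [0.01] * 4)
        res = est.egger(data)
        assert res.i2_gx == 0.0

    def test_orientation_internal_only(self):
        bx = np.array([0.05, -0.1, 0.2, -0.3])
        by = 0.4 * bx + np.array([0.001, -0.002, 0.001, 0.0])
        data = make_harmonized(bx, [0.01] * 4, by, [0.01] * 4)
        before = [p.beta_exp for p in data.pairs]
        est.egger(data)
        assert [p.beta_exp for p in data.pairs] == before

    def test_two_snps_not_computable(self):
        data = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        res = est.egger(data)
        assert isinstance(res, est.NotComputable)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        data = make_harmonized([1, 1, 1], [0.01] * 3, [1, 2, 3], [1, 1, 1])
        e = est.weighted_median(data, n_boot=50, seed=0)
        assert e.b == pytest.approx(2.0)

    def test_weight_crossing_inside_middle_rank(self):
        # ratios (1,2,10), weights prop to (0.45,0.10,0.45): the centered
        # cumulative weight hits 0.5 exactly at the middle ratio
        sy = 1.0 / np.sqrt(np.array([0.45, 0.10, 0.45]))
        data = make_harmonized([1, 1, 1], [0.001] * 3, [1.0, 2.0, 10.0], sy)
        e = est.weighted_median(data, n_boot=50, seed=0)
        assert e.b == pytest.approx(2.0)

    def test_degenerate_identical_ratios(self):
        data = make_harmonized([0.1] * 4, [1e-8] * 4, [0.25] * 4, [1e-8] * 4)
        e = est.weighted_median(data, n_boot=100, seed=0)
        assert e.b == pytest.approx(2.5)
        assert e.se < 1e-5

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        from mrsuite.estimators import _weighted_median_point
        for _ in range(50):
            n = int(rng.integers(3, 11))
            ratios = rng.normal(size=n)
            weights = rng.uniform(0.1, 2.0, size=n)
            ours = _weighted_median_point(ratios, weights)
            oracle = brute_force_weighted_median(ratios, weights)
            assert ours == pytest.approx(oracle, abs=1e-9)


class TestWeightedMode:
    def test_dominant_cluster(self):
        data = make_harmonized([1, 1, 1, 1], [0.01] * 4, [2, 2, 2, 5], [1] * 4)
        e = est.weighted_mode(data, n_boot=50, seed=0)
        assert e.b == pytest.approx(2.0, abs=0.1)

    def test_tie_breaks_toward_smaller_magnitude(self):
        # two equal clusters, symmetric around 0
        data = make_harmonized([1] * 6, [0.001] * 6,
                               [-2.0, -2.0, -2.0, 2.0, 2.0, 2.0], [1] * 6)
        e = est.weighted_mode(data, n_boot=20, seed=0)
        assert abs(e.b) <= 2.0
        assert e.extras["multimodal"]

    def test_identical_ratios_zero_bandwidth(self):
        data = make_harmonized([0.1] * 3, [0.001] * 3, [0.3] * 3, [0.01] * 3)
        e = est.weighted_mode(data, n_boot=30, seed=0)
        assert e.b == pytest.approx(3.0)

    def test_matches_dense_grid_oracle(self, rng):
        from mrsuite.estimators import _mode_bandwidth, _weighted_mode_point
        cfg = SimConfig(n_snp=20, true_b=0.1, seed=1)
        exp, out, _ = simulate_summary_stats(cfg)
        data = harmonize_simulated(exp, out)
        bx, sx, by, sy = data.arrays()
        ratios = by / bx
        weights = bx**2 / sy**2
        ours, _ = _weighted_mode_point(ratios, weights, phi=1.0)
        # dense-grid oracle
        h = _mode_bandwidth(ratios, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200_001)
        w = weights / weights.sum()
        dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2), axis=1)
        oracle = grid[np.argmax(dens)]
        assert ours == pytest.approx(oracle, abs=(grid[-1] - grid[0]) / 510)


class TestRaps:
    def test_noiseless_limit_recovers_common_ratio(self):
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        data = make_harmonized(bx, [1e-6] * 4, 0.42 * bx, [1e-6] * 4)
        e = est.mr_raps(data)
        assert e.b == pytest.approx(0.42, abs=1e-6)
        assert e.extras["tau2"] == pytest.approx(0.0, abs=1e-10)

    def test_null_pleiotropy_recovery(self):
        cfg = SimConfig(n_snp=76, true_b=-0.1, seed=5)
        exp, out, truth = simulate_summary_stats(cfg)
        data = harmonize_simulated(exp, out)
        e = est.mr_raps(data)
        assert e.b == pytest.approx(truth.true_b, abs=3 * e.se)
        assert e.extras["tau2"] < 1e-4

    def test_balanced_pleiotropy_overdispersion_and_bias(self):
        # tau^2 should be detected and b stay unbiased within MC error
        errs = []
        tau2s = []
        for r in range(30):
            cfg = SimConfig(n_snp=76, true_b=-0.1, prop_invalid=0.9,
                            tau_alpha=0.002, seed=100 + r)
            exp, out, _ = simulate_summary_stats(cfg)
            e = est.mr_raps(harmonize_simulated(exp, out))
            if isinstance(e, est.NotComputable):
                continue
            errs.append(e.b + 0.1)
            tau2s.append(e.extras["tau2"])
        assert np.median(tau2s) > 0
        mc_se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 4 * mc_se + 0.005


class TestLeaveOneOut:
    def test_homogeneous_estimates_all_equal(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        data = make_harmonized(bx, [0.01] * 4, 1.5 * bx, [0.01] * 4)
        res = est.leave_one_out(data)
        for e in res.estimates:
            assert e.b == pytest.approx(res.full.b, abs=1e-12)
        assert not any(res.flags)

    def test_structure_with_three_snps(self):
        data = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3,
                               [0.2, 0.41, 0.58], [0.01] * 3)
        res = est.leave_one_out(data)
        assert len(res.estimates) == 3
        assert all(e.n_snp == 2 for e in res.estimates)

    def test_injected_outlier_is_flagged(self):
        # nine concordant SNPs with ratio 0.05 plus one gross outlier whose
        # removal changes the sign of the pooled estimate
        bx = np.full(10, 0.1)
        by = 0.05 * bx
        k = 4
        by[k] = -0.5
        data = make_harmonized(bx, np.full(10, 0.005), by, np.full(10, 0.01))
        res = est.leave_one_out(data)
        flagged = [i for i, f in enumerate(res.flags) if f]
        assert flagged == [k]
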