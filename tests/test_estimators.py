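"""Causal estimators: Wald ratio, IVW, weighted median, MR-Egger."""
import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from mrkit.estimators import egger, ivw, wald_ratio, weighted_median, _weighted_median

from conftest import make_instruments


class TestWaldRatio:
    def test_hand_arithmetic(self):
        (i,) = make_instruments([0.1], [0.05], [0.01])
        est = wald_ratio(i)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_numerator(self):
        (i,) = make_instruments([0.1], [0.0], [0.01])
        est = wald_ratio(i)
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_simultaneous_sign_flip_invariance(self):
        (a,) = make_instruments([0.1], [0.05], [0.01])
        (b,) = make_instruments([-0.1], [-0.05], [0.01])
        assert wald_ratio(a).beta == wald_ratio(b).beta

    def test_zero_denominator_is_an_error(self):
        (i,) = make_instruments([0.0], [0.05], [0.01])
        with pytest.raises(ValueError, match="ratio undefined"):
            wald_ratio(i)


class TestIVW:
    def test_two_identical_instruments_pool_to_single_ratio(self):
        instrs = make_instruments([0.1, 0.1], [0.05, 0.05], [0.01, 0.01])
        est = ivw(instrs, model="fe")
        single = wald_ratio(instrs[0])
        assert est.beta == pytest.approx(single.beta)
        assert est.se == pytest.approx(single.se / np.sqrt(2))

    def test_matches_zero_intercept_wls_oracle(self):
        import statsmodels.api as sm

        g = np.array([0.1, 0.2, 0.15])
        G = np.array([0.05, 0.08, 0.09])
        sG = np.array([0.01, 0.02, 0.015])
        est = ivw(make_instruments(g, G, sG), model="fe")
        fit = sm.WLS(G, g, weights=1.0 / sG**2).fit()
        assert est.beta == pytest.approx(float(fit.params[0]), rel=1e-10)
        base_se = float(fit.bse[0]) / np.sqrt(fit.scale)
        assert est.se == pytest.approx(base_se, rel=1e-10)

    def test_mre_floor_engages_on_homogeneous_data(self):
        g = np.full(4, 0.1)
        G = 0.5 * g + np.array([1e-5, -1e-5, 2e-5, 0.0])
        instrs = make_instruments(g, G, np.full(4, 0.05))
        assert ivw(instrs, model="mre").se == ivw(instrs, model="fe").se

    def test_mre_inflates_under_heterogeneity(self):
        instrs = make_instruments([0.1, 0.1, 0.1], [0.02, 0.05, 0.09], [0.001, 0.001, 0.001])
        assert ivw(instrs, model="mre").se > ivw(instrs, model="fe").se

    def test_equal_weights_reduce_to_mean_of_ratios(self):
        g = np.full(5, 0.2)
        G = np.array([0.02, 0.05, 0.03, 0.06, 0.04])
        instrs = make_instruments(g, G, np.full(5, 0.01))
        assert ivw(instrs, model="fe").beta == pytest.approx(np.mean(G / g), rel=1e-12)

    def test_single_instrument_delegates_to_wald(self):
        instrs = make_instruments([0.1], [0.05], [0.01])
        est = ivw(instrs)
        assert est.method == "wald"

    def test_ordering_and_sign_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0.05, 0.3, 6)
        G = 0.3 * g + rng.normal(0, 0.01, 6)
        sG = rng.uniform(0.005, 0.02, 6)
        base = ivw(make_instruments(g, G, sG)).beta
        perm = rng.permutation(6)
        assert ivw(make_instruments(g[perm], G[perm], sG[perm])).beta == pytest.approx(base, rel=1e-12)
        assert ivw(make_instruments(-g, -G, sG)).beta == pytest.approx(base, rel=1e-12)


def brute_force_weighted_median(ratios, weights):
    """Independent oracle: walk the weighted CDF midpoints segment by segment."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order] / np.sum(weights)
    s = [np.sum(w[: j + 1]) - w[j] / 2.0 for j in range(len(r))]
    if 0.5 <= s[0]:
        return r[0]
    for j in range(len(r) - 1):
        if s[j] <= 0.5 <= s[j + 1]:
            frac = (0.5 - s[j]) / (s[j + 1] - s[j])
            return r[j] + frac * (r[j + 1] - r[j])
    return r[-1]


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        g = np.full(3, 0.1)
        G = g * np.array([0.2, 0.5, 0.9])
        est = weighted_median(make_instruments(g, G, np.full(3, 0.01)), seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_constant_ratios_return_constant(self):
        g = np.array([0.1, 0.2, 0.3, 0.15])
        est = weighted_median(make_instruments(g, 0.7 * g, [0.01, 0.04, 0.02, 0.03]), seed=1)
        assert est.beta == pytest.approx(0.7, rel=1e-12)

    def test_matches_brute_force_cdf_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = 5
            ratios = rng.normal(0.3, 0.5, k)
            weights = rng.uniform(0.1, 5.0, k)
            assert _weighted_median(ratios, weights) == pytest.approx(
                brute_force_weighted_median(ratios, weights), abs=1e-12
            )

    def test_equal_weights_equal_unweighted_interpolated_median(self):
        ratios = np.array([0.1, 0.9, 0.4, 0.7, 0.2])
        w = np.ones(5)
        # unweighted interpolated median at midpoints (j+0.5)/k
        s = (np.arange(5) + 0.5) / 5
        expected = np.interp(0.5, s, np.sort(ratios))
        assert _weighted_median(ratios, w) == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_is_seed_reproducible(self):
        g = np.array([0.1, 0.2, 0.15, 0.12])
        G = 0.4 * g + np.array([0.01, -0.02, 0.0, 0.005])
        instrs = make_instruments(g, G, np.full(4, 0.01))
        a = weighted_median(instrs, n_boot=200, seed=9)
        b = weighted_median(instrs, n_boot=200, seed=9)
        assert a.se == b.se

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match=">= 3"):
            weighted_median(make_instruments([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]), seed=1)


class TestEgger:
    def test_exact_proportional_data(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        intercept, slope = egger(make_instruments(g, 0.3 * g, np.full(4, 0.01)))
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_data(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        intercept, slope = egger(make_instruments(g, 0.02 + 0.3 * g, np.full(4, 0.01)))
        assert intercept.beta == pytest.approx(0.02, abs=1e-12)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)

    def test_matches_wls_oracle_on_noisy_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        g = rng.uniform(0.05, 0.3, 4)
        sG = rng.uniform(0.005, 0.02, 4)
        G = 0.01 + 0.25 * g + rng.normal(0, sG)
        intercept, slope = egger(make_instruments(g, G, sG))
        X = sm.add_constant(g)
        fit = sm.WLS(G, X, weights=1.0 / sG**2).fit()
        assert intercept.beta == pytest.approx(float(fit.params[0]), rel=1e-10)
        assert slope.beta == pytest.approx(float(fit.params[1]), rel=1e-10)

    def test_orients_exposure_effects_positive(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(0.05, 0.3, 5)
        sG = np.full(5, 0.01)
        G = 0.01 + 0.25 * g
        base_int, base_slope = egger(make_instruments(g, G, sG))
        flip = np.array([1, -1, 1, -1, 1.0])
        fl_int, fl_slope = egger(make_instruments(g * flip, G * flip, sG))
        assert fl_slope.beta == pytest.approx(base_slope.beta, rel=1e-12)
        assert fl_int.beta == pytest.approx(base_int.beta, rel=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match=">= 3"):
            egger(make_instruments([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(0.02, 0.5), st.floats(-0.3, 0.3), st.floats(0.005, 0.05)
        ),
        min_size=3,
        max_size=10,
    ),
    st.randoms(use_true_random=False),
)
def test_all_estimators_invariant_to_order_and_joint_sign_flips(data, rnd):
    """Permuting instruments or negating (gamma, Gamma) pairs together never
    changes any estimator's point estimate."""
    g = np.array([d[0] for d in data])
    G = np.array([d[1] for d in data])
    sG = np.array([d[2] for d in data])
    assume(np.ptp(np.abs(g)) > 1e-3)  # Egger needs spread in |gamma|
    base_ivw = ivw(make_instruments(g, G, sG)).beta
    base_wm = weighted_median(make_instruments(g, G, sG), n_boot=50, seed=1).beta
    base_slope = egger(make_instruments(g, G, sG))[1].beta

    idx = list(range(len(g)))
    rnd.shuffle(idx)
    signs = np.array([rnd.choice([-1.0, 1.0]) for _ in idx])
    g2, G2, sG2 = g[idx] * signs, G[idx] * signs, sG[idx]
    assert ivw(make_instruments(g2, G2, sG2)).beta == pytest.approx(base_ivw, rel=1e-9)
    assert weighted_median(make_instruments(g2, G2, sG2), n_boot=50, seed=1).beta == pytest.approx(
        base_wm, rel=1e-9
    )
    assert egger(make_instruments(g2, G2, sG2))[1].beta == pytest.approx(base_slope, rel=1e-9)
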