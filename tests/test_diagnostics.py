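"""Heterogeneity and pleiotropy diagnostics: Q, MR-PRESSO, intercept, LOO."""
import numpy as np
import pytest
from scipy import stats

from mrkit.diagnostics import (
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    pleiotropy_report,
    presso,
)
from mrkit.estimators import ivw

from conftest import make_instruments


def _planted_outlier_set(seed=123, k=10, theta=0.3, shift=10.0):
    """k-1 consistent instruments plus one with its outcome effect shifted."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.05, 0.3, k)
    sG = rng.uniform(0.008, 0.02, k)
    G = theta * g + rng.normal(0, 0.2 * sG, k)
    G[-1] += shift * sG[-1]
    return make_instruments(g, G, sG)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        g = np.array([0.1, 0.2, 0.3])
        res = cochran_q(make_instruments(g, 0.5 * g, np.full(3, 0.01)))
        assert res.q_stat == pytest.approx(0.0, abs=1e-20)
        assert res.q_pval == pytest.approx(1.0)

    def test_two_instrument_hand_value(self):
        # ratios 0 and 1 with unit weights: pooled 0.5, Q = 0.5
        instrs = make_instruments([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        res = cochran_q(instrs)
        assert res.q_stat == pytest.approx(0.5)
        assert res.q_df == 1

    def test_null_mean_matches_chi_square_df(self):
        """Under homogeneity, E[Q] = k - 1 (checked at 2,000 simulations)."""
        rng = np.random.default_rng(5)
        k, n_sim = 10, 2000
        g = rng.uniform(0.05, 0.3, k)
        sG = rng.uniform(0.01, 0.03, k)
        qs = np.empty(n_sim)
        for i in range(n_sim):
            G = 0.2 * g + rng.normal(0, sG)
            qs[i] = cochran_q(make_instruments(g, G, sG)).q_stat
        mc_se = np.std(qs, ddof=1) / np.sqrt(n_sim)
        assert abs(qs.mean() - (k - 1)) < 2 * mc_se

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(8)
        k = 10
        g = rng.uniform(0.05, 0.3, k)
        sG = rng.uniform(0.01, 0.03, k)
        pvals = np.empty(1000)
        for i in range(1000):
            G = 0.2 * g + rng.normal(0, sG)
            pvals[i] = cochran_q(make_instruments(g, G, sG)).q_pval
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_scaling_law(self):
        """Multiplying all outcome SEs by c divides Q by c^2."""
        rng = np.random.default_rng(3)
        g = rng.uniform(0.05, 0.3, 6)
        G = 0.3 * g + rng.normal(0, 0.02, 6)
        sG = rng.uniform(0.01, 0.03, 6)
        q1 = cochran_q(make_instruments(g, G, sG)).q_stat
        q3 = cochran_q(make_instruments(g, G, 3.0 * sG)).q_stat
        assert q3 == pytest.approx(q1 / 9.0, rel=1e-12)

    def test_needs_two_instruments(self):
        with pytest.raises(ValueError):
            cochran_q(make_instruments([0.1], [0.05], [0.01]))


class TestPresso:
    def test_null_data_has_large_global_p_and_no_outliers(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0.05, 0.3, 8)
        sG = np.full(8, 0.01)
        G = 0.3 * g + rng.normal(0, 0.05 * sG, 8)  # tiny noise vs stated SE
        res = presso(make_instruments(g, G, sG), n_sim=500, seed=2)
        assert res.global_pval > 0.5
        assert res.outliers == []
        assert res.distortion_pval is None

    def test_planted_outlier_is_flagged_alone(self):
        instrs = _planted_outlier_set()
        res = presso(instrs, n_sim=1000, seed=77)
        assert res.outliers == [instrs[-1].variant_id]
        assert res.global_pval < 0.05
        assert res.distortion_pval is not None

    def test_fixed_seed_is_bit_reproducible(self):
        instrs = _planted_outlier_set()
        a = presso(instrs, n_sim=300, seed=5)
        b = presso(instrs, n_sim=300, seed=5)
        assert a.global_pval == b.global_pval
        assert a.outlier_pvals == b.outlier_pvals

    def test_global_p_never_zero(self):
        res = presso(_planted_outlier_set(shift=50.0), n_sim=200, seed=3)
        assert res.global_pval >= 1.0 / 201

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError, match="insufficient instruments"):
            presso(make_instruments([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.01] * 3),
                   n_sim=200, seed=1)


class TestEggerInterceptTest:
    def test_proportional_data_shows_no_pleiotropy(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(0.05, 0.3, 8)
        sG = np.full(8, 0.01)
        G = 0.3 * g + rng.normal(0, 0.3 * sG)  # scatter well below stated SE
        assert egger_intercept_test(make_instruments(g, G, sG)) > 0.05

    def test_strong_directional_pleiotropy_detected(self):
        g = np.array([0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
        G = 0.05 + 0.3 * g  # constant pleiotropic offset, negligible noise
        G = G + np.array([1e-4, -1e-4, 5e-5, -5e-5, 2e-5, 0.0])
        assert egger_intercept_test(make_instruments(g, G, np.full(6, 0.01))) < 0.05

    def test_minimal_case_in_domain(self):
        p = egger_intercept_test(
            make_instruments([0.1, 0.2, 0.3], [0.04, 0.05, 0.1], [0.01] * 3)
        )
        assert 0 < p <= 1


class TestLeaveOneOut:
    def test_identical_instruments_leave_estimate_unchanged(self):
        g = np.full(5, 0.1)
        instrs = make_instruments(g, 0.5 * g, np.full(5, 0.01))
        full = ivw(instrs).beta
        for entry in leave_one_out(instrs):
            assert entry.estimate.beta == pytest.approx(full, rel=1e-12)

    def test_removing_discordant_instrument_shifts_toward_consensus(self):
        instrs = _planted_outlier_set(theta=0.3)
        full = ivw(instrs).beta
        outlier_id = instrs[-1].variant_id
        (entry,) = leave_one_out(instrs, exclude=outlier_id)
        assert abs(entry.estimate.beta - 0.3) < abs(full - 0.3)

    def test_one_entry_per_instrument(self):
        instrs = _planted_outlier_set(k=7)
        entries = leave_one_out(instrs)
        assert [e.excluded_id for e in entries] == [i.variant_id for i in instrs]

    def test_unknown_exclusion_id(self):
        with pytest.raises(KeyError):
            leave_one_out(_planted_outlier_set(), exclude="rs_not_there")


def test_combined_report_consistency():
    instrs = _planted_outlier_set()
    rep = pleiotropy_report(instrs, n_sim=300, seed=11)
    assert rep.q_df == len(instrs) - 1
    assert rep.presso is not None
    assert set(rep.presso.outliers) <= {i.variant_id for i in instrs}
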