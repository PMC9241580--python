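"""Meta-analysis pooling, Bonferroni classification, and analytic power."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrkit.meta import (
    PowerSpec,
    bonferroni_threshold,
    ci_to_se,
    classify_pvalue,
    fixed_effect_meta,
    mr_power_binary,
)


class TestCiToSe:
    def test_degenerate_interval_warns(self):
        with pytest.warns(UserWarning, match="zero-width"):
            log_or, se = ci_to_se(1.0, 1.0, 1.0)
        assert (log_or, se) == (0.0, 0.0)

    def test_heart_failure_study_row(self):
        log_or, se = ci_to_se(1.06, 1.02, 1.10)
        assert log_or == pytest.approx(0.0583, abs=5e-5)
        assert se == pytest.approx(0.0193, abs=5e-5)

    def test_round_trip_recovers_log_or_and_se(self):
        log_or, se = 0.0583, 0.0193
        or_point = math.exp(log_or)
        lo = math.exp(log_or - 1.959964 * se)
        hi = math.exp(log_or + 1.959964 * se)
        back_log_or, back_se = ci_to_se(or_point, lo, hi)
        assert back_log_or == pytest.approx(log_or, abs=5e-4)
        assert back_se == pytest.approx(se, abs=5e-4)

    def test_ordering_violation_is_fatal(self):
        with pytest.raises(ValueError, match="ordering"):
            ci_to_se(1.0, 1.1, 1.2)


class TestFixedEffectMeta:
    def test_single_study_passes_through(self):
        res = fixed_effect_meta([("only", 0.05, 0.02)])
        assert res.pooled.beta == pytest.approx(0.05)
        assert res.pooled.se == pytest.approx(0.02)

    def test_two_heart_failure_studies_reproduce_pooled_row(self):
        """OR 1.06 (1.02-1.10) + OR 1.10 (1.02-1.18) pool to 1.07 (1.03-1.10)."""
        studies = [
            ("discovery", *ci_to_se(1.06, 1.02, 1.10)),
            ("replication", *ci_to_se(1.10, 1.02, 1.18)),
        ]
        res = fixed_effect_meta(studies)
        assert round(math.exp(res.pooled.beta), 2) == 1.07
        assert round(math.exp(res.pooled.ci_low), 2) == 1.03
        assert round(math.exp(res.pooled.ci_high), 2) == 1.10
        assert res.pooled.pval == pytest.approx(1.11e-4, rel=0.05)
        assert res.q_between < res.q_df + 1  # no between-study heterogeneity

    def test_identical_studies_shrink_se_by_sqrt2(self):
        res = fixed_effect_meta([("a", 0.06, 0.02), ("b", 0.06, 0.02)])
        assert res.pooled.beta == pytest.approx(0.06)
        assert res.pooled.se == pytest.approx(0.02 / math.sqrt(2))

    def test_pooled_variance_no_larger_than_best_study(self):
        rng = np.random.default_rng(2)
        studies = [(f"s{i}", rng.normal(0, 0.1), rng.uniform(0.01, 0.1)) for i in range(5)]
        res = fixed_effect_meta(studies)
        assert res.pooled.se <= min(s[2] for s in studies)

    def test_permutation_invariance_and_bounds(self):
        studies = [("a", 0.02, 0.01), ("b", 0.08, 0.03), ("c", 0.05, 0.02)]
        res = fixed_effect_meta(studies)
        perm = fixed_effect_meta(studies[::-1])
        assert res.pooled.beta == pytest.approx(perm.pooled.beta, rel=1e-12)
        betas = [s[1] for s in studies]
        assert min(betas) <= res.pooled.beta <= max(betas)

    def test_empty_input_is_fatal(self):
        with pytest.raises(ValueError):
            fixed_effect_meta([])


class TestBonferroni:
    def test_nine_outcome_threshold(self):
        thr = bonferroni_threshold(0.05, 9)
        assert float(f"{thr:.2g}") == 0.0056

    def test_single_test_threshold(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_published_study_pvalues_classify(self):
        assert classify_pvalue(0.004, 0.05, 9) == "significant"
        assert classify_pvalue(0.010, 0.05, 9) == "suggestive"
        assert classify_pvalue(0.2, 0.05, 9) == "null"


class TestPower:
    def test_null_limit_equals_alpha(self):
        spec = PowerSpec(n_outcome=10_000, case_fraction=0.1, r2_x=1e-12, or_alt=1.2)
        assert mr_power_binary(spec) == pytest.approx(0.05, abs=1e-6)

    def test_consistency_limit(self):
        spec = PowerSpec(n_outcome=10**9, case_fraction=0.1, r2_x=0.05, or_alt=1.05)
        assert mr_power_binary(spec) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.integers(1_000, 1_000_000),
        st.floats(0.01, 0.5),
        st.floats(1e-4, 0.2),
        st.floats(1.01, 2.0),
    )
    def test_monotone_in_sample_size_r2_and_effect(self, n, k_frac, r2, or_alt):
        base = mr_power_binary(PowerSpec(n, k_frac, r2, or_alt))
        assert mr_power_binary(PowerSpec(2 * n, k_frac, r2, or_alt)) >= base - 1e-12
        assert mr_power_binary(PowerSpec(n, k_frac, 2 * r2, or_alt)) >= base - 1e-12
        assert mr_power_binary(PowerSpec(n, k_frac, r2, or_alt**1.5)) >= base - 1e-12

    def test_matches_monte_carlo_score_test_oracle(self):
        """Simulate the genetic score -> binary outcome design and compare the
        empirical rejection rate of the per-replicate association test with
        the analytic approximation (10,000 replicates)."""
        n, K, R2, OR = 10_000, 0.5, 0.05, 1.2
        spec = PowerSpec(n_outcome=n, case_fraction=K, r2_x=R2, or_alt=OR)
        approx = mr_power_binary(spec)
        b = math.log(OR)

        # intercept for marginal prevalence K under logit(P) = a + b * x
        from scipy.optimize import brentq

        xs = np.random.default_rng(0).normal(0, 1, 200_000)
        a = brentq(lambda a0: np.mean(1 / (1 + np.exp(-(a0 + b * xs)))) - K, -5, 5)

        rng = np.random.default_rng(1)
        z = stats.norm.ppf(0.975)
        reps, chunk, rej = 10_000, 500, 0
        done = 0
        while done < reps:
            m = min(chunk, reps - done)
            done += m
            g = rng.normal(0, math.sqrt(R2), (m, n))
            x = g + rng.normal(0, math.sqrt(1 - R2), (m, n))
            p = 1 / (1 + np.exp(-(a + b * x)))
            y = (rng.random((m, n)) < p).astype(float)
            gm = g - g.mean(1, keepdims=True)
            ym = y - y.mean(1, keepdims=True)
            bh = (gm * ym).sum(1) / (gm * gm).sum(1)
            resid = ym - bh[:, None] * gm
            se = np.sqrt((resid**2).sum(1) / (n - 2) / (gm * gm).sum(1))
            rej += int((np.abs(bh / se) > z).sum())
        mc_power = rej / reps
        mc_se = math.sqrt(approx * (1 - approx) / reps)
        assert abs(mc_power - approx) < 2 * mc_se
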