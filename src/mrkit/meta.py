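"""Fixed-effect meta-analysis of log odds ratios, multiple-testing control
and analytic power for MR with a binary outcome.

Study-level results reported as OR (95% CI) are converted back to
(log OR, SE) with se = (ln hi - ln lo) / (2 * 1.959964) and pooled with
inverse-variance weights; between-study heterogeneity is summarised by a
Q statistic.  With the two heart-failure-scale studies this package
targets, between-study Q stays below its df, so DerSimonian-Laird would
collapse to the fixed-effect model anyway.

Power uses the standard non-central approximation behind the mRnd-style
calculators: ncp = N * R2_x * K(1-K) * ln(OR)^2, where R2_x is the
variance the instruments explain in the exposure and K the outcome case
fraction; power = Phi(sqrt(ncp) - z) + Phi(-sqrt(ncp) - z).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, Z975, _finish

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NULL = "null"


@dataclass
class MetaResult:
    pooled: MREstimate
    per_study: list[tuple[str, MREstimate]]
    weights: dict[str, float]
    q_between: float
    q_df: int
    q_pval: float


@dataclass
class PowerSpec:
    """Inputs for the binary-outcome MR power approximation.

    ``n_outcome`` is the total outcome-GWAS sample size, ``case_fraction``
    its proportion of cases, ``r2_x`` the exposure variance explained by
    the instruments, and ``or_alt`` the odds ratio under the alternative.
    """

    n_outcome: int
    case_fraction: float
    r2_x: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_outcome <= 0:
            raise ValueError("n_outcome must be positive")
        for name in ("case_fraction", "r2_x", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")


def ci_to_se(or_point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (log OR, SE) from a reported OR with a 95% CI."""
    if not (0 < ci_low <= or_point <= ci_high):
        raise ValueError(
            f"CI ordering violated: need 0 < {ci_low} <= {or_point} <= {ci_high}"
        )
    log_or = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z975)
    if se == 0.0:
        warnings.warn("zero-width confidence interval: SE is 0", stacklevel=2)
    return log_or, se


def fixed_effect_meta(per_study: Sequence[tuple[str, float, float]]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of (name, log_or, se) studies."""
    if not per_study:
        raise ValueError("no studies to pool")
    names = [s[0] for s in per_study]
    b = np.array([s[1] for s in per_study], dtype=float)
    se = np.array([s[2] for s in per_study], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all study SEs must be > 0")
    v = 1.0 / se**2
    pooled_b = float(np.sum(v * b) / np.sum(v))
    pooled_se = float(np.sum(v) ** -0.5)
    pooled = _finish("meta_fe", pooled_b, pooled_se, k=len(per_study))
    q = float(np.sum(v * (b - pooled_b) ** 2))
    q_df = len(per_study) - 1
    q_pval = float(stats.chi2.sf(q, q_df)) if q_df > 0 else 1.0
    studies = [
        (name, _finish("study", float(bi), float(si), k=1))
        for name, bi, si in zip(names, b, se)
    ]
    weights = {name: float(vi / np.sum(v)) for name, vi in zip(names, v)}
    return MetaResult(pooled, studies, weights, q, q_df, q_pval)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def classify_pvalue(pval: float, alpha: float = 0.05, n_tests: int = 1) -> str:
    """Label a primary p-value against the Bonferroni threshold.

    ``significant`` below alpha/n_tests, ``suggestive`` for nominal-only
    (p < alpha but above the corrected threshold), else ``null``.
    """
    threshold = bonferroni_threshold(alpha, n_tests)
    if pval < threshold:
        return SIGNIFICANT
    if pval < alpha:
        return SUGGESTIVE
    return NULL


def mr_power_binary(spec: PowerSpec) -> float:
    """Approximate power of a two-sided MR test for a binary outcome."""
    z = float(stats.norm.ppf(1.0 - spec.alpha / 2.0))
    ncp = (
        spec.n_outcome
        * spec.r2_x
        * spec.case_fraction
        * (1.0 - spec.case_fraction)
        * math.log(spec.or_alt) ** 2
    )
    root = math.sqrt(ncp)
    return float(stats.norm.cdf(root - z) + stats.norm.cdf(-root - z))


def write_meta_table(result: MetaResult, path: str | Path, or_decimals: int = 2) -> None:
    """Tabular forest plot: one row per study plus the pooled row."""
    rows = []
    for name, est in result.per_study:
        rows.append(_meta_row(name, est, result.weights[name], or_decimals))
    rows.append(_meta_row("pooled", result.pooled, 1.0, or_decimals))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _meta_row(name: str, est: MREstimate, weight: float, nd: int) -> dict:
    return {
        "study": name,
        "or": round(math.exp(est.beta), nd),
        "ci_low": round(math.exp(est.ci_low), nd),
        "ci_high": round(math.exp(est.ci_high), nd),
        "weight_pct": round(100.0 * weight, 1),
        "pval": est.pval,
    }
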