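"""Causal-effect estimators for two-sample MR on harmonized instruments.

All estimators operate on the aligned per-variant association pairs
(gamma_hat_j, se_exp_j) and (Gamma_hat_j, se_out_j) and return effects on
the log-odds scale; exponentiation to odds ratios happens only at
reporting.  First-order inverse-variance weights w_j = gamma_hat_j^2 /
se_out_j^2 are used throughout (exposure-side uncertainty enters only the
weighted-median bootstrap), matching the standard implementations.

* Wald ratio — Gamma_hat/gamma_hat per variant, delta-method SE.
* IVW — precision-weighted mean of Wald ratios, equivalent to a
  zero-intercept weighted regression of Gamma_hat on gamma_hat.  The
  multiplicative random-effects variant inflates the fixed-effect SE by
  sqrt(Q/(k-1)), floored at 1.
* Weighted median — the 50% point of the weight-ordered ratios; consistent
  when at least half the weight comes from valid instruments.  SE by
  seeded parametric bootstrap.
* MR-Egger — weighted regression with a free intercept; the intercept
  estimates average directional pleiotropy, the slope the causal effect.
  Inference uses the t distribution with k-2 df and SEs inflated by the
  residual scale, floored at 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

#: exact 97.5% normal quantile used for all normal-theory intervals
Z975 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect (or intercept) estimate with normal- or t-based inference."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    df: int | None = None  # None -> normal reference distribution

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


def _finish(method: str, beta: float, se: float, k: int, df: int | None = None) -> MREstimate:
    if se < 0 or not math.isfinite(beta):
        raise ValueError(f"{method}: invalid estimate (beta={beta}, se={se})")
    if se == 0.0:
        pval = 1.0 if beta == 0.0 else 0.0
        return MREstimate(method, beta, se, beta, beta, pval, k, df)
    if df is not None:
        half = float(stats.t.ppf(0.975, df)) * se
        pval = float(2.0 * stats.t.sf(abs(beta) / se, df))
    else:
        half = Z975 * se
        pval = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MREstimate(method, beta, se, beta - half, beta + half, max(pval, 5e-324), k, df)


def _usable(instrs: Sequence[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    return [i for i in instrs if i.usable]


def _arrays(instrs: Sequence[HarmonizedInstrument]):
    g = np.array([i.beta_exp for i in instrs], dtype=float)
    sg = np.array([i.se_exp for i in instrs], dtype=float)
    G = np.array([i.beta_out for i in instrs], dtype=float)
    sG = np.array([i.se_out for i in instrs], dtype=float)
    if np.any(g == 0.0):
        raise ValueError("zero exposure effect: Wald ratio undefined")
    return g, sg, G, sG


def wald_ratio(instr: HarmonizedInstrument) -> MREstimate:
    """Single-variant ratio estimate with first-order (delta method) SE."""
    if instr.beta_exp == 0.0:
        raise ValueError(f"{instr.variant_id}: beta_exp is zero, ratio undefined")
    theta = instr.beta_out / instr.beta_exp
    se = instr.se_out / abs(instr.beta_exp)
    return _finish("wald", theta, se, k=1)


def ivw(instrs: Sequence[HarmonizedInstrument], model: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``model="fe"`` gives the fixed-effect SE (sum of weights)^-1/2;
    ``model="mre"`` (default, the primary model here) multiplies it by
    sqrt(Q/(k-1)) floored at 1, absorbing between-instrument heterogeneity.
    A single instrument delegates to :func:`wald_ratio`.
    """
    if model not in ("fe", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    instrs = _usable(instrs)
    k = len(instrs)
    if k == 0:
        raise ValueError("no usable instruments for IVW")
    if k == 1:
        return wald_ratio(instrs[0])
    g, _, G, sG = _arrays(instrs)
    w = g**2 / sG**2
    ratios = G / g
    theta = float(np.sum(w * ratios) / np.sum(w))
    se_fe = float(np.sum(w) ** -0.5)
    if model == "fe":
        return _finish("ivw_fe", theta, se_fe, k)
    q = float(np.sum(w * (ratios - theta) ** 2))
    infl = max(1.0, math.sqrt(q / (k - 1)))
    return _finish("ivw_mre", theta, se_fe * infl, k)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical CDF of the ratios."""
    order = np.argsort(ratios)
    r = ratios[order]
    wn = weights[order] / np.sum(weights)
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    instrs: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    *,
    seed: int,
) -> MREstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Each bootstrap replicate redraws gamma_hat* and Gamma_hat* from normal
    distributions centred on the observed values with their reported SEs,
    recomputes ratios and weights, and re-evaluates the weighted median;
    the SE is the standard deviation across replicates.  ``seed`` is
    mandatory so results are reproducible.
    """
    instrs = _usable(instrs)
    k = len(instrs)
    if k < 3:
        raise ValueError(f"weighted median needs >= 3 instruments, got {k}")
    g, sg, G, sG = _arrays(instrs)
    w = g**2 / sG**2
    theta = _weighted_median(G / g, w)

    rng = np.random.default_rng(seed)
    gs = rng.normal(g, sg, size=(n_boot, k))
    Gs = rng.normal(G, sG, size=(n_boot, k))
    ratios_b = Gs / gs
    w_b = gs**2 / sG**2
    order = np.argsort(ratios_b, axis=1)
    r_sorted = np.take_along_axis(ratios_b, order, axis=1)
    w_sorted = np.take_along_axis(w_b, order, axis=1)
    wn = w_sorted / np.sum(w_sorted, axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - wn / 2.0
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = np.interp(0.5, s[i], r_sorted[i])
    se = float(np.std(boot, ddof=1))
    return _finish("weighted_median", theta, se, k)


def egger(instrs: Sequence[HarmonizedInstrument]) -> tuple[MREstimate, MREstimate]:
    """MR-Egger weighted regression; returns (intercept, slope) estimates.

    Instruments are first oriented so every exposure effect is positive
    (both betas negated together — estimates are invariant to such flips,
    the intercept's sign convention is not).  The fit is weighted least
    squares of Gamma_hat on gamma_hat with weights 1/se_out^2; SEs are the
    unscaled WLS SEs inflated by the residual scale max(1, sigma), and
    p-values use the t distribution with k-2 df.
    """
    instrs = _usable(instrs)
    k = len(instrs)
    if k < 3:
        raise ValueError(f"MR-Egger needs >= 3 instruments, got {k}")
    g, _, G, sG = _arrays(instrs)
    sign = np.sign(g)
    x = g * sign
    y = G * sign
    w = 1.0 / sG**2

    sw = np.sum(w)
    swx = np.sum(w * x)
    swx2 = np.sum(w * x * x)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    den = sw * swx2 - swx**2
    if den <= 0:
        raise ValueError("degenerate design: exposure effects carry no spread")
    slope = (sw * swxy - swx * swy) / den
    intercept = (swx2 * swy - swx * swxy) / den

    resid = y - intercept - slope * x
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    infl = max(1.0, math.sqrt(sigma2))
    se_slope = math.sqrt(sw / den) * infl
    se_intercept = math.sqrt(swx2 / den) * infl

    est_int = _finish("egger_intercept", float(intercept), se_intercept, k, df=k - 2)
    est_slope = _finish("egger_slope", float(slope), se_slope, k, df=k - 2)
    return est_int, est_slope
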