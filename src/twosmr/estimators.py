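"""Causal-effect estimators for two-sample MR.

All estimators consume a :class:`~twosmr.harmonization.HarmonizedSet`
of aligned per-SNP effect pairs (beta_exp_j, beta_out_j) with standard
errors.  The per-SNP Wald ratio theta_j = beta_out_j / beta_exp_j is the
elementary causal estimate; the methods differ in how they pool the
ratios and which invalid-instrument patterns they tolerate:

* **IVW** — inverse-variance-weighted mean of the ratios; equivalent to
  weighted least squares of beta_out on beta_exp through the origin.
  The conventional (random-effects) mode inflates the fixed-effects SE
  by max(1, sqrt(Q/(J-1))) under heterogeneity; Cochran's Q itself is
  the heterogeneity diagnostic.
* **Weighted median** — the 50% point of the weight-ordered ratios;
  consistent while valid instruments carry >50% of the weight.
* **MR-Egger** — weighted regression *with* an intercept; the intercept
  estimates average directional pleiotropy and the slope remains a
  causal estimate under the InSIDE assumption.
* **MVMR** — joint weighted regression on several exposures' effects,
  giving each exposure's direct effect adjusted for the others.

Estimates are on the log-odds scale for binary outcomes; ``or_`` fields
carry the exponentiated (odds-ratio) scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import CollinearityError, ValidationError
from .harmonization import HarmonizedPair, HarmonizedSet

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "mr_egger",
    "mvmr_ivw",
    "to_odds_scale",
]


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on the log-odds (beta) and odds-ratio scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    or_: float = float("nan")
    or_ci_low: float = float("nan")
    or_ci_high: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValidationError(
                f"{self.method}: CI ({self.ci_low}, {self.ci_high}) does not bracket {self.beta}"
            )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios, chi-square with J-1 df."""

    q_stat: float
    df: int
    pvalue: float


def _estimate(
    method: str,
    beta: float,
    se: float,
    n_snps: int,
    alpha: float = 0.05,
    t_df: Optional[int] = None,
) -> MREstimate:
    """Assemble an MREstimate with normal (default) or t-based CI and p."""
    if t_df is not None:
        crit = stats.t.ppf(1 - alpha / 2, df=t_df)
        pvalue = 2 * stats.t.sf(abs(beta / se), df=t_df) if se > 0 else float(beta == 0)
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
        pvalue = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else float(beta == 0)
    lo, hi = beta - crit * se, beta + crit * se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        pvalue=float(pvalue),
        n_snps=n_snps,
        or_=math.exp(beta),
        or_ci_low=math.exp(lo),
        or_ci_high=math.exp(hi),
    )


def to_odds_scale(est: MREstimate) -> MREstimate:
    """Populate the odds-ratio fields by exponentiating the beta-scale CI."""
    return replace(
        est,
        or_=math.exp(est.beta),
        or_ci_low=math.exp(est.ci_low),
        or_ci_high=math.exp(est.ci_high),
    )


def wald_ratio(pair: HarmonizedPair, se_mode: str = "delta1", alpha: float = 0.05) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp.

    The default SE is the first-order delta method se_out/|beta_exp|,
    appropriate for strong instruments; ``se_mode='delta2'`` adds the
    second-order term carrying the exposure-side uncertainty.
    """
    if pair.beta_exp == 0:
        raise ValidationError(f"{pair.snp_id}: degenerate instrument (beta_exp = 0)")
    beta = pair.beta_out / pair.beta_exp
    if se_mode == "delta1":
        se = pair.se_out / abs(pair.beta_exp)
    elif se_mode == "delta2":
        se = math.sqrt(
            pair.se_out**2 / pair.beta_exp**2
            + pair.beta_out**2 * pair.se_exp**2 / pair.beta_exp**4
        )
    else:
        raise ValidationError(f"unknown se_mode {se_mode!r}")
    return _estimate("wald", beta, se, n_snps=1, alpha=alpha)


def wald_ratios(hset: HarmonizedSet, se_mode: str = "delta1"):
    """Per-SNP ratios and their SEs as arrays (the estimators' raw input)."""
    x, y, sy = hset.beta_exp, hset.beta_out, hset.se_out
    if np.any(x == 0):
        bad = [p.snp_id for p in hset if p.beta_exp == 0]
        raise ValidationError(f"degenerate instruments (beta_exp = 0): {bad}")
    theta = y / x
    if se_mode == "delta1":
        se = sy / np.abs(x)
    elif se_mode == "delta2":
        sx = hset.se_exp
        se = np.sqrt(sy**2 / x**2 + y**2 * sx**2 / x**4)
    else:
        raise ValidationError(f"unknown se_mode {se_mode!r}")
    return theta, se


def ivw(
    hset: HarmonizedSet,
    mode: str = "random",
    se_mode: str = "delta1",
    alpha: float = 0.05,
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate and Cochran's Q heterogeneity.

    ``mode='fixed'`` uses the plain inverse-variance SE; ``'random'``
    (the conventional IVW of the standard MR toolchain) multiplies it by
    max(1, sqrt(Q/(J-1))), a multiplicative random-effects correction
    that never shrinks the SE below the fixed-effects one.
    """
    if mode not in ("random", "fixed"):
        raise ValidationError(f"unknown IVW mode {mode!r}")
    J = len(hset)
    if J == 0:
        raise ValidationError("empty harmonized set")
    if J == 1:
        warnings.warn("single instrument: IVW degenerates to the Wald ratio")
        est = wald_ratio(hset.pairs[0], se_mode=se_mode, alpha=alpha)
        return replace(est, method=f"ivw_{mode}" if mode == "fixed" else "ivw"), (
            HeterogeneityResult(0.0, 0, float("nan"))
        )
    theta, se = wald_ratios(hset, se_mode)
    w = 1.0 / se**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    df = J - 1
    q_p = float(stats.chi2.sf(q, df=df))
    het = HeterogeneityResult(q, df, q_p)
    if mode == "fixed":
        return _estimate("ivw_fixed", beta, se_fixed, J, alpha), het
    se_re = se_fixed * max(1.0, math.sqrt(q / df))
    return _estimate("ivw", beta, se_re, J, alpha), het


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: the 0.5 point of the centered
    normalized cumulative weights over the sorted ratios."""
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    ww = w[order]
    s = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    if 0.5 <= s[0]:
        return float(t[0])
    if 0.5 >= s[-1]:
        return float(t[-1])
    return float(np.interp(0.5, s, t))


def weighted_median(
    hset: HarmonizedSet,
    reps: int = 1000,
    seed: int = 0,
    se_mode: str = "delta1",
    alpha: float = 0.05,
) -> MREstimate:
    """Weighted-median causal estimate.

    The point estimate is deterministic; its SE comes from a parametric
    bootstrap resampling each ratio from Normal(theta_j, se_j^2) with the
    given seed.
    """
    if len(hset) < 3:
        raise ValidationError("weighted median needs at least 3 instruments")
    if reps < 100:
        warnings.warn(f"bootstrap reps={reps} < 100: SE will be unstable")
    theta, se = wald_ratios(hset, se_mode)
    w = 1.0 / se**2
    beta = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se, size=(reps, len(theta)))
    boots = np.array([_weighted_median(d, w) for d in draws])
    se_boot = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", beta, se_boot, len(hset), alpha)


def mr_egger(
    hset: HarmonizedSet, alpha: float = 0.05
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Pairs are oriented so every exposure effect is positive, then
    beta_out is regressed on beta_exp with an intercept, weights
    1/se_out^2.  The slope is the pleiotropy-adjusted causal estimate;
    an intercept away from zero signals average directional pleiotropy.
    SEs carry a multiplicative overdispersion factor max(1, sigma_hat)
    and inference uses the t distribution with J-2 df.
    """
    J = len(hset)
    if J < 3:
        raise ValidationError("MR-Egger needs at least 3 instruments")
    x, y, sy = hset.beta_exp, hset.beta_out, hset.se_out
    sgn = np.where(x < 0, -1.0, 1.0)
    x, y = x * sgn, y * sgn
    w = 1.0 / sy**2
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0:
        raise ValidationError("no spread in exposure effects: Egger slope unidentified")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    df = J - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    infl = max(1.0, math.sqrt(sigma2))
    se_slope = math.sqrt(1.0 / sxx) * infl
    se_int = math.sqrt(1.0 / W + xbar**2 / sxx) * infl
    return (
        _estimate("egger_slope", slope, se_slope, J, alpha, t_df=df),
        _estimate("egger_intercept", intercept, se_int, J, alpha, t_df=df),
    )


def mvmr_ivw(
    exposures: Union[pd.DataFrame, np.ndarray],
    beta_out: Sequence[float],
    se_out: Sequence[float],
    alpha: float = 0.05,
) -> list[MREstimate]:
    """Multivariable IVW: joint weighted regression on several exposures.

    ``exposures`` is a J x E matrix of per-SNP effects on each exposure,
    harmonized to a common effect allele across all traits; column order
    defines the returned estimate order (put the exposure of interest
    first and the confounders after it).  Weighted least squares without
    intercept, weights 1/se_out^2, with the same multiplicative
    overdispersion as IVW.  With E=1 the coefficient equals the
    fixed-effects IVW estimate exactly.
    """
    if isinstance(exposures, pd.DataFrame):
        names = [str(c) for c in exposures.columns]
        X = exposures.to_numpy(dtype=float)
    else:
        X = np.asarray(exposures, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"exposure_{i}" for i in range(X.shape[1])]
    y = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    J, E = X.shape
    if J <= E:
        raise ValidationError(f"need more SNPs ({J}) than exposures ({E})")
    if np.any(sy <= 0):
        raise ValidationError("outcome standard errors must be positive")

    # Rank check with named offenders via pivoted QR on the weighted design.
    sw = 1.0 / sy
    Xw = X * sw[:, None]
    _, R, piv = linalg.qr(Xw, pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(J, E) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < E:
        raise CollinearityError([names[i] for i in piv[rank:]])

    yw = y * sw
    XtX = Xw.T @ Xw
    coef = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ coef
    sigma2 = float(resid @ resid) / (J - E)
    infl2 = max(1.0, sigma2)
    cov = np.linalg.inv(XtX) * infl2
    ses = np.sqrt(np.diag(cov))
    return [
        _estimate(f"mvmr:{names[e]}", float(coef[e]), float(ses[e]), J, alpha)
        for e in range(E)
    ]
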