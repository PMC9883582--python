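"""Sensitivity and validity diagnostics.

* **Leave-one-out** — re-estimates IVW dropping each instrument in turn;
  a single SNP driving the result shows up as a large shift.
* **MR-PRESSO** — a simulation-based residual-sum test.  For each SNP j
  the expected outcome effect is predicted from the leave-one-out IVW
  slope; the weighted residual sum of squares is compared against its
  parametric-bootstrap null, globally (pleiotropy anywhere?) and per SNP
  (which instrument is the outlier?), and the estimate is recomputed
  after outlier removal.
* **Steiger directionality** — compares the variance the instruments
  explain in the exposure versus the outcome; a valid exposure->outcome
  direction requires the exposure side to dominate.
* **plot_data** — funnel/scatter/forest tables for any plotting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw, wald_ratios
from .exceptions import ValidationError
from .harmonization import HarmonizedSet
from .instruments import variance_explained

__all__ = [
    "LeaveOneOutRow",
    "PressoResult",
    "SteigerResult",
    "leave_one_out",
    "leave_one_out_frame",
    "mr_presso",
    "steiger",
    "plot_data",
]


@dataclass(frozen=True)
class LeaveOneOutRow:
    dropped_snp: Optional[str]  # None marks the full-set reference row
    estimate: MREstimate


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_p: float
    outliers: tuple[str, ...]
    raw: MREstimate
    corrected: MREstimate
    distortion_p: float
    reps: int
    seed: int


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    pvalue: float


def leave_one_out(hset: HarmonizedSet, mode: str = "random") -> list[LeaveOneOutRow]:
    """IVW re-estimated without each SNP, plus a full-set reference row."""
    if len(hset) < 3:
        raise ValidationError("leave-one-out needs at least 3 instruments")
    rows = []
    for p in hset.pairs:
        est, _ = ivw(hset.drop(p.snp_id), mode=mode)
        rows.append(LeaveOneOutRow(p.snp_id, est))
    full, _ = ivw(hset, mode=mode)
    rows.append(LeaveOneOutRow(None, full))
    return rows


def leave_one_out_frame(rows: Sequence[LeaveOneOutRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dropped_snp": [r.dropped_snp if r.dropped_snp is not None else "(none)" for r in rows],
            "beta": [r.estimate.beta for r in rows],
            "se": [r.estimate.se for r in rows],
            "ci_low": [r.estimate.ci_low for r in rows],
            "ci_high": [r.estimate.ci_high for r in rows],
            "pvalue": [r.estimate.pvalue for r in rows],
            "or_": [r.estimate.or_ for r in rows],
        }
    )


def _loo_slopes(x, y, w):
    """Leave-one-out weighted through-origin slopes for every SNP at once."""
    a = np.sum(w * x * y, axis=-1, keepdims=True) - w * x * y
    b = np.sum(w * x * x, axis=-1, keepdims=True) - w * x * x
    return a / b


def mr_presso(
    hset: HarmonizedSet,
    reps: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
    mode: str = "random",
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    The observed statistic is RSS = sum_j w_j (beta_out_j -
    theta_{-j} * beta_exp_j)^2 with w_j = 1/se_out_j^2 and theta_{-j} the
    leave-one-out IVW slope.  The null distribution resimulates both
    sides from their standard errors around the leave-one-out fit.
    Per-SNP outlier p-values are Bonferroni-corrected over J and flagged
    below ``threshold``; the corrected estimate is IVW on the survivors.
    The distortion p compares the raw-vs-corrected shift against the
    shift from removing equally many SNPs at random.
    """
    J = len(hset)
    if J < 4:
        raise ValidationError("MR-PRESSO needs at least 4 instruments")
    if reps < 100:
        raise ValidationError("reps < 100 gives unstable simulation p-values")
    x, y, sy, sx = hset.beta_exp, hset.beta_out, hset.se_out, hset.se_exp
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(x, y, w)
    obs_res2 = w * (y - theta_loo * x) ** 2
    obs_rss = float(np.sum(obs_res2))

    rng = np.random.default_rng(seed)
    xs = rng.normal(x, sx, size=(reps, J))
    ys = rng.normal(theta_loo * x, sy, size=(reps, J))
    theta_sim = _loo_slopes(xs, ys, w)
    sim_res2 = w * (ys - theta_sim * xs) ** 2
    sim_rss = np.sum(sim_res2, axis=1)
    global_p = float(np.mean(sim_rss >= obs_rss))

    p_snp = np.mean(sim_res2 >= obs_res2, axis=0)
    p_bonf = np.minimum(1.0, p_snp * J)
    flagged = p_bonf < threshold
    snp_ids = np.array(hset.snp_ids)
    outliers = tuple(snp_ids[flagged])

    raw, _ = ivw(hset, mode=mode)
    if outliers and J - len(outliers) >= 2:
        corrected, _ = ivw(hset.subset(snp_ids[~flagged]), mode=mode)
        obs_shift = abs(raw.beta - corrected.beta)
        n_out = int(np.sum(flagged))
        shifts = np.empty(reps)
        wx2 = w * x * x
        wxy = w * x * y
        for r in range(reps):
            drop = rng.choice(J, size=n_out, replace=False)
            keep = np.ones(J, dtype=bool)
            keep[drop] = False
            shifts[r] = abs(raw.beta - np.sum(wxy[keep]) / np.sum(wx2[keep]))
        distortion_p = float(np.mean(shifts >= obs_shift))
    else:
        corrected = raw
        distortion_p = float("nan")
    return PressoResult(
        global_rss=obs_rss,
        global_p=global_p,
        outliers=outliers,
        raw=raw,
        corrected=corrected,
        distortion_p=distortion_p,
        reps=reps,
        seed=seed,
    )


def steiger(
    hset: HarmonizedSet,
    n_exp: int,
    n_out: int,
    outcome_binary: bool = True,
    case_fraction: Optional[float] = None,
) -> SteigerResult:
    """Steiger directionality test: does the instrument set explain more
    variance in the exposure than in the outcome?

    Exposure-side R2 uses 2*EAF*(1-EAF)*beta^2.  For a binary outcome the
    per-SNP variance explained is recovered from the association
    z-statistic as z^2/(z^2 + n), which needs no frequency or prevalence
    input (``case_fraction`` is accepted for interface symmetry).  The
    p-value compares Fisher z-transforms of the two correlation scales.
    """
    if n_exp <= 2 or n_out <= 2:
        raise ValidationError("sample sizes must exceed 2")
    r2_exp = float(np.sum(variance_explained(hset.eaf_exp, hset.beta_exp)))
    if outcome_binary:
        z = hset.beta_out / hset.se_out
        r2_out = float(np.sum(z**2 / (z**2 + n_out)))
    else:
        eaf_out = np.array([p.eaf_out for p in hset.pairs])
        r2_out = float(np.sum(variance_explained(eaf_out, hset.beta_out)))
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    zstat = (z_exp - z_out) / np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    pvalue = float(2 * stats.norm.sf(abs(zstat)))
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction_ok=bool(r2_exp > r2_out),
        pvalue=pvalue,
    )


def plot_data(
    hset: HarmonizedSet,
    estimates: Sequence[MREstimate] = (),
    se_mode: str = "delta1",
) -> dict[str, pd.DataFrame]:
    """Plain tables behind the standard MR figures.

    Returns ``funnel`` (per-SNP ratio vs precision), ``scatter`` (effect
    pairs), ``scatter_lines`` (per-method fitted lines: IVW and the
    weighted median pass through the origin, Egger carries its fitted
    intercept), and ``forest`` (per-SNP Wald CIs plus one summary row per
    supplied estimate).
    """
    theta, se = wald_ratios(hset, se_mode)
    funnel = pd.DataFrame({"snp": hset.snp_ids, "wald_ratio": theta, "precision": 1.0 / se})
    scatter = pd.DataFrame(
        {
            "snp": hset.snp_ids,
            "beta_exp": hset.beta_exp,
            "se_exp": hset.se_exp,
            "beta_out": hset.beta_out,
            "se_out": hset.se_out,
        }
    )
    ests = {e.method: e for e in estimates}
    lines = []
    for method, est in ests.items():
        if method == "egger_intercept":
            continue
        intercept = 0.0
        if method == "egger_slope" and "egger_intercept" in ests:
            intercept = ests["egger_intercept"].beta
        lines.append({"method": method, "intercept": intercept, "slope": est.beta})
    scatter_lines = pd.DataFrame(lines, columns=["method", "intercept", "slope"])
    crit = stats.norm.ppf(0.975)
    forest_rows = [
        {
            "label": s,
            "kind": "snp",
            "beta": t,
            "ci_low": t - crit * e,
            "ci_high": t + crit * e,
        }
        for s, t, e in zip(hset.snp_ids, theta, se)
    ]
    for method, est in ests.items():
        if method == "egger_intercept":
            continue
        forest_rows.append(
            {
                "label": method,
                "kind": "summary",
                "beta": est.beta,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    forest = pd.DataFrame(forest_rows, columns=["label", "kind", "beta", "ci_low", "ci_high"])
    return {
        "funnel": funnel,
        "scatter": scatter,
        "scatter_lines": scatter_lines,
        "forest": forest,
    }
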