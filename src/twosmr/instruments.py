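"""Instrument strength and statistical power.

An instrument's strength is summarized by the variance in the exposure
it explains, R2 = 2*EAF*(1-EAF)*beta^2, and by the F-statistic
F = R2*(n-1-k) / ((1-R2)*k); F > 10 is the conventional non-weak
threshold.  Study power for a binary outcome uses the noncentral
chi-square approximation of Burgess (the calculation behind the mRnd
web tool): the causal log-odds effect is mapped to a noncentrality
parameter through the case fraction and the aggregate instrument R2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .harmonization import HarmonizedSet
from .summary_data import AssociationTable

__all__ = [
    "InstrumentStrength",
    "PowerInputs",
    "variance_explained",
    "f_statistic",
    "total_variance_explained",
    "strength_table",
    "binary_outcome_power",
    "power_table",
]


@dataclass(frozen=True)
class InstrumentStrength:
    snp_id: str
    r2: float
    f_stat: float


@dataclass(frozen=True)
class PowerInputs:
    """Inputs of the binary-outcome power calculation."""

    n_cases: int
    n_controls: int
    odds_ratio: float
    r2_total: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("case and control counts must be >= 1")
        if not self.odds_ratio > 0:
            raise ValidationError("odds_ratio must be positive")
        if not 0 < self.r2_total < 1:
            raise ValidationError("r2_total must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


def variance_explained(eaf: float, beta: float) -> float:
    """Exposure variance explained by one SNP: 2*EAF*(1-EAF)*beta^2."""
    eaf = np.asarray(eaf, dtype=float)
    if np.any(eaf < 0) or np.any(eaf > 1):
        raise ValidationError("eaf outside [0, 1]")
    out = 2.0 * eaf * (1.0 - eaf) * np.asarray(beta, dtype=float) ** 2
    return float(out) if out.ndim == 0 else out


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """Instrument F-statistic: R2*(n-1-k) / ((1-R2)*k)."""
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 < 0) or np.any(r2 >= 1):
        raise ValidationError("r2 must be in [0, 1)")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n <= k + 1:
        raise ValidationError(f"sample size n={n} must exceed k+1={k + 1}")
    out = r2 * (n - 1 - k) / ((1.0 - r2) * k)
    return float(out) if out.ndim == 0 else out


def _iter_eaf_beta(data: Union[AssociationTable, HarmonizedSet]):
    if isinstance(data, HarmonizedSet):
        for p in data:
            yield p.snp_id, p.eaf_exp, p.beta_exp
    else:
        for r in data:
            yield r.snp_id, r.eaf, r.beta


def total_variance_explained(data: Union[AssociationTable, HarmonizedSet]) -> float:
    """Aggregate R2 of an instrument set: sum of per-SNP 2*EAF*(1-EAF)*beta^2."""
    if len(data) == 0:
        raise ValidationError("instrument set is empty")
    return float(sum(variance_explained(eaf, beta) for _, eaf, beta in _iter_eaf_beta(data)))


def strength_table(
    data: Union[AssociationTable, HarmonizedSet],
    n: int | None = None,
    k: int = 1,
) -> pd.DataFrame:
    """Per-SNP R2 and F.  ``n`` defaults to the table's per-record (or
    default) sample size; ``k=1`` treats each SNP as its own instrument,
    the convention under which the packaged table's printed F values are
    reproduced."""
    rows = []
    for snp_id, eaf, beta in _iter_eaf_beta(data):
        if n is None:
            if isinstance(data, AssociationTable):
                n_snp = data[snp_id].n
            else:
                raise ValidationError("n is required for a HarmonizedSet")
        else:
            n_snp = n
        r2 = variance_explained(eaf, beta)
        rows.append(
            {"snp": snp_id, "r2": r2, "f_stat": f_statistic(r2, n_snp, k)}
        )
    return pd.DataFrame(rows)


def binary_outcome_power(inputs: PowerInputs) -> float:
    """Power of a two-sample MR study with a binary outcome.

    With total sample N and case fraction K, the expected per-unit
    log-odds association translates into b = K*(OR/(1+K*(OR-1)) - 1),
    attenuated variance v = K*(1-K) - b^2, and a noncentral chi-square
    test with NCP = N * R2 * b^2 / v against the central chi-square(1)
    critical value at level alpha.
    """
    N = inputs.n_cases + inputs.n_controls
    K = inputs.n_cases / N
    OR = inputs.odds_ratio
    b = K * (OR / (1.0 + K * (OR - 1.0)) - 1.0)
    v = K * (1.0 - K) - b * b
    if v <= 0:
        raise ValidationError("degenerate design: K*(1-K) - b^2 <= 0")
    ncp = N * inputs.r2_total * b * b / v
    crit = stats.chi2.ppf(1.0 - inputs.alpha, df=1)
    return float(1.0 - stats.ncx2.cdf(crit, df=1, nc=ncp)) if ncp > 0 else inputs.alpha


def power_table(
    n_cases: int,
    n_controls: int,
    r2_total: float,
    odds_ratios: Iterable[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power over a grid of expected odds ratios."""
    rows = [
        {
            "odds_ratio": float(orr),
            "power": binary_outcome_power(
                PowerInputs(n_cases, n_controls, float(orr), r2_total, alpha)
            ),
        }
        for orr in odds_ratios
    ]
    return pd.DataFrame(rows)
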