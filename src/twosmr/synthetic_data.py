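"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model follows the causal diagram of an instrumental-
variable study: independent SNPs affect the exposure with true effects
gamma_j; the outcome effect of SNP j is causal_beta * gamma_j plus a
per-SNP pleiotropy term alpha_j.  Observed summary statistics are drawn
at the summary level — Normal noise around the true effects with
standard errors implied by allele frequency and sample size — which is
exactly the regime the estimators assume, and keeps simulations fast.

Pleiotropy modes map to the classical validity violations:

* ``none`` — all instruments valid.
* ``balanced`` — alpha_j ~ Normal(0, sd^2): InSIDE holds, IVW unbiased
  but overdispersed.
* ``directional`` — alpha_j ~ Normal(mean != 0, sd^2): IVW biased by the
  mean pleiotropy while the MR-Egger intercept recovers it.
* ``planted_outliers`` — large offsets on chosen SNPs only, the
  MR-PRESSO detection target.

Binary traits are simulated on the log-odds scale; the outcome SE
carries the case-fraction factor, se = 1/sqrt(2*EAF*(1-EAF)*n*K*(1-K)).
Defaults mirror the MDD -> breast cancer study: 92 instruments with
per-allele effect magnitudes 0.02-0.05 on an exposure GWAS of 807,553,
an outcome GWAS of 228,951 with 53.7% cases, and a causal effect of
0.0834 log-odds (OR 1.087) per log-odds of exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .summary_data import AssociationTable, VariantAssociation, load_packaged_instruments

__all__ = ["SimConfig", "SimTruth", "simulate_two_sample", "simulate_study_like"]

_PLEIOTROPY_MODES = ("none", "balanced", "directional", "planted_outliers")

# Non-palindromic allele pairs used for simulated variants.
_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PAL_PAIRS = [("A", "T"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the study-scale conditions."""

    n_snps: int = 92
    n_exposure_sample: int = 807_553
    n_outcome_sample: int = 228_951
    causal_beta: float = 0.0834
    gamma_low: float = 0.02
    gamma_high: float = 0.05
    eaf_low: float = 0.10
    eaf_high: float = 0.95
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.005
    pleiotropy_mean: float = 0.005
    outlier_ids: tuple[int, ...] = ()
    outlier_offset_scale: float = 10.0
    outlier_random_sign: bool = False
    case_fraction_outcome: float = 122_977 / 228_951
    palindromic_fraction: float = 0.0
    swap_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise ConfigurationError("n_snps must be >= 3")
        if self.n_exposure_sample <= 100 or self.n_outcome_sample <= 100:
            raise ConfigurationError("sample sizes must exceed 100")
        if not 0 < self.case_fraction_outcome < 1:
            raise ConfigurationError("case_fraction_outcome must be in (0, 1)")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ConfigurationError(f"pleiotropy_mode must be one of {_PLEIOTROPY_MODES}")
        if not 0 < self.gamma_low <= self.gamma_high:
            raise ConfigurationError("need 0 < gamma_low <= gamma_high")
        if not 0 < self.eaf_low < self.eaf_high < 1:
            raise ConfigurationError("need 0 < eaf_low < eaf_high < 1")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        if not 0 <= self.palindromic_fraction <= 1 or not 0 <= self.swap_fraction <= 1:
            raise ConfigurationError("fractions must be in [0, 1]")
        if self.pleiotropy_mode == "planted_outliers" and not self.outlier_ids:
            raise ConfigurationError("planted_outliers mode requires outlier_ids")
        if any(not 0 <= i < self.n_snps for i in self.outlier_ids):
            raise ConfigurationError("outlier_ids out of range")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth stored alongside every generated dataset."""

    causal_beta: float
    gamma: tuple[float, ...]
    alpha: tuple[float, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "causal_beta": self.causal_beta,
            "gamma": list(self.gamma),
            "alpha": list(self.alpha),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            causal_beta=float(d["causal_beta"]),
            gamma=tuple(d["gamma"]),
            alpha=tuple(d["alpha"]),
            seed=int(d["seed"]),
        )


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _draw_alpha(
    cfg: SimConfig, rng: np.random.Generator, se_out: np.ndarray, gamma: np.ndarray
) -> np.ndarray:
    # Directional pleiotropy is defined relative to the exposure-increasing
    # allele (the orientation MR-Egger regresses in); applying it in the
    # reported-allele frame would cancel under random effect signs.
    alpha = np.zeros(cfg.n_snps)
    if cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, cfg.n_snps)
    elif cfg.pleiotropy_mode == "directional":
        alpha = np.sign(gamma) * rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, cfg.n_snps)
    elif cfg.pleiotropy_mode == "planted_outliers":
        idx = np.array(cfg.outlier_ids, dtype=int)
        if cfg.outlier_random_sign:
            sgn = rng.choice([-1.0, 1.0], size=idx.size)
        else:
            sgn = np.sign(gamma[idx])
        alpha[idx] = cfg.outlier_offset_scale * se_out[idx] * sgn
    return alpha


def simulate_two_sample(cfg: SimConfig) -> tuple[AssociationTable, AssociationTable, SimTruth]:
    """Generate matched exposure and outcome association tables.

    A configurable fraction of SNPs receives palindromic alleles and a
    configurable fraction of outcome records arrives with effect/other
    alleles swapped (beta negated, EAF reflected), so the harmonization
    path is exercised end to end.  Fixed seeds give bit-identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps
    eaf = rng.uniform(cfg.eaf_low, cfg.eaf_high, J)
    gamma = rng.uniform(cfg.gamma_low, cfg.gamma_high, J) * rng.choice([-1.0, 1.0], J)

    K = cfg.case_fraction_outcome
    se_exp = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_exposure_sample)
    se_out = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_outcome_sample * K * (1.0 - K))

    alpha = _draw_alpha(cfg, rng, se_out, gamma)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(cfg.causal_beta * gamma + alpha, se_out)

    pal = rng.random(J) < cfg.palindromic_fraction
    swap = rng.random(J) < cfg.swap_fraction
    pair_idx = rng.integers(0, len(_NONPAL_PAIRS), J)
    pal_idx = rng.integers(0, len(_PAL_PAIRS), J)

    exp_records, out_records = [], []
    for j in range(J):
        ea, oa = _PAL_PAIRS[pal_idx[j]] if pal[j] else _NONPAL_PAIRS[pair_idx[j]]
        snp = f"rs{9000000 + j}"
        exp_records.append(
            VariantAssociation(
                snp_id=snp,
                chrom=str(1 + j % 22),
                pos=1_000_000 + 1000 * j,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[j]),
                beta=float(beta_exp[j]),
                se=float(se_exp[j]),
                pvalue=float(_pvalue(beta_exp[j], se_exp[j])),
                n=cfg.n_exposure_sample,
                trait="sim_exposure",
            )
        )
        if swap[j]:
            o_ea, o_oa, o_beta, o_eaf = oa, ea, -beta_out[j], 1.0 - eaf[j]
        else:
            o_ea, o_oa, o_beta, o_eaf = ea, oa, beta_out[j], eaf[j]
        out_records.append(
            VariantAssociation(
                snp_id=snp,
                chrom=str(1 + j % 22),
                pos=1_000_000 + 1000 * j,
                effect_allele=o_ea,
                other_allele=o_oa,
                eaf=float(o_eaf),
                beta=float(o_beta),
                se=float(se_out[j]),
                pvalue=float(_pvalue(beta_out[j], se_out[j])),
                n=cfg.n_outcome_sample,
                trait="sim_outcome",
            )
        )
    exposure = AssociationTable(
        exp_records, role="exposure", trait="sim_exposure", n_default=cfg.n_exposure_sample
    )
    outcome = AssociationTable(
        out_records, role="outcome", trait="sim_outcome", n_default=cfg.n_outcome_sample
    )
    truth = SimTruth(
        causal_beta=cfg.causal_beta,
        gamma=tuple(float(g) for g in gamma),
        alpha=tuple(float(a) for a in alpha),
        seed=cfg.seed,
    )
    return exposure, outcome, truth


def simulate_study_like(
    seed: int = 0, causal_beta: float = 0.0834
) -> tuple[AssociationTable, AssociationTable, SimTruth]:
    """An outcome dataset shaped like the breast-cancer study.

    The packaged 102-SNP MDD instrument table is taken as the observed
    exposure GWAS (its EAFs, effects, and alleles verbatim, including the
    13 palindromic SNPs of which 6 are frequency-ambiguous).  A synthetic
    outcome GWAS of 228,951 (53.7% cases) is simulated around
    ``causal_beta`` times the exposure effects, with the same four SNPs
    withheld that the real outcome data lack and a quarter of the
    remaining records allele-swapped.  Harmonizing the two reproduces the
    102 -> 92 instrument reduction end to end.
    """
    exposure = load_packaged_instruments()
    rng = np.random.default_rng(seed)
    n_out = 228_951
    K = 122_977 / 228_951
    missing = {"rs78337797", "rs56314503", "rs10774600", "rs3213572"}
    out_records = []
    gamma, alpha = [], []
    for j, rec in enumerate(exposure):
        gamma.append(rec.beta)
        alpha.append(0.0)
        if rec.snp_id in missing:
            continue
        se_out = 1.0 / np.sqrt(2.0 * rec.eaf * (1.0 - rec.eaf) * n_out * K * (1.0 - K))
        beta_out = float(rng.normal(causal_beta * rec.beta, se_out))
        swap = j % 4 == 1
        out_records.append(
            VariantAssociation(
                snp_id=rec.snp_id,
                chrom=rec.chrom,
                pos=rec.pos,
                effect_allele=rec.other_allele if swap else rec.effect_allele,
                other_allele=rec.effect_allele if swap else rec.other_allele,
                eaf=1.0 - rec.eaf if swap else rec.eaf,
                beta=-beta_out if swap else beta_out,
                se=float(se_out),
                pvalue=float(_pvalue(np.array(beta_out), np.array(se_out))),
                n=n_out,
                trait="sim_breast_cancer",
            )
        )
    outcome = AssociationTable(
        out_records, role="outcome", trait="sim_breast_cancer", n_default=n_out
    )
    truth = SimTruth(
        causal_beta=causal_beta, gamma=tuple(gamma), alpha=tuple(alpha), seed=seed
    )
    return exposure, outcome, truth
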