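"""Align exposure and outcome summary statistics to a common effect allele.

Two-sample MR combines per-SNP effects estimated in different studies,
which may report them on opposite alleles or opposite strands.
Harmonization aligns every outcome record to the exposure's effect
allele, flipping effect signs and allele frequencies where needed, and
excludes variants that cannot be aligned:

* SNPs absent from the outcome data (``missing_in_outcome``);
* palindromic SNPs (A/T or C/G) whose allele frequency is too close to
  0.5 to resolve the strand (``palindromic_ambiguous``);
* variants whose alleles are irreconcilable (``allele_mismatch``).

On the packaged MDD instrument set against the breast-cancer outcome
data this reproduces the 102 -> 92 instrument reduction (4 missing,
6 ambiguous palindromes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .summary_data import (
    AssociationTable,
    StudyConfig,
    VALID_ALLELES,
    VariantAssociation,
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ExclusionReason(str, Enum):
    MISSING_IN_OUTCOME = "missing_in_outcome"
    PALINDROMIC_AMBIGUOUS = "palindromic_ambiguous"
    ALLELE_MISMATCH = "allele_mismatch"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effect pair aligned to the exposure effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValidationError(f"{self.snp_id}: standard errors must be positive")


class HarmonizedSet:
    """Ordered harmonized pairs plus the exclusion log."""

    def __init__(self, pairs, exclusions=()):
        self.pairs: list[HarmonizedPair] = list(pairs)
        self.exclusions: list[tuple[str, ExclusionReason]] = [
            (s, ExclusionReason(r)) for s, r in exclusions
        ]
        kept = {p.snp_id for p in self.pairs}
        dropped = {s for s, _ in self.exclusions}
        if kept & dropped:
            raise ValidationError(f"SNPs both kept and excluded: {sorted(kept & dropped)}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    # Convenience arrays used throughout the estimators.
    @property
    def beta_exp(self) -> np.ndarray:
        return np.array([p.beta_exp for p in self.pairs])

    @property
    def se_exp(self) -> np.ndarray:
        return np.array([p.se_exp for p in self.pairs])

    @property
    def beta_out(self) -> np.ndarray:
        return np.array([p.beta_out for p in self.pairs])

    @property
    def se_out(self) -> np.ndarray:
        return np.array([p.se_out for p in self.pairs])

    @property
    def eaf_exp(self) -> np.ndarray:
        return np.array([p.eaf_exp for p in self.pairs])

    def subset(self, keep_snp_ids) -> "HarmonizedSet":
        keep = set(keep_snp_ids)
        return HarmonizedSet([p for p in self.pairs if p.snp_id in keep], [])

    def drop(self, snp_id: str) -> "HarmonizedSet":
        return HarmonizedSet([p for p in self.pairs if p.snp_id != snp_id], [])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "beta_exp": self.beta_exp,
                "se_exp": self.se_exp,
                "beta_out": self.beta_out,
                "se_out": self.se_out,
                "eaf_exp": self.eaf_exp,
                "eaf_out": [p.eaf_out for p in self.pairs],
                "flipped": [p.flipped for p in self.pairs],
            }
        )

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": [s for s, _ in self.exclusions],
                "reason": [r.value for _, r in self.exclusions],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    def write_exclusions(self, path) -> None:
        self.exclusions_frame().to_csv(path, sep="\t", index=False)


def set_from_frame(df: pd.DataFrame) -> HarmonizedSet:
    """Rebuild a HarmonizedSet from a TSV written by :meth:`HarmonizedSet.write`."""
    pairs = [
        HarmonizedPair(
            snp_id=str(r.snp),
            beta_exp=float(r.beta_exp),
            se_exp=float(r.se_exp),
            beta_out=float(r.beta_out),
            se_out=float(r.se_out),
            eaf_exp=float(r.eaf_exp),
            eaf_out=float(r.eaf_out),
            flipped=bool(r.flipped),
        )
        for r in df.itertuples(index=False)
    ]
    return HarmonizedSet(pairs)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff {a1, a2} is {A, T} or {C, G} (same pair on both strands)."""
    a1, a2 = a1.upper(), a2.upper()
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValidationError(f"invalid allele in ({a1!r}, {a2!r})")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _ambiguous(eaf: Optional[float], window: float) -> bool:
    return eaf is not None and (0.5 - window) <= eaf <= (0.5 + window)


def align_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    window: float = 0.08,
    palindromic_check: str = "both",
) -> Union[HarmonizedPair, ExclusionReason]:
    """Align one outcome record to the exposure's effect allele.

    Alleles are compared directly, after effect/other swap (negate the
    outcome beta, take 1-EAF), after strand complement, and after both.
    Palindromic SNPs whose EAF lies within ``window`` of 0.5 — on the
    exposure side, or on either side when ``palindromic_check='both'`` —
    are excluded as strand-ambiguous; retained palindromic SNPs are taken
    at face value (no frequency-based strand inference).
    """
    if exp.snp_id != out.snp_id:
        raise ValidationError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")

    if is_palindromic(exp.effect_allele, exp.other_allele):
        check_out = palindromic_check == "both"
        if _ambiguous(exp.eaf, window) or (check_out and _ambiguous(out.eaf, window)):
            return ExclusionReason.PALINDROMIC_AMBIGUOUS

    ea, oa = out.effect_allele, out.other_allele
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (ea, oa) == (exp.effect_allele, exp.other_allele):
        flip = False
    elif (ea, oa) == (exp.other_allele, exp.effect_allele):
        flip = True
    elif (cea, coa) == (exp.effect_allele, exp.other_allele):
        flip = False
    elif (cea, coa) == (exp.other_allele, exp.effect_allele):
        flip = True
    else:
        return ExclusionReason.ALLELE_MISMATCH

    return HarmonizedPair(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=-out.beta if flip else out.beta,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=1.0 - out.eaf if flip else out.eaf,
        flipped=flip,
    )


def harmonize_tables(
    exposure: AssociationTable,
    outcome: AssociationTable,
    config: Optional[StudyConfig] = None,
    proxies: Optional[Mapping[str, str]] = None,
) -> HarmonizedSet:
    """Harmonize every exposure instrument against the outcome table.

    ``proxies`` optionally maps an exposure snp_id to a high-LD stand-in
    snp_id present in the outcome table (the caller supplies the LD
    evidence; no panel lookup happens here).  Output pair order follows
    exposure order and the exclusion log records every dropped SNP, so
    ``len(pairs) + len(exclusions) == len(exposure)``.
    """
    if len(exposure) == 0:
        raise ValidationError("exposure table is empty")
    config = config or StudyConfig()
    proxies = proxies or {}
    pairs: list[HarmonizedPair] = []
    exclusions: list[tuple[str, ExclusionReason]] = []
    for exp_rec in exposure:
        out_id = exp_rec.snp_id if exp_rec.snp_id in outcome else proxies.get(exp_rec.snp_id)
        out_rec = outcome.get(out_id) if out_id else None
        if out_rec is None:
            exclusions.append((exp_rec.snp_id, ExclusionReason.MISSING_IN_OUTCOME))
            continue
        if out_rec.snp_id != exp_rec.snp_id:
            # proxy stands in for the exposure SNP; align under the exposure id
            out_rec = VariantAssociation(
                snp_id=exp_rec.snp_id,
                chrom=out_rec.chrom,
                pos=out_rec.pos,
                effect_allele=out_rec.effect_allele,
                other_allele=out_rec.other_allele,
                eaf=out_rec.eaf,
                beta=out_rec.beta,
                se=out_rec.se,
                pvalue=out_rec.pvalue,
                n=out_rec.n,
                trait=out_rec.trait,
            )
        result = align_pair(
            exp_rec,
            out_rec,
            window=config.ambiguity_window,
            palindromic_check=config.palindromic_check,
        )
        if isinstance(result, HarmonizedPair):
            pairs.append(result)
        else:
            exclusions.append((exp_rec.snp_id, result))
    return HarmonizedSet(pairs, exclusions)
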