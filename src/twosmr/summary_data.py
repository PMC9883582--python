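"""Data model and I/O for GWAS summary statistics.

Summary-level association tables are the raw material of two-sample
Mendelian randomization: one table gives per-SNP effects on the exposure
(here major depressive disorder, MDD), another gives the same SNPs'
effects on the outcome (breast cancer risk, on the log-odds scale).
This module defines the validated record and table types, delimited-text
readers configurable enough to ingest IEU OpenGWAS exports, the packaged
MDD instrument table, and report serialization.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import ConfigurationError, DataError, ValidationError

VALID_ALLELES = frozenset("ACGT")
ROLES = ("exposure", "outcome", "confounder")

#: Sample size of the MDD GWAS meta-analysis behind the packaged instruments.
MDD_SAMPLE_SIZE = 807_553


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the additive per-allele effect of ``effect_allele``;
    for binary traits it is on the log-odds scale.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    trait: str = ""

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single-base A/C/G/T, got {ea}/{oa}"
            )
        if ea == oa:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical ({ea})")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"{self.snp_id}: p-value {self.pvalue} outside (0, 1]")
        if not (math.isfinite(self.beta) and math.isfinite(self.se)):
            raise ValidationError(f"{self.snp_id}: non-finite effect or SE")
        if int(self.n) <= 1:
            raise ValidationError(f"{self.snp_id}: sample size must exceed 1, got {self.n}")


class AssociationTable:
    """Ordered, snp_id-unique collection of :class:`VariantAssociation`."""

    def __init__(
        self,
        records: Sequence[VariantAssociation],
        role: str,
        trait: str = "",
        n_default: Optional[int] = None,
    ) -> None:
        if role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {role!r}")
        self.role = role
        self.trait = trait
        self.n_default = n_default
        self._records = list(records)
        self._index: dict[str, VariantAssociation] = {}
        for rec in self._records:
            if rec.snp_id in self._index:
                raise DataError(f"duplicate snp_id {rec.snp_id!r}")
            self._index[rec.snp_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self._records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __getitem__(self, snp_id: str) -> VariantAssociation:
        return self._index[snp_id]

    def get(self, snp_id: str) -> Optional[VariantAssociation]:
        return self._index.get(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self._records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self._records])

    def write(self, path) -> None:
        """Write in the package's canonical TSV dialect (readable back with
        the default column map)."""
        df = self.to_frame().rename(columns={"snp_id": "snp", "pvalue": "pval"})
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class StudyConfig:
    """Analysis-wide thresholds and seeds.

    ``ambiguity_window`` is the half-width around EAF 0.5 inside which a
    palindromic (A/T or C/G) SNP is considered strand-ambiguous; the
    default 0.08 gives the interval [0.42, 0.58].  ``bonferroni_m`` is the
    number of outcomes tested (overall, ER+, ER- breast cancer), so
    alpha/m = 0.05/3 ~= 0.017 separates strong from suggestive evidence.
    """

    gw_threshold: float = 5e-8
    ambiguity_window: float = 0.08
    alpha: float = 0.05
    bonferroni_m: int = 3
    bootstrap_reps: int = 1000
    presso_reps: int = 1000
    seed: int = 0
    palindromic_check: str = "both"  # "both" or "exposure"
    wald_se: str = "delta1"  # "delta1" or "delta2"

    def __post_init__(self) -> None:
        if not 0 < self.gw_threshold < 1:
            raise ValidationError("gw_threshold must be in (0, 1)")
        if not 0 <= self.ambiguity_window < 0.5:
            raise ValidationError("ambiguity_window must be in [0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.palindromic_check not in ("both", "exposure"):
            raise ValidationError("palindromic_check must be 'both' or 'exposure'")
        if self.wald_se not in ("delta1", "delta2"):
            raise ValidationError("wald_se must be 'delta1' or 'delta2'")

    def significance_label(self, pvalue: float) -> str:
        """Bonferroni annotation: 'strong' below alpha/m, 'suggestive' below alpha."""
        if pvalue < self.alpha / self.bonferroni_m:
            return "strong"
        if pvalue < self.alpha:
            return "suggestive"
        return "ns"


#: Canonical column names used by the package's own TSV dialect.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "snp_id": "snp",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

#: Column names of IEU OpenGWAS exports (e.g. the BCAC datasets
#: ieu-a-1126/-1127/-1128 used as breast-cancer outcomes).
IEU_COLUMNS: Mapping[str, str] = {
    "snp_id": "SNP",
    "chrom": "chr",
    "pos": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "samplesize",
}

_REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue")


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_association_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    role: str = "exposure",
    trait: str = "",
    n_default: Optional[int] = None,
    sep: Optional[str] = None,
) -> AssociationTable:
    """Read a delimited summary-statistics file into an AssociationTable.

    ``column_map`` maps VariantAssociation field names to file columns
    (default: the package dialect; pass :data:`IEU_COLUMNS` for IEU
    OpenGWAS exports).  Chromosome/position and per-row sample size are
    optional; missing n falls back to ``n_default``.  Any row violating a
    record invariant aborts the read with a row-numbered message.
    """
    cmap = dict(DEFAULT_COLUMNS if column_map is None else column_map)
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for fld in _REQUIRED_FIELDS:
        col = cmap.get(fld)
        if col is None or col not in df.columns:
            raise ConfigurationError(
                f"required column {col!r} (field {fld!r}) not found in {path}"
            )
    has_n = cmap.get("n") in df.columns
    if not has_n and n_default is None:
        raise ConfigurationError(
            f"{path}: no sample-size column {cmap.get('n')!r} and no n_default supplied"
        )
    has_chrom = cmap.get("chrom") in df.columns
    has_pos = cmap.get("pos") in df.columns

    records = []
    errors = []
    for pos_idx in range(len(df)):
        raw = df.iloc[pos_idx]
        i = pos_idx + 2  # 1-based file line number, after the header
        try:
            n_val = raw[cmap["n"]] if has_n and pd.notna(raw[cmap["n"]]) else n_default
            rec = VariantAssociation(
                snp_id=str(raw[cmap["snp_id"]]),
                chrom=str(raw[cmap["chrom"]]) if has_chrom else "",
                pos=int(raw[cmap["pos"]]) if has_pos else 0,
                effect_allele=str(raw[cmap["effect_allele"]]),
                other_allele=str(raw[cmap["other_allele"]]),
                eaf=float(raw[cmap["eaf"]]),
                beta=float(raw[cmap["beta"]]),
                se=float(raw[cmap["se"]]),
                pvalue=float(raw[cmap["pvalue"]]),
                n=int(n_val),
                trait=trait,
            )
        except ValidationError as exc:
            errors.append(f"row {i}: {exc}")
            continue
        records.append(rec)
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors))
    return AssociationTable(records, role=role, trait=trait, n_default=n_default)


def packaged_instruments_frame() -> pd.DataFrame:
    """Raw packaged MDD instrument table, including the printed R2/F columns.

    The printed per-SNP R2 column of the source table is inconsistent with
    the 2*EAF*(1-EAF)*beta^2 formula (the printed F column matches the
    formula); the raw values are kept verbatim here for reference, while
    all computations in :mod:`twosmr.instruments` use the formula.
    """
    resource = importlib.resources.files("twosmr.data").joinpath("mdd_instruments.tsv")
    with importlib.resources.as_file(resource) as p:
        return pd.read_csv(p, sep="\t", float_precision="round_trip")


def load_packaged_instruments() -> AssociationTable:
    """The 102 MDD-associated SNPs used as genetic instruments.

    Genome-wide significant (p < 5e-8), LD-clumped variants from a
    European-ancestry MDD GWAS meta-analysis of 807,553 individuals.
    """
    df = packaged_instruments_frame()
    records = [
        VariantAssociation(
            snp_id=row.snp,
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            eaf=float(row.eaf),
            beta=float(row.beta),
            se=float(row.se),
            pvalue=float(row.pval),
            n=MDD_SAMPLE_SIZE,
            trait="MDD",
        )
        for row in df.itertuples(index=False)
    ]
    return AssociationTable(records, role="exposure", trait="MDD", n_default=MDD_SAMPLE_SIZE)


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

#: Deterministic column order of the tabular report (one row per
#: method per outcome, mirroring the layout of a standard MR results table).
REPORT_COLUMNS = [
    "outcome",
    "method",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "or_",
    "or_ci_low",
    "or_ci_high",
    "q_stat",
    "q_df",
    "q_pvalue",
    "evidence",
    "or_ci_display",
]


def report_frame(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Normalize result rows into the fixed report column order."""
    df = pd.DataFrame(list(rows), columns=REPORT_COLUMNS)
    disp = []
    for _, r in df.iterrows():
        if pd.notna(r["or_"]) and pd.notna(r["or_ci_low"]):
            disp.append(f"{r['or_']:.3f} ({r['or_ci_low']:.3f}-{r['or_ci_high']:.3f})")
        elif pd.notna(r["or_"]):
            disp.append(f"{r['or_']:.3f}")
        else:
            disp.append("")
    df["or_ci_display"] = disp
    return df


def write_report(results, path, format: str = "tsv") -> None:
    """Write study results to ``path`` as TSV or JSON.

    ``results`` is either a report DataFrame (see :func:`report_frame`) or
    a sequence of row mappings.  Numbers are serialized at full precision;
    the TSV additionally carries a 3-decimal OR (CI) display column.
    JSON output round-trips to the same values.
    """
    df = results if isinstance(results, pd.DataFrame) else report_frame(results)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "json":
        records = json.loads(df.to_json(orient="records", double_precision=15))
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ConfigurationError(f"unknown report format {format!r}")


def read_report(path, format: str = "tsv") -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    with open(path, "r", encoding="utf-8") as fh:
        return pd.DataFrame(json.load(fh))
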