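"""Config-driven end-to-end study run.

``run_study`` reproduces the full analysis workflow for one exposure and
any number of outcome datasets: harmonize, measure instrument strength,
estimate (IVW random/fixed, weighted median, MR-Egger), run diagnostics
(Cochran's Q, MR-PRESSO, leave-one-out, Steiger), and write a results
table shaped like a standard MR report plus a JSON document with the
full diagnostics, an exclusion log, and a provenance manifest.

The YAML run config mirrors :class:`~twosmr.summary_data.StudyConfig`
keys plus file locations::

    seed: 1
    exposure: null            # null -> packaged MDD instrument table
    exposure_n_cases: 246363  # optional, Steiger exposure sample size
    outcomes:
      overall:
        path: bcac_overall.tsv
        columns: ieu          # 'ieu', 'default', or a field->column map
        n_cases: 122977
        n_controls: 105974
    outdir: results/
    presso_reps: 1000
    bootstrap_reps: 1000
    mvmr_matrix: null         # optional TSV: snp, beta_out, se_out, <exposure cols...>

All randomness (weighted-median bootstrap, MR-PRESSO simulations) is
seeded from the single run seed, so a rerun with the same config and
inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .diagnostics import leave_one_out, leave_one_out_frame, mr_presso, steiger
from .estimators import ivw, mr_egger, mvmr_ivw, weighted_median
from .exceptions import ConfigurationError
from .harmonization import HarmonizedSet, harmonize_tables
from .instruments import f_statistic, strength_table, total_variance_explained
from .summary_data import (
    DEFAULT_COLUMNS,
    IEU_COLUMNS,
    AssociationTable,
    StudyConfig,
    load_packaged_instruments,
    read_association_table,
    report_frame,
    write_report,
)

logger = logging.getLogger("twosmr")

_COLUMN_PRESETS = {"default": DEFAULT_COLUMNS, "ieu": IEU_COLUMNS}


@dataclass
class OutcomeSpec:
    label: str
    path: str
    columns: Mapping[str, str]
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None


@dataclass
class RunConfig:
    study: StudyConfig
    outcomes: list[OutcomeSpec]
    exposure_path: Optional[str] = None
    exposure_columns: Mapping[str, str] = None
    exposure_n: Optional[int] = None
    outdir: str = "."
    mvmr_matrix: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        study_keys = {f.name for f in dataclasses.fields(StudyConfig)}
        study = StudyConfig(**{k: v for k, v in raw.items() if k in study_keys})
        outcomes_raw = raw.get("outcomes")
        if not outcomes_raw:
            raise ConfigurationError(f"{path}: config lists no outcomes")
        outcomes = []
        for label, spec in outcomes_raw.items():
            if isinstance(spec, str):
                spec = {"path": spec}
            cols = spec.get("columns", "ieu")
            if isinstance(cols, str):
                if cols not in _COLUMN_PRESETS:
                    raise ConfigurationError(
                        f"unknown column preset {cols!r}; use one of {sorted(_COLUMN_PRESETS)}"
                    )
                cols = _COLUMN_PRESETS[cols]
            outcomes.append(
                OutcomeSpec(
                    label=str(label),
                    path=spec["path"],
                    columns=cols,
                    n_cases=spec.get("n_cases"),
                    n_controls=spec.get("n_controls"),
                )
            )
        exp_cols = raw.get("exposure_columns", "default")
        if isinstance(exp_cols, str):
            exp_cols = _COLUMN_PRESETS[exp_cols]
        return cls(
            study=study,
            outcomes=outcomes,
            exposure_path=raw.get("exposure"),
            exposure_columns=exp_cols,
            exposure_n=raw.get("exposure_n"),
            outdir=raw.get("outdir", "."),
            mvmr_matrix=raw.get("mvmr_matrix"),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _estimate_row(outcome: str, est, het=None, evidence="") -> dict:
    return {
        "outcome": outcome,
        "method": est.method,
        "n_snps": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "or_": est.or_,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
        "q_stat": het.q_stat if het else float("nan"),
        "q_df": het.df if het else float("nan"),
        "q_pvalue": het.pvalue if het else float("nan"),
        "evidence": evidence,
    }


def analyse_outcome(
    label: str,
    hset: HarmonizedSet,
    study: StudyConfig,
    n_exp: int,
    n_out: int,
) -> tuple[list[dict], dict]:
    """All estimators and diagnostics for one harmonized outcome.

    Returns (report rows, JSON-ready diagnostics document).
    """
    est_rand, het = ivw(hset, mode="random", se_mode=study.wald_se, alpha=study.alpha)
    est_fix, _ = ivw(hset, mode="fixed", se_mode=study.wald_se, alpha=study.alpha)
    est_med = weighted_median(
        hset, reps=study.bootstrap_reps, seed=study.seed, se_mode=study.wald_se,
        alpha=study.alpha,
    )
    est_slope, est_int = mr_egger(hset, alpha=study.alpha)
    presso = mr_presso(
        hset, reps=study.presso_reps, seed=study.seed, threshold=study.alpha
    )
    corrected = dataclasses.replace(presso.corrected, method="presso_corrected")
    loo = leave_one_out(hset, mode="random")
    st = steiger(hset, n_exp=n_exp, n_out=n_out, outcome_binary=True)

    rows = []
    for est in (est_rand, est_fix, est_med, est_slope, corrected):
        rows.append(
            _estimate_row(
                label,
                est,
                het if est.method == "ivw" else None,
                evidence=study.significance_label(est.pvalue),
            )
        )
    rows.append(_estimate_row(label, est_int))

    diag = {
        "heterogeneity": {"q_stat": het.q_stat, "df": het.df, "pvalue": het.pvalue},
        "egger_intercept": {
            "beta": est_int.beta,
            "se": est_int.se,
            "pvalue": est_int.pvalue,
        },
        "presso": {
            "global_rss": presso.global_rss,
            "global_p": presso.global_p,
            "outliers": list(presso.outliers),
            "corrected_beta": presso.corrected.beta,
            "corrected_or": presso.corrected.or_,
            "distortion_p": None if math.isnan(presso.distortion_p) else presso.distortion_p,
            "reps": presso.reps,
            "seed": presso.seed,
        },
        "leave_one_out": leave_one_out_frame(loo).to_dict(orient="records"),
        "steiger": {
            "r2_exposure": st.r2_exposure,
            "r2_outcome": st.r2_outcome,
            "direction_ok": st.direction_ok,
            "pvalue": st.pvalue,
        },
    }
    return rows, diag


def run_study(config, outdir: Optional[str] = None) -> dict:
    """Run the full pipeline from a YAML config path or a RunConfig.

    Writes ``report.tsv``, ``report.json``, ``exclusions.tsv``, and
    ``manifest.json`` under the configured output directory and returns
    the manifest dictionary.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_yaml(config)
    study = cfg.study
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    checksums = {}
    if cfg.exposure_path:
        exposure = read_association_table(
            cfg.exposure_path, column_map=cfg.exposure_columns, role="exposure",
            trait="exposure", n_default=cfg.exposure_n,
        )
        checksums[str(cfg.exposure_path)] = _sha256(cfg.exposure_path)
    else:
        exposure = load_packaged_instruments()
        logger.info("using packaged MDD instrument table (%d SNPs)", len(exposure))
    # genome-wide significance filter on user-supplied instruments
    strong = [r for r in exposure if r.pvalue < study.gw_threshold]
    if len(strong) < len(exposure):
        logger.warning(
            "dropping %d instruments above the genome-wide threshold %.1e",
            len(exposure) - len(strong), study.gw_threshold,
        )
        exposure = AssociationTable(
            strong, role="exposure", trait=exposure.trait, n_default=exposure.n_default
        )

    n_exp = exposure.n_default or max(r.n for r in exposure)
    all_rows: list[dict] = []
    diagnostics: dict = {}
    exclusion_frames = []
    summary: dict = {}
    for spec in cfg.outcomes:
        if not Path(spec.path).exists():
            raise FileNotFoundError(f"outcome file not found: {spec.path}")
        checksums[str(spec.path)] = _sha256(spec.path)
        outcome = read_association_table(
            spec.path, column_map=spec.columns, role="outcome", trait=spec.label,
            n_default=(spec.n_cases or 0) + (spec.n_controls or 0) or None,
        )
        hset = harmonize_tables(exposure, outcome, study)
        excl = hset.exclusions_frame()
        excl.insert(0, "outcome", spec.label)
        exclusion_frames.append(excl)
        logger.info(
            "%s: %d pairs retained, %d excluded", spec.label, len(hset), len(hset.exclusions)
        )
        if len(hset) < 3:
            logger.warning("%s: fewer than 3 harmonized pairs, skipping outcome", spec.label)
            summary[spec.label] = {"n_snps": len(hset), "skipped": True}
            continue
        n_out = outcome.n_default or max(r.n for r in outcome)
        rows, diag = analyse_outcome(spec.label, hset, study, n_exp=n_exp, n_out=n_out)
        r2_total = total_variance_explained(hset)
        fstats = strength_table(hset, n=n_exp)["f_stat"]
        diag["instrument_strength"] = {
            "r2_total": r2_total,
            "aggregate_f": f_statistic(r2_total, n_exp, k=len(hset)),
            "min_f": float(fstats.min()),
            "max_f": float(fstats.max()),
        }
        all_rows.extend(rows)
        diagnostics[spec.label] = diag
        ivw_row = rows[0]
        summary[spec.label] = {
            "n_snps": len(hset),
            "ivw_or": ivw_row["or_"],
            "ivw_p": ivw_row["pvalue"],
            "evidence": ivw_row["evidence"],
        }

    if cfg.mvmr_matrix:
        checksums[str(cfg.mvmr_matrix)] = _sha256(cfg.mvmr_matrix)
        mv = pd.read_csv(cfg.mvmr_matrix, sep="\t", float_precision="round_trip")
        required = {"snp", "beta_out", "se_out"}
        if not required.issubset(mv.columns):
            raise ConfigurationError(
                f"MVMR matrix must carry columns {sorted(required)} plus one per exposure"
            )
        exp_cols = [c for c in mv.columns if c not in required]
        ests = mvmr_ivw(mv[exp_cols], mv["beta_out"], mv["se_out"], alpha=study.alpha)
        for est in ests:
            all_rows.append(
                _estimate_row("mvmr", est, evidence=study.significance_label(est.pvalue))
            )

    report = report_frame(all_rows)
    write_report(report, out / "report.tsv", "tsv")
    write_report(report, out / "report.json", "json")
    exclusions = (
        pd.concat(exclusion_frames, ignore_index=True)
        if exclusion_frames
        else pd.DataFrame(columns=["outcome", "snp", "reason"])
    )
    exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    with open(out / "diagnostics.json", "w", encoding="utf-8") as fh:
        json.dump(diagnostics, fh, indent=1)

    manifest = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": study.seed,
        "config": dataclasses.asdict(study),
        "input_checksums": checksums,
        "exclusion_counts": exclusions.groupby("reason").size().to_dict()
        if len(exclusions)
        else {},
        "outcomes": summary,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
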