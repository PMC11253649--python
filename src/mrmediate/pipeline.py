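"""Orchestration of the MR screens and the estimator-selection rules.

A screen runs the same per-trait pipeline over a catalogue of exposures
against one outcome: instrument selection → allele harmonization → causal
estimation with IVW, MR-Egger and the weighted median → diagnostics → a
verdict.  Two decision rules are applied to the diagnostics:

* primary-estimator rule — pleiotropy (Egger intercept p < α) promotes
  MR-Egger; otherwise heterogeneity (Cochran Q p < α) promotes the weighted
  median; otherwise IVW is preferred;
* exclusion rule — analyses showing BOTH significant pleiotropy AND
  significant heterogeneity are excluded outright.

Screening significance is judged on the IVW p-value (with the chosen
primary estimator reported alongside), and no multiple-testing correction
is applied across traits by default; a Benjamini-Hochberg option is
available.  Significant pairs can be re-tested in the reverse direction
(outcome as exposure) to flag bidirectional relationships.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._exceptions import InsufficientInstrumentsError
from .diagnostics import DiagnosticsBundle, run_diagnostics
from .estimators import MRResult, egger, ivw, wald_ratio, weighted_median
from .instruments import ConfounderTable, LdTable, select_instruments
from .io import HarmonizedInstrumentSet, SnpAssociation, harmonize, read_summary_stats

logger = logging.getLogger("mrmediate")

__all__ = [
    "ScreenConfig",
    "AnalysisVerdict",
    "decide_primary",
    "apply_exclusion",
    "run_analysis",
    "run_screen",
    "reverse_mr",
    "verdicts_to_table",
]

#: float formatting used for every emitted table — fixed so identical runs
#: produce byte-identical files
TABLE_FLOAT_FORMAT = "%.10g"


@dataclass
class ScreenConfig:
    """All thresholds of one screen; defaults follow the study design.

    ``p_exposure`` is the instrument p-value cutoff (5e-8 standard,
    relaxed to 1e-5 for exposures with few genome-wide-significant hits,
    e.g. microbial abundance traits).
    """

    p_exposure: float = 5e-8
    f_min: float = 10.0
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    alpha: float = 0.05
    n_boot: int = 1000
    presso_sim: int = 1000
    seed: int = 0
    palindromic_policy: str = "drop"
    remove_presso_outliers: bool = True
    bh_correction: bool = False
    reverse_p_exposure: float = 1e-5
    confounder_traits: list[str] | None = None
    confounder_p: float = 5e-8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class AnalysisVerdict:
    """Outcome of one exposure-outcome MR analysis."""

    exposure_id: str
    outcome_id: str
    primary_method: str | None
    primary_result: MRResult | None
    ivw_result: MRResult | None
    egger_result: MRResult | None
    wm_result: MRResult | None
    diagnostics: DiagnosticsBundle | None
    status: str  # significant | nonsignificant | excluded_heterogeneity_and_pleiotropy | insufficient_instruments
    n_instruments: int
    presso_outliers_removed: tuple[str, ...] = ()
    reverse_result: MRResult | None = None
    bidirectional_flag: bool = False

    @property
    def significant(self) -> bool:
        return self.status == "significant"


def _sig(p: float | None, alpha: float) -> bool:
    """NaN/None p-values count as no evidence, not as significance."""
    return p is not None and not math.isnan(p) and p < alpha


def decide_primary(diag: DiagnosticsBundle, alpha: float = 0.05) -> str:
    """Estimator preference ladder given the diagnostics.

    Pleiotropy (Egger intercept p < alpha) → ``egger``; otherwise
    heterogeneity (Q p < alpha) → ``weighted_median``; otherwise ``ivw``.
    """
    if diag is None:
        raise ValueError("diagnostics required to choose the primary estimator")
    if _sig(diag.egger_intercept_pval, alpha):
        return "egger"
    if _sig(diag.q_pval, alpha):
        return "weighted_median"
    return "ivw"


def apply_exclusion(diag: DiagnosticsBundle, alpha: float = 0.05) -> bool:
    """True (exclude) when pleiotropy AND heterogeneity are both significant."""
    return _sig(diag.egger_intercept_pval, alpha) and _sig(diag.q_pval, alpha)


def _load_stats(source) -> list[SnpAssociation]:
    if isinstance(source, (str, Path)):
        records, _ = read_summary_stats(source)
        return records
    return list(source)


def run_analysis(
    exposure_stats: Sequence[SnpAssociation] | str | Path,
    outcome_stats: Sequence[SnpAssociation] | str | Path,
    ld: LdTable,
    config: ScreenConfig,
    confounders: ConfounderTable | None = None,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> AnalysisVerdict:
    """One full exposure→outcome MR analysis.

    Select instruments, harmonize, estimate with every applicable method,
    diagnose, optionally re-estimate after removing MR-PRESSO outliers, and
    apply the decision and exclusion rules.  With a single instrument the
    Wald ratio is the (only) estimate and diagnostics are unavailable.
    """
    exposure = _load_stats(exposure_stats)
    outcome = _load_stats(outcome_stats)

    instruments, _report = select_instruments(
        exposure,
        ld,
        confounders,
        p_threshold=config.p_exposure,
        f_min=config.f_min,
        clump_r2=config.clump_r2,
        clump_kb=config.clump_kb,
        confounder_traits=config.confounder_traits,
        confounder_p=config.confounder_p,
    )
    if not instruments:
        return AnalysisVerdict(exposure_id, outcome_id, None, None, None, None, None, None,
                               "insufficient_instruments", 0)

    hset = harmonize(instruments, outcome, config.palindromic_policy, exposure_id, outcome_id)
    removed: tuple[str, ...] = ()
    if hset.n_snp == 0:
        return AnalysisVerdict(exposure_id, outcome_id, None, None, None, None, None, None,
                               "insufficient_instruments", 0)

    if hset.n_snp == 1:
        row = hset.kept.iloc[0]
        res = wald_ratio(row["beta_exp"], row["beta_out"], row["se_out"])
        status = "significant" if res.pval < config.alpha else "nonsignificant"
        return AnalysisVerdict(exposure_id, outcome_id, "wald_ratio", res, None, None, None, None,
                               status, 1)

    diag = _diagnose(hset, config)
    if config.remove_presso_outliers and diag.presso is not None and diag.presso.outliers:
        keep = [s for s in hset.snp_ids if s not in diag.presso.outliers]
        if len(keep) >= 2:
            logger.info("%s -> %s: removing %d MR-PRESSO outlier(s): %s",
                        exposure_id, outcome_id, len(diag.presso.outliers), ",".join(diag.presso.outliers))
            removed = diag.presso.outliers
            hset = hset.subset(keep)
            diag = _diagnose(hset, config)

    ivw_res = ivw(hset)
    egger_res = wm_res = None
    if hset.n_snp >= 3:
        egger_res, _ = egger(hset)
        wm_res = weighted_median(hset, n_boot=config.n_boot, seed=config.seed)

    excluded = apply_exclusion(diag, config.alpha) if hset.n_snp >= 3 else False
    method = decide_primary(diag, config.alpha) if hset.n_snp >= 3 else "ivw"
    primary = {"ivw": ivw_res, "egger": egger_res, "weighted_median": wm_res}[method]
    if excluded:
        status = "excluded_heterogeneity_and_pleiotropy"
    else:
        status = "significant" if ivw_res.pval < config.alpha else "nonsignificant"
    return AnalysisVerdict(exposure_id, outcome_id, method, primary, ivw_res, egger_res, wm_res,
                           diag, status, hset.n_snp, removed)


def _diagnose(hset: HarmonizedInstrumentSet, config: ScreenConfig) -> DiagnosticsBundle:
    return run_diagnostics(hset, presso_sim=config.presso_sim, seed=config.seed,
                           with_presso=hset.n_snp >= 4)


def run_screen(
    exposures: Mapping[str, Sequence[SnpAssociation] | str | Path],
    outcome: Sequence[SnpAssociation] | str | Path,
    ld: LdTable,
    config: ScreenConfig,
    confounders: ConfounderTable | None = None,
    outcome_id: str = "outcome",
) -> list[AnalysisVerdict]:
    """Run the per-trait analysis over a whole exposure catalogue.

    ``exposures`` maps trait ids to record lists or file paths; unresolvable
    files are logged and skipped, never abort the screen.  Optional
    Benjamini-Hochberg adjustment of the screening (IVW) p-values is applied
    across the catalogue when ``config.bh_correction`` is set.
    """
    outcome_records = _load_stats(outcome)
    verdicts: list[AnalysisVerdict] = []
    for trait_id, source in exposures.items():
        try:
            exposure_records = _load_stats(source)
        except (OSError, ValueError) as exc:
            logger.warning("skipping %s: %s", trait_id, exc)
            continue
        verdict = run_analysis(exposure_records, outcome_records, ld, config, confounders,
                               exposure_id=trait_id, outcome_id=outcome_id)
        logger.info("%s -> %s: status=%s n_snp=%d", trait_id, outcome_id, verdict.status, verdict.n_instruments)
        verdicts.append(verdict)

    if config.bh_correction:
        _apply_bh(verdicts, config.alpha)
    return verdicts


def _apply_bh(verdicts: list[AnalysisVerdict], alpha: float) -> None:
    """Benjamini-Hochberg across the screen's IVW p-values (in place)."""
    scored = [v for v in verdicts if v.ivw_result is not None and v.status in ("significant", "nonsignificant")]
    if not scored:
        return
    pvals = np.array([v.ivw_result.pval for v in scored])
    order = np.argsort(pvals)
    m = len(pvals)
    passed = np.zeros(m, bool)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = pvals[order] <= thresh
    if below.any():
        cutoff = np.max(np.nonzero(below)[0])
        passed[order[: cutoff + 1]] = True
    for v, ok in zip(scored, passed):
        v.status = "significant" if ok else "nonsignificant"


def reverse_mr(
    verdicts: Sequence[AnalysisVerdict],
    exposures: Mapping[str, Sequence[SnpAssociation] | str | Path],
    outcome: Sequence[SnpAssociation] | str | Path,
    ld: LdTable,
    config: ScreenConfig,
) -> list[AnalysisVerdict]:
    """Reverse-direction MR for every significant pair (in place, returned).

    The outcome trait becomes the exposure (instrumented at
    ``config.reverse_p_exposure``) and each significant exposure becomes the
    outcome; a reverse IVW p < alpha sets ``bidirectional_flag``.  Pairs
    without usable reverse instruments keep a missing reverse result and a
    False flag.
    """
    outcome_records = _load_stats(outcome)
    reverse_config = ScreenConfig(**{**asdict(config), "p_exposure": config.reverse_p_exposure})
    for verdict in verdicts:
        if not verdict.significant:
            continue
        try:
            exposure_records = _load_stats(exposures[verdict.exposure_id])
        except (KeyError, OSError, ValueError) as exc:
            logger.warning("reverse MR skipped for %s: %s", verdict.exposure_id, exc)
            continue
        rev = run_analysis(outcome_records, exposure_records, ld, reverse_config,
                           exposure_id=verdict.outcome_id, outcome_id=verdict.exposure_id)
        if rev.ivw_result is not None:
            verdict.reverse_result = rev.ivw_result
            verdict.bidirectional_flag = rev.ivw_result.pval < config.alpha
        elif rev.primary_result is not None:  # single-instrument reverse panel
            verdict.reverse_result = rev.primary_result
            verdict.bidirectional_flag = rev.primary_result.pval < config.alpha
        else:
            logger.info("no reverse instruments for %s -> %s", verdict.outcome_id, verdict.exposure_id)
    return list(verdicts)


def _result_row(exposure: str, outcome: str, res: MRResult) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "method": res.method,
        "n_snp": res.n_snp,
        "beta": res.beta_hat,
        "se": res.se_hat,
        "OR": res.or_hat,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pval": res.pval,
    }


def verdicts_to_table(verdicts: Sequence[AnalysisVerdict]) -> pd.DataFrame:
    """Long results table: one row per (analysis, estimator), plus verdict columns."""
    rows = []
    for v in verdicts:
        for res in (v.ivw_result, v.egger_result, v.wm_result,
                    v.primary_result if v.primary_method == "wald_ratio" else None):
            if res is None:
                continue
            row = _result_row(v.exposure_id, v.outcome_id, res)
            row["primary"] = res.method == v.primary_method
            row["status"] = v.status
            row["bidirectional"] = v.bidirectional_flag
            rows.append(row)
        if v.primary_result is None:
            rows.append({"exposure": v.exposure_id, "outcome": v.outcome_id, "method": "none",
                         "n_snp": 0, "beta": np.nan, "se": np.nan, "OR": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "pval": np.nan, "primary": False, "status": v.status,
                         "bidirectional": False})
    return pd.DataFrame(rows)


def diagnostics_table(verdicts: Sequence[AnalysisVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        if v.diagnostics is None:
            continue
        row = {"exposure": v.exposure_id, "outcome": v.outcome_id}
        row.update(v.diagnostics.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with fixed float formatting (byte-stable across runs)."""
    df.to_csv(path, sep="\t", index=False, float_format=TABLE_FLOAT_FORMAT)


def _verdicts_from_table(df: pd.DataFrame) -> list[AnalysisVerdict]:
    """Minimal verdict reconstruction from a written results table.

    Only the primary-estimate rows are used; diagnostics and secondary
    estimators are not round-tripped.  Used by the CLI's mediation command.
    """
    verdicts = []
    for _, row in df[df["primary"] == True].iterrows():  # noqa: E712 (TSV booleans)
        res = MRResult(str(row["method"]), float(row["beta"]), float(row["se"]), float(row["pval"]),
                       float(row["OR"]), float(row["ci_low"]), float(row["ci_high"]), int(row["n_snp"]))
        verdicts.append(AnalysisVerdict(str(row["exposure"]), str(row["outcome"]), res.method, res,
                                        None, None, None, None, str(row["status"]), res.n_snp))
    return verdicts
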