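"""Heterogeneity, pleiotropy, outlier and sensitivity diagnostics.

Four complementary checks of the instrumental-variable assumptions:

* Cochran's Q — weighted dispersion of per-SNP Wald ratios about the IVW
  estimate; a significant Q flags heterogeneity (some instruments estimate
  a different effect);
* the MR-Egger intercept test — non-zero intercept flags average
  directional pleiotropy;
* MR-PRESSO — a resampling test on the leave-one-out residual sum of
  squares that detects (global test) and localizes (outlier test) SNPs
  whose outcome effects are inconsistent with the rest of the panel, plus a
  distortion test for whether removing them changes the estimate;
* leave-one-out — re-estimation with each SNP omitted, flagging omissions
  that flip the sign of the estimate or move it across the significance
  boundary.

Outlier removal is reported, never silently applied: the screening pipeline
decides what to do with flagged SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import InsufficientInstrumentsError
from .estimators import EggerEstimator, EggerIntercept, IVWEstimator, MRResult
from .io import HarmonizedInstrumentSet

__all__ = [
    "DiagnosticsBundle",
    "PressoResult",
    "MRPRESSO",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "run_diagnostics",
]


def cochran_q(hset: HarmonizedInstrumentSet) -> tuple[float, int, float]:
    """Cochran's Q over the instrument panel: (Q, df, p).

    Q = Σ wⱼ(ratioⱼ − β_IVW)² with first-order inverse-variance weights;
    p is the chi-square upper tail on k−1 degrees of freedom.
    """
    bx, _, by, sy = hset.arrays()
    if len(bx) < 2:
        raise InsufficientInstrumentsError("cochran_q", 2, len(bx))
    w = bx**2 / sy**2
    ratio = by / bx
    beta = (w * ratio).sum() / w.sum()
    q = float((w * (ratio - beta) ** 2).sum())
    df = len(bx) - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(hset: HarmonizedInstrumentSet) -> EggerIntercept:
    """MR-Egger intercept with t-based p on k−2 df (≥ 3 instruments).

    A residual variance of exactly zero (collinear construction) makes the
    p-value degenerate; it is reported as NaN.
    """
    bx, _, by, sy = hset.arrays()
    if len(bx) < 3:
        raise InsufficientInstrumentsError("egger_intercept", 3, len(bx))
    est = EggerEstimator().fit(bx, by, sy)
    return est.intercept_result_()


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_pval: float
    outliers: tuple[str, ...]
    outlier_pvals: dict[str, float]
    distortion_pval: float | None
    beta_all: float
    beta_no_outliers: float | None
    note: str = ""


class MRPRESSO(BaseEstimator):
    """Pleiotropy residual-sum-and-outlier test (resampling based).

    The panel is standardized by the outcome se; for each SNP the IVW slope
    is re-fit without it and the squared standardized residual of the SNP
    against that leave-one-out prediction is accumulated into the observed
    RSS.  The null distribution comes from ``n_sim`` parametric redraws of
    the outcome betas around their leave-one-out predictions.  Per-SNP
    empirical outlier p-values are Bonferroni-corrected; when outliers are
    found, a distortion test compares the estimate without them against a
    null of removing equally many random SNPs.

    All resampling is driven by ``seed``; identical seeds give identical
    results.  Requires ≥ 3 instruments for the global test and ≥ 4 for the
    outlier test.
    """

    def __init__(self, n_sim: int = 1000, seed: int = 0, outlier_threshold: float = 0.05):
        self.n_sim = n_sim
        self.seed = seed
        self.outlier_threshold = outlier_threshold

    @staticmethod
    def _loo_slopes(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Zero-intercept OLS slope on standardized data, leaving out each SNP."""
        sxy, sxx = xs @ ys, xs @ xs
        return (sxy - xs * ys) / (sxx - xs * xs)

    def fit(self, X, y, se_out):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        s = np.asarray(se_out, float).reshape(-1)
        k = len(x)
        if k < 3:
            raise InsufficientInstrumentsError("mr_presso", 3, k)
        rng = np.random.default_rng(self.seed)
        xs, ys = x / s, y / s

        slopes_loo = self._loo_slopes(xs, ys)
        obs_resid2 = (ys - slopes_loo * xs) ** 2
        self.global_rss_ = float(obs_resid2.sum())

        # parametric null: redraw outcome betas around their LOO predictions
        y_null = rng.normal(slopes_loo * x, s, size=(self.n_sim, k))
        ysn = y_null / s
        sxy_n = ysn @ xs
        sxx = xs @ xs
        slopes_n = (sxy_n[:, None] - xs[None, :] * ysn) / (sxx - xs * xs)
        resid2_n = (ysn - slopes_n * xs[None, :]) ** 2
        rss_n = resid2_n.sum(axis=1)
        self.global_pval_ = float((1 + (rss_n >= self.global_rss_).sum()) / (self.n_sim + 1))

        self.outlier_pvals_ = None
        self.outlier_mask_ = np.zeros(k, bool)
        self.note_ = ""
        if k >= 4:
            p_emp = (1 + (resid2_n >= obs_resid2[None, :]).sum(axis=0)) / (self.n_sim + 1)
            p_bonf = np.minimum(1.0, p_emp * k)
            self.outlier_pvals_ = p_bonf
            self.outlier_mask_ = p_bonf < self.outlier_threshold
        else:
            self.note_ = "outlier test skipped: fewer than 4 instruments"

        w = xs**2
        beta_all = float((xs * ys).sum() / w.sum())
        self.beta_all_ = beta_all
        self.beta_no_outliers_ = None
        self.distortion_pval_ = None
        n_out = int(self.outlier_mask_.sum())
        if 0 < n_out < k - 1:
            keep = ~self.outlier_mask_
            beta_no = float((xs[keep] * ys[keep]).sum() / (w[keep]).sum())
            self.beta_no_outliers_ = beta_no
            if beta_no != 0:
                d_obs = 100.0 * (beta_all - beta_no) / abs(beta_no)
                d_null = np.empty(self.n_sim)
                idx = np.arange(k)
                for i in range(self.n_sim):
                    drop = rng.choice(idx, size=n_out, replace=False)
                    m = np.ones(k, bool)
                    m[drop] = False
                    b = float((xs[m] * ys[m]).sum() / w[m].sum())
                    d_null[i] = 100.0 * (beta_all - b) / abs(b) if b != 0 else np.inf
                self.distortion_pval_ = float(
                    (1 + (np.abs(d_null) >= abs(d_obs)).sum()) / (self.n_sim + 1)
                )
        return self


def mr_presso(hset: HarmonizedInstrumentSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """Run MR-PRESSO on a harmonized set; see :class:`MRPRESSO`."""
    bx, _, by, sy = hset.arrays()
    est = MRPRESSO(n_sim=n_sim, seed=seed).fit(bx, by, sy)
    snps = np.asarray(hset.snp_ids)
    outliers = tuple(snps[est.outlier_mask_])
    pvals = (
        {} if est.outlier_pvals_ is None else {s: float(p) for s, p in zip(snps, est.outlier_pvals_)}
    )
    return PressoResult(
        global_rss=est.global_rss_,
        global_pval=est.global_pval_,
        outliers=outliers,
        outlier_pvals=pvals,
        distortion_pval=est.distortion_pval_,
        beta_all=est.beta_all_,
        beta_no_outliers=est.beta_no_outliers_,
        note=est.note_,
    )


def leave_one_out(hset: HarmonizedInstrumentSet, alpha: float = 0.05) -> pd.DataFrame:
    """IVW re-estimated k times, omitting one SNP each time.

    Returns a table (omitted_snp, beta, se, pval, sign_flip,
    significance_change) where the flags compare each omission against the
    full-panel IVW estimate.
    """
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("leave_one_out", 3, k)
    full = IVWEstimator().fit(bx, by, sy)
    rows = []
    for i, snp in enumerate(hset.snp_ids):
        m = np.ones(k, bool)
        m[i] = False
        est = IVWEstimator().fit(bx[m], by[m], sy[m])
        rows.append(
            {
                "omitted_snp": snp,
                "beta": est.beta_,
                "se": est.se_,
                "pval": est.pval_,
                "sign_flip": bool(np.sign(est.beta_) != np.sign(full.beta_) and est.beta_ != 0 and full.beta_ != 0),
                "significance_change": bool((est.pval_ < alpha) != (full.pval_ < alpha)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DiagnosticsBundle:
    """All diagnostics for one exposure-outcome analysis."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso: PressoResult | None = None
    loo: pd.DataFrame | None = None

    @property
    def presso_global_pval(self) -> float | None:
        return None if self.presso is None else self.presso.global_pval

    @property
    def presso_outliers(self) -> tuple[str, ...]:
        return () if self.presso is None else self.presso.outliers

    def as_row(self) -> dict:
        return {
            "q": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_pval": self.egger_intercept_pval,
            "presso_global_pval": np.nan if self.presso is None else self.presso.global_pval,
            "presso_outliers": ";".join(self.presso_outliers),
            "distortion_pval": np.nan
            if self.presso is None or self.presso.distortion_pval is None
            else self.presso.distortion_pval,
        }


def run_diagnostics(
    hset: HarmonizedInstrumentSet,
    presso_sim: int = 1000,
    seed: int = 0,
    with_presso: bool = True,
    with_loo: bool = True,
) -> DiagnosticsBundle:
    """Assemble the full diagnostics bundle for one analysis (≥ 3 SNPs for
    Egger/PRESSO/LOO; Q alone needs only 2 — missing pieces are NaN)."""
    k = hset.n_snp
    q, df, qp = cochran_q(hset)
    if k >= 3:
        inter = egger_intercept_test(hset)
        presso = mr_presso(hset, n_sim=presso_sim, seed=seed) if with_presso else None
        loo = leave_one_out(hset) if with_loo else None
    else:
        inter = EggerIntercept(float("nan"), float("nan"), float("nan"))
        presso, loo = None, None
    return DiagnosticsBundle(q, df, qp, inter.intercept, inter.se, inter.pval, presso, loo)
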