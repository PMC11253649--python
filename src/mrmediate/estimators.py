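"""Causal-effect estimators for two-sample MR.

Each estimator consumes per-SNP summary associations — exposure betas ``X``,
outcome betas ``y`` and their standard errors — and returns a causal effect
of the exposure on the outcome (log-odds per exposure unit for a binary
outcome).  Three multi-SNP estimators are provided:

* inverse-variance weighting (IVW): the 1/se² weighted mean of per-SNP Wald
  ratios, equal to the zero-intercept weighted least-squares slope of
  outcome betas on exposure betas; unbiased when every instrument is valid;
* MR-Egger: the same regression with a free intercept, whose intercept
  estimates the average directional pleiotropy and whose slope remains
  consistent under the InSIDE assumption;
* weighted median: the cumulative-weight interpolated median of Wald
  ratios, consistent while less than half the total weight comes from
  invalid instruments.

Classes follow the scikit-learn estimator protocol (``fit``, fitted
attributes with trailing underscores, ``get_params``/``set_params``) so they
compose with sklearn tooling; the module-level functions ``ivw``, ``egger``,
``weighted_median`` and ``wald_ratio`` are thin wrappers operating on a
:class:`~mrmediate.io.HarmonizedInstrumentSet`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import InsufficientInstrumentsError
from .io import HarmonizedInstrumentSet

__all__ = [
    "MRResult",
    "EggerIntercept",
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "to_odds_scale",
    "ratio_estimates",
]

#: 97.5% normal quantile used for every 95% interval
CI_Z = 1.959964

_P_FLOOR = 1e-300  # keep p-values strictly positive


def _wald_p(beta: float, se: float, df: int | None = None) -> float:
    """Two-sided p for beta/se, normal by default or Student-t on df."""
    if se == 0:
        return 1.0 if beta == 0 else _P_FLOOR
    if not np.isfinite(se):
        return float("nan")
    z = abs(beta / se)
    p = 2 * (stats.t.sf(z, df) if df is not None else stats.norm.sf(z))
    return max(float(p), _P_FLOOR)


def to_odds_scale(beta_hat: float, se_hat: float) -> tuple[float, float, float, float]:
    """Map a log-odds effect and its se to (OR, ci_low, ci_high, p).

    The 95% CI is symmetric on the log scale, so the OR is the geometric
    mean of its bounds.  A NaN se (e.g. a skipped bootstrap) propagates to
    NaN bounds and p.
    """
    if se_hat < 0:
        raise ValueError("se_hat must be non-negative")
    or_hat = float(np.exp(beta_hat))
    lo = float(np.exp(beta_hat - CI_Z * se_hat))
    hi = float(np.exp(beta_hat + CI_Z * se_hat))
    return or_hat, lo, hi, _wald_p(beta_hat, se_hat)


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal estimate with OR-scale presentation."""

    method: str
    beta_hat: float
    se_hat: float
    pval: float
    or_hat: float
    ci_low: float
    ci_high: float
    n_snp: int

    @classmethod
    def from_log_scale(
        cls, method: str, beta_hat: float, se_hat: float, n_snp: int, pval: float | None = None
    ) -> "MRResult":
        or_hat, lo, hi, wald_p = to_odds_scale(beta_hat, se_hat)
        return cls(method, float(beta_hat), float(se_hat), wald_p if pval is None else pval, or_hat, lo, hi, n_snp)


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: the average directional-pleiotropy estimate."""

    intercept: float
    se: float
    pval: float


def ratio_estimates(
    beta_exp: np.ndarray,
    beta_out: np.ndarray,
    se_out: np.ndarray,
    se_exp: np.ndarray | None = None,
    second_order: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios, their standard errors, and inverse-variance weights.

    The default (first-order) delta approximation ``se_out/|beta_exp|``
    ignores exposure-side sampling error; ``second_order=True`` adds the
    ``beta_out²·se_exp²/beta_exp⁴`` term.
    """
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    se_out = np.asarray(se_out, float)
    if np.any(beta_exp == 0):
        raise ValueError("Wald ratio undefined for beta_exp = 0")
    ratio = beta_out / beta_exp
    var = se_out**2 / beta_exp**2
    if second_order:
        if se_exp is None:
            raise ValueError("second-order ratio se requires se_exp")
        var = var + beta_out**2 * np.asarray(se_exp, float) ** 2 / beta_exp**4
    ratio_se = np.sqrt(var)
    return ratio, ratio_se, 1.0 / var


def _validate_xy(X, y, se_out) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(X, float).reshape(-1)
    y = np.asarray(y, float).reshape(-1)
    s = np.asarray(se_out, float).reshape(-1)
    if not (len(x) == len(y) == len(s)):
        raise ValueError("X, y and se_out must have equal length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("betas must be finite")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("se_out must be positive and finite")
    return x, y, s


class _BaseMR(BaseEstimator, RegressorMixin):
    """Shared fit plumbing; subclasses set ``method`` and ``_estimate``."""

    method: str = ""
    _min_snps: int = 2

    def _check(self, X, y, se_out):
        x, y, s = _validate_xy(X, y, se_out)
        if len(x) < self._min_snps:
            raise InsufficientInstrumentsError(self.method, self._min_snps, len(x))
        return x, y, s

    def _finalize(self, beta: float, se: float, n_snp: int, pval: float | None = None) -> None:
        self.beta_ = float(beta)
        self.se_ = float(se)
        res = MRResult.from_log_scale(self.method, beta, se, n_snp, pval)
        self.pval_ = res.pval
        self.or_ = res.or_hat
        self.ci_low_ = res.ci_low
        self.ci_high_ = res.ci_high
        self.n_snp_ = n_snp

    def result_(self) -> MRResult:
        return MRResult(self.method, self.beta_, self.se_, self.pval_, self.or_, self.ci_low_, self.ci_high_, self.n_snp_)

    def predict(self, X):
        x = np.asarray(X, float).reshape(-1)
        return getattr(self, "intercept_", 0.0) + self.beta_ * x


class IVWEstimator(_BaseMR):
    """Inverse-variance-weighted estimator.

    Parameters
    ----------
    random_effects : bool
        Fixed-effect by default; the multiplicative random-effects variant
        inflates the se by max(1, sqrt(Q/(k−1))).
    """

    method = "ivw"
    _min_snps = 2

    def __init__(self, random_effects: bool = False):
        self.random_effects = random_effects

    def fit(self, X, y, se_out):
        x, y, s = self._check(X, y, se_out)
        w = x**2 / s**2  # == 1/ratio_se² (first-order)
        ratio = y / x
        sw = w.sum()
        beta = float((w * ratio).sum() / sw)
        se = float(np.sqrt(1.0 / sw))
        if self.random_effects and len(x) > 1:
            q = float((w * (ratio - beta) ** 2).sum())
            se *= max(1.0, np.sqrt(q / (len(x) - 1)))
        self._finalize(beta, se, len(x))
        return self


class EggerEstimator(_BaseMR):
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Instruments are oriented so every exposure beta is non-negative (signs
    of both betas flipped together) before fitting; inference on both
    coefficients uses Student-t on k−2 degrees of freedom with the weighted
    residual variance.
    """

    method = "egger"
    _min_snps = 3

    def fit(self, X, y, se_out):
        x, y, s = self._check(X, y, se_out)
        flip = np.where(x < 0, -1.0, 1.0)
        x, y = x * flip, y * flip
        w = 1.0 / s**2
        # closed-form 2-parameter WLS
        sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
        swy, swxy = (w * y).sum(), (w * x * y).sum()
        det = sw * swxx - swx**2
        if det <= 0 or not np.isfinite(det):
            raise ValueError("degenerate design: exposure betas carry no spread")
        slope = (sw * swxy - swx * swy) / det
        intercept = (swxx * swy - swx * swxy) / det
        resid = y - intercept - slope * x
        df = len(x) - 2
        sigma2 = float((w * resid**2).sum() / df)
        if sigma2 <= 1e-20 * float((w * y**2).sum() / df + 1e-300):
            sigma2 = 0.0  # exactly collinear construction up to rounding
        slope_se = float(np.sqrt(sigma2 * sw / det))
        int_se = float(np.sqrt(sigma2 * swxx / det))
        self._finalize(slope, slope_se, len(x), pval=_wald_p(slope, slope_se, df=df))
        self.intercept_ = float(intercept)
        self.intercept_se_ = int_se
        self.intercept_pval_ = _wald_p(intercept, int_se, df=df) if sigma2 > 0 else float("nan")
        if sigma2 == 0:
            # exactly collinear construction: residual variance 0, p degenerate
            self.pval_ = float("nan")
        return self

    def intercept_result_(self) -> EggerIntercept:
        return EggerIntercept(self.intercept_, self.intercept_se_, self.intercept_pval_)


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    r, w = ratio[order], weight[order]
    p = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, p, r))


class WeightedMedianEstimator(_BaseMR):
    """Weighted median of per-SNP Wald ratios.

    The point estimate interpolates the ordered ratios at cumulative
    standardized weight 0.5; the se comes from a seeded parametric bootstrap
    that redraws both betas from their sampling distributions
    (``n_boot=0`` skips the bootstrap, leaving se/p as NaN).
    """

    method = "weighted_median"
    _min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, se_out, se_exp=None):
        x, y, s = self._check(X, y, se_out)
        ratio, _, w = ratio_estimates(x, y, s)
        beta = _weighted_median_point(ratio, w)
        if self.n_boot:
            rng = np.random.default_rng(self.seed)
            sx = np.zeros_like(x) if se_exp is None else np.asarray(se_exp, float).reshape(-1)
            bx = rng.normal(x, sx, size=(self.n_boot, len(x)))
            by = rng.normal(y, s, size=(self.n_boot, len(x)))
            bx[bx == 0] = np.finfo(float).tiny  # guard degenerate redraws
            draws = np.empty(self.n_boot)
            for i in range(self.n_boot):
                r_i = by[i] / bx[i]
                w_i = bx[i] ** 2 / s**2
                draws[i] = _weighted_median_point(r_i, w_i)
            se = float(draws.std(ddof=1))
        else:
            se = float("nan")
        self._finalize(beta, se, len(x))
        return self


def wald_ratio(
    beta_exp: float, beta_out: float, se_out: float, se_exp: float | None = None, second_order: bool = False
) -> MRResult:
    """Single-SNP causal estimate: beta_out/beta_exp with delta-method se."""
    if beta_exp == 0:
        raise ValueError("Wald ratio undefined for beta_exp = 0")
    ratio, ratio_se, _ = ratio_estimates(
        np.array([beta_exp]), np.array([beta_out]), np.array([se_out]),
        None if se_exp is None else np.array([se_exp]), second_order,
    )
    return MRResult.from_log_scale("wald_ratio", float(ratio[0]), float(ratio_se[0]), 1)


def _fit_on_set(est: _BaseMR, hset: HarmonizedInstrumentSet, **fit_kw) -> _BaseMR:
    bx, sx, by, sy = hset.arrays()
    return est.fit(bx, by, sy, **fit_kw)


def ivw(hset: HarmonizedInstrumentSet, random_effects: bool = False) -> MRResult:
    """IVW causal estimate for a harmonized instrument set (≥ 2 SNPs)."""
    return _fit_on_set(IVWEstimator(random_effects=random_effects), hset).result_()


def egger(hset: HarmonizedInstrumentSet) -> tuple[MRResult, EggerIntercept]:
    """MR-Egger slope and pleiotropy intercept for a set (≥ 3 SNPs)."""
    est = _fit_on_set(EggerEstimator(), hset)
    return est.result_(), est.intercept_result_()


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median causal estimate for a set (≥ 3 SNPs)."""
    est = WeightedMedianEstimator(n_boot=n_boot, seed=seed)
    bx, sx, by, sy = hset.arrays()
    return est.fit(bx, by, sy, se_exp=sx).result_()
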