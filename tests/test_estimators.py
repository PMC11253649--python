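"""IVW, MR-Egger, weighted-median and Wald-ratio estimators."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from sklearn.base import clone

from mrmediate import (
    EggerEstimator,
    InsufficientInstrumentsError,
    IVWEstimator,
    WeightedMedianEstimator,
    egger,
    ivw,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)
from tests.conftest import mk_hset, random_panel


class TestWaldRatio:
    def test_unit_exposure_effect(self):
        res = wald_ratio(1.0, 0.3, 0.1)
        assert res.beta_hat == pytest.approx(0.3) and res.se_hat == pytest.approx(0.1)

    def test_hand_evaluated_negative_exposure(self):
        res = wald_ratio(-0.5, 0.2, 0.1)
        assert res.beta_hat == pytest.approx(-0.4)
        assert res.se_hat == pytest.approx(0.2)

    def test_scale_invariance(self):
        a = wald_ratio(0.2, 0.06, 0.01)
        b = wald_ratio(0.2 * 3.7, 0.06 * 3.7, 0.01)
        assert a.beta_hat == pytest.approx(b.beta_hat)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            wald_ratio(0.0, 0.1, 0.1)

    def test_second_order_se_exceeds_first_order(self):
        first = wald_ratio(0.1, 0.05, 0.02)
        second = wald_ratio(0.1, 0.05, 0.02, se_exp=0.02, second_order=True)
        assert second.se_hat > first.se_hat


class TestIVW:
    def test_hand_computed_weighted_mean(self):
        # ratios 0.5 (se 0.1, w=100) and 0.7 (se 0.2, w=25)
        h = mk_hset([1.0, 1.0], [0.5, 0.7], [0.1, 0.2])
        res = ivw(h)
        assert res.beta_hat == pytest.approx(0.54)
        assert res.se_hat == pytest.approx(np.sqrt(1 / 125))

    def test_degenerate_consensus(self):
        h = mk_hset([0.5, 1.0, 2.0], [0.15, 0.3, 0.6], [0.1, 0.3, 0.2])
        assert ivw(h).beta_hat == pytest.approx(0.3)

    def test_equals_zero_intercept_wls_closed_form(self, rng):
        """IVW is the zero-intercept WLS slope with weights 1/se_out²."""
        for _ in range(25):
            bx, sx, by, sy, _ = random_panel(rng, k=int(rng.integers(2, 40)))
            est = IVWEstimator().fit(bx, by, sy)
            wls = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
            assert est.beta_ == pytest.approx(wls.params[0], rel=1e-10)

    def test_random_effects_never_shrinks_se(self, rng):
        bx, sx, by, sy, _ = random_panel(rng, k=15)
        fe = IVWEstimator().fit(bx, by, sy)
        re = IVWEstimator(random_effects=True).fit(bx, by, sy)
        assert re.se_ >= fe.se_ and re.beta_ == pytest.approx(fe.beta_)

    def test_single_instrument_error_points_to_wald_ratio(self):
        with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
            ivw(mk_hset([1.0], [0.3], [0.1]))

    def test_matches_wald_ratio_in_two_copy_limit(self):
        """A single SNP duplicated: IVW collapses to that SNP's Wald ratio."""
        res1 = wald_ratio(0.2, 0.05, 0.01)
        res2 = ivw(mk_hset([0.2, 0.2], [0.05, 0.05], [0.01, 0.01]))
        assert res2.beta_hat == pytest.approx(res1.beta_hat)


class TestEgger:
    def test_exact_collinear_construction(self):
        # y = 0.01 + 0.2·x exactly: slope 0.2, intercept 0.01, zero residuals
        est = EggerEstimator().fit([0.1, 0.2, 0.3], [0.03, 0.05, 0.07], [0.01, 0.01, 0.01])
        assert est.beta_ == pytest.approx(0.2, abs=1e-12)
        assert est.intercept_ == pytest.approx(0.01, abs=1e-12)
        assert est.se_ == 0.0 and np.isnan(est.pval_)  # degenerate boundary case

    def test_matches_statsmodels_wls(self, rng):
        for _ in range(10):
            bx, sx, by, sy, _ = random_panel(rng, k=int(rng.integers(4, 30)))
            bx = np.abs(bx)  # pre-oriented so the oracle sees identical data
            est = EggerEstimator().fit(bx, by, sy)
            X = sm.add_constant(bx)
            wls = sm.WLS(by, X, weights=1.0 / sy**2).fit()
            assert est.intercept_ == pytest.approx(wls.params[0], rel=1e-9, abs=1e-12)
            assert est.beta_ == pytest.approx(wls.params[1], rel=1e-9)
            assert est.intercept_se_ == pytest.approx(wls.bse[0], rel=1e-9)
            assert est.se_ == pytest.approx(wls.bse[1], rel=1e-9)
            assert est.pval_ == pytest.approx(wls.pvalues[1], rel=1e-9)

    def test_zero_intercept_reduces_to_ivw(self, rng):
        """Forcing the intercept to zero reproduces IVW — checked numerically
        via the zero-intercept WLS identity on an oriented panel."""
        bx, sx, by, sy, _ = random_panel(rng, k=20)
        bx = np.abs(bx)
        ivw_beta = IVWEstimator().fit(bx, by, sy).beta_
        wls0 = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        assert ivw_beta == pytest.approx(wls0.params[0], rel=1e-12)

    def test_recovers_directional_pleiotropy_mean(self, rng):
        """With every SNP carrying a pleiotropic offset ~N(0.05, 0.01²), the
        mean intercept estimate over replicates approaches 0.05."""
        intercepts = []
        for _ in range(400):
            bx, sx, by, sy, gamma = random_panel(rng, k=25, theta=0.2)
            by = by + rng.normal(0.05, 0.01, size=25) * np.sign(bx)
            est = EggerEstimator().fit(bx, by, sy)
            intercepts.append(est.intercept_)
        mean = np.mean(intercepts)
        mc_se = np.std(intercepts) / np.sqrt(len(intercepts))
        assert abs(mean - 0.05) < 4 * mc_se + 1.5e-3

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(mk_hset([1.0, 1.0], [0.1, 0.2], [0.1, 0.1]))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        res = weighted_median(mk_hset([1, 1, 1], [0.4, 0.5, 0.6], [1, 1, 1]), n_boot=50)
        assert res.beta_hat == pytest.approx(0.5)

    def test_hand_evaluated_interpolation(self):
        # ratios (0.1, 0.2, 0.6), weights (1, 2, 1) via se_out = 1/sqrt(w):
        # cumulative standardized weights (0.125, 0.5, 0.875) → exactly 0.2
        h = mk_hset([1, 1, 1], [0.1, 0.2, 0.6], [1.0, 1 / np.sqrt(2), 1.0])
        assert weighted_median(h, n_boot=0).beta_hat == pytest.approx(0.2)

    def test_dominant_weight_returns_that_ratio(self):
        # one SNP holding 97% of the weight pins the interpolated median
        w = np.array([0.015, 0.97, 0.015])
        h = mk_hset([1, 1, 1], [0.0, 0.5, 1.0], 1 / np.sqrt(w))
        est = weighted_median(h, n_boot=0).beta_hat
        assert abs(est - 0.5) < 0.05 * 0.5  # within 5% of the neighbour gap

    def test_robust_to_forty_percent_invalid(self, rng):
        """Directional pleiotropy on 40% of instruments biases IVW more than
        the weighted median (spot check; the full 500-rep comparison lives
        in the acceptance suite)."""
        wins = 0
        for _ in range(60):
            bx, sx, by, sy, gamma = random_panel(rng, k=30, theta=0.2)
            bad = rng.choice(30, size=12, replace=False)
            by[bad] += 0.2 * np.sign(bx[bad])
            h = mk_hset(bx, by, sy, se_exp=sx)
            wm = weighted_median(h, n_boot=0).beta_hat
            iv = ivw(h).beta_hat
            wins += abs(wm - 0.2) < abs(iv - 0.2)
        assert wins >= 54

    def test_bootstrap_se_is_seed_reproducible(self):
        h = mk_hset([0.1, 0.2, 0.3, 0.15], [0.03, 0.07, 0.05, 0.04], [0.01, 0.02, 0.01, 0.015])
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se_hat == b.se_hat and a.se_hat > 0


class TestOddsScale:
    def test_null_effect(self):
        or_hat, lo, hi, p = to_odds_scale(0.0, 0.1)
        assert or_hat == 1.0 and lo * hi == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_printed_reverse_mr_presentation(self):
        """(beta, se) inverted from a printed OR/CI reproduce OR 0.957 and
        CI (0.930, 0.985) at the printed precision."""
        or_hat, lo, hi, p = to_odds_scale(-0.043842, 0.014658)
        assert round(or_hat, 3) == 0.957
        assert round(lo, 3) == 0.930 and round(hi, 3) == 0.985

    @given(st.floats(-2, 2), st.floats(0.001, 1))
    def test_or_is_geometric_mean_of_ci(self, beta, se):
        or_hat, lo, hi, _ = to_odds_scale(beta, se)
        assert np.sqrt(lo * hi) == pytest.approx(or_hat, rel=1e-9)


class TestEstimatorProperties:
    def test_sign_equivariance(self, rng):
        bx, sx, by, sy, _ = random_panel(rng, k=12)
        h_pos = mk_hset(bx, by, sy, se_exp=sx)
        h_neg = mk_hset(-bx, by, sy, se_exp=sx)
        assert ivw(h_neg).beta_hat == pytest.approx(-ivw(h_pos).beta_hat, rel=1e-12)
        assert weighted_median(h_neg, n_boot=0).beta_hat == pytest.approx(
            -weighted_median(h_pos, n_boot=0).beta_hat, rel=1e-12)
        # Egger orients exposure betas non-negative, so global negation of the
        # exposure flips the oriented outcome and negates both coefficients
        a, ia = egger(h_pos)
        b, ib = egger(h_neg)
        assert a.beta_hat == pytest.approx(-b.beta_hat, rel=1e-12)
        assert ia.intercept == pytest.approx(-ib.intercept, rel=1e-12)

    def test_egger_invariant_under_per_snp_sign_flips(self, rng):
        bx, sx, by, sy, _ = random_panel(rng, k=15)
        flip = rng.choice([-1.0, 1.0], size=15)
        r1, i1 = egger(mk_hset(bx, by, sy))
        r2, i2 = egger(mk_hset(bx * flip, by * flip, sy))
        assert r1.beta_hat == pytest.approx(r2.beta_hat, rel=1e-12)
        assert i1.intercept == pytest.approx(i2.intercept, rel=1e-12)

    def test_ci_coverage_on_clean_panels(self, rng):
        """95% CIs of all three estimators cover the simulated truth in at
        least 90% of replicates on homogeneous strong-instrument panels."""
        theta = 0.3
        cover = {"ivw": 0, "egger": 0, "wm": 0}
        n_rep = 500
        for _ in range(n_rep):
            bx, sx, by, sy, _ = random_panel(rng, k=20, theta=theta)
            h = mk_hset(bx, by, sy, se_exp=sx)
            r_ivw = ivw(h)
            r_egger, _i = egger(h)
            r_wm = weighted_median(h, n_boot=60, seed=int(rng.integers(2**31)))
            for name, r in (("ivw", r_ivw), ("egger", r_egger), ("wm", r_wm)):
                lo, hi = r.beta_hat - 1.959964 * r.se_hat, r.beta_hat + 1.959964 * r.se_hat
                cover[name] += lo <= theta <= hi
        for name, c in cover.items():
            assert c / n_rep >= 0.90, (name, c / n_rep)

    def test_sklearn_protocol(self):
        est = WeightedMedianEstimator(n_boot=10, seed=3)
        assert est.get_params() == {"n_boot": 10, "seed": 3}
        est2 = clone(est).set_params(n_boot=20)
        assert est2.n_boot == 20
        fitted = IVWEstimator().fit([0.1, 0.2], [0.03, 0.05], [0.01, 0.01])
        pred = fitted.predict([0.1, 0.2])
        assert pred == pytest.approx(fitted.beta_ * np.array([0.1, 0.2]))
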