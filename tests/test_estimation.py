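"""Weighted nonlinear least-squares estimation of the cessation rate."""

import numpy as np
import pytest

from quitkinetics import PeriodRates, PrevalencePoint, fit_all, fit_period, prevalence_at
from quitkinetics.estimation import PeriodInputs


def make_series(pi0, rates, years=None, se=0.0025, noise=None, rng=None):
    years = years or list(range(rates.period_start, rates.period_end + 1))
    pts = []
    for y in years:
        tru = prevalence_at(pi0, rates, float(y - rates.period_start))
        obs = tru if noise is None else float(np.clip(tru + rng.normal(0, noise), 0, 1))
        pts.append(PrevalencePoint(y, obs, se))
    return pts


TRUE = PeriodRates(0.0022, 0.045, 0.0083, 2014, 2019)


class TestFitPeriod:
    def test_exact_recovery_on_noiseless_data(self):
        pts = make_series(0.18, TRUE)
        est = fit_period(pts, TRUE.lambda_init, TRUE.mu_mort, period=(2014, 2019))
        assert est.theta_hat == pytest.approx(0.045, abs=1e-6)
        assert est.pi0_hat == pytest.approx(0.18, abs=1e-6)
        assert est.n_points == 6

    def test_optimum_beats_grid_search_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            theta = rng.uniform(0.01, 0.09)
            lam = rng.uniform(0.001, 0.006)
            mu = rng.uniform(0.005, 0.012)
            pi0 = rng.uniform(0.1, 0.3)
            rates = PeriodRates(lam, theta, mu, 2014, 2019)
            pts = make_series(pi0, rates, noise=0.0025, rng=rng)
            est = fit_period(pts, lam, mu, period=(2014, 2019))

            t = np.arange(6.0)
            y = np.array([p.pi for p in pts])
            w = 1.0 / np.array([p.se**2 for p in pts])

            def obj(p0, th):
                k = th + mu
                model = (p0 - lam / k) * np.exp(-k * t) + lam / k
                return np.sum(w * (y - model) ** 2)

            p0_grid = np.linspace(0.05, 0.4, 200)
            th_grid = np.linspace(1e-4, 0.2, 200)
            P0, TH = np.meshgrid(p0_grid, th_grid)
            K = TH + mu
            S = lam / K
            model = (P0[..., None] - S[..., None]) * np.exp(
                -K[..., None] * t
            ) + S[..., None]
            grid_min = np.min(np.sum(w * (y - model) ** 2, axis=-1))
            assert obj(est.pi0_hat, est.theta_hat) <= grid_min + 1e-12

    def test_point_estimate_invariant_to_weight_scaling(self):
        rng = np.random.default_rng(4)
        pts = make_series(0.2, TRUE, noise=0.003, rng=rng)
        scaled = [
            PrevalencePoint(p.year, p.pi, p.se * 7.5) for p in pts
        ]
        a = fit_period(pts, TRUE.lambda_init, TRUE.mu_mort, period=(2014, 2019))
        b = fit_period(scaled, TRUE.lambda_init, TRUE.mu_mort, period=(2014, 2019))
        assert a.theta_hat == pytest.approx(b.theta_hat, abs=1e-9)
        assert a.pi0_hat == pytest.approx(b.pi0_hat, abs=1e-9)

    def test_interpolates_two_distinct_noiseless_points_exactly(self):
        # two free parameters; duplicated exact observations at two times
        rates = PeriodRates(0.003, 0.06, 0.008, 2014, 2019)
        y0 = prevalence_at(0.22, rates, 0.0)
        y5 = prevalence_at(0.22, rates, 5.0)
        pts = [
            PrevalencePoint(2014, y0, 0.002),
            PrevalencePoint(2014, y0, 0.002),
            PrevalencePoint(2019, y5, 0.002),
            PrevalencePoint(2019, y5, 0.002),
        ]
        # duplicate years are fine here: fit_period takes the series as given
        est = fit_period(pts, 0.003, 0.008, period=(2014, 2019))
        fitted = PeriodRates(0.003, est.theta_hat, 0.008, 2014, 2019)
        assert prevalence_at(est.pi0_hat, fitted, 0.0) == pytest.approx(y0, abs=1e-8)
        assert prevalence_at(est.pi0_hat, fitted, 5.0) == pytest.approx(y5, abs=1e-8)

    def test_missing_year_fit_uses_remaining_points(self):
        pts = make_series(0.18, TRUE)
        pts[-1] = PrevalencePoint(2019, pts[-1].pi, pts[-1].se, missing=True)
        est = fit_period(pts, TRUE.lambda_init, TRUE.mu_mort, period=(2014, 2019))
        assert est.n_points == 5
        assert est.theta_hat == pytest.approx(0.045, abs=1e-6)

    def test_pinned_anchor_option(self):
        pts = make_series(0.18, TRUE)
        est = fit_period(
            pts, TRUE.lambda_init, TRUE.mu_mort, period=(2014, 2019), pin_pi0=True
        )
        assert est.pi0_hat == pts[0].pi
        assert est.theta_hat == pytest.approx(0.045, abs=1e-6)

    def test_bootstrap_ci_is_seeded_and_reproducible(self):
        rng = np.random.default_rng(8)
        pts = make_series(0.18, TRUE, noise=0.0025, rng=rng)
        kw = dict(period=(2014, 2019), ci_method="bootstrap", n_boot=200, seed=99)
        a = fit_period(pts, TRUE.lambda_init, TRUE.mu_mort, **kw)
        b = fit_period(pts, TRUE.lambda_init, TRUE.mu_mort, **kw)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.theta_hat <= a.ci_high

    def test_uniform_weights_used_when_ses_absent(self):
        pts = [
            PrevalencePoint(p.year, p.pi, None) for p in make_series(0.18, TRUE)
        ]
        est = fit_period(pts, TRUE.lambda_init, TRUE.mu_mort, period=(2014, 2019))
        assert est.theta_hat == pytest.approx(0.045, abs=1e-6)
        with pytest.raises(ValueError, match="inverse-variance"):
            fit_period(
                pts, TRUE.lambda_init, TRUE.mu_mort,
                period=(2014, 2019), weights="inverse_variance",
            )

    def test_too_few_points_rejected(self):
        pts = make_series(0.18, TRUE)[:3]
        with pytest.raises(ValueError, match="at least 4"):
            fit_period(pts, TRUE.lambda_init, TRUE.mu_mort)
        missing = [
            PrevalencePoint(p.year, p.pi, p.se, missing=True)
            for p in make_series(0.18, TRUE)
        ]
        with pytest.raises(ValueError, match="missing"):
            fit_period(missing, TRUE.lambda_init, TRUE.mu_mort)


class TestFitAll:
    def test_single_period_matches_fit_period(self):
        pts = make_series(0.18, TRUE)
        one = fit_period(
            pts, TRUE.lambda_init, TRUE.mu_mort, survey="nhis", period=(2014, 2019)
        )
        table = [PeriodInputs("nhis", 2014, 2019, TRUE.lambda_init, TRUE.mu_mort)]
        many = fit_all({"nhis": pts}, table)
        assert len(many) == 1
        assert many[0].theta_hat == one.theta_hat
        assert many[0].survey == "nhis"

    def test_two_surveys_give_one_estimate_per_cell(self, study_like_estimates):
        surveys = {e.survey for e in study_like_estimates}
        assert surveys == {"nhis", "nsduh"}
        assert len(study_like_estimates) == 8  # 5 NHIS + 3 NSDUH periods
        nhis_last = next(
            e for e in study_like_estimates
            if e.survey == "nhis" and e.period == (2014, 2019)
        )
        assert nhis_last.n_points == 5  # 2019 unusable in the NHIS-like survey

    def test_estimates_track_rising_truth_at_low_noise(self):
        rng = np.random.default_rng(13)
        thetas = [0.024, 0.034, 0.044, 0.054, 0.064]
        pi = 0.26
        series, table = [], []
        for i, th in enumerate(thetas):
            rates = PeriodRates(0.003, th, 0.008, 1990 + 6 * i, 1995 + 6 * i)
            series += make_series(pi, rates, se=0.0002, noise=0.0002, rng=rng)
            pi = prevalence_at(pi, rates, 6.0)
            table.append(
                PeriodInputs("nhis", rates.period_start, rates.period_end, 0.003, 0.008)
            )
        ests = fit_all({"nhis": series}, table)
        fitted = [e.theta_hat for e in ests]
        assert fitted == sorted(fitted)

    def test_overlapping_periods_rejected(self):
        pts = make_series(0.18, TRUE)
        table = [
            PeriodInputs("nhis", 2008, 2013, 0.003, 0.008),
            PeriodInputs("nhis", 2013, 2018, 0.003, 0.008),
        ]
        with pytest.raises(ValueError, match="overlap"):
            fit_all({"nhis": pts}, table)

    def test_estimate_invariants_hold(self, study_like_estimates):
        for e in study_like_estimates:
            assert e.ci_low <= e.theta_hat <= e.ci_high
            assert e.se > 0
            assert e.n_points >= 4
            assert 0 <= e.theta_hat < 1
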