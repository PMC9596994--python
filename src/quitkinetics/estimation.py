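"""Period-wise cessation-rate estimation by weighted nonlinear least squares.

Within one analysis period the initiation rate ``lambda`` and smoker
mortality ``mu`` are treated as known inputs, and the cessation rate
``theta`` together with the anchor prevalence ``pi(0)`` are estimated by
minimising the weighted squared deviation between observed annual prevalence
and the closed-form relaxation curve.  Weights are the inverse survey
sampling variances when standard errors are available (uniform otherwise),
so the asymptotic covariance of the estimator follows directly from the
weighted Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .model import PrevalencePoint

__all__ = [
    "CessationEstimate",
    "PeriodInputs",
    "fit_period",
    "fit_all",
    "DEFAULT_THETA_STARTS",
]

Z_95 = 1.959964  # two-sided 95% normal quantile

#: Multi-start grid for theta, guarding against local minima.
DEFAULT_THETA_STARTS: Tuple[float, ...] = (0.01, 0.03, 0.05, 0.10)


@dataclass
class CessationEstimate:
    """A fitted per-period, per-survey cessation rate with 95% CI.

    Rates are proportions per year internally; multiply by 100 for the
    percent scale used in reports.
    """

    survey: str
    period: Tuple[int, int]
    theta_hat: float
    ci_low: float
    ci_high: float
    se: float
    pi0_hat: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.theta_hat <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.n_points < 4:
            raise ValueError("at least 4 observations required per period")


@dataclass(frozen=True)
class PeriodInputs:
    """One row of the estimation plan: fixed inputs for a (survey, period) cell."""

    survey: str
    period_start: int
    period_end: int
    lambda_init: float
    mu_mort: float


def _model_curve(t: np.ndarray, pi0: float, theta: float, lam: float, mu: float) -> np.ndarray:
    k = theta + mu
    s = lam / k
    return (pi0 - s) * np.exp(-k * t) + s


def _model_jac(t: np.ndarray, pi0: float, theta: float, lam: float, mu: float) -> np.ndarray:
    k = theta + mu
    s = lam / k
    e = np.exp(-k * t)
    d_pi0 = e
    ds = -lam / k**2
    d_theta = ds * (1.0 - e) - (pi0 - s) * t * e
    return np.column_stack([d_pi0, d_theta])


def _usable(points: Sequence[PrevalencePoint]) -> list:
    return [p for p in points if not p.missing]


def fit_period(
    series: Sequence[PrevalencePoint],
    lambda_init: float,
    mu_mort: float,
    *,
    survey: str = "",
    period: Optional[Tuple[int, int]] = None,
    weights: str = "auto",
    pin_pi0: bool = False,
    ci_method: str = "wald",
    n_boot: int = 1000,
    seed: Optional[int] = None,
    theta_starts: Sequence[float] = DEFAULT_THETA_STARTS,
) -> CessationEstimate:
    """Fit (pi0, theta) for one period by weighted nonlinear least squares.

    Parameters
    ----------
    series
        Annual observations inside the period; points flagged missing are
        ignored.  At least 4 usable points are required.
    lambda_init, mu_mort
        Fixed initiation and mortality rates for the period (proportion/yr).
    period
        ``(start, end)`` calendar years; inferred from the data if omitted.
        Time is measured in integer years from the period start.
    weights
        ``"inverse_variance"`` (requires SEs on every point), ``"uniform"``,
        or ``"auto"`` (inverse variance when all SEs are present).
    pin_pi0
        Fix the anchor prevalence to the first usable observation instead of
        estimating it jointly.
    ci_method
        ``"wald"`` (asymptotic, from the weighted Jacobian) or
        ``"bootstrap"`` (parametric, percentile, ``n_boot`` draws, seeded).
    theta_starts
        Multi-start grid for theta; the best converged fit wins.
    """
    pts = _usable(series)
    if not pts:
        raise ValueError("all observations missing")
    if len(pts) < 4:
        raise ValueError(f"only {len(pts)} usable points; need at least 4")
    if period is None:
        period = (min(p.year for p in pts), max(p.year for p in pts))
    start, end = period

    t = np.array([float(p.year - start) for p in pts])
    y = np.array([p.pi for p in pts])
    ses = [p.se for p in pts]
    have_ses = all(s is not None and s > 0 for s in ses)
    if weights == "auto":
        weights = "inverse_variance" if have_ses else "uniform"
    if weights == "inverse_variance":
        if not have_ses:
            raise ValueError("inverse-variance weights need a positive SE on every point")
        w = 1.0 / np.array([s**2 for s in ses])
        known_var = True
    elif weights == "uniform":
        w = np.ones_like(y)
        known_var = False
    else:
        raise ValueError(f"unknown weights mode {weights!r}")
    sw = np.sqrt(w)

    lam, mu = float(lambda_init), float(mu_mort)
    theta_lo = 1e-10 if mu == 0.0 else 0.0  # keep theta+mu > 0
    theta_hi = 1.0 - 1e-9
    pi0_start = float(np.clip(y[0], 1e-6, 1 - 1e-6))

    def run_fit(yy: np.ndarray):
        best = None
        if pin_pi0:
            pi0_fixed = float(yy[0])

            def resid(x):
                return sw * (yy - _model_curve(t, pi0_fixed, x[0], lam, mu))

            def jac(x):
                return -sw[:, None] * _model_jac(t, pi0_fixed, x[0], lam, mu)[:, 1:2]

            for th0 in theta_starts:
                res = least_squares(
                    resid, [th0], jac=jac, bounds=([theta_lo], [theta_hi]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                if res.success and (best is None or res.cost < best.cost):
                    best = res
            if best is None:
                raise RuntimeError("cessation-rate fit failed to converge (pinned pi0)")
            return pi0_fixed, float(best.x[0]), best

        def resid(x):
            return sw * (yy - _model_curve(t, x[0], x[1], lam, mu))

        def jac(x):
            return -sw[:, None] * _model_jac(t, x[0], x[1], lam, mu)

        for th0 in theta_starts:
            res = least_squares(
                resid, [pi0_start, th0], jac=jac,
                bounds=([0.0, theta_lo], [1.0, theta_hi]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise RuntimeError(
                "cessation-rate fit failed to converge from all starts "
                f"(theta starts {tuple(theta_starts)})"
            )
        return float(best.x[0]), float(best.x[1]), best

    pi0_hat, theta_hat, best = run_fit(y)

    # Asymptotic covariance from the weighted Jacobian at the optimum.
    J = best.jac if not pin_pi0 else (
        sw[:, None] * _model_jac(t, pi0_hat, theta_hat, lam, mu)[:, 1:2]
    )
    JtJ = J.T @ J
    try:
        cov = np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JtJ)
    if not known_var:
        dof = max(1, len(y) - (1 if pin_pi0 else 2))
        cov = cov * (2.0 * best.cost / dof)
    se_theta = float(math.sqrt(max(cov[-1, -1], 1e-30)))

    if ci_method == "wald":
        lo, hi = theta_hat - Z_95 * se_theta, theta_hat + Z_95 * se_theta
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        sig = (
            np.array([s for s in ses], float)
            if known_var
            else np.full_like(y, math.sqrt(2.0 * best.cost / max(1, len(y) - 2)))
        )
        fitted = _model_curve(t, pi0_hat, theta_hat, lam, mu)
        draws = []
        for _ in range(n_boot):
            yy = np.clip(fitted + rng.normal(0.0, sig), 0.0, 1.0)
            try:
                _, th_b, _ = run_fit(yy)
            except RuntimeError:
                continue
            draws.append(th_b)
        if len(draws) < max(10, n_boot // 2):
            raise RuntimeError("bootstrap failed on most replicates")
        lo, hi = np.percentile(draws, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return CessationEstimate(
        survey=survey,
        period=(start, end),
        theta_hat=theta_hat,
        ci_low=float(min(lo, theta_hat)),
        ci_high=float(max(hi, theta_hat)),
        se=se_theta,
        pi0_hat=pi0_hat,
        n_points=len(pts),
    )


def fit_all(
    series: Union[Mapping[str, Sequence[PrevalencePoint]], Sequence[PrevalencePoint]],
    period_table: Sequence[Union[PeriodInputs, tuple]],
    **fit_kwargs,
) -> list:
    """Fit every (survey, period) cell of an estimation plan.

    ``series`` is either a mapping of survey label to annual observations or
    a single flat sequence (used for every row).  ``period_table`` rows are
    :class:`PeriodInputs` (or ``(survey, (start, end), lambda, mu)`` tuples);
    periods of a survey must not overlap.  Extra keyword arguments pass
    through to :func:`fit_period`.
    """
    rows = []
    for r in period_table:
        if isinstance(r, PeriodInputs):
            rows.append(r)
        else:
            survey, (start, end), lam, mu = r
            rows.append(PeriodInputs(survey, int(start), int(end), float(lam), float(mu)))

    by_survey: dict = {}
    for r in rows:
        by_survey.setdefault(r.survey, []).append(r)
    for survey, rs in by_survey.items():
        rs = sorted(rs, key=lambda q: q.period_start)
        for a, b in zip(rs, rs[1:]):
            if b.period_start <= a.period_end:
                raise ValueError(
                    f"overlapping periods for survey {survey!r}: "
                    f"{a.period_start}-{a.period_end} and {b.period_start}-{b.period_end}"
                )

    out = []
    for r in rows:
        pts = series[r.survey] if isinstance(series, Mapping) else series
        window = [p for p in pts if r.period_start <= p.year <= r.period_end]
        out.append(
            fit_period(
                window,
                r.lambda_init,
                r.mu_mort,
                survey=r.survey,
                period=(r.period_start, r.period_end),
                **fit_kwargs,
            )
        )
    return out
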