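"""Random-effects meta-regression of period cessation-rate estimates.

The per-period, per-survey cessation estimates are aggregated in a classical
random-effects meta-regression: each estimate ``y_i`` (percent/year) is
modelled as Gaussian with mean

    b0 + b1 * I_nsduh + b2 * t + b3 * I_last_period

and variance ``v_i + tau2``, where ``v_i`` is the within-estimate sampling
variance (recovered from the reported 95% CI) and ``tau2`` a shared
between-estimate heterogeneity variance.  The model is fit by maximum
likelihood: for fixed ``tau2`` the coefficients have the closed-form GLS
solution, and the profiled marginal likelihood is maximised over
``tau2 >= 0``.  Inference is Wald with a normal reference.  The survey term
can be dropped (the reduced model), and the time index can run in analysis
periods or in calendar years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "MetaPoint",
    "MetaRegressionFit",
    "TrendDeparture",
    "se_from_ci",
    "fit_meta",
    "trend_departure_test",
    "meta_points_from_estimates",
]

Z_95 = 1.959964

#: Years per analysis period, used by the ``t_scale="year"`` convention.
PERIOD_LENGTH_YEARS = 6


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a normal 95% CI: half-width / 1.959964."""
    width = ci_high - ci_low
    if width <= 0:
        raise ValueError(f"CI ({ci_low}, {ci_high}) has non-positive width")
    return width / (2.0 * Z_95)


@dataclass(frozen=True)
class MetaPoint:
    """One aggregated estimate entering the meta-regression (percent scale)."""

    theta_hat: float            # percent per year
    variance: float             # percent^2, within-estimate sampling variance
    t_index: int                # sequential period index (1-based)
    is_nsduh: int               # 1 = NSDUH-like survey, 0 = NHIS-like
    is_last_period: int         # 1 = final analysis period
    survey: str = ""
    period: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.is_nsduh not in (0, 1) or self.is_last_period not in (0, 1):
            raise ValueError("indicators must be 0 or 1")


@dataclass
class MetaRegressionFit:
    """ML fit of the random-effects meta-regression."""

    names: List[str]
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    tau2: float
    loglik: float
    n_points: int
    include_survey_term: bool
    t_scale: str
    tau2_fixed: bool = False
    _by_name: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {n: i for i, n in enumerate(self.names)}

    def coef(self, name: str) -> float:
        return float(self.beta[self._by_name[name]])

    def _get(self, name, arr):
        i = self._by_name.get(name)
        return None if i is None else float(arr[i])

    @property
    def beta0(self):
        return self.coef("intercept")

    @property
    def beta1(self):
        return self._get("nsduh", self.beta)

    @property
    def beta2(self):
        return self.coef("t")

    @property
    def beta3(self):
        return self.coef("last_period")

    def summary(self) -> str:
        lines = [
            f"Random-effects meta-regression (ML), n={self.n_points}, "
            f"t in {self.t_scale}s, tau^2={self.tau2:.4g}, loglik={self.loglik:.4f}"
        ]
        for i, n in enumerate(self.names):
            lines.append(
                f"  {n:<12} {self.beta[i]:8.4f}  se {self.se[i]:.4f}  "
                f"95% CI ({self.ci_low[i]:.4f}, {self.ci_high[i]:.4f})  "
                f"p={self.p_values[i]:.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                n: {
                    "estimate": float(self.beta[i]),
                    "se": float(self.se[i]),
                    "ci_low": float(self.ci_low[i]),
                    "ci_high": float(self.ci_high[i]),
                    "p_value": float(self.p_values[i]),
                }
                for i, n in enumerate(self.names)
            },
            "tau2": self.tau2,
            "loglik": self.loglik,
            "n_points": self.n_points,
            "include_survey_term": self.include_survey_term,
            "t_scale": self.t_scale,
        }


def _design(points: Sequence[MetaPoint], include_survey_term: bool, t_scale: str):
    if t_scale == "period":
        t = np.array([p.t_index for p in points], float)
    elif t_scale == "year":
        t = np.array([(p.t_index - 1) * PERIOD_LENGTH_YEARS for p in points], float)
    else:
        raise ValueError(f"unknown t_scale {t_scale!r}; use 'period' or 'year'")
    cols = [np.ones(len(points))]
    names = ["intercept"]
    if include_survey_term:
        cols.append(np.array([p.is_nsduh for p in points], float))
        names.append("nsduh")
    cols.append(t)
    names.append("t")
    cols.append(np.array([p.is_last_period for p in points], float))
    names.append("last_period")
    return np.column_stack(cols), names


def _gls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    Xw = X * w[:, None]
    A = X.T @ Xw
    cov = np.linalg.inv(A)
    beta = cov @ (Xw.T @ y)
    return beta, cov


def _neg_loglik(tau2: float, X, y, v) -> float:
    var = v + tau2
    w = 1.0 / var
    beta, _ = _gls(X, y, w)
    r = y - X @ beta
    return 0.5 * (np.sum(np.log(2.0 * np.pi * var)) + np.sum(w * r * r))


def fit_meta(
    points: Sequence[MetaPoint],
    include_survey_term: bool = True,
    *,
    t_scale: str = "period",
    tau2: Optional[float] = None,
) -> MetaRegressionFit:
    """Fit the meta-regression by maximum likelihood.

    Parameters
    ----------
    points
        At least 5 aggregated estimates with positive variances.
    include_survey_term
        Include the survey-source indicator; ``False`` gives the reduced
        model without it.
    t_scale
        ``"period"``: t is the sequential period index (the convention the
        aggregated fits use); ``"year"``: t counts calendar years from the
        first period, i.e. 6 years per index step.
    tau2
        Fix the heterogeneity variance at a value instead of estimating it
        (``0.0`` recovers weighted least squares with known variances).
    """
    points = list(points)
    if len(points) < 5:
        raise ValueError(f"need at least 5 points, got {len(points)}")
    X, names = _design(points, include_survey_term, t_scale)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    y = np.array([p.theta_hat for p in points], float)
    v = np.array([p.variance for p in points], float)

    if tau2 is None:
        hi = max(10.0 * float(np.var(y)), 10.0 * float(v.max()), 1.0)
        res = minimize_scalar(
            _neg_loglik, args=(X, y, v), bounds=(0.0, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        tau2_hat = float(res.x)
        # the bounded minimiser can hover just off the boundary; check it
        if _neg_loglik(0.0, X, y, v) <= res.fun:
            tau2_hat = 0.0
        fixed = False
    else:
        if tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        tau2_hat = float(tau2)
        fixed = True

    w = 1.0 / (v + tau2_hat)
    beta, cov = _gls(X, y, w)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    ll = -_neg_loglik(tau2_hat, X, y, v)
    return MetaRegressionFit(
        names=names,
        beta=beta,
        se=se,
        p_values=p,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        tau2=tau2_hat,
        loglik=float(ll),
        n_points=len(points),
        include_survey_term=include_survey_term,
        t_scale=t_scale,
        tau2_fixed=fixed,
    )


@dataclass(frozen=True)
class TrendDeparture:
    """Wald summary of the final-period above-trend coefficient."""

    estimate: float
    ci: Tuple[float, float]
    p: float


def trend_departure_test(fit: MetaRegressionFit) -> TrendDeparture:
    """Above-trend coefficient for the final period, with Wald CI and p-value.

    The significance decision (e.g. at alpha = 0.05) is left to the caller.
    """
    i = fit._by_name["last_period"]
    return TrendDeparture(
        estimate=float(fit.beta[i]),
        ci=(float(fit.ci_low[i]), float(fit.ci_high[i])),
        p=float(fit.p_values[i]),
    )


def meta_points_from_estimates(estimates, nsduh_labels=("nsduh",)) -> List[MetaPoint]:
    """Convert :class:`~quitkinetics.estimation.CessationEstimate` rows.

    Period indices are assigned by sorting the distinct calendar periods;
    the latest period is flagged as the above-trend indicator.  Variances
    come from the reported CIs (so Wald and bootstrap intervals are treated
    uniformly).  Estimates are converted to the percent scale.
    """
    periods = sorted({e.period for e in estimates})
    index = {p: i + 1 for i, p in enumerate(periods)}
    last = periods[-1]
    out = []
    for e in estimates:
        se_pct = se_from_ci(100.0 * e.ci_low, 100.0 * e.ci_high)
        out.append(
            MetaPoint(
                theta_hat=100.0 * e.theta_hat,
                variance=se_pct**2,
                t_index=index[e.period],
                is_nsduh=int(e.survey.lower() in nsduh_labels),
                is_last_period=int(e.period == last),
                survey=e.survey,
                period=e.period,
            )
        )
    return out
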