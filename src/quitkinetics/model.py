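"""Closed-form prevalence dynamics for a single-compartment smoking model.

Adult smoking prevalence :math:`\\pi(t)` evolves under three piecewise-constant
annual rates: initiation :math:`\\lambda` (new 18-year-old smokers as a
fraction of the whole adult population), permanent cessation :math:`\\theta`
(net of relapse), and smoker mortality :math:`\\mu`.  The balance equation

.. math:: \\frac{d\\pi}{dt} = \\lambda - (\\theta + \\mu)\\,\\pi

has the closed-form solution

.. math:: \\pi(t) = \\Big(\\pi(0) - \\frac{\\lambda}{\\theta+\\mu}\\Big)
          e^{-(\\theta+\\mu)t} + \\frac{\\lambda}{\\theta+\\mu},

an exponential relaxation toward the steady-state prevalence
:math:`\\lambda/(\\theta+\\mu)`.  This module evaluates that solution, chains
it across rate periods to project prevalence forward, and decomposes a
prevalence change into the parts attributable to cessation and initiation
changes via counterfactual rate swaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "PeriodRates",
    "PrevalencePoint",
    "Trajectory",
    "DecompositionResult",
    "prevalence_at",
    "steady_state",
    "project",
    "decompose",
]


@dataclass(frozen=True)
class PeriodRates:
    """Annual rates assumed constant over one analysis period.

    Parameters
    ----------
    lambda_init
        Initiation rate: 18-year-old smokers as a proportion of the entire
        adult population, per year.
    theta_cess
        Permanent cessation rate (net of relapse), per year.
    mu_mort
        Overall smoker death rate, per year.
    period_start, period_end
        Inclusive calendar years the rates apply to.  Analysis periods span
        6 years (occasionally 7).
    """

    lambda_init: float
    theta_cess: float
    mu_mort: float
    period_start: int
    period_end: int

    def __post_init__(self) -> None:
        for name in ("lambda_init", "theta_cess", "mu_mort"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1)")
        n_years = self.period_end - self.period_start + 1
        if n_years not in (6, 7):
            raise ValueError(
                f"period {self.period_start}-{self.period_end} spans {n_years} "
                "years; analysis periods must span 6 or 7"
            )

    @property
    def outflow(self) -> float:
        """Total per-capita smoker outflow rate, theta + mu."""
        return self.theta_cess + self.mu_mort

    @property
    def n_years(self) -> int:
        return self.period_end - self.period_start + 1

    def replace(self, **kw) -> "PeriodRates":
        d = dict(
            lambda_init=self.lambda_init,
            theta_cess=self.theta_cess,
            mu_mort=self.mu_mort,
            period_start=self.period_start,
            period_end=self.period_end,
        )
        d.update(kw)
        return PeriodRates(**d)


@dataclass
class PrevalencePoint:
    """One annual survey prevalence observation (proportion scale)."""

    year: int
    pi: float
    se: Optional[float] = None
    adjusted: bool = False  # True once the 1990-91 definition correction ran
    missing: bool = False   # excluded from fitting (e.g. incompatible survey year)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"prevalence {self.pi!r} outside [0, 1]")
        if self.se is not None and self.se < 0:
            raise ValueError(f"standard error {self.se!r} negative")


@dataclass
class Trajectory:
    """Annual prevalence path anchored at ``anchor_year``."""

    anchor_year: int
    pi0: float
    rates: Sequence[PeriodRates]
    values: dict = field(default_factory=dict)  # year -> proportion

    def __getitem__(self, year: int) -> float:
        return self.values[year]

    @property
    def years(self) -> list:
        return sorted(self.values)

    def to_frame(self):
        """Trajectory as a DataFrame with percent-scale prevalence."""
        import pandas as pd

        years = self.years
        return pd.DataFrame(
            {"year": years, "prevalence_pct": [100.0 * self.values[y] for y in years]}
        )


@dataclass
class DecompositionResult:
    """Attribution of a prevalence drop to cessation vs initiation changes.

    Percentage-point fields (``pp_*``, ``excess_drop``, ``total_drop``) are on
    the percent scale; ``baseline_pi_end`` / ``actual_pi_end`` are proportions;
    shares are fractions of the excess drop (``None`` when the excess drop is
    zero and the attribution is undefined).
    """

    baseline_pi_end: float
    actual_pi_end: float
    excess_drop: float
    total_drop: float
    pp_cessation: float
    pp_initiation: float
    share_cessation: Optional[float]
    share_initiation: Optional[float]
    share_recent: Optional[float]

    def to_dict(self) -> dict:
        return {
            "baseline_prevalence_end_pct": 100.0 * self.baseline_pi_end,
            "actual_prevalence_end_pct": 100.0 * self.actual_pi_end,
            "excess_drop_pp": self.excess_drop,
            "total_drop_pp": self.total_drop,
            "pp_cessation": self.pp_cessation,
            "pp_initiation": self.pp_initiation,
            "share_cessation": self.share_cessation,
            "share_initiation": self.share_initiation,
            "share_recent": self.share_recent,
        }


def prevalence_at(
    pi0: float,
    rates: PeriodRates,
    t: float,
    *,
    allow_degenerate: bool = False,
) -> float:
    """Prevalence ``t`` years after an anchor with prevalence ``pi0``.

    Evaluates the closed-form relaxation toward the steady state
    ``lambda/(theta+mu)``.  The degenerate case ``theta + mu == 0`` (pure
    linear growth ``pi0 + lambda*t``) is rejected unless ``allow_degenerate``
    is set, in which case the result is capped at 1.
    """
    if t < 0:
        raise ValueError(f"t={t} must be non-negative")
    k = rates.outflow
    if k == 0.0:
        if not allow_degenerate:
            raise ValueError(
                "theta + mu = 0: no relaxation; pass allow_degenerate=True "
                "for the linear-growth limit"
            )
        return min(1.0, pi0 + rates.lambda_init * t)
    ssp = rates.lambda_init / k
    pi = (pi0 - ssp) * math.exp(-k * t) + ssp
    # closed form cannot leave [0, 1] for admissible inputs; clip fp dust
    return min(1.0, max(0.0, pi))


def steady_state(rates: PeriodRates) -> float:
    """Long-run prevalence ``lambda/(theta+mu)`` under constant rates.

    This is the level at which initiation inflow balances the cessation and
    mortality outflow; ``prevalence_at`` converges to it as ``t -> inf``.
    """
    k = rates.outflow
    if k == 0.0:
        raise ValueError("theta + mu = 0: no steady state exists")
    ssp = rates.lambda_init / k
    if ssp > 1.0:
        raise ValueError(
            f"steady state {ssp:.4f} exceeds 1; lambda > theta + mu is inadmissible"
        )
    return ssp


def _validate_schedule(schedule: Sequence[PeriodRates]) -> None:
    for a, b in zip(schedule, schedule[1:]):
        if b.period_start != a.period_end + 1:
            kind = "overlap" if b.period_start <= a.period_end else "gap"
            raise ValueError(
                f"schedule {kind} between {a.period_start}-{a.period_end} and "
                f"{b.period_start}-{b.period_end}"
            )


def project(
    pi0: float,
    anchor_year: int,
    schedule: Sequence[PeriodRates],
    target_year: int,
    *,
    allow_degenerate: bool = False,
) -> Trajectory:
    """Chain the closed form across rate periods from anchor to target year.

    The schedule must be contiguous and non-overlapping and cover every year
    stepped through; the last period's rates extend indefinitely beyond its
    end.  The end value of each period is the anchor of the next, so the path
    is continuous and, within a period, identical to a single closed-form
    evaluation over the whole span.
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("empty rate schedule")
    _validate_schedule(schedule)
    if target_year < anchor_year:
        raise ValueError(f"target year {target_year} precedes anchor {anchor_year}")
    first, last = schedule[0], schedule[-1]
    if anchor_year + 1 < first.period_start:
        raise ValueError(
            f"schedule starts {first.period_start}, leaving years "
            f"{anchor_year + 1}-{first.period_start - 1} uncovered"
        )

    def rates_for(year: int) -> PeriodRates:
        if year > last.period_end:
            return last
        for p in schedule:
            if p.period_start <= year <= p.period_end:
                return p
        raise ValueError(f"year {year} not covered by the rate schedule")

    values = {anchor_year: pi0}
    pi = pi0
    for year in range(anchor_year + 1, target_year + 1):
        pi = prevalence_at(pi, rates_for(year), 1.0, allow_degenerate=allow_degenerate)
        values[year] = pi
    return Trajectory(anchor_year=anchor_year, pi0=pi0, rates=schedule, values=values)


def _end_prevalence(
    pi_start: float, lam: float, theta: float, mu: float, horizon: float
) -> float:
    r = PeriodRates(lam, theta, mu, 2000, 2005)  # span is irrelevant here
    return prevalence_at(pi_start, r, horizon)


def decompose(
    pi_start: float,
    start_year: int,
    old_rates: PeriodRates,
    new_rates: PeriodRates,
    horizon: float,
    *,
    attribution: str = "averaged",
) -> DecompositionResult:
    """Attribute the extra prevalence drop under new rates to its sources.

    Four counterfactual end-of-horizon prevalences are computed from
    ``pi_start``: (i) old initiation and old cessation, (ii) new initiation
    and new cessation, (iii) old initiation with new cessation, (iv) new
    initiation with old cessation.  The excess drop (i) - (ii) is split into
    a cessation part and an initiation part by one-at-a-time substitution.
    ``attribution`` selects the substitution order: ``"averaged"`` (default)
    averages both orders, which is symmetric and exactly additive;
    ``"cessation_first"`` / ``"initiation_first"`` are the fixed-order
    variants.  Mortality travels with the cessation rate, both being smoker
    outflow; with equal old and new mortality this reduces to holding mu
    fixed throughout.

    ``total_drop`` is the fall from ``pi_start`` to scenario (ii), and
    ``share_recent = excess_drop / total_drop`` is the fraction of that fall
    attributable to the rate changes rather than to momentum already in the
    system.  Shares are ``None`` when the excess drop is exactly zero.
    """
    if horizon <= 0:
        raise ValueError(f"horizon {horizon} must be positive")
    if attribution not in ("averaged", "cessation_first", "initiation_first"):
        raise ValueError(f"unknown attribution mode {attribution!r}")

    lam_o, th_o, mu_o = old_rates.lambda_init, old_rates.theta_cess, old_rates.mu_mort
    lam_n, th_n, mu_n = new_rates.lambda_init, new_rates.theta_cess, new_rates.mu_mort

    p_i = _end_prevalence(pi_start, lam_o, th_o, mu_o, horizon)     # old lam, old theta
    p_ii = _end_prevalence(pi_start, lam_n, th_n, mu_n, horizon)    # new lam, new theta
    p_iii = _end_prevalence(pi_start, lam_o, th_n, mu_n, horizon)   # old lam, new theta
    p_iv = _end_prevalence(pi_start, lam_n, th_o, mu_o, horizon)    # new lam, old theta

    excess = 100.0 * (p_i - p_ii)
    if attribution == "averaged":
        pp_cess = 100.0 * 0.5 * ((p_i - p_iii) + (p_iv - p_ii))
        pp_init = 100.0 * 0.5 * ((p_i - p_iv) + (p_iii - p_ii))
    elif attribution == "cessation_first":
        pp_cess = 100.0 * (p_i - p_iii)
        pp_init = 100.0 * (p_iii - p_ii)
    else:  # initiation_first
        pp_init = 100.0 * (p_i - p_iv)
        pp_cess = 100.0 * (p_iv - p_ii)

    total = 100.0 * (pi_start - p_ii)
    if excess == 0.0:
        share_c = share_i = share_recent = None
    else:
        share_c = pp_cess / excess
        share_i = pp_init / excess
        share_recent = excess / total if total != 0.0 else None

    return DecompositionResult(
        baseline_pi_end=p_i,
        actual_pi_end=p_ii,
        excess_drop=excess,
        total_drop=total,
        pp_cessation=pp_cess,
        pp_initiation=pp_init,
        share_cessation=share_c,
        share_initiation=share_i,
        share_recent=share_recent,
    )
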