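"""Synthetic survey data with known truth, for end-to-end testing.

The generator lays down a true prevalence trajectory from the compartmental
model under piecewise-constant period rates, then emulates the statistical
structure of the two national surveys it mimics: additive Gaussian sampling
noise with survey-specific standard errors, a constant level offset for the
survey whose current-smoker definition is broader (NSDUH-like series run
4.5-6 percentage points above NHIS-like ones), missing years, and the
NSDUH-like series starting only in 2002.  It also fabricates consistent
census counts (18-year-olds as a smooth fraction of adults, near 0.018) and
an age-gender-year mortality table whose population-weighted mean equals
each period's true smoker death rate exactly, so the input-preparation
stage can be exercised against known values.

:func:`published_cessation_estimates` returns the eight published
period-by-survey cessation-rate estimates (NHIS 1990-2019, NSDUH 2002-2019)
that the meta-regression reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import PeriodRates, PrevalencePoint, Trajectory, project
from .metareg import MetaPoint, se_from_ci

__all__ = [
    "SurveyDesign",
    "ScenarioSpec",
    "SyntheticData",
    "generate",
    "default_scenario",
    "published_cessation_estimates",
    "PUBLISHED_TABLE",
]


@dataclass(frozen=True)
class SurveyDesign:
    """How one survey observes the true trajectory.

    ``offset_pp`` is a constant level shift in percentage points (the
    definition-driven gap between surveys); ``se_pp`` the sampling standard
    error in percentage points; ``missing_years`` are omitted from the
    output; ``first_year``/``last_year`` clip the observed span.
    """

    label: str
    offset_pp: float = 0.0
    se_pp: float = 0.25
    missing_years: frozenset = frozenset()
    first_year: Optional[int] = None
    last_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.offset_pp < 0:
            raise ValueError("offset must be non-negative")
        if self.se_pp <= 0:
            raise ValueError("se must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete data-generating scenario: truth plus observation designs."""

    periods: Tuple[PeriodRates, ...]
    pi_start: float
    surveys: Tuple[SurveyDesign, ...]
    seed: int = 0
    census_ratio: float = 0.018
    n_adult_start: float = 185e6
    n_adult_growth: float = 2.2e6  # persons per year

    def __post_init__(self) -> None:
        for a, b in zip(self.periods, self.periods[1:]):
            if b.period_start != a.period_end + 1:
                raise ValueError(
                    f"periods not contiguous at {a.period_end}/{b.period_start}"
                )

    @property
    def years(self) -> range:
        return range(self.periods[0].period_start, self.periods[-1].period_end + 1)


@dataclass
class SyntheticData:
    """Generator output: observed series, auxiliary tables, and the truth."""

    prevalence: Dict[str, List[PrevalencePoint]]
    census: list                      # list of prep.CensusCounts
    mortality: pd.DataFrame
    prev18: Dict[str, Dict[int, float]]  # survey -> year -> 18-year-old prevalence
    truth: Trajectory
    spec: ScenarioSpec

    def write_inputs(self, outdir) -> dict:
        """Write the CSV inputs the preparation stage consumes; returns paths."""
        import os

        from .prep import write_prevalence_csv

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "prevalence": os.path.join(outdir, "prevalence.csv"),
            "census": os.path.join(outdir, "census.csv"),
            "mortality": os.path.join(outdir, "mortality.csv"),
            "prev18": os.path.join(outdir, "prev18.csv"),
            "truth": os.path.join(outdir, "truth.csv"),
        }
        write_prevalence_csv(self.prevalence, paths["prevalence"])
        pd.DataFrame(
            [{"year": c.year, "n_18": c.n_18, "n_adult": c.n_adult} for c in self.census]
        ).to_csv(paths["census"], index=False)
        self.mortality.to_csv(paths["mortality"], index=False)
        pd.DataFrame(
            [
                {"survey": label, "year": y, "prev18_pct": 100.0 * v}
                for label, by_year in self.prev18.items()
                for y, v in by_year.items()
            ]
        ).to_csv(paths["prev18"], index=False)
        self.truth.to_frame().to_csv(paths["truth"], index=False)
        return paths


def default_scenario(seed: int = 0) -> ScenarioSpec:
    """The study-like scenario: five 6-year periods, 1990-2019.

    True cessation rates rise 2.4% -> 5.4%/yr across periods with an
    above-trend final step, initiation falls 0.55% -> 0.22%/yr, and smoker
    mortality sits near 0.83%/yr.  An NHIS-like survey observes the
    trajectory directly (SE 0.25 pp, 1996 and 2019 missing); an NSDUH-like
    survey observes it from 2002 with a +5 pp definition offset (SE 0.2 pp).
    """
    thetas = (0.024, 0.034, 0.035, 0.042, 0.054)
    lambdas = (0.0055, 0.0050, 0.0045, 0.00355, 0.0022)
    mu = 0.0083
    periods = tuple(
        PeriodRates(lam, th, mu, 1990 + 6 * i, 1995 + 6 * i)
        for i, (lam, th) in enumerate(zip(lambdas, thetas))
    )
    surveys = (
        SurveyDesign(
            "nhis", offset_pp=0.0, se_pp=0.25, missing_years=frozenset({1996, 2019})
        ),
        SurveyDesign("nsduh", offset_pp=5.0, se_pp=0.20, first_year=2002),
    )
    return ScenarioSpec(periods=periods, pi_start=0.26, surveys=surveys, seed=seed)


def _make_census(spec: ScenarioSpec):
    from .prep import CensusCounts

    out = []
    for i, year in enumerate(spec.years):
        n_adult = spec.n_adult_start + spec.n_adult_growth * i
        # ratio drifts smoothly and deterministically around its centre
        ratio = spec.census_ratio * (1.0 + 0.02 * np.sin(2.0 * np.pi * i / 30.0))
        out.append(CensusCounts(year=year, n_18=ratio * n_adult, n_adult=n_adult))
    return out


#: Relative spread of stratum death rates around the period mean; the
#: symmetric pattern with equal populations keeps the weighted mean exact.
_STRATUM_FACTORS = (-0.6, -0.2, 0.2, 0.6)
_AGE_GROUPS = ("18-34", "35-54", "55-74", "75+")


def _make_mortality(spec: ScenarioSpec) -> pd.DataFrame:
    rows = []
    for p in spec.periods:
        for year in range(p.period_start, p.period_end + 1):
            for gender in ("female", "male"):
                for age, f in zip(_AGE_GROUPS, _STRATUM_FACTORS):
                    rows.append(
                        {
                            "age_group": age,
                            "gender": gender,
                            "year": year,
                            "death_rate": p.mu_mort * (1.0 + f),
                            "population": 1.0e6,
                        }
                    )
    return pd.DataFrame(rows)


def generate(spec: ScenarioSpec, seed: Optional[int] = None) -> SyntheticData:
    """Generate observed survey series plus census and mortality fixtures.

    One master seed (``seed`` argument, falling back to ``spec.seed``) drives
    everything; each survey draws its noise from an independently spawned
    child stream, so outputs are reproducible and surveys are uncorrelated.
    A warning is issued if clipping observed prevalence into [0, 1] touches
    more than 1% of draws (noise too large for the scenario).
    """
    master = spec.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(len(spec.surveys))

    truth = project(
        spec.pi_start,
        spec.periods[0].period_start,
        spec.periods,
        spec.periods[-1].period_end,
    )

    prevalence: Dict[str, List[PrevalencePoint]] = {}
    n_draws = n_clipped = 0
    for design, child in zip(spec.surveys, children):
        rng = np.random.default_rng(child)
        pts: List[PrevalencePoint] = []
        for year in spec.years:
            if design.first_year is not None and year < design.first_year:
                continue
            if design.last_year is not None and year > design.last_year:
                continue
            if year in design.missing_years:
                continue
            se = design.se_pp / 100.0
            raw = truth[year] + design.offset_pp / 100.0 + rng.normal(0.0, se)
            n_draws += 1
            obs = float(np.clip(raw, 0.0, 1.0))
            if obs != raw:
                n_clipped += 1
            pts.append(PrevalencePoint(year=year, pi=obs, se=se))
        prevalence[design.label] = pts

    if n_draws and n_clipped / n_draws > 0.01:
        warnings.warn(
            f"{n_clipped}/{n_draws} observations clipped to [0, 1]; "
            "noise too large for this scenario",
            RuntimeWarning,
            stacklevel=2,
        )

    census = _make_census(spec)
    ratio_by_year = {c.year: c.ratio for c in census}

    def period_for(year: int) -> PeriodRates:
        for p in spec.periods:
            if p.period_start <= year <= p.period_end:
                return p
        raise ValueError(f"year {year} outside scenario periods")

    # Survey-specific 18-year-old prevalence consistent with each observed
    # series: a series level-shifted by a constant c obeys the same dynamics
    # with initiation lambda + (theta+mu)*c, which is why the broader-
    # definition survey also reports a larger initiation rate.  Dividing by
    # the census ratio lets the preparation stage recover each period's
    # effective lambda exactly.
    prev18: Dict[str, Dict[int, float]] = {}
    for design in spec.surveys:
        by_year = {}
        for y in spec.years:
            p = period_for(y)
            lam_eff = p.lambda_init + p.outflow * design.offset_pp / 100.0
            by_year[y] = lam_eff / ratio_by_year[y]
        prev18[design.label] = by_year

    return SyntheticData(
        prevalence=prevalence,
        census=census,
        mortality=_make_mortality(spec),
        prev18=prev18,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Published period-by-survey cessation estimates (percent/year, 95% CIs)
# ---------------------------------------------------------------------------

#: (survey, period, theta_hat_pct, ci_low_pct, ci_high_pct)
PUBLISHED_TABLE: Tuple[Tuple[str, Tuple[int, int], float, float, float], ...] = (
    ("nhis", (1990, 1995), 2.4, 1.5, 3.3),
    ("nhis", (1996, 2001), 3.4, 3.1, 3.7),
    ("nhis", (2002, 2007), 3.5, 2.7, 4.3),
    ("nhis", (2008, 2013), 4.2, 3.5, 4.9),
    ("nhis", (2014, 2019), 5.4, 3.1, 7.6),
    ("nsduh", (2002, 2007), 3.2, 2.6, 3.8),
    ("nsduh", (2008, 2013), 4.2, 3.6, 4.8),
    ("nsduh", (2014, 2019), 5.6, 4.9, 6.3),
)

_PERIOD_INDEX = {
    (1990, 1995): 1,
    (1996, 2001): 2,
    (2002, 2007): 3,
    (2008, 2013): 4,
    (2014, 2019): 5,
}


def published_cessation_estimates() -> List[MetaPoint]:
    """The eight published cessation-rate estimates as meta-regression points.

    Five NHIS periods (1990-2019) and three NSDUH periods (2002-2019), on
    the percent scale, with variances recovered from the 95% CI half-widths.
    """
    out = []
    for survey, period, theta, lo, hi in PUBLISHED_TABLE:
        out.append(
            MetaPoint(
                theta_hat=theta,
                variance=se_from_ci(lo, hi) ** 2,
                t_index=_PERIOD_INDEX[period],
                is_nsduh=int(survey == "nsduh"),
                is_last_period=int(period == (2014, 2019)),
                survey=survey,
                period=period,
            )
        )
    return out
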