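"""Construction of the model's exogenous inputs from tabular data.

Three inputs surround the cessation-rate estimation: the initiation rate
(18-year-old smoking prevalence converted, via census counts, to new smokers
as a fraction of all adults), the overall smoker mortality rate (a
population-weighted mean of age-gender-year death-rate strata), and the
survey prevalence series themselves, which need survey-specific cleaning:
a +1 percentage-point correction where the current-smoker definition changed,
dropping years made incomparable by survey redesigns, and flagging
incompatible years as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import PeriodRates, PrevalencePoint

__all__ = [
    "CensusCounts",
    "MORTALITY_COLUMNS",
    "initiation_rate",
    "prev18_from_lambda",
    "overall_mortality",
    "clean_series",
    "read_prevalence_csv",
    "write_prevalence_csv",
    "read_census_csv",
    "read_mortality_csv",
    "build_period_rates",
]

#: Labels of the two emulated survey designs.
NHIS_LIKE = "nhis"
NSDUH_LIKE = "nsduh"

#: Required columns of a mortality table (one row per age-gender-year stratum).
MORTALITY_COLUMNS = ("age_group", "gender", "year", "death_rate", "population")


@dataclass(frozen=True)
class CensusCounts:
    """Census-style population counts for one year."""

    year: int
    n_18: float
    n_adult: float

    def __post_init__(self) -> None:
        if not (0 < self.n_18 < self.n_adult):
            raise ValueError(
                f"need 0 < n_18 ({self.n_18}) < n_adult ({self.n_adult})"
            )

    @property
    def ratio(self) -> float:
        return self.n_18 / self.n_adult


def initiation_rate(prev18: float, counts: CensusCounts) -> float:
    """Initiation rate: 18-year-old smokers as a fraction of all adults.

    ``prev18`` is the smoking prevalence of 18-year-olds; the number of
    18-year-old smokers is ``prev18 * n_18``, expressed as a proportion of the
    entire adult population.
    """
    if not (0.0 <= prev18 <= 1.0):
        raise ValueError(f"prev18={prev18!r} outside [0, 1]")
    return prev18 * counts.n_18 / counts.n_adult


def prev18_from_lambda(lambda_init: float, counts: CensusCounts) -> float:
    """Exact inverse of :func:`initiation_rate` (back to 18-year-old prevalence)."""
    if not (0.0 <= lambda_init <= 1.0):
        raise ValueError(f"lambda_init={lambda_init!r} outside [0, 1]")
    prev18 = lambda_init * counts.n_adult / counts.n_18
    if prev18 > 1.0:
        raise ValueError(
            f"implied 18-year-old prevalence {prev18:.4f} exceeds 1; "
            "initiation rate inconsistent with census counts"
        )
    return prev18


def overall_mortality(table: pd.DataFrame, year_range: Tuple[int, int]) -> float:
    """Population-weighted mean smoker death rate over all strata in a year range.

    ``table`` has one row per (age_group, gender, year) stratum with columns
    ``death_rate`` (proportion/year) and ``population``.  Both endpoints of
    ``year_range`` are inclusive.
    """
    missing = set(MORTALITY_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"mortality table lacks columns: {sorted(missing)}")
    y0, y1 = year_range
    sel = table[(table["year"] >= y0) & (table["year"] <= y1)]
    if sel.empty:
        raise ValueError(f"mortality table has no rows in {y0}-{y1}")
    rates = sel["death_rate"].to_numpy(float)
    pops = sel["population"].to_numpy(float)
    if (rates < 0).any() or (rates > 1).any():
        raise ValueError("death rates must lie in [0, 1]")
    if (pops <= 0).any():
        raise ValueError("populations must be positive")
    return float(np.average(rates, weights=pops))


def clean_series(
    raw: Sequence[PrevalencePoint], survey: str
) -> List[PrevalencePoint]:
    """Apply the survey-specific corrections and exclusions to a raw series.

    NHIS-like: the 1990 and 1991 estimates (collected under the older
    "smoke now" current-smoker definition) are raised by 1 percentage point
    and flagged ``adjusted``; 1996 (no data collected) and 2019 (survey
    redesign incompatible with earlier years) are flagged missing.
    NSDUH-like: years before 2002 are dropped (the 2002 redesign broke
    comparability).  Idempotent: a second pass changes nothing.
    """
    survey = survey.lower()
    if survey not in (NHIS_LIKE, NSDUH_LIKE):
        raise ValueError(f"unknown survey label {survey!r}")
    years = [p.year for p in raw]
    dupes = {y for y in years if years.count(y) > 1}
    if dupes:
        raise ValueError(f"duplicate years in series: {sorted(dupes)}")

    out: List[PrevalencePoint] = []
    for p in sorted(raw, key=lambda q: q.year):
        if survey == NSDUH_LIKE:
            if p.year < 2002:
                continue
            out.append(PrevalencePoint(p.year, p.pi, p.se, p.adjusted, p.missing))
            continue
        pi, adjusted = p.pi, p.adjusted
        if p.year in (1990, 1991) and not p.adjusted:
            pi, adjusted = min(1.0, p.pi + 0.01), True
        missing = p.missing or p.year in (1996, 2019)
        out.append(PrevalencePoint(p.year, pi, p.se, adjusted, missing))
    return out


# ---------------------------------------------------------------------------
# CSV I/O.  All prevalence-like columns are on the percent scale and suffixed
# _pct in files; proportions internally.
# ---------------------------------------------------------------------------

def read_prevalence_csv(path) -> Mapping[str, List[PrevalencePoint]]:
    """Read a prevalence CSV (survey, year, prevalence_pct[, se_pct])."""
    df = pd.read_csv(path)
    need = {"survey", "year", "prevalence_pct"}
    if not need <= set(df.columns):
        raise ValueError(f"prevalence CSV lacks columns: {sorted(need - set(df.columns))}")
    out: dict = {}
    for survey, grp in df.groupby("survey", sort=False):
        pts = []
        for row in grp.itertuples(index=False):
            se = getattr(row, "se_pct", None)
            se = None if se is None or pd.isna(se) else float(se) / 100.0
            missing = bool(getattr(row, "missing", False))
            pi = getattr(row, "prevalence_pct")
            if pd.isna(pi):
                continue
            pts.append(
                PrevalencePoint(
                    int(row.year),
                    float(pi) / 100.0,
                    se,
                    bool(getattr(row, "adjusted", False)),
                    missing,
                )
            )
        out[str(survey)] = sorted(pts, key=lambda p: p.year)
    return out


def write_prevalence_csv(series: Mapping[str, Sequence[PrevalencePoint]], path) -> None:
    rows = []
    for survey, pts in series.items():
        for p in pts:
            rows.append(
                {
                    "survey": survey,
                    "year": p.year,
                    "prevalence_pct": 100.0 * p.pi,
                    "se_pct": None if p.se is None else 100.0 * p.se,
                    "adjusted": p.adjusted,
                    "missing": p.missing,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_census_csv(path) -> List[CensusCounts]:
    df = pd.read_csv(path)
    need = {"year", "n_18", "n_adult"}
    if not need <= set(df.columns):
        raise ValueError(f"census CSV lacks columns: {sorted(need - set(df.columns))}")
    return [
        CensusCounts(int(r.year), float(r.n_18), float(r.n_adult))
        for r in df.itertuples(index=False)
    ]


def read_mortality_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MORTALITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mortality CSV lacks columns: {sorted(missing)}")
    return df


def build_period_rates(
    periods: Iterable[Tuple[int, int]],
    prev18_by_year: Mapping[int, float],
    census: Sequence[CensusCounts],
    mortality: pd.DataFrame,
) -> List[PeriodRates]:
    """Assemble per-period (lambda, mu) inputs from annual data.

    Period-level lambda is the simple mean of annual initiation rates within
    the period (the dynamics assume constant rates inside a period, so the
    annual values are averaged); mu is the population-weighted mortality over
    the period's years.  theta is left at 0 — it is the quantity later
    estimated from the prevalence series.
    """
    census_by_year = {c.year: c for c in census}
    out = []
    for start, end in periods:
        lams = []
        for year in range(start, end + 1):
            if year in prev18_by_year and year in census_by_year:
                lams.append(initiation_rate(prev18_by_year[year], census_by_year[year]))
        if not lams:
            raise ValueError(f"no initiation inputs for period {start}-{end}")
        mu = overall_mortality(mortality, (start, end))
        out.append(
            PeriodRates(
                lambda_init=float(np.mean(lams)),
                theta_cess=0.0,
                mu_mort=mu,
                period_start=start,
                period_end=end,
            )
        )
    return out
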