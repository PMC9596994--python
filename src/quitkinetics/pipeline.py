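"""Configuration and orchestration of the full analysis pipeline.

The pipeline mirrors the study design: clean the survey prevalence series
and assemble period-level initiation and mortality inputs (*prep*), estimate
the period cessation rates by weighted nonlinear least squares (*estimate*),
run the random-effects meta-regression for trend and above-trend departure
(*metareg*), and finally project prevalence forward and decompose the recent
prevalence drop into cessation- and initiation-driven parts
(*project*/*decompose*).  A :class:`RunConfig` (usually loaded from a YAML
file) names the input CSVs and options; :func:`run_pipeline` executes the
stages and writes ``estimates.csv``, ``fit.json``, ``trajectory.csv``,
``decomposition.json`` and a human-readable ``summary.txt``.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import pandas as pd
import yaml

from . import estimation, metareg, prep
from .model import PeriodRates, decompose, prevalence_at, project

__all__ = ["RunConfig", "run_pipeline", "load_config", "estimates_to_frame"]

log = logging.getLogger("quitkinetics")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``periods`` are ``(start, end)`` calendar-year pairs, contiguous and
    non-overlapping.  ``surveys`` maps each series label in the prevalence
    CSV to its cleaning kind (``nhis`` or ``nsduh``).  Options default to the
    analysis choices described in :mod:`quitkinetics` docs.
    """

    prevalence_csv: str
    census_csv: str
    mortality_csv: str
    prev18_csv: str
    outdir: str
    periods: List[Tuple[int, int]] = field(
        default_factory=lambda: [
            (1990, 1995), (1996, 2001), (2002, 2007), (2008, 2013), (2014, 2019)
        ]
    )
    surveys: dict = field(default_factory=lambda: {"nhis": "nhis", "nsduh": "nsduh"})
    reference_survey: str = "nhis"
    weights: str = "auto"
    ci_method: str = "wald"
    bootstrap_reps: int = 1000
    t_scale: str = "period"
    attribution: str = "averaged"
    projection_target: int = 2030
    seed: int = 0
    strict: bool = False

    def validate(self) -> None:
        for path_attr in ("prevalence_csv", "census_csv", "mortality_csv", "prev18_csv"):
            p = getattr(self, path_attr)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{path_attr}: {p}")
        ps = sorted(self.periods)
        for (a0, a1), (b0, b1) in zip(ps, ps[1:]):
            if b0 <= a1:
                raise ValueError(f"overlapping periods {a0}-{a1} and {b0}-{b1}")
            if b0 != a1 + 1:
                raise ValueError(f"gap between periods {a0}-{a1} and {b0}-{b1}")
        if self.reference_survey not in self.surveys:
            raise ValueError(f"reference survey {self.reference_survey!r} not in surveys")


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file (keys mirror the fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    inputs = raw.get("inputs", {})
    options = raw.get("options", {})
    cfg = RunConfig(
        prevalence_csv=inputs["prevalence"],
        census_csv=inputs["census"],
        mortality_csv=inputs["mortality"],
        prev18_csv=inputs["prev18"],
        outdir=raw.get("outdir", "out"),
        seed=int(raw.get("seed", 0)),
    )
    if "periods" in raw:
        cfg.periods = [(int(p["start"]), int(p["end"])) for p in raw["periods"]]
    if "surveys" in raw:
        cfg.surveys = {str(s["label"]): str(s.get("kind", s["label"])) for s in raw["surveys"]}
    for key in (
        "reference_survey", "weights", "ci_method", "bootstrap_reps",
        "t_scale", "attribution", "projection_target", "strict",
    ):
        if key in options:
            setattr(cfg, key, options[key])
    return cfg


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Cessation estimates as a percent-scale table (one row per fit)."""
    return pd.DataFrame(
        [
            {
                "survey": e.survey,
                "period_start": e.period[0],
                "period_end": e.period[1],
                "theta_pct": 100.0 * e.theta_hat,
                "ci_low_pct": 100.0 * e.ci_low,
                "ci_high_pct": 100.0 * e.ci_high,
                "se_pct": 100.0 * e.se,
                "pi0_pct": 100.0 * e.pi0_hat,
                "n_points": e.n_points,
            }
            for e in estimates
        ]
    )


def _fitted_end_prevalence(est, lam: float, mu: float) -> float:
    """Model prevalence at the period's final year from a fitted cell."""
    rates = PeriodRates(lam, est.theta_hat, mu, est.period[0], est.period[1])
    return prevalence_at(est.pi0_hat, rates, float(est.period[1] - est.period[0]))


def run_pipeline(config: RunConfig) -> dict:
    """Execute prep -> estimate -> metareg -> project/decompose; write artifacts."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    if config.strict:
        import warnings

        warnings.filterwarnings("error", category=RuntimeWarning)

    # ---- prep -------------------------------------------------------------
    raw_series = prep.read_prevalence_csv(config.prevalence_csv)
    census = prep.read_census_csv(config.census_csv)
    mortality = prep.read_mortality_csv(config.mortality_csv)
    prev18_df = pd.read_csv(config.prev18_csv)
    prev18_by_survey: dict = {}
    if "survey" in prev18_df.columns:
        for label, grp in prev18_df.groupby("survey"):
            prev18_by_survey[str(label)] = {
                int(r.year): float(r.prev18_pct) / 100.0
                for r in grp.itertuples(index=False)
            }
    else:
        shared = {
            int(r.year): float(r.prev18_pct) / 100.0
            for r in prev18_df.itertuples(index=False)
        }
        prev18_by_survey = {label: shared for label in config.surveys}
    cleaned = {}
    for label, kind in config.surveys.items():
        if label not in raw_series:
            raise ValueError(f"prevalence CSV has no series labelled {label!r}")
        cleaned[label] = prep.clean_series(raw_series[label], kind)
        log.info(
            "prep: %s -> %d points (%d usable)",
            label, len(cleaned[label]), sum(not p.missing for p in cleaned[label]),
        )
    rates_by_survey = {
        label: prep.build_period_rates(
            config.periods, prev18_by_survey[label], census, mortality
        )
        for label in config.surveys
    }
    ref_rates = rates_by_survey[config.reference_survey]
    rates_by_period = {(r.period_start, r.period_end): r for r in ref_rates}

    # ---- estimate ---------------------------------------------------------
    plan = []
    for label in config.surveys:
        for r in rates_by_survey[label]:
            window = [
                p for p in cleaned[label]
                if r.period_start <= p.year <= r.period_end and not p.missing
            ]
            if len(window) < 4:
                log.info(
                    "estimate: skipping %s %d-%d (%d usable points)",
                    label, r.period_start, r.period_end, len(window),
                )
                continue
            plan.append(
                estimation.PeriodInputs(
                    label, r.period_start, r.period_end, r.lambda_init, r.mu_mort
                )
            )
    estimates = estimation.fit_all(
        cleaned,
        plan,
        weights=config.weights,
        ci_method=config.ci_method,
        n_boot=config.bootstrap_reps,
        seed=config.seed,
    )
    est_frame = estimates_to_frame(estimates)
    est_path = os.path.join(config.outdir, "estimates.csv")
    est_frame.to_csv(est_path, index=False)
    log.info("estimate: %d (survey, period) cells -> %s", len(estimates), est_path)

    # ---- metareg ----------------------------------------------------------
    nsduh_labels = tuple(l for l, k in config.surveys.items() if k == "nsduh")
    points = metareg.meta_points_from_estimates(estimates, nsduh_labels=nsduh_labels)
    full = metareg.fit_meta(points, include_survey_term=True, t_scale=config.t_scale)
    reduced = metareg.fit_meta(points, include_survey_term=False, t_scale=config.t_scale)
    departure = metareg.trend_departure_test(full)
    fit_path = os.path.join(config.outdir, "fit.json")
    with open(fit_path, "w") as fh:
        json.dump({"full": full.to_dict(), "reduced": reduced.to_dict()}, fh, indent=2)
    log.info("metareg: %d points -> %s", len(points), fit_path)

    # ---- project / decompose ---------------------------------------------
    ref = config.reference_survey
    ref_ests = {e.period: e for e in estimates if e.survey == ref}
    last_period = max(ref_ests)
    prev_period = max(p for p in ref_ests if p != last_period)
    last_est, prev_est = ref_ests[last_period], ref_ests[prev_period]
    last_base = rates_by_period[last_period]
    prev_base = rates_by_period[prev_period]
    new_rates = last_base.replace(theta_cess=last_est.theta_hat)
    old_rates = prev_base.replace(theta_cess=prev_est.theta_hat)

    pi_anchor = _fitted_end_prevalence(last_est, last_base.lambda_init, last_base.mu_mort)
    schedule = [
        PeriodRates(
            new_rates.lambda_init, new_rates.theta_cess, new_rates.mu_mort,
            last_period[1] + 1, last_period[1] + new_rates.n_years,
        )
    ]
    traj = project(pi_anchor, last_period[1], schedule, config.projection_target)
    traj_path = os.path.join(config.outdir, "trajectory.csv")
    traj.to_frame().to_csv(traj_path, index=False)
    log.info("project: %d -> %d, %d years -> %s",
             last_period[1], config.projection_target, len(traj.values), traj_path)

    pi_2013 = _fitted_end_prevalence(prev_est, prev_base.lambda_init, prev_base.mu_mort)
    horizon = last_period[1] - prev_period[1]
    decomp = decompose(
        pi_2013, prev_period[1], old_rates, new_rates, float(horizon),
        attribution=config.attribution,
    )
    decomp_path = os.path.join(config.outdir, "decomposition.json")
    with open(decomp_path, "w") as fh:
        json.dump(decomp.to_dict(), fh, indent=2)
    log.info("decompose: %s", decomp_path)

    from .model import steady_state

    ssp = steady_state(new_rates)
    summary = _summary_text(
        est_frame, full, reduced, departure, ssp, traj, config, decomp,
        last_period, prev_period,
    )
    summary_path = os.path.join(config.outdir, "summary.txt")
    with open(summary_path, "w") as fh:
        fh.write(summary)

    return {
        "estimates": estimates,
        "estimates_frame": est_frame,
        "meta_full": full,
        "meta_reduced": reduced,
        "trend_departure": departure,
        "steady_state": ssp,
        "trajectory": traj,
        "decomposition": decomp,
        "paths": {
            "estimates": est_path,
            "fit": fit_path,
            "trajectory": traj_path,
            "decomposition": decomp_path,
            "summary": summary_path,
        },
    }


def _summary_text(
    est_frame, full, reduced, departure, ssp, traj, config, decomp,
    last_period, prev_period,
) -> str:
    end_year = config.projection_target
    lines = [
        "quitkinetics pipeline summary",
        "=" * 32,
        "",
        "Cessation-rate estimates (percent/year):",
        est_frame.to_string(
            index=False,
            columns=["survey", "period_start", "period_end", "theta_pct",
                     "ci_low_pct", "ci_high_pct"],
            float_format=lambda v: f"{v:.1f}",
        ),
        "",
        "Meta-regression (full model):",
        full.summary(),
        "",
        "Meta-regression (reduced, no survey term):",
        reduced.summary(),
        "",
        f"Above-trend departure in {last_period[0]}-{last_period[1]}: "
        f"{departure.estimate:.2f} pp "
        f"(95% CI {departure.ci[0]:.2f}, {departure.ci[1]:.2f}; p={departure.p:.3g})",
        "",
        f"Steady-state prevalence at current rates: {100.0 * ssp:.2f}%",
        f"Projected prevalence in {end_year}: {100.0 * traj[end_year]:.1f}%",
        "",
        f"Decomposition of the {prev_period[1]}->{last_period[1]} prevalence drop:",
        f"  baseline (old rates) end prevalence: {100.0 * decomp.baseline_pi_end:.1f}%",
        f"  actual (new rates) end prevalence:   {100.0 * decomp.actual_pi_end:.1f}%",
        f"  total drop: {decomp.total_drop:.1f} pp; excess over old-rate trend: "
        f"{decomp.excess_drop:.1f} pp",
    ]
    if decomp.share_cessation is not None:
        lines.append(
            f"  cessation share {100.0 * decomp.share_cessation:.0f}% "
            f"({decomp.pp_cessation:.2f} pp); initiation share "
            f"{100.0 * decomp.share_initiation:.0f}% ({decomp.pp_initiation:.2f} pp)"
        )
        if decomp.share_recent is not None:
            lines.append(
                f"  recent rate changes account for {100.0 * decomp.share_recent:.0f}% "
                "of the total drop"
            )
    lines.append("")
    return "\n".join(lines)
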