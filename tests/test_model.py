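"""Closed-form dynamics: fixed points, oracle agreement, projection, decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from quitkinetics import (
    PeriodRates,
    decompose,
    prevalence_at,
    project,
    steady_state,
)


def rk4_prevalence(pi0, lam, theta, mu, t, h=1e-3):
    """Numerically integrate d(pi)/dt = lambda - (theta+mu) pi (RK4)."""
    k = theta + mu

    def f(p):
        return lam - k * p

    n = int(t / h)  # floor: the remainder below is then non-negative
    p = pi0
    for _ in range(n):
        k1 = f(p)
        k2 = f(p + 0.5 * h * k1)
        k3 = f(p + 0.5 * h * k2)
        k4 = f(p + h * k3)
        p += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    rem = t - n * h
    if rem > 0:
        k1 = f(p)
        k2 = f(p + 0.5 * rem * k1)
        k3 = f(p + 0.5 * rem * k2)
        k4 = f(p + rem * k3)
        p += (rem / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return p


RATES = PeriodRates(0.0022, 0.054, 0.0083, 2014, 2019)

rate_strategy = st.tuples(
    st.floats(0.0, 1.0),        # pi0
    st.floats(0.0, 0.02),       # lambda
    st.floats(1e-3, 0.2),       # theta
    st.floats(0.0, 0.02),       # mu
    st.floats(0.0, 10.0),       # t
)


class TestPrevalenceAt:
    def test_steady_state_is_fixed_point(self):
        ssp = steady_state(RATES)
        for t in (0.0, 1.0, 6.0, 50.0):
            assert prevalence_at(ssp, RATES, t) == pytest.approx(ssp, abs=1e-15)

    def test_identity_at_anchor(self):
        assert prevalence_at(0.37, RATES, 0.0) == 0.37

    def test_six_year_projection_matches_printed_2019_prevalence(self):
        # pi(2013)=17.71%, lambda=0.22%/yr, relaxation rate lambda/SSP with
        # SSP=3.53% -> the model's 2019 prevalence, 13.28-13.29%
        k = 0.0022 / 0.0353
        r = PeriodRates(0.0022, k - 0.0083, 0.0083, 2014, 2019)
        val = 100.0 * prevalence_at(0.1771, r, 6.0)
        assert 13.28 <= round(val, 2) <= 13.29

    def test_matches_rk4_on_reference_case(self):
        got = prevalence_at(0.20, PeriodRates(0.003, 0.05, 0.01, 2014, 2019), 6.0)
        want = rk4_prevalence(0.20, 0.003, 0.05, 0.01, 6.0)
        assert got == pytest.approx(want, abs=1e-8)

    @given(rate_strategy)
    def test_closed_form_agrees_with_rk4(self, params):
        pi0, lam, theta, mu, t = params
        got = prevalence_at(pi0, PeriodRates(lam, theta, mu, 2014, 2019), t)
        want = rk4_prevalence(pi0, lam, theta, mu, t)
        assert got == pytest.approx(want, abs=1e-8)

    @given(rate_strategy)
    def test_geometric_decay_toward_steady_state(self, params):
        """|pi(t) - SSP| shrinks by exactly exp(-(theta+mu)) per year."""
        pi0, lam, theta, mu, t = params
        r = PeriodRates(lam, theta, mu, 2014, 2019)
        ssp = lam / r.outflow
        gap_t = prevalence_at(pi0, r, t) - ssp
        gap_t1 = prevalence_at(pi0, r, t + 1.0) - ssp
        assert gap_t1 == pytest.approx(gap_t * math.exp(-r.outflow), abs=1e-12)
        assert abs(gap_t1) <= abs(gap_t) + 1e-15

    def test_degenerate_outflow_rejected_unless_flagged(self):
        r = PeriodRates(0.01, 0.0, 0.0, 2014, 2019)
        with pytest.raises(ValueError, match="theta \\+ mu"):
            prevalence_at(0.2, r, 5.0)
        assert prevalence_at(0.2, r, 5.0, allow_degenerate=True) == pytest.approx(0.25)
        assert prevalence_at(0.9, r, 50.0, allow_degenerate=True) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            prevalence_at(0.2, RATES, -1.0)


class TestSteadyState:
    def test_no_initiation_dies_out(self):
        assert steady_state(PeriodRates(0.0, 0.05, 0.01, 2014, 2019)) == 0.0

    def test_matches_printed_long_run_prevalence(self):
        # lambda=0.22%/yr with theta=5.4%/yr and mu=0.83%/yr -> 3.53%
        assert round(steady_state(RATES), 4) == 0.0353

    def test_boundary_full_prevalence(self):
        r = PeriodRates(0.06, 0.05, 0.01, 2014, 2019)
        assert steady_state(r) == pytest.approx(1.0)

    def test_zero_outflow_is_an_error(self):
        with pytest.raises(ValueError, match="steady state"):
            steady_state(PeriodRates(0.01, 0.0, 0.0, 2014, 2019))


def _schedule():
    return [
        PeriodRates(0.0035, 0.042, 0.0083, 2008, 2013),
        PeriodRates(0.0022, 0.054, 0.0083, 2014, 2019),
    ]


class TestProject:
    def test_target_equals_anchor(self):
        traj = project(0.2, 2008, _schedule(), 2008)
        assert traj.values == {2008: 0.2}

    def test_flat_at_steady_state(self):
        sched = [_schedule()[1]]
        ssp = steady_state(sched[0])
        traj = project(ssp, 2014, sched, 2030)
        assert all(v == pytest.approx(ssp, abs=1e-14) for v in traj.values.values())

    def test_single_period_equals_direct_evaluation(self):
        sched = [_schedule()[0]]
        traj = project(0.2, 2008, sched, 2013)
        for year in range(2008, 2014):
            want = prevalence_at(0.2, sched[0], float(year - 2008))
            assert traj[year] == pytest.approx(want, abs=1e-12)

    def test_semigroup_chaining_within_a_period(self):
        r = _schedule()[0]
        one_hop = prevalence_at(0.2, r, 5.0)
        stepped = 0.2
        for _ in range(5):
            stepped = prevalence_at(stepped, r, 1.0)
        assert stepped == pytest.approx(one_hop, abs=1e-12)

    def test_last_period_rates_extend_beyond_schedule(self):
        sched = _schedule()
        traj = project(0.1771, 2013, sched[1:], 2030)
        # printed inputs give ~8.3-8.4% in 2030
        assert 100.0 * traj[2030] == pytest.approx(8.35, abs=0.15)

    def test_continuity_across_period_boundary(self):
        traj = project(0.2, 2008, _schedule(), 2019)
        direct_2013 = prevalence_at(0.2, _schedule()[0], 5.0)
        assert traj[2013] == pytest.approx(direct_2013, abs=1e-12)
        assert traj[2014] == pytest.approx(
            prevalence_at(direct_2013, _schedule()[1], 1.0), abs=1e-12
        )

    def test_gap_and_overlap_are_rejected_with_years_named(self):
        gap = [
            PeriodRates(0.003, 0.04, 0.008, 2008, 2013),
            PeriodRates(0.002, 0.05, 0.008, 2015, 2020),
        ]
        with pytest.raises(ValueError, match="gap.*2008-2013.*2015-2020"):
            project(0.2, 2008, gap, 2020)
        overlap = [
            PeriodRates(0.003, 0.04, 0.008, 2008, 2013),
            PeriodRates(0.002, 0.05, 0.008, 2013, 2018),
        ]
        with pytest.raises(ValueError, match="overlap"):
            project(0.2, 2008, overlap, 2018)


class TestDecompose:
    OLD = PeriodRates(0.00355, 0.042, 0.0083, 2008, 2013)
    NEW = PeriodRates(0.0022, 0.054, 0.0083, 2014, 2019)

    def test_identical_rates_leave_shares_undefined(self):
        d = decompose(0.18, 2013, self.OLD, self.OLD, 6.0)
        assert d.excess_drop == 0.0
        assert d.share_cessation is None and d.share_initiation is None
        pure_trend = 100.0 * (0.18 - prevalence_at(0.18, self.OLD, 6.0))
        assert d.total_drop == pytest.approx(pure_trend, abs=1e-12)

    @pytest.mark.parametrize(
        "mode", ["averaged", "cessation_first", "initiation_first"]
    )
    def test_attributions_sum_to_excess_drop(self, mode):
        rng = np.random.default_rng(5)
        for _ in range(25):
            lam_o, lam_n = rng.uniform(0.001, 0.01, 2)
            th_o, th_n = rng.uniform(0.01, 0.1, 2)
            old = PeriodRates(lam_o, th_o, 0.008, 2008, 2013)
            new = PeriodRates(lam_n, th_n, 0.008, 2014, 2019)
            d = decompose(0.2, 2013, old, new, 6.0, attribution=mode)
            assert d.pp_cessation + d.pp_initiation == pytest.approx(
                d.excess_drop, abs=1e-9
            )
            if d.share_cessation is not None:
                assert d.share_cessation + d.share_initiation == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_swapping_old_and_new_negates_the_excess_drop(self):
        d = decompose(0.18, 2013, self.OLD, self.NEW, 6.0)
        r = decompose(0.18, 2013, self.NEW, self.OLD, 6.0)
        assert r.excess_drop == pytest.approx(-d.excess_drop, abs=1e-12)
        assert r.pp_cessation == pytest.approx(-d.pp_cessation, abs=1e-12)
        assert r.pp_initiation == pytest.approx(-d.pp_initiation, abs=1e-12)

    def test_shares_match_independent_four_scenario_recomputation(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            lam_o, lam_n = rng.uniform(0.001, 0.01, 2)
            th_o, th_n = rng.uniform(0.01, 0.1, 2)
            mu = rng.uniform(0.005, 0.012)
            old = PeriodRates(lam_o, th_o, mu, 2008, 2013)
            new = PeriodRates(lam_n, th_n, mu, 2014, 2019)
            d = decompose(0.2, 2013, old, new, 6.0)

            def end(lam, th):
                sched = [PeriodRates(lam, th, mu, 2014, 2019)]
                return project(0.2, 2013, sched, 2019)[2019]

            p1, p2 = end(lam_o, th_o), end(lam_n, th_n)
            p3, p4 = end(lam_o, th_n), end(lam_n, th_o)
            pp_c = 100.0 * 0.5 * ((p1 - p3) + (p4 - p2))
            pp_i = 100.0 * 0.5 * ((p1 - p4) + (p3 - p2))
            assert d.excess_drop == pytest.approx(100 * (p1 - p2), abs=1e-10)
            assert d.pp_cessation == pytest.approx(pp_c, abs=1e-10)
            assert d.pp_initiation == pytest.approx(pp_i, abs=1e-10)

    def test_rejects_nonpositive_horizon(self):
        with pytest.raises(ValueError):
            decompose(0.2, 2013, self.OLD, self.NEW, 0.0)


class TestPeriodRates:
    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PeriodRates(-0.01, 0.05, 0.01, 2014, 2019)
        with pytest.raises(ValueError):
            PeriodRates(0.01, 1.0, 0.01, 2014, 2019)

    def test_period_span_must_be_six_or_seven_years(self):
        PeriodRates(0.01, 0.05, 0.01, 2008, 2014)  # 7-year span allowed
        with pytest.raises(ValueError, match="span"):
            PeriodRates(0.01, 0.05, 0.01, 2014, 2016)
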