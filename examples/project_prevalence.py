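"""Steady state and forward projection from the most recent period's rates.

Builds the 2014-2019 rate triple from its printed inputs (initiation
0.22%/yr, cessation 5.4%/yr, smoker mortality back-solved from the 3.53%
long-run prevalence), then projects adult smoking prevalence from the
model's 2013 level (17.71%) out to 2030.
"""

from quitkinetics import PeriodRates, prevalence_at, project, steady_state

lam, theta, ssp = 0.0022, 0.054, 0.0353
mu = lam / ssp - theta
rates = PeriodRates(lam, theta, mu, 2014, 2019)

print(f"steady-state prevalence: {100 * steady_state(rates):.2f}%")
print(f"model 2019 prevalence:   {100 * prevalence_at(0.1771, rates, 6.0):.2f}%")

traj = project(0.1771, 2013, [rates], 2030)
for year in (2019, 2025, 2030):
    print(f"projected {year}: {100 * traj[year]:.1f}%")

# The 2019 value is the six-year relaxation of the 2013 level toward the
# steady state; by 2030 prevalence has closed most of the remaining gap.
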