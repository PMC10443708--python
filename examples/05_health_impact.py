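"""Convert dietary shifts into diet-related NCD deaths averted.

A comparative risk assessment: dietary changes are mediated into BMI
(via steady-state energy balance), systolic blood pressure (via salt)
and serum cholesterol (via saturated fat %TE); fiber acts directly.
Potential impact fractions against log-linear dose-response curves are
multiplied into baseline death counts per sex, five-year age band and
cause, with Monte Carlo uncertainty from the RR standard errors.
"""

import pandas as pd

from fopl_impact import SynthConfig, default_pathway_params, mediate, run_prime, attribute_by_factor
from fopl_impact.config import AGE_BANDS
from fopl_impact.synth import generate_mortality_tables

deaths, population = generate_mortality_tables(SynthConfig())
print(f"baseline: {deaths['deaths'].sum():,} diet-related NCD deaths")

baseline = pd.DataFrame([
    dict(sex=s, age_band=b, factor=f, mean=m, sd=sd, shape=sh)
    for s in ("M", "F") for b in AGE_BANDS
    for f, m, sd, sh in [("bmi", 27.0, 4.5, "lognormal"), ("sbp", 122.0, 15.0, "normal"),
                         ("cholesterol", 5.0, 1.0, "normal"), ("fiber", 17.0, 6.0, "normal")]
])
heights = pd.DataFrame([dict(sex=s, age_band=b, height_m=1.70)
                        for s in ("M", "F") for b in AGE_BANDS])
# the full-substitution dietary deltas reported for the scenario family
shifts = pd.DataFrame([
    dict(sex=s, age_band=b, energy=-46.0, sodium=-259.0, satfat_pctTE=0.04, fiber=-0.02)
    for s in ("M", "F") for b in AGE_BANDS
])

params = default_pathway_params()
cf = mediate(shifts, heights, baseline, params)
res = run_prime(deaths, baseline, cf, params, n_iter=10_000, seed=1)

t, lo, hi = res.totals["total"]
print(f"deaths averted or delayed: {t:,.0f} (95% UI {lo:,.0f}-{hi:,.0f})")
print(f"  of which under 75: {res.totals['under_75'][0]:,.0f}; "
      f"males {res.totals['sex:M'][0]:,.0f}")
print(attribute_by_factor(deaths, baseline, cf, params, n_iter=2000, seed=1)
      .round(1).to_string(index=False))
# Energy (through BMI) dominates; the slight saturated-fat %TE rise and
# fiber decline appear as small negative attribution rows.
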