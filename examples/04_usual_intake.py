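"""Estimate usual nutrient intakes from two 24-h recalls per person.

Daily recall totals mix long-run (usual) intake with day-to-day noise.
The Box-Cox random-intercept model separates the two, adjusts for sex,
age group, weekend, recall sequence and misreporting status, and
back-transforms person means with a second-order bias correction.
Because the data are synthetic, the estimates can be compared with the
generator's planted truth.
"""

from fopl_impact import (SynthConfig, attach_nutrients, daily_totals,
                         estimate_usual_means, fit_amount_model,
                         misreporting_status, prepare_model_frame)
from fopl_impact.synth import generate_food_db, generate_population

cfg = SynthConfig(n_respondents=1500, seed=9)
foods, _ = generate_food_db(cfg)
respondents, recalls, truth = generate_population(cfg, foods)

totals = daily_totals(attach_nutrients(recalls, foods))
status = misreporting_status(
    respondents, totals.groupby("respondent_id")["energy_kcal"].mean()
)
print(status.value_counts().to_string())

for nutrient, unit in [("energy", "kcal/d"), ("sodium", "mg/d"), ("fiber", "g/d")]:
    frame = prepare_model_frame(totals, respondents, nutrient, status)
    model = fit_amount_model(frame, nutrient)
    est = [e for e in estimate_usual_means(model, n_boot=300, seed=0)
           if e.stratum == "overall"][0]
    tm = truth.stratum_means
    true = tm[(tm.stratum == "overall") & (tm.nutrient == nutrient)]["true_mean"].iloc[0]
    print(f"{nutrient:7s} lambda={model.boxcox_lambda:4.2f}  "
          f"usual mean {est.mean:8.1f} +/- {est.se:5.1f} {unit} "
          f"(95% CI {est.ci95[0]:.1f}-{est.ci95[1]:.1f}); planted truth {true:8.1f}")
# The energy CI covers the planted truth for most seeds, and the
# misreporting adjustment removes the planted reporting bias. For the most
# skewed nutrients (sodium, fiber) the transform-scale model sits a few
# percent below the truth — see the methods note; scenario *differences*
# are unaffected because the bias is shared by baseline and counterfactual.
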