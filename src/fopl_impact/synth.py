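"""Synthetic study world: food supply, recall survey, and vital statistics.

Generates every input table the pipeline needs with the statistical
structure the analysis assumes, so the full method is testable without
any restricted data:

* a generic food table and a branded-product table, categorized into
  major/minor categories, with per-100 g nutrient profiles drawn as
  log-normal multiples of the applicable 'high in' threshold so that a
  configurable share of foods classifies 'high in' and a configurable
  share of those has healthier branded alternatives;
* an adult respondent table (DRI age-sex demographics, heights, BMIs,
  survey weights) with exactly two 24-h recall days each, built
  compositionally (foods x grams) and calibrated so that daily energy
  equals predicted total energy expenditure times log-normal person- and
  day-level effects, with planted under/over-reporters;
* cause-by-sex-by-age-band mortality and population tables.

Ground truth (person effects, true usual intakes, stratum means) is
retained in a :class:`SynthTruth` object for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import AGE_BANDS, DRI_GROUPS, SEXES, ConfigurationError, SynthConfig

__all__ = [
    "generate_food_db",
    "generate_population",
    "generate_mortality_tables",
    "SynthTruth",
    "NUTRIENT_COLS",
    "dri_group_of_age",
]

#: per-100 g nutrient columns shared by food and branded tables
NUTRIENT_COLS = ["energy_kcal", "sodium_mg", "sugars_g", "satfat_g", "fiber_g"]

# (major category, sampling weight, reference amount g, typical consumed g,
#  median energy kcal/100 g) -- loosely modeled on Canadian reference-amount
# major categories
_CATALOG = [
    ("Bakery products", 2.0, 55.0, 70.0, 330.0),
    ("Beverages", 1.5, 355.0, 330.0, 40.0),
    ("Cereals and grain products", 1.2, 40.0, 45.0, 370.0),
    ("Dairy products and substitutes", 1.5, 125.0, 150.0, 120.0),
    ("Desserts", 0.8, 125.0, 100.0, 250.0),
    ("Fats and oils", 0.6, 10.0, 12.0, 700.0),
    ("Fruit and fruit juices", 1.5, 140.0, 120.0, 55.0),
    ("Meats and substitutes", 2.0, 125.0, 120.0, 220.0),
    ("Combination dishes", 1.0, 250.0, 350.0, 150.0),
    ("Sauces, dips, gravies and condiments", 0.8, 30.0, 25.0, 180.0),
    ("Snacks", 0.8, 40.0, 50.0, 480.0),
    ("Soups", 0.8, 250.0, 250.0, 45.0),
    ("Sugars and sweets", 0.8, 20.0, 25.0, 380.0),
    ("Vegetables", 1.5, 85.0, 100.0, 35.0),
]

_DV = {"sodium_mg": 2300.0, "sugars_g": 100.0, "satfat_g": 20.0}
_SYMBOL_COLS = list(_DV)

_FOOD_COLUMNS = [
    "food_id", "major_category", "minor_category", "reference_amount_g",
    "exempt", "typical_gram", "popularity",
] + NUTRIENT_COLS
_BRANDED_COLUMNS = [
    "branded_id", "major_category", "minor_category", "reference_amount_g",
    "exempt",
] + NUTRIENT_COLS


def dri_group_of_age(age) -> np.ndarray:
    """DRI age group label(s) for adult age(s) in years."""
    age = np.asarray(age)
    out = np.select(
        [age <= 30, age <= 50, age <= 70], ["19-30", "31-50", "51-70"], "71+"
    )
    return out


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer counts summing exactly to ``total``, by largest remainder."""
    weights = np.asarray(weights, float)
    if weights.sum() <= 0:
        raise ConfigurationError("apportionment weights must have positive sum")
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:short]] += 1
    return counts


def _threshold_geometry(ra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation basis (g) and %DV fraction for reference amounts,
    mirroring the classifier's default policy."""
    basis = np.where(ra <= 30.0, 50.0, ra)
    frac = np.where(ra >= 200.0, 0.30, 0.15)
    return basis, frac


def _draw_symbol_nutrients(rng, ratio_params, high_flags, healthy, basis, frac):
    """Per-100 g symbol-nutrient amounts from threshold-ratio components.

    ``high_flags`` is (n, 3) boolean; healthy records ignore it and draw all
    three nutrients from the well-below-threshold component.
    """
    n = len(basis)
    out = {}
    mu_hi, sd_hi = ratio_params["high_ratio"]
    mu_lo, sd_lo = ratio_params["low_ratio"]
    mu_he, sd_he = ratio_params["healthy_ratio"]
    for j, col in enumerate(_SYMBOL_COLS):
        mu = np.where(high_flags[:, j], mu_hi, mu_lo)
        sd = np.where(high_flags[:, j], sd_hi, sd_lo)
        mu = np.where(healthy, mu_he, mu)
        sd = np.where(healthy, sd_he, sd)
        ratio = np.exp(rng.normal(mu, sd, size=n))
        threshold_amount = frac * _DV[col]
        out[col] = threshold_amount * ratio * 100.0 / basis
    return out


def generate_food_db(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the generic food table and the branded-product table.

    Foods carry major/minor category labels; per-100 g energy, sodium,
    total sugars, saturated fat and fiber are drawn from category-specific
    log-normals. A latent per-nutrient 'high' indicator (calibrated so
    that about ``frac_high_in_target`` of non-exempt foods classify
    'high in') places each symbol nutrient either well above or well
    below its threshold. A sampled fraction ``alt_coverage_target`` of
    non-exempt minor categories contains branded products drawn from a
    below-threshold component (healthier alternatives); the remaining
    categories hold only products at or above every threshold.
    Deterministic under ``cfg.seed``.
    """
    if cfg.n_foods == 0:
        return (
            pd.DataFrame(columns=_FOOD_COLUMNS),
            pd.DataFrame(columns=_BRANDED_COLUMNS),
        )
    rng = _rng(cfg, 1)

    majors = [c[0] for c in _CATALOG]
    major_w = np.array([c[1] for c in _CATALOG])
    ra_by_major = {c[0]: c[2] for c in _CATALOG}
    typ_by_major = {c[0]: c[3] for c in _CATALOG}
    energy_by_major = {c[0]: c[4] for c in _CATALOG}

    n_minor = max(len(majors), cfg.n_foods // max(1, cfg.foods_per_minor_category))
    minors_per_major = np.maximum(1, _apportion(n_minor, major_w))
    minor_labels, minor_major = [], []
    for m, k in zip(majors, minors_per_major):
        for i in range(k):
            minor_labels.append(f"{m} #{i + 1}")
            minor_major.append(m)
    minor_labels = np.array(minor_labels)
    minor_major = np.array(minor_major)
    n_minor = len(minor_labels)

    # assign foods to minor categories (uniform within the major's minors)
    food_minor_idx = rng.choice(
        n_minor, size=cfg.n_foods, p=np.repeat(major_w / major_w.sum(), minors_per_major)
        / np.repeat(minors_per_major, minors_per_major),
    )
    f_major = minor_major[food_minor_idx]
    f_minor = minor_labels[food_minor_idx]
    ra = np.array([ra_by_major[m] for m in f_major])
    exempt = np.isin(f_major, list(cfg.exempt_majors))
    basis, frac = _threshold_geometry(ra)

    # latent per-nutrient 'high' flags: P(at least one of 3) = target
    q = 1.0 - (1.0 - cfg.frac_high_in_target) ** (1.0 / 3.0)
    high_flags = rng.random((cfg.n_foods, 3)) < q

    params = cfg.nutrient_lognormal_params
    nutrients = _draw_symbol_nutrients(
        rng, params, high_flags, np.zeros(cfg.n_foods, bool), basis, frac
    )
    mu_e, sd_e = params["energy_kcal"]
    energy_med = np.array([energy_by_major[m] for m in f_major])
    nutrients["energy_kcal"] = energy_med * np.exp(rng.normal(mu_e, sd_e, cfg.n_foods))
    mu_f, sd_f = params["fiber_g"]
    nutrients["fiber_g"] = np.exp(rng.normal(mu_f, sd_f, cfg.n_foods))

    foods = pd.DataFrame({
        "food_id": [f"F{i:05d}" for i in range(cfg.n_foods)],
        "major_category": f_major,
        "minor_category": f_minor,
        "reference_amount_g": ra,
        "exempt": exempt,
        "typical_gram": np.array([typ_by_major[m] for m in f_major]),
        "popularity": rng.lognormal(0.0, 1.0, cfg.n_foods),
    })
    for col in NUTRIENT_COLS:
        foods[col] = nutrients[col]
    foods["popularity"] /= foods["popularity"].sum()

    # branded products, clustered within minor categories; an exact share of
    # non-exempt minor categories is "covered" with healthier alternatives
    nonexempt_minors = np.flatnonzero(~np.isin(minor_major, list(cfg.exempt_majors)))
    n_cov = int(np.floor(cfg.alt_coverage_target * len(nonexempt_minors) + 0.5))
    covered_idx = rng.choice(nonexempt_minors, size=n_cov, replace=False)
    covered = np.zeros(n_minor, bool)
    covered[covered_idx] = True

    b_minor_idx = rng.choice(
        n_minor, size=cfg.n_branded, p=np.repeat(major_w / major_w.sum(), minors_per_major)
        / np.repeat(minors_per_major, minors_per_major),
    )
    b_major = minor_major[b_minor_idx]
    b_minor = minor_labels[b_minor_idx]
    b_ra = np.array([ra_by_major[m] for m in b_major])
    b_exempt = np.isin(b_major, list(cfg.exempt_majors))
    b_basis, b_frac = _threshold_geometry(b_ra)

    in_covered = covered[b_minor_idx]
    healthy = in_covered & (rng.random(cfg.n_branded) < cfg.healthy_branded_frac)
    # non-healthy brands in covered categories mirror the generic mix; in
    # uncovered categories every brand sits above all three thresholds
    b_high = rng.random((cfg.n_branded, 3)) < q
    b_high[~in_covered] = True

    b_nutrients = _draw_symbol_nutrients(rng, params, b_high, healthy, b_basis, b_frac)
    b_energy_med = np.array([energy_by_major[m] for m in b_major])
    energy_factor = np.where(healthy, 0.85, 1.0)
    b_nutrients["energy_kcal"] = (
        b_energy_med * energy_factor * np.exp(rng.normal(mu_e, sd_e, cfg.n_branded))
    )
    b_nutrients["fiber_g"] = np.exp(rng.normal(mu_f, sd_f, cfg.n_branded))

    branded = pd.DataFrame({
        "branded_id": [f"B{i:05d}" for i in range(cfg.n_branded)],
        "major_category": b_major,
        "minor_category": b_minor,
        "reference_amount_g": b_ra,
        "exempt": b_exempt,
    })
    for col in NUTRIENT_COLS:
        branded[col] = b_nutrients[col]
    return foods, branded


@dataclass
class SynthTruth:
    """Ground truth retained by the population generator.

    ``person`` has one row per respondent: the log-scale person effect,
    the planted misreporting bias/category, predicted TEE, and true usual
    intakes of each pipeline quantity. ``stratum_means`` holds the
    survey-weighted true usual means overall and per DRI age-sex group.
    """

    person: pd.DataFrame
    stratum_means: pd.DataFrame
    e_ratio: Mapping[str, float]
    var_between: float
    var_within: float


def _tee_mifflin(sex, age, weight_kg, height_m, pal=1.6):
    """Total energy expenditure: Mifflin-St Jeor REE x physical activity."""
    ree = 10.0 * weight_kg + 625.0 * height_m - 5.0 * age
    ree = ree + np.where(np.asarray(sex) == "M", 5.0, -161.0)
    return pal * ree


def _simulate_menu_ratios(cfg, foods, rng, n_days):
    """Monte Carlo E[nutrient-to-energy ratio] of a recall day's menu."""
    k = 3 + rng.poisson(max(cfg.mean_items_per_day - 3.0, 0.0), n_days)
    total = int(k.sum())
    day_idx = np.repeat(np.arange(n_days), k)
    items = rng.choice(len(foods), size=total, p=foods["popularity"].to_numpy())
    grams = foods["typical_gram"].to_numpy()[items] * np.exp(
        rng.normal(0.0, cfg.gram_jitter_sd, total)
    )
    energy = np.zeros(n_days)
    np.add.at(energy, day_idx, grams * foods["energy_kcal"].to_numpy()[items] / 100.0)
    ratios = {}
    for col in ("sodium_mg", "sugars_g", "satfat_g", "fiber_g"):
        amt = np.zeros(n_days)
        np.add.at(amt, day_idx, grams * foods[col].to_numpy()[items] / 100.0)
        ratios[col] = float(np.mean(amt / energy))
    return ratios


def generate_population(
    cfg: SynthConfig, foods: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Generate respondents with exactly two 24-h recall days each.

    Daily menus are compositional (food selections x gram amounts); gram
    amounts are rescaled so that a day's true energy equals the person's
    predicted TEE times ``exp(b_i + d_ij)`` times the weekend effect,
    where ``b_i`` is the person-level effect (SD ``between_person_sd``)
    and ``d_ij`` day-level noise with variance
    ``within_between_ratio x var(b)``. Recorded gram amounts additionally
    carry the planted misreporting bias factor.
    """
    if foods.empty:
        raise ConfigurationError("food table required before generating a population")
    rng = _rng(cfg, 2)
    n = cfg.n_respondents

    groups = list(cfg.demographic_weights)
    gw = np.array([cfg.demographic_weights[g] for g in groups])
    which = rng.choice(len(groups), size=n, p=gw / gw.sum())
    sex = np.array([groups[i][0] for i in which])
    dri = np.array([groups[i][1] for i in which])
    lo = {"19-30": 19, "31-50": 31, "51-70": 51, "71+": 71}
    hi = {"19-30": 30, "31-50": 50, "51-70": 70, "71+": 90}
    age = np.array([rng.integers(lo[g], hi[g] + 1) for g in dri])

    height = np.where(
        sex == "M", rng.normal(1.76, 0.07, n), rng.normal(1.62, 0.065, n)
    )
    bmi = np.exp(rng.normal(np.log(26.5), 0.17, n))
    weight = bmi * height**2
    tee = _tee_mifflin(sex, age, weight, height)

    svy_w = np.exp(rng.normal(0.0, cfg.weight_dispersion, n)) if cfg.weight_dispersion > 0 else np.ones(n)

    u = rng.random(n)
    bias_cat = np.where(
        u < cfg.underreport_frac, "under",
        np.where(u < cfg.underreport_frac + cfg.overreport_frac, "over", "plausible"),
    )
    bias = np.where(
        bias_cat == "under", cfg.underreport_bias,
        np.where(bias_cat == "over", cfg.overreport_bias, 1.0),
    )

    sd_b = cfg.between_person_sd
    sd_w = np.sqrt(cfg.within_between_ratio) * sd_b
    b = rng.normal(0.0, sd_b, n) if sd_b > 0 else np.zeros(n)

    respondents = pd.DataFrame({
        "respondent_id": [f"R{i:05d}" for i in range(n)],
        "sex": sex, "age": age, "dri_group": dri,
        "height_m": height, "weight_kg": weight, "bmi": bmi,
        "survey_weight": svy_w,
    })

    # two recall days per respondent
    n_days = 2 * n
    resp_of_day = np.repeat(np.arange(n), 2)
    day_no = np.tile([1, 2], n)
    weekend = rng.random(n_days) < cfg.weekend_prob
    d = rng.normal(0.0, sd_w, n_days) if sd_w > 0 else np.zeros(n_days)
    target_energy = (
        tee[resp_of_day]
        * np.exp(b[resp_of_day] + d)
        * np.where(weekend, cfg.weekend_effect, 1.0)
    )

    k = 3 + rng.poisson(max(cfg.mean_items_per_day - 3.0, 0.0), n_days)
    total = int(k.sum())
    day_idx = np.repeat(np.arange(n_days), k)
    items = rng.choice(len(foods), size=total, p=foods["popularity"].to_numpy())
    grams_raw = foods["typical_gram"].to_numpy()[items] * np.exp(
        rng.normal(0.0, cfg.gram_jitter_sd, total)
    )
    raw_energy = np.zeros(n_days)
    np.add.at(
        raw_energy, day_idx, grams_raw * foods["energy_kcal"].to_numpy()[items] / 100.0
    )
    scale = target_energy / raw_energy
    grams_true = grams_raw * scale[day_idx]
    grams_reported = grams_true * bias[resp_of_day][day_idx]

    recalls = pd.DataFrame({
        "respondent_id": respondents["respondent_id"].to_numpy()[resp_of_day][day_idx],
        "day": day_no[day_idx],
        "sequence": day_no[day_idx],
        "weekend": weekend[day_idx].astype(int),
        "food_id": foods["food_id"].to_numpy()[items],
        "grams": grams_reported,
    })

    # ground truth: usual intake = TEE exp(b) E[exp(d)] E[weekend mult] E[R]
    rng_truth = _rng(cfg, 3)
    e_ratio = _simulate_menu_ratios(cfg, foods, rng_truth, cfg.truth_menu_days)
    day_mult = float(np.exp(sd_w**2 / 2.0) * (
        (1 - cfg.weekend_prob) + cfg.weekend_prob * cfg.weekend_effect
    ))
    usual_energy = tee * np.exp(b) * day_mult
    person = pd.DataFrame({
        "respondent_id": respondents["respondent_id"],
        "person_effect": b, "bias_category": bias_cat, "bias": bias, "tee": tee,
        "usual_energy": usual_energy,
        "usual_sodium": usual_energy * e_ratio["sodium_mg"],
        "usual_sugars": usual_energy * e_ratio["sugars_g"],
        "usual_satfat": usual_energy * e_ratio["satfat_g"],
        "usual_fiber": usual_energy * e_ratio["fiber_g"],
        "usual_satfat_pctTE": np.full(n, 900.0 * e_ratio["satfat_g"]),
    })

    rows = []
    nutr_cols = [c for c in person.columns if c.startswith("usual_")]
    for label, mask in [("overall", np.ones(n, bool))] + [
        (f"{s}|{g}", (sex == s) & (dri == g)) for s in SEXES for g in DRI_GROUPS
    ]:
        if mask.sum() == 0:
            continue
        w = svy_w[mask]
        for c in nutr_cols:
            rows.append({
                "stratum": label,
                "nutrient": c.removeprefix("usual_"),
                "true_mean": float(np.average(person.loc[mask, c], weights=w)),
                "n": int(mask.sum()),
            })
    stratum_means = pd.DataFrame(rows)

    truth = SynthTruth(
        person=person, stratum_means=stratum_means, e_ratio=e_ratio,
        var_between=sd_b**2, var_within=float(sd_w**2),
    )
    return respondents, recalls, truth


def generate_mortality_tables(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cause-by-sex-by-age-band death counts and population counts.

    Death counts rise with age at cause-specific Gompertz-like slopes and
    sum exactly to ``round(cfg.total_deaths)`` (largest-remainder
    apportionment); population declines at older ages and sums to
    ``round(cfg.total_population)``.
    """
    mids = np.array([(int(b.split("-")[0]) + int(b.split("-")[1])) / 2.0
                     if "-" in b else 90.0 for b in AGE_BANDS])
    slopes = {"CVD": 0.10, "cancer": 0.07, "diabetes": 0.08,
              "chronic_renal_failure": 0.10, "liver_disease": 0.03}

    pop_age_w = np.minimum(1.0, np.exp(-0.045 * np.maximum(0.0, mids - 62.0)))
    sexes, bands, persons_w = [], [], []
    for s in SEXES:
        sexes += [s] * len(AGE_BANDS)
        bands += list(AGE_BANDS)
        persons_w += list(pop_age_w * 0.5)
    persons = _apportion(int(round(cfg.total_population)), np.array(persons_w))
    population = pd.DataFrame({"sex": sexes, "age_band": bands, "persons": persons})

    causes = list(cfg.cause_weights)
    rows_sex, rows_band, rows_cause, w = [], [], [], []
    for s in SEXES:
        sw = cfg.sex_death_weights.get(s, 0.0)
        for c in causes:
            cw = cfg.cause_weights[c]
            aw = np.exp(slopes[c] * (mids - 70.0)) * pop_age_w
            for band, a in zip(AGE_BANDS, aw):
                rows_sex.append(s)
                rows_band.append(band)
                rows_cause.append(c)
                w.append(sw * cw * a)
    w = np.array(w)
    if w.sum() <= 0:
        raise ConfigurationError("death weights are all zero")
    deaths = _apportion(int(round(cfg.total_deaths)), w)
    mortality = pd.DataFrame({
        "sex": rows_sex, "age_band": rows_band, "cause": rows_cause, "deaths": deaths,
    })

    check = mortality.groupby(["sex", "age_band"])["deaths"].sum().reset_index()
    merged = check.merge(population, on=["sex", "age_band"])
    if (merged["deaths"] > merged["persons"]).any():
        raise ConfigurationError("generated deaths exceed population in a stratum")
    return mortality, population
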