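"""Output surfaces and end-to-end pipeline orchestration.

Produces the analysis' reporting tables — the matching-coverage summary,
the baseline-vs-scenario usual-intake table with CI-overlap significance
stars, the per-risk-factor attribution table — plus share breakdowns
(by cause, sex, under-75 age, factor), percent-of-total-deaths context
figures, and a machine-readable bundle with a reproducibility manifest.

Rounding convention throughout: half away from zero, at the precision
each surface prints.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .classify import ThresholdPolicy, classify_table
from .config import AGE_BANDS, DRI_GROUPS, SEXES, ConfigurationError, SynthConfig
from .matching import find_all_alternatives, summarize_matching
from .prime import (PathwayParams, PrimeResult, band_lower_age,
                    default_pathway_params, mediate, run_prime,
                    attribute_by_factor)
from .scenario import (ScenarioSpec, apply_substitution, attach_nutrients,
                       daily_totals, eligible_respondents, select_participants)
from .synth import (generate_food_db, generate_mortality_tables,
                    generate_population)
from .usual_intake import (UsualEstimate, compare_scenarios, estimate_usual_means,
                           fit_amount_model, misreporting_status,
                           prepare_model_frame, usual_person_values)

__all__ = [
    "PipelineConfig", "PipelineResult", "ShareTable",
    "round_half_away", "scenario_table", "impact_shares",
    "percent_of_total_deaths", "dri_group_of_band", "build_exposure_baseline",
    "run_full_pipeline",
]

NUTRIENTS = ("energy", "sodium", "sugars", "satfat", "satfat_pctTE", "fiber")


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention of all printed shares)."""
    x = np.asarray(x, float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def dri_group_of_band(band: str) -> str:
    """DRI age group containing the five-year band's midpoint."""
    lo = band_lower_age(band)
    mid = lo + 2.5 if "-" in band else lo + 5
    if mid <= 30:
        return "19-30"
    if mid <= 50:
        return "31-50"
    if mid <= 70:
        return "51-70"
    return "71+"


# ------------------------------------------------------------ share tables

@dataclass
class ShareTable:
    """Counts with percentage shares of their total."""

    rows: pd.DataFrame  # label, count, share_pct
    total: float

    def __post_init__(self):
        if self.total <= 0:
            raise ConfigurationError("share table requires a positive total")
        # internal consistency: every printed share re-derives from count/total
        for _, r in self.rows.iterrows():
            expect = round_half_away(100.0 * r["count"] / self.total, self._decimals(r))
            if abs(r["share_pct"] - expect) > 1e-9:
                raise AssertionError(f"share/count mismatch in row {r['label']}")

    @staticmethod
    def _decimals(row):
        return int(row.get("decimals", 0))


def _make_share_table(pairs, total, decimals=0) -> ShareTable:
    rows = pd.DataFrame([
        {"label": lab, "count": cnt,
         "share_pct": round_half_away(100.0 * cnt / total, decimals),
         "decimals": decimals}
        for lab, cnt in pairs
    ])
    return ShareTable(rows=rows, total=total)


def impact_shares(result: PrimeResult, group_by: str, decimals: int = 0) -> ShareTable:
    """Share breakdown of deaths averted by cause, sex, under-75 age, or factor."""
    total = result.totals["total"][0]
    if total <= 0:
        raise ConfigurationError("cannot compute shares of a nonpositive total")
    if group_by == "cause":
        pairs = [(k.removeprefix("cause:"), v[0])
                 for k, v in result.totals.items() if k.startswith("cause:")]
    elif group_by == "sex":
        pairs = [(s, result.totals[f"sex:{s}"][0]) for s in SEXES]
    elif group_by in ("age<75", "age"):
        u75 = result.totals["under_75"][0]
        pairs = [("<75", u75), ("75+", total - u75)]
    elif group_by == "factor":
        by_f: dict[str, float] = {}
        for imp in result.impacts:
            for f, v in imp.by_factor.items():
                by_f[f] = by_f.get(f, 0.0) + v
        pairs = sorted(by_f.items())
    else:
        raise ConfigurationError(f"unknown grouping {group_by!r}")
    pairs = sorted(pairs, key=lambda t: -t[1])
    return _make_share_table(pairs, total, decimals)


def percent_of_total_deaths(
    result: PrimeResult, mortality: pd.DataFrame
) -> dict[str, float]:
    """Deaths averted as a percentage of all diet-related NCD deaths.

    Returns the overall percentage and per-sex percentages, one-decimal
    half-away-from-zero rounding.
    """
    total_deaths = float(mortality["deaths"].sum())
    if total_deaths <= 0:
        raise ConfigurationError("mortality table has no deaths")
    out = {"overall": round_half_away(100.0 * result.totals["total"][0] / total_deaths, 1)}
    for s in SEXES:
        sex_deaths = float(mortality.loc[mortality["sex"] == s, "deaths"].sum())
        if sex_deaths > 0:
            out[s] = round_half_away(
                100.0 * result.totals[f"sex:{s}"][0] / sex_deaths, 1
            )
    return out


# ---------------------------------------------------------- scenario table

def scenario_table(
    estimates: dict[str, list[UsualEstimate]], baseline_key: str = "baseline"
) -> pd.DataFrame:
    """Baseline vs counterfactual usual means, deltas and significance.

    One row per nutrient (overall stratum): baseline mean (SE), then per
    scenario the mean (SE), the delta computed from unrounded means, and
    a star when the 95% CIs are disjoint.
    """
    if baseline_key not in estimates:
        raise ConfigurationError("baseline estimates required")
    base = {e.nutrient: e for e in estimates[baseline_key] if e.stratum == "overall"}
    scen_keys = [k for k in estimates if k != baseline_key]
    rows = []
    for nutrient in base:
        row = {"nutrient": nutrient,
               "baseline_mean": base[nutrient].mean, "baseline_se": base[nutrient].se}
        for k in scen_keys:
            cf = {e.nutrient: e for e in estimates[k] if e.stratum == "overall"}.get(nutrient)
            if cf is None:
                import warnings

                warnings.warn(f"scenario {k} has no estimate for {nutrient}; "
                              "column left blank", stacklevel=2)
                row[f"{k}_mean"] = np.nan
                row[f"{k}_delta"] = np.nan
                row[f"{k}_significant"] = False
                continue
            delta, sig = compare_scenarios(base[nutrient], cf)
            row[f"{k}_mean"] = cf.mean
            row[f"{k}_se"] = cf.se
            row[f"{k}_delta"] = delta
            row[f"{k}_significant"] = sig
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------- exposure input assembly

def build_exposure_baseline(
    respondents: pd.DataFrame,
    fiber_by_stratum: dict[str, tuple[float, float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline exposure distributions and stratum mean heights per band.

    BMI means/SDs come from the respondent table per DRI age-sex group
    (log-normal shape); systolic blood pressure and serum cholesterol
    use conventional age-graded population values (normal shape); fiber
    means/SDs are the usual-intake estimates passed in. DRI-group values
    are broadcast to each five-year band via the band midpoint.
    """
    rows, heights = [], []
    for s in SEXES:
        for band in AGE_BANDS:
            g = dri_group_of_band(band)
            sub = respondents[(respondents["sex"] == s) & (respondents["dri_group"] == g)]
            if sub.empty:
                raise ConfigurationError(f"no respondents in stratum {s}|{g}")
            w = sub["survey_weight"].to_numpy()
            bmi_m = float(np.average(sub["bmi"], weights=w))
            bmi_sd = float(np.sqrt(np.average((sub["bmi"] - bmi_m) ** 2, weights=w)))
            heights.append({"sex": s, "age_band": band,
                            "height_m": float(np.average(sub["height_m"], weights=w))})
            mid = band_lower_age(band) + 2.5
            fiber_m, fiber_sd = fiber_by_stratum[f"{s}|{g}"]
            rows += [
                {"sex": s, "age_band": band, "factor": "bmi",
                 "mean": bmi_m, "sd": bmi_sd, "shape": "lognormal"},
                {"sex": s, "age_band": band, "factor": "sbp",
                 "mean": 105.0 + 0.35 * mid, "sd": 14.0, "shape": "normal"},
                {"sex": s, "age_band": band, "factor": "cholesterol",
                 "mean": 4.3 + 0.01 * mid, "sd": 1.0, "shape": "normal"},
                {"sex": s, "age_band": band, "factor": "fiber",
                 "mean": fiber_m, "sd": max(fiber_sd, 1e-6), "shape": "normal"},
            ]
    return pd.DataFrame(rows), pd.DataFrame(heights)


def _stratum_usual_sd(model) -> dict[str, float]:
    person = usual_person_values(model)
    out = {}
    for s in SEXES:
        for g in DRI_GROUPS:
            sub = person[(person["sex"] == s) & (person["dri_group"] == g)]
            if len(sub) > 1:
                m = np.average(sub["usual"], weights=sub["weight"])
                out[f"{s}|{g}"] = float(
                    np.sqrt(np.average((sub["usual"] - m) ** 2, weights=sub["weight"]))
                )
    return out


# ----------------------------------------------------------- full pipeline

@dataclass
class PipelineConfig:
    """End-to-end run configuration: stages, sizes and seeds."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    scenario_fractions: tuple[float, ...] = (0.30, 0.50, 0.70, 1.00)
    n_boot: int = 500
    n_iter: int = 10_000
    seed: int = 0
    strict_eligibility: bool = False
    aggregation: str = "mean"
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    pathway_params: PathwayParams = field(default_factory=default_pathway_params)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "synth" in raw:
            kw["synth"] = SynthConfig(**{
                k: (tuple(v) if isinstance(v, list) else v) for k, v in raw["synth"].items()
            })
        for key in ("scenario_fractions",):
            if key in raw:
                kw[key] = tuple(raw[key])
        for key in ("n_boot", "n_iter", "seed", "strict_eligibility", "aggregation"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


@dataclass
class PipelineResult:
    """Everything one end-to-end run produces."""

    tables: dict[str, pd.DataFrame]
    estimates: dict[str, list[UsualEstimate]]
    prime_results: dict[str, PrimeResult]
    shares: dict[str, ShareTable]
    pct_of_total_deaths: dict[str, dict[str, float]]
    manifest: dict


def _derive_seed(master: int, idx: int) -> int:
    return int(np.random.SeedSequence([int(master) % (2**31), idx]).generate_state(1)[0] % (2**31))


def run_full_pipeline(config: PipelineConfig, out_dir=None, log=None) -> PipelineResult:
    """Execute synth -> classify -> match -> scenarios -> usual intake ->
    risk assessment -> report, deterministically under ``config``.

    When ``out_dir`` is given, all tables plus a manifest (seeds, row
    counts, bundle hash) are written there; reruns with an identical
    config produce bit-identical bundles.
    """
    t_start = time.time()
    stages = []

    def _log(stage, **info):
        stages.append({"stage": stage, "t": round(time.time() - t_start, 2), **info})
        if log:
            log(f"[{stage}] {info}")

    cfg = config.synth
    foods, branded = generate_food_db(cfg)
    respondents, recalls, truth = generate_population(cfg, foods)
    mortality, population = generate_mortality_tables(cfg)
    _log("synth", foods=len(foods), branded=len(branded),
         respondents=len(respondents), recalls=len(recalls))

    symbols, high_share = classify_table(foods, config.policy)
    b_symbols, _ = classify_table(branded, config.policy)
    _log("classify", high_in_share=round(high_share, 4))

    alternative_sets = find_all_alternatives(
        foods, symbols, branded, b_symbols, config.policy, config.aggregation
    )
    match_summary = summarize_matching(foods, alternative_sets)
    _log("match", matched=len(alternative_sets))

    base_items = attach_nutrients(recalls, foods)
    base_totals = daily_totals(base_items)
    mis = misreporting_status(
        respondents, base_totals.groupby("respondent_id")["energy_kcal"].mean()
    )

    eligible = eligible_respondents(
        recalls, symbols, alternative_sets, require_alternative=config.strict_eligibility
    )
    scen_totals = {"baseline": base_totals}
    scen_meta = {}
    for i, frac in enumerate(config.scenario_fractions):
        name = f"S{i + 1}"
        spec = ScenarioSpec(name=name, fraction=frac,
                            seed=_derive_seed(config.seed, 100 + i))
        selected = select_participants(eligible, spec)
        cf_items = apply_substitution(base_items, selected, alternative_sets)
        scen_totals[name] = daily_totals(cf_items)
        scen_meta[name] = {"fraction": frac, "seed": spec.seed,
                           "n_eligible": len(eligible), "n_selected": len(selected)}
    _log("scenarios", **{k: v["n_selected"] for k, v in scen_meta.items()})

    estimates: dict[str, list[UsualEstimate]] = {}
    fiber_sd = {}
    fiber_models = {}
    for key, totals in scen_totals.items():
        ests = []
        for j, nutrient in enumerate(NUTRIENTS):
            frame = prepare_model_frame(totals, respondents, nutrient, mis)
            model = fit_amount_model(frame, nutrient)
            ests += estimate_usual_means(
                model, n_boot=config.n_boot, seed=_derive_seed(config.seed, 200 + j)
            )
            if nutrient == "fiber":
                fiber_models[key] = model
        estimates[key] = ests
    _log("usual_intake", scenarios=len(estimates))

    fiber_sd = _stratum_usual_sd(fiber_models["baseline"])
    fiber_means = {e.stratum: e.mean for e in estimates["baseline"]
                   if e.nutrient == "fiber" and e.stratum != "overall"}
    fiber_by_stratum = {
        k: (m, fiber_sd.get(k, 1e-6)) for k, m in fiber_means.items()
    }
    baseline_dists, heights = build_exposure_baseline(respondents, fiber_by_stratum)

    def _stratum_means(key, nutrient):
        return {e.stratum: e.mean for e in estimates[key] if e.nutrient == nutrient}

    prime_results: dict[str, PrimeResult] = {}
    table3_rows = []
    shares: dict[str, ShareTable] = {}
    pct_ctx: dict[str, dict[str, float]] = {}
    for i, name in enumerate(scen_meta):
        shift_rows = []
        for s in SEXES:
            for band in AGE_BANDS:
                g = f"{s}|{dri_group_of_band(band)}"
                row = {"sex": s, "age_band": band}
                for nutrient, col in (("energy", "energy"), ("sodium", "sodium"),
                                      ("satfat_pctTE", "satfat_pctTE"), ("fiber", "fiber")):
                    row[col] = _stratum_means(name, nutrient).get(g, np.nan) - \
                        _stratum_means("baseline", nutrient).get(g, np.nan)
                shift_rows.append(row)
        shifts = pd.DataFrame(shift_rows)
        cf_dists = mediate(shifts, heights, baseline_dists, config.pathway_params)
        res = run_prime(
            mortality, baseline_dists, cf_dists, config.pathway_params,
            n_iter=config.n_iter, seed=_derive_seed(config.seed, 300 + i),
        )
        prime_results[name] = res
        att = attribute_by_factor(
            mortality, baseline_dists, cf_dists, config.pathway_params,
            n_iter=config.n_iter, seed=_derive_seed(config.seed, 300 + i),
        )
        att.insert(0, "scenario", name)
        table3_rows.append(att)
        for grouping in ("cause", "sex", "age"):
            try:
                shares[f"{name}:{grouping}"] = impact_shares(res, grouping)
            except ConfigurationError:
                pass
        pct_ctx[name] = percent_of_total_deaths(res, mortality)
        _log(f"prime:{name}", total=round(res.total(), 1))

    table2 = scenario_table(estimates)
    table3 = pd.concat(table3_rows, ignore_index=True)

    usual_rows = []
    for key, ests in estimates.items():
        for e in ests:
            usual_rows.append({
                "scenario": key, "stratum": e.stratum, "nutrient": e.nutrient,
                "mean": e.mean, "se": e.se, "lo": e.ci95[0], "hi": e.ci95[1],
                "n": e.n, "stable": e.stable,
            })
    usual_df = pd.DataFrame(usual_rows)

    impact_rows = []
    for name, res in prime_results.items():
        t = res.table.copy()
        t.insert(0, "scenario", name)
        impact_rows.append(t)
    impacts_df = pd.concat(impact_rows, ignore_index=True)

    tables = {
        "foods": foods, "branded": branded, "respondents": respondents,
        "recalls": recalls, "deaths": mortality, "population": population,
        "symbols": symbols, "match_summary": match_summary,
        "usual_intakes": usual_df, "impacts": impacts_df,
        "table1": match_summary, "table2": table2, "table3": table3,
    }
    for key, st in shares.items():
        tables[f"shares_{key.replace(':', '_')}"] = st.rows

    manifest = {
        "seed": config.seed,
        "scenario_fractions": list(config.scenario_fractions),
        "n_boot": config.n_boot, "n_iter": config.n_iter,
        "scenarios": scen_meta,
        "high_in_share": high_share,
        "n_matched_foods": len(alternative_sets),
        "pct_of_total_deaths": pct_ctx,
        "row_counts": {k: len(v) for k, v in tables.items()},
        "stages": stages,
    }

    if out_dir is not None:
        paths = _io.write_tables(tables, out_dir)
        manifest["bundle_sha256"] = _io.bundle_hash(paths.values())
        _io.write_manifest(manifest, out_dir)

    return PipelineResult(
        tables=tables, estimates=estimates, prime_results=prime_results,
        shares=shares, pct_of_total_deaths=pct_ctx, manifest=manifest,
    )
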