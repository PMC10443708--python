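"""Healthier-alternative matching between generic foods and branded products.

A branded product is a *healthier alternative* to a generic consumed food
when it shares the food's minor category and would display strictly fewer
'high in' symbols ("at least one less"). The nutrient profiles of all
alternatives of a food are aggregated (arithmetic mean per 100 g by
default, median by option) into the substitution profile used by the
counterfactual scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import DataError, SymbolProfile, ThresholdPolicy, classify
from .synth import NUTRIENT_COLS

__all__ = ["AlternativeSet", "find_alternatives", "find_all_alternatives", "summarize_matching"]


@dataclass
class AlternativeSet:
    """Healthier branded alternatives of one generic food."""

    fid_id: str
    alternatives: list[str]
    aggregate_profile: dict[str, float]  # per-100 g means over members
    n_alternatives: int = 0
    #: symbol count of the aggregate profile itself, re-classified with the
    #: generic food's reference amount (may exceed members' counts when the
    #: members reduce different symbols)
    aggregate_symbol_count: int | None = None

    def __post_init__(self):
        if not self.alternatives:
            raise ValueError("an AlternativeSet requires at least one alternative")
        self.n_alternatives = len(self.alternatives)


def _aggregate(profiles: pd.DataFrame, how: str) -> dict[str, float]:
    if how == "median":
        agg = profiles[NUTRIENT_COLS].median()
    else:
        agg = profiles[NUTRIENT_COLS].mean()
    return {c: float(agg[c]) for c in NUTRIENT_COLS}


def find_alternatives(
    fid_food,
    branded_table: pd.DataFrame,
    branded_symbols: pd.DataFrame,
    policy: ThresholdPolicy = ThresholdPolicy(),
    food_symbol_count: int | None = None,
    aggregation: str = "mean",
) -> AlternativeSet | None:
    """Healthier alternatives of one generic food, or ``None``.

    Returns every branded product in the food's minor category with
    strictly fewer 'high in' symbols than the food itself; ``None`` when
    the food is exempt, displays no symbol, or no such product exists.
    """
    if food_symbol_count is None:
        profile = classify(fid_food, policy)
        if profile.exempt:
            return None
        food_symbol_count = profile.count
    if food_symbol_count < 1:
        return None

    cands = branded_table[branded_table["minor_category"] == fid_food["minor_category"]]
    if cands.empty:
        return None
    sym = branded_symbols.set_index("branded_id").loc[cands["branded_id"]]
    keep = (~sym["exempt"].to_numpy(bool)) & (
        sym["count"].to_numpy(int) < food_symbol_count
    )
    members = cands[keep]
    if members.empty:
        return None

    agg = _aggregate(members, aggregation)
    agg_food = dict(agg)
    agg_food["reference_amount_g"] = fid_food["reference_amount_g"]
    agg_count = classify(agg_food, policy).count
    if agg_count >= food_symbol_count:
        warnings.warn(
            f"aggregate profile of {fid_food['food_id']} does not itself display "
            f"fewer symbols ({agg_count} vs {food_symbol_count}); members reduce "
            "different symbols",
            stacklevel=2,
        )
    return AlternativeSet(
        fid_id=fid_food["food_id"],
        alternatives=members["branded_id"].tolist(),
        aggregate_profile=agg,
        aggregate_symbol_count=agg_count,
    )


def find_all_alternatives(
    foods: pd.DataFrame,
    food_symbols: pd.DataFrame,
    branded_table: pd.DataFrame,
    branded_symbols: pd.DataFrame,
    policy: ThresholdPolicy = ThresholdPolicy(),
    aggregation: str = "mean",
) -> dict[str, AlternativeSet]:
    """Vectorized :func:`find_alternatives` over a whole food table."""
    fs = food_symbols.set_index("food_id")
    bs = branded_symbols.set_index("branded_id")
    branded = branded_table.assign(
        _count=bs.loc[branded_table["branded_id"], "count"].to_numpy(int),
        _exempt=bs.loc[branded_table["branded_id"], "exempt"].to_numpy(bool),
    )
    by_minor = {k: g for k, g in branded.groupby("minor_category")}

    out: dict[str, AlternativeSet] = {}
    counts = fs.loc[foods["food_id"], "count"].to_numpy(int)
    exempt = fs.loc[foods["food_id"], "exempt"].to_numpy(bool)
    for i, (_, food) in enumerate(foods.iterrows()):
        if exempt[i] or counts[i] < 1:
            continue
        g = by_minor.get(food["minor_category"])
        if g is None:
            continue
        members = g[(~g["_exempt"]) & (g["_count"] < counts[i])]
        if members.empty:
            continue
        agg = _aggregate(members, aggregation)
        agg_food = dict(agg)
        agg_food["reference_amount_g"] = food["reference_amount_g"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            agg_count = classify(agg_food, policy).count
        out[food["food_id"]] = AlternativeSet(
            fid_id=food["food_id"],
            alternatives=members["branded_id"].tolist(),
            aggregate_profile=agg,
            aggregate_symbol_count=agg_count,
        )
    return out


def _round1(x: float) -> float:
    # half away from zero, one decimal
    return float(np.sign(x) * np.floor(abs(x) * 10 + 0.5) / 10)


def summarize_matching(
    foods: pd.DataFrame, alternative_sets: dict[str, AlternativeSet]
) -> pd.DataFrame:
    """Coverage summary per major food category and grand total.

    For each major category: number of generic foods, number (and %) with
    at least one healthier alternative, number of branded alternatives,
    and the mean (min-max) number of branded alternatives per matched
    food, rounded to one decimal.
    """
    matched_ids = set(alternative_sets)
    rows = []
    groups = list(foods.groupby("major_category")) + [("Grand total", foods)]
    for label, g in groups:
        ids = g["food_id"]
        matched = [alternative_sets[i] for i in ids if i in matched_ids]
        n_matched = len(matched)
        sizes = [m.n_alternatives for m in matched]
        n_alt = int(sum(sizes))
        rows.append({
            "major_category": label,
            "n_foods": int(len(g)),
            "n_matched": n_matched,
            "pct_matched": _round1(100.0 * n_matched / len(g)) if len(g) else float("nan"),
            "n_alternative_products": n_alt,
            "mean_alternatives_per_matched": _round1(n_alt / n_matched) if n_matched else 0.0,
            "min_alternatives": int(min(sizes)) if sizes else 0,
            "max_alternatives": int(max(sizes)) if sizes else 0,
        })
    return pd.DataFrame(rows)
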