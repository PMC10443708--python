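"""Counterfactual food-substitution scenarios.

For a randomly selected fraction of eligible respondents (those who
consumed at least one 'high in' food on either recall day), every recall
item whose food has a healthier-alternative set gets that set's
aggregate per-100 g nutrient values for energy, sodium, total sugars,
saturated fat and fiber — gram amounts never change. Scenario fractions
follow consumer-response evidence: 30%, 50%, 70%, and 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matching import AlternativeSet
from .synth import NUTRIENT_COLS

__all__ = [
    "ScenarioSpec",
    "ScenarioError",
    "attach_nutrients",
    "eligible_respondents",
    "select_participants",
    "apply_substitution",
    "daily_totals",
]

#: Atwater energy factor for fat, kcal per gram
FAT_KCAL_PER_G = 9.0


class ScenarioError(ValueError):
    """Invalid scenario specification or empty eligible set."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A named substitution scenario: fraction of eligible respondents."""

    name: str
    fraction: float
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fraction <= 1):
            raise ScenarioError(f"scenario fraction must lie in (0,1], got {self.fraction}")


def attach_nutrients(recalls: pd.DataFrame, foods: pd.DataFrame) -> pd.DataFrame:
    """Join per-100 g nutrient columns of each item's food onto the recalls."""
    cols = ["food_id"] + NUTRIENT_COLS
    out = recalls.merge(foods[cols], on="food_id", how="left", validate="m:1")
    missing = out[NUTRIENT_COLS].isna().any(axis=1)
    if missing.any():
        bad = out.loc[missing, "food_id"].unique().tolist()
        raise ScenarioError(f"recall items reference unknown foods: {bad[:5]}")
    return out


def eligible_respondents(
    recalls: pd.DataFrame,
    symbols: pd.DataFrame,
    alternative_sets: dict[str, AlternativeSet] | None = None,
    require_alternative: bool = False,
) -> set[str]:
    """Respondents who consumed >= 1 'high in' food on any recall day.

    Eligibility counts 'high in' consumption regardless of whether an
    alternative exists (substitution later applies only where one does);
    ``require_alternative=True`` switches to the strict reading where
    only substitutable consumption qualifies.
    """
    high = set(symbols.loc[(symbols["count"] >= 1) & (~symbols["exempt"]), "food_id"])
    if require_alternative:
        if alternative_sets is None:
            raise ScenarioError("strict eligibility requires the alternative sets")
        high &= set(alternative_sets)
    mask = recalls["food_id"].isin(high)
    return set(recalls.loc[mask, "respondent_id"])


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def select_participants(eligible: set[str], spec: ScenarioSpec) -> set[str]:
    """Simple random sample (without replacement) of the eligible set.

    Sample size is ``round(fraction x |eligible|)`` with half-away-from-
    zero rounding; deterministic under ``spec.seed``; fraction 1 returns
    the full set.
    """
    if not eligible:
        raise ScenarioError("eligible set is empty")
    if spec.fraction >= 1.0:
        return set(eligible)
    ids = sorted(eligible)
    k = _round_half_away(spec.fraction * len(ids))
    rng = np.random.default_rng([int(spec.seed) % (2**31), 11])
    chosen = rng.choice(len(ids), size=k, replace=False)
    return {ids[i] for i in chosen}


def apply_substitution(
    recalls_with_nutrients: pd.DataFrame,
    selected: set[str],
    alternative_sets: dict[str, AlternativeSet],
) -> pd.DataFrame:
    """Counterfactual recalls: replace nutrient composition, keep grams.

    For selected respondents only, every item whose food has an
    alternative set receives the set's aggregate per-100 g values for the
    five substituted quantities. All other items, and all columns other
    than the five nutrient columns, are unchanged. Idempotent.
    """
    out = recalls_with_nutrients.copy()
    if not selected or not alternative_sets:
        return out
    mask = out["respondent_id"].isin(selected) & out["food_id"].isin(alternative_sets)
    if not mask.any():
        return out
    sub_foods = out.loc[mask, "food_id"]
    profile = pd.DataFrame(
        {fid: s.aggregate_profile for fid, s in alternative_sets.items()}
    ).T
    for col in NUTRIENT_COLS:
        out.loc[mask, col] = profile.loc[sub_foods, col].to_numpy()
    return out


def daily_totals(recalls_with_nutrients: pd.DataFrame) -> pd.DataFrame:
    """Per respondent-day totals of the pipeline quantities.

    Returns energy (kcal), sodium (mg), sugars (g), saturated fat (g),
    saturated fat as % of total energy (Atwater 9 kcal/g; NaN when the
    day's energy is 0), and fiber (g), with the day's weekend and
    sequence indicators carried through.
    """
    df = recalls_with_nutrients
    if (df["grams"] < 0).any():
        raise ScenarioError("negative gram amounts in recalls")
    work = df[["respondent_id", "day", "sequence", "weekend"]].copy()
    for col in NUTRIENT_COLS:
        work[col] = df["grams"].to_numpy() * df[col].to_numpy() / 100.0
    totals = (
        work.groupby(["respondent_id", "day", "sequence", "weekend"], as_index=False)[
            NUTRIENT_COLS
        ].sum()
    )
    energy = totals["energy_kcal"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(
            energy > 0, totals["satfat_g"] * FAT_KCAL_PER_G / energy * 100.0, np.nan
        )
    totals["satfat_pctTE"] = pct
    return totals
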