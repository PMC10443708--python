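"""'High in' front-of-package symbol classification.

Packaged foods that meet or exceed percent-daily-value thresholds for
sodium, total sugars, or saturated fat must display a 'high in' nutrition
symbol. The rules are expressed against a regulated *reference amount*
(RA) per food category:

* general foods: nutrient content in the RA (or the serving of stated
  size, whichever is larger) at or above 15% of the daily value (DV);
* main dishes with RA >= 200 g: threshold raised to 30% DV;
* small-RA foods (RA <= 30 g): evaluated per 50 g instead of the RA.

Every constant lives in :class:`ThresholdPolicy` and can be overridden;
the defaults encode a simplified reading of the 2022 Canadian
regulations. Energy and fiber are never symbol nutrients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdPolicy",
    "SymbolProfile",
    "SYMBOL_NUTRIENTS",
    "evaluation_basis",
    "classify",
    "classify_table",
]

#: the three nutrients that can trigger a 'high in' symbol, with the food
#: table columns holding their per-100 g amounts
SYMBOL_NUTRIENTS = {
    "sodium": "sodium_mg",
    "sugars": "sugars_g",
    "satfat": "satfat_g",
}

# relative slack so that amounts constructed to sit exactly on a threshold
# are flagged despite float round-trip error ("meet or exceed")
_BOUNDARY_RTOL = 1e-9


class DataError(ValueError):
    """Raised for invalid food records (missing nutrients, bad RA)."""


@dataclass(frozen=True)
class ThresholdPolicy:
    """Threshold rules for 'high in' symbol assignment.

    Parameters
    ----------
    daily_values
        Reference daily amounts per nutrient, in the units of the food
        table columns (sodium mg, sugars g, saturated fat g).
    general_frac
        %DV threshold for ordinary foods (default 15%).
    main_dish_frac
        %DV threshold for main dishes (default 30%).
    main_dish_min_ra_g
        Minimum reference amount for a food to be treated as a main
        dish (default 200 g).
    small_ra_max_g, small_ra_eval_basis_g
        Foods with RA <= ``small_ra_max_g`` (default 30 g) are evaluated
        per ``small_ra_eval_basis_g`` (default 50 g).
    exempt_categories
        Category labels whose foods never display a symbol.
    """

    daily_values: Mapping[str, float] = field(
        default_factory=lambda: {"sodium": 2300.0, "sugars": 100.0, "satfat": 20.0}
    )
    general_frac: float = 0.15
    main_dish_frac: float = 0.30
    main_dish_min_ra_g: float = 200.0
    small_ra_max_g: float = 30.0
    small_ra_eval_basis_g: float = 50.0
    exempt_categories: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not (0 < self.general_frac <= self.main_dish_frac <= 1):
            raise ValueError("require 0 < general_frac <= main_dish_frac <= 1")
        if any(v <= 0 for v in self.daily_values.values()):
            raise ValueError("daily values must be positive")
        object.__setattr__(self, "exempt_categories", frozenset(self.exempt_categories))

    @classmethod
    def from_yaml(cls, path) -> "ThresholdPolicy":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "exempt_categories" in raw:
            raw["exempt_categories"] = frozenset(raw["exempt_categories"])
        return cls(**raw)


@dataclass(frozen=True)
class SymbolProfile:
    """The 'high in' flags of one food and their count."""

    high_sodium: bool
    high_sugars: bool
    high_satfat: bool
    exempt: bool = False

    def __post_init__(self):
        if self.exempt and (self.high_sodium or self.high_sugars or self.high_satfat):
            raise ValueError("exempt foods carry no symbols")

    @property
    def count(self) -> int:
        return int(self.high_sodium) + int(self.high_sugars) + int(self.high_satfat)


EXEMPT_PROFILE = SymbolProfile(False, False, False, exempt=True)


def _ra_of(food) -> float:
    ra = float(food["reference_amount_g"])
    if not np.isfinite(ra) or ra <= 0:
        raise DataError(f"nonpositive reference amount: {ra!r}")
    return ra


def evaluation_basis(food, policy: ThresholdPolicy = ThresholdPolicy()) -> float:
    """Grams of food against which thresholds are evaluated.

    Small-RA foods (RA <= ``small_ra_max_g``) are assessed per
    ``small_ra_eval_basis_g``; otherwise the basis is the reference
    amount or the stated serving size, whichever is larger.
    """
    ra = _ra_of(food)
    if ra <= policy.small_ra_max_g:
        return policy.small_ra_eval_basis_g
    serving = food.get("serving_size_g") if hasattr(food, "get") else None
    if serving is not None and np.isfinite(serving) and serving > 0:
        return max(ra, float(serving))
    return ra


def _is_exempt(food, policy: ThresholdPolicy) -> bool:
    if hasattr(food, "get") and bool(food.get("exempt", False)):
        return True
    for key in ("minor_category", "major_category", "category"):
        if hasattr(food, "get") and food.get(key) in policy.exempt_categories:
            return True
    return False


def classify(food, policy: ThresholdPolicy = ThresholdPolicy()) -> SymbolProfile:
    """Assign the 'high in' symbol profile of a single food.

    ``food`` is any mapping (dict, Series) with per-100 g nutrient columns
    ``sodium_mg``, ``sugars_g``, ``satfat_g`` and a ``reference_amount_g``.
    The comparison is "meet or exceed" (>=).
    """
    if _is_exempt(food, policy):
        return EXEMPT_PROFILE
    ra = _ra_of(food)
    basis = evaluation_basis(food, policy)
    frac = policy.main_dish_frac if ra >= policy.main_dish_min_ra_g else policy.general_frac
    flags = {}
    for nutrient, col in SYMBOL_NUTRIENTS.items():
        per100 = food[col]
        if per100 is None or not np.isfinite(per100):
            raise DataError(f"missing {nutrient} value for food {food.get('food_id', '?')}")
        if per100 < 0:
            raise DataError(f"negative {nutrient} value for food {food.get('food_id', '?')}")
        amount = per100 * basis / 100.0
        threshold = frac * policy.daily_values[nutrient]
        flags[nutrient] = bool(amount >= threshold * (1 - _BOUNDARY_RTOL))
    return SymbolProfile(flags["sodium"], flags["sugars"], flags["satfat"])


def classify_table(
    foods: pd.DataFrame, policy: ThresholdPolicy = ThresholdPolicy()
) -> tuple[pd.DataFrame, float]:
    """Vectorized classification of a food or branded-product table.

    Returns a symbols table indexed like ``foods`` with columns
    ``food_id, high_sodium, high_sugars, high_satfat, count, exempt``, and
    the share of non-exempt foods displaying at least one symbol (NaN with
    a warning if the table is empty or wholly exempt).
    """
    id_col = "food_id" if "food_id" in foods.columns else "branded_id"
    if foods.empty:
        warnings.warn("empty food table: high-in share undefined", stacklevel=2)
        cols = [id_col, "high_sodium", "high_sugars", "high_satfat", "count", "exempt"]
        return pd.DataFrame(columns=cols), float("nan")

    ra = foods["reference_amount_g"].to_numpy(float)
    if np.any(~np.isfinite(ra)) or np.any(ra <= 0):
        bad = foods.loc[~np.isfinite(ra) | (ra <= 0), id_col].tolist()
        raise DataError(f"nonpositive reference amount for foods {bad}")

    basis = ra.copy()
    small = ra <= policy.small_ra_max_g
    basis[small] = policy.small_ra_eval_basis_g
    if "serving_size_g" in foods.columns:
        serving = foods["serving_size_g"].to_numpy(float)
        ok = np.isfinite(serving) & (serving > 0) & ~small
        basis[ok] = np.maximum(basis[ok], serving[ok])
    frac = np.where(ra >= policy.main_dish_min_ra_g, policy.main_dish_frac, policy.general_frac)

    if "exempt" in foods.columns:
        exempt = foods["exempt"].to_numpy(bool)
    else:
        exempt = np.zeros(len(foods), bool)
    for key in ("minor_category", "major_category", "category"):
        if key in foods.columns and policy.exempt_categories:
            exempt |= foods[key].isin(policy.exempt_categories).to_numpy()

    out = pd.DataFrame({id_col: foods[id_col].to_numpy()})
    for nutrient, col in SYMBOL_NUTRIENTS.items():
        per100 = foods[col].to_numpy(float)
        if np.any(~np.isfinite(per100) | (per100 < 0)):
            bad = foods.loc[~np.isfinite(per100) | (per100 < 0), id_col].tolist()
            raise DataError(f"missing or negative {nutrient} for foods {bad}")
        amount = per100 * basis / 100.0
        threshold = frac * policy.daily_values[nutrient]
        out[f"high_{nutrient}"] = (amount >= threshold * (1 - _BOUNDARY_RTOL)) & ~exempt
    out["count"] = (
        out[["high_sodium", "high_sugars", "high_satfat"]].sum(axis=1).astype(int)
    )
    out["exempt"] = exempt

    n_nonexempt = int((~exempt).sum())
    if n_nonexempt == 0:
        share = 0.0  # wholly exempt table displays no symbols
    else:
        share = float((out.loc[~exempt, "count"] >= 1).sum() / n_nonexempt)
    return out, share
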