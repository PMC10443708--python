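"""Configuration objects for the synthetic-data generator and pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

__all__ = ["SynthConfig", "ConfigurationError", "DRI_GROUPS", "AGE_BANDS", "SEXES"]

#: Dietary Reference Intake age groups for adults, by lower/upper age
DRI_GROUPS = ("19-30", "31-50", "51-70", "71+")
SEXES = ("M", "F")

#: five-year mortality age bands, 20 through 85+
AGE_BANDS = tuple(
    [f"{lo}-{lo + 4}" for lo in range(20, 85, 5)] + ["85+"]
)


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


def _default_demographics() -> dict:
    # rough adult age structure, split evenly by sex
    age = {"19-30": 0.20, "31-50": 0.34, "51-70": 0.32, "71+": 0.14}
    return {(s, g): w / 2 for s in SEXES for g, w in age.items()}


def _default_lognormal_params() -> dict:
    # symbol nutrients are drawn as log-normal multiples of the applicable
    # 'high in' threshold ("ratio" components); energy and fiber as absolute
    # per-100 g log-normals around category medians
    return {
        "high_ratio": (math.log(2.0), 0.30),
        "low_ratio": (math.log(0.30), 0.40),
        "healthy_ratio": (math.log(0.25), 0.35),
        "energy_kcal": (0.0, 0.35),
        "fiber_g": (math.log(1.2), 0.70),
    }


@dataclass
class SynthConfig:
    """Knobs of the synthetic study world.

    The defaults emulate the empirical structure of the study population:
    roughly a third of foods classifying 'high in' for at least one symbol
    nutrient, healthier branded alternatives covering about a quarter of
    those foods, two 24-h recalls per adult respondent with log-scale
    between- and within-person variation, DRI age-sex demographics with
    heights and BMIs, and cause-by-age-by-sex death counts.
    """

    n_foods: int = 2784
    n_branded: int = 11000
    n_respondents: int = 2000
    frac_high_in_target: float = 0.33
    alt_coverage_target: float = 0.26
    nutrient_lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_lognormal_params
    )
    #: within-person (day) to between-person variance ratio of daily intake,
    #: on the log scale
    within_between_ratio: float = 2.5
    #: between-person log-scale SD of daily energy intake around predicted TEE
    between_person_sd: float = 0.06
    demographic_weights: Mapping[tuple[str, str], float] = field(
        default_factory=_default_demographics
    )
    seed: int = 0

    # food-supply structure
    foods_per_minor_category: int = 8
    exempt_majors: tuple[str, ...] = ("Fruit and fruit juices", "Vegetables")
    healthy_branded_frac: float = 0.7  # within covered minor categories

    # recall structure
    mean_items_per_day: float = 10.0
    gram_jitter_sd: float = 0.40
    weekend_effect: float = 1.05  # multiplicative energy shift on weekend days
    weekend_prob: float = 2.0 / 7.0

    # misreporting plants
    underreport_frac: float = 0.12
    overreport_frac: float = 0.08
    underreport_bias: float = 0.60
    overreport_bias: float = 1.50

    # survey weights
    weight_dispersion: float = 0.0  # log-normal SD; 0 => all weights 1

    # mortality / population world
    total_deaths: float = 92845.0
    total_population: float = 29_000_000.0
    sex_death_weights: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.502, "F": 0.498}
    )
    cause_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "CVD": 0.55,
            "cancer": 0.25,
            "diabetes": 0.10,
            "chronic_renal_failure": 0.05,
            "liver_disease": 0.05,
        }
    )

    # ground-truth nutrient-to-energy ratio estimation (simulated menu days)
    truth_menu_days: int = 4000

    def __post_init__(self):
        for name in ("n_foods", "n_branded", "n_respondents"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ConfigurationError(f"{name} must be a nonnegative integer, got {v!r}")
        for name in ("frac_high_in_target", "alt_coverage_target"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0,1), got {v!r}")
        if self.within_between_ratio < 0:
            raise ConfigurationError("within_between_ratio must be >= 0")
        if self.between_person_sd < 0:
            raise ConfigurationError("between_person_sd must be >= 0")
        total = sum(self.demographic_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ConfigurationError(f"demographic weights must sum to 1, got {total}")
        if any(w < 0 for w in self.demographic_weights.values()):
            raise ConfigurationError("demographic weights must be nonnegative")
        for key, (mu, sigma) in self.nutrient_lognormal_params.items():
            if sigma < 0:
                raise ConfigurationError(f"lognormal sigma for {key} must be >= 0")
        if self.underreport_frac + self.overreport_frac >= 1:
            raise ConfigurationError("misreporting fractions must sum to < 1")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "demographic_weights" in raw:
            raw["demographic_weights"] = {
                (sex, group): w for sex, group, w in raw["demographic_weights"]
            }
        if "nutrient_lognormal_params" in raw:
            raw["nutrient_lognormal_params"] = {
                k: tuple(v) for k, v in raw["nutrient_lognormal_params"].items()
            }
        if "exempt_majors" in raw:
            raw["exempt_majors"] = tuple(raw["exempt_majors"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["demographic_weights"] = [
            [s, g, w] for (s, g), w in self.demographic_weights.items()
        ]
        d["nutrient_lognormal_params"] = {
            k: list(v) for k, v in self.nutrient_lognormal_params.items()
        }
        d["exempt_majors"] = list(self.exempt_majors)
        return d
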