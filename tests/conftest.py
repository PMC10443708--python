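import numpy as np
import pandas as pd
import pytest

from fopl_impact.classify import ThresholdPolicy, classify_table
from fopl_impact.config import SynthConfig
from fopl_impact.matching import find_all_alternatives
from fopl_impact.synth import generate_food_db, generate_mortality_tables, generate_population


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(n_foods=2784, n_branded=8000, n_respondents=400, seed=12345)


@pytest.fixture(scope="session")
def food_db(small_cfg):
    return generate_food_db(small_cfg)


@pytest.fixture(scope="session")
def foods(food_db):
    return food_db[0]


@pytest.fixture(scope="session")
def branded(food_db):
    return food_db[1]


@pytest.fixture(scope="session")
def symbols(foods):
    sym, share = classify_table(foods)
    return sym


@pytest.fixture(scope="session")
def branded_symbols(branded):
    sym, _ = classify_table(branded)
    return sym


@pytest.fixture(scope="session")
def alternative_sets(foods, symbols, branded, branded_symbols):
    return find_all_alternatives(foods, symbols, branded, branded_symbols)


@pytest.fixture(scope="session")
def population(small_cfg, foods):
    return generate_population(small_cfg, foods)


@pytest.fixture(scope="session")
def respondents(population):
    return population[0]


@pytest.fixture(scope="session")
def recalls(population):
    return population[1]


@pytest.fixture(scope="session")
def truth(population):
    return population[2]


@pytest.fixture(scope="session")
def mortality_tables(small_cfg):
    return generate_mortality_tables(small_cfg)


def make_food(
    food_id="F1",
    minor_category="cat #1",
    major_category="cat",
    ra=100.0,
    sodium=0.0,
    sugars=0.0,
    satfat=0.0,
    energy=200.0,
    fiber=1.0,
    exempt=False,
    **extra,
):
    """Hand-built food record for unit tests."""
    rec = {
        "food_id": food_id,
        "major_category": major_category,
        "minor_category": minor_category,
        "reference_amount_g": ra,
        "exempt": exempt,
        "energy_kcal": energy,
        "sodium_mg": sodium,
        "sugars_g": sugars,
        "satfat_g": satfat,
        "fiber_g": fiber,
    }
    rec.update(extra)
    return rec


@pytest.fixture
def toy_food():
    return make_food
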