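"""Comparative risk assessment: mediation, expected RR, PIF, runner."""

import numpy as np
import pandas as pd
import pytest

from fopl_impact.config import AGE_BANDS, ConfigurationError
from fopl_impact.prime import (ExposureDistribution, PathwayParams, RRPathway,
                               attribute_by_factor, combine_pifs,
                               default_pathway_params, expected_rr,
                               expected_rr_closed_form, impact_fraction, mediate,
                               run_prime)


def _dist(factor="sbp", mean=0.0, sd=1.0, shape="normal", sex="M", band="50-54"):
    return ExposureDistribution(sex, band, factor, mean, sd, shape)


def _dist_table(bmi=27.0, sbp=122.0, chol=5.0, fiber=17.0):
    rows = []
    for s in ("M", "F"):
        for b in AGE_BANDS:
            rows += [
                dict(sex=s, age_band=b, factor="bmi", mean=bmi, sd=4.5, shape="lognormal"),
                dict(sex=s, age_band=b, factor="sbp", mean=sbp, sd=15.0, shape="normal"),
                dict(sex=s, age_band=b, factor="cholesterol", mean=chol, sd=1.0,
                     shape="normal"),
                dict(sex=s, age_band=b, factor="fiber", mean=fiber, sd=6.0, shape="normal"),
            ]
    return pd.DataFrame(rows)


def _shift_table(energy=0.0, sodium=0.0, satfat=0.0, fiber=0.0):
    rows = []
    for s in ("M", "F"):
        for b in AGE_BANDS:
            rows.append(dict(sex=s, age_band=b, energy=energy, sodium=sodium,
                             satfat_pctTE=satfat, fiber=fiber))
    return pd.DataFrame(rows)


def _heights(h=1.70):
    return pd.DataFrame([
        dict(sex=s, age_band=b, height_m=h) for s in ("M", "F") for b in AGE_BANDS
    ])


class TestMediate:
    def test_zero_energy_shift_leaves_bmi_unchanged(self):
        base = _dist_table()
        cf = mediate(_shift_table(), _heights(), base, default_pathway_params())
        pd.testing.assert_frame_equal(cf, base)

    def test_energy_to_bmi_arithmetic(self):
        # -220 kcal/day at 22 kcal/kg -> -10 kg; at 1.70 m -> -3.46 BMI
        cf = mediate(_shift_table(energy=-220.0), _heights(1.70), _dist_table(),
                     default_pathway_params())
        d = cf[cf.factor == "bmi"]["mean"].iloc[0] - 27.0
        assert d == pytest.approx(-10.0 / 1.70**2, rel=1e-9)
        assert d == pytest.approx(-3.46, abs=0.01)

    def test_sodium_salt_sbp_conversion(self):
        params = default_pathway_params()
        params.sbp_per_g_salt = {b: 1.0 for b in AGE_BANDS}
        cf = mediate(_shift_table(sodium=-1000.0), _heights(), _dist_table(), params)
        d = cf[cf.factor == "sbp"]["mean"].iloc[0] - 122.0
        assert d == pytest.approx(-2.5)  # 1000 mg sodium = 2.5 g salt

    def test_sd_unchanged(self):
        base = _dist_table()
        cf = mediate(_shift_table(energy=-100, sodium=-300), _heights(), base,
                     default_pathway_params())
        assert (cf["sd"] == base["sd"]).all()

    def test_missing_height_errors(self):
        with pytest.raises(ConfigurationError):
            mediate(_shift_table(energy=-1.0), _heights().iloc[:3], _dist_table(),
                    default_pathway_params())


class TestExpectedRR:
    def test_null_rr_gives_one(self):
        assert expected_rr(_dist(mean=3.0, sd=2.0), 1.0, 1.0, 0.0) == pytest.approx(1.0)

    def test_point_mass(self):
        d = _dist(mean=1.0, sd=0.0)
        assert expected_rr(d, 0.8, 1.0, 0.0) == pytest.approx(0.8)

    def test_lognormal_normal_closed_form(self):
        # normal with mu' = unit, sigma = unit, rr = 2:
        # E[RR] = exp(ln2 + (ln2)^2/2)
        d = _dist(mean=1.0, sd=1.0)
        expect = np.exp(np.log(2) + np.log(2) ** 2 / 2)
        assert expected_rr(d, 2.0, 1.0, 0.0) == pytest.approx(expect, rel=1e-6)

    @pytest.mark.parametrize("mean,sd,rr,unit", [
        (120.0, 15.0, 1.9, 20.0), (27.0, 4.5, 1.4, 5.0), (17.0, 6.0, 0.91, 7.0),
        (5.0, 1.0, 1.25, 1.0), (0.0, 1.0, 2.0, 1.0), (-3.0, 0.5, 0.5, 2.0),
    ])
    def test_quadrature_matches_closed_form(self, mean, sd, rr, unit):
        d = _dist(mean=mean, sd=sd)
        q = expected_rr(d, rr, unit, x_ref=mean - unit)
        c = expected_rr_closed_form(d, rr, unit, x_ref=mean - unit)
        assert q == pytest.approx(c, rel=1e-6)


class TestImpactFraction:
    P = RRPathway("sbp", "CVD", 1.9, 20.0)

    def test_identical_distributions_give_zero(self):
        d = _dist(mean=120.0, sd=15.0)
        assert impact_fraction(d, d, self.P) == pytest.approx(0.0, abs=1e-12)

    def test_ratio_semantics(self):
        # point masses: E[RR] ratio 0.5 -> PIF 0.5
        base = _dist(mean=20.0, sd=0.0)
        cf = _dist(mean=20.0 - 20.0 * np.log(2) / np.log(1.9), sd=0.0)
        assert impact_fraction(base, cf, self.P) == pytest.approx(0.5, rel=1e-9)

    def test_harmful_shift_negative(self):
        base = _dist(mean=120.0, sd=15.0)
        worse = _dist(mean=130.0, sd=15.0)
        assert impact_fraction(base, worse, self.P) < 0

    def test_multiplicative_combination(self):
        pifs = np.array([0.2, 0.1])
        assert combine_pifs(pifs) == pytest.approx(1 - 0.8 * 0.9)


def _single_stratum_world():
    deaths = pd.DataFrame([{"sex": "M", "age_band": "50-54", "cause": "CVD",
                            "deaths": 1000}])
    base = pd.DataFrame([{"sex": "M", "age_band": "50-54", "factor": "sbp",
                          "mean": 20.0, "sd": 0.0, "shape": "normal"}])
    cf = base.copy()
    cf["mean"] = 20.0 - 20.0  # one unit of rr=2 per 20 -> E[RR] ratio 0.5
    params = PathwayParams(pathways=(RRPathway("sbp", "CVD", 2.0, 20.0, 0.05),))
    return deaths, base, cf, params


class TestRunPrime:
    def test_null_counterfactual_zero_everywhere(self):
        deaths, base, _, params = _single_stratum_world()
        res = run_prime(deaths, base, base, params, n_iter=100, seed=0)
        assert res.total() == 0.0
        assert res.totals["total"][1:] == (0.0, 0.0)
        assert all(i.deaths_averted == 0.0 and i.ui95 == (0.0, 0.0)
                   for i in res.impacts)

    def test_closed_form_pif_times_deaths(self):
        deaths, base, cf, params = _single_stratum_world()
        res = run_prime(deaths, base, cf, params, n_iter=100, seed=0)
        assert res.total() == pytest.approx(500.0, rel=1e-9)

    def test_zero_rr_se_collapses_ui(self):
        deaths, base, cf, _ = _single_stratum_world()
        params = PathwayParams(pathways=(RRPathway("sbp", "CVD", 2.0, 20.0, 0.0),))
        res = run_prime(deaths, base, cf, params, n_iter=50, seed=0)
        t = res.totals["total"]
        assert t[1] == pytest.approx(t[0]) and t[2] == pytest.approx(t[0])

    def test_too_few_iterations_rejected(self):
        deaths, base, cf, params = _single_stratum_world()
        with pytest.raises(ConfigurationError):
            run_prime(deaths, base, cf, params, n_iter=1)

    def test_conservation_and_stratum_sums(self, mortality_tables):
        mort, _ = mortality_tables
        base = _dist_table()
        params = default_pathway_params()
        shifts = _shift_table(energy=-150.0, sodium=-400.0, satfat=0.03, fiber=-0.1)
        cf = mediate(shifts, _heights(), base, params)
        res = run_prime(mort, base, cf, params, n_iter=500, seed=2)
        merged = res.table.merge(mort, on=["sex", "age_band", "cause"])
        assert (merged["deaths_averted"].abs() <= merged["deaths"] + 1e-9).all()
        assert res.total() == pytest.approx(res.table["deaths_averted"].sum())
        assert res.totals["sex:M"][0] + res.totals["sex:F"][0] == pytest.approx(res.total())

    def test_monotone_in_shift_scale(self, mortality_tables):
        """Deaths averted never decrease as the (protective) counterfactual
        shift is scaled up."""
        mort, _ = mortality_tables
        base = _dist_table()
        params = default_pathway_params()
        totals = []
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            shifts = _shift_table(energy=-150.0 * alpha, sodium=-400.0 * alpha)
            cf = mediate(shifts, _heights(), base, params)
            res = run_prime(mort, base, cf, params, n_iter=10, seed=0)
            totals.append(res.total())
        assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_ui_stable_across_seeds(self, mortality_tables):
        mort, _ = mortality_tables
        deaths, base, cf, params = _single_stratum_world()
        r1 = run_prime(deaths, base, cf, params, n_iter=10_000, seed=1)
        r2 = run_prime(deaths, base, cf, params, n_iter=10_000, seed=2)
        for i in (1, 2):
            assert abs(r1.totals["total"][i] - r2.totals["total"][i]) \
                / r1.totals["total"][i] < 0.02


class TestAttribution:
    def test_unshifted_factors_exactly_zero(self, mortality_tables):
        mort, _ = mortality_tables
        base = _dist_table()
        params = default_pathway_params()
        cf = mediate(_shift_table(sodium=-500.0), _heights(), base, params)
        att = attribute_by_factor(mort, base, cf, params, n_iter=50, seed=0)
        by = att.set_index("factor")["deaths_averted"]
        assert by["bmi"] == 0.0 and by["cholesterol"] == 0.0 and by["fiber"] == 0.0
        assert by["sbp"] > 0

    def test_harmful_factor_yields_negative_row(self, mortality_tables):
        mort, _ = mortality_tables
        base = _dist_table()
        params = default_pathway_params()
        # saturated fat %TE rising slightly -> cholesterol up -> negative row
        cf = mediate(_shift_table(sodium=-500.0, satfat=0.04), _heights(), base, params)
        att = attribute_by_factor(mort, base, cf, params, n_iter=50, seed=0)
        by = att.set_index("factor")["deaths_averted"]
        assert by["cholesterol"] < 0

    def test_share_arithmetic(self, mortality_tables):
        """Shares print as row/total x 100 rounded half away from zero."""
        mort, _ = mortality_tables
        base = _dist_table()
        params = default_pathway_params()
        cf = mediate(_shift_table(energy=-150.0, sodium=-400.0), _heights(), base, params)
        att = attribute_by_factor(mort, base, cf, params, n_iter=10, seed=0)
        total = att.set_index("factor")["deaths_averted"]["total"]
        for _, row in att.iterrows():
            if row["factor"] in ("total", "residual_vs_sum_of_singles"):
                continue
            expect = 100.0 * row["deaths_averted"] / total
            expect = np.sign(expect) * np.floor(abs(expect) + 0.5)
            assert row["share_pct"] == expect
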