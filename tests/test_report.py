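"""Report surfaces: shares, context percentages, tables, full pipeline."""

import warnings

import numpy as np
import pandas as pd
import pytest

from fopl_impact.config import ConfigurationError, SynthConfig
from fopl_impact.report import (PipelineConfig, dri_group_of_band, impact_shares,
                                percent_of_total_deaths, round_half_away,
                                run_full_pipeline, scenario_table)
from fopl_impact.usual_intake import UsualEstimate


class TestRounding:
    @pytest.mark.parametrize("x,d,expect", [
        (2.5, 0, 3.0), (-2.5, 0, -3.0), (2.25, 1, 2.3), (-2.25, 1, -2.3),
        (0.049, 1, 0.0), (36.36, 1, 36.4),
    ])
    def test_half_away_from_zero(self, x, d, expect):
        assert round_half_away(x, d) == expect


class TestDriMapping:
    @pytest.mark.parametrize("band,group", [
        ("20-24", "19-30"), ("25-29", "19-30"), ("30-34", "31-50"),
        ("45-49", "31-50"), ("50-54", "51-70"), ("65-69", "51-70"),
        ("70-74", "71+"), ("85+", "71+"),
    ])
    def test_band_midpoint_assignment(self, band, group):
        assert dri_group_of_band(band) == group


class _FakeResult:
    """Minimal stand-in exposing the totals/impacts surface of a risk run."""

    def __init__(self, totals, impacts=()):
        self.totals = totals
        self.impacts = impacts


class TestShares:
    def _result(self):
        return _FakeResult({
            "total": (2148.0, 1913.0, 2386.0),
            "under_75": (782.0, 695.0, 866.0),
            "sex:M": (1203.0, 1064.0, 1343.0),
            "sex:F": (945.0, 832.0, 1068.0),
            "cause:CVD": (1499.0, 1284.0, 1716.0),
            "cause:diabetes": (293.0, 225.0, 353.0),
            "cause:cancer": (187.0, 145.0, 229.0),
            "cause:liver_disease": (113.0, 70.0, 154.0),
            "cause:chronic_renal_failure": (56.0, 29.0, 88.0),
        })

    def test_sex_share_rounds_to_integer_percent(self):
        st = impact_shares(self._result(), "sex")
        male = st.rows.set_index("label").loc["M"]
        assert male["share_pct"] == 56.0  # 1203 / 2148

    def test_under75_share_one_decimal(self):
        st = impact_shares(self._result(), "age", decimals=1)
        u75 = st.rows.set_index("label").loc["<75"]
        assert u75["share_pct"] == 36.4  # 782 / 2148

    def test_cause_share(self):
        st = impact_shares(self._result(), "cause", decimals=1)
        cvd = st.rows.set_index("label").loc["CVD"]
        assert cvd["share_pct"] == 69.8  # 1499 / 2148

    def test_single_group_is_100(self):
        res = _FakeResult({"total": (10.0, 9.0, 11.0), "under_75": (10.0, 9.0, 11.0),
                           "sex:M": (10.0, 9.0, 11.0), "sex:F": (0.0, 0.0, 0.0),
                           "cause:CVD": (10.0, 9.0, 11.0)})
        st = impact_shares(res, "cause")
        assert st.rows["share_pct"].iloc[0] == 100.0

    def test_zero_total_rejected(self):
        res = _FakeResult({"total": (0.0, 0.0, 0.0)})
        with pytest.raises(ConfigurationError):
            impact_shares(res, "sex")


class TestPercentOfTotalDeaths:
    def _mortality(self):
        return pd.DataFrame({
            "sex": ["M", "F"], "age_band": ["50-54"] * 2, "cause": ["CVD"] * 2,
            "deaths": [46568, 46277],
        })

    def test_context_percentages(self):
        res = _FakeResult({"total": (2148.0, 0, 0), "sex:M": (1203.0, 0, 0),
                           "sex:F": (945.0, 0, 0)})
        out = percent_of_total_deaths(res, self._mortality())
        assert out["overall"] == 2.3  # 2148 / 92845

    def test_scenario_four_magnitude(self):
        res = _FakeResult({"total": (7047.0, 0, 0), "sex:M": (3949.0, 0, 0),
                           "sex:F": (3098.0, 0, 0)})
        out = percent_of_total_deaths(res, self._mortality())
        assert out["overall"] == 7.6  # 7047 / 92845

    def test_zero_averted_is_zero_percent(self):
        res = _FakeResult({"total": (0.0, 0, 0), "sex:M": (0.0, 0, 0),
                           "sex:F": (0.0, 0, 0)})
        assert percent_of_total_deaths(res, self._mortality())["overall"] == 0.0

    def test_zero_denominator_rejected(self):
        res = _FakeResult({"total": (1.0, 0, 0)})
        mort = self._mortality().assign(deaths=0)
        with pytest.raises(ConfigurationError):
            percent_of_total_deaths(res, mort)


class TestScenarioTable:
    def _est(self, nutrient, mean, lo, hi):
        return UsualEstimate(stratum="overall", nutrient=nutrient, mean=mean,
                             se=1.0, ci95=(lo, hi), n=100)

    def test_deltas_from_unrounded_means(self):
        base = {"baseline": [self._est("sodium", 2729.4, 2660.0, 2800.0)],
                "S4": [self._est("sodium", 2470.1, 2400.0, 2530.0)]}
        t = scenario_table(base)
        assert t["S4_delta"].iloc[0] == pytest.approx(-259.3)
        assert bool(t["S4_significant"].iloc[0])

    def test_identical_scenario_no_stars(self):
        e = self._est("sodium", 2729.0, 2660.0, 2800.0)
        t = scenario_table({"baseline": [e], "S1": [e]})
        assert t["S1_delta"].iloc[0] == 0.0
        assert not t["S1_significant"].iloc[0]

    def test_missing_scenario_nutrient_warns(self):
        base = {"baseline": [self._est("sodium", 2729.0, 2660.0, 2800.0)],
                "S1": []}
        with pytest.warns(UserWarning):
            t = scenario_table(base)
        assert np.isnan(t["S1_mean"].iloc[0])


@pytest.fixture(scope="module")
def small_pipeline(tmp_path_factory):
    cfg = PipelineConfig(
        synth=SynthConfig(n_foods=1200, n_branded=4000, n_respondents=250,
                          seed=77, truth_menu_days=500),
        n_boot=40, n_iter=300, seed=77,
    )
    out = tmp_path_factory.mktemp("bundle")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_full_pipeline(cfg, out_dir=out)
    return cfg, out, res


class TestFullPipeline:
    def test_emits_all_tables(self, small_pipeline):
        _, out, res = small_pipeline
        for name in ("foods", "branded", "respondents", "recalls", "deaths",
                     "population", "table1", "table2", "table3", "usual_intakes",
                     "impacts"):
            assert (out / f"{name}.csv").exists()
        assert (out / "manifest.json").exists()

    def test_four_scenario_blocks(self, small_pipeline):
        _, _, res = small_pipeline
        assert set(res.prime_results) == {"S1", "S2", "S3", "S4"}
        assert set(res.estimates) == {"baseline", "S1", "S2", "S3", "S4"}

    def test_bit_identical_rerun(self, small_pipeline, tmp_path):
        cfg, out, res = small_pipeline
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = run_full_pipeline(cfg, out_dir=tmp_path)
        assert res.manifest["bundle_sha256"] == res2.manifest["bundle_sha256"]

    def test_share_tables_internally_consistent(self, small_pipeline):
        _, _, res = small_pipeline
        for st in res.shares.values():
            total = st.total
            for _, row in st.rows.iterrows():
                expect = round_half_away(100.0 * row["count"] / total,
                                         int(row["decimals"]))
                assert row["share_pct"] == expect
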