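"""Survey-processing operations: calibration, allometric biomass,
schooling truncation, domain filters, aggregation and the benthic
log-ratio, each checked against direct arithmetic or brute-force oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import reefbayes.surveys as sv
from conftest import type7_quantile


@pytest.fixture
def obs():
    return pd.DataFrame({
        "transect_id": [1, 1, 2],
        "source_dataset": ["ds_a", "ds_a", "ds_b"],
        "species_code": ["SCPS", "KYSP", "SCPS"],
        "count": [3.0, 1.0, 2.0],
        "total_length": [20.0, 30.0, 15.0],
    })


@pytest.fixture
def allometry():
    return pd.DataFrame({
        "species_code": ["SCPS", "KYSP"],
        "a": [0.0135, 0.0161],
        "b": [3.05, 3.02],
        "functional_group": ["scraper", "browser"],
    })


class TestCalibration:
    def test_factor_one_is_identity(self, obs):
        cal = pd.DataFrame({"species_code": ["SCPS", "KYSP", "SCPS"],
                            "method": ["ds_a", "ds_a", "ds_b"],
                            "factor": [1.0, 1.0, 1.0]})
        out = sv.calibrate_counts(obs, cal)
        pd.testing.assert_series_equal(out["count"], obs["count"])

    def test_factor_scales_counts(self, obs):
        cal = pd.DataFrame({"species_code": ["SCPS"], "method": ["ds_a"],
                            "factor": [2.0]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = sv.calibrate_counts(obs, cal)
        assert out.loc[0, "count"] == 6.0   # 3 * 2
        assert out.loc[1, "count"] == 1.0   # missing pair -> unchanged

    def test_missing_pair_warns(self, obs):
        cal = pd.DataFrame({"species_code": ["SCPS"], "method": ["ds_a"],
                            "factor": [2.0]})
        with pytest.warns(UserWarning, match="no calibration factor"):
            sv.calibrate_counts(obs, cal)

    def test_negative_factor_rejected(self, obs):
        cal = pd.DataFrame({"species_code": ["SCPS"], "method": ["ds_a"],
                            "factor": [-1.0]})
        with pytest.raises(ValueError):
            sv.calibrate_counts(obs, cal)


class TestBiomass:
    def test_linear_identity(self):
        one = pd.DataFrame({"species_code": ["X"], "count": [1.0],
                            "total_length": [10.0]})
        table = pd.DataFrame({"species_code": ["X"], "a": [1.0], "b": [1.0]})
        assert sv.compute_biomass(one, table, survey_area=1.0).iloc[0] == 10.0

    def test_zero_count_zero_biomass(self, obs, allometry):
        obs = obs.assign(count=0.0)
        assert (sv.compute_biomass(obs, allometry, 125.0) == 0).all()

    def test_power_law_against_direct_evaluation(self, allometry):
        row = pd.DataFrame({"species_code": ["SCPS"], "count": [2.0],
                            "total_length": [20.0]})
        got = sv.compute_biomass(row, allometry, survey_area=125.0).iloc[0]
        expected = 2.0 * 0.0135 * math.pow(20.0, 3.05) / 125.0
        assert got == pytest.approx(expected, rel=1e-12)

    def test_unknown_species_is_error(self, allometry):
        row = pd.DataFrame({"species_code": ["NOPE"], "count": [1.0],
                            "total_length": [10.0]})
        with pytest.raises(KeyError, match="NOPE"):
            sv.compute_biomass(row, allometry, 125.0)

    @given(scale=st.floats(0.1, 50.0))
    def test_homogeneous_in_count(self, scale):
        table = pd.DataFrame({"species_code": ["X"], "a": [0.02], "b": [3.0]})
        row = pd.DataFrame({"species_code": ["X"], "count": [4.0],
                            "total_length": [22.0]})
        base = sv.compute_biomass(row, table, 100.0).iloc[0]
        scaled = sv.compute_biomass(row.assign(count=4.0 * scale),
                                    table, 100.0).iloc[0]
        assert scaled == pytest.approx(scale * base, rel=1e-12)


class TestSchoolingTruncation:
    def test_all_equal_counts_unchanged(self):
        df = pd.DataFrame({"species_code": ["A"] * 10, "count": [5.0] * 10})
        out, report = sv.truncate_schooling(df)
        pd.testing.assert_frame_equal(out, df)
        assert len(report) == 0

    def test_outlier_truncated_to_sort_based_quantile(self):
        counts = np.arange(1.0, 1000.0).tolist() + [1e6]
        df = pd.DataFrame({"species_code": ["A"] * 1000, "count": counts})
        out, report = sv.truncate_schooling(df)
        q99 = type7_quantile(counts, 0.99)
        assert out["count"].max() == pytest.approx(q99)
        assert len(report) >= 1
        np.testing.assert_allclose(report["truncated_to"], q99)

    def test_non_herbivore_outliers_left_alone(self):
        counts = [1.0] * 999 + [1e6]
        df = pd.DataFrame({"species_code": ["JACK"] * 1000, "count": counts})
        groups = pd.DataFrame({"species_code": ["JACK"],
                               "functional_group": ["other"]})
        out, report = sv.truncate_schooling(df, species_groups=groups)
        pd.testing.assert_frame_equal(out, df)
        assert len(report) == 0

    def test_never_increases_and_idempotent(self):
        # idempotence holds once the whole extreme tail is clamped, i.e.
        # when the outlying counts belong to flagged herbivore species
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "species_code": ["A"] * 500,
            "count": rng.gamma(1.0, 10.0, 500),
        })
        once, _ = sv.truncate_schooling(df)
        assert (once["count"] <= df["count"]).all()
        twice, rep2 = sv.truncate_schooling(once)
        pd.testing.assert_frame_equal(twice, once)
        assert len(rep2) == 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            sv.truncate_schooling(pd.DataFrame(columns=["species_code", "count"]))


class TestDomainFilter:
    @pytest.mark.parametrize("hard,depth,year,kept", [
        (True, 10.0, 2010, True),
        (True, 35.0, 2010, False),
        (True, 10.0, 2016, False),
        (False, 10.0, 2010, False),
        (True, 30.0, 2004, True),   # boundaries included
    ])
    def test_rules(self, hard, depth, year, kept):
        df = pd.DataFrame({"hardbottom_flag": [hard], "depth": [depth],
                           "year": [year]})
        assert (len(sv.filter_domain(df)) == 1) is kept

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "hardbottom_flag": rng.random(100) < 0.7,
            "depth": rng.uniform(0, 40, 100),
            "year": rng.integers(2000, 2020, 100),
        })
        once = sv.filter_domain(df)
        pd.testing.assert_frame_equal(sv.filter_domain(once), once)

    def test_missing_fields_schema_error(self):
        with pytest.raises(KeyError):
            sv.filter_domain(pd.DataFrame({"depth": [1.0]}))


class TestAggregation:
    def test_mean_within_key(self):
        df = pd.DataFrame({
            "source_dataset": ["a", "a"], "latitude": [20.0, 20.0],
            "longitude": [-156.0, -156.0], "depth": [5.0, 5.0],
            "year": [2010, 2010], "biomass": [10.0, 20.0],
        })
        out = sv.aggregate_replicates(df)
        assert len(out) == 1 and out.loc[0, "biomass"] == 15.0
        assert out.loc[0, "n_transects"] == 2

    def test_distinct_keys_preserved(self):
        df = pd.DataFrame({
            "source_dataset": ["a", "b"], "latitude": [20.0, 21.0],
            "longitude": [-156.0, -156.0], "depth": [5.0, 5.0],
            "year": [2010, 2010], "biomass": [10.0, 20.0],
        })
        assert len(sv.aggregate_replicates(df)) == 2

    def test_matches_brute_force_group_means(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "source_dataset": rng.choice(["a", "b"], 50),
            "latitude": rng.choice([20.1, 20.2], 50),
            "longitude": -156.0,
            "depth": rng.choice([5.0, 10.0], 50),
            "year": rng.choice([2008, 2012], 50),
            "biomass": rng.gamma(2.0, 10.0, 50),
        })
        out = sv.aggregate_replicates(df).set_index(sv.REPLICATE_KEY)
        for key, sub in df.groupby(sv.REPLICATE_KEY):
            assert out.loc[key, "biomass"] == pytest.approx(
                sub["biomass"].mean()
            )

    def test_aggregation_commutes_with_totaling(self):
        # mean of sums equals sum of means (linearity)
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "source_dataset": "a", "latitude": rng.choice([20.1, 20.2], 40),
            "longitude": -156.0, "depth": 5.0, "year": 2010,
            "grazer": rng.gamma(2, 5, 40), "scraper": rng.gamma(2, 5, 40),
        })
        agg = sv.aggregate_replicates(df)
        total_then_agg = sv.aggregate_replicates(
            df.assign(total=df["grazer"] + df["scraper"])
        )["total"]
        np.testing.assert_allclose(agg["grazer"] + agg["scraper"],
                                   total_then_agg)


class TestSiteSubsample:
    def _reps(self):
        return pd.DataFrame({
            "site": ["kahekili", "kahekili", "elsewhere"],
            "latitude": [20.93, 20.93, 21.5], "longitude": [-156.69] * 3,
            "year": [2012, 2014, 2012],
        })

    def test_keep_year_only_at_site(self):
        out = sv.subsample_site(self._reps(), "kahekili", keep_year=2014)
        assert len(out) == 2
        assert set(out["year"]) == {2014, 2012}

    def test_no_site_rows_identity(self):
        reps = self._reps().assign(site="elsewhere")
        out = sv.subsample_site(reps, "kahekili", keep_year=2014, center=(20.0, -150.0))
        pd.testing.assert_frame_equal(out, reps)

    def test_site_without_keep_year_removed_with_warning(self):
        reps = self._reps()
        with pytest.warns(UserWarning, match="no data in 2013"):
            out = sv.subsample_site(reps, "kahekili", keep_year=2013)
        assert (out["site"] == "elsewhere").all()

    def test_radius_rule(self):
        reps = self._reps().drop(columns=["site"])
        out = sv.subsample_site(reps, "kahekili", keep_year=2014,
                                center=(20.93, -156.69), radius_km=2.5)
        assert len(out) == 2

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError):
            sv.subsample_site(self._reps(), "nowhere", keep_year=2014)


class TestSparseMoku:
    @pytest.mark.parametrize("n,kept", [(4, False), (5, True)])
    def test_min_replicates_boundary(self, n, kept):
        df = pd.DataFrame({"moku_id": ["m1"] * n + ["m2"] * 10})
        out = sv.drop_sparse_moku(df, min_n=5)
        assert ("m1" in set(out["moku_id"])) is kept

    def test_min_n_one_is_identity(self):
        df = pd.DataFrame({"moku_id": ["m1", "m2", "m2"]})
        pd.testing.assert_frame_equal(sv.drop_sparse_moku(df, min_n=1), df)

    def test_all_sparse_warns_empty(self):
        df = pd.DataFrame({"moku_id": ["m1", "m2"]})
        with pytest.warns(UserWarning, match="all moku"):
            out = sv.drop_sparse_moku(df, min_n=5)
        assert len(out) == 0


class TestFunctionalGroups:
    def test_canonical_assignments(self, allometry):
        table = pd.concat([allometry, pd.DataFrame({
            "species_code": ["ACTR", "CHMU"], "a": [0.03, 0.02],
            "b": [2.9, 3.0], "functional_group": ["grazer", "other"],
        })])
        got = sv.assign_functional_groups(
            ["SCPS", "KYSP", "ACTR", "CHMU"], table
        )
        # parrotfish -> scraper, chub -> browser, surgeonfish -> grazer
        assert list(got) == ["scraper", "browser", "grazer", "other"]

    def test_unmapped_species_is_error(self, allometry):
        with pytest.raises(KeyError, match="ZZZZ"):
            sv.assign_functional_groups(["ZZZZ"], allometry)


class TestBenthicCondition:
    def test_equal_covers_give_zero(self):
        assert sv.benthic_condition(20.0, 10.0, 30.0) == 0.0

    def test_all_zero_covers_give_zero(self):
        assert sv.benthic_condition(0.0, 0.0, 0.0) == 0.0

    def test_direct_evaluation_with_floor(self):
        got = sv.benthic_condition(40.0, 10.0, 5.0, floor=0.1)
        assert got == pytest.approx(math.log(50.1 / 5.1), rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1, 0, 0), (0, 101, 0), (0, 0, 200)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sv.benthic_condition(*bad)

    @given(calc=st.floats(0, 100), macro=st.floats(0, 100))
    def test_antisymmetric_under_swap(self, calc, macro):
        fwd = sv.benthic_condition(calc, 0.0, macro)
        rev = sv.benthic_condition(macro, 0.0, calc)
        assert fwd == pytest.approx(-rev, abs=1e-12)
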