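import numpy as np
import pytest

from adofp import core_io
from adofp.core_io import (
    CountryDemography,
    EstimateRecord,
    ObservationError,
    SurveyObservation,
    read_demography,
    read_estimates,
    read_meta,
    read_observations,
    validate_dataset,
    write_estimates,
    write_meta,
    write_observations,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadObservations:
    def test_percent_units_converted(self, tmp_path):
        p = write(
            tmp_path, "obs.csv",
            "country_code,marital_group,ref_year,p_any,units\nCOL,married,2015.5,58.1,percent\n",
        )
        (rec,) = read_observations(p)
        assert rec.p_any == pytest.approx(0.581)
        assert rec.country_code == "COL"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = write(tmp_path, "obs.csv", "country_code,marital_group,ref_year,p_any\n")
        assert read_observations(p) == []

    def test_method_sum_identity_enforced(self, tmp_path):
        # |0.30 + 0.10 - 0.50| = 0.10 > 0.005
        p = write(
            tmp_path, "obs.csv",
            "country_code,marital_group,ref_year,p_any,p_modern,p_traditional\n"
            "COL,married,2000,0.50,0.30,0.10\n",
        )
        with pytest.raises(ObservationError, match="identity"):
            read_observations(p)

    def test_missing_mandatory_column_named(self, tmp_path):
        p = write(tmp_path, "obs.csv", "country_code,p_any\nCOL,0.5\n")
        with pytest.raises(ValueError, match="marital_group"):
            read_observations(p)

    def test_unknown_column_warns(self, tmp_path):
        p = write(
            tmp_path, "obs.csv",
            "country_code,marital_group,ref_year,p_any,extra_col\nCOL,married,2000,0.5,x\n",
        )
        with pytest.warns(UserWarning, match="extra_col"):
            recs = read_observations(p)
        assert len(recs) == 1

    def test_percent_out_of_range_rejected(self, tmp_path):
        p = write(
            tmp_path, "obs.csv",
            "country_code,marital_group,ref_year,p_any,units\nCOL,married,2000,130,percent\n",
        )
        with pytest.raises(ObservationError, match="p_any"):
            read_observations(p)

    def test_flags_parsed(self, tmp_path):
        p = write(
            tmp_path, "obs.csv",
            "country_code,marital_group,ref_year,p_any,baseline_flags,misclass_flags\n"
            "COL,married,2000,0.5,age_truncated|geographic_subset,modern_inflated\n",
        )
        (rec,) = read_observations(p)
        assert rec.baseline_flags == {"age_truncated", "geographic_subset"}
        assert rec.misclass_flags == {"modern_inflated"}

    def test_roundtrip_through_writer(self, tmp_path, small_observations):
        path = tmp_path / "obs.csv"
        write_observations(small_observations, path)
        back = read_observations(path)
        assert len(back) == len(small_observations)
        for a, b in zip(small_observations, back):
            assert a.country_code == b.country_code
            assert a.p_any == pytest.approx(b.p_any, abs=1e-12)
            assert a.baseline_flags == b.baseline_flags


class TestReadDemography:
    def test_linear_interpolation_midpoint(self, tmp_path):
        p = write(
            tmp_path, "dem.csv",
            "country_code,year,pop_15_19,prop_married\nAAA,2010,100,0.20\nAAA,2012,100,0.10\n",
        )
        d = read_demography(p)["AAA"]
        assert d.at(2011)[1] == pytest.approx(0.15)
        assert d.interpolated

    def test_single_year_constant_extension(self, tmp_path):
        p = write(tmp_path, "dem.csv", "country_code,year,pop_15_19,prop_married\nAAA,2000,100,0.25\n")
        d = read_demography(p)["AAA"]
        assert d.years[0] == 1970 and d.years[-1] == 2030
        assert d.at(1970)[1] == pytest.approx(0.25)
        assert d.at(2030)[1] == pytest.approx(0.25)
        assert d.interpolated

    def test_bound_violation(self, tmp_path):
        p = write(tmp_path, "dem.csv", "country_code,year,pop_15_19,prop_married\nAAA,2000,100,1.2\n")
        with pytest.raises(ValueError):
            read_demography(p)

    def test_gap_without_interpolation_rejected(self, tmp_path):
        p = write(
            tmp_path, "dem.csv",
            "country_code,year,pop_15_19,prop_married\nAAA,2010,100,0.2\nAAA,2012,100,0.1\n",
        )
        with pytest.raises(ValueError, match="non-contiguous"):
            read_demography(p, interpolate=False)


class TestValidateDataset:
    def test_orphan_country_listed(self, three_country_demog, three_country_meta):
        obs = [SurveyObservation("ZZZ", "married", 2000.5, p_any=0.3)]
        report = validate_dataset(obs, three_country_demog, three_country_meta)
        assert "ZZZ" in report.orphan_countries

    def test_observation_counts(self, three_country_demog, three_country_meta):
        obs = [SurveyObservation("AAA", "married", 2000.5, p_any=0.3)]
        report = validate_dataset(obs, three_country_demog, three_country_meta)
        assert report.obs_counts[("AAA", "married")] == 1

    def test_consistent_fixture_is_clean(self, small_observations, small_truth):
        report = validate_dataset(small_observations, small_truth.demography, small_truth.meta)
        assert report.issues == []

    def test_json_summary(self, three_country_demog, three_country_meta):
        report = validate_dataset([], three_country_demog, three_country_meta)
        assert "orphan_countries" in report.to_json()


class TestEstimateRecords:
    def test_roundtrip_bit_exact(self, tmp_path):
        records = [
            EstimateRecord("AAA", "married", "use_any", "proportion", 2019, 0.1234567890123, 0.1, 0.2),
            EstimateRecord("world", "all", "unmet", "count", 1990, 1.5e7, 1.2e7, 3.9e7),
        ]
        path = tmp_path / "est.csv"
        write_estimates(records, path)
        back = read_estimates(path)
        for a, b in zip(records, back):
            assert a == b

    def test_interval_ordering_enforced(self):
        with pytest.raises(ValueError):
            EstimateRecord("AAA", "married", "use_any", "proportion", 2019, 0.5, 0.6, 0.7)

    def test_proportion_bounds_enforced(self):
        with pytest.raises(ValueError):
            EstimateRecord("AAA", "married", "use_any", "proportion", 2019, 1.5, 1.4, 1.6)


class TestMeta:
    def test_duplicate_country_rejected(self, tmp_path):
        p = write(
            tmp_path, "meta.csv",
            "country_code,name,subregion,region\nAAA,A,s1,r1\nAAA,A,s2,r1\n",
        )
        with pytest.raises(ValueError, match="more than once"):
            read_meta(p)

    def test_roundtrip(self, tmp_path, three_country_meta):
        path = tmp_path / "meta.csv"
        write_meta(three_country_meta, path)
        back = read_meta(path)
        assert back == three_country_meta


class TestSurveyObservationInvariants:
    def test_year_bounds(self):
        with pytest.raises(ObservationError):
            SurveyObservation("AAA", "married", 1940.0, p_any=0.2)

    def test_unknown_flag_rejected(self):
        with pytest.raises(ObservationError):
            SurveyObservation("AAA", "married", 2000.0, p_any=0.2, baseline_flags={"bogus"})

    def test_generator_records_all_valid(self, small_observations):
        # reader/validator totality on the synthetic generator output
        assert len(small_observations) > 0
        for o in small_observations:
            assert 0.0 <= o.p_any <= 1.0
            assert abs(o.p_modern + o.p_traditional - o.p_any) <= core_io.METHOD_SUM_TOL
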