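import numpy as np
import pytest

from adofp.core_io import CountryDemography
from adofp.indicators import (
    AggregateSpec,
    adolescent_share,
    aggregate,
    combine_marital,
    counts_from_proportions,
    need_satisfied_modern,
    proportions_from_counts,
    summarize,
    suppression_filter,
)
from conftest import degenerate_samples

YEARS = np.arange(2018, 2021)


def const_demog(countries, pop, w):
    years = np.arange(1970, 2031)
    return {
        c: CountryDemography(c, years, np.full(years.size, pop), np.full(years.size, w))
        for c in countries
    }


def values_for(p_any, p_modern, p_unmet):
    return {
        "use_any": p_any,
        "use_modern": p_modern,
        "use_traditional": p_any - p_modern,
        "unmet": p_unmet,
        "need": p_any + p_unmet,
        "no_need": 1.0 - p_any - p_unmet,
    }


class TestCombineMarital:
    def test_worked_global_1990_prevalence(self):
        # married 15.2%, unmarried 3.8%, proportion married 18.5% -> 5.9%
        married = degenerate_samples(values_for(0.152, 0.10, 0.2), ["AAA"], YEARS, "married")
        unmarried = degenerate_samples(values_for(0.038, 0.03, 0.02), ["AAA"], YEARS, "unmarried")
        demog = const_demog(["AAA"], 1e6, 0.185)
        combined = combine_marital(married, unmarried, demog)
        value = np.median(combined.data["use_any"][:, 0, 0])
        assert round(100 * value, 1) == 5.9

    def test_weight_one_returns_married(self):
        married = degenerate_samples(values_for(0.3, 0.2, 0.1), ["AAA"], YEARS, "married")
        unmarried = degenerate_samples(values_for(0.1, 0.05, 0.02), ["AAA"], YEARS, "unmarried")
        demog = const_demog(["AAA"], 1e6, 1.0)
        combined = combine_marital(married, unmarried, demog)
        np.testing.assert_allclose(combined.data["use_any"], married.data["use_any"])

    def test_convexity_per_draw(self):
        married = degenerate_samples(values_for(0.3, 0.2, 0.1), ["AAA"], YEARS, "married", jitter=0.01, seed=1)
        unmarried = degenerate_samples(values_for(0.1, 0.05, 0.02), ["AAA"], YEARS, "unmarried", jitter=0.01, seed=2)
        demog = const_demog(["AAA"], 1e6, 0.4)
        combined = combine_marital(married, unmarried, demog)
        lo = np.minimum(married.data["use_any"], unmarried.data["use_any"])
        hi = np.maximum(married.data["use_any"], unmarried.data["use_any"])
        assert np.all(combined.data["use_any"] >= lo - 1e-12)
        assert np.all(combined.data["use_any"] <= hi + 1e-12)

    def test_mismatched_draws_rejected(self):
        married = degenerate_samples(values_for(0.3, 0.2, 0.1), ["AAA"], YEARS, "married", n_draws=150)
        unmarried = degenerate_samples(values_for(0.1, 0.05, 0.02), ["AAA"], YEARS, "unmarried", n_draws=200)
        with pytest.raises(ValueError, match="mismatch"):
            combine_marital(married, unmarried, const_demog(["AAA"], 1e6, 0.4))


class TestCounts:
    def test_simple_product(self):
        s = degenerate_samples(values_for(0.10, 0.08, 0.02), ["AAA"], YEARS, "all")
        counts = counts_from_proportions(s, const_demog(["AAA"], 300e6, 0.2))
        assert counts.data["use_any"][0, 0, 0] == pytest.approx(30e6)

    def test_zero_population(self):
        s = degenerate_samples(values_for(0.5, 0.4, 0.1), ["AAA"], YEARS, "all")
        counts = counts_from_proportions(s, const_demog(["AAA"], 0.0, 0.2))
        assert np.all(counts.data["use_any"] == 0.0)

    def test_worked_table_identity_married_plus_unmarried(self):
        # married 11.0M users + unmarried 18.8M users -> 29.8M all-women users
        pop, w = 300e6, 0.1
        demog = const_demog(["AAA"], pop, w)
        married = degenerate_samples(values_for(11.0e6 / (pop * w), 0.3, 0.1), ["AAA"], YEARS, "married")
        unmarried = degenerate_samples(values_for(18.8e6 / (pop * (1 - w)), 0.05, 0.01), ["AAA"], YEARS, "unmarried")
        cm = counts_from_proportions(married, demog)
        cu = counts_from_proportions(unmarried, demog)
        total = cm.data["use_any"] + cu.data["use_any"]
        assert np.median(total[:, 0, 0]) / 1e6 == pytest.approx(29.8, abs=1e-9)

    def test_missing_population_year_rejected(self):
        s = degenerate_samples(values_for(0.5, 0.4, 0.1), ["AAA"], np.array([2035]), "all")
        with pytest.raises(KeyError):
            counts_from_proportions(s, const_demog(["AAA"], 1e6, 0.2))


class TestAggregate:
    def _counts(self, countries, vals=None):
        v = values_for(0.2, 0.15, 0.05)
        s = degenerate_samples(v, countries, YEARS, "all", jitter=0.0)
        return counts_from_proportions(s, const_demog(countries, 1e6, 0.3))

    def test_two_equal_countries_double(self):
        counts = self._counts(["AAA", "BBB"])
        agg = aggregate(counts, AggregateSpec("test", {"pair": ["AAA", "BBB"]}))["pair"]
        np.testing.assert_allclose(
            agg.data["use_any"][:, 0, :], 2 * counts.data["use_any"][:, 0, :]
        )

    def test_world_equals_sum_of_regions_drawwise(self):
        countries = ["AAA", "BBB", "CCC", "DDD"]
        base = degenerate_samples(values_for(0.2, 0.15, 0.05), countries, YEARS, "all", jitter=0.02, seed=3)
        base.data = {k: np.abs(v) for k, v in base.data.items()}
        counts = counts_from_proportions(base, const_demog(countries, 1e6, 0.3))
        spec = AggregateSpec("regions", {"r1": ["AAA", "BBB"], "r2": ["CCC", "DDD"]})
        regions = aggregate(counts, spec)
        world = aggregate(counts, AggregateSpec("world", {"world": countries}))["world"]
        summed = regions["r1"].data["use_any"] + regions["r2"].data["use_any"]
        # differing summation groupings may flip the last ulp
        np.testing.assert_allclose(world.data["use_any"], summed, rtol=1e-14)

    def test_single_member_identity(self):
        counts = self._counts(["AAA", "BBB"])
        agg = aggregate(counts, AggregateSpec("solo", {"only": ["AAA"]}))["only"]
        np.testing.assert_array_equal(agg.data["unmet"][:, 0, :], counts.data["unmet"][:, 0, :])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="appears in both"):
            AggregateSpec("bad", {"a": ["AAA"], "b": ["AAA"]})

    def test_aggregate_proportions_are_count_weighted(self):
        counts = self._counts(["AAA", "BBB"])
        agg = aggregate(counts, AggregateSpec("test", {"pair": ["AAA", "BBB"]}))["pair"]
        props = proportions_from_counts(agg)
        assert props.data["use_any"][0, 0, 0] == pytest.approx(0.2)


class TestNeedSatisfiedModern:
    def test_worked_sdg_ratio(self):
        # modern 26.2%, need 51.6% -> 50.8%
        s = degenerate_samples(values_for(0.309, 0.262, 0.207), ["AAA"], YEARS, "married")
        ratio = need_satisfied_modern(s)
        assert round(100 * np.median(ratio[:, 0, 0]), 1) == 50.8

    def test_zero_modern(self):
        s = degenerate_samples(values_for(0.3, 0.0, 0.1), ["AAA"], YEARS, "married")
        assert np.all(need_satisfied_modern(s) == 0.0)

    def test_all_need_satisfied_modern_only(self):
        s = degenerate_samples(values_for(0.4, 0.4, 0.0), ["AAA"], YEARS, "married")
        np.testing.assert_allclose(need_satisfied_modern(s), 1.0)

    def test_zero_need_is_nan_not_error(self):
        s = degenerate_samples(values_for(0.0, 0.0, 0.0), ["AAA"], YEARS, "married")
        assert np.all(np.isnan(need_satisfied_modern(s)))


class TestSummarize:
    def test_median_equals_mean_for_symmetric_draws(self):
        s = degenerate_samples(values_for(0.3, 0.25, 0.1), ["AAA"], YEARS, "married", jitter=0.01, seed=4, n_draws=4000)
        recs = summarize(s, years=[2019])
        rec = next(r for r in recs if r.indicator == "use_any")
        assert rec.median == pytest.approx(0.3, abs=0.002)

    def test_identity_adjustment_exact(self):
        rng = np.random.default_rng(5)
        s = degenerate_samples(values_for(0.3, 0.2, 0.1), ["AAA"], YEARS, "married", n_draws=500)
        # skew modern draws so raw medians do not satisfy the identity; keep
        # traditional dispersed so the adjustment stays inside its interval
        s.data["use_modern"] = s.data["use_modern"] + 0.005 * rng.gamma(1.0, 1.0, s.data["use_modern"].shape)
        s.data["use_traditional"] = s.data["use_traditional"] + 0.01 * rng.standard_normal(s.data["use_traditional"].shape)
        recs = summarize(s, years=[2019])
        by = {r.indicator: r for r in recs}
        total = by["use_modern"].median + by["use_traditional"].median
        assert total == pytest.approx(by["use_any"].median, abs=1e-12)

    def test_adjustment_is_identity_when_consistent(self):
        s = degenerate_samples(values_for(0.3, 0.2, 0.1), ["AAA"], YEARS, "married")
        recs = summarize(s, years=[2019])
        by = {r.indicator: r for r in recs}
        assert by["use_modern"].median == pytest.approx(0.2, abs=1e-12)

    def test_worked_modern_share(self):
        # 9.1 / 10.2 -> 89.2%
        s = degenerate_samples(values_for(0.102, 0.091, 0.051), ["AAA"], YEARS, "all")
        recs = summarize(s, years=[2019])
        by = {r.indicator: r for r in recs}
        share = 100 * by["use_modern"].median / by["use_any"].median
        assert round(share, 1) == 89.2

    def test_interval_ordering_invariant(self):
        s = degenerate_samples(
            values_for(0.3, 0.2, 0.1), ["AAA", "BBB"], YEARS, "married", jitter=0.03, seed=6, n_draws=1000
        )
        s.data = {k: np.clip(v, 0.0, 1.0) for k, v in s.data.items()}
        for r in summarize(s):
            assert r.ui_low <= r.median <= r.ui_high

    def test_too_few_draws_rejected(self):
        s = degenerate_samples(values_for(0.3, 0.2, 0.1), ["AAA"], YEARS, "married", n_draws=50)
        with pytest.raises(ValueError, match="draws"):
            summarize(s)


class TestSuppression:
    def _records(self):
        s = degenerate_samples(values_for(0.3, 0.2, 0.1), ["AAA", "BBB"], YEARS, "married")
        return summarize(s, years=[2019])

    def test_single_observation_country_suppressed(self):
        spec = AggregateSpec("x", {"all": ["AAA", "BBB"]})
        recs = suppression_filter(self._records(), {"AAA": 1, "BBB": 5}, spec)
        assert all(r.suppressed for r in recs if r.location == "AAA")
        assert not any(r.suppressed for r in recs if r.location == "BBB")

    def test_two_observations_reported(self):
        spec = AggregateSpec("x", {"all": ["AAA", "BBB"]})
        recs = suppression_filter(self._records(), {"AAA": 2, "BBB": 2}, spec)
        assert not any(r.suppressed for r in recs)

    def test_ratio_suppressed_on_small_need(self):
        spec = AggregateSpec("x", {"all": ["AAA", "BBB"]}, min_need_for_ratio=1e5)
        recs = suppression_filter(self._records(), {"AAA": 9, "BBB": 9}, spec, need_medians={"AAA": 5e4})
        ratio_a = [r for r in recs if r.location == "AAA" and r.indicator == "need_satisfied_modern"]
        assert ratio_a and all(r.suppressed for r in ratio_a)
        other_a = [r for r in recs if r.location == "AAA" and r.indicator == "use_any"]
        assert not any(r.suppressed for r in other_a)

    def test_suppressed_country_still_in_aggregate(self):
        # suppression marks records only; aggregation upstream is unaffected
        countries = ["AAA", "BBB"]
        s = degenerate_samples(values_for(0.2, 0.15, 0.05), countries, YEARS, "all")
        counts = counts_from_proportions(s, const_demog(countries, 1e6, 0.3))
        agg = aggregate(counts, AggregateSpec("x", {"all": countries}))["all"]
        expected = counts.data["use_any"][:, 0, :] + counts.data["use_any"][:, 1, :]
        np.testing.assert_array_equal(agg.data["use_any"][:, 0, :], expected)


class TestAdolescentShare:
    def test_simple_ratio(self):
        assert adolescent_share({"use_any": 10.0}, {"use_any": 100.0})["use_any"] == pytest.approx(10.0)

    def test_equal_counts(self):
        assert adolescent_share({"unmet": 5.0}, {"unmet": 5.0})["unmet"] == pytest.approx(100.0)

    def test_zero_denominator_suppressed(self):
        assert adolescent_share({"unmet": 5.0}, {"unmet": 0.0})["unmet"] is None

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError, match="all-age"):
            adolescent_share({"use_any": 1.0}, {})


class TestCommutation:
    def test_combine_then_aggregate_equals_aggregate_then_combine(self):
        countries = ["AAA", "BBB", "CCC"]
        years = np.arange(1970, 2031)
        demog = {}
        rng = np.random.default_rng(7)
        for i, c in enumerate(countries):
            demog[c] = CountryDemography(
                c, years, np.full(years.size, 1e6 * (i + 1)),
                np.full(years.size, 0.1 + 0.1 * i),
            )
        vm = values_for(0.3, 0.2, 0.1)
        vu = values_for(0.1, 0.08, 0.02)
        married = degenerate_samples(vm, countries, YEARS, "married", jitter=0.01, seed=8)
        unmarried = degenerate_samples(vu, countries, YEARS, "unmarried", jitter=0.01, seed=9)
        spec = AggregateSpec("x", {"all": countries})

        # route 1: combine proportions, convert to counts, aggregate
        combined = combine_marital(married, unmarried, demog)
        c1 = aggregate(counts_from_proportions(combined, demog), spec)["all"]
        # route 2: counts per group, aggregate, add
        am = aggregate(counts_from_proportions(married, demog), spec)["all"]
        au = aggregate(counts_from_proportions(unmarried, demog), spec)["all"]
        for k in vm:
            np.testing.assert_allclose(
                c1.data[k], am.data[k] + au.data[k], rtol=1e-12, atol=1e-3
            )
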