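"""Rate-table containers, CSV round-trip, standardization, subtype pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ascertain.tables import (
    AgeBand,
    Measure,
    RateTable,
    SchemaError,
    StandardPopulation,
    age_standardize,
    aggregate_stroke_subtypes,
    approximate_year_inputs,
    poisson_rate_ci,
    read_rate_table,
    write_rate_table,
)
from conftest import make_table


class TestAgeBand:
    def test_half_open_semantics(self):
        band = AgeBand(0, 5)
        assert list(band.ages()) == [0, 1, 2, 3, 4]
        assert band.midpoint == 2.5

    def test_open_tail_knot_and_cap(self):
        tail = AgeBand(95, open_ended=True)
        assert tail.midpoint == 100.0
        assert list(tail.ages()) == [95, 96, 97, 98, 99]

    @pytest.mark.parametrize("lo,hi", [(-1, 5), (5, 5), (10, 5)])
    def test_invalid_bounds_rejected(self, lo, hi):
        with pytest.raises(ValueError):
            AgeBand(lo, hi)


class TestRateTableIO:
    def test_round_trip_preserves_values_bitwise(self, tmp_path):
        table = make_table([0.001, 0.0025], measure=Measure.csmr)
        table.se = np.array([1e-4, 2e-4])
        path = tmp_path / "t.csv"
        write_rate_table(table, path)
        back = read_rate_table(path, schema=Measure.csmr)
        assert back == table

    def test_round_trip_with_open_tail_and_counts(self, tmp_path):
        table = make_table([0.01, 0.03], open_tail=True)
        table.count = np.array([100.0, 300.0])
        table.person_years = np.array([10000.0, 10000.0])
        table.values = table.count / table.person_years
        path = tmp_path / "t.csv"
        write_rate_table(table, path)
        assert read_rate_table(path) == table

    def test_overlapping_bands_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "disease": "synthetic", "sex": "male", "year": 2015,
                "age_lo": [0, 3], "age_hi": [5, 10],
                "measure": "incidence", "value": [0.1, 0.2],
            }
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="overlap"):
            read_rate_table(path)

    def test_missing_column_and_range_violations(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"disease": ["x"], "value": [0.1]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="missing column"):
            read_rate_table(path)
        with pytest.raises(SchemaError, match="out of range"):
            make_table([0.5, 1.5], measure=Measure.prevalence)
        with pytest.raises(SchemaError, match="out of range"):
            make_table([0.1, -0.2])

    def test_count_person_year_consistency_enforced(self):
        table = make_table([0.01, 0.03])
        with pytest.raises(SchemaError, match="count/person_years"):
            RateTable(
                disease="synthetic", sex="male", year=2015,
                measure=Measure.incidence, bands=table.bands,
                values=np.array([0.01, 0.03]),
                count=np.array([50.0, 300.0]),  # 50/1e4 != 0.01
                person_years=np.array([1e4, 1e4]),
            )


class TestAgeStandardize:
    def test_constant_rate_is_invariant(self):
        std = StandardPopulation.who_world()
        table = make_table([0.002] * len(std.bands))
        table.bands = list(std.bands)
        assert age_standardize(table, std).value == pytest.approx(0.002, rel=1e-12)

    def test_two_band_arithmetic(self):
        std = StandardPopulation(
            bands=[AgeBand(0, 50), AgeBand(50, open_ended=True)],
            weights=np.array([0.5, 0.5]),
        )
        table = RateTable(
            disease="synthetic", sex="male", year=2015, measure=Measure.incidence,
            bands=std.bands, values=np.array([100e-5, 300e-5]),
        )
        assert age_standardize(table, std).value == pytest.approx(200e-5)

    def test_matches_brute_force_weighted_sum(self, rng):
        std = StandardPopulation.who_world()
        values = rng.uniform(1e-5, 1e-2, size=len(std.bands))
        table = RateTable(
            disease="synthetic", sex="male", year=2015, measure=Measure.incidence,
            bands=list(std.bands), values=values,
        )
        expected = sum(w * v for w, v in zip(std.weights, values))
        assert age_standardize(table, std).value == pytest.approx(expected, abs=1e-12)

    def test_coarse_table_aggregates_standard_weights(self):
        std = StandardPopulation.who_world()
        # 65+ tail: weights of all 65+ standard bands must pool into it
        bands = [b for b in std.bands if not b.open_ended and b.hi <= 65]
        bands.append(AgeBand(65, open_ended=True))
        values = np.concatenate([np.full(len(bands) - 1, 1e-3), [5e-3]])
        table = RateTable(
            disease="synthetic", sex="male", year=2015, measure=Measure.incidence,
            bands=bands, values=values,
        )
        w_tail = sum(w for b, w in zip(std.bands, std.weights) if b.lo >= 65)
        expected = (1 - w_tail) * 1e-3 + w_tail * 5e-3
        assert age_standardize(table, std).value == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1e-2), min_size=20, max_size=20))
    def test_standardized_rate_bounded_by_band_extremes(self, values):
        std = StandardPopulation.who_world()
        table = RateTable(
            disease="synthetic", sex="male", year=2015, measure=Measure.incidence,
            bands=list(std.bands), values=np.array(values[: len(std.bands)]),
        )
        out = age_standardize(table, std).value
        assert min(values) - 1e-15 <= out <= max(values) + 1e-15


class TestPoissonRateCI:
    def test_zero_count_lower_bound_is_zero(self):
        lo, hi = poisson_rate_ci(0, 1e5)
        assert lo == 0.0 and hi > 0

    def test_matches_exact_poisson_interval(self):
        # exact interval via the chi-square (gamma) relation
        count, py = 100, 1e5
        lo, hi = poisson_rate_ci(count, py)
        exact_lo = stats.chi2.ppf(0.025, 2 * count) / 2 / py
        exact_hi = stats.chi2.ppf(0.975, 2 * (count + 1)) / 2 / py
        assert lo == pytest.approx(exact_lo, rel=0.02)
        assert hi == pytest.approx(exact_hi, rel=0.02)

    def test_large_count_matches_normal_limit(self):
        count, py = 10_000, 1e7
        lo, hi = poisson_rate_ci(count, py)
        se = np.sqrt(count) / py
        assert lo == pytest.approx(count / py - 1.96 * se, rel=0.005)
        assert hi == pytest.approx(count / py + 1.96 * se, rel=0.005)

    def test_invalid_person_years(self):
        with pytest.raises(ValueError):
            poisson_rate_ci(10, 0.0)


class TestSubtypeAggregation:
    def _subtypes(self, prevs, rems, rrs):
        mk = lambda vals, meas: make_table(vals, measure=meas, disease="stroke")
        return (
            [mk(p, Measure.prevalence) for p in prevs],
            [mk(r, Measure.remission) for r in rems],
            [mk(x, Measure.relative_risk) for x in rrs],
        )

    def test_equal_remissions_pass_through(self):
        prev, rem, rr = self._subtypes(
            [[0.01, 0.02], [0.03, 0.01]], [[0.1, 0.1], [0.1, 0.1]], [[2.0, 2.0], [2.0, 2.0]]
        )
        _, rem_all, rr_all = aggregate_stroke_subtypes(prev, rem, rr)
        assert np.allclose(rem_all.values, 0.1)
        assert np.allclose(rr_all.values, 2.0)

    def test_stated_weighted_mean(self):
        prev, rem, rr = self._subtypes(
            [[0.01, 0.01], [0.03, 0.03]], [[0.2, 0.2], [0.4, 0.4]], [[1.5, 1.5], [2.5, 2.5]]
        )
        prev_all, rem_all, _ = aggregate_stroke_subtypes(prev, rem, rr)
        assert np.allclose(prev_all.values, 0.04)
        assert np.allclose(rem_all.values, 0.35)

    def test_matches_brute_force_over_random_subtypes(self, rng):
        n_sub, n_band = 4, 6
        prevs = rng.uniform(0.001, 0.05, (n_sub, n_band))
        rems = rng.uniform(0.0, 0.5, (n_sub, n_band))
        rrs = rng.uniform(1.0, 4.0, (n_sub, n_band))
        prev, rem, rr = self._subtypes(prevs, rems, rrs)
        prev_all, rem_all, rr_all = aggregate_stroke_subtypes(prev, rem, rr)
        for k in range(n_band):
            total = sum(prevs[s][k] for s in range(n_sub))
            rem_exp = sum(prevs[s][k] * rems[s][k] for s in range(n_sub)) / total
            rr_exp = sum(prevs[s][k] * rrs[s][k] for s in range(n_sub)) / total
            assert prev_all.values[k] == pytest.approx(total, abs=1e-12)
            assert rem_all.values[k] == pytest.approx(rem_exp, abs=1e-12)
            assert rr_all.values[k] == pytest.approx(rr_exp, abs=1e-12)
        # convexity: pooled values within subtype extremes
        assert (rem_all.values <= rems.max(axis=0) + 1e-12).all()
        assert (rem_all.values >= rems.min(axis=0) - 1e-12).all()

    def test_zero_total_prevalence_with_nonzero_inputs_rejected(self):
        prev, rem, rr = self._subtypes([[0.0, 0.01]], [[0.2, 0.2]], [[2.0, 2.0]])
        with pytest.raises(ValueError, match="zero total prevalence"):
            aggregate_stroke_subtypes(prev, rem, rr)


class TestYearApproximation:
    def test_mean_of_equal_tables_is_identity(self):
        a = make_table([0.01, 0.02], year=2005)
        b = make_table([0.01, 0.02], year=2010)
        out = approximate_year_inputs(a, b, rule="mean", target_year=2007)
        assert np.array_equal(out.values, a.values)
        assert out.year == 2007

    def test_mean_rule_arithmetic(self):
        a = make_table([10.0, 10.0], year=2005)
        b = make_table([20.0, 20.0], year=2010)
        out = approximate_year_inputs(a, b, rule="mean", target_year=2007)
        assert np.allclose(out.values, 15.0)

    def test_take_rule_relabels_only(self):
        a = make_table([0.01, 0.02], year=2016)
        out = approximate_year_inputs(a, rule="take", target_year=2015)
        assert np.array_equal(out.values, a.values)
        assert out.year == 2015

    def test_band_mismatch_rejected(self):
        a = make_table([0.01, 0.02], year=2005)
        b = make_table([0.01, 0.02, 0.03], year=2010)
        with pytest.raises(ValueError):
            approximate_year_inputs(a, b, rule="mean", target_year=2007)
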