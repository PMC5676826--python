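"""Filters, incidence arithmetic, standardization, pooling, under-reporting
and female/male ratios."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fraxbuild import (
    FilterCriteria,
    age_standardize,
    compute_incidence,
    filter_cases,
    fm_ratio,
    missed_fraction,
    national_projection,
    pool_regions,
    round_half_up,
)
from fraxbuild.case_ascertainment import BandMismatchError, UndefinedRatioError
from tests.conftest import make_record


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

class TestFilters:
    def test_age_boundary_forty_nine_excluded_fifty_kept(self):
        ret, audit = filter_cases(
            [make_record(age=49, person_id="a"), make_record(age=50, person_id="b")]
        )
        assert [r.person_id for r in ret] == ["b"]
        assert audit["under_age"] == 1

    @pytest.mark.parametrize(
        "override, rule",
        [
            ({"trauma_energy": "high"}, "high_energy"),
            ({"pathological": 1}, "pathological"),
            ({"resident": 0}, "non_resident"),
        ],
    )
    def test_record_level_exclusions(self, override, rule):
        ret, audit = filter_cases([make_record(**override)])
        assert ret == [] and audit[rule] == 1

    def test_readmission_within_window_collapses_to_one_event(self):
        recs = [
            make_record(event_date=dt.date(2013, 3, 1)),
            make_record(event_date=dt.date(2013, 3, 11)),  # 10 days later
        ]
        ret, audit = filter_cases(recs)
        assert len(ret) == 1
        assert ret[0].event_date == dt.date(2013, 3, 1)  # earliest retained
        assert audit["duplicate_admission"] == 1

    def test_same_site_event_outside_window_is_new_event(self):
        recs = [
            make_record(event_date=dt.date(2013, 1, 1)),
            make_record(event_date=dt.date(2013, 6, 1)),  # 151 days later
        ]
        ret, _ = filter_cases(recs)
        assert len(ret) == 2

    def test_different_site_same_day_not_deduplicated(self):
        recs = [
            make_record(site="hip", icd10="S72.0"),
            make_record(site="forearm", icd10="S52.5"),
        ]
        ret, _ = filter_cases(recs)
        assert len(ret) == 2

    def test_icd_site_mismatch_quarantined_not_dropped_silently(self):
        ret, audit = filter_cases([make_record(site="hip", icd10="S42.2")])
        assert ret == []
        assert audit["icd_site_mismatch"] == 1
        assert len(audit["quarantined"]) == 1

    def test_ten_record_toy_registry_hand_count(self):
        # 10 records: 1 high-energy, 1 pathological, 1 non-resident,
        # 1 duplicate admission -> 6 retained (hand enumeration)
        recs = [make_record(person_id=f"p{i}", event_date=dt.date(2013, 1, 1 + i))
                for i in range(6)]
        recs += [
            make_record(person_id="p0", event_date=dt.date(2013, 1, 20)),  # readmission
            make_record(person_id="x1", trauma_energy="high"),
            make_record(person_id="x2", pathological=1),
            make_record(person_id="x3", resident=0),
        ]
        ret, audit = filter_cases(recs)
        assert len(recs) == 10 and len(ret) == 6
        assert audit["retained"] == 6

    def test_record_level_rules_order_independent(self):
        recs = [
            make_record(person_id="a", age=45),
            make_record(person_id="b", trauma_energy="high", pathological=1),
            make_record(person_id="c"),
            make_record(person_id="d", resident=0),
        ]
        base = [r.person_id for r in filter_cases(recs)[0]]
        for perm in ([3, 2, 1, 0], [1, 3, 0, 2]):
            got = [r.person_id for r in filter_cases([recs[i] for i in perm])[0]]
            assert sorted(got) == sorted(base) == ["c"]

    def test_dedup_window_configurable(self):
        recs = [
            make_record(event_date=dt.date(2013, 1, 1)),
            make_record(event_date=dt.date(2013, 1, 15)),
        ]
        assert len(filter_cases(recs, FilterCriteria(dedup_window_days=7))[0]) == 2
        assert len(filter_cases(recs, FilterCriteria(dedup_window_days=30))[0]) == 1


# ---------------------------------------------------------------------------
# Incidence
# ---------------------------------------------------------------------------

class TestIncidence:
    def test_crude_rate_matches_hand_division(self, single_band_population):
        # 114 female hip cases over 55,838 women 50+ in one year
        cases = [make_record(person_id=f"p{i}") for i in range(114)]
        inc = compute_incidence(cases, single_band_population, years=1.0)
        row = inc[(inc["sex"] == "female") & (inc["site"] == "hip")].iloc[0]
        assert row["count"] == 114
        assert row["rate_per_100k"] == pytest.approx(1e5 * 114 / 55_838)
        assert row["rate_per_100k"] == pytest.approx(204.2, abs=0.05)

    def test_zero_cases_zero_rate(self, single_band_population):
        inc = compute_incidence([], single_band_population)
        assert (inc["rate_per_100k"] == 0).all()

    def test_doubling_person_years_halves_rates(self, single_band_population):
        cases = [make_record(person_id=f"p{i}") for i in range(50)]
        r1 = compute_incidence(cases, single_band_population, years=1.0)
        r2 = compute_incidence(cases, single_band_population, years=2.0)
        merged = r1.merge(r2, on=["sex", "age_lo", "age_hi", "site"])
        np.testing.assert_allclose(
            merged["rate_per_100k_y"], merged["rate_per_100k_x"] / 2
        )

    def test_case_in_zero_person_year_band_is_an_error(self):
        pop = pd.DataFrame(
            {"sex": ["female"], "age_lo": [50], "age_hi": [np.nan],
             "person_years": [0.0]}
        )
        with pytest.raises(ValueError, match="person-years"):
            compute_incidence([make_record()], pop)

    def test_case_outside_all_bands_is_an_error(self, single_band_population):
        with pytest.raises(ValueError, match="outside"):
            compute_incidence([make_record(age=40)], single_band_population)


class TestStandardization:
    def test_equal_band_rates_are_invariant(self):
        inc = pd.DataFrame(
            {"sex": "female", "age_lo": [50, 55], "age_hi": [55.0, np.nan],
             "site": "hip", "count": [5, 50],
             "person_years": [5000.0, 10000.0],
             "rate_per_100k": [150.0, 150.0]}
        )
        ref = pd.DataFrame(
            {"sex": "female", "age_lo": [50, 55], "age_hi": [55.0, np.nan],
             "person_years": [1.0, 9.0]}
        )
        std = age_standardize(inc, ref)
        assert std["rate_per_100k"].iloc[0] == pytest.approx(150.0)

    def test_two_band_weighted_mean(self):
        inc = pd.DataFrame(
            {"sex": "female", "age_lo": [50, 55], "age_hi": [55.0, np.nan],
             "site": "hip", "count": [1, 1], "person_years": [1.0, 1.0],
             "rate_per_100k": [100.0, 300.0]}
        )
        ref = pd.DataFrame(
            {"sex": "female", "age_lo": [50, 55], "age_hi": [55.0, np.nan],
             "person_years": [0.25, 0.75]}
        )
        assert age_standardize(inc, ref)["rate_per_100k"].iloc[0] == pytest.approx(250.0)

    def test_band_mismatch_rejected(self):
        inc = pd.DataFrame(
            {"sex": "female", "age_lo": [50], "age_hi": [np.nan], "site": "hip",
             "count": [1], "person_years": [1.0], "rate_per_100k": [100.0]}
        )
        ref = pd.DataFrame(
            {"sex": "female", "age_lo": [55], "age_hi": [np.nan],
             "person_years": [1.0]}
        )
        with pytest.raises(BandMismatchError):
            age_standardize(inc, ref)

    @given(
        rates=st.lists(st.floats(0, 1000), min_size=2, max_size=6),
        weights=st.lists(st.floats(0.1, 100), min_size=2, max_size=6),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_brute_force_weighted_sum(self, rates, weights):
        n = min(len(rates), len(weights))
        rates, weights = rates[:n], weights[:n]
        lows = 50 + 5 * np.arange(n)
        his = [float(lo + 5) for lo in lows[:-1]] + [np.nan]
        inc = pd.DataFrame(
            {"sex": "female", "age_lo": lows, "age_hi": his, "site": "hip",
             "count": 0, "person_years": 1.0, "rate_per_100k": rates}
        )
        ref = pd.DataFrame(
            {"sex": "female", "age_lo": lows, "age_hi": his,
             "person_years": weights}
        )
        expected = sum(r * w for r, w in zip(rates, weights)) / sum(weights)
        got = age_standardize(inc, ref)["rate_per_100k"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestPooling:
    def _table(self, rates, py):
        return pd.DataFrame(
            {"sex": "female", "age_lo": [50], "age_hi": [np.nan], "site": "hip",
             "count": [r * p / 1e5 for r, p in zip(rates, py)],
             "person_years": py, "rate_per_100k": rates}
        )

    def test_self_pool_doubles_counts_keeps_rates(self):
        t = self._table([200.0], [1000.0])
        pooled = pool_regions([t, t])
        assert pooled["count"].iloc[0] == pytest.approx(2 * t["count"].iloc[0])
        assert pooled["person_years"].iloc[0] == pytest.approx(2000.0)
        assert pooled["rate_per_100k"].iloc[0] == pytest.approx(200.0)

    def test_person_year_weighting(self):
        a = self._table([100.0], [3000.0])
        b = self._table([200.0], [1000.0])
        assert pool_regions([a, b])["rate_per_100k"].iloc[0] == pytest.approx(125.0)

    def test_band_scheme_mismatch_rejected(self):
        a = self._table([100.0], [1000.0])
        b = a.copy()
        b["age_lo"] = 55
        with pytest.raises(BandMismatchError):
            pool_regions([a, b])

    @given(
        rates=st.lists(st.floats(0, 500), min_size=2, max_size=4),
        pys=st.lists(st.floats(100, 10_000), min_size=2, max_size=4),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_pooled_rate_between_regional_extremes(self, rates, pys):
        n = min(len(rates), len(pys))
        tables = [self._table([r], [p]) for r, p in zip(rates[:n], pys[:n])]
        pooled = pool_regions(tables)["rate_per_100k"].iloc[0]
        assert min(rates[:n]) - 1e-9 <= pooled <= max(rates[:n]) + 1e-9

    def test_pooling_equals_concatenated_computation(self, single_band_population):
        # compute_incidence then pool == compute_incidence on concatenated
        # cases with summed populations
        cases_a = [make_record(person_id=f"a{i}") for i in range(30)]
        cases_b = [make_record(person_id=f"b{i}", region="Vayots Dzor")
                   for i in range(10)]
        pop_a = single_band_population.assign(person_years=[40_000.0, 30_000.0])
        pop_b = single_band_population.assign(person_years=[15_000.0, 15_000.0])
        pooled = pool_regions([
            compute_incidence(cases_a, pop_a, sites=("hip",)),
            compute_incidence(cases_b, pop_b, sites=("hip",)),
        ])
        pop_sum = pop_a.copy()
        pop_sum["person_years"] += pop_b["person_years"]
        direct = compute_incidence(cases_a + cases_b, pop_sum, sites=("hip",))
        merged = pooled.merge(direct, on=["sex", "age_lo", "age_hi", "site"])
        np.testing.assert_allclose(merged["rate_per_100k_x"], merged["rate_per_100k_y"])
        np.testing.assert_allclose(merged["count_x"], merged["count_y"])


# ---------------------------------------------------------------------------
# Under-reporting, F/M ratio, projection
# ---------------------------------------------------------------------------

class TestMissedFraction:
    @pytest.mark.parametrize(
        "partial, full, pct",
        [
            ((93, 106), 177, 44),   # hip
            ((58, 72), 126, 48),    # forearm
            ((36, 31), 66, 49),     # humerus
            ((187, 209), 369, 46),  # all sites
            ((100, 100), 100, 0),
        ],
    )
    def test_printed_table_counts(self, partial, full, pct):
        est = missed_fraction(partial, full)
        assert est.percent == pct
        assert est.missed_fraction == pytest.approx(
            1 - (sum(partial) / len(partial)) / full
        )

    def test_negative_estimate_flagged_not_clamped(self):
        est = missed_fraction((120, 130), 100)
        assert est.negative and est.missed_fraction < 0

    def test_zero_full_count_rejected(self):
        with pytest.raises(ValueError):
            missed_fraction((10,), 0)


class TestRatios:
    @pytest.mark.parametrize(
        "f, m, expected", [(114, 63, 1.8), (100, 26, 3.8), (48, 18, 2.7), (10, 10, 1.0)]
    )
    def test_crude_female_male_ratios(self, f, m, expected):
        assert fm_ratio(f, m).rounded == expected

    def test_zero_male_count_undefined(self):
        with pytest.raises(UndefinedRatioError):
            fm_ratio(5, 0)

    def test_round_half_up_convention(self):
        assert round_half_up(43.5, 0) == 44.0
        assert round_half_up(1.85, 1) == 1.9
        assert round_half_up(0.415, 2) == 0.42


class TestProjection:
    def test_single_band_arithmetic(self):
        rates = pd.DataFrame(
            {"sex": ["female"], "age_lo": [50], "age_hi": [np.nan],
             "rate_per_100k": [100.0]}
        )
        pop = pd.DataFrame(
            {"sex": ["female"], "age_lo": [50], "age_hi": [np.nan],
             "person_years": [1_000_000.0]}
        )
        assert national_projection(rates, pop) == pytest.approx(1000.0)

    def test_zero_rates_project_zero(self):
        rates = pd.DataFrame(
            {"sex": ["female"], "age_lo": [50], "age_hi": [np.nan],
             "rate_per_100k": [0.0]}
        )
        pop = rates.drop(columns="rate_per_100k").assign(person_years=5e5)
        assert national_projection(rates, pop) == 0.0

    def test_missing_band_rejected(self):
        rates = pd.DataFrame(
            {"sex": ["female"], "age_lo": [50], "age_hi": [55.0],
             "rate_per_100k": [10.0]}
        )
        pop = pd.DataFrame(
            {"sex": ["female"], "age_lo": [55], "age_hi": [np.nan],
             "person_years": [1000.0]}
        )
        with pytest.raises(BandMismatchError):
            national_projection(rates, pop)

    @given(
        rates=st.lists(st.floats(0, 500), min_size=1, max_size=5),
        pys=st.lists(st.floats(1000, 1e6), min_size=1, max_size=5),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_per_band_brute_force(self, rates, pys):
        n = min(len(rates), len(pys))
        lows = 50 + 5 * np.arange(n)
        his = [float(lo + 5) for lo in lows[:-1]] + [np.nan]
        rates_df = pd.DataFrame(
            {"sex": "female", "age_lo": lows, "age_hi": his,
             "rate_per_100k": rates[:n]}
        )
        pop = pd.DataFrame(
            {"sex": "female", "age_lo": lows, "age_hi": his,
             "person_years": pys[:n]}
        )
        expected = sum(r * p / 1e5 for r, p in zip(rates[:n], pys[:n]))
        assert national_projection(rates_df, pop) == pytest.approx(expected, rel=1e-12)
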