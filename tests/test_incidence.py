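"""Case projection: per-suburb arithmetic, catchments, spokes, linearity."""

import numpy as np
import pytest

from msu_siting import (CityConfig, ProviderSpec, catchment_cases, catchment_table,
                        compute_hub_to_hospital_matrix, compute_travel_matrix,
                        generate_city, generate_incidence_schedule,
                        load_incidence_schedule, spoke_proximity, suburb_cases,
                        write_incidence_schedule)
from msu_siting.incidence import IncidenceSchedule
from msu_siting.synthetic_city import AgeBand, City, Hospital
from conftest import BANDS, make_matrix, make_suburb


def flat_schedule(rate, name="flat"):
    return IncidenceSchedule(name=name, rates={b: rate for b in BANDS})


TWO_BAND = {"0-4": 10_000, "85+": 5_000}  # 10k @ rate 50 + 5k @ rate 1000


def two_band_schedule():
    rates = {b: 0.0 for b in BANDS}
    rates[AgeBand(0, 4)] = 50.0
    rates[AgeBand(85, None)] = 1000.0
    return IncidenceSchedule(name="two", rates=rates)


class TestSuburbCases:
    def test_direct_proportion(self):
        s = make_suburb("s", 0, 0, total=100_000)
        assert suburb_cases(s, flat_schedule(200.0)) == pytest.approx(200.0)

    def test_zero_population(self):
        s = make_suburb("s", 0, 0, total=0)
        assert suburb_cases(s, flat_schedule(500.0)) == 0.0

    def test_hand_summed_two_band_example(self):
        s = make_suburb("s", 0, 0, band_pops=TWO_BAND)
        assert suburb_cases(s, two_band_schedule()) == pytest.approx(55.0)

    def test_missing_band_is_error(self):
        s = make_suburb("s", 0, 0, total=10)
        sched = IncidenceSchedule(name="partial", rates={AgeBand(0, 4): 10.0})
        with pytest.raises(ValueError, match="missing from schedule"):
            suburb_cases(s, sched)

    def test_additivity_under_suburb_merge(self):
        a = make_suburb("a", 0, 0, band_pops={"0-4": 100, "85+": 7})
        b = make_suburb("b", 0, 0, band_pops={"0-4": 40, "85+": 13})
        merged = make_suburb("m", 0, 0, band_pops={"0-4": 140, "85+": 20})
        sched = generate_incidence_schedule("high")
        assert suburb_cases(merged, sched) == pytest.approx(
            suburb_cases(a, sched) + suburb_cases(b, sched), rel=1e-12)


class TestCatchmentCases:
    def _city(self):
        suburbs = [make_suburb("near", 0.0, 0.0, total=10_000),
                   make_suburb("far", 0.0, 0.5, total=7_000)]
        hosp = [Hospital(id="hub", name="hub", lat=0.0, lon=0.25,
                         thrombolysis_capable=True, ecr_capable=True)]
        return City(suburbs=suburbs, hospitals=hosp, band_scheme=BANDS)

    def test_hand_filtered_sums(self):
        city = self._city()
        mat = make_matrix(["hub"], ["near", "far"], [[20.0, 40.0]])
        sched = flat_schedule(100.0)  # 10 and 7 cases
        assert catchment_cases("hub", mat, city, sched, "minutes", 30.0) == pytest.approx(10.0)
        assert catchment_cases("hub", mat, city, sched, "minutes", 45.0) == pytest.approx(17.0)

    def test_empty_catchment(self):
        city = self._city()
        mat = make_matrix(["hub"], ["near", "far"], [[20.0, 40.0]])
        assert catchment_cases("hub", mat, city, flat_schedule(100.0), "minutes", 5.0) == 0.0

    def test_infinite_threshold_is_total_for_every_hub(self, default_city, default_matrix):
        sched = generate_incidence_schedule("high")
        total = sum(suburb_cases(s, sched) for s in default_city.suburbs)
        for h in default_city.ecr_hospitals():
            got = catchment_cases(h.id, default_matrix, default_city, sched,
                                  "minutes", float("inf"))
            assert got == pytest.approx(total, rel=1e-12)

    def test_unknown_metric_is_error(self):
        city = self._city()
        mat = make_matrix(["hub"], ["near", "far"], [[1.0, 2.0]])
        with pytest.raises(ValueError, match="metric"):
            catchment_cases("hub", mat, city, flat_schedule(1.0), "miles", 10.0)


class TestCatchmentTable:
    def test_single_colocated_suburb_fills_every_cell(self):
        suburb = make_suburb("s", 0.0, 0.0, band_pops=TWO_BAND)
        hub = Hospital(id="hub", name="hub", lat=0.0, lon=0.0,
                       thrombolysis_capable=True, ecr_capable=True)
        city = City(suburbs=[suburb], hospitals=[hub], band_scheme=BANDS)
        mat = make_matrix(["hub"], ["s"], [[0.0]])
        table = catchment_table(city, mat, [two_band_schedule()])
        assert table.frame.cases.to_numpy() == pytest.approx([55.0] * 6)
        assert len(table.frame) == 6  # 3 minute + 3 km thresholds

    def test_rows_non_decreasing_and_low_below_high(self, default_city, default_matrix):
        scheds = [generate_incidence_schedule(p) for p in ("high", "low")]
        table = catchment_table(default_city, default_matrix, scheds)
        f = table.frame
        for (_, _, _), grp in f.groupby(["hospital_id", "metric", "schedule"]):
            cases = grp.sort_values("threshold").cases.to_numpy()
            assert np.all(np.diff(cases) >= 0)
        merged = f.pivot_table(index=["hospital_id", "metric", "threshold"],
                               columns="schedule", values="cases")
        nonempty = merged[merged["high"] > 0]
        assert (nonempty["low"] < nonempty["high"]).all()

    def test_linearity_in_population(self, default_city, default_matrix):
        import dataclasses
        sched = generate_incidence_schedule("high")
        doubled = City(
            suburbs=[dataclasses.replace(s, population={b: 2 * n for b, n in s.population.items()})
                     for s in default_city.suburbs],
            hospitals=default_city.hospitals, band_scheme=default_city.band_scheme)
        t1 = catchment_table(default_city, default_matrix, [sched])
        t2 = catchment_table(doubled, default_matrix, [sched])
        np.testing.assert_allclose(t2.frame.cases, 2.0 * t1.frame.cases, rtol=1e-9)

    def test_wide_layout_matches_cells(self, default_city, default_matrix):
        scheds = [generate_incidence_schedule(p) for p in ("high", "low")]
        table = catchment_table(default_city, default_matrix, scheds)
        wide = table.to_wide()
        assert wide.shape == (5, 12)
        hub = wide.index[0]
        assert wide.loc[hub, "high 30 min"] == pytest.approx(
            table.cell(hub, "minutes", 30.0, "high"))
        assert wide.loc[hub, "low 50 km"] == pytest.approx(
            table.cell(hub, "km", 50.0, "low"))

    def test_rejects_unsorted_thresholds(self, default_city, default_matrix):
        with pytest.raises(ValueError, match="ascending"):
            catchment_table(default_city, default_matrix,
                            [generate_incidence_schedule("high")],
                            minute_thresholds=[45.0, 30.0])


class TestSpokeProximity:
    def test_nearest_spokes_sorted_by_minutes(self, default_city):
        mat = compute_hub_to_hospital_matrix(default_city, ProviderSpec(kind="network"), "peak")
        spokes = spoke_proximity(default_city, mat, max_spokes=2)
        spoke_ids = {h.id for h in default_city.hospitals
                     if h.thrombolysis_capable and not h.ecr_capable}
        for hub_id, lst in spokes.items():
            assert len(lst) == 2
            assert lst[0][1] <= lst[1][1]
            assert all(sid in spoke_ids for sid, _, _ in lst)
            assert hub_id not in [sid for sid, _, _ in lst]

    def test_truncation_without_padding(self, toy_city):
        mat = compute_hub_to_hospital_matrix(toy_city, ProviderSpec(kind="haversine"), "offpeak")
        spokes = spoke_proximity(toy_city, mat, max_spokes=5)
        assert spokes == {"h_ecr": [("h_tpa", pytest.approx(mat.minutes_between("h_ecr", "h_tpa")),
                                     pytest.approx(mat.km_between("h_ecr", "h_tpa")))]}

    def test_no_spokes_is_error(self):
        hub = Hospital(id="hub", name="hub", lat=0.0, lon=0.0,
                       thrombolysis_capable=True, ecr_capable=True)
        city = City(suburbs=[make_suburb("s", 0, 0.1, total=1)], hospitals=[hub],
                    band_scheme=BANDS)
        mat = make_matrix(["hub"], ["hub"], [[0.0]])
        with pytest.raises(ValueError, match="spoke"):
            spoke_proximity(city, mat)


class TestScheduleCsv:
    def test_round_trip(self, tmp_path):
        sched = generate_incidence_schedule("high")
        path = tmp_path / "high.csv"
        write_incidence_schedule(sched, path)
        loaded = load_incidence_schedule(path, name="high")
        assert loaded.rates == sched.rates
        assert loaded.name == "high"
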