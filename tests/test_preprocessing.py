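"""Tests of the rule-based telemetry preprocessing."""

import numpy as np
import pandas as pd
import pytest

from migroute.datatypes import DetectionRecord, Flight
from migroute.preprocessing import (BirdRecord, apply_exclusions,
                                    build_encounter_history, classify_route,
                                    detect_departure, haversine_km,
                                    identify_flights, night_of,
                                    relative_departure_time, stopover_days,
                                    summarize_flights)


def rec(tag, time, receiver, lat, lon, antenna="A1", strength=100.0):
    return DetectionRecord(tag_id=tag, timestamp=pd.Timestamp(time),
                           receiver_id=receiver, receiver_lat=lat,
                           receiver_lon=lon, antenna_id=antenna,
                           signal_strength=strength)


class TestIdentifyFlights:
    def test_distance_rule_two_receivers(self):
        # ~36 km between endpoints, only two receivers, 2 h apart
        records = [rec("a", "2021-04-10 21:00Z", "R1", 53.60, 8.00),
                   rec("a", "2021-04-10 23:00Z", "R2", 53.925, 8.00)]
        flights = identify_flights(records)
        assert len(flights) == 1
        assert flights[0].distance_km >= 35.0

    def test_receiver_rule_short_track(self):
        # ~20 km over three distinct receivers with 2 h / 3 h gaps
        records = [rec("a", "2021-04-10 20:00Z", "R1", 53.60, 8.00),
                   rec("a", "2021-04-10 22:00Z", "R2", 53.69, 8.00),
                   rec("a", "2021-04-11 01:00Z", "R3", 53.78, 8.00)]
        flights = identify_flights(records)
        assert len(flights) == 1
        assert flights[0].distance_km < 35.0
        assert len(flights[0].receiver_sequence) == 3

    def test_neither_rule_no_flight(self):
        records = [rec("a", "2021-04-10 20:00Z", "R1", 53.60, 8.00),
                   rec("a", "2021-04-11 04:00Z", "R2", 53.69, 8.00)]
        assert identify_flights(records) == []

    def test_gap_splits_runs(self):
        # three receivers but one 8-h gap: two runs, neither qualifies
        records = [rec("a", "2021-04-10 10:00Z", "R1", 53.60, 8.00),
                   rec("a", "2021-04-10 11:00Z", "R2", 53.65, 8.00),
                   rec("a", "2021-04-10 19:30Z", "R3", 53.70, 8.00)]
        assert identify_flights(records) == []

    def test_order_insensitive(self, rng):
        records = [rec("a", "2021-04-10 21:00Z", "R1", 53.60, 8.00),
                   rec("a", "2021-04-10 22:00Z", "R2", 53.80, 8.10),
                   rec("a", "2021-04-10 23:00Z", "R3", 54.00, 8.20),
                   rec("b", "2021-04-10 22:30Z", "R1", 53.60, 8.00),
                   rec("b", "2021-04-10 23:30Z", "R2", 53.80, 8.10)]
        base = identify_flights(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        again = identify_flights(shuffled)
        assert [(f.tag_id, f.start_time) for f in base] == \
            [(f.tag_id, f.start_time) for f in again]

    def test_track_distance_method(self):
        # dogleg: endpoint displacement small, summed track long
        records = [rec("a", "2021-04-10 21:00Z", "R1", 53.60, 8.00),
                   rec("a", "2021-04-10 22:00Z", "R2", 53.90, 8.00),
                   rec("a", "2021-04-10 23:00Z", "R1", 53.60, 8.00)]
        assert identify_flights(records, min_receivers=5) == []
        flights = identify_flights(records, min_receivers=5,
                                   distance_method="track")
        assert len(flights) == 1


def _flight(start_lon, final_lat, receivers=("R1", "R2"), final_lon=None):
    return Flight(tag_id="a", start_time=pd.Timestamp("2021-04-10 21:00Z"),
                  end_time=pd.Timestamp("2021-04-10 23:00Z"),
                  start_lon=start_lon, start_lat=53.6, final_lat=final_lat,
                  final_lon=final_lon if final_lon is not None else start_lon,
                  receiver_sequence=tuple(receivers), distance_km=40.0)


class TestClassifyRoute:
    def test_west_start_north_end_is_offshore(self):
        assert classify_route(_flight(7.90, 54.20)) == "offshore"

    def test_offshore_station_overrides_thresholds(self):
        f = _flight(8.30, 54.50, receivers=("R1", "Helgoland"))
        assert classify_route(f) == "offshore"

    def test_complement_is_onshore(self):
        assert classify_route(_flight(8.30, 53.90)) == "onshore"

    def test_boundary_needs_both_conditions(self):
        assert classify_route(_flight(7.90, 53.90)) == "onshore"
        assert classify_route(_flight(8.30, 54.50)) == "onshore"


class TestDetectDeparture:
    def _series(self, strengths, spacing_s=60, antenna="A1",
                last="2021-04-12 20:30Z"):
        last = pd.Timestamp(last)
        times = [last - pd.Timedelta(seconds=spacing_s * k)
                 for k in range(len(strengths) - 1, -1, -1)]
        return [rec("a", t, "R1", 53.6, 8.0, antenna=antenna, strength=s)
                for t, s in zip(times, strengths)]

    def test_plateau_then_decline_is_departure(self):
        series = self._series([100, 100, 100, 100, 100, 90, 80, 70, 60, 50])
        result = detect_departure(series)
        assert result.status == "departure"
        assert result.time == pd.Timestamp("2021-04-12 20:30Z")
        assert result.last5_mean == 70.0
        assert result.peak_window_mean == 100.0

    def test_constant_strength_is_not_departure(self):
        result = detect_departure(self._series([100.0] * 8))
        assert result.status == "no_departure"
        assert result.last5_mean == result.peak_window_mean

    def test_too_few_detections_undetermined(self):
        result = detect_departure(self._series([100, 90, 80, 70]))
        assert result.status == "undetermined"
        assert result.time is None

    def test_uses_antenna_with_latest_detections(self):
        quiet = self._series([100.0] * 6, antenna="A1",
                             last="2021-04-12 18:00Z")
        declining = self._series([100, 100, 100, 100, 100, 80, 60, 50, 40, 30],
                                 antenna="A2", last="2021-04-12 20:30Z")
        result = detect_departure(quiet + declining)
        assert result.status == "departure"
        assert result.antenna_id == "A2"


class TestExclusions:
    def _bird(self, tag="a", species="Dunnock", flights=(), departure=None,
              deploy="2021-04-01 09:00Z"):
        return BirdRecord(tag_id=tag, species=species, tag_type="NTQB",
                          deployment_time=pd.Timestamp(deploy),
                          flights=list(flights), departure_time=departure)

    def test_long_stopover_excluded_boundary_retained(self):
        late = self._bird("late", departure=pd.Timestamp("2021-05-12 21:00Z"))
        exact = self._bird("exact", departure=pd.Timestamp("2021-05-11 21:00Z"))
        out = apply_exclusions([late, exact], max_stopover_days=40)
        assert [b.tag_id for b in out.retained] == ["exact"]
        row = out.log[out.log["tag_id"] == "late"].iloc[0]
        assert row["rule"] == "stopover>40d"

    def test_only_first_flight_kept(self):
        f1 = _flight(8.3, 53.9)
        f2 = Flight(tag_id="a", start_time=pd.Timestamp("2021-04-12 21:00Z"),
                    end_time=pd.Timestamp("2021-04-12 23:00Z"), start_lon=8.3,
                    start_lat=53.9, final_lat=54.1, final_lon=8.5,
                    receiver_sequence=("R3", "R4"), distance_km=40.0)
        out = apply_exclusions([self._bird(flights=[f2, f1])])
        assert len(out.retained) == 1
        assert out.retained[0].flights == [f1]
        assert (out.log["rule"] == "not_first_flight").sum() == 1

    def test_westward_short_flight_dropped(self):
        west = Flight(tag_id="a", start_time=pd.Timestamp("2021-04-10 21:00Z"),
                      end_time=pd.Timestamp("2021-04-10 22:00Z"), start_lon=8.3,
                      start_lat=53.7, final_lat=53.72, final_lon=8.05,
                      receiver_sequence=("R1", "R2", "R3"), distance_km=18.0)
        out = apply_exclusions([self._bird(flights=[west])])
        assert out.retained == []
        assert set(out.log["rule"]) == {"westward_coastal_flight",
                                        "departure_undetermined"}

    def test_deployment_morning_rule_is_species_specific(self):
        dep = pd.Timestamp("2021-04-01 10:30Z")
        blackcap = self._bird("bc", species="Blackcap", departure=dep)
        dunnock = self._bird("dn", species="Dunnock", departure=dep)
        out = apply_exclusions([blackcap, dunnock])
        assert [b.tag_id for b in out.retained] == ["dn"]
        assert "deployment_morning_departure" in set(out.log["rule"])

    def test_individual_accounting_balances(self):
        birds = [self._bird(f"b{k}", departure=pd.Timestamp("2021-04-05 22:00Z"))
                 for k in range(4)]
        birds.append(self._bird("nodep"))
        out = apply_exclusions(birds)
        individual_log = out.log[out.log["level"] == "individual"]
        assert len(out.retained) + individual_log["tag_id"].nunique() == 5


class TestEncounterHistoryBuilding:
    def test_detected_offshore_flight(self):
        f = _flight(7.9, 54.2)
        f.route = "offshore"
        h = build_encounter_history("2021-04-01", "2021-04-04", f, T=8,
                                    tag_id="a", species="Dunnock")
        np.testing.assert_array_equal(h.codes, [1, 1, 1, 2, 4, 4, 4, 4])

    def test_unseen_departure(self):
        h = build_encounter_history("2021-04-01", "2021-04-02", None, T=6,
                                    tag_id="a", species="Dunnock")
        np.testing.assert_array_equal(h.codes, [1, 4, 4, 4, 4, 4])

    def test_undetermined_not_emitted(self):
        assert build_encounter_history("2021-04-01", None, None) is None

    def test_departure_before_deployment_rejected(self):
        with pytest.raises(ValueError):
            build_encounter_history("2021-04-10", "2021-04-01", None)

    def test_sunrise_departure_belongs_to_previous_night(self):
        assert night_of("2021-04-11 05:10Z") == pd.Timestamp("2021-04-10",
                                                             tz="UTC")
        assert night_of("2021-04-10 22:00Z") == pd.Timestamp("2021-04-10",
                                                             tz="UTC")
        assert stopover_days("2021-04-01 09:00Z", "2021-04-11 05:10Z") == 9


class TestRelativeDepartureTime:
    def test_boundaries_and_midpoint(self):
        sunset = pd.Timestamp("2021-04-10 19:00Z")
        sunrise = pd.Timestamp("2021-04-11 04:18Z")  # a 9.3-hour night
        assert relative_departure_time(sunset, sunset, sunrise) == 0.0
        assert relative_departure_time(sunrise, sunset, sunrise) == 1.0
        mid = sunset + pd.Timedelta(hours=4.65)
        assert relative_departure_time(mid, sunset, sunrise) == pytest.approx(0.5)

    def test_diurnal_departure_exceeds_one(self):
        sunset = pd.Timestamp("2021-04-10 19:00Z")
        sunrise = pd.Timestamp("2021-04-11 05:00Z")
        late = pd.Timestamp("2021-04-11 06:00Z")
        assert relative_departure_time(late, sunset, sunrise) > 1.0

    def test_zero_night_rejected(self):
        t = pd.Timestamp("2021-04-10 19:00Z")
        with pytest.raises(ValueError):
            relative_departure_time(t, t, t)


class TestSummaries:
    def test_single_flight_sd_zero(self):
        f = _flight(7.9, 54.48)
        f.route, f.species = "offshore", "Dunnock"
        table = summarize_flights([f])
        assert table.loc[0, "mean_final_lat"] == 54.48
        assert table.loc[0, "sd_final_lat"] == 0.0

    def test_constructed_group_means(self, rng):
        lats = 54.0 + rng.uniform(0.2, 0.5, 10)
        flights = []
        for lat in lats:
            f = _flight(7.9, lat)
            f.route, f.species = "offshore", "Blackcap"
            flights.append(f)
        table = summarize_flights(flights)
        assert table.loc[0, "n"] == 10
        assert table.loc[0, "mean_final_lat"] == pytest.approx(lats.mean())
        assert table.loc[0, "sd_final_lat"] == pytest.approx(lats.std(ddof=1))
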