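"""Rule-based preprocessing of raw telemetry into encounter histories.

The rules mirror the study protocol for coastal radio-telemetry: continuous
movements ("flights") are runs of detections whose gaps stay below a
maximum span; a run is a flight if it covers a minimum distance or touches
a minimum number of distinct receivers; flights are routed offshore or
onshore from their start longitude, final latitude and offshore-island
receivers; departures of birds without a detected flight are read from the
signal-strength pattern at the stopover site (a terminal decline below the
recent peak); and individuals are filtered by explicit exclusion rules
before being written as daily encounter histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import Code, DetectionRecord, EncounterHistory, Flight

DEFAULT_OFFSHORE_STATIONS = frozenset({"Helgoland", "FINO3"})


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres (WGS84 mean-radius sphere)."""
    r = 6371.0088
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return float(2 * r * np.arcsin(np.sqrt(a)))


def _track_length_km(records: Sequence[DetectionRecord]) -> float:
    d = 0.0
    for a, b in zip(records[:-1], records[1:]):
        d += haversine_km(a.receiver_lat, a.receiver_lon, b.receiver_lat, b.receiver_lon)
    return d


def identify_flights(records: Iterable[DetectionRecord],
                     min_distance_km: float = 35.0,
                     min_receivers: int = 3,
                     max_span_hours: float = 7.0,
                     distance_method: str = "endpoint") -> list:
    """Segment detection records into flights.

    Candidate movements are maximal runs of detections (per tag) in which
    every inter-detection gap is below ``max_span_hours``; runs of fewer
    than two records are never flights.  A run qualifies as a flight iff it
    covers at least ``min_distance_km`` (great-circle between the first and
    last detection by default; ``distance_method='track'`` sums the
    receiver-to-receiver legs) or touches at least ``min_receivers``
    distinct receivers.  Flights are returned in time order.
    """
    if distance_method not in ("endpoint", "track"):
        raise ValueError("distance_method must be 'endpoint' or 'track'")
    records = sorted(records, key=lambda r: (r.tag_id, r.timestamp))
    flights = []
    max_gap = pd.Timedelta(hours=max_span_hours)
    run: list = []

    def close_run(run):
        if len(run) < 2:
            return
        first, last = run[0], run[-1]
        if distance_method == "endpoint":
            dist = haversine_km(first.receiver_lat, first.receiver_lon,
                                last.receiver_lat, last.receiver_lon)
        else:
            dist = _track_length_km(run)
        receivers = []
        for rec in run:
            if rec.receiver_id not in receivers:
                receivers.append(rec.receiver_id)
        if dist >= min_distance_km or len(receivers) >= min_receivers:
            flights.append(Flight(
                tag_id=first.tag_id, start_time=first.timestamp,
                end_time=last.timestamp,
                start_lon=first.receiver_lon, start_lat=first.receiver_lat,
                final_lat=last.receiver_lat, final_lon=last.receiver_lon,
                receiver_sequence=tuple(receivers), distance_km=dist))

    for rec in records:
        if run and (rec.tag_id != run[-1].tag_id
                    or rec.timestamp - run[-1].timestamp >= max_gap):
            close_run(run)
            run = []
        run.append(rec)
    close_run(run)
    flights.sort(key=lambda f: (f.start_time, f.tag_id))
    return flights


def classify_route(flight: Flight,
                   lon_threshold: float = 8.08,
                   lat_threshold: float = 54.135,
                   offshore_station_ids: frozenset = DEFAULT_OFFSHORE_STATIONS) -> str:
    """Label a flight offshore or onshore.

    Offshore iff it began west of ``lon_threshold`` and ended north of
    ``lat_threshold``, or it was detected at an offshore receiver station.
    """
    if any(rid in offshore_station_ids for rid in flight.receiver_sequence):
        return "offshore"
    if flight.start_lon < lon_threshold and flight.final_lat > lat_threshold:
        return "offshore"
    return "onshore"


@dataclass
class DepartureResult:
    time: Optional[pd.Timestamp]
    status: str  # {"departure", "no_departure", "undetermined"}
    antenna_id: Optional[str] = None
    last5_mean: Optional[float] = None
    peak_window_mean: Optional[float] = None


def detect_departure(stopover_records: Sequence[DetectionRecord],
                     peak_window_minutes: float = 10.0) -> DepartureResult:
    """Read a departure from the terminal signal-strength pattern.

    On the antenna with the latest detections (among antennas with at least
    five detections): compare the mean of the last five detections (A)
    against the mean of the highest signal strength within the final
    ``peak_window_minutes`` before signal loss together with its up to four
    temporally neighbouring values on the same antenna (B).  A departure at
    the last detection time is declared iff A < B (strictly).  If no
    antenna has five detections the departure is undetermined.
    """
    by_antenna: dict = {}
    for rec in sorted(stopover_records, key=lambda r: r.timestamp):
        by_antenna.setdefault((rec.receiver_id, rec.antenna_id), []).append(rec)
    eligible = {k: v for k, v in by_antenna.items() if len(v) >= 5}
    if not eligible:
        return DepartureResult(time=None, status="undetermined")
    key = max(eligible, key=lambda k: eligible[k][-1].timestamp)
    recs = eligible[key]
    strengths = np.array([r.signal_strength for r in recs], dtype=float)
    last_time = recs[-1].timestamp
    a = float(strengths[-5:].mean())
    window = pd.Timedelta(minutes=peak_window_minutes)
    in_window = np.array([r.timestamp > last_time - window for r in recs])
    if not in_window.any():
        in_window[-1] = True  # the last detection itself defines the window
    window_idx = np.nonzero(in_window)[0]
    peak = window_idx[np.argmax(strengths[window_idx])]
    lo, hi = max(0, peak - 2), min(len(strengths), peak + 3)
    b = float(strengths[lo:hi].mean())
    if a < b:
        return DepartureResult(time=last_time, status="departure",
                               antenna_id=key[1], last5_mean=a, peak_window_mean=b)
    return DepartureResult(time=None, status="no_departure",
                           antenna_id=key[1], last5_mean=a, peak_window_mean=b)


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass
class BirdRecord:
    """Per-individual preprocessing state entering the exclusion filter."""

    tag_id: str
    species: str
    tag_type: str
    deployment_time: pd.Timestamp
    flights: list = field(default_factory=list)
    departure_time: Optional[pd.Timestamp] = None  # from signal loss, if any

    def best_departure_time(self) -> Optional[pd.Timestamp]:
        if self.flights:
            return self.flights[0].start_time
        return self.departure_time


def night_of(timestamp: pd.Timestamp) -> pd.Timestamp:
    """Date of the evening a nocturnal event belongs to.

    Events before local noon (UTC used throughout) are attributed to the
    previous day's night, so a departure around sunrise counts toward the
    night that began the evening before.
    """
    return (pd.Timestamp(timestamp) - pd.Timedelta(hours=12)).normalize()


def stopover_days(deployment_time: pd.Timestamp, departure_time: pd.Timestamp) -> int:
    """Minimum stopover duration in whole days on the night grid.

    Days elapsed between the deployment day and the night of departure;
    a bird leaving on the evening of its deployment day has stopover 0.
    """
    return int((night_of(departure_time) - pd.Timestamp(deployment_time).normalize())
               / pd.Timedelta(days=1))


MORNING_RULE_SPECIES = ("Blackcap", "Garden Warbler")


@dataclass
class ExclusionOutcome:
    retained: list  # BirdRecord with at most one flight each
    log: pd.DataFrame  # columns: tag_id, level, rule, detail


def apply_exclusions(individuals: Sequence[BirdRecord],
                     max_stopover_days: int = 40,
                     morning_cutoff_hour: int = 12,
                     min_flight_km: float = 35.0) -> ExclusionOutcome:
    """Apply the study's exclusion rules, logging every decision.

    Flight-level rules first: short westward coastal flights (westward
    displacement under ``min_flight_km``) are discarded as non-migratory,
    and flights or signal-loss departures of the two warbler species on the
    morning of tag deployment are discarded as post-release stopover
    movements.  Then only each bird's first flight is kept.  Finally
    individuals whose minimum stopover exceeds ``max_stopover_days`` (or
    that retain neither a flight nor a departure) are excluded.
    """
    log_rows = []
    retained = []
    for bird in individuals:
        flights = sorted(bird.flights, key=lambda f: f.start_time)
        departure_time = bird.departure_time
        kept_flights = []
        for f in flights:
            westward = f.final_lon < f.start_lon
            if westward and f.distance_km < min_flight_km:
                log_rows.append((bird.tag_id, "flight", "westward_coastal_flight",
                                 f"{f.distance_km:.1f} km westward"))
                continue
            same_morning = (f.start_time.normalize() ==
                            pd.Timestamp(bird.deployment_time).normalize()
                            and f.start_time.hour < morning_cutoff_hour)
            if bird.species in MORNING_RULE_SPECIES and same_morning:
                log_rows.append((bird.tag_id, "flight", "deployment_morning_flight",
                                 str(f.start_time)))
                continue
            kept_flights.append(f)
        if departure_time is not None and bird.species in MORNING_RULE_SPECIES:
            dep = pd.Timestamp(departure_time)
            if (dep.normalize() == pd.Timestamp(bird.deployment_time).normalize()
                    and dep.hour < morning_cutoff_hour):
                log_rows.append((bird.tag_id, "departure",
                                 "deployment_morning_departure", str(dep)))
                departure_time = None
        for extra in kept_flights[1:]:
            log_rows.append((bird.tag_id, "flight", "not_first_flight",
                             str(extra.start_time)))
        kept_flights = kept_flights[:1]

        candidate = BirdRecord(
            tag_id=bird.tag_id, species=bird.species, tag_type=bird.tag_type,
            deployment_time=bird.deployment_time, flights=kept_flights,
            departure_time=departure_time)
        dep_time = candidate.best_departure_time()
        if dep_time is None:
            log_rows.append((bird.tag_id, "individual", "departure_undetermined", ""))
            continue
        days = stopover_days(bird.deployment_time, dep_time)
        if days > max_stopover_days:
            log_rows.append((bird.tag_id, "individual", "stopover>40d", f"{days} days"))
            continue
        retained.append(candidate)
    log = pd.DataFrame(log_rows, columns=["tag_id", "level", "rule", "detail"])
    return ExclusionOutcome(retained=retained, log=log)


# ---------------------------------------------------------------------------
# encounter histories and derived quantities
# ---------------------------------------------------------------------------

def build_encounter_history(deployment_day, departure_day,
                            flight: Optional[Flight],
                            T: int = 36,
                            tag_id: str = "", species: str = "",
                            tag_type: str = "NTQB") -> Optional[EncounterHistory]:
    """Write one bird's daily encounter history.

    Occasion 1 is the night following tag deployment; the departure falls
    on occasion (departure_day - deployment_day + 1).  The departure
    occasion holds the route code if a flight was detected and routed, and
    NOT_SEEN otherwise; later occasions are NOT_SEEN.  Birds without a
    determined departure are not emitted (returns None).
    """
    if departure_day is None:
        return None
    deployment_day = pd.Timestamp(deployment_day).normalize()
    departure_day = pd.Timestamp(departure_day).normalize()
    delta = int((departure_day - deployment_day) / pd.Timedelta(days=1))
    if delta < 0:
        raise ValueError("departure before deployment")
    occ = delta + 1
    if occ > T:
        raise ValueError(f"departure occasion {occ} beyond the {T}-occasion window")
    codes = np.full(T, int(Code.STOPOVER))
    if flight is not None and flight.route in ("offshore", "onshore"):
        codes[occ - 1] = int(Code.OFFSHORE if flight.route == "offshore"
                             else Code.ONSHORE)
    else:
        codes[occ - 1] = int(Code.NOT_SEEN)
    codes[occ:] = int(Code.NOT_SEEN)
    return EncounterHistory(tag_id=tag_id, species=species,
                            tag_type=tag_type, codes=codes)


def relative_departure_time(departure, sunset, next_sunrise) -> float:
    """Departure time as a fraction of night length (sunset -> sunrise).

    Values outside [0, 1] are legitimate for diurnal departures.
    """
    departure, sunset, next_sunrise = map(pd.Timestamp, (departure, sunset, next_sunrise))
    night = (next_sunrise - sunset).total_seconds()
    if night <= 0:
        raise ValueError("night length must be positive (sunset before sunrise)")
    return (departure - sunset).total_seconds() / night


def summarize_flights(flights: Sequence[Flight]) -> pd.DataFrame:
    """Per route and species: count, mean and SD of the final-detection
    latitude (SD reported as 0.0 for singleton groups)."""
    rows = [{"route": f.route, "species": f.species, "final_lat": f.final_lat}
            for f in flights]
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["route", "species", "n", "mean_final_lat",
                                     "sd_final_lat"])
    out = (frame.groupby(["route", "species"], dropna=False)["final_lat"]
           .agg(n="size", mean_final_lat="mean", sd_final_lat="std")
           .reset_index())
    out["sd_final_lat"] = out["sd_final_lat"].fillna(0.0)
    return out
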