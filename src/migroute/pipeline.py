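"""Configuration and staged pipeline tying the analysis together.

Stages: ``simulate`` (synthetic raw-data bundle), ``preprocess`` (records
-> flights, departures, exclusions, encounter histories), ``fit``
(posterior sampling), ``summarize`` (species means, contrasts, offshore
count), ``ppc`` (posterior predictive checks), and ``all``.  One config
object drives everything; every output table carries a header comment
with the producing command and a config hash, and each run writes a log
with the config echo, seed and filter accounting.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import (DEFAULT_N_OCCASIONS, EncounterHistory, DetectionRecord,
                        histories_from_frame, histories_to_frame)
from .glms import (DepartureTimeObservation, StopoverObservation,
                   fit_departure_time_model, fit_stopover_model)
from .hmm import CovariateBasis
from .inference import (PosteriorDraws, PriorSpec, diagnostics,
                        draws_from_frame, posterior_predictive_check,
                        sample_posterior)
from .preprocessing import (BirdRecord, apply_exclusions,
                            build_encounter_history, classify_route,
                            detect_departure, haversine_km, identify_flights,
                            night_of, relative_departure_time, stopover_days,
                            summarize_flights)
from .summaries import (attribute_unknown_routes, distance_contrast,
                        species_mean_departure, species_mean_routing)
from .synthetic_data import (WeatherParams, build_raw_bundle,
                             default_species_configs, simulate_covariates,
                             simulate_individuals)

log = logging.getLogger("migroute")

COMMANDS = ("simulate", "preprocess", "fit", "summarize", "ppc", "all")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one place (YAML-serializable)."""

    out_dir: str = "migroute_output"
    # preprocessing rule thresholds
    min_distance_km: float = 35.0
    min_receivers: int = 3
    max_span_hours: float = 7.0
    lon_threshold: float = 8.08
    lat_threshold: float = 54.135
    offshore_station_ids: tuple = ("Helgoland", "FINO3")
    max_stopover_days: int = 40
    stopover_radius_km: float = 20.0
    # simulation
    n_scale: float = 1.0
    n_occasions: int = DEFAULT_N_OCCASIONS
    wind_sd: float = 4.0
    pressure_change_sd: float = 5.0
    humidity_lo: float = 40.0
    humidity_hi: float = 100.0
    rain_prob: float = 10 / 128
    # model settings
    seed: int = 1
    n_chains: int = 4
    n_iter: int = 24000
    n_warmup: int = 6000
    backend: str = "metropolis"
    prior_intercept_sd: float = 1.5
    prior_slope_sd: float = 1.0
    # summaries
    hpdi_mass: float = 0.90
    ppc_replicates: int = 100

    def __post_init__(self):
        if not 0.0 < self.hpdi_mass < 1.0:
            raise ValueError("hpdi_mass must lie in (0, 1)")
        for name in ("min_distance_km", "min_receivers", "max_span_hours",
                     "max_stopover_days", "n_occasions", "n_chains", "n_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "offshore_station_ids" in data:
            data["offshore_station_ids"] = tuple(data["offshore_station_ids"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["offshore_station_ids"] = list(self.offshore_station_ids)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in asdict(self).items()}, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]

    @property
    def weather(self) -> WeatherParams:
        return WeatherParams(wind_sd=self.wind_sd,
                             pressure_change_sd=self.pressure_change_sd,
                             humidity_range=(self.humidity_lo, self.humidity_hi),
                             rain_prob=self.rain_prob)

    @property
    def priors(self) -> PriorSpec:
        return PriorSpec(intercept_sd=self.prior_intercept_sd,
                         slope_sd=self.prior_slope_sd)


# ---------------------------------------------------------------------------
# table I/O with provenance header
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: Path, command: str,
                config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# migroute {__version__} {command} config={config.config_hash()}\n")
        frame.to_csv(fh, index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _setup_logging(out_dir: Path, command: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.INFO)
    log.handlers = [logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / f"{command}.log", mode="w")]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    configs = default_species_configs(scale=config.n_scale)
    n_total = sum(c.n_individuals for c in configs)
    covariates = simulate_covariates(n_total, config.n_occasions,
                                     config.weather, seed=config.seed)
    sim = simulate_individuals(configs, covariates, n_occasions=config.n_occasions,
                               seed=config.seed + 1)
    bundle = build_raw_bundle(sim, seed=config.seed + 2)
    for name, frame in bundle.items():
        write_table(frame, out / f"{name}.csv", "simulate", config)
    log.info("simulate: %d tagged, %d determined, %d detection records",
             n_total, len(sim.histories), len(bundle["records"]))


def _stage_preprocess(config: PipelineConfig, out: Path) -> None:
    records_frame = read_table(out / "records.csv",
                               parse_dates=["timestamp"])
    metadata = read_table(out / "metadata.csv", parse_dates=["deployment_time"])
    sunsets = read_table(out / "sunsets.csv", parse_dates=["sunset", "sunrise"])
    records = [DetectionRecord(**row) for row in
               records_frame.to_dict(orient="records")]

    flights = identify_flights(records, config.min_distance_km,
                               config.min_receivers, config.max_span_hours)
    for f in flights:
        f.route = classify_route(f, config.lon_threshold, config.lat_threshold,
                                 frozenset(config.offshore_station_ids))
    flights_by_tag: dict = {}
    for f in flights:
        flights_by_tag.setdefault(f.tag_id, []).append(f)

    recs_by_tag: dict = {}
    for r in records:
        recs_by_tag.setdefault(r.tag_id, []).append(r)

    birds = []
    for _, m in metadata.iterrows():
        tag_id = m["tag_id"]
        tag_flights = flights_by_tag.get(tag_id, [])
        stop_recs = [r for r in recs_by_tag.get(tag_id, [])
                     if haversine_km(r.receiver_lat, r.receiver_lon,
                                     m["deployment_lat"], m["deployment_lon"])
                     < config.stopover_radius_km]
        departure_time = None
        if not tag_flights:
            result = detect_departure(stop_recs)
            if result.status == "departure":
                departure_time = result.time
        birds.append(BirdRecord(
            tag_id=tag_id, species=m["species"], tag_type=m["tag_type"],
            deployment_time=m["deployment_time"], flights=tag_flights,
            departure_time=departure_time))

    outcome = apply_exclusions(birds, config.max_stopover_days,
                               min_flight_km=config.min_distance_km)
    meta_by_tag = metadata.set_index("tag_id")
    sun_by_day = sunsets.assign(day=pd.to_datetime(sunsets["day"])).set_index("day")

    histories, stop_rows, time_rows = [], [], []
    for bird in outcome.retained:
        m = meta_by_tag.loc[bird.tag_id]
        dep_time = bird.best_departure_time()
        dep_day = night_of(dep_time)
        flight = bird.flights[0] if bird.flights else None
        if flight is not None:
            flight.species = m["model_group"]
        h = build_encounter_history(
            deployment_day=pd.Timestamp(bird.deployment_time).normalize(),
            departure_day=dep_day, flight=flight, T=config.n_occasions,
            tag_id=bird.tag_id, species=m["model_group"], tag_type=bird.tag_type)
        histories.append(h)
        if flight is not None:
            stop_rows.append({
                "tag_id": bird.tag_id, "species": m["model_group"],
                "distance_group": m["distance_group"], "route": flight.route,
                "duration": stopover_days(bird.deployment_time, dep_time)})
            sun = sun_by_day.loc[dep_day]
            time_rows.append({
                "tag_id": bird.tag_id, "species": m["model_group"],
                "route": flight.route,
                "rel_time": relative_departure_time(
                    dep_time, sun["sunset"], sun["sunrise"])})

    write_table(pd.DataFrame(
        [{"tag_id": f.tag_id, "start_time": f.start_time, "end_time": f.end_time,
          "start_lon": f.start_lon, "final_lat": f.final_lat,
          "final_lon": f.final_lon, "distance_km": f.distance_km,
          "n_receivers": len(f.receiver_sequence), "route": f.route}
         for f in flights]), out / "flights.csv", "preprocess", config)
    write_table(outcome.log, out / "exclusions.csv", "preprocess", config)
    write_table(histories_to_frame(histories), out / "histories.csv",
                "preprocess", config)
    write_table(pd.DataFrame(stop_rows), out / "stopover.csv", "preprocess", config)
    write_table(pd.DataFrame(time_rows), out / "departure_times.csv",
                "preprocess", config)
    write_table(summarize_flights(flights), out / "flight_summary.csv",
                "preprocess", config)
    n_excluded = outcome.log[outcome.log["level"] == "individual"]["tag_id"].nunique()
    log.info("preprocess: %d birds in, %d histories out, %d excluded "
             "(%d flights identified)", len(birds), len(histories),
             n_excluded, len(flights))


def _load_model_inputs(config: PipelineConfig, out: Path):
    hist_frame = read_table(out / "histories.csv")
    histories = histories_from_frame(hist_frame)
    covariates = read_table(out / "covariates.csv")
    wanted = {h.tag_id for h in histories}
    covariates = covariates[covariates["individual"].isin(wanted)]
    basis = CovariateBasis.from_table(covariates)
    order = {tag: k for k, tag in enumerate(basis.individuals)}
    histories.sort(key=lambda h: order[h.tag_id])
    return histories, basis


def _stage_fit(config: PipelineConfig, out: Path) -> None:
    histories, basis = _load_model_inputs(config, out)
    draws = sample_posterior(
        histories, basis, priors=config.priors, n_chains=config.n_chains,
        n_iter=config.n_iter, n_warmup=config.n_warmup, seed=config.seed,
        backend=config.backend)
    write_table(draws.to_frame(), out / "draws.csv", "fit", config)
    diag = diagnostics(draws)
    write_table(diag.reset_index(names="parameter"), out / "diagnostics.csv",
                "fit", config)
    log.info("fit: %d histories, backend=%s, worst rhat=%.3f",
             len(histories), config.backend, diag["rhat"].max())


def _reload_draws(config: PipelineConfig, out: Path) -> PosteriorDraws:
    frame = read_table(out / "draws.csv")
    return draws_from_frame(frame, backend=config.backend, seed=config.seed)


def _stage_summarize(config: PipelineConfig, out: Path) -> None:
    histories, basis = _load_model_inputs(config, out)
    draws = _reload_draws(config, out)
    metadata = read_table(out / "metadata.csv")
    grouping = (metadata.drop_duplicates("model_group")
                .set_index("model_group")["distance_group"].to_dict())

    dep = species_mean_departure(draws, histories, basis, mass=config.hpdi_mass)
    route = species_mean_routing(draws, histories, basis, mass=config.hpdi_mass)
    rows = [dep.table, route.table]
    sp_cols = [c for c in dep.per_draw.columns if c != "overall"]
    for label, summary in (("departure", dep), ("routing", route)):
        c = distance_contrast(summary.per_draw[sp_cols], grouping,
                              mass=config.hpdi_mass)
        c.pop("draws")
        c["quantity"] = f"{label}_{c['quantity']}"
        rows.append(pd.DataFrame([c]))
    attribution = attribute_unknown_routes(draws, histories, basis,
                                           seed=config.seed,
                                           mass=config.hpdi_mass)
    rows.append(attribution.table)
    summary = pd.concat(rows, ignore_index=True)
    write_table(summary, out / "summary.csv", "summarize", config)

    stop_frame = read_table(out / "stopover.csv")
    if len(stop_frame):
        stop_obs = [StopoverObservation(int(r.duration), r.species, r.route,
                                        r.distance_group)
                    for r in stop_frame.itertuples()]
        stop_fit = fit_stopover_model(stop_obs, seed=config.seed,
                                      n_chains=config.n_chains,
                                      n_iter=config.n_iter,
                                      n_warmup=config.n_warmup,
                                      backend=config.backend,
                                      mass=config.hpdi_mass)
        write_table(stop_fit.table, out / "stopover_model.csv", "summarize", config)
    time_frame = read_table(out / "departure_times.csv")
    if len(time_frame):
        time_obs = [DepartureTimeObservation(float(r.rel_time), r.species, r.route)
                    for r in time_frame.itertuples()]
        time_fit = fit_departure_time_model(time_obs, seed=config.seed,
                                            n_chains=config.n_chains,
                                            n_iter=config.n_iter,
                                            n_warmup=config.n_warmup,
                                            backend=config.backend,
                                            mass=config.hpdi_mass)
        write_table(time_fit.table, out / "departure_time_model.csv",
                    "summarize", config)
    log.info("summarize: %d quantities", len(summary))


def _stage_ppc(config: PipelineConfig, out: Path) -> None:
    histories, basis = _load_model_inputs(config, out)
    draws = _reload_draws(config, out)
    table = posterior_predictive_check(draws, histories, basis,
                                       seed=config.seed,
                                       n_rep=config.ppc_replicates)
    write_table(table, out / "ppc.csv", "ppc", config)
    log.info("ppc: %d/%d statistics inside the central 95%% interval",
             int(table["inside"].sum()), len(table))


def run_pipeline(command: str, config: PipelineConfig) -> int:
    """Run one pipeline stage (or ``all``); returns a process exit status."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")
    out = Path(config.out_dir)
    _setup_logging(out, command)
    log.info("migroute %s | command=%s seed=%d config=%s",
             __version__, command, config.seed, config.config_hash())
    config.to_yaml(out / "config_used.yaml")
    stages = {"simulate": _stage_simulate, "preprocess": _stage_preprocess,
              "fit": _stage_fit, "summarize": _stage_summarize,
              "ppc": _stage_ppc}
    try:
        if command == "all":
            for name in ("simulate", "preprocess", "fit", "summarize", "ppc"):
                stages[name](config, out)
        else:
            stages[command](config, out)
    except (FileNotFoundError, KeyError, ValueError) as err:
        log.error("%s failed: %s", command, err)
        return 1
    return 0
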