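"""Posterior summaries: HPD intervals, species means, contrasts, and the
detection-corrected offshore flight count.

The headline quantities of the analysis are species-level mean departure
(psi) and offshore-routing (chi) probabilities, long- minus short-distance
contrasts, and a latent count of offshore flights that attributes each
route-unknown departure to the offshore route with probability

    P(offshore | departure not seen) = chi (1-pX) / (chi (1-pX) + (1-chi)(1-pC))

evaluated at that individual's departure-night covariates and tag type.
All intervals are highest-posterior-density intervals (shortest window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import TAG_TYPES, Code, EncounterHistory
from .hmm import CovariateBasis
from .inference import PosteriorDraws


def hpdi(samples, mass: float = 0.90) -> tuple:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties are broken toward the lowest starting value.
    """
    samples = np.sort(np.asarray(samples, dtype=float))
    n = samples.size
    if n < 20:
        raise ValueError("hpdi needs at least 20 samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    m = int(np.ceil(mass * n))
    widths = samples[m - 1:] - samples[: n - m + 1]
    start = int(np.argmin(widths))
    return float(samples[start]), float(samples[start + m - 1])


def summarize_draws(values: np.ndarray, name: str, mass: float = 0.90) -> dict:
    lo, hi = hpdi(values, mass)
    mean = float(np.mean(values))
    return {"quantity": name, "mean": mean, "hpdi_lo": lo, "hpdi_hi": hi,
            "mass": mass, "flagged": not lo <= mean <= hi}


# ---------------------------------------------------------------------------
# per-draw probability means
# ---------------------------------------------------------------------------

def _modeled_rows_by_species(histories: Sequence[EncounterHistory],
                             basis: CovariateBasis, species: Sequence[str]):
    """Design rows of each species' modeled individual-occasions.

    An individual contributes its pre-departure transition nights
    (occasions 1 .. d-1; all T-1 for right-censored birds), i.e. exactly
    the rows entering the likelihood.
    """
    rows = {s: [] for s in species}
    for i, h in enumerate(histories):
        X = basis.rows(i)
        d = h.departure_occasion
        upto = (h.n_occasions if d is None else d) - 1
        rows[h.species].append(X[:upto])
    return {s: (np.vstack(r) if r else np.zeros((0, 7))) for s, r in rows.items()}


def _per_draw_species_means(draws: PosteriorDraws, rows_by_species: dict,
                            kind: str, thin: Optional[int] = None) -> pd.DataFrame:
    """Per-draw mean probability per species; kind in {'departure', 'routing'}."""
    flat = draws.flat()
    if thin:
        flat = flat[np.linspace(0, len(flat) - 1, thin).round().astype(int)]
    b = draws.layout.unpack(flat)
    species = draws.layout.species
    out = {}
    for s, name in enumerate(species):
        X = rows_by_species[name]
        if len(X) == 0:
            out[name] = np.full(len(flat), np.nan)
            continue
        if kind == "departure":
            C = np.concatenate([
                b["beta_wind_psi"][:, s, :].T,
                b["beta_dp_psi"][:, s][None, :],
                b["beta_h_psi"][:, s][None, :],
                b["beta_rain_psi"].T], axis=0)
            eta = X @ C + b["beta0_psi"][:, s]
        elif kind == "routing":
            eta = X[:, :4] @ b["beta_wind_chi"].T + b["beta0_chi"][:, s]
        else:
            raise ValueError(kind)
        out[name] = (1.0 / (1.0 + np.exp(-eta))).mean(axis=0)
    return pd.DataFrame(out)


def species_mean_departure(draws: PosteriorDraws,
                           histories: Sequence[EncounterHistory],
                           basis: CovariateBasis,
                           mass: float = 0.90,
                           weighted: bool = False,
                           thin: Optional[int] = 2000) -> "ProbabilitySummary":
    """Posterior species mean day-to-day departure probabilities.

    Per draw, psi is averaged over each species' modeled individual-
    occasions; the overall mean is the unweighted mean across species
    (``weighted=True`` weights species by their number of modeled rows).
    """
    rows = _modeled_rows_by_species(histories, basis, draws.layout.species)
    per_draw = _per_draw_species_means(draws, rows, "departure", thin=thin)
    return ProbabilitySummary.build(per_draw, rows, mass, weighted,
                                    label="departure_probability")


def species_mean_routing(draws: PosteriorDraws,
                         histories: Sequence[EncounterHistory],
                         basis: CovariateBasis,
                         mass: float = 0.90,
                         weighted: bool = False,
                         thin: Optional[int] = 2000) -> "ProbabilitySummary":
    """Posterior species mean offshore-routing probabilities."""
    rows = _modeled_rows_by_species(histories, basis, draws.layout.species)
    per_draw = _per_draw_species_means(draws, rows, "routing", thin=thin)
    return ProbabilitySummary.build(per_draw, rows, mass, weighted,
                                    label="offshore_probability")


@dataclass
class ProbabilitySummary:
    per_draw: pd.DataFrame  # one column per species + 'overall'
    table: pd.DataFrame  # mean + HPDI rows
    mass: float

    @classmethod
    def build(cls, per_draw: pd.DataFrame, rows_by_species: dict, mass: float,
              weighted: bool, label: str) -> "ProbabilitySummary":
        species = list(per_draw.columns)
        if weighted:
            w = np.array([len(rows_by_species[s]) for s in species], dtype=float)
            w /= w.sum()
            overall = per_draw.to_numpy() @ w
        else:
            overall = per_draw.to_numpy().mean(axis=1)
        per_draw = per_draw.copy()
        per_draw["overall"] = overall
        rows = [summarize_draws(per_draw[c].to_numpy(), f"{label}[{c}]", mass)
                for c in per_draw.columns]
        return cls(per_draw=per_draw, table=pd.DataFrame(rows), mass=mass)


def distance_contrast(per_draw: pd.DataFrame, grouping: dict,
                      mass: float = 0.90) -> dict:
    """Posterior of (long-distance mean - short-distance mean).

    ``per_draw`` holds per-draw species means (one column per species);
    ``grouping`` maps species name to 'short' or 'long'.
    """
    long_sp = [s for s in per_draw.columns
               if grouping.get(s) == "long"]
    short_sp = [s for s in per_draw.columns
                if grouping.get(s) == "short"]
    if not long_sp or not short_sp:
        raise ValueError("both distance groups must be non-empty")
    contrast = (per_draw[long_sp].to_numpy().mean(axis=1)
                - per_draw[short_sp].to_numpy().mean(axis=1))
    out = summarize_draws(contrast, "contrast[long - short]", mass)
    out["draws"] = contrast
    return out


# ---------------------------------------------------------------------------
# detection-corrected offshore count
# ---------------------------------------------------------------------------

def unknown_route_offshore_probability(chi, pX, pC):
    """P(route = offshore | departure, flight not detected).

    Reduces to chi when pX == pC and to 0 when pX == 1 (an undetected
    flight cannot have been offshore if offshore detection is certain).
    """
    chi = np.asarray(chi, dtype=float)
    num = chi * (1.0 - np.asarray(pX, dtype=float))
    den = num + (1.0 - chi) * (1.0 - np.asarray(pC, dtype=float))
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


@dataclass
class RouteAttribution:
    count_draws: np.ndarray  # posterior offshore counts (sampled routes)
    proportion_draws: np.ndarray
    expected_count_draws: np.ndarray  # plug-in expectations per draw
    table: pd.DataFrame
    n_individuals: int
    observed_offshore: int
    observed_onshore: int
    n_unknown: int


def attribute_unknown_routes(draws: PosteriorDraws,
                             histories: Sequence[EncounterHistory],
                             basis: CovariateBasis,
                             seed: int = 0, mass: float = 0.90,
                             thin: Optional[int] = 2000) -> RouteAttribution:
    """Posterior of the total offshore-flight count and proportion.

    Observed routes are kept fixed; each route-unknown departure is
    attributed per draw by sampling offshore with the detection-corrected
    probability at its departure-night covariates.  Per-draw expectations
    (no route resampling) are returned alongside for reference.
    """
    species = draws.layout.species
    rng = np.random.default_rng(seed)
    obs_off = sum(1 for h in histories if h.outcome == Code.OFFSHORE)
    obs_on = sum(1 for h in histories if h.outcome == Code.ONSHORE)
    unknown = [(i, h) for i, h in enumerate(histories)
               if h.outcome == Code.NOT_SEEN]
    no_dep = [h for h in histories if h.departure_occasion is None]
    if no_dep:
        import warnings
        warnings.warn(f"{len(no_dep)} histories without a departure occasion "
                      "are excluded from route attribution", RuntimeWarning)
    n_total = obs_off + obs_on + len(unknown)

    flat = draws.flat()
    if thin:
        flat = flat[np.linspace(0, len(flat) - 1, thin).round().astype(int)]
    b = draws.layout.unpack(flat)
    pX, pC = draws.layout.detection(flat)  # (D, 2)
    D = len(flat)

    if unknown:
        Xd = np.vstack([basis.rows(i)[h.departure_occasion - 2]
                        for i, h in unknown])  # (k, 7)
        sp = np.array([species.index(h.species) for _, h in unknown])
        tg = np.array([TAG_TYPES.index(h.tag_type) for _, h in unknown])
        eta = Xd[:, :4] @ b["beta_wind_chi"].T + b["beta0_chi"][:, sp].T  # (k, D)
        chi = 1.0 / (1.0 + np.exp(-eta))
        p_off = unknown_route_offshore_probability(
            chi, pX[:, tg].T, pC[:, tg].T)  # (k, D)
        extra = (rng.random(p_off.shape) < p_off).sum(axis=0)
        expected_extra = p_off.sum(axis=0)
    else:
        extra = np.zeros(D)
        expected_extra = np.zeros(D)

    counts = obs_off + extra
    expected = obs_off + expected_extra
    props = counts / n_total if n_total else counts * np.nan
    rows = [summarize_draws(counts, "offshore_count", mass),
            summarize_draws(props, "offshore_proportion", mass),
            summarize_draws(expected, "offshore_count_expected", mass)]
    return RouteAttribution(
        count_draws=counts, proportion_draws=props,
        expected_count_draws=expected, table=pd.DataFrame(rows),
        n_individuals=n_total, observed_offshore=obs_off,
        observed_onshore=obs_on, n_unknown=len(unknown))
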