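"""Four-state multistate capture-recapture model as a hidden Markov model.

Latent states are {stopover, offshore flight, onshore flight, departed}.
Each night a bird at stopover departs with probability psi and, given
departure, crosses the sea with probability chi; flight states are visited
for exactly one occasion before absorption in "departed".  The state-
transition matrix Omega and observation matrix Theta are

    Omega = [[1-psi, psi*chi, psi*(1-chi), 0],      Theta = [[1, 0,  0,  0   ],
             [0,     0,       0,           1],               [0, pX, 0,  1-pX],
             [0,     0,       0,           1],               [0, 0,  pC, 1-pC],
             [0,     0,       0,           1]]               [0, 0,  0,  1   ]]

where pX and pC are route-specific detection probabilities (per tag type).
Departure probability follows a logistic regression on orthogonal-polynomial
wind bases (linear + quadratic for the eastward and northward components),
standardized 24-h pressure change, standardized relative humidity, and a
binary rain indicator; all slopes except the rain slope are species
specific.  Routing probability uses a species intercept with shared wind
slopes.  The marginal likelihood of an encounter history integrates over
the latent trajectory via the forward algorithm in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .datatypes import TAG_TYPES, Code, EncounterHistory

N_STATES = 4
N_CODES = 4

# Column order of the covariate design matrix.
BASIS_COLUMNS = ("ul", "uq", "vl", "vq", "dp", "h", "r")


# ---------------------------------------------------------------------------
# covariate transformations
# ---------------------------------------------------------------------------

def standardize(x) -> tuple:
    """Center a column and scale it to one standard deviation (ddof=1).

    Returns ``(standardized, center, scale)`` so the same affine map can be
    applied to new data at prediction time.
    """
    x = np.asarray(x, dtype=float)
    center = float(np.mean(x))
    scale = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if scale == 0.0 or not np.isfinite(scale):
        raise ValueError("cannot standardize a column with zero variance")
    return (x - center) / scale, center, scale


@dataclass
class OrthoPoly:
    """Degree-2 orthogonal polynomial basis fitted on a training column.

    Columns are mutually orthogonal, orthogonal to the constant, and have
    unit Euclidean norm on the training data (the convention of R's
    ``poly``).  ``coef`` maps the monomial basis (1, x, x^2) onto the two
    orthogonal columns, so the fitted basis can be evaluated exactly at new
    x values.
    """

    coef: np.ndarray  # (3, 2) monomial coefficients for (linear, quadratic)
    linear: np.ndarray
    quadratic: np.ndarray

    @classmethod
    def fit(cls, x, degree: int = 2) -> "OrthoPoly":
        x = np.asarray(x, dtype=float)
        if degree != 2:
            raise ValueError("only degree-2 bases are supported")
        if np.unique(x).size < 3:
            raise ValueError("orthogonal polynomial basis needs >= 3 distinct values")
        # center first for numerical stability; fold the shift back into coef
        mu = x.mean()
        xc = x - mu
        V = np.column_stack([np.ones_like(xc), xc, xc**2])
        Q, R = np.linalg.qr(V)
        signs = np.sign(np.diag(R))
        Q = Q * signs
        R = signs[:, None] * R
        C = np.linalg.solve(R, np.eye(3))[:, 1:3]  # V @ C = Q[:, 1:3]
        # re-express in raw x: (1, x, x^2) @ shift == (1, x-mu, (x-mu)^2)
        shift = np.array(
            [[1.0, -mu, mu**2], [0.0, 1.0, -2.0 * mu], [0.0, 0.0, 1.0]]
        )
        coef = shift @ C
        return cls(coef=coef, linear=Q[:, 1].copy(), quadratic=Q[:, 2].copy())

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the fitted basis at new x values; returns (n, 2)."""
        x = np.asarray(x, dtype=float)
        V = np.column_stack([np.ones_like(x), x, x**2])
        return V @ self.coef


def orthogonal_poly_basis(x, degree: int = 2):
    """Functional wrapper: returns (linear, quadratic, OrthoPoly)."""
    p = OrthoPoly.fit(x, degree=degree)
    return p.linear, p.quadratic, p


# ---------------------------------------------------------------------------
# covariate basis
# ---------------------------------------------------------------------------

@dataclass
class CovariateBasis:
    """Design arrays for all modeled individual-occasions.

    All transforms (orthogonal wind polynomials, standardization of
    pressure change and humidity) are fitted once over the union of all
    rows and stored for prediction.  The orthogonal-polynomial columns are
    rescaled to unit standard deviation so regression slopes live on a
    comparable scale across sample sizes.
    """

    individuals: np.ndarray  # (N,) individual ids in row order
    design: np.ndarray  # (N, T, 7) columns = BASIS_COLUMNS
    u_poly: OrthoPoly
    v_poly: OrthoPoly
    poly_scales: np.ndarray  # (4,) sd rescaling of ul, uq, vl, vq
    dp_center: float
    dp_scale: float
    h_center: float
    h_scale: float

    @property
    def n_individuals(self) -> int:
        return self.design.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.design.shape[1]

    def rows(self, i: int) -> np.ndarray:
        """Design rows (T, 7) of individual i."""
        return self.design[i]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "CovariateBasis":
        """Build the basis from a long covariate table.

        Expected columns: individual, occasion (1-based), u, v, dp,
        humidity, rain.  Every individual must have a full set of
        occasions.
        """
        required = {"individual", "occasion", "u", "v", "dp", "humidity", "rain"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
        table = table.sort_values(["individual", "occasion"])
        counts = table.groupby("individual").size()
        if counts.nunique() != 1:
            raise ValueError("covariate gaps: unequal occasion counts per individual")
        T = int(counts.iloc[0])
        individuals = counts.index.to_numpy()
        n = len(individuals)

        u = table["u"].to_numpy(dtype=float)
        v = table["v"].to_numpy(dtype=float)
        u_poly = OrthoPoly.fit(u)
        v_poly = OrthoPoly.fit(v)
        poly = np.column_stack([u_poly.linear, u_poly.quadratic,
                                v_poly.linear, v_poly.quadratic])
        scales = poly.std(axis=0, ddof=1)
        poly = poly / scales

        dp_std, dp_c, dp_s = standardize(table["dp"].to_numpy(dtype=float))
        h_std, h_c, h_s = standardize(table["humidity"].to_numpy(dtype=float))
        r = table["rain"].to_numpy(dtype=float)
        if not np.isin(r, [0.0, 1.0]).all():
            raise ValueError("rain must be binary")

        design = np.column_stack([poly, dp_std, h_std, r]).reshape(n, T, 7)
        return cls(
            individuals=individuals,
            design=design,
            u_poly=u_poly,
            v_poly=v_poly,
            poly_scales=scales,
            dp_center=dp_c,
            dp_scale=dp_s,
            h_center=h_c,
            h_scale=h_s,
        )

    def transform_new(self, table: pd.DataFrame) -> np.ndarray:
        """Apply the stored transforms to new covariate rows; returns (n, 7)."""
        up = self.u_poly.evaluate(table["u"].to_numpy(dtype=float))
        vp = self.v_poly.evaluate(table["v"].to_numpy(dtype=float))
        poly = np.column_stack([up, vp]) / self.poly_scales
        dp = (table["dp"].to_numpy(dtype=float) - self.dp_center) / self.dp_scale
        h = (table["humidity"].to_numpy(dtype=float) - self.h_center) / self.h_scale
        r = table["rain"].to_numpy(dtype=float)
        return np.column_stack([poly, dp, h, r])


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """All coefficients of the departure/routing regressions plus detection.

    Arrays are indexed by the position of the species in ``species``;
    detection probabilities are indexed by ``TAG_TYPES`` order (ACT, NTQB).
    """

    species: tuple
    beta0_psi: np.ndarray  # (S,)
    beta_wind_psi: np.ndarray  # (S, 4) slopes for ul, uq, vl, vq
    beta_dp_psi: np.ndarray  # (S,)
    beta_h_psi: np.ndarray  # (S,)
    beta_rain_psi: float
    beta0_chi: np.ndarray  # (S,)
    beta_wind_chi: np.ndarray  # (4,) shared slopes for ul, uq, vl, vq
    p_offshore: np.ndarray  # (2,) pX per tag type
    p_onshore: np.ndarray  # (2,) pC per tag type

    def __post_init__(self):
        self.species = tuple(self.species)
        for name in ("beta0_psi", "beta_wind_psi", "beta_dp_psi", "beta_h_psi",
                     "beta0_chi", "beta_wind_chi", "p_offshore", "p_onshore"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        S = len(self.species)
        if self.beta0_psi.shape != (S,) or self.beta_wind_psi.shape != (S, 4):
            raise ValueError("departure coefficient shapes do not match species")
        for p in (self.p_offshore, self.p_onshore):
            if p.shape != (2,) or (p < 0).any() or (p > 1).any():
                raise ValueError("detection probabilities must be two values in [0, 1]")
        iact, intqb = TAG_TYPES.index("ACT"), TAG_TYPES.index("NTQB")
        if self.p_offshore[iact] < self.p_offshore[intqb] - 1e-12 or \
           self.p_onshore[iact] < self.p_onshore[intqb] - 1e-12:
            raise ValueError("ACT detection probabilities must be >= NTQB")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def psi_coefficients(self, s: int) -> np.ndarray:
        """Length-7 slope vector aligned with BASIS_COLUMNS for species s."""
        return np.concatenate([
            self.beta_wind_psi[s],
            [self.beta_dp_psi[s], self.beta_h_psi[s], self.beta_rain_psi],
        ])

    # -- flat named-vector serialization -----------------------------------
    def to_series(self) -> pd.Series:
        entries = {}
        for s, name in enumerate(self.species):
            entries[f"beta0_psi[{name}]"] = self.beta0_psi[s]
            for j, c in enumerate(("ul", "uq", "vl", "vq")):
                entries[f"beta_{c}_psi[{name}]"] = self.beta_wind_psi[s, j]
            entries[f"beta_dp_psi[{name}]"] = self.beta_dp_psi[s]
            entries[f"beta_h_psi[{name}]"] = self.beta_h_psi[s]
            entries[f"beta0_chi[{name}]"] = self.beta0_chi[s]
        entries["beta_rain_psi"] = self.beta_rain_psi
        for j, c in enumerate(("ul", "uq", "vl", "vq")):
            entries[f"beta_{c}_chi"] = self.beta_wind_chi[j]
        for g, tag in enumerate(TAG_TYPES):
            entries[f"pX[{tag}]"] = self.p_offshore[g]
            entries[f"pC[{tag}]"] = self.p_onshore[g]
        return pd.Series(entries)

    @classmethod
    def from_series(cls, s: pd.Series, species: Sequence[str]) -> "ModelParams":
        species = tuple(species)
        wind = ("ul", "uq", "vl", "vq")
        return cls(
            species=species,
            beta0_psi=[s[f"beta0_psi[{n}]"] for n in species],
            beta_wind_psi=[[s[f"beta_{c}_psi[{n}]"] for c in wind] for n in species],
            beta_dp_psi=[s[f"beta_dp_psi[{n}]"] for n in species],
            beta_h_psi=[s[f"beta_h_psi[{n}]"] for n in species],
            beta_rain_psi=float(s["beta_rain_psi"]),
            beta0_chi=[s[f"beta0_chi[{n}]"] for n in species],
            beta_wind_chi=[s[f"beta_{c}_chi"] for c in wind],
            p_offshore=[s[f"pX[{t}]"] for t in TAG_TYPES],
            p_onshore=[s[f"pC[{t}]"] for t in TAG_TYPES],
        )


# ---------------------------------------------------------------------------
# probabilities and matrices
# ---------------------------------------------------------------------------

def departure_logit(rows: np.ndarray, params: ModelParams, species: int) -> np.ndarray:
    """Linear predictor of the departure probability for design rows (..., 7)."""
    rows = np.asarray(rows, dtype=float)
    return params.beta0_psi[species] + rows @ params.psi_coefficients(species)


def departure_probability(rows: np.ndarray, params: ModelParams, species: int) -> np.ndarray:
    """Day-to-day departure probability psi for design rows of one species."""
    return expit(departure_logit(rows, params, species))


def routing_logit(rows: np.ndarray, params: ModelParams, species: int) -> np.ndarray:
    """Linear predictor of the offshore-routing probability (species intercept,
    shared wind slopes; pressure, humidity and rain do not enter)."""
    rows = np.asarray(rows, dtype=float)
    return params.beta0_chi[species] + rows[..., :4] @ params.beta_wind_chi


def routing_probability(rows: np.ndarray, params: ModelParams, species: int) -> np.ndarray:
    """Probability chi that a departure is an offshore flight."""
    return expit(routing_logit(rows, params, species))


def build_transition_matrix(psi: float, chi: float) -> np.ndarray:
    if not (0.0 <= psi <= 1.0 and 0.0 <= chi <= 1.0):
        raise ValueError("psi and chi must lie in [0, 1]")
    return np.array([
        [1.0 - psi, psi * chi, psi * (1.0 - chi), 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [0.0, 0.0, 0.0, 1.0],
        [0.0, 0.0, 0.0, 1.0],
    ])


def build_observation_matrix(p_offshore: float, p_onshore: float) -> np.ndarray:
    if not (0.0 <= p_offshore <= 1.0 and 0.0 <= p_onshore <= 1.0):
        raise ValueError("detection probabilities must lie in [0, 1]")
    return np.array([
        [1.0, 0.0, 0.0, 0.0],
        [0.0, p_offshore, 0.0, 1.0 - p_offshore],
        [0.0, 0.0, p_onshore, 1.0 - p_onshore],
        [0.0, 0.0, 0.0, 1.0],
    ])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def forward_loglik(history: EncounterHistory, basis_rows, params: ModelParams) -> float:
    """Exact marginal log-likelihood of one encounter history.

    ``basis_rows`` are that individual's design rows (T, 7); the transition
    from occasion t to t+1 uses the occasion-t (sunset) covariates.  The
    recursion runs in log space with log-sum-exp so probabilities near 0/1
    stay numerically safe.  Conditioning is on the known initial state
    (stopover at occasion 1); an observation sequence impossible under the
    observation matrix yields -inf with a warning.
    """
    codes = history.codes
    T = len(codes)
    rows = np.asarray(basis_rows, dtype=float)
    if rows.shape[0] < T:
        raise ValueError("basis rows shorter than the history")
    s = params.species_index(history.species)
    g = TAG_TYPES.index(history.tag_type)
    psi = departure_probability(rows[: T - 1], params, s)
    chi = routing_probability(rows[: T - 1], params, s)
    with np.errstate(divide="ignore"):
        log_theta = np.log(build_observation_matrix(
            params.p_offshore[g], params.p_onshore[g]))
        log_alpha = np.full(N_STATES, -np.inf)
        log_alpha[0] = 0.0  # z_1 = stopover, emits STOPOVER with probability 1
        for t in range(1, T):
            log_omega = np.log(build_transition_matrix(psi[t - 1], chi[t - 1]))
            log_alpha = (
                logsumexp(log_alpha[:, None] + log_omega, axis=0)
                + log_theta[:, codes[t] - 1]
            )
    ll = float(logsumexp(log_alpha))
    if not np.isfinite(ll):
        warnings.warn(
            f"history {history.tag_id}: observation sequence has zero probability",
            RuntimeWarning,
        )
    return ll


def _log_expit(eta: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -eta)


def _log1m_expit(eta: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, eta)


def total_loglik(histories: Sequence[EncounterHistory], basis: CovariateBasis,
                 params: ModelParams) -> float:
    """Joint log-likelihood of a set of histories (independent individuals).

    Histories are paired with ``basis`` rows by position.  The four-state
    chain admits a closed-form marginal per history (survive stopover,
    depart, outcome term), which this evaluates vectorized; it equals the
    sum of per-individual :func:`forward_loglik` values.
    """
    if len(histories) == 0:
        return 0.0
    if len(histories) != basis.n_individuals:
        raise ValueError("histories and basis rows are misaligned")
    T = basis.n_occasions
    for h in histories:
        if h.n_occasions > T:
            raise ValueError("history longer than basis occasions")
    species_idx = np.array([params.species_index(h.species) for h in histories])
    tag_idx = np.array([TAG_TYPES.index(h.tag_type) for h in histories])
    dep = np.array([h.departure_occasion or 0 for h in histories])
    outcome = np.array([int(h.outcome) if h.outcome is not None else 0
                        for h in histories])
    n_occ = np.array([h.n_occasions for h in histories])

    X = basis.design
    total = 0.0
    for s in range(params.n_species):
        mask = species_idx == s
        if not mask.any():
            continue
        idx = np.nonzero(mask)[0]
        eta = params.beta0_psi[s] + X[idx] @ params.psi_coefficients(s)  # (m, T)
        lp_stay = _log1m_expit(eta)
        lp_dep = _log_expit(eta)
        eta_chi = params.beta0_chi[s] + X[idx][:, :, :4] @ params.beta_wind_chi
        l_chi = _log_expit(eta_chi)
        l_1mchi = _log1m_expit(eta_chi)
        for k, i in enumerate(idx):
            d = dep[i]
            if d == 0:  # right-censored: survived all transitions
                total += lp_stay[k, : n_occ[i] - 1].sum()
                continue
            total += lp_stay[k, : d - 2].sum() + lp_dep[k, d - 2]
            g = tag_idx[i]
            pX, pC = params.p_offshore[g], params.p_onshore[g]
            lc, l1c = l_chi[k, d - 2], l_1mchi[k, d - 2]
            with np.errstate(divide="ignore"):
                if outcome[i] == Code.OFFSHORE:
                    total += lc + np.log(pX)
                elif outcome[i] == Code.ONSHORE:
                    total += l1c + np.log(pC)
                else:  # departure seen from stopover data only
                    total += np.logaddexp(lc + np.log1p(-pX), l1c + np.log1p(-pC))
    return float(total)
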