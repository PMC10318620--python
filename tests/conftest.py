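import numpy as np
import pandas as pd
import pytest

from migroute.hmm import CovariateBasis, ModelParams, OrthoPoly
from migroute.synthetic_data import (SpeciesConfig, simulate_covariates,
                                     simulate_individuals)

RECOVERY_DETECTION = {"offshore": {"ACT": 0.60, "NTQB": 0.50},
                      "onshore": {"ACT": 0.97, "NTQB": 0.95}}


def recovery_configs(n_per_species: int = 100):
    """Two-species setup (one per tag type and migration distance) used for
    parameter-recovery checks."""
    return [
        SpeciesConfig("Thrush-like", "short", n_per_species, "ACT",
                      (-1.6, 0.3, -0.3, -0.1, -0.3, 0.15, -0.25, -1.2), 0.2),
        SpeciesConfig("Warbler-like", "long", n_per_species, "NTQB",
                      (-0.9, 0.3, -0.3, -0.1, -0.3, 0.10, -0.20, -1.2), -0.4),
    ]


def simulate_recovery_dataset(seed: int, n_per_species: int = 100,
                              n_occasions: int = 36):
    configs = recovery_configs(n_per_species)
    cov = simulate_covariates(2 * n_per_species, n_occasions, seed=seed)
    return simulate_individuals(configs, cov, detection=RECOVERY_DETECTION,
                                n_occasions=n_occasions, seed=seed + 1)


def simulate_calibration_replicate(rep: int, base_seed: int = 7300,
                                   n_per_species: int = 100,
                                   n_occasions: int = 36):
    """One simulation-based-calibration replicate.

    The generating regression coefficients are drawn from the model's own
    priors (Normal(0, 1.5) intercepts, Normal(0, 1) slopes), so for an
    exact sampler the 90% posterior intervals cover the generating values
    in exactly 90% of replicates.  Detection probabilities are drawn from
    their ordered-uniform prior (ACT base uniform, NTQB equal to the base
    times a uniform fraction).  Censored birds are kept as right-censored
    histories so the fitted model matches the generator exactly.
    """
    rng = np.random.default_rng(base_seed + rep)
    rain = float(rng.normal(0, 1))
    configs = []
    for name, dist, tag in (("Thrush-like", "short", "ACT"),
                            ("Warbler-like", "long", "NTQB")):
        b0 = float(rng.normal(0, 1.5))
        slopes = rng.normal(0, 1, 6)
        chi0 = float(rng.normal(0, 1.5))
        configs.append(SpeciesConfig(name, dist, n_per_species, tag,
                                     (b0, *slopes, rain), chi0))
    chi_wind = tuple(rng.normal(0, 1, 4))
    pX_act, pC_act = rng.uniform(), rng.uniform()
    detection = {
        "offshore": {"ACT": pX_act, "NTQB": pX_act * rng.uniform()},
        "onshore": {"ACT": pC_act, "NTQB": pC_act * rng.uniform()},
    }
    cov = simulate_covariates(2 * n_per_species, n_occasions,
                              seed=int(rng.integers(2**31 - 1)))
    return simulate_individuals(configs, cov, detection=detection,
                                n_occasions=n_occasions,
                                seed=int(rng.integers(2**31 - 1)),
                                routing_wind_betas=chi_wind,
                                keep_censored=True)


@pytest.fixture(scope="session")
def recovery_sim():
    """One simulated 200-bird dataset from known parameters."""
    return simulate_recovery_dataset(seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_null_basis(n: int, T: int) -> CovariateBasis:
    """A basis whose design rows are all zero (null covariates)."""
    x = np.linspace(-1, 1, 7)
    poly = OrthoPoly.fit(x)
    return CovariateBasis(
        individuals=np.arange(n), design=np.zeros((n, T, 7)),
        u_poly=poly, v_poly=poly, poly_scales=np.ones(4),
        dp_center=0.0, dp_scale=1.0, h_center=0.0, h_scale=1.0)


def constant_params(species, psi=0.3, chi=0.5, pX=(0.6, 0.5), pC=(0.97, 0.95)):
    """Intercept-only parameters giving constant psi and chi."""
    from scipy.special import logit

    S = len(species)
    return ModelParams(
        species=species,
        beta0_psi=np.full(S, logit(psi)), beta_wind_psi=np.zeros((S, 4)),
        beta_dp_psi=np.zeros(S), beta_h_psi=np.zeros(S), beta_rain_psi=0.0,
        beta0_chi=np.full(S, logit(chi)), beta_wind_chi=np.zeros(4),
        p_offshore=pX, p_onshore=pC)
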