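"""Tests of HPD intervals, species means, contrasts and route attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migroute.inference import ParamLayout, PosteriorDraws
from migroute.summaries import (attribute_unknown_routes, distance_contrast,
                                hpdi, species_mean_departure,
                                species_mean_routing,
                                unknown_route_offshore_probability)

from conftest import constant_params, make_null_basis, simulate_recovery_dataset


class TestHpdi:
    def test_degenerate_samples(self):
        assert hpdi(np.full(25, 3.7)) == (3.7, 3.7)

    def test_integer_ladder_shortest_window(self):
        # 100 points, mass 0.9 -> any 90-point window has width 89;
        # the tie-break picks the lowest start
        lo, hi = hpdi(np.arange(1, 101), 0.9)
        assert (lo, hi) == (1.0, 90.0)
        assert hi - lo == 89.0

    def test_standard_normal_quantiles(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hpdi(x, 0.9)
        # width is tightly determined; endpoint placement jitters a little
        # because the shortest-window objective is flat for symmetric samples
        assert (hi - lo) == pytest.approx(2 * 1.645, abs=0.05)
        assert abs(lo + 1.645) < 0.08
        assert abs(hi - 1.645) < 0.08

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(10))
        with pytest.raises(ValueError):
            hpdi(np.arange(30), mass=1.2)

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_never_wider_than_equal_tailed(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 2.0, 500)
        lo, hi = hpdi(x, 0.9)
        q_lo, q_hi = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) <= (q_hi - q_lo) + 1e-12

    def test_matches_arviz_on_smooth_samples(self):
        import arviz as az
        x = np.random.default_rng(7).normal(2.0, 1.3, 20_000)
        lo, hi = hpdi(x, 0.9)
        ref = az.hdi(x, hdi_prob=0.9)
        assert abs(lo - ref[0]) < 0.02 and abs(hi - ref[1]) < 0.02


def _degenerate_draws(params, n=200):
    layout = ParamLayout(params.species)
    theta = layout.from_model_params(params)
    arr = np.tile(theta, (2, n // 2, 1))
    arr += 1e-6 * np.random.default_rng(0).standard_normal(arr.shape)
    return PosteriorDraws(draws=arr, layout=layout, backend="degenerate", seed=0)


def _intercept_only_setup(psi_by_species, chi_by_species, T=6, n_per=10):
    from scipy.special import logit

    from migroute.datatypes import EncounterHistory

    species = tuple(sorted(psi_by_species))
    S = len(species)
    from migroute.hmm import ModelParams
    params = ModelParams(
        species=species,
        beta0_psi=[logit(psi_by_species[s]) for s in species],
        beta_wind_psi=np.zeros((S, 4)), beta_dp_psi=np.zeros(S),
        beta_h_psi=np.zeros(S), beta_rain_psi=0.0,
        beta0_chi=[logit(chi_by_species[s]) for s in species],
        beta_wind_chi=np.zeros(4),
        p_offshore=(0.6, 0.5), p_onshore=(0.97, 0.95))
    histories = []
    for s in species:
        for k in range(n_per):
            codes = np.ones(T, dtype=int)
            codes[3:] = [2, 4, 4][: T - 3]
            histories.append(EncounterHistory(f"{s}{k}", s, "NTQB", codes))
    basis = make_null_basis(len(histories), T)
    return params, histories, basis


class TestSpeciesMeans:
    def test_intercept_zero_gives_half(self):
        params, histories, basis = _intercept_only_setup(
            {"A": 0.5}, {"A": 0.5})
        draws = _degenerate_draws(params)
        result = species_mean_departure(draws, histories, basis)
        overall = result.table.set_index("quantity").loc[
            "departure_probability[overall]"]
        assert overall["mean"] == pytest.approx(0.5, abs=1e-4)

    def test_overall_is_unweighted_species_mean(self):
        params, histories, basis = _intercept_only_setup(
            {"A": 0.2, "B": 0.4}, {"A": 0.5, "B": 0.5})
        draws = _degenerate_draws(params)
        result = species_mean_departure(draws, histories, basis)
        t = result.table.set_index("quantity")
        a = t.loc["departure_probability[A]", "mean"]
        b = t.loc["departure_probability[B]", "mean"]
        overall = t.loc["departure_probability[overall]", "mean"]
        assert overall == pytest.approx((a + b) / 2, abs=1e-12)
        assert a == pytest.approx(0.2, abs=1e-4)

    def test_constant_psi_recovered_from_fit(self):
        """Simulated data with constant psi: the posterior species mean HPDI
        should cover the generating value."""
        from migroute.inference import sample_posterior
        from migroute.synthetic_data import (SpeciesConfig,
                                             simulate_covariates,
                                             simulate_individuals)
        from scipy.special import logit
        cfgs = [SpeciesConfig("A", "short", 150, "NTQB",
                              (logit(0.2), 0, 0, 0, 0, 0, 0, 0), 0.0),
                SpeciesConfig("B", "long", 150, "ACT",
                              (logit(0.2), 0, 0, 0, 0, 0, 0, 0), 0.0)]
        cov = simulate_covariates(300, 36, seed=13)
        sim = simulate_individuals(cfgs, cov, n_occasions=36, seed=14)
        draws = sample_posterior(sim.histories, sim.modeled_basis(),
                                 n_iter=8000, n_warmup=2000, seed=15)
        result = species_mean_departure(draws, sim.histories,
                                        sim.modeled_basis())
        row = result.table.set_index("quantity").loc[
            "departure_probability[overall]"]
        assert row["hpdi_lo"] <= 0.2 <= row["hpdi_hi"]


class TestDistanceContrast:
    def test_identical_groups_give_zero(self):
        per_draw = pd.DataFrame({"A": np.full(100, 0.3),
                                 "B": np.full(100, 0.3)})
        out = distance_contrast(per_draw, {"A": "short", "B": "long"})
        assert out["mean"] == pytest.approx(0.0)

    def test_degenerate_contrast_value(self):
        per_draw = pd.DataFrame({"A": np.full(100, 0.1),
                                 "B": np.full(100, 0.3)})
        out = distance_contrast(per_draw, {"A": "short", "B": "long"})
        assert out["mean"] == pytest.approx(0.2)

    def test_empty_group_rejected(self):
        per_draw = pd.DataFrame({"A": np.full(100, 0.1)})
        with pytest.raises(ValueError):
            distance_contrast(per_draw, {"A": "short"})


class TestUnknownRouteProbability:
    def test_equal_detection_reduces_to_chi(self):
        chi = np.array([0.1, 0.5, 0.9])
        np.testing.assert_allclose(
            unknown_route_offshore_probability(chi, 0.7, 0.7), chi)

    def test_certain_offshore_detection_gives_zero(self):
        assert unknown_route_offshore_probability(0.5, 1.0, 0.95) == 0.0

    def test_direct_arithmetic(self):
        # chi (1-pX) / (chi (1-pX) + (1-chi)(1-pC)) at chi=.5, pX=.5, pC=.95
        value = unknown_route_offshore_probability(0.5, 0.5, 0.95)
        assert value == pytest.approx(0.25 / 0.275)

    @given(st.floats(0.01, 0.99), st.floats(0.0, 0.99), st.floats(0.0, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_closed_form_on_random_inputs(self, chi, pX, pC):
        num = chi * (1 - pX)
        den = num + (1 - chi) * (1 - pC)
        expected = num / den if den else 0.0
        assert unknown_route_offshore_probability(chi, pX, pC) == \
            pytest.approx(expected)


class TestRouteAttribution:
    def test_counts_bounded_by_observed_and_unknown(self):
        sim = simulate_recovery_dataset(seed=201, n_per_species=60)
        draws = _degenerate_draws(sim.params)
        out = attribute_unknown_routes(draws, sim.histories,
                                       sim.modeled_basis(), seed=1)
        assert (out.count_draws >= out.observed_offshore).all()
        assert (out.count_draws <= out.observed_offshore + out.n_unknown).all()

    def test_recovers_true_offshore_count(self):
        """With draws at the generating parameters the posterior mean count
        should fall within three posterior SDs of the true count."""
        sim = simulate_recovery_dataset(seed=202, n_per_species=100)
        det = sim.roster[sim.roster["determined"]]
        true_count = (det["route_true"] == "offshore").sum()
        draws = _degenerate_draws(sim.params, n=600)
        out = attribute_unknown_routes(draws, sim.histories,
                                       sim.modeled_basis(), seed=2)
        sd = max(out.count_draws.std(), 1.0)
        assert abs(out.count_draws.mean() - true_count) <= 3 * sd
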