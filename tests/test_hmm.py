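"""Unit and property tests for the four-state model's building blocks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from migroute.datatypes import EncounterHistory
from migroute.hmm import (CovariateBasis, ModelParams, build_observation_matrix,
                          build_transition_matrix, departure_logit,
                          departure_probability, forward_loglik,
                          orthogonal_poly_basis, routing_probability,
                          standardize, total_loglik)

from conftest import constant_params, make_null_basis, simulate_recovery_dataset


# ---------------------------------------------------------------------------
# covariate transforms
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_closed_form(self):
        z, center, scale = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert center == 2.0 and scale == 1.0

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            standardize([5.0, 5.0, 5.0])

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=60, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_zero_mean_unit_sd(self, xs):
        z, _, _ = standardize(xs)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-10


class TestOrthogonalPoly:
    def test_hand_derived_basis(self):
        # Gram-Schmidt on {1, x, x^2} at x = (-1, 0, 1)
        lin, quad, _ = orthogonal_poly_basis(np.array([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(lin, np.array([-1, 0, 1]) / np.sqrt(2),
                                   atol=1e-12)
        np.testing.assert_allclose(quad, np.array([1, -2, 1]) / np.sqrt(6),
                                   atol=1e-12)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            orthogonal_poly_basis(np.array([1.0, 1.0, 2.0, 2.0]))

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_orthonormal_and_reproducible(self, seed):
        x = np.random.default_rng(seed).normal(0, 3, 50)
        lin, quad, poly = orthogonal_poly_basis(x)
        assert abs(np.dot(lin, quad)) < 1e-10
        assert abs(lin.sum()) < 1e-8 and abs(quad.sum()) < 1e-8
        np.testing.assert_allclose([np.dot(lin, lin), np.dot(quad, quad)],
                                   1.0, atol=1e-10)
        # evaluating the stored basis at training x reproduces the columns
        np.testing.assert_allclose(poly.evaluate(x),
                                   np.column_stack([lin, quad]), atol=1e-10)


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------

class TestProbabilities:
    def test_null_covariates_give_half(self):
        params = constant_params(("A",), psi=0.5, chi=0.5)
        basis = make_null_basis(1, 3)
        np.testing.assert_allclose(
            departure_probability(basis.rows(0), params, 0), 0.5)
        np.testing.assert_allclose(
            routing_probability(basis.rows(0), params, 0), 0.5)

    def test_rain_shifts_predictor_by_shared_slope(self):
        rng = np.random.default_rng(3)
        params = _random_params(rng, ("A", "B"))
        row_dry = rng.normal(size=7)
        row_dry[6] = 0.0
        row_wet = row_dry.copy()
        row_wet[6] = 1.0
        for s in (0, 1):
            shift = (departure_logit(row_wet, params, s)
                     - departure_logit(row_dry, params, s))
            np.testing.assert_allclose(shift, params.beta_rain_psi, atol=1e-12)

    def test_routing_species_differ_only_by_intercept(self):
        rng = np.random.default_rng(4)
        params = _random_params(rng, ("A", "B"))
        row = rng.normal(size=7)
        from migroute.hmm import routing_logit
        d = routing_logit(row, params, 0) - routing_logit(row, params, 1)
        np.testing.assert_allclose(
            d, params.beta0_chi[0] - params.beta0_chi[1], atol=1e-12)

    def test_matches_independent_dot_product(self):
        rng = np.random.default_rng(5)
        params = _random_params(rng, ("A",))
        rows = rng.normal(size=(6, 7))
        eta = (params.beta0_psi[0]
               + rows[:, :4] @ params.beta_wind_psi[0]
               + rows[:, 4] * params.beta_dp_psi[0]
               + rows[:, 5] * params.beta_h_psi[0]
               + rows[:, 6] * params.beta_rain_psi)
        np.testing.assert_allclose(departure_probability(rows, params, 0),
                                   expit(eta), rtol=1e-12)
        eta_chi = params.beta0_chi[0] + rows[:, :4] @ params.beta_wind_chi
        np.testing.assert_allclose(routing_probability(rows, params, 0),
                                   expit(eta_chi), rtol=1e-12)


def _random_params(rng, species):
    S = len(species)
    pX = np.sort(rng.uniform(0.2, 0.9, 2))[::-1]
    pC = np.sort(rng.uniform(0.5, 1.0, 2))[::-1]
    return ModelParams(
        species=species,
        beta0_psi=rng.normal(0, 1, S), beta_wind_psi=rng.normal(0, 0.5, (S, 4)),
        beta_dp_psi=rng.normal(0, 0.5, S), beta_h_psi=rng.normal(0, 0.5, S),
        beta_rain_psi=float(rng.normal(0, 1)),
        beta0_chi=rng.normal(0, 1, S), beta_wind_chi=rng.normal(0, 0.5, 4),
        p_offshore=pX, p_onshore=pC)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

class TestMatrices:
    @pytest.mark.parametrize("psi,chi,row", [
        (0.0, 0.7, (1.0, 0.0, 0.0, 0.0)),
        (1.0, 1.0, (0.0, 1.0, 0.0, 0.0)),
        (0.5, 0.4, (0.5, 0.2, 0.3, 0.0)),
    ])
    def test_transition_first_row(self, psi, chi, row):
        omega = build_transition_matrix(psi, chi)
        np.testing.assert_allclose(omega[0], row)
        np.testing.assert_allclose(omega.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(omega[1:, 3], 1.0)

    def test_observation_structure(self):
        theta = build_observation_matrix(1.0, 1.0)
        np.testing.assert_allclose(theta, np.array(
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]]))
        theta0 = build_observation_matrix(0.0, 0.9)
        np.testing.assert_allclose(theta0[1], [0, 0, 0, 1])

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_rows_stochastic(self, p_off, p_on):
        theta = build_observation_matrix(p_off, p_on)
        omega = build_transition_matrix(p_off, p_on)
        np.testing.assert_allclose(theta.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(omega.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(1.2, 0.5)
        with pytest.raises(ValueError):
            build_observation_matrix(-0.1, 0.5)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def enumeration_loglik(codes, psi, chi, p_off, p_on):
    """Independent oracle: sum over every latent sequence explicitly."""
    T = len(codes)
    omega = [np.array([[1 - ps, ps * ch, ps * (1 - ch), 0],
                       [0, 0, 0, 1], [0, 0, 0, 1], [0, 0, 0, 1]])
             for ps, ch in zip(psi, chi)]
    theta = np.array([[1, 0, 0, 0],
                      [0, p_off, 0, 1 - p_off],
                      [0, 0, p_on, 1 - p_on],
                      [0, 0, 0, 1]])
    total = 0.0
    for seq in itertools.product((1, 2, 3, 4), repeat=T - 1):
        p, prev = 1.0, 1
        for t, z in enumerate(seq):
            p *= omega[t][prev - 1, z - 1] * theta[z - 1, codes[t + 1] - 1]
            prev = z
        total += p
    return np.log(total)


def all_valid_histories(T):
    """Every admissible code sequence of length T."""
    seqs = [np.ones(T, dtype=int)]
    for d in range(2, T + 1):
        for outcome in (2, 3, 4):
            codes = np.ones(T, dtype=int)
            codes[d - 1] = outcome
            codes[d:] = 4
            seqs.append(codes)
    return seqs


class TestForwardLoglik:
    def test_two_occasion_stay(self):
        params = constant_params(("A",), psi=0.3)
        h = EncounterHistory("x", "A", "ACT", [1, 1])
        ll = forward_loglik(h, make_null_basis(1, 2).rows(0), params)
        np.testing.assert_allclose(ll, np.log(0.7), rtol=1e-12)

    def test_two_occasion_offshore(self):
        params = constant_params(("A",), psi=0.5, chi=0.6, pX=(1.0, 1.0))
        h = EncounterHistory("x", "A", "ACT", [1, 2])
        ll = forward_loglik(h, make_null_basis(1, 2).rows(0), params)
        np.testing.assert_allclose(ll, np.log(0.3), rtol=1e-12)

    def test_unseen_departure_matches_enumeration(self):
        params = constant_params(("A",), psi=0.4, chi=0.5,
                                 pX=(0.6, 0.6), pC=(0.9, 0.9))
        h = EncounterHistory("x", "A", "ACT", [1, 4, 4])
        ll = forward_loglik(h, make_null_basis(1, 3).rows(0), params)
        oracle = enumeration_loglik([1, 4, 4], [0.4] * 2, [0.5] * 2, 0.6, 0.9)
        np.testing.assert_allclose(ll, oracle, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_forward_equals_enumeration_random_parameters(self, seed):
        """Forward recursion vs exhaustive latent-sequence enumeration with
        occasion-varying covariates, for every admissible history (T <= 6)."""
        rng = np.random.default_rng(seed)
        params = _random_params(rng, ("A",))
        for T in (2, 4, 6):
            rows = rng.normal(0, 0.8, size=(T, 7))
            rows[:, 6] = rng.integers(0, 2, T)
            # independent arithmetic for the per-occasion probabilities
            eta_psi = (params.beta0_psi[0] + rows @ np.concatenate(
                [params.beta_wind_psi[0],
                 [params.beta_dp_psi[0], params.beta_h_psi[0],
                  params.beta_rain_psi]]))
            eta_chi = params.beta0_chi[0] + rows[:, :4] @ params.beta_wind_chi
            psi, chi = expit(eta_psi), expit(eta_chi)
            for codes in all_valid_histories(T):
                h = EncounterHistory("x", "A", "ACT", codes)
                ll = forward_loglik(h, rows, params)
                oracle = enumeration_loglik(
                    codes, psi, chi, params.p_offshore[0], params.p_onshore[0])
                np.testing.assert_allclose(ll, oracle, rtol=1e-10)

    def test_impossible_observation_flagged(self):
        params = constant_params(("A",), psi=0.5, chi=1.0, pX=(1.0, 1.0))
        h = EncounterHistory("x", "A", "ACT", [1, 3])  # onshore impossible
        with pytest.warns(RuntimeWarning):
            ll = forward_loglik(h, make_null_basis(1, 2).rows(0), params)
        assert ll == -np.inf


class TestTotalLoglik:
    def test_additivity_and_order_invariance(self):
        sim = simulate_recovery_dataset(seed=7, n_per_species=25)
        hs, params = sim.histories, sim.params
        sub = sim.modeled_basis()
        total = total_loglik(hs, sub, params)
        singles = [forward_loglik(h, sub.rows(k), params)
                   for k, h in enumerate(hs)]
        np.testing.assert_allclose(total, np.sum(singles), rtol=1e-12, atol=1e-9)

    def test_duplicated_individual_doubles(self):
        params = constant_params(("A",), psi=0.35, chi=0.5)
        h = EncounterHistory("x", "A", "ACT", [1, 1, 2, 4])
        basis = make_null_basis(2, 4)
        single = total_loglik([h], make_null_basis(1, 4), params)
        double = total_loglik([h, h], basis, params)
        np.testing.assert_allclose(double, 2 * single, rtol=1e-12)

    def test_fully_observed_history_is_product_of_transitions(self):
        params = constant_params(("A",), psi=0.25, chi=0.4,
                                 pX=(1.0, 1.0), pC=(1.0, 1.0))
        h = EncounterHistory("x", "A", "ACT", [1, 1, 1, 3, 4])
        ll = total_loglik([h], make_null_basis(1, 5), params)
        np.testing.assert_allclose(
            ll, np.log(0.75 * 0.75 * 0.25 * 0.6), rtol=1e-12)
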