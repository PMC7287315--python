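"""Likelihood and probability computations checked against brute-force
linear-space oracles and closed-form values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mixrhlp as m
from mixrhlp.model import InvalidParameterError, component_logliks

from conftest import random_parameters


# ---------------------------------------------------------------------------
# brute-force oracles: plain linear-space evaluation of the model density,
# only usable at tiny N_t, independent of the log-space implementation
# ---------------------------------------------------------------------------

def _normal_pdf(y, mean, var):
    return np.exp(-0.5 * (y - mean) ** 2 / var) / np.sqrt(2 * np.pi * var)


def brute_component_density(y_i, t, params, k):
    X = np.vander(t, params.degree + 1, increasing=True)
    dens = 1.0
    for j in range(t.size):
        logits = params.omega[k, :, 0] + params.omega[k, :, 1] * t[j]
        pi = np.exp(logits) / np.exp(logits).sum()
        mix = sum(
            pi[r] * _normal_pdf(y_i[j], X[j] @ params.beta[k, r], params.sigma2[k, r])
            for r in range(params.n_regimes)
        )
        dens *= mix
    return dens


def brute_total_loglik(data, params):
    total = 0.0
    for i in range(data.n_subjects):
        total += np.log(sum(
            params.alpha[k] * brute_component_density(data.values[i], data.grid.points, params, k)
            for k in range(params.n_clusters)
        ))
    return total


# ---------------------------------------------------------------------------
# regime probabilities
# ---------------------------------------------------------------------------

class TestRegimeProbabilities:
    def test_zero_coefficients_give_uniform(self):
        probs = m.regime_probabilities(np.zeros((4, 2)), np.linspace(0, 1, 7))
        assert np.allclose(probs, 0.25)

    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.0, (0.03512, 0.70539, 0.25949)),
            (1.0, (0.68967, 0.05661, 0.25372)),
        ],
    )
    def test_benchmark_cluster1_values(self, truth_params, t, expected):
        """Direct softmax evaluation of the cluster-1 logistic coefficients."""
        probs = m.regime_probabilities(truth_params.omega[0], np.array([t]))
        assert probs[0] == pytest.approx(expected, abs=1e-5)

    def test_nonfinite_omega_rejected(self):
        with pytest.raises(InvalidParameterError):
            m.regime_probabilities(np.array([[np.inf, 0], [0, 0]]), np.array([0.0, 1.0]))

    def test_time_translation_covariance(self, truth_params):
        """Shifting time by delta while moving the intercepts by -slope*delta
        leaves the regime probabilities unchanged (d=1 affine covariance)."""
        t = np.linspace(0, 1, 11)
        delta = 0.37
        om = truth_params.omega[0]
        om_shift = om.copy()
        om_shift[:, 0] = om[:, 0] - om[:, 1] * delta
        assert np.allclose(
            m.regime_probabilities(om, t),
            m.regime_probabilities(om_shift, t + delta),
            atol=1e-12,
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        R = rng.integers(1, 5)
        omega = rng.normal(0, 3, size=(R, 2))
        omega[-1] = 0
        probs = m.regime_probabilities(omega, np.sort(rng.uniform(-2, 2, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs >= 0)


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

class TestEmission:
    def test_known_values(self):
        assert m.emission_logdensity(0.0, 0.0, 1.0) == pytest.approx(-0.918939, abs=1e-6)
        assert m.emission_logdensity(1.0, 0.0, 1.0) == pytest.approx(-1.418939, abs=1e-6)

    def test_normalizing_constant_cancels(self):
        # at the mean with variance 1/(2 pi) the log-density is exactly zero
        assert m.emission_logdensity(0.7, 0.7, 1 / (2 * np.pi)) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            m.emission_logdensity(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# component / total log-likelihood
# ---------------------------------------------------------------------------

class TestLoglik:
    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        K, R, d, n_t = rng.integers(1, 4), rng.integers(1, 4), rng.integers(0, 3), 4
        params = random_parameters(rng, K, R, d)
        data = m.PanelData(m.TimeGrid(np.sort(rng.uniform(0, 1, n_t))),
                           rng.normal(0, 1, size=(3, n_t)))
        for k in range(K):
            got = m.component_loglik(data.values[0], data.grid, params, k)
            want = np.log(brute_component_density(data.values[0], data.grid.points, params, k))
            assert got == pytest.approx(want, abs=1e-8)
        assert m.total_loglik(data, params) == pytest.approx(
            brute_total_loglik(data, params), abs=1e-8)

    def test_single_regime_reduces_to_emission_sum(self):
        rng = np.random.default_rng(0)
        params = random_parameters(rng, 2, 1, 1)
        t = np.linspace(0, 1, 6)
        y = rng.normal(size=6)
        X = np.vander(t, 2, increasing=True)
        want = m.emission_logdensity(y, X @ params.beta[0, 0], params.sigma2[0, 0]).sum()
        got = m.component_loglik(y, m.TimeGrid(t), params, 0)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_weight_component_drops(self):
        rng = np.random.default_rng(1)
        params = random_parameters(rng, 2, 2, 1)
        params.alpha = np.array([1.0, 0.0])
        data = m.PanelData(m.TimeGrid(np.linspace(0, 1, 5)), rng.normal(size=(3, 5)))
        want = sum(m.component_loglik(data.values[i], data.grid, params, 0) for i in range(3))
        assert m.total_loglik(data, params) == pytest.approx(want, abs=1e-8)

    def test_label_switching_symmetry(self, small_sim, truth_params):
        """Permuting cluster indices with matching parameter permutation
        leaves the total log-likelihood unchanged."""
        p = truth_params
        swapped = m.Parameters(p.alpha[::-1].copy(), p.omega[::-1].copy(),
                               p.beta[::-1].copy(), p.sigma2[::-1].copy(), p.spec)
        assert m.total_loglik(small_sim.data, swapped) == pytest.approx(
            m.total_loglik(small_sim.data, p), abs=1e-8)

    def test_large_variance_drives_loglik_down(self, small_sim, truth_params):
        inflated = truth_params.copy()
        inflated.sigma2 = truth_params.sigma2 * 1e6
        assert m.total_loglik(small_sim.data, inflated) < m.total_loglik(
            small_sim.data, truth_params)

    def test_incomplete_panel_rejected(self, truth_params):
        values = np.ones((2, 5))
        mask = np.ones((2, 5), dtype=bool)
        mask[0, 2] = False
        data = m.PanelData(m.TimeGrid(np.linspace(0, 1, 5)), values, mask)
        with pytest.raises(ValueError):
            m.total_loglik(data, truth_params)


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------

class TestPosteriors:
    @pytest.mark.parametrize("seed", range(4))
    def test_rows_normalized(self, seed):
        rng = np.random.default_rng(seed)
        params = random_parameters(rng, 3, 3, 1)
        data = m.PanelData(m.TimeGrid(np.linspace(0, 1, 12)), rng.normal(size=(6, 12)))
        tau = m.posterior_cluster(data, params)
        assert np.allclose(tau.sum(axis=1), 1.0, atol=1e-12)
        g = m.posterior_regime(data.values[0], data.grid, params, 1)
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-12)

    def test_single_cluster_posterior_is_one(self):
        rng = np.random.default_rng(2)
        params = random_parameters(rng, 1, 2, 1)
        data = m.PanelData(m.TimeGrid(np.linspace(0, 1, 8)), rng.normal(size=(4, 8)))
        assert np.allclose(m.posterior_cluster(data, params), 1.0)

    def test_symmetric_components_split_evenly(self):
        rng = np.random.default_rng(3)
        p1 = random_parameters(rng, 1, 2, 1)
        params = m.Parameters(
            np.array([0.5, 0.5]),
            np.stack([p1.omega[0], p1.omega[0]]),
            np.stack([p1.beta[0], p1.beta[0]]),
            np.stack([p1.sigma2[0], p1.sigma2[0]]),
        )
        data = m.PanelData(m.TimeGrid(np.linspace(0, 1, 8)), rng.normal(size=(4, 8)))
        assert np.allclose(m.posterior_cluster(data, params), 0.5, atol=1e-12)

    def test_equal_emissions_pass_prior_through(self, truth_params):
        """With identical emission parameters across regimes, the regime
        posterior equals the logistic prior."""
        p = truth_params.copy()
        p.beta[:] = p.beta[:, :1, :]
        p.sigma2[:] = p.sigma2[:, :1]
        t = m.TimeGrid(np.linspace(0, 1, 9))
        y = np.random.default_rng(4).normal(size=9)
        got = m.posterior_regime(y, t, p, 0)
        want = m.regime_probabilities(p.omega[0], t.points)
        assert np.allclose(got, want, atol=1e-12)


# ---------------------------------------------------------------------------
# types and serialization
# ---------------------------------------------------------------------------

class TestTypes:
    def test_parameters_json_roundtrip(self, truth_params, tmp_path):
        path = tmp_path / "params.json"
        truth_params.to_json(path)
        back = m.Parameters.from_json(path)
        assert np.array_equal(back.alpha, truth_params.alpha)
        assert np.array_equal(back.omega, truth_params.omega)
        assert np.array_equal(back.beta, truth_params.beta)
        assert np.array_equal(back.sigma2, truth_params.sigma2)
        assert back.spec == truth_params.spec
        assert np.all(back.omega[:, -1, :] == 0)

    def test_invariant_violations_rejected(self, truth_params):
        with pytest.raises(InvalidParameterError):
            m.Parameters(np.array([0.6, 0.6]), truth_params.omega,
                         truth_params.beta, truth_params.sigma2)
        bad_omega = truth_params.omega.copy()
        bad_omega[0, -1, 0] = 1.0
        with pytest.raises(InvalidParameterError):
            m.Parameters(truth_params.alpha, bad_omega,
                         truth_params.beta, truth_params.sigma2)
        with pytest.raises(InvalidParameterError):
            m.Parameters(truth_params.alpha, truth_params.omega,
                         truth_params.beta, truth_params.sigma2 * 0)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            m.TimeGrid(np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            m.TimeGrid(np.array([1.0]))

    def test_design_matrix_powers(self):
        X = m.design_matrix(np.array([0.0, 0.5, 2.0]), 2)
        assert np.allclose(X, [[1, 0, 0], [1, 0.5, 0.25], [1, 2, 4]])
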