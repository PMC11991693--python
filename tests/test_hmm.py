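"""HMM core: links, likelihood, decoding, stationary law, model nesting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import vonmises

from allomove.hmm import (
    EmissionSpec,
    FitConfig,
    FitResult,
    HMMParameters,
    ModelStructure,
    ObservationSeries,
    fit_hmm,
    log_likelihood,
    stationary_curves,
    stationary_distribution,
    viterbi,
)
from allomove.hmm.decode import state_names
from allomove.hmm.params import DEFAULT_EMISSIONS


def _random_params(structure, rng, scale=0.5):
    return HMMParameters.unpack(structure, rng.normal(0, scale, structure.n_params))


def _series(rng, T, csi=0.3, missing=0.0):
    def gam(mu, sd):
        x = rng.gamma((mu / sd) ** 2, sd**2 / mu, T)
        x[rng.random(T) < missing] = np.nan
        return x

    turn = rng.uniform(-np.pi, np.pi, T)
    turn[rng.random(T) < missing] = np.nan
    return ObservationSeries(
        id="x", csi=csi, step=gam(2000, 1000), turn=turn,
        max_depth=gam(150, 80), wiggles=gam(90, 60), dist_shore=gam(4, 2),
    )


class TestTransitionMatrix:
    def test_zero_coefficients_give_uniform_rows(self):
        st = ModelStructure(n_states=3)
        p = HMMParameters.unpack(st, np.zeros(st.n_params))
        assert np.allclose(p.transition_matrix(0.7), 1.0 / 3.0)

    def test_c_zero_reduces_to_intercepts(self, rng):
        st = ModelStructure(n_states=3)
        p = _random_params(st, rng)
        q = HMMParameters.unpack(st, p.pack())
        q.beta1 = rng.normal(0, 2, (3, 3))
        assert np.allclose(p.transition_matrix(0.0), q.transition_matrix(0.0))

    def test_matches_direct_softmax(self, rng):
        st = ModelStructure(n_states=3)
        for _ in range(20):
            p = _random_params(st, rng, scale=1.5)
            c = rng.uniform(-2, 2)
            G = p.transition_matrix(c)
            for i in range(3):
                eta = np.array(
                    [0.0 if j == i else p.beta0[i, j] + p.beta1[i, j] * c for j in range(3)]
                )
                ref = np.exp(eta) / np.exp(eta).sum()
                assert np.allclose(G[i], ref, atol=1e-12)

    def test_rows_sum_to_one_across_covariate_range(self, rng):
        st = ModelStructure(n_states=4)
        for _ in range(10):
            p = _random_params(st, rng, scale=2.0)
            for c in np.linspace(-5, 5, 11):
                assert np.allclose(p.transition_matrix(c).sum(axis=1), 1.0, atol=1e-12)


class TestEmissionLink:
    def test_zero_slope_constant_mean(self, rng):
        st = ModelStructure(n_states=2)
        p = _random_params(st, rng)
        p.alpha1["wiggles"] = np.zeros(2)  # wiggles carries no covariate anyway
        assert p.emission_mean("wiggles", 0, 0.0) == p.emission_mean("wiggles", 0, 1.5)

    def test_positive_slope_monotone(self, rng):
        st = ModelStructure(n_states=2)
        p = _random_params(st, rng)
        p.alpha1["step"] = np.array([0.5, 0.5])
        grid = np.linspace(0, 1, 9)
        means = [p.emission_mean("step", 0, c) for c in grid]
        assert np.all(np.diff(means) > 0)

    def test_shape_rate_moments(self, rng):
        st = ModelStructure(n_states=1, emissions=(EmissionSpec("step", "gamma"),))
        p = HMMParameters(structure=st)
        p.alpha0["step"] = np.array([np.log(2500.0)])
        p.alpha1["step"] = np.zeros(1)
        p.log_sd["step"] = np.array([np.log(1200.0)])
        shape, rate = p.gamma_shape_rate("step", 0)
        draws = rng.gamma(shape, 1.0 / rate, 100_000)
        assert draws.mean() == pytest.approx(2500.0, rel=0.02)
        assert draws.std() == pytest.approx(1200.0, rel=0.02)


class TestLikelihood:
    def test_single_state_equals_sum_of_densities(self, rng):
        st = ModelStructure(n_states=1)
        p = HMMParameters(structure=st)
        for stream, mu, sd in (
            ("step", 2000.0, 900.0), ("max_depth", 150.0, 70.0),
            ("wiggles", 90.0, 50.0), ("dist_shore", 4.0, 2.0),
        ):
            p.alpha0[stream] = np.array([np.log(mu)])
            p.alpha1[stream] = np.zeros(1)
            p.log_sd[stream] = np.array([np.log(sd)])
        p.turn_mean = np.zeros(1)
        p.turn_log_kappa = np.array([0.3])
        p.beta0 = np.zeros((1, 1))
        p.beta1 = np.zeros((1, 1))
        p.initial_logits = np.zeros(0)
        ser = _series(rng, 30, missing=0.2)
        expected = 0.0
        for stream in ("step", "max_depth", "wiggles", "dist_shore"):
            x = getattr(ser, stream)
            x = x[np.isfinite(x)]
            shape, rate = p.gamma_shape_rate(stream, 0, ser.csi)
            expected += gamma_dist.logpdf(x, shape, scale=1.0 / rate).sum()
        turn = ser.turn[np.isfinite(ser.turn)]
        expected += vonmises.logpdf(turn, np.exp(0.3)).sum()
        assert log_likelihood(p, [ser]) == pytest.approx(expected, abs=1e-8)

    def test_fully_missing_data_is_vacuous(self, rng):
        st = ModelStructure(n_states=3)
        p = _random_params(st, rng)
        T = 12
        nanarr = np.full(T, np.nan)
        ser = ObservationSeries(
            id="e", csi=0.4, step=nanarr, turn=nanarr, max_depth=nanarr,
            wiggles=nanarr, dist_shore=nanarr,
        )
        assert log_likelihood(p, [ser]) == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_dataset_doubles_loglik(self, rng):
        st = ModelStructure(n_states=2)
        p = _random_params(st, rng)
        ser = _series(rng, 40)
        ll1 = log_likelihood(p, [ser])
        ll2 = log_likelihood(p, [ser, ser])
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_invariant_to_state_relabelling(self, rng):
        st = ModelStructure(n_states=3)
        for _ in range(5):
            p = _random_params(st, rng)
            ser = _series(rng, 25, missing=0.15)
            base = log_likelihood(p, [ser])
            perm = rng.permutation(3)
            assert log_likelihood(p.permuted(perm), [ser]) == pytest.approx(
                base, abs=1e-8
            )

    def test_invalid_parameters_give_minus_inf(self, rng):
        st = ModelStructure(n_states=2)
        p = _random_params(st, rng)
        p.alpha0["step"][0] = np.nan
        assert log_likelihood(p, [_series(rng, 10)]) == -np.inf


class TestViterbi:
    def test_uninformative_model_ties_to_state_one(self):
        st = ModelStructure(n_states=3)
        p = HMMParameters.unpack(st, np.zeros(st.n_params))
        T = 15
        nanarr = np.full(T, np.nan)
        ser = ObservationSeries(
            id="t", csi=0.0, step=nanarr, turn=nanarr, max_depth=nanarr,
            wiggles=nanarr, dist_shore=nanarr,
        )
        track = viterbi(p, ser)
        assert np.all(track.states == 1)

    def test_separated_emissions_recover_truth(self, truth):
        from allomove.simulate import SimulationConfig, simulate_tracks

        sharp = truth.permuted([0, 1, 2])
        for stream in sharp.log_sd:
            sharp.log_sd[stream] = sharp.alpha0[stream] + np.log(0.05)
        sharp.turn_log_kappa = np.log(np.array([80.0, 80.0, 80.0]))
        sharp.turn_mean = np.array([0.0, 2.0, -2.0])
        cfg = SimulationConfig(1, 300, [0.4], sharp, seed=12)
        series, sim = simulate_tracks(cfg)
        track = viterbi(sharp, series[0])
        assert np.mean(track.states == sim.states["SIM-001"]) > 0.99

    def test_state_naming_orders_by_depth(self, truth):
        names = state_names(truth)
        assert names == ("transiting", "foraging_shallow", "foraging_deep")


class TestStationary:
    def test_doubly_stochastic_gives_uniform(self):
        G = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        assert np.allclose(stationary_distribution(G), 1.0 / 3.0)

    def test_two_state_closed_form(self, rng):
        for _ in range(10):
            a, b = rng.uniform(0.05, 0.95, 2)
            G = np.array([[1 - a, a], [b, 1 - b]])
            assert np.allclose(
                stationary_distribution(G), np.array([b, a]) / (a + b), atol=1e-12
            )

    def test_matches_power_iteration(self, rng):
        for _ in range(10):
            G = rng.dirichlet(np.ones(4), size=4)
            delta = stationary_distribution(G)
            power = np.full(4, 0.25) @ np.linalg.matrix_power(G, 2000)
            assert np.allclose(delta, power, atol=1e-12)

    def test_reducible_chain_rejected(self):
        G = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="reducible|periodic"):
            stationary_distribution(G)


class TestStationaryCurves:
    def _fit_result(self, params, cov):
        return FitResult(
            mle=params, loglik=0.0, n_params=params.structure.n_params,
            covariance=cov,
        )

    def test_zero_slopes_give_flat_curves(self, rng):
        st = ModelStructure(n_states=3)
        p = _random_params(st, rng)
        p.beta1 = np.zeros((3, 3))
        fit = self._fit_result(p, None)
        curves = stationary_curves(fit, np.linspace(0, 0.75, 5))
        for _, g in curves.groupby("state"):
            assert g["delta"].std() < 1e-12

    def test_zero_covariance_gives_zero_width_cis(self, rng):
        st = ModelStructure(n_states=3)
        p = _random_params(st, rng)
        fit = self._fit_result(p, np.zeros((st.n_params, st.n_params)))
        curves = stationary_curves(fit, np.array([0.0, 0.5]))
        assert np.allclose(curves["hi"] - curves["lo"], 0.0, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        st = ModelStructure(n_states=3)
        p = _random_params(st, rng)
        curves = stationary_curves(self._fit_result(p, None), np.array([0.2]))
        assert curves["delta"].sum() == pytest.approx(1.0)


class TestFitting:
    def test_fit_from_truth_never_worse_than_truth(self, truth, small_sim):
        series, _ = small_sim
        ll_truth = log_likelihood(truth, series)
        fit = fit_hmm(
            series, truth.structure,
            FitConfig(seed=0, n_restarts=1, ftol=1e-6, compute_hessian=False),
            start=truth,
        )
        assert fit.loglik >= ll_truth - 1e-6
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_nested_model_never_beats_full_on_loglik(self, small_sim):
        series, _ = small_sim
        full = ModelStructure(n_states=2, emissions=DEFAULT_EMISSIONS)
        reduced = full.without_covariate("both")
        cfg = FitConfig(seed=3, n_restarts=2, ftol=1e-6, compute_hessian=False)
        fit_full = fit_hmm(series, full, cfg)
        fit_reduced = fit_hmm(series, reduced, cfg)
        assert fit_full.loglik >= fit_reduced.loglik - 1e-4

    def test_duplicated_data_doubles_loglik_at_same_mle(self, small_sim):
        series, _ = small_sim
        st = ModelStructure(n_states=2, emissions=DEFAULT_EMISSIONS)
        cfg = FitConfig(seed=1, n_restarts=1, ftol=1e-7, compute_hessian=False)
        fit1 = fit_hmm(series, st, cfg)
        ll = log_likelihood(fit1.mle, series + series)
        assert ll == pytest.approx(2 * fit1.loglik, rel=1e-9)
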