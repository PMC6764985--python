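import numpy as np
import pytest
from scipy import integrate, stats

from _oracles import exhaustive_loglik, exhaustive_viterbi
from conftest import make_series
from whalemove.hmm import (
    HMMConfig,
    StateParams,
    aic,
    fit_hmm,
    forward_loglik,
    gamma_density,
    select_model,
    stationary_distribution,
    viterbi,
    wrapped_cauchy_density,
)
from whalemove.params import (
    GammaParams,
    SexLabel,
    TransitionMatrix,
    WrappedCauchyParams,
)


def _random_state_params(rng) -> StateParams:
    mu = np.sort(rng.uniform(0.5, 6.0, 2))[::-1]
    sig = mu * rng.uniform(0.3, 0.8, 2)
    lam = rng.uniform(-np.pi, np.pi, 2)
    kap = rng.uniform(0.05, 0.9, 2)
    ptr, prt = rng.uniform(0.05, 0.9, 2)
    return StateParams(
        gamma=(GammaParams(mu[0], sig[0]), GammaParams(mu[1], sig[1])),
        wrapped_cauchy=(WrappedCauchyParams(lam[0], kap[0]), WrappedCauchyParams(lam[1], kap[1])),
        tm=TransitionMatrix.from_switch_probs(ptr, prt),
    )


def _random_series(rng, T):
    speeds = rng.gamma(2.0, 1.5, size=T) + 1e-3
    turns = rng.uniform(-np.pi, np.pi, size=T)
    turns[0] = np.nan
    return make_series(speeds, turns)


class TestDensities:
    def test_gamma_normalizes(self):
        p = GammaParams(3.2, 1.7)
        val, _ = integrate.quad(lambda x: gamma_density(x, p), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_gamma_exponential_limit_at_origin(self):
        # mu = sigma = 2 -> shape 1 (exponential, rate 1/scale = 0.5)
        p = GammaParams(2.0, 2.0)
        assert gamma_density(1e-12, p) == pytest.approx(0.5, rel=1e-6)

    def test_gamma_sampling_mean(self):
        p = GammaParams(5.15, 2.0)
        rng = np.random.default_rng(0)
        x = rng.gamma(p.shape, p.scale, size=100_000)
        assert x.mean() == pytest.approx(p.mu, abs=3 * p.sigma / np.sqrt(x.size))

    def test_mean_sd_shape_scale_round_trip(self):
        p = GammaParams(3.16, 1.58)
        q = GammaParams.from_shape_scale(p.shape, p.scale)
        assert (q.mu, q.sigma) == (pytest.approx(3.16), pytest.approx(1.58))

    def test_wrapped_cauchy_uniform_limit(self):
        p = WrappedCauchyParams(1.0, 0.0)
        theta = np.linspace(-np.pi, np.pi, 7)
        np.testing.assert_allclose(wrapped_cauchy_density(theta, p), 1 / (2 * np.pi))

    def test_wrapped_cauchy_normalizes_and_symmetric(self):
        p = WrappedCauchyParams(0.7, 0.62)
        val, _ = integrate.quad(lambda t: wrapped_cauchy_density(t, p), -np.pi, np.pi)
        assert val == pytest.approx(1.0, abs=1e-8)
        x = np.linspace(0, np.pi, 50)
        np.testing.assert_allclose(
            wrapped_cauchy_density(p.lam + x, p), wrapped_cauchy_density(p.lam - x, p), rtol=1e-12
        )

    def test_wrapped_cauchy_matches_scipy(self):
        lam, kappa = 0.4, 0.55
        p = WrappedCauchyParams(lam, kappa)
        theta = np.linspace(-np.pi, np.pi - 1e-9, 101)
        ours = wrapped_cauchy_density(theta, p)
        scipys = stats.wrapcauchy.pdf(np.mod(theta - lam, 2 * np.pi), c=kappa)
        np.testing.assert_allclose(ours, scipys, rtol=1e-10)

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            WrappedCauchyParams(0.0, 1.0)


class TestStationary:
    def test_printed_transition_probabilities(self):
        pi = stationary_distribution(TransitionMatrix.from_switch_probs(0.035, 0.017))
        assert pi[1] == pytest.approx(0.035 / 0.052, rel=1e-12)
        # power-iteration oracle
        p = TransitionMatrix.from_switch_probs(0.035, 0.017).p
        v = np.array([0.5, 0.5])
        for _ in range(10_000):
            v = v @ p
        np.testing.assert_allclose(pi, v, atol=1e-12)

    def test_symmetric_chain(self):
        pi = stationary_distribution(TransitionMatrix.from_switch_probs(0.5, 0.5))
        np.testing.assert_allclose(pi, [0.5, 0.5])

    def test_fixed_point_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            tm = TransitionMatrix.from_switch_probs(*rng.uniform(0.01, 0.99, 2))
            pi = stationary_distribution(tm)
            assert np.linalg.norm(pi @ tm.p - pi) < 1e-12

    def test_reducible_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(TransitionMatrix(np.eye(2)))


class TestForward:
    def test_matches_exhaustive_toy(self):
        rng = np.random.default_rng(5)
        sp = _random_state_params(rng)
        series = _random_series(rng, 6)
        ours = forward_loglik(series, sp)
        oracle = exhaustive_loglik(
            series.speed,
            series.turn,
            [(g.mu, g.sigma) for g in sp.gamma],
            [(w.lam, w.kappa) for w in sp.wrapped_cauchy],
            sp.tm.p,
            stationary_distribution(sp.tm),
        )
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_single_observation_is_delta_mixture(self):
        rng = np.random.default_rng(6)
        sp = _random_state_params(rng)
        series = make_series([2.0], [np.nan])
        delta = stationary_distribution(sp.tm)
        expected = np.log(
            delta[0] * gamma_density(2.0, sp.gamma[0]) + delta[1] * gamma_density(2.0, sp.gamma[1])
        )
        assert forward_loglik(series, sp) == pytest.approx(float(expected), abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(7)
        sp = _random_state_params(rng)
        swapped = StateParams(
            gamma=sp.gamma[::-1],
            wrapped_cauchy=sp.wrapped_cauchy[::-1],
            tm=TransitionMatrix(sp.tm.p[::-1, ::-1]),
        )
        series = _random_series(rng, 40)
        assert forward_loglik(series, sp) == pytest.approx(
            forward_loglik(series, swapped), abs=1e-9
        )


class TestViterbi:
    def test_matches_exhaustive_t8(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            sp = _random_state_params(rng)
            series = _random_series(rng, 8)
            ours = viterbi(sp, series)
            oracle_path, _ = exhaustive_viterbi(
                series.speed,
                series.turn,
                [(g.mu, g.sigma) for g in sp.gamma],
                [(w.lam, w.kappa) for w in sp.wrapped_cauchy],
                sp.tm.p,
                stationary_distribution(sp.tm),
            )
            np.testing.assert_array_equal(ours.states, oracle_path)

    def test_tie_broken_toward_transit(self):
        sp = StateParams(
            gamma=(GammaParams(2.0, 1.0), GammaParams(2.0, 1.0)),
            wrapped_cauchy=(WrappedCauchyParams(0, 0.3), WrappedCauchyParams(0, 0.3)),
            tm=TransitionMatrix.from_switch_probs(0.5, 0.5),
        )
        series = _random_series(np.random.default_rng(9), 12)
        assert np.all(viterbi(sp, series).states == 0)

    def test_posteriors_sum_to_one_and_agree_with_viterbi_when_separated(self, sim_series_12):
        _, series = sim_series_12[0]
        sp = StateParams(
            gamma=(GammaParams(5.15, 2.575), GammaParams(2.15, 1.075)),
            wrapped_cauchy=(WrappedCauchyParams(0.0, 0.62), WrappedCauchyParams(np.pi, 0.1)),
            tm=TransitionMatrix.from_switch_probs(0.035, 0.017),
        )
        dec = viterbi(sp, series)
        np.testing.assert_allclose(dec.posteriors.sum(axis=1), 1.0, atol=1e-10)
        agree = np.mean(dec.states == np.argmax(dec.posteriors, axis=1))
        assert agree >= 0.95

    def test_decoding_accuracy_well_separated(self, sim_series_12):
        path, series = sim_series_12[1]  # a male: mu 3.16 vs 0.89
        sp = StateParams(
            gamma=(GammaParams(3.16, 1.58), GammaParams(0.89, 0.445)),
            wrapped_cauchy=(WrappedCauchyParams(0.0, 0.38), WrappedCauchyParams(np.pi, 0.1)),
            tm=TransitionMatrix.from_switch_probs(0.035, 0.017),
        )
        dec = viterbi(sp, series)
        assert np.mean(dec.states == path.states) > 0.90


class TestFitAndSelect:
    def test_aic_arithmetic_and_tie_rule(self):
        from dataclasses import replace

        fit = fit_hmm(
            [make_series([1.0, 2.0, 3.0, 2.5], [np.nan, 0.1, -0.2, 0.3], sid="a"),
             make_series([1.5, 2.2, 0.8, 2.1], [np.nan, 0.2, 0.1, -0.1], sid="b")],
            HMMConfig.from_id(1),
            n_restarts=1,
            seed=0,
            compute_cov=False,
        )
        synthetic = replace(fit, loglik=-100.0, n_params=10)
        assert aic(synthetic) == pytest.approx(220.0)
        bigger = replace(fit, loglik=-100.0, n_params=14)
        assert select_model([synthetic, bigger]).n_params == 10

    def test_parameter_counts(self):
        assert [HMMConfig.from_id(i).n_params() for i in (1, 2, 3, 4)] == [10, 14, 26, 30]

    def test_fit_requires_all_sex_levels_for_sex_configs(self):
        rng = np.random.default_rng(10)
        series = [_random_series(rng, 30) for _ in range(3)]  # all 'unknown'
        with pytest.raises(ValueError, match="levels"):
            fit_hmm(series, HMMConfig.from_id(3), n_restarts=1, seed=0)

    def test_track_order_exchangeability(self, sim_series_12):
        series = [s for _, s in sim_series_12[:6]]
        f1 = fit_hmm(series, 1, n_restarts=1, seed=0, compute_cov=False)
        f2 = fit_hmm(series[::-1], 1, n_restarts=1, seed=0, compute_cov=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_single_state_data_degenerates(self):
        rng = np.random.default_rng(11)
        series = [
            make_series(
                rng.gamma(4.0, 1.0, size=200), np.r_[np.nan, rng.uniform(-0.3, 0.3, 199)], sid=f"s{i}"
            )
            for i in range(3)
        ]
        fit = fit_hmm(series, 1, n_restarts=2, seed=1, compute_cov=False)
        pi = stationary_distribution(fit.params_for_sex(SexLabel.unknown).tm)
        assert min(pi) < 0.05  # one state's occupancy pushed towards zero

    def test_transit_state_has_higher_mean_speed(self, sim_series_12):
        series = [s for _, s in sim_series_12[:6]]
        fit = fit_hmm(series, 1, n_restarts=1, seed=0, compute_cov=False)
        sp = fit.params_for_sex(SexLabel.unknown)
        assert sp.gamma[0].mu > sp.gamma[1].mu

    def test_zero_inflated_speeds_handled(self):
        rng = np.random.default_rng(12)
        speeds = rng.gamma(4.0, 1.0, size=150)
        speeds[::10] = 0.0
        series = [
            make_series(speeds, np.r_[np.nan, rng.uniform(-1, 1, 149)], sid=f"z{i}") for i in range(2)
        ]
        fit = fit_hmm(series, 1, n_restarts=1, seed=0, compute_cov=False)
        assert fit.zero_mass
        assert fit.n_params == 12  # 10 + two zero-mass probabilities
        pz = fit.params_for_sex(SexLabel.unknown).zero_mass
        assert 0 < max(pz) < 0.5
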