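"""The synaptic-sampling learning rule and its training loop."""

import numpy as np
import pytest

from synsample.encoding import Encoder, TuningBank
from synsample.plasticity import (
    ALPHA_DEFAULT,
    PlasticityConfig,
    SynapseState,
    evaluate,
    noise_increment,
    one_hot,
    prior_drift,
    sampling_step,
    stdp_drift,
    stdp_drift_per_bin,
    train,
    update_increment,
    weights_from_params,
)
from synsample.synthdata import Sample
from synsample.wta import WTAConfig


class TestWeightsFromParams:
    def test_values_and_monotonicity(self):
        assert weights_from_params(np.array(3.0), 3.0) == pytest.approx(1.0)
        assert weights_from_params(np.array(3.0 + np.log(2)), 3.0) == pytest.approx(2.0)
        th = np.linspace(-5, 5, 11)
        w = weights_from_params(th, 3.0)
        assert np.all(np.diff(w) > 0) and np.all(w > 0)


class TestPriorDrift:
    @pytest.mark.parametrize(
        "theta,mu,sigma,expected",
        [(0.0, 0.0, 1.0, 0.0), (1.0, 0.0, 1.0, -1.0), (-2.0, 0.0, 2.0, 0.5)],
    )
    def test_values(self, theta, mu, sigma, expected):
        assert prior_drift(np.array(theta), mu, sigma) == pytest.approx(expected)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            prior_drift(np.zeros(2), 0.0, 0.0)


class TestSTDPDrift:
    def test_zero_at_input_fixed_point(self):
        w = np.full((3, 4), 0.5)
        xbar = ALPHA_DEFAULT * np.exp(0.5) * np.ones(4)
        d = stdp_drift(xbar, np.array([1.0, 0, 0]), one_hot(1, 3), w)
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_zero_when_output_matches_label(self):
        w = np.random.default_rng(0).random((3, 4))
        d = stdp_drift(np.ones(4), one_hot(2, 3), one_hot(2, 3), w)
        np.testing.assert_allclose(d, 0.0)

    def test_sign_structure_on_misclassification(self):
        # wrong neuron fires everything: its row is depressed, the label
        # row is potentiated (inputs above the weight threshold)
        w = np.full((3, 4), 0.1)
        d = stdp_drift(np.ones(4), one_hot(0, 3), one_hot(1, 3), w)
        assert np.all(d[0] < 0)  # fired but wrong
        assert np.all(d[1] > 0)  # should have fired
        np.testing.assert_allclose(d[2], 0.0)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            stdp_drift(np.ones(3), np.ones(3), np.ones(3), np.ones((3, 4)))

    def test_per_bin_reduces_to_aggregated_in_expectation(self, rng):
        # with the teaching rate equal to the output budget and output
        # spikes exactly at the expected density, the per-bin drift over
        # a flat trace equals the aggregated drift scaled by spike mass
        w = np.full((2, 3), 0.2)
        T = 200
        traces = np.ones((3, T)) * 0.5
        out = np.zeros((2, T), dtype=np.uint8)
        out[0, ::10] = 1  # 20 spikes, all from neuron 0
        h = one_hot(0, 2)
        per_bin = stdp_drift_per_bin(traces, out, h, w, ALPHA_DEFAULT, 100.0, 1.0)
        np.testing.assert_allclose(per_bin, 0.0, atol=1e-12)


class TestNoiseIncrement:
    def test_off_gives_zeros(self, rng):
        cfg = PlasticityConfig(noise_on=False)
        assert not noise_increment(np.ones((3, 3)), cfg, rng).any()

    def test_empirical_std_matches_scale(self):
        # std at w=1, N=1000, alpha=e^-6 is 1000*e^-5 ~ 6.7379 (within 2%)
        cfg = PlasticityConfig()
        rng = np.random.default_rng(11)
        draws = np.array(
            [noise_increment(np.ones((1, 1)), cfg, rng)[0, 0] for _ in range(100_000)]
        )
        assert draws.std() == pytest.approx(1000 * np.exp(-5.0), rel=0.02)
        assert abs(draws.mean()) < 0.05

    def test_std_monotone_in_weight(self):
        cfg = PlasticityConfig()
        rng = np.random.default_rng(2)
        stds = []
        for w in (0.5, 1.0, 2.0):
            d = noise_increment(np.full((200, 200), w), cfg, rng)
            stds.append(d.std())
        assert stds[0] < stds[1] < stds[2]

    def test_variance_reading_flag(self):
        cfg = PlasticityConfig(noise_param_is_std=False)
        rng = np.random.default_rng(3)
        d = noise_increment(np.ones((400, 400)), cfg, rng)
        assert d.std() == pytest.approx(np.sqrt(1000 * np.exp(-5.0)), rel=0.05)


class TestSamplingStep:
    def _state(self):
        return SynapseState(theta=np.zeros((2, 3)), theta0=3.0)

    def test_zero_learning_rate_freezes_parameters(self, rng):
        cfg = PlasticityConfig(b=0.0)
        st = self._state()
        sampling_step(st, np.ones(3), one_hot(0, 2), one_hot(1, 2), cfg, rng)
        np.testing.assert_array_equal(st.theta, 0.0)

    def test_zero_drift_noise_off_freezes(self, rng):
        cfg = PlasticityConfig(noise_on=False, mu=0.0)
        st = self._state()
        xfix = ALPHA_DEFAULT * np.exp(st.weights[0, 0]) * np.ones(3)
        sampling_step(st, xfix, one_hot(0, 2), one_hot(0, 2), cfg, rng)
        np.testing.assert_allclose(st.theta, 0.0, atol=1e-15)

    def test_seeded_determinism(self):
        cfg = PlasticityConfig()
        outs = []
        for _ in range(2):
            st = self._state()
            rng = np.random.default_rng(77)
            sampling_step(st, np.ones(3), one_hot(0, 2), one_hot(1, 2), cfg, rng)
            outs.append(st.theta.copy())
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_single_substep_matches_increment_formula(self, rng):
        cfg = PlasticityConfig(dt_update=0.4, max_substep=0.5, noise_on=False)
        assert cfg.n_substeps == 1
        st = self._state()
        expected = update_increment(
            st.copy(), np.ones(3), one_hot(0, 2), one_hot(1, 2), cfg, rng
        )
        sampling_step(st, np.ones(3), one_hot(0, 2), one_hot(1, 2), cfg, rng)
        np.testing.assert_allclose(st.theta, np.clip(expected, -0.25, 0.25), atol=1e-12)

    def test_weights_stay_positive_under_updates(self, rng):
        cfg = PlasticityConfig()
        st = self._state()
        for _ in range(50):
            sampling_step(st, rng.random(3), one_hot(0, 2), one_hot(1, 2), cfg, rng)
            assert np.all(st.weights > 0)

    def test_non_finite_update_is_named(self):
        st = self._state()
        with pytest.raises(FloatingPointError, match=r"\(0, 1\)"):
            st.apply_increment(np.array([[0.0, np.nan, 0.0], [0, 0, 0]]), (-10, 10))


class TestPriorPull:
    def test_matches_closed_form_relaxation(self, rng):
        # likelihood and noise off: theta(t) = mu + (theta_init - mu)e^{-bt/sigma^2}
        cfg = PlasticityConfig(b=0.01, noise_on=False, mu=1.0, sigma=1.0)
        st = SynapseState(theta=np.full((1, 1), 4.0), theta0=3.0)
        n_steps = 300
        for _ in range(n_steps):
            # keep the STDP factor at its fixed point so only the prior acts
            xfix = ALPHA_DEFAULT * np.exp(st.weights[0, 0]) * np.ones(1)
            sampling_step(st, xfix, one_hot(0, 1), one_hot(0, 1), cfg, rng)
        expected = 1.0 + 3.0 * np.exp(-cfg.b * n_steps / cfg.sigma**2)
        assert st.theta[0, 0] == pytest.approx(expected, rel=1e-2)


def _toy_two_class():
    """Two disjoint single-coordinate stimuli, trivially separable."""
    bank = TuningBank(
        coord_index=np.array([0] * 5 + [0] * 5),
        preferred=np.array([0.0] * 5 + [1.0] * 5),
        sigma_tc=0.1,
    )
    enc = Encoder(bank=bank, T_ms=200.0, dt_ms=1.0)
    samples = [
        Sample(np.array([float(label), 0.0, 0.0]), label)
        for label in (0, 1)
        for _ in range(60)
    ]
    order = np.random.default_rng(5).permutation(len(samples))
    return enc, [samples[i] for i in order] * 3


class TestTrainEvaluate:
    def test_one_sample_one_update(self, small_encoder, small_wta, sample3d):
        cfg = PlasticityConfig()
        report, state = train([sample3d], cfg, small_encoder, small_wta, seed=1)
        assert len(report.curve) == 1
        init = SynapseState.from_prior(10, 20, cfg, np.random.default_rng(0))
        assert state.theta.shape == init.theta.shape

    def test_separable_toy_reaches_perfect_running_accuracy(self):
        enc, samples = _toy_two_class()
        wta = WTAConfig(n_outputs=2, R_total_hz=100.0)
        cfg = PlasticityConfig(noise_on=False)
        report, state = train(samples, cfg, enc, wta, seed=3, record_every=20)
        assert report.curve[-1][1] == 1.0
        # the attained fixed point: output matches the label on every sample
        assert evaluate(samples, state, enc, wta, seed=9) == 1.0

    def test_oracle_weights_give_perfect_accuracy(self, small_wta):
        enc, samples = _toy_two_class()
        wta = WTAConfig(n_outputs=2, R_total_hz=100.0)
        theta = np.full((2, 10), -5.0)
        theta[0, :5] = 5.0  # class 0 neurons watch preferred=0
        theta[1, 5:] = 5.0
        state = SynapseState(theta=theta, theta0=0.0)
        assert evaluate(samples, state, enc, wta, seed=1) == 1.0

    def test_uniform_weights_give_chance_level(self, small_encoder, small_wta, clusters):
        from synsample.synthdata import generate_dataset

        samples = generate_dataset(clusters, 400, seed=2)
        state = SynapseState(theta=np.zeros((10, 20)), theta0=3.0)
        acc = evaluate(samples, state, small_encoder, small_wta, seed=4)
        assert abs(acc - 0.1) < 0.06

    def test_evaluate_invariant_to_sample_order(self, small_encoder, small_wta, tiny_dataset):
        state = SynapseState(
            theta=np.random.default_rng(1).normal(size=(10, 20)), theta0=3.0
        )
        a = evaluate(tiny_dataset, state, small_encoder, small_wta, seed=5)
        b = evaluate(tiny_dataset[::-1], state, small_encoder, small_wta, seed=5)
        assert a == b

    def test_noise_off_run_is_bitwise_reproducible(self, small_encoder, small_wta, tiny_dataset):
        cfg = PlasticityConfig(noise_on=False)
        _, s1 = train(tiny_dataset, cfg, small_encoder, small_wta, seed=11)
        _, s2 = train(tiny_dataset, cfg, small_encoder, small_wta, seed=11)
        np.testing.assert_array_equal(s1.theta, s2.theta)

    def test_empty_dataset_rejected(self, small_encoder, small_wta):
        with pytest.raises(ValueError):
            train([], PlasticityConfig(), small_encoder, small_wta, seed=1)
        st = SynapseState(theta=np.zeros((10, 20)))
        with pytest.raises(ValueError):
            evaluate([], st, small_encoder, small_wta, seed=1)
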