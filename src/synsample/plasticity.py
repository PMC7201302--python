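"""Synaptic-sampling learning rule with weight-dependent noise.

Synaptic parameters theta evolve by a stochastic differential equation
combining three forces, applied once per 200-ms stimulus presentation
(Euler step of effective length dt_update):

    d theta = b * [ (mu - theta)/sigma^2              (prior pull)
                  + N * w*(xbar - alpha*e^w)*(Theta{h} - Sbar)   (STDP drift)
                  + xi ] * dt_update

with w = exp(theta - theta0) the synaptic weight, xbar the time-averaged
EPSP input trace, Sbar the normalized output spike counts, Theta{h} the
one-hot label, and xi ~ Normal(0, N*alpha*e^w) drawn independently per
synapse, the second parameter read as a *standard deviation*.  The noise
scale grows with the weight, the model's analogue of larger dendritic
spines fluctuating more.  With the noise switched off the rule is the
exact deterministic gradient scheme, which serves as the baseline arm of
every comparison.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import Encoder, mean_trace
from .synthdata import Sample
from .wta import WTAConfig, membrane_potentials, predict, sample_output_spikes, wta_rates

__all__ = [
    "ALPHA_DEFAULT",
    "PlasticityConfig",
    "SynapseState",
    "TrainReport",
    "weights_from_params",
    "prior_drift",
    "stdp_drift",
    "stdp_drift_per_bin",
    "noise_increment",
    "update_increment",
    "apply_presentation_update",
    "sampling_step",
    "train",
    "evaluate",
    "one_hot",
]

ALPHA_DEFAULT = float(np.exp(-6.0))

# cap on exponent arguments so a clipped-out theta still yields finite
# drift and noise scales (e^60 is astronomically past any equilibrium)
_EXP_CAP = 60.0


def _exp_w(weights: np.ndarray) -> np.ndarray:
    return np.exp(np.minimum(weights, _EXP_CAP))


@dataclass(frozen=True)
class PlasticityConfig:
    """All scalars of the learning rule and its integration scheme.

    N is the sample-count constant that scales both the likelihood drift
    and the noise; alpha the rate scale of the implicit Poisson model;
    b the learning rate; (mu, sigma) the Gaussian prior on theta;
    theta0 the weight offset (initial weights ~ exp(-theta0)).
    ``noise_scaling`` selects how the noise enters the Euler step:
    "drift" adds b*dt*xi (noise at drift order, the default) and
    "wiener" adds b*sqrt(dt)*xi (Wiener increment).
    """

    N: float = 1000.0
    alpha: float = ALPHA_DEFAULT
    b: float = 1e-4
    mu: float = 0.0
    sigma: float = 1.0
    theta0: float = 3.0
    dt_update: float = 1.0
    noise_on: bool = True
    noise_param_is_std: bool = True
    noise_scaling: str = "drift"
    stdp_mode: str = "aggregated"  # or "per_bin"
    rho_target_hz: float | None = None  # per-bin teaching rate; None -> R_total
    theta_clip: tuple[float, float] = (-10.0, 5.75)
    max_substep: float = 0.5
    max_dtheta: float = 0.25

    @property
    def n_substeps(self) -> int:
        """Euler sub-steps per presentation.

        The likelihood drift is stiff near the weight equilibrium
        alpha*e^w = xbar (local relaxation rate ~ b*N*w^2*xbar), so the
        per-presentation step dt_update is split into sub-steps no longer
        than ``max_substep`` with the drift recomputed at each.
        """
        return max(1, int(np.ceil(self.dt_update / self.max_substep)))

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.noise_scaling not in ("drift", "wiener"):
            raise ValueError(f"unknown noise_scaling {self.noise_scaling!r}")
        if self.stdp_mode not in ("aggregated", "per_bin"):
            raise ValueError(f"unknown stdp_mode {self.stdp_mode!r}")

    def with_noise(self, on: bool) -> "PlasticityConfig":
        return replace(self, noise_on=on)


def weights_from_params(theta: np.ndarray, theta0: float) -> np.ndarray:
    """w = exp(theta - theta0), elementwise; always strictly positive."""
    return np.exp(np.asarray(theta, dtype=float) - theta0)


@dataclass
class SynapseState:
    """Parameter matrix theta (K x I) with offset theta0; w = e^(theta-theta0)."""

    theta: np.ndarray
    theta0: float = 3.0

    def __post_init__(self) -> None:
        self.theta = np.array(self.theta, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape

    @property
    def weights(self) -> np.ndarray:
        return weights_from_params(self.theta, self.theta0)

    @classmethod
    def from_prior(
        cls,
        n_out: int,
        n_in: int,
        config: PlasticityConfig,
        rng: np.random.Generator,
    ) -> "SynapseState":
        """Initial theta drawn from the prior p_S(theta) = N(mu, sigma^2)."""
        theta = rng.normal(config.mu, config.sigma, size=(n_out, n_in))
        return cls(theta=theta, theta0=config.theta0)

    def apply_increment(self, dtheta: np.ndarray, clip: tuple[float, float]) -> None:
        if not np.all(np.isfinite(dtheta)):
            k, i = np.argwhere(~np.isfinite(dtheta))[0]
            raise FloatingPointError(f"non-finite update at synapse ({k}, {i})")
        np.clip(self.theta + dtheta, clip[0], clip[1], out=self.theta)

    def copy(self) -> "SynapseState":
        return SynapseState(theta=self.theta.copy(), theta0=self.theta0)


def prior_drift(theta: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """(mu - theta) / sigma^2: gradient of the log Gaussian prior."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return (mu - np.asarray(theta, dtype=float)) / sigma**2


def stdp_drift(
    x_mean: np.ndarray,
    s_norm: np.ndarray,
    h_onehot: np.ndarray,
    weights: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
) -> np.ndarray:
    """Likelihood drift w*(xbar - alpha*e^w)*(Theta{h} - Sbar), per synapse.

    The first factor is a simplified STDP window: potentiation while the
    input trace exceeds the weight-dependent threshold alpha*e^w,
    depression beyond it.  The second factor is the supervision error:
    positive on the label row, negative on rows that fired instead.
    """
    x_mean = np.asarray(x_mean, dtype=float)
    s_norm = np.asarray(s_norm, dtype=float)
    h_onehot = np.asarray(h_onehot, dtype=float)
    K, I = np.asarray(weights).shape
    if x_mean.shape != (I,) or s_norm.shape != (K,) or h_onehot.shape != (K,):
        raise ValueError(
            f"shape mismatch: w {weights.shape}, xbar {x_mean.shape}, "
            f"Sbar {s_norm.shape}, h {h_onehot.shape}"
        )
    err = (h_onehot - s_norm)[:, None]
    return weights * (x_mean[None, :] - alpha * _exp_w(weights)) * err


def stdp_drift_per_bin(
    traces: np.ndarray,
    out_spikes: np.ndarray,
    h_onehot: np.ndarray,
    weights: np.ndarray,
    alpha: float,
    rho_target_hz: float,
    dt_ms: float,
) -> np.ndarray:
    """Per-bin likelihood drift: sum_t w*(x_i(t) - alpha*e^w)*(h_k*rho*dt - s_k(t)).

    Unlike the per-sample aggregated form, depression here reads the
    input trace at the actual output spike times, so the credit carries
    pre/post timing correlations.  The teaching rate ``rho_target_hz``
    defaults to the WTA budget so that an output stream fully
    concentrated on the label neuron zeroes the drift in expectation.
    """
    K, I = np.asarray(weights).shape
    T = traces.shape[1]
    if traces.shape[0] != I or out_spikes.shape != (K, T):
        raise ValueError("shape mismatch between traces, output spikes and weights")
    e = h_onehot[:, None] * (rho_target_hz * dt_ms * 1e-3) - out_spikes
    corr = e @ traces.T  # (K, I): sum_t e_k(t) x_i(t)
    mass = e.sum(axis=1)  # (K,)
    return weights * (corr - alpha * _exp_w(weights) * mass[:, None])


def noise_increment(
    weights: np.ndarray, config: PlasticityConfig, rng: np.random.Generator
) -> np.ndarray:
    """xi ~ Normal(0, N*alpha*e^w) per synapse; zero matrix when noise is off.

    The scale parameter N*alpha*e^w is a standard deviation by default
    (``noise_param_is_std``); flip the flag to read it as a variance.
    """
    w = np.asarray(weights, dtype=float)
    if not config.noise_on:
        return np.zeros_like(w)
    scale = config.N * config.alpha * _exp_w(w)
    if not config.noise_param_is_std:
        scale = np.sqrt(scale)
    return rng.normal(0.0, 1.0, size=w.shape) * scale


def update_increment(
    state: SynapseState,
    x_mean: np.ndarray,
    s_norm: np.ndarray,
    h_onehot: np.ndarray,
    config: PlasticityConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler increment b*dt*(prior + N*stdp + noise) at the current state.

    This is the single-step formula; :func:`apply_presentation_update`
    integrates it over sub-steps for stability.
    """
    w = state.weights
    drift = prior_drift(state.theta, config.mu, config.sigma)
    drift += config.N * stdp_drift(x_mean, s_norm, h_onehot, w, config.alpha)
    xi = noise_increment(w, config, rng)
    dt = config.dt_update
    if config.noise_scaling == "wiener":
        return config.b * (dt * drift + np.sqrt(dt) * xi)
    return config.b * dt * (drift + xi)


def apply_presentation_update(
    state: SynapseState,
    x_mean: np.ndarray,
    s_norm: np.ndarray,
    h_onehot: np.ndarray,
    config: PlasticityConfig,
    rng: np.random.Generator,
    *,
    traces: np.ndarray | None = None,
    out_spikes: np.ndarray | None = None,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """Integrate one presentation's update in place; returns the total dtheta.

    The drift is recomputed at every sub-step (the STDP factor is
    strongly mean-reverting in w, so long single steps overshoot); the
    noise is drawn once per presentation at the entering weight scale and
    spread uniformly over the sub-steps, so its per-presentation
    contribution is exactly b*dt*xi (or b*sqrt(dt)*xi under Wiener
    scaling) regardless of the sub-step count.

    In ``per_bin`` mode the raw traces and the output spike raster must
    be supplied; the aggregated mode needs only their per-window means.
    """
    per_bin = config.stdp_mode == "per_bin"
    if per_bin and (traces is None or out_spikes is None):
        raise ValueError("per_bin mode needs traces and out_spikes")
    rho_tgt = config.rho_target_hz if config.rho_target_hz is not None else 100.0
    n_sub = config.n_substeps
    h = config.dt_update / n_sub
    xi = noise_increment(state.weights, config, rng)
    if per_bin:
        # the bin-summed likelihood drift carries the window's spike
        # mass (rho_tgt * T); the noise enters at drift order, so it
        # carries the same mass to keep the Eq. noise-to-drift ratio
        xi = xi * (rho_tgt * traces.shape[1] * dt_ms * 1e-3)
    if config.noise_scaling == "wiener":
        noise_per_sub = config.b * np.sqrt(config.dt_update) * xi / n_sub
    else:
        noise_per_sub = config.b * h * xi
    cap = config.max_dtheta
    theta_before = state.theta.copy()
    for _ in range(n_sub):
        drift = prior_drift(state.theta, config.mu, config.sigma)
        if per_bin:
            drift += config.N * stdp_drift_per_bin(
                traces, out_spikes, h_onehot, state.weights, config.alpha,
                rho_tgt, dt_ms,
            )
        else:
            drift += config.N * stdp_drift(
                x_mean, s_norm, h_onehot, state.weights, config.alpha
            )
        step = config.b * h * drift + noise_per_sub
        # trust region: the STDP factor is exponentially stiff in theta,
        # so a single mean-reverting overshoot is capped per sub-step
        np.clip(step, -cap, cap, out=step)
        state.apply_increment(step, config.theta_clip)
    return state.theta - theta_before


def sampling_step(
    state: SynapseState,
    x_mean: np.ndarray,
    s_norm: np.ndarray,
    h_onehot: np.ndarray,
    config: PlasticityConfig,
    rng: np.random.Generator,
    **kwargs,
) -> SynapseState:
    """Apply one presentation's update in place; returns the state."""
    apply_presentation_update(state, x_mean, s_norm, h_onehot, config, rng, **kwargs)
    return state


def one_hot(label: int, n_classes: int) -> np.ndarray:
    h = np.zeros(n_classes)
    h[label] = 1.0
    return h


@dataclass
class TrainReport:
    """Learning curve and snapshots of one training run."""

    curve: list[tuple[int, float]] = field(default_factory=list)
    final_accuracy: float = 0.0
    seed: int = 0
    snapshots: dict[int, SynapseState] = field(default_factory=dict)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def train(
    samples: list[Sample],
    config: PlasticityConfig,
    encoder: Encoder,
    wta: WTAConfig,
    seed: int,
    *,
    snapshot_iters: tuple[int, ...] = (),
    record_every: int = 100,
    initial_state: SynapseState | None = None,
) -> tuple[TrainReport, SynapseState]:
    """Sequential presentation training loop.

    Each sample is encoded into a fresh 200-ms window, the WTA output is
    sampled, and one Euler step of the learning rule is applied.  Running
    accuracy (trailing window of ``record_every`` presentations) is
    recorded on the learning curve; parameter snapshots are stored at the
    requested iterations (1-based).

    Four independent RNG streams (init / encoding / output sampling /
    noise) are spawned from the seed, so a noise-off run consumes exactly
    the same encoding and output-sampling randomness as its matched
    noise-on twin.
    """
    if not samples:
        raise ValueError("dataset must be non-empty")
    rng_init, rng_enc, rng_net, rng_noise = _spawn_rngs(seed, 4)
    if config.stdp_mode == "per_bin" and config.rho_target_hz is None:
        config = replace(config, rho_target_hz=wta.R_total_hz)
    state = (
        initial_state.copy()
        if initial_state is not None
        else SynapseState.from_prior(wta.n_outputs, encoder.bank.n_neurons, config, rng_init)
    )
    report = TrainReport(seed=seed)
    snapshot_set = set(snapshot_iters)
    hits: list[bool] = []
    for it, sample in enumerate(samples, 1):
        traces = encoder.encode(sample, rng_enc)
        xbar = mean_trace(traces)
        u = membrane_potentials(traces, state.weights)
        rho = wta_rates(u, wta.R_total_hz)
        out = sample_output_spikes(rho, encoder.dt_ms, rng_net)
        hits.append(predict(out) == sample.label)
        h = one_hot(sample.label, wta.n_outputs)
        sampling_step(
            state, xbar, out.normalized, h, config, rng_noise,
            traces=traces, out_spikes=out.spike_matrix, dt_ms=encoder.dt_ms,
        )
        if it % record_every == 0 or it == len(samples):
            window = hits[-record_every:]
            report.curve.append((it, float(np.mean(window))))
        if it in snapshot_set:
            report.snapshots[it] = state.copy()
    report.final_accuracy = report.curve[-1][1] if report.curve else 0.0
    return report, state


def _sample_rng(seed: int, sample: Sample, salt: int = 0) -> np.random.Generator:
    """Content-keyed RNG so evaluation is invariant to sample order."""
    key = zlib.crc32(sample.features.tobytes())
    return np.random.default_rng([seed, key, sample.label, salt])


def evaluate(
    samples: list[Sample],
    state: SynapseState,
    encoder: Encoder,
    wta: WTAConfig,
    seed: int,
) -> float:
    """Fraction of samples whose predicted label matches; no learning."""
    if not samples:
        raise ValueError("dataset must be non-empty")
    weights = state.weights
    n_correct = 0
    for sample in samples:
        rng = _sample_rng(seed, sample)
        traces = encoder.encode(sample, rng)
        rho = wta_rates(membrane_potentials(traces, weights), wta.R_total_hz)
        out = sample_output_spikes(rho, encoder.dt_ms, rng)
        n_correct += predict(out) == sample.label
    return n_correct / len(samples)
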