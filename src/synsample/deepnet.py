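"""Three-layer noisy spiking network with spike-based back-propagation.

The hidden layer is a second WTA group: hidden potentials are weighted
EPSP sums of the input traces, hidden spikes are drawn under a shared
rate budget R_hidden, and the resulting spike trains are filtered by the
same EPSP kernel to form the next layer's input traces y_j(t).

Learning proceeds top-down per presentation.  The output layer applies
the same synaptic-sampling rule as the two-layer network, with the
hidden traces as inputs, and its applied increment dtheta^L is reused to
update the hidden layer:

    dtheta_ji = (beta/alpha) * xbar_i * (dtheta^L_kj + dtheta^L_mj)

where k is the output neuron that actually fired most and m the desired
(label) neuron — a delta-rule credit assignment that needs no stored
activations beyond the current presentation.  The transport gain
beta/alpha defaults to 0.01; see DeepConfig for why larger gains let a
few hidden units capture the whole code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import Encoder, epsp_traces, mean_trace
from .plasticity import (
    PlasticityConfig,
    SynapseState,
    TrainReport,
    apply_presentation_update,
    one_hot,
    _sample_rng,
    _spawn_rngs,
)
from .synthdata import Sample
from .wta import WTAConfig, WTAOutput, membrane_potentials, predict, sample_output_spikes, wta_rates

__all__ = [
    "DeepConfig",
    "LayeredState",
    "hidden_forward",
    "output_layer_update",
    "hidden_layer_update",
    "train_deep",
    "evaluate_deep",
]


@dataclass(frozen=True)
class DeepConfig:
    """Three-layer geometry and the hidden-update scale beta.

    ``beta=None`` means beta = 0.01*alpha (transport gain beta/alpha =
    0.01): the back-propagated outer-product update has a strong
    rich-get-richer mode — hidden units that respond get their active
    inputs potentiated and respond more — and larger gains let a few
    hidden units capture the whole code within a few thousand
    presentations.  The hidden WTA group has its own rate budget,
    saturated by default at one spike per 1-ms bin (1000 Hz), and its
    own weight offset ``hidden_theta0``; the smaller offset gives the
    untrained hidden layer large, dispersed potentials and hence a
    sparse stimulus-selective random feature code.
    """

    n_hidden: int = 500
    R_hidden_hz: float = 1000.0
    beta: float | None = None
    hidden_theta0: float | None = 2.0
    center_hidden_update: bool = False

    def beta_over_alpha(self, alpha: float) -> float:
        return 0.01 if self.beta is None else self.beta / alpha


@dataclass
class LayeredState:
    """Per-layer synapse states, input-side first (I->J, then J->K)."""

    layers: list[SynapseState]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.layers, self.layers[1:]):
            if lo.shape[0] != hi.shape[1]:
                raise ValueError(
                    f"layer shapes do not compose: {lo.shape} then {hi.shape}"
                )

    @property
    def hidden(self) -> SynapseState:
        return self.layers[0]

    @property
    def output(self) -> SynapseState:
        return self.layers[-1]

    def copy(self) -> "LayeredState":
        return LayeredState(layers=[s.copy() for s in self.layers])


def hidden_forward(
    traces: np.ndarray,
    hidden_state: SynapseState,
    encoder: Encoder,
    R_hidden_hz: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, WTAOutput]:
    """Input traces -> (hidden EPSP traces y_j(t), hidden spike raster)."""
    u = membrane_potentials(traces, hidden_state.weights)
    rho = wta_rates(u, R_hidden_hz)
    out = sample_output_spikes(rho, encoder.dt_ms, rng)
    y = epsp_traces(out.spike_matrix, encoder.kernel, encoder.dt_ms)
    return y, out


def output_layer_update(
    output_state: SynapseState,
    y_mean: np.ndarray,
    s_norm: np.ndarray,
    h_onehot: np.ndarray,
    config: PlasticityConfig,
    rng: np.random.Generator,
    **kwargs,
) -> np.ndarray:
    """Apply the top-layer rule (hidden traces as inputs); return dtheta^L."""
    return apply_presentation_update(
        output_state, y_mean, s_norm, h_onehot, config, rng, **kwargs
    )


def hidden_layer_update(
    hidden_state: SynapseState,
    x_mean: np.ndarray,
    dtheta_out: np.ndarray,
    k_fired: int,
    m_desired: int,
    beta_over_alpha: float,
    clip: tuple[float, float],
    center: bool = False,
) -> np.ndarray:
    """Back-propagated hidden increment (beta/alpha)*xbar_i*(dtheta^L_k + dtheta^L_m).

    ``k_fired`` is the output neuron that released the spike(s),
    ``m_desired`` the label neuron; their rows of the applied top-layer
    increment carry the credit signal down to every hidden synapse.

    With ``center`` the credit vector is mean-centred across hidden
    units, so the update redistributes drive between hidden neurons
    instead of inflating all of them together (the raw outer product has
    a large common mode that otherwise swamps the differential signal).
    """
    K = dtheta_out.shape[0]
    if not (0 <= k_fired < K and 0 <= m_desired < K):
        raise ValueError(f"neuron indices ({k_fired}, {m_desired}) out of range [0, {K})")
    g = dtheta_out[k_fired] + dtheta_out[m_desired]  # (J,)
    if center:
        g = g - g.mean()
    dtheta = beta_over_alpha * np.outer(g, np.asarray(x_mean, dtype=float))
    hidden_state.apply_increment(dtheta, clip)
    return dtheta


def init_layers(
    sizes: tuple[int, int, int],
    config: PlasticityConfig,
    rng: np.random.Generator,
    hidden_theta0: float | None = None,
) -> LayeredState:
    """Draw all layers from the prior; sizes = (I, J, K).

    ``hidden_theta0`` overrides the weight offset of the input->hidden
    layer only.  A smaller offset gives the untrained hidden WTA larger,
    more dispersed potentials, i.e. a sparse input-selective random
    feature code instead of near-uniform firing — without it the hidden
    layer transmits almost no stimulus information before learning
    shapes it.
    """
    n_in, n_hidden, n_out = sizes
    first = SynapseState.from_prior(n_hidden, n_in, config, rng)
    if hidden_theta0 is not None:
        first.theta0 = hidden_theta0
    return LayeredState(
        layers=[
            first,
            SynapseState.from_prior(n_out, n_hidden, config, rng),
        ]
    )


def train_deep(
    samples: list[Sample],
    config: PlasticityConfig,
    deep: DeepConfig,
    encoder: Encoder,
    wta: WTAConfig,
    seed: int,
    *,
    snapshot_iters: tuple[int, ...] = (),
    record_every: int = 100,
    initial_state: LayeredState | None = None,
) -> tuple[TrainReport, LayeredState]:
    """Three-layer training loop: output update, then hidden update, per sample.

    RNG streams are spawned in the order (init, encoding, hidden
    sampling, output sampling, noise) so the forward randomness is
    shared between matched noise-on/off runs.  With beta = 0 the hidden
    layer is frozen and the loop reduces to two-layer training on the
    hidden traces.
    """
    if not samples:
        raise ValueError("dataset must be non-empty")
    from dataclasses import replace as _replace

    rng_init, rng_enc, rng_hid, rng_net, rng_noise = _spawn_rngs(seed, 5)
    if config.stdp_mode == "per_bin" and config.rho_target_hz is None:
        config = _replace(config, rho_target_hz=wta.R_total_hz)
    state = (
        initial_state.copy()
        if initial_state is not None
        else init_layers(
            (encoder.bank.n_neurons, deep.n_hidden, wta.n_outputs),
            config,
            rng_init,
            hidden_theta0=deep.hidden_theta0,
        )
    )
    boa = deep.beta_over_alpha(config.alpha)
    report = TrainReport(seed=seed)
    snapshot_set = set(snapshot_iters)
    hits: list[bool] = []
    for it, sample in enumerate(samples, 1):
        traces = encoder.encode(sample, rng_enc)
        y_traces, _ = hidden_forward(traces, state.hidden, encoder, deep.R_hidden_hz, rng_hid)
        u = membrane_potentials(y_traces, state.output.weights)
        out = sample_output_spikes(wta_rates(u, wta.R_total_hz), encoder.dt_ms, rng_net)
        hits.append(predict(out) == sample.label)
        h = one_hot(sample.label, wta.n_outputs)
        dtheta_out = output_layer_update(
            state.output, mean_trace(y_traces), out.normalized, h, config, rng_noise,
            traces=y_traces, out_spikes=out.spike_matrix, dt_ms=encoder.dt_ms,
        )
        if boa != 0.0:
            hidden_layer_update(
                state.hidden,
                mean_trace(traces),
                dtheta_out,
                predict(out),
                sample.label,
                boa,
                config.theta_clip,
                center=deep.center_hidden_update,
            )
        if it % record_every == 0 or it == len(samples):
            report.curve.append((it, float(np.mean(hits[-record_every:]))))
        if it in snapshot_set:
            report.snapshots[it] = state.copy()
    report.final_accuracy = report.curve[-1][1] if report.curve else 0.0
    return report, state


def evaluate_deep(
    samples: list[Sample],
    state: LayeredState,
    deep: DeepConfig,
    encoder: Encoder,
    wta: WTAConfig,
    seed: int,
) -> float:
    """Held-out accuracy of a three-layer network; no learning."""
    if not samples:
        raise ValueError("dataset must be non-empty")
    w_out = state.output.weights
    n_correct = 0
    for sample in samples:
        rng = _sample_rng(seed, sample)
        traces = encoder.encode(sample, rng)
        y_traces, _ = hidden_forward(traces, state.hidden, encoder, deep.R_hidden_hz, rng)
        out = sample_output_spikes(
            wta_rates(membrane_potentials(y_traces, w_out), wta.R_total_hz),
            encoder.dt_ms,
            rng,
        )
        n_correct += predict(out) == sample.label
    return n_correct / len(samples)
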