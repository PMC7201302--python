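"""Spike-based winner-take-all output circuit.

Output neurons receive the weighted EPSP traces as membrane potentials
u_k(t) = sum_i w_ki x_i(t) and fire with an instantaneous rate that
depends exponentially on the potential.  Lateral inhibition is modelled
as exact divisive normalization: the K neurons share a fixed rate budget
R_total, so rho_k(t) = R_total * softmax(u(t))_k, and at most one output
spike is emitted per time bin.  The predicted label is the neuron with
the most spikes in the window (ties broken by lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WTAConfig",
    "WTAOutput",
    "membrane_potentials",
    "wta_rates",
    "sample_output_spikes",
    "predict",
]


@dataclass(frozen=True)
class WTAConfig:
    """Output-layer geometry: K competing neurons sharing R_total Hz."""

    n_outputs: int = 10
    R_total_hz: float = 100.0


@dataclass(frozen=True)
class WTAOutput:
    """One window of output activity.

    ``normalized`` is n_k / sum(n) when any spike occurred, else all
    zeros; it is the S-bar statistic the plasticity rule consumes.
    """

    spike_matrix: np.ndarray  # (K, n_bins) binary
    dt_ms: float

    @property
    def counts(self) -> np.ndarray:
        return self.spike_matrix.sum(axis=1)

    @property
    def normalized(self) -> np.ndarray:
        counts = self.counts.astype(float)
        total = counts.sum()
        return counts / total if total > 0 else counts

    @property
    def predicted(self) -> int:
        return int(np.argmax(self.counts))


def membrane_potentials(traces: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """u_k(t) = sum_i w_ki x_i(t); shapes (I, T) x (K, I) -> (K, T)."""
    traces = np.asarray(traces, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or traces.ndim != 2 or weights.shape[1] != traces.shape[0]:
        raise ValueError(
            f"shape mismatch: weights {weights.shape} vs traces {traces.shape}"
        )
    return weights @ traces


def wta_rates(potentials: np.ndarray, R_total_hz: float) -> np.ndarray:
    """rho_k(t) = R_total * exp(u_k) / sum_l exp(u_l), per bin.

    Computed with max-subtraction so adding a constant to all potentials
    leaves the result unchanged even for very large u.
    """
    u = np.asarray(potentials, dtype=float)
    shifted = u - u.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    return R_total_hz * e / e.sum(axis=0, keepdims=True)


def sample_output_spikes(
    rates: np.ndarray, dt_ms: float, rng: np.random.Generator
) -> WTAOutput:
    """Draw the output raster: at most one spike per bin (WTA inhibition).

    In each bin a spike occurs with probability min(sum_k rho_k * dt, 1)
    and is assigned to neuron k with probability rho_k / sum_l rho_l.
    """
    rho = np.asarray(rates, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rates must be >= 0")
    K, T = rho.shape
    total = rho.sum(axis=0)
    p_spike = np.minimum(total * dt_ms * 1e-3, 1.0)
    spike_here = rng.random(T) < p_spike
    safe_total = np.where(total > 0, total, 1.0)
    cum = np.cumsum(rho / safe_total, axis=0)
    pick = (cum < rng.random(T)[None, :]).sum(axis=0).clip(0, K - 1)
    matrix = np.zeros((K, T), dtype=np.uint8)
    cols = np.flatnonzero(spike_here & (total > 0))
    matrix[pick[cols], cols] = 1
    return WTAOutput(spike_matrix=matrix, dt_ms=dt_ms)


def predict(output: WTAOutput) -> int:
    """Most-active output neuron; ties (including all-silent) -> lowest index."""
    return output.predicted
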