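"""Strict-saddle certification diagnostics.

A twice-differentiable objective is a strict saddle at a stationary
point if its Hessian has at least one strictly positive eigenvalue, so a
descent direction always exists and weight-dependent noise can find it.
Because tr(H) = sum of eigenvalues, positivity of the Hessian trace is a
cheap sufficient certificate.  For the synaptic-sampling objective the
trace decomposes into three scalars:

    A = -K*I / sigma^2                       (prior curvature; always < 0)
    B = sum_ki (theta_ki - mu) / sigma^2     (parameter displacement)
    C = sum_n sum_ki w*alpha*e^w*(S_k - Theta{h_k})   (misclassification mass)

and the configuration is certified as a strict saddle iff A + B + C > 0.
Counting certified (weight snapshot, input) pairs under noise-trained
vs. noiseless-trained networks, and the reduction rate (S2-S1)/S2,
quantify how much of the saddle structure the noise removed.

The module also exposes the moment identities behind the noise model: a
sum of N Poisson(alpha*e^w) variables has mean = variance = N*alpha*e^w,
which is the normal approximation the noise distribution is built on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .encoding import Encoder
from .plasticity import SynapseState, one_hot
from .synthdata import Sample
from .wta import WTAConfig, membrane_potentials, sample_output_spikes, wta_rates

__all__ = [
    "HessianTraceTerms",
    "hessian_trace_terms",
    "strict_saddle_certified",
    "count_certified",
    "reduction_rate",
    "format_reduction_rate",
    "poisson_sum_moments",
    "gaussian_central_mass",
]


@dataclass(frozen=True)
class HessianTraceTerms:
    """The (A, B, C) Hessian-trace decomposition and its certificate."""

    A: float
    B: float
    C: float

    @property
    def total(self) -> float:
        return self.A + self.B + self.C

    @property
    def certified(self) -> bool:
        return self.total > 0.0


def _c_row_weights(state: SynapseState, alpha: float) -> np.ndarray:
    """R_k = sum_i w_ki * alpha * e^{w_ki}; C = sum_k (S_k - h_k) * R_k."""
    w = state.weights
    return (w * alpha * np.exp(w)).sum(axis=1)


def hessian_trace_terms(
    state: SynapseState,
    batch: list[tuple[np.ndarray, np.ndarray]],
    sigma: float,
    mu: float,
    alpha: float,
) -> HessianTraceTerms:
    """Compute (A, B, C) for a parameter configuration and a batch.

    ``batch`` is a list of (S, h) pairs, each a length-K vector: S the
    realized output statistic (normalized spike counts by default, or
    per-bin count sums) and h the one-hot label.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    K, I = state.shape
    A = -K * I / sigma**2
    B = float((state.theta - mu).sum() / sigma**2)
    row = _c_row_weights(state, alpha)
    C = 0.0
    for s_vec, h_vec in batch:
        C += float(((np.asarray(s_vec, float) - np.asarray(h_vec, float)) * row).sum())
    return HessianTraceTerms(A=A, B=B, C=C)


def strict_saddle_certified(terms: HessianTraceTerms) -> bool:
    """True iff A + B + C > 0 (strict inequality)."""
    return terms.certified


def count_certified(
    snapshots: list[SynapseState],
    inputs: list[Sample],
    encoder: Encoder,
    wta: WTAConfig,
    sigma: float,
    mu: float,
    alpha: float,
    seed: int,
) -> int:
    """Number of (snapshot, input) pairs whose certificate holds.

    Each input is encoded once; for every snapshot the WTA output is
    sampled (seeded per pair) and the certificate is evaluated with that
    single input as the batch.
    """
    if not snapshots:
        raise ValueError("snapshots must be non-empty")
    if not inputs:
        raise ValueError("inputs must be non-empty")
    pre = []
    for state in snapshots:
        K, I = state.shape
        pre.append(
            (
                state.weights,
                -K * I / sigma**2 + float((state.theta - mu).sum() / sigma**2),
                _c_row_weights(state, alpha),
            )
        )
    n_outputs = snapshots[0].shape[0]
    count = 0
    for i_in, sample in enumerate(inputs):
        rng_enc = np.random.default_rng([seed, i_in])
        traces = encoder.encode(sample, rng_enc)
        h = one_hot(sample.label, n_outputs)
        for i_sn, (w, ab, row) in enumerate(pre):
            rho = wta_rates(membrane_potentials(traces, w), wta.R_total_hz)
            rng_net = np.random.default_rng([seed, i_in, i_sn])
            out = sample_output_spikes(rho, encoder.dt_ms, rng_net)
            C = float(((out.normalized - h) * row).sum())
            count += ab + C > 0.0
    return count


def reduction_rate(s1: int, s2: int) -> float:
    """(S2 - S1) / S2: fractional drop in certified saddles due to noise.

    S1 counts certified pairs under noise-trained snapshots, S2 under
    noiseless-trained ones.  S1 > S2 is allowed (negative rate).
    """
    if s2 <= 0:
        raise ValueError("S2 must be > 0")
    return (s2 - s1) / s2


def format_reduction_rate(s1: int, s2: int) -> str:
    """The rate as a percentage string with two decimals, e.g. '82.90'."""
    return f"{100.0 * reduction_rate(s1, s2):.2f}"


def poisson_sum_moments(w: float, N: int, alpha: float) -> tuple[float, float]:
    """Mean and variance of a sum of N independent Poisson(alpha*e^w) draws.

    Both equal N*alpha*e^w — the moment identity that makes the normal
    noise approximation N(0, N*alpha*e^w) consistent.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    m = N * alpha * np.exp(w)
    return float(m), float(m)


def gaussian_central_mass(k: float) -> float:
    """P(|X - mu| < k*sigma) for a normal X; e.g. k=1 -> 0.6826..."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return float(2.0 * norm.cdf(k) - 1.0)
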