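"""Spike encoding: Gaussian tuning curves, Poisson trains, EPSP traces.

A stimulus is presented for a fixed window (200 ms by default).  Input
neurons convert it to firing rates through Gaussian tuning curves (or a
linear pixel map for image data), with a 5 Hz background rate added.
Poisson spike trains are drawn per neuron at 1-ms resolution (Bernoulli
per bin, exact as dt -> 0), and each train is filtered with a
peak-normalized double-exponential EPSP kernel to yield the continuous
input trace x_i(t) that drives the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .synthdata import Sample

__all__ = [
    "EPSPKernel",
    "TuningBank",
    "SpikeTrain",
    "Encoder",
    "firing_rates",
    "poisson_spike_matrix",
    "poisson_spikes",
    "spike_matrix_to_trains",
    "trains_to_spike_matrix",
    "epsp_traces",
    "epsp_trace",
    "mean_trace",
    "write_spike_trains",
    "read_spike_trains",
]


@dataclass(frozen=True)
class EPSPKernel:
    """Double-exponential EPSP shape, normalized to peak 1.

    eps(s) = (exp(-s/tau_d) - exp(-s/tau_r)) / eta  for s >= 0, else 0,
    where eta makes the maximum exactly 1.  Truncated at ``trunc_ms``.
    """

    tau_r_ms: float = 1.0
    tau_d_ms: float = 10.0
    trunc_ms: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_r_ms < self.tau_d_ms:
            raise ValueError("need 0 < tau_r_ms < tau_d_ms")

    @property
    def peak_time_ms(self) -> float:
        tr, td = self.tau_r_ms, self.tau_d_ms
        return np.log(td / tr) * tr * td / (td - tr)

    def _norm(self) -> float:
        s = self.peak_time_ms
        return np.exp(-s / self.tau_d_ms) - np.exp(-s / self.tau_r_ms)

    def __call__(self, lags_ms: np.ndarray) -> np.ndarray:
        s = np.asarray(lags_ms, dtype=float)
        val = (np.exp(-s / self.tau_d_ms) - np.exp(-s / self.tau_r_ms)) / self._norm()
        return np.where((s >= 0) & (s <= self.trunc_ms), val, 0.0)

    def taps(self, dt_ms: float) -> np.ndarray:
        """Kernel sampled at lags 0, dt, 2*dt, ... up to the truncation."""
        lags = np.arange(0.0, self.trunc_ms + dt_ms / 2, dt_ms)
        return self(lags)


@dataclass(frozen=True)
class TuningBank:
    """Input-layer rate code.

    In ``tuning`` mode neuron i responds to feature coordinate
    ``coord_index[i]`` with a Gaussian bump centred at ``preferred[i]``
    of width ``sigma_tc``; in ``pixel`` mode neuron i reads pixel i
    linearly.  A background rate is always added, so every neuron fires
    at r_bg even far from its preferred stimulus.
    """

    coord_index: np.ndarray
    preferred: np.ndarray
    sigma_tc: float = 0.2
    r_max_hz: float = 80.0
    r_bg_hz: float = 5.0
    mode: str = "tuning"

    def __post_init__(self) -> None:
        if self.r_max_hz < 0 or self.r_bg_hz < 0:
            raise ValueError("rates must be >= 0")
        if self.mode not in ("tuning", "pixel"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "coord_index", np.asarray(self.coord_index, dtype=int))
        object.__setattr__(self, "preferred", np.asarray(self.preferred, dtype=float))

    @property
    def n_neurons(self) -> int:
        return self.coord_index.shape[0]

    @classmethod
    def random(
        cls,
        n_neurons: int,
        n_features: int,
        seed: int,
        *,
        sigma_tc: float = 0.2,
        r_max_hz: float = 80.0,
        r_bg_hz: float = 5.0,
        preferred_lo: float = -0.5,
        preferred_hi: float = 1.5,
    ) -> "TuningBank":
        """Random bank: each neuron watches one feature coordinate drawn
        uniformly, with preferred value ~ Uniform(preferred_lo, preferred_hi).

        The default preferred range covers roughly +-2 standard
        deviations of the cluster-feature distribution, so stimuli in
        the tails still excite tuned neurons rather than falling back to
        background everywhere.
        """
        rng = np.random.default_rng(seed)
        return cls(
            coord_index=rng.integers(0, n_features, size=n_neurons),
            preferred=rng.uniform(preferred_lo, preferred_hi, size=n_neurons),
            sigma_tc=sigma_tc,
            r_max_hz=r_max_hz,
            r_bg_hz=r_bg_hz,
            mode="tuning",
        )

    @classmethod
    def pixel(
        cls, n_pixels: int, *, r_max_hz: float = 80.0, r_bg_hz: float = 5.0
    ) -> "TuningBank":
        """One neuron per pixel; rate = r_max * pixel + r_bg."""
        return cls(
            coord_index=np.arange(n_pixels),
            preferred=np.zeros(n_pixels),
            r_max_hz=r_max_hz,
            r_bg_hz=r_bg_hz,
            mode="pixel",
        )


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (ms) of one neuron within a presentation window."""

    neuron: int
    times_ms: np.ndarray
    window_ms: float = 200.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= self.window_ms):
            raise ValueError("spike times must be strictly increasing in [0, T)")
        object.__setattr__(self, "times_ms", t)


def firing_rates(sample: Sample, bank: TuningBank) -> np.ndarray:
    """Per-neuron firing rate (Hz) for one stimulus."""
    v = sample.features
    if bank.mode == "pixel":
        if v.shape[0] != bank.n_neurons:
            raise ValueError(
                f"pixel mode needs {bank.n_neurons} features, got {v.shape[0]}"
            )
        return bank.r_max_hz * v + bank.r_bg_hz
    if bank.coord_index.size and bank.coord_index.max() >= v.shape[0]:
        raise ValueError(
            f"bank watches coordinate {bank.coord_index.max()} but sample has "
            f"{v.shape[0]} features"
        )
    d = v[bank.coord_index] - bank.preferred
    return bank.r_max_hz * np.exp(-(d**2) / (2.0 * bank.sigma_tc**2)) + bank.r_bg_hz


def _n_bins(T_ms: float, dt_ms: float) -> int:
    n = T_ms / dt_ms
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"T={T_ms} ms must be a multiple of dt={dt_ms} ms")
    return int(round(n))


def poisson_spike_matrix(
    rates_hz: np.ndarray, T_ms: float, dt_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary (n_neurons, n_bins) spike raster; Bernoulli(rate*dt) per bin."""
    rates_hz = np.asarray(rates_hz, dtype=float)
    if np.any(rates_hz < 0):
        raise ValueError("rates must be >= 0")
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    n_bins = _n_bins(T_ms, dt_ms)
    p = np.minimum(rates_hz * dt_ms * 1e-3, 1.0)
    return (rng.random((rates_hz.shape[0], n_bins)) < p[:, None]).astype(np.uint8)


def poisson_spikes(
    rates_hz: np.ndarray, T_ms: float, dt_ms: float, seed: int
) -> list[SpikeTrain]:
    """Seeded Poisson trains, one per neuron (bin-centre spike times)."""
    mat = poisson_spike_matrix(rates_hz, T_ms, dt_ms, np.random.default_rng(seed))
    return spike_matrix_to_trains(mat, dt_ms, T_ms)


def spike_matrix_to_trains(
    matrix: np.ndarray, dt_ms: float, T_ms: float
) -> list[SpikeTrain]:
    return [
        SpikeTrain(neuron=i, times_ms=np.flatnonzero(row) * dt_ms, window_ms=T_ms)
        for i, row in enumerate(matrix)
    ]


def trains_to_spike_matrix(
    trains: list[SpikeTrain], dt_ms: float, T_ms: float, n_neurons: int | None = None
) -> np.ndarray:
    n = n_neurons if n_neurons is not None else 1 + max(t.neuron for t in trains)
    mat = np.zeros((n, _n_bins(T_ms, dt_ms)), dtype=np.uint8)
    for tr in trains:
        mat[tr.neuron, np.round(tr.times_ms / dt_ms).astype(int)] = 1
    return mat


def epsp_traces(
    spike_matrix: np.ndarray, kernel: EPSPKernel, dt_ms: float
) -> np.ndarray:
    """Causal convolution of every spike row with the EPSP kernel.

    Returns an array of the same shape as ``spike_matrix``; contributions
    falling beyond the presentation window are discarded.
    """
    taps = kernel.taps(dt_ms)
    out = fftconvolve(spike_matrix.astype(float), taps[None, :], mode="full", axes=1)
    out = out[:, : spike_matrix.shape[1]]
    # fft round-off can leave tiny negatives; the trace is non-negative
    np.clip(out, 0.0, None, out=out)
    return out


def epsp_trace(train: SpikeTrain, kernel: EPSPKernel, dt_ms: float) -> np.ndarray:
    """x_i(t) for a single train, as a 1-D series over the window."""
    mat = trains_to_spike_matrix([SpikeTrain(0, train.times_ms, train.window_ms)],
                                 dt_ms, train.window_ms, n_neurons=1)
    return epsp_traces(mat, kernel, dt_ms)[0]


def mean_trace(traces: np.ndarray) -> np.ndarray:
    """Time-average of the trace(s) over the presentation window."""
    traces = np.asarray(traces, dtype=float)
    if traces.shape[-1] == 0:
        raise ValueError("empty window")
    return traces.mean(axis=-1)


@dataclass(frozen=True)
class Encoder:
    """Bundles tuning bank, EPSP kernel and time grid into one front end."""

    bank: TuningBank
    kernel: EPSPKernel = field(default_factory=EPSPKernel)
    T_ms: float = 200.0
    dt_ms: float = 1.0

    @property
    def n_bins(self) -> int:
        return _n_bins(self.T_ms, self.dt_ms)

    def encode(self, sample: Sample, rng: np.random.Generator) -> np.ndarray:
        """Sample -> input traces x_i(t), shape (n_neurons, n_bins)."""
        rates = firing_rates(sample, self.bank)
        spikes = poisson_spike_matrix(rates, self.T_ms, self.dt_ms, rng)
        return epsp_traces(spikes, self.kernel, self.dt_ms)


def write_spike_trains(trains: list[SpikeTrain], path: str | Path) -> None:
    """Two-column delimited text: neuron_id, spike time (ms)."""
    with Path(path).open("w") as fh:
        fh.write("# neuron_id,time_ms\n")
        for tr in trains:
            for t in tr.times_ms:
                fh.write(f"{tr.neuron},{t}\n")


def read_spike_trains(path: str | Path, window_ms: float) -> list[SpikeTrain]:
    by_neuron: dict[int, list[float]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            neuron, t = line.split(",")
            by_neuron.setdefault(int(neuron), []).append(float(t))
    return [
        SpikeTrain(neuron=k, times_ms=np.sort(v), window_ms=window_ms)
        for k, v in sorted(by_neuron.items())
    ]
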