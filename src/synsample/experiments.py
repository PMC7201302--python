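"""Reproducible experiment harness for the noise-vs-no-noise comparisons.

`run_comparison` trains matched-seed pairs of runs — identical data,
encoder, initialization and forward randomness, differing only in
whether the weight-dependent noise term is on — and reports mean and
standard deviation of learning-phase and test-phase accuracy per
condition.  Snapshots taken near convergence feed `run_saddle_pipeline`,
which counts certified strict-saddle (snapshot, input) pairs per
condition and computes the reduction rate.

Profiles: `ExperimentConfig.full_synthesis()` mirrors the full-scale
study (1,000 input neurons, 14,400 training samples, 10 runs);
`ExperimentConfig.reduced_synthesis()` is the reduced-scale profile
(200 input neurons, 3,000 training samples, 3 run pairs) used by the
test suite and the acceptance script.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import deepnet, plasticity, saddle
from .encoding import Encoder, EPSPKernel, SpikeTrain, TuningBank, write_spike_trains
from .plasticity import PlasticityConfig, SynapseState, TrainReport
from .synthdata import Sample, generate_dataset, sample_cluster_params
from .wta import WTAConfig, membrane_potentials, sample_output_spikes, wta_rates

__all__ = [
    "ExperimentConfig",
    "RunRecord",
    "ComparisonResult",
    "SaddleReport",
    "run_comparison",
    "run_saddle_pipeline",
    "export_raster",
    "write_manifest",
    "write_snapshot",
    "read_snapshot",
]

CONDITIONS = ("noise_on", "noise_off")


@dataclass(frozen=True)
class ExperimentConfig:
    """Every knob of a comparison experiment, defaults made explicit."""

    # data
    n_classes: int = 10
    n_features: int = 3
    n_train: int = 14400
    n_test: int = 1000
    # architecture
    n_inputs: int = 1000
    n_hidden: int | None = None  # None -> two-layer network
    R_total_hz: float = 100.0
    R_hidden_hz: float = 1000.0
    beta: float | None = None  # None -> DeepConfig default 0.01*alpha
    hidden_theta0: float = 2.0
    # encoder
    T_ms: float = 200.0
    dt_ms: float = 1.0
    r_max_hz: float = 80.0
    r_bg_hz: float = 5.0
    sigma_tc: float = 0.2
    preferred_lo: float = -0.5
    preferred_hi: float = 1.5
    tau_r_ms: float = 1.0
    tau_d_ms: float = 10.0
    trunc_ms: float = 50.0
    # plasticity
    N: float = 1000.0
    alpha: float = plasticity.ALPHA_DEFAULT
    b: float = 1e-4
    mu: float = 0.0
    sigma: float = 1.0
    theta0: float = 3.0
    dt_update: float = 1.0
    noise_param_is_std: bool = True
    noise_scaling: str = "drift"
    stdp_mode: str = "aggregated"
    theta_clip_lo: float = -10.0
    theta_clip_hi: float = 5.75
    # orchestration
    n_runs: int = 10
    seed: int = 0
    record_every: int = 100
    n_snapshots: int = 3

    @classmethod
    def full_synthesis(cls, **overrides) -> "ExperimentConfig":
        """Full-scale two-layer profile (10 runs, 14,400 samples, I=1,000)."""
        return cls(**overrides)

    @classmethod
    def reduced_synthesis(cls, **overrides) -> "ExperimentConfig":
        """Desk-scale profile: I=200, 3,000 train / 1,000 test, 3 run pairs."""
        defaults = dict(n_inputs=200, n_train=3000, n_test=1000, n_runs=3)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in mapping:
            if key not in known:
                raise KeyError(f"unknown config key: {key!r}")
        return cls(**mapping)

    def plasticity_config(self, noise_on: bool) -> PlasticityConfig:
        return PlasticityConfig(
            N=self.N,
            alpha=self.alpha,
            b=self.b,
            mu=self.mu,
            sigma=self.sigma,
            theta0=self.theta0,
            dt_update=self.dt_update,
            noise_on=noise_on,
            noise_param_is_std=self.noise_param_is_std,
            noise_scaling=self.noise_scaling,
            stdp_mode=self.stdp_mode,
            theta_clip=(self.theta_clip_lo, self.theta_clip_hi),
        )

    def encoder(self, bank_seed: int) -> Encoder:
        bank = TuningBank.random(
            self.n_inputs,
            self.n_features,
            bank_seed,
            sigma_tc=self.sigma_tc,
            r_max_hz=self.r_max_hz,
            r_bg_hz=self.r_bg_hz,
            preferred_lo=self.preferred_lo,
            preferred_hi=self.preferred_hi,
        )
        kernel = EPSPKernel(self.tau_r_ms, self.tau_d_ms, self.trunc_ms)
        return Encoder(bank=bank, kernel=kernel, T_ms=self.T_ms, dt_ms=self.dt_ms)

    def wta(self) -> WTAConfig:
        return WTAConfig(n_outputs=self.n_classes, R_total_hz=self.R_total_hz)

    def deep(self) -> deepnet.DeepConfig:
        if self.n_hidden is None:
            raise ValueError("n_hidden is not set; this is a two-layer config")
        return deepnet.DeepConfig(
            n_hidden=self.n_hidden,
            R_hidden_hz=self.R_hidden_hz,
            beta=self.beta,
            hidden_theta0=self.hidden_theta0,
        )

    def snapshot_iters(self) -> tuple[int, ...]:
        """Evenly spaced tail iterations (convergence-stage snapshots)."""
        n = min(self.n_snapshots, self.n_train)
        step = max(1, self.n_train // (2 * max(n, 1)))
        return tuple(self.n_train - step * i for i in range(n))[::-1]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunRecord:
    """One matched seed pair: shared data/encoder, two trained arms."""

    run_index: int
    data_seed: int
    bank_seed: int
    train_seed: int
    eval_seed: int
    encoder: Encoder
    test_samples: list[Sample]
    reports: dict[str, TrainReport] = field(default_factory=dict)
    states: dict[str, object] = field(default_factory=dict)
    learn_acc: dict[str, float] = field(default_factory=dict)
    test_acc: dict[str, float] = field(default_factory=dict)


@dataclass
class ComparisonResult:
    """All runs of a comparison plus per-condition summary statistics."""

    config: ExperimentConfig
    runs: list[RunRecord]

    def accuracies(self, condition: str, phase: str = "test") -> np.ndarray:
        key = "test_acc" if phase == "test" else "learn_acc"
        return np.array([getattr(r, key)[condition] for r in self.runs])

    def mean_accuracy(self, condition: str, phase: str = "test") -> float:
        return float(self.accuracies(condition, phase).mean())

    def std_accuracy(self, condition: str, phase: str = "test") -> float:
        return float(self.accuracies(condition, phase).std())

    def gain(self, phase: str = "test") -> float:
        return self.mean_accuracy("noise_on", phase) - self.mean_accuracy(
            "noise_off", phase
        )


def _derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Per-run sub-seeds, deterministic in the base seed, all < 2^31."""
    return np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n)


def run_comparison(config: ExperimentConfig, progress: bool = False) -> ComparisonResult:
    """Train paired noise-on / noise-off runs and collect accuracies.

    Each run draws its own cluster parameters, datasets, tuning bank and
    initialization; within a run the two arms share every seed so that
    only the stochastic noise term differs between them.
    """
    seeds = _derive_seeds(config.seed, 4 * config.n_runs).reshape(config.n_runs, 4)
    wta_cfg = config.wta()
    runs = []
    for r in range(config.n_runs):
        data_seed, bank_seed, train_seed, eval_seed = (int(s) for s in seeds[r])
        clusters = sample_cluster_params(config.n_classes, data_seed)
        train_set = generate_dataset(clusters, config.n_train, data_seed + 1)
        test_set = generate_dataset(clusters, config.n_test, data_seed + 2)
        encoder = config.encoder(bank_seed)
        record = RunRecord(
            run_index=r,
            data_seed=data_seed,
            bank_seed=bank_seed,
            train_seed=train_seed,
            eval_seed=eval_seed,
            encoder=encoder,
            test_samples=test_set,
        )
        for condition in CONDITIONS:
            pcfg = config.plasticity_config(noise_on=(condition == "noise_on"))
            if config.n_hidden is None:
                report, state = plasticity.train(
                    train_set,
                    pcfg,
                    encoder,
                    wta_cfg,
                    train_seed,
                    snapshot_iters=config.snapshot_iters(),
                    record_every=config.record_every,
                )
                test_acc = plasticity.evaluate(
                    test_set, state, encoder, wta_cfg, eval_seed
                )
            else:
                report, state = deepnet.train_deep(
                    train_set,
                    pcfg,
                    config.deep(),
                    encoder,
                    wta_cfg,
                    train_seed,
                    snapshot_iters=config.snapshot_iters(),
                    record_every=config.record_every,
                )
                test_acc = deepnet.evaluate_deep(
                    test_set, state, config.deep(), encoder, wta_cfg, eval_seed
                )
            record.reports[condition] = report
            record.states[condition] = state
            record.learn_acc[condition] = report.final_accuracy
            record.test_acc[condition] = test_acc
            if progress:
                print(
                    f"run {r} {condition}: learn={report.final_accuracy:.3f} "
                    f"test={test_acc:.3f}",
                    flush=True,
                )
        runs.append(record)
    return ComparisonResult(config=config, runs=runs)


@dataclass
class SaddleReport:
    """Certified-saddle counts per condition and the reduction rate."""

    s1: int  # noise-trained snapshots
    s2: int  # noiseless-trained snapshots
    per_run: dict[str, list[int]]
    n_inputs: int

    @property
    def rate(self) -> float | None:
        return None if self.s2 == 0 else saddle.reduction_rate(self.s1, self.s2)

    def as_row(self) -> str:
        rate = "undefined" if self.rate is None else f"{100 * self.rate:.2f}"
        return f"S1={self.s1}\tS2={self.s2}\treduction_rate_pct={rate}"


def run_saddle_pipeline(
    result: ComparisonResult, n_inputs: int = 1000, seed: int = 0
) -> SaddleReport:
    """Count certified strict-saddle pairs over convergence-stage snapshots.

    Only defined for two-layer comparisons (the certificate is a
    property of a single synapse matrix).  Inputs are drawn from each
    run's own held-out set; counts are summed over runs per condition.
    """
    config = result.config
    if config.n_hidden is not None:
        raise ValueError("saddle pipeline applies to two-layer comparisons")
    per_run: dict[str, list[int]] = {c: [] for c in CONDITIONS}
    for record in result.runs:
        inputs = record.test_samples[:n_inputs]
        for condition in CONDITIONS:
            snaps = list(record.reports[condition].snapshots.values())
            if not snaps:
                raise ValueError(
                    f"run {record.run_index} has no {condition} snapshots"
                )
            per_run[condition].append(
                saddle.count_certified(
                    snaps,
                    inputs,
                    record.encoder,
                    config.wta(),
                    config.sigma,
                    config.mu,
                    config.alpha,
                    seed + record.run_index,
                )
            )
    return SaddleReport(
        s1=int(sum(per_run["noise_on"])),
        s2=int(sum(per_run["noise_off"])),
        per_run=per_run,
        n_inputs=min(n_inputs, config.n_test),
    )


def export_raster(
    state: SynapseState,
    samples: list[Sample],
    encoder: Encoder,
    wta_cfg: WTAConfig,
    seed: int,
    path: str | Path | None = None,
) -> float:
    """Concatenated output raster over consecutive presentations.

    Presents the samples back to back (20 samples x 200 ms = one 4-s
    epoch by default), writes the raster as two-column text when a path
    is given, and returns the preference score: the fraction of output
    spikes emitted by the label neuron of the sample on screen.
    """
    rngs = plasticity._spawn_rngs(seed, 2)
    weights = state.weights
    all_times: dict[int, list[float]] = {k: [] for k in range(wta_cfg.n_outputs)}
    label_spikes = 0
    total_spikes = 0
    for j, sample in enumerate(samples):
        traces = encoder.encode(sample, rngs[0])
        rho = wta_rates(membrane_potentials(traces, weights), wta_cfg.R_total_hz)
        out = sample_output_spikes(rho, encoder.dt_ms, rngs[1])
        counts = out.counts
        total_spikes += int(counts.sum())
        label_spikes += int(counts[sample.label])
        offset = j * encoder.T_ms
        for k in range(wta_cfg.n_outputs):
            bins = np.flatnonzero(out.spike_matrix[k])
            all_times[k].extend((bins * encoder.dt_ms + offset).tolist())
    if path is not None:
        window = len(samples) * encoder.T_ms
        trains = [
            SpikeTrain(neuron=k, times_ms=np.sort(v), window_ms=window)
            for k, v in all_times.items()
        ]
        write_spike_trains(trains, path)
    return label_spikes / total_spikes if total_spikes else 0.0


# ---------------------------------------------------------------------------
# Artifact writers


def write_snapshot(state: SynapseState, path: str | Path, iteration: int = 0) -> None:
    K, I = state.shape
    header = f"# K={K} I={I} theta0={state.theta0} iteration={iteration}"
    np.savetxt(path, state.theta, delimiter=",", header=header, comments="")


def read_snapshot(path: str | Path) -> tuple[SynapseState, int]:
    with Path(path).open() as fh:
        header = fh.readline()
    fields = dict(
        part.split("=") for part in header.lstrip("#").split() if "=" in part
    )
    theta = np.loadtxt(path, delimiter=",", skiprows=1)
    state = SynapseState(theta=np.atleast_2d(theta), theta0=float(fields["theta0"]))
    return state, int(fields["iteration"])


def write_curves(result: ComparisonResult, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("iteration,accuracy,condition,seed\n")
        for record in result.runs:
            for condition, report in record.reports.items():
                for it, acc in report.curve:
                    fh.write(f"{it},{acc},{condition},{record.train_seed}\n")


def write_manifest(result: ComparisonResult, out_dir: str | Path) -> Path:
    """Write config, seeds, accuracies, curves and snapshots to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_curves(result, out / "curves.csv")
    snapshot_paths = []
    for record in result.runs:
        for condition, report in record.reports.items():
            for it, snap in report.snapshots.items():
                states = snap.layers if hasattr(snap, "layers") else [snap]
                for li, st in enumerate(states):
                    p = out / f"snapshot_r{record.run_index}_{condition}_i{it}_l{li}.csv"
                    write_snapshot(st, p, iteration=it)
                    snapshot_paths.append(str(p))
    manifest = {
        "config": result.config.to_dict(),
        "seeds": [
            {
                "run": r.run_index,
                "data_seed": r.data_seed,
                "bank_seed": r.bank_seed,
                "train_seed": r.train_seed,
                "eval_seed": r.eval_seed,
            }
            for r in result.runs
        ],
        "accuracy": {
            condition: {
                "learn": [r.learn_acc[condition] for r in result.runs],
                "test": [r.test_acc[condition] for r in result.runs],
                "learn_mean": result.mean_accuracy(condition, "learn"),
                "learn_std": result.std_accuracy(condition, "learn"),
                "test_mean": result.mean_accuracy(condition, "test"),
                "test_std": result.std_accuracy(condition, "test"),
            }
            for condition in CONDITIONS
        },
        "gain_test": result.gain("test"),
        "gain_learn": result.gain("learn"),
        "curves": str(out / "curves.csv"),
        "snapshots": snapshot_paths,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
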