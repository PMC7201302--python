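"""Synthetic 3-D Gaussian-cluster sensory environment.

Each sensory category is a Gaussian cluster of points in 3-D feature
space.  Cluster means are drawn per coordinate from a normal with mean
0.5 so clusters sit roughly inside the unit cube; each covariance is
built as ``0.04*I + 0.01*xi`` with ``xi`` an i.i.d. standard-normal
matrix, then projected to the nearest symmetric positive-semidefinite
matrix (symmetrize, clip negative eigenvalues at zero).  A dataset is a
balanced, shuffled sequence of labelled draws from these clusters.

The module also ships the delimited-text serialization used by the CLI
and, as optional extras, loaders for the raw MNIST IDX and CIFAR-10
binary formats with pixel values normalized to [0, 1].
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ClusterParams",
    "Sample",
    "DatasetFormatError",
    "sample_cluster_params",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "split_dataset",
    "load_mnist_idx",
    "load_cifar10_batch",
]


@dataclass(frozen=True)
class ClusterParams:
    """One class-conditional Gaussian: mean, PSD covariance, class label."""

    mean: np.ndarray
    covariance: np.ndarray
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))


@dataclass(frozen=True)
class Sample:
    """A feature vector plus its integer class label."""

    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "features", np.ascontiguousarray(self.features, dtype=float)
        )


class DatasetFormatError(ValueError):
    """Raised when a dataset file cannot be parsed."""


def _psd_project(mat: np.ndarray) -> np.ndarray:
    """Nearest symmetric PSD matrix: symmetrize then clip eigenvalues at 0."""
    sym = (mat + mat.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    eigval = np.clip(eigval, 0.0, None)
    return (eigvec * eigval) @ eigvec.T


def sample_cluster_params(
    n_classes: int,
    seed: int,
    *,
    n_features: int = 3,
    mean_loc: float = 0.5,
    mean_scale: float = 0.2,
    scale_is_std: bool = False,
    diag_var: float = 0.04,
    noise_scale: float = 0.01,
) -> list[ClusterParams]:
    """Draw one Gaussian cluster per class.

    Parameters
    ----------
    n_classes
        Number of clusters (= classes); must be >= 1.
    seed
        Seed for the numpy Generator; fixed seed gives identical output.
    mean_loc, mean_scale
        Per-coordinate normal for the cluster means.  ``mean_scale`` is
        read as a variance by default (std ~ 0.45, the separation at
        which an ideal observer reaches the low-80s accuracy the
        well-trained network attains); set ``scale_is_std`` to read it
        as a standard deviation instead.
    diag_var, noise_scale
        The covariance is ``diag_var*I + noise_scale*xi`` with ``xi``
        i.i.d. standard normal, projected to symmetric PSD.
    """
    if n_classes < 1:
        raise ValueError(f"n_classes must be >= 1, got {n_classes}")
    rng = np.random.default_rng(seed)
    std = mean_scale if scale_is_std else float(np.sqrt(mean_scale))
    out = []
    for label in range(n_classes):
        mean = rng.normal(mean_loc, std, size=n_features)
        xi = rng.normal(0.0, 1.0, size=(n_features, n_features))
        cov = _psd_project(diag_var * np.eye(n_features) + noise_scale * xi)
        out.append(ClusterParams(mean=mean, covariance=cov, label=label))
    return out


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor A with A @ A.T = cov (eigen route: PSD-safe)."""
    eigval, eigvec = np.linalg.eigh(cov)
    return eigvec * np.sqrt(np.clip(eigval, 0.0, None))


def generate_dataset(
    params: list[ClusterParams], n_samples: int, seed: int
) -> list[Sample]:
    """Draw a balanced, shuffled dataset from the given clusters.

    Class counts differ by at most one; when ``n_samples`` is divisible
    by the number of classes every class appears exactly
    ``n_samples / n_classes`` times.
    """
    if not params:
        raise ValueError("params must be non-empty")
    if n_samples < 0:
        raise ValueError(f"n_samples must be >= 0, got {n_samples}")
    rng = np.random.default_rng(seed)
    n_classes = len(params)
    base, extra = divmod(n_samples, n_classes)
    counts = np.full(n_classes, base, dtype=int)
    if extra:
        # the classes receiving one extra sample are chosen at random
        counts[rng.choice(n_classes, size=extra, replace=False)] += 1
    labels = rng.permutation(np.repeat(np.arange(n_classes), counts))
    factors = {p.label: _cov_factor(p.covariance) for p in params}
    means = {p.label: p.mean for p in params}
    samples = []
    for label in labels:
        z = rng.standard_normal(means[label].shape[0])
        samples.append(Sample(features=means[label] + factors[label] @ z, label=int(label)))
    return samples


def write_dataset(samples: list[Sample], path: str | Path) -> None:
    """Write samples as delimited text: comma-separated features, then label."""
    path = Path(path)
    n_features = samples[0].features.shape[0] if samples else 0
    n_classes = 1 + max((s.label for s in samples), default=-1)
    with path.open("w") as fh:
        fh.write(f"# synsample dataset n_features={n_features} n_classes={n_classes}\n")
        for s in samples:
            feats = ",".join(repr(float(v)) for v in s.features)
            fh.write(f"{feats},{s.label}\n")


def read_dataset(path: str | Path) -> list[Sample]:
    """Read a dataset written by :func:`write_dataset`.

    Raises :class:`DatasetFormatError` naming the offending line on any
    malformed row.
    """
    path = Path(path)
    samples: list[Sample] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise DatasetFormatError(
                    f"{path}:{lineno}: expected features and a label, got {line!r}"
                )
            try:
                feats = np.array([float(p) for p in parts[:-1]])
                label = int(parts[-1])
            except ValueError as exc:
                raise DatasetFormatError(f"{path}:{lineno}: {exc}") from None
            samples.append(Sample(features=feats, label=label))
    return samples


def split_dataset(
    samples: list[Sample], n_test: int, seed: int
) -> tuple[list[Sample], list[Sample]]:
    """Seeded shuffle-split into (train, test); ``n_test`` samples held out."""
    if not 0 <= n_test <= len(samples):
        raise ValueError(f"n_test must be in [0, {len(samples)}], got {n_test}")
    order = np.random.default_rng(seed).permutation(len(samples))
    test = [samples[i] for i in order[:n_test]]
    train = [samples[i] for i in order[n_test:]]
    return train, test


# ---------------------------------------------------------------------------
# Optional image-data loaders (not used by the core experiments)

_IDX_IMAGES_MAGIC = 2051
_IDX_LABELS_MAGIC = 2049


def load_mnist_idx(images_path: str | Path, labels_path: str | Path) -> list[Sample]:
    """Load raw MNIST IDX files; pixels are normalized to [0, 1]."""
    with Path(images_path).open("rb") as fh:
        magic, n, rows, cols = struct.unpack(">IIII", fh.read(16))
        if magic != _IDX_IMAGES_MAGIC:
            raise DatasetFormatError(f"{images_path}: bad IDX image magic {magic}")
        pixels = np.frombuffer(fh.read(), dtype=np.uint8).reshape(n, rows * cols)
    with Path(labels_path).open("rb") as fh:
        magic, n_lab = struct.unpack(">II", fh.read(8))
        if magic != _IDX_LABELS_MAGIC:
            raise DatasetFormatError(f"{labels_path}: bad IDX label magic {magic}")
        labels = np.frombuffer(fh.read(), dtype=np.uint8)
    if n != n_lab:
        raise DatasetFormatError("image/label counts differ")
    return [
        Sample(features=pixels[i] / 255.0, label=int(labels[i])) for i in range(n)
    ]


def load_cifar10_batch(path: str | Path) -> list[Sample]:
    """Load one CIFAR-10 binary batch (3073-byte records, pixels to [0, 1])."""
    raw = np.frombuffer(Path(path).read_bytes(), dtype=np.uint8)
    if raw.size % 3073:
        raise DatasetFormatError(f"{path}: size {raw.size} not a multiple of 3073")
    records = raw.reshape(-1, 3073)
    return [
        Sample(features=rec[1:] / 255.0, label=int(rec[0])) for rec in records
    ]
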