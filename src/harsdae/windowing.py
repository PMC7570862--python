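"""Sliding-window segmentation, instance layout, standardization and splits.

A recording is cut into fixed-length windows of ``window_size`` samples with
fractional ``overlap`` (step = round(window * (1 - overlap))); each window is
flattened channel-block-wise to a single vector

    [acc_x(n), acc_y(n), acc_z(n), gyr_x(n), gyr_y(n), gyr_z(n)]

of length M = 6n (M = 3072 for the default 512-sample window).  Instances are
standardized per feature by a z-score followed by a min-max rescale of the
z-values to [0, 1] (statistics from the fitting set only; out-of-range values
in held-out data are clipped), and the labelled set is split 6:2:2 into
train/validation/test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import SensorRecording

__all__ = [
    "Instance",
    "InstanceSet",
    "StandardizationParams",
    "SplitSet",
    "segment",
    "segment_all",
    "flatten",
    "unflatten",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
    "split",
    "select_channels",
]

META_COLUMNS = ("subject_id", "bout", "start")


def _round_half_away(v: float) -> int:
    """Round to nearest integer, ties away from zero (unlike banker's round)."""
    return int(np.floor(v + 0.5)) if v >= 0 else -int(np.floor(-v + 0.5))


@dataclass
class Instance:
    """One flattened window: feature vector, class label, provenance."""

    x: np.ndarray
    label: str
    subject_id: str = ""
    bout: int = 0
    start: int = 0


class InstanceSet:
    """An ordered labelled collection of flattened windows.

    Stores features as a dense ``(n_instances, n_features)`` array ``X``,
    labels as ``y`` and optional provenance as a DataFrame ``meta`` with
    columns ``subject_id, bout, start``.  This is the unit of resampling,
    splitting and training.
    """

    def __init__(self, X: np.ndarray, y: Sequence[str], meta: pd.DataFrame | None = None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=object)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        if meta is not None:
            meta = meta.reset_index(drop=True)
            if len(meta) != len(self.y):
                raise ValueError("meta must have one row per instance")
        self.meta = meta

    @classmethod
    def from_instances(cls, instances: Sequence[Instance]) -> "InstanceSet":
        if not instances:
            return cls(np.empty((0, 0)), [])
        X = np.vstack([inst.x for inst in instances])
        y = [inst.label for inst in instances]
        meta = pd.DataFrame(
            [(i.subject_id, i.bout, i.start) for i in instances],
            columns=list(META_COLUMNS),
        )
        return cls(X, y, meta)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def class_counts(self) -> Counter:
        return Counter(self.y.tolist())

    def take(self, idx) -> "InstanceSet":
        idx = np.asarray(idx, dtype=int)
        meta = self.meta.iloc[idx] if self.meta is not None else None
        return InstanceSet(self.X[idx], self.y[idx], meta)

    def concat(self, other: "InstanceSet") -> "InstanceSet":
        if len(other) == 0:
            return self
        if len(self) == 0:
            return other
        meta = None
        if self.meta is not None and other.meta is not None:
            meta = pd.concat([self.meta, other.meta], ignore_index=True)
        return InstanceSet(
            np.vstack([self.X, other.X]), np.concatenate([self.y, other.y]), meta
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: f0000..fNNNN feature columns + label + provenance."""
        width = max(4, len(str(max(self.n_features - 1, 0))))
        cols = [f"f{i:0{width}d}" for i in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.y
        if self.meta is not None:
            for c in META_COLUMNS:
                df[c] = self.meta[c].to_numpy()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InstanceSet":
        fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        meta = None
        if all(c in df.columns for c in META_COLUMNS):
            meta = df[list(META_COLUMNS)].copy()
        return cls(df[fcols].to_numpy(dtype=float), df["label"].to_numpy(object), meta)


def flatten(acc_window: np.ndarray, gyr_window: np.ndarray) -> np.ndarray:
    """Concatenate six equal-length channel blocks into one vector of 6n."""
    acc_window = np.atleast_2d(np.asarray(acc_window, dtype=float))
    gyr_window = np.atleast_2d(np.asarray(gyr_window, dtype=float))
    if acc_window.shape[0] != 3 or gyr_window.shape[0] != 3:
        raise ValueError("expected 3 accelerometer and 3 gyroscope channels")
    if acc_window.shape[1] != gyr_window.shape[1]:
        raise ValueError("all six channels must share the window length")
    return np.concatenate([acc_window.ravel(), gyr_window.ravel()])


def unflatten(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`flatten`: recover the (3, n) acc and gyr blocks."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size % 6 != 0:
        raise ValueError("flattened instance length must be a multiple of 6")
    n = x.size // 6
    blocks = x.reshape(6, n)
    return blocks[:3].copy(), blocks[3:].copy()


def segment(
    recording: SensorRecording, window_size: int = 512, overlap: float = 0.5
) -> list[Instance]:
    """Cut one recording into flattened windows.

    Windows start at 0, step, 2*step, ... while ``start + window_size <= N``;
    a trailing partial window is discarded and windows never span recordings.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    step = _round_half_away(window_size * (1.0 - overlap))
    if step < 1:
        raise ValueError(
            f"window_size={window_size}, overlap={overlap} give step {step} < 1"
        )
    out: list[Instance] = []
    n = recording.n_samples
    for start in range(0, n - window_size + 1, step):
        sl = slice(start, start + window_size)
        out.append(
            Instance(
                x=flatten(recording.acc[:, sl], recording.gyr[:, sl]),
                label=recording.activity,
                subject_id=recording.subject_id,
                bout=recording.bout,
                start=start,
            )
        )
    return out


def segment_all(
    recordings: Iterable[SensorRecording], window_size: int = 512, overlap: float = 0.5
) -> InstanceSet:
    """Segment every recording and pool the windows into one InstanceSet."""
    instances: list[Instance] = []
    for rec in recordings:
        instances.extend(segment(rec, window_size, overlap))
    return InstanceSet.from_instances(instances)


@dataclass
class StandardizationParams:
    """Per-feature z-score + min-max parameters learned from one set.

    ``sigma == 0`` features (constant in the fitting set) are mapped to the
    midpoint 0.5 everywhere.
    """

    mu: np.ndarray
    sigma: np.ndarray
    zmin: np.ndarray
    zmax: np.ndarray

    @property
    def n_features(self) -> int:
        return self.mu.shape[0]


def fit_standardizer(train: InstanceSet) -> StandardizationParams:
    if len(train) == 0:
        raise ValueError("cannot fit standardizer on an empty set")
    mu = train.X.mean(axis=0)
    sigma = train.X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (train.X - mu) / sigma, 0.0)
    return StandardizationParams(mu=mu, sigma=sigma, zmin=z.min(axis=0), zmax=z.max(axis=0))


def _transform(params: StandardizationParams, X: np.ndarray) -> np.ndarray:
    if X.shape[1] != params.n_features:
        raise ValueError(
            f"instance length {X.shape[1]} != standardizer feature count {params.n_features}"
        )
    span = params.zmax - params.zmin
    degenerate = (params.sigma == 0) | (span == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (X - params.mu) / np.where(params.sigma > 0, params.sigma, 1.0)
        scaled = (z - params.zmin) / np.where(span > 0, span, 1.0)
    scaled = np.clip(scaled, 0.0, 1.0)
    scaled[:, degenerate] = 0.5
    return scaled


def apply_standardizer(params: StandardizationParams, s: InstanceSet) -> InstanceSet:
    """Map every feature into [0, 1] using the fitted statistics (clipping)."""
    return InstanceSet(_transform(params, s.X), s.y, s.meta)


def invert_standardizer(params: StandardizationParams, s: InstanceSet) -> InstanceSet:
    """Undo the [0,1] mapping (exact for in-range, non-degenerate features)."""
    span = params.zmax - params.zmin
    z = s.X * span + params.zmin
    X = z * params.sigma + params.mu
    degenerate = (params.sigma == 0) | (span == 0)
    X[:, degenerate] = params.mu[degenerate]
    return InstanceSet(X, s.y, s.meta)


@dataclass
class SplitSet:
    """Disjoint train/validation/test portions of one InstanceSet."""

    train: InstanceSet
    validation: InstanceSet
    test: InstanceSet
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)


def _cut_indices(n: int, ratios, rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    perm = rng.permutation(n)
    c1 = _round_half_away(ratios[0] * n)
    c2 = _round_half_away((ratios[0] + ratios[1]) * n)
    return perm[:c1], perm[c1:c2], perm[c2:]


def split(
    s: InstanceSet,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    stratified: bool = False,
) -> SplitSet:
    """Randomly partition into train/validation/test at the given ratios.

    The permutation is drawn under ``seed``; cut points are placed at
    ``round(r1*N)`` and ``round((r1+r2)*N)``.  In stratified mode the cuts
    are applied class by class.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be three positive numbers summing to 1")
    rng = np.random.default_rng(seed)
    if stratified:
        tr_idx, va_idx, te_idx = [], [], []
        for cls in sorted(set(s.y.tolist())):
            cls_idx = np.flatnonzero(s.y == cls)
            a, b, c = _cut_indices(len(cls_idx), ratios, rng)
            tr_idx.append(cls_idx[a]); va_idx.append(cls_idx[b]); te_idx.append(cls_idx[c])
        cat = lambda parts: np.concatenate(parts) if parts else np.array([], dtype=int)
        tr, va, te = cat(tr_idx), cat(va_idx), cat(te_idx)
    else:
        tr, va, te = _cut_indices(len(s), ratios, rng)
    return SplitSet(s.take(tr), s.take(va), s.take(te), ratios)


def select_channels(s: InstanceSet, channels: str = "acc+gyr") -> InstanceSet:
    """Restrict instances to the accelerometer or gyroscope half.

    ``channels`` is ``"acc"`` (first 3n features), ``"gyr"`` (last 3n) or
    ``"acc+gyr"`` (all 6n, unchanged).
    """
    if channels == "acc+gyr":
        return s
    if s.n_features % 6 != 0:
        raise ValueError("instance length must be a multiple of 6")
    half = s.n_features // 2
    if channels == "acc":
        return InstanceSet(s.X[:, :half], s.y, s.meta)
    if channels == "gyr":
        return InstanceSet(s.X[:, half:], s.y, s.meta)
    raise ValueError("channels must be one of 'acc', 'gyr', 'acc+gyr'")
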