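"""Class rebalancing: random oversampling, random undersampling and SMOTE.

Transitional activities last seconds while sustained activities last minutes,
so their window counts differ by roughly 5:1; all three methods equalize the
per-class counts.  Oversampling duplicates minority instances uniformly with
replacement; undersampling keeps a uniform without-replacement subset of each
majority class; SMOTE synthesizes minority points by interpolating between an
instance and one of its k nearest same-class neighbours (Euclidean):

    x_new = x + r * (x_n - x),   r ~ U[0, 1)

with one shared r per synthetic point.  A "literal" variant that instead adds
r times the scalar Euclidean distance ||x - x_n|| to every component is kept
behind a flag for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .windowing import InstanceSet

__all__ = [
    "ResamplePlan",
    "random_oversample",
    "random_undersample",
    "smote",
    "resample",
]


@dataclass
class ResamplePlan:
    """How to equalize class counts.

    ``target`` defaults to the majority count for oversample/smote and the
    minority count for undersample.  ``smote_k`` is capped at class size - 1.
    """

    method: Literal["none", "oversample", "undersample", "smote"] = "oversample"
    target: int | None = None
    smote_k: int = 5
    seed: int = 0
    literal_distance: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("none", "oversample", "undersample", "smote"):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.target is not None and self.target < 1:
            raise ValueError("target count must be >= 1")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


def _class_indices(s: InstanceSet) -> dict[str, np.ndarray]:
    return {cls: np.flatnonzero(s.y == cls) for cls in sorted(set(s.y.tolist()))}


def random_oversample(s: InstanceSet, plan: ResamplePlan) -> InstanceSet:
    """Grow every class to the target by uniform duplication with replacement.

    All original instances are retained; only classes below the target gain
    copies.  Already-balanced input at the target is returned unchanged.
    """
    by_class = _class_indices(s)
    for cls, idx in by_class.items():
        if len(idx) == 0:
            raise ValueError(f"class {cls!r} is empty; cannot oversample")
    target = plan.target or max(len(v) for v in by_class.values())
    rng = np.random.default_rng(plan.seed)
    keep = [np.arange(len(s))]
    for cls in sorted(by_class):
        idx = by_class[cls]
        need = target - len(idx)
        if need > 0:
            keep.append(rng.choice(idx, size=need, replace=True))
    idx_all = np.concatenate(keep)
    if len(idx_all) == len(s):
        return s
    return s.take(idx_all)


def random_undersample(s: InstanceSet, plan: ResamplePlan) -> InstanceSet:
    """Shrink every class to the target by uniform sampling without replacement."""
    by_class = _class_indices(s)
    for cls, idx in by_class.items():
        if len(idx) == 0:
            raise ValueError(f"class {cls!r} is empty; cannot undersample")
    target = plan.target or min(len(v) for v in by_class.values())
    rng = np.random.default_rng(plan.seed)
    keep = []
    for cls in sorted(by_class):
        idx = by_class[cls]
        if target > len(idx):
            raise ValueError(
                f"class {cls!r} has {len(idx)} instances, fewer than target {target}"
            )
        keep.append(
            idx if len(idx) == target else rng.choice(idx, size=target, replace=False)
        )
    idx_all = np.concatenate(keep)
    if len(idx_all) == len(s):
        return s
    return s.take(idx_all)


def smote(s: InstanceSet, plan: ResamplePlan) -> InstanceSet:
    """Grow every class to the target with synthetic interpolated instances.

    For each needed point: a class instance x is drawn uniformly, a neighbour
    x_n uniformly among its k nearest same-class neighbours, and the emitted
    point is x + r (x_n - x) with a single r ~ U[0,1), so every synthetic
    point lies on the segment between its two parents.  Originals are always
    retained; classes of size 1 that need growth are an error (no neighbour).
    """
    by_class = _class_indices(s)
    target = plan.target or max(len(v) for v in by_class.values())
    rng = np.random.default_rng(plan.seed)

    out = s
    new_X, new_y, new_meta_rows = [], [], []
    for cls in sorted(by_class):
        idx = by_class[cls]
        need = target - len(idx)
        if need <= 0:
            continue
        if len(idx) < 2:
            raise ValueError(
                f"class {cls!r} has a single instance; SMOTE needs a neighbour"
            )
        Xc = s.X[idx]
        k = min(plan.smote_k, len(idx) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        # first neighbour is the point itself; drop it
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(idx), size=need)
        pick = rng.integers(0, k, size=need)
        r = rng.random(size=need)
        x = Xc[base]
        xn = Xc[neigh[base, pick]]
        if plan.literal_distance:
            d = np.linalg.norm(x - xn, axis=1)
            synth = x + (r * d)[:, None]
        else:
            synth = x + r[:, None] * (xn - x)
        new_X.append(synth)
        new_y.extend([cls] * need)
        if s.meta is not None:
            new_meta_rows.append(s.meta.iloc[idx[base]])
    if not new_X:
        return out
    meta = None
    if s.meta is not None:
        import pandas as pd

        meta = pd.concat(new_meta_rows, ignore_index=True)
    addition = InstanceSet(np.vstack(new_X), new_y, meta)
    return out.concat(addition)


def resample(s: InstanceSet, plan: ResamplePlan) -> InstanceSet:
    """Dispatch on ``plan.method`` (``"none"`` returns the input unchanged)."""
    if plan.method == "none":
        return s
    fn = {
        "oversample": random_oversample,
        "undersample": random_undersample,
        "smote": smote,
    }[plan.method]
    return fn(s, plan)
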