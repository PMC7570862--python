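"""End-to-end orchestration: simulate -> segment -> rebalance -> standardize
-> split -> pretrain -> fine-tune -> evaluate.

The default ``mode="paper"`` keeps the reference stage order (resample and
standardize the whole pooled instance set, then split 6:2:2), which lets
resampled copies and fitting statistics cross the split boundary;
``mode="leakfree"`` splits first and resamples/standardizes on the training
portion only.  Every run emits a manifest recording seeds, stage order and
per-stage class counts, from which all artifacts are recomputable.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import MetricsReport
from .model import SdaeClassifier, SdaeResults
from .rebalance import ResamplePlan, resample
from .simulate import ACTIVITIES, StudyProtocol, default_activity_models, generate_study
from .windowing import (
    InstanceSet,
    apply_standardizer,
    fit_standardizer,
    segment_all,
    select_channels,
    split,
)

__all__ = ["RunConfig", "RunResult", "run", "sweep"]

SWEEP_AXES = (
    "iterations",
    "pretrain_lr",
    "finetune_lr",
    "hidden_layers",
    "resample_method",
    "channels",
)


@dataclass
class RunConfig:
    """Full configuration of one end-to-end run (YAML-serializable).

    Defaults follow the reference setup: 512-sample windows with 50% overlap,
    random oversampling, 6:2:2 split, a 2x500 sigmoid stack with denoising
    factor 0.5, pretraining rate 1e-7, fine-tuning rate 0.01, 200 iterations,
    batch size 64.
    """

    # study protocol
    n_subjects: int = 10
    continuous_bout_s: float = 300.0
    transitional_hold_s: float = 15.0
    continuous_repeats: int = 1
    transitional_repeats: int = 2
    sampling_rate: float = 102.4
    # segmentation
    window_size: int = 512
    overlap: float = 0.5
    channels: str = "acc+gyr"
    # rebalancing
    resample_method: str = "oversample"
    smote_k: int = 5
    # split
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratified: bool = False
    # training
    hidden_sizes: tuple[int, ...] = (500, 500)
    corruption: float = 0.5
    pretrain_lr: float = 1e-7
    finetune_lr: float = 0.01
    iterations: int = 200
    pretrain_epochs: int | None = None
    finetune_epochs: int | None = None
    batch_size: int = 64
    dtype: str = "float64"
    # evaluation / bookkeeping
    averaging: str = "micro"
    mode: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "leakfree"):
            raise ValueError("mode must be 'paper' or 'leakfree'")
        self.ratios = tuple(float(r) for r in self.ratios)
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["ratios"] = list(self.ratios)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d


@dataclass
class RunResult:
    """Artifacts of one run, kept in memory; ``save`` writes them to disk."""

    config: RunConfig
    results: SdaeResults
    report: MetricsReport
    manifest: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.save(out / "model.npz")
        self.report.to_csv(out / "metrics_per_class.csv", out / "confusion.csv")
        self.results.traces_frame().to_csv(out / "traces.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2)
        self.config.to_yaml(out / "config.yaml")


def _counts(s: InstanceSet) -> dict[str, int]:
    return {k: int(v) for k, v in sorted(s.class_counts.items())}


def prepare_instances(config: RunConfig, log=None) -> tuple:
    """Simulate, segment, rebalance, standardize and split per the config.

    Returns ``(train, validation, test, stage_counts)`` with all three sets
    standardized to [0, 1].
    """
    stage_counts: dict[str, dict[str, int]] = {}

    protocol = StudyProtocol(
        n_subjects=config.n_subjects,
        continuous_bout_s=config.continuous_bout_s,
        transitional_hold_s=config.transitional_hold_s,
        continuous_repeats=config.continuous_repeats,
        transitional_repeats=config.transitional_repeats,
        sampling_rate=config.sampling_rate,
        seed=config.seed,
    )
    recordings = generate_study(protocol, default_activity_models())
    instances = segment_all(recordings, config.window_size, config.overlap)
    instances = select_channels(instances, config.channels)
    stage_counts["after_segmentation"] = _counts(instances)
    if log:
        log(f"segmented {len(instances)} instances of length {instances.n_features}")

    plan = ResamplePlan(
        method=config.resample_method, smote_k=config.smote_k, seed=config.seed
    )
    if config.mode == "paper":
        balanced = resample(instances, plan)
        stage_counts["after_resampling"] = _counts(balanced)
        params = fit_standardizer(balanced)
        balanced = apply_standardizer(params, balanced)
        parts = split(balanced, config.ratios, seed=config.seed,
                      stratified=config.stratified)
        train, val, test = parts.train, parts.validation, parts.test
    else:
        parts = split(instances, config.ratios, seed=config.seed,
                      stratified=config.stratified)
        train = resample(parts.train, plan)
        stage_counts["after_resampling_train_only"] = _counts(train)
        params = fit_standardizer(train)
        train = apply_standardizer(params, train)
        val = apply_standardizer(params, parts.validation)
        test = apply_standardizer(params, parts.test)
    for name, part in (("train", train), ("validation", val), ("test", test)):
        stage_counts[f"split_{name}"] = _counts(part)
    if log:
        log(f"split sizes: {len(train)}/{len(val)}/{len(test)} ({config.mode} mode)")
    return train, val, test, stage_counts


def run(config: RunConfig, out_dir=None, log=None) -> RunResult:
    """Execute the whole pipeline; optionally persist artifacts to out_dir."""
    train, val, test, stage_counts = prepare_instances(config, log=log)

    clf = SdaeClassifier.from_instance_sets(
        train,
        validation=val,
        classes=[a for a in ACTIVITIES if a in set(train.y)],
        hidden_sizes=config.hidden_sizes,
        corruption=config.corruption,
    )
    results = clf.fit(
        pretrain_lr=config.pretrain_lr,
        finetune_lr=config.finetune_lr,
        iterations=config.iterations,
        pretrain_epochs=config.pretrain_epochs,
        finetune_epochs=config.finetune_epochs,
        batch_size=config.batch_size,
        seed=config.seed,
        dtype=config.dtype,
    )
    if log:
        log("training complete; evaluating on the test portion")
    report = results.evaluate(test, mode=config.averaging)

    manifest = {
        "harsdae_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config": config.as_dict(),
        "stage_order": (
            ["simulate", "segment", "resample", "standardize", "split",
             "pretrain", "fine_tune", "evaluate"]
            if config.mode == "paper"
            else ["simulate", "segment", "split", "resample(train)",
                  "standardize(train-fit)", "pretrain", "fine_tune", "evaluate"]
        ),
        "stage_counts": stage_counts,
        "overall": {
            k: (float(v) if k != "mode" else v)
            for k, v in report.overall.items()
        },
    }
    result = RunResult(config=config, results=results, report=report, manifest=manifest)
    if out_dir is not None:
        result.save(out_dir)
    return result


def _apply_axis(config: RunConfig, axis: str, value) -> RunConfig:
    d = config.as_dict()
    if axis == "hidden_layers":
        width = config.hidden_sizes[0] if config.hidden_sizes else 500
        d["hidden_sizes"] = [width] * int(value)
    elif axis in ("iterations",):
        d[axis] = int(value)
    elif axis in ("pretrain_lr", "finetune_lr"):
        d[axis] = float(value)
    elif axis in ("resample_method", "channels"):
        d[axis] = str(value)
    else:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {SWEEP_AXES}")
    return RunConfig(**d)


def sweep(config: RunConfig, axis: str, values, out_dir=None, log=None) -> pd.DataFrame:
    """One run per axis value with all other settings (and seeds) shared.

    Returns a long-format table with the overall metrics of each run.
    """
    rows = []
    for value in values:
        cfg = _apply_axis(config, axis, value)
        if log:
            log(f"sweep {axis}={value}")
        res = run(cfg, log=log)
        ov = res.report.overall
        rows.append(
            {
                "axis": axis,
                "value": value,
                "accuracy": float(ov["accuracy"]),
                "precision": float(ov["precision"]),
                "recall": float(ov["recall"]),
                "f1": float(ov["f1"]),
                "hidden_sizes": "x".join(map(str, cfg.hidden_sizes)),
                "n_test": res.report.cm.total,
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"sweep_{axis}.csv", index=False)
    return table
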