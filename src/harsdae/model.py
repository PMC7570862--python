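"""Model/Results front door for the stacked denoising autoencoder classifier.

``SdaeClassifier`` is constructed from data (feature matrix + labels, or
:class:`~harsdae.windowing.InstanceSet` objects); ``fit()`` runs greedy
layer-wise pretraining followed by supervised fine-tuning and returns an
``SdaeResults`` carrying the trained network, the loss traces, prediction
methods and a ``summary()`` table, in the spirit of statsmodels' model /
results split.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import sdae
from .metrics import MetricsReport, evaluate
from .windowing import InstanceSet

__all__ = ["SdaeClassifier", "SdaeResults"]


class SdaeClassifier:
    """A stacked-denoising-autoencoder activity classifier bound to data.

    Parameters
    ----------
    X, y
        Training features (rows in [0, 1]) and string labels.
    validation
        Optional ``(X_val, y_val)`` pair monitored during fine-tuning.
    classes
        Class ordering for the softmax head; defaults to the sorted label set.
    hidden_sizes, corruption
        Architecture: sigmoid hidden layer widths and the masking-noise
        probability used during pretraining.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence[str],
        validation: tuple[np.ndarray, Sequence[str]] | None = None,
        classes: Sequence[str] | None = None,
        hidden_sizes: Sequence[int] = (500, 500),
        corruption: float = 0.5,
    ):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=object)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        self.validation = validation
        self.classes = list(classes) if classes is not None else sorted(set(self.y))
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.corruption = float(corruption)

    @classmethod
    def from_instance_sets(
        cls,
        train: InstanceSet,
        validation: InstanceSet | None = None,
        classes: Sequence[str] | None = None,
        hidden_sizes: Sequence[int] = (500, 500),
        corruption: float = 0.5,
    ) -> "SdaeClassifier":
        val = (validation.X, validation.y) if validation is not None else None
        return cls(
            train.X, train.y, validation=val, classes=classes,
            hidden_sizes=hidden_sizes, corruption=corruption,
        )

    def fit(
        self,
        pretrain_lr: float = 1e-7,
        finetune_lr: float = 0.01,
        iterations: int = 200,
        pretrain_epochs: int | None = None,
        finetune_epochs: int | None = None,
        batch_size: int = 64,
        seed: int = 0,
        dtype: str = "float64",
        restore_best: bool = True,
    ) -> "SdaeResults":
        """Pretrain the stack greedily, then fine-tune with a softmax head.

        With a validation set attached, the epoch with the best validation
        accuracy supplies the final parameters (its model-selection role).
        """
        config = sdae.TrainConfig(
            hidden_sizes=self.hidden_sizes,
            corruption=self.corruption,
            pretrain_lr=pretrain_lr,
            finetune_lr=finetune_lr,
            iterations=iterations,
            pretrain_epochs=pretrain_epochs,
            finetune_epochs=finetune_epochs,
            batch_size=batch_size,
            seed=seed,
            dtype=dtype,
            restore_best=restore_best,
        )
        model, pretrain_traces = sdae.pretrain_stack(self.X, config)
        X_val = y_val = None
        if self.validation is not None:
            X_val, y_val = self.validation
        model, history = sdae.fine_tune(
            model, self.X, self.y, self.classes, config, X_val=X_val, y_val=y_val
        )
        return SdaeResults(self, model, config, pretrain_traces, history)


class SdaeResults:
    """Fitted network plus training diagnostics."""

    def __init__(self, classifier, model, config, pretrain_traces, history):
        self.classifier = classifier
        self.model = model
        self.config = config
        self.pretrain_traces = pretrain_traces
        self.history = history

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    def predict(self, X) -> np.ndarray:
        X = X.X if isinstance(X, InstanceSet) else X
        labels, _ = sdae.predict(self.model, np.asarray(X, dtype=self.config.dtype))
        return labels

    def predict_proba(self, X) -> np.ndarray:
        X = X.X if isinstance(X, InstanceSet) else X
        _, proba = sdae.predict(self.model, np.asarray(X, dtype=self.config.dtype))
        return proba

    def evaluate(self, X, y=None, mode: str = "micro") -> MetricsReport:
        """Score a labelled set and return the full metrics report."""
        if isinstance(X, InstanceSet):
            X, y = X.X, X.y
        if y is None:
            raise ValueError("labels are required to evaluate")
        return evaluate(y, self.predict(X), self.classes, mode=mode)

    def save(self, path) -> None:
        sdae.save_model(self.model, self.config, path)

    def summary(self) -> str:
        """Human-readable account of architecture, training and traces."""
        m = self.model
        shapes = " -> ".join(
            [str(m.layers[0].d_in)] + [str(l.d_hidden) for l in m.layers]
            + [str(len(m.classes))]
        ) if m.layers else "(no layers)"
        lines = [
            "Stacked Denoising Autoencoder classifier",
            "=" * 44,
            f"architecture:        {shapes}",
            f"denoising factor:    {self.config.corruption}",
            f"pretrain lr/epochs:  {self.config.pretrain_lr} / {self.config.n_pretrain_epochs}",
            f"finetune lr/epochs:  {self.config.finetune_lr} / {self.config.n_finetune_epochs}",
            f"batch size / seed:   {self.config.batch_size} / {self.config.seed}",
            f"training instances:  {self.classifier.X.shape[0]}",
        ]
        for l, trace in enumerate(self.pretrain_traces):
            lines.append(
                f"layer {l} recon loss:  {trace[0]:.4f} -> {trace[-1]:.4f}"
                f"  ({len(trace)} epochs)"
            )
        tl = self.history["train_loss"]
        lines.append(f"finetune loss:       {tl[0]:.4f} -> {tl[-1]:.4f}  ({len(tl)} epochs)")
        if "val_accuracy" in self.history:
            va = self.history["val_accuracy"]
            if "best_epoch" in self.history:
                be = self.history["best_epoch"]
                lines.append(
                    f"validation accuracy: {max(va) * 100.0:.2f}% "
                    f"(best epoch {be}, parameters restored)"
                )
            else:
                lines.append(f"validation accuracy: {va[-1] * 100.0:.2f}% (final epoch)")
        return "\n".join(lines)

    def traces_frame(self) -> pd.DataFrame:
        """Long-format per-epoch traces (phase, layer, epoch, value)."""
        rows = []
        for l, trace in enumerate(self.pretrain_traces):
            for e, v in enumerate(trace):
                rows.append(("pretrain_loss", l, e, v))
        for e, v in enumerate(self.history["train_loss"]):
            rows.append(("finetune_loss", -1, e, v))
        for e, v in enumerate(self.history.get("val_accuracy", [])):
            rows.append(("val_accuracy", -1, e, v))
        return pd.DataFrame(rows, columns=["phase", "layer", "epoch", "value"])
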