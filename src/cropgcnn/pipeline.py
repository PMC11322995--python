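"""Training, evaluation and the per-color-space comparison experiment.

The comparison protocol: split the dataset once, then for every requested
color space convert and renormalize the three splits, build a fresh GCNN
from the same seed, train it, and evaluate on the held-out test set.
Rows therefore differ only in the input representation — the variable of
interest.  The execution-time column is recorded for parity with the
published table layout but is hardware-dependent and never asserted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score

from . import colorspace
from .colorspace import ImageBatch, convert_color, normalize_channels
from .data import LabeledImageSet, SplitConfig, split
from .model import GCNNConfig, GCNNModel, MultiBranchModel, build_gcnn, build_multibranch
from .nn import cross_entropy, fit_network, predict_proba

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "ExperimentTable",
    "TrainingHistory",
    "compute_metrics",
    "train",
    "evaluate",
    "prepare_space_inputs",
    "run_colorspace_comparison",
    "run_multibranch",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults: adam, 1e-3, 10 x 32)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size >= 1 and learning_rate > 0 required")


@dataclass
class MetricsReport:
    """Evaluation metrics for one model on one test set.

    accuracy and macro_f1 are fractions in [0, 1]; cross_entropy is the
    mean per-sample loss in nats; confusion is the K x K count matrix
    with true classes on rows.
    """

    accuracy: float
    cross_entropy: float
    macro_f1: float
    per_class_f1: np.ndarray
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "cross_entropy": self.cross_entropy,
            "macro_f1": self.macro_f1,
            "per_class_f1": [float(v) for v in self.per_class_f1],
            "confusion": self.confusion.tolist(),
        }


@dataclass
class ExperimentTable:
    """One row per color space: the machine-readable comparison table."""

    rows: list[dict] = field(default_factory=list)
    columns = ("color_space", "execution_time_s", "accuracy", "cross_entropy", "macro_f1")

    def add_row(self, color_space, execution_time_s, report: MetricsReport):
        if any(r["color_space"] == color_space for r in self.rows):
            raise ValueError(f"duplicate color space row {color_space!r}")
        self.rows.append(
            {
                "color_space": color_space,
                "execution_time_s": execution_time_s,
                "accuracy": report.accuracy,
                "cross_entropy": report.cross_entropy,
                "macro_f1": report.macro_f1,
            }
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=list(self.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


#: Per-epoch training curves, the machine twin of loss/accuracy plots.
TrainingHistory = list  # list of dicts: train_loss/train_accuracy/val_loss/val_accuracy


def compute_metrics(true_labels: np.ndarray, probs: np.ndarray) -> MetricsReport:
    """Accuracy, mean cross-entropy (nats), macro-F1 and confusion matrix.

    ``probs`` rows must sum to 1 within 1e-4.  Macro-F1 averages the
    per-class F1 over all K classes, scoring 0 for a class with neither
    support nor predictions.
    """
    true_labels = np.asarray(true_labels)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or len(true_labels) != len(probs):
        raise ValueError(
            f"need labels (n,) and probs (n, K); got {true_labels.shape} "
            f"and {probs.shape}"
        )
    if len(probs) == 0:
        raise ValueError("empty input")
    K = probs.shape[1]
    if true_labels.min() < 0 or true_labels.max() >= K:
        raise ValueError("labels outside [0, K)")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-4:
        raise ValueError("probability rows must sum to 1 within 1e-4")
    pred = probs.argmax(axis=1)
    labels = np.arange(K)
    conf = confusion_matrix(true_labels, pred, labels=labels)
    per_class = f1_score(
        true_labels, pred, labels=labels, average=None, zero_division=0.0
    )
    ce = float(
        -np.log(
            np.clip(probs[np.arange(len(true_labels)), true_labels], 1e-12, 1.0)
        ).mean()
    )
    return MetricsReport(
        accuracy=float(np.trace(conf) / conf.sum()),
        cross_entropy=ce,
        macro_f1=float(per_class.mean()),
        per_class_f1=per_class,
        confusion=conf,
    )


def _as_array(data) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept a LabeledImageSet or a bare (pixels) batch."""
    if isinstance(data, LabeledImageSet):
        return data.images.pixels, data.labels
    if isinstance(data, ImageBatch):
        return data.pixels, None
    return np.asarray(data), None


def train(model, train_data, val_data=None, cfg: TrainConfig | None = None):
    """Fit ``model`` by mini-batch cross-entropy descent.

    ``train_data``/``val_data`` are LabeledImageSets whose pixel batches
    are already in the representation the model expects (converted and
    normalized, or raw RGB for the multi-branch model).  Returns
    ``(model, history)``.
    """
    cfg = cfg or TrainConfig()
    X, y = _as_array(train_data)
    if y is None:
        raise ValueError("train_data must carry labels")
    n_classes = model.cfg.n_classes
    if y.max() >= n_classes:
        raise ValueError(
            f"labels reach {y.max()} but the model has {n_classes} classes"
        )
    X_val = y_val = None
    if val_data is not None:
        X_val, y_val = _as_array(val_data)
    history = fit_network(
        model,
        X,
        y,
        X_val,
        y_val,
        optimizer=cfg.optimizer,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
        early_stop_patience=cfg.early_stop_patience,
    )
    return model, history


def evaluate(model, test_data, batch_size: int = 256) -> MetricsReport:
    """Inference-mode forward pass followed by :func:`compute_metrics`."""
    X, y = _as_array(test_data)
    if y is None:
        raise ValueError("test_data must carry labels")
    probs = predict_proba(model, X, batch_size=batch_size)
    return compute_metrics(y, probs)


def prepare_space_inputs(ds: LabeledImageSet, space: str) -> LabeledImageSet:
    """Convert an RGB dataset into ``space`` and normalize to [0, 1]."""
    batch = normalize_channels(convert_color(ds.images, space))
    return LabeledImageSet(batch, ds.labels, list(ds.class_names))


def run_colorspace_comparison(
    ds: LabeledImageSet,
    spaces=colorspace.COLOR_SPACES,
    split_cfg: SplitConfig | None = None,
    train_cfg: TrainConfig | None = None,
    model_cfg: GCNNConfig | None = None,
    out_csv=None,
) -> tuple[ExperimentTable, dict]:
    """Train one fresh single-branch GCNN per color space and tabulate.

    All spaces share the dataset split and the model/training seeds, so
    table rows differ only by input representation.  Returns the table
    and a per-space dict of training histories.
    """
    if ds.n_classes < 2:
        raise ValueError("comparison requires at least 2 classes")
    spaces = tuple(spaces)
    if len(set(spaces)) != len(spaces):
        raise ValueError(f"duplicate spaces requested: {spaces}")
    split_cfg = split_cfg or SplitConfig()
    train_cfg = train_cfg or TrainConfig()
    model_cfg = model_cfg or GCNNConfig(
        input_size=(ds.images.pixels.shape[1], ds.images.pixels.shape[2]),
        n_classes=ds.n_classes,
    )
    tr, va, te = split(ds, split_cfg)
    table = ExperimentTable()
    histories: dict[str, TrainingHistory] = {}
    for space in spaces:
        t0 = time.perf_counter()
        model = build_gcnn(model_cfg)
        _, hist = train(
            model,
            prepare_space_inputs(tr, space),
            prepare_space_inputs(va, space),
            train_cfg,
        )
        report = evaluate(model, prepare_space_inputs(te, space))
        table.add_row(space, time.perf_counter() - t0, report)
        histories[space] = hist
    if out_csv is not None:
        table.to_csv(out_csv)
    return table, histories


def run_multibranch(
    ds: LabeledImageSet,
    split_cfg: SplitConfig | None = None,
    train_cfg: TrainConfig | None = None,
    model_cfg: GCNNConfig | None = None,
    spaces=colorspace.EXPANSION_SPACES,
    fusion: str = "concat_features",
) -> tuple[MetricsReport, TrainingHistory]:
    """Train the fused multi-color-space model end-to-end on RGB input."""
    split_cfg = split_cfg or SplitConfig()
    train_cfg = train_cfg or TrainConfig()
    model_cfg = model_cfg or GCNNConfig(
        input_size=(ds.images.pixels.shape[1], ds.images.pixels.shape[2]),
        n_classes=ds.n_classes,
    )
    tr, va, te = split(ds, split_cfg)
    model = build_multibranch(model_cfg, spaces=spaces, fusion=fusion)
    _, hist = train(model, tr, va, train_cfg)
    return evaluate(model, te), hist
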