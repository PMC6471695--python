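"""Multi-class evaluation: confusion matrices, agreement, per-class
diagnostics, voxel accuracy, the resolution-boundary scan, and the
cross-model evaluation grid.

Percentages are rounded half-up to one decimal (and formatted with two
decimals for report parity, e.g. ``19/26 -> 73.1 -> "73.10%"``).
Undefined ratios (zero denominators) surface as NaN / ``"NA"``, never
as 0 or 100.

Per-class sensitivity, specificity, PPV and NPV follow the partial
class membership formulation: memberships may be soft (rows of class
weights summing to 1), in which case the TP/FP/TN/FN counts are the
expected co-memberships; for crisp one-hot labels they reduce exactly
to one-vs-rest counting on the confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .preprocess import ResolutionClass3
from .simulate import SimulationSpec, make_synthetic_model, simulate_map
from .preprocess import minmax_normalize

__all__ = [
    "CLASS_NAMES",
    "ConfusionMatrix",
    "MetricUndefinedError",
    "confusion_matrix",
    "combined_agreement",
    "class_metrics",
    "partial_class_metrics",
    "categorical_accuracy",
    "BoundaryScanResult",
    "boundary_scan",
    "default_resolution_grid",
    "cross_evaluate",
    "round_percent",
    "format_percent",
]

CLASS_NAMES = ("high", "medium", "low")


class MetricUndefinedError(ZeroDivisionError):
    """A requested metric has an empty denominator."""


def round_percent(value: float) -> float:
    """Round a percentage half-up to one decimal (NaN passes through)."""
    if np.isnan(value):
        return float("nan")
    return float(Decimal(repr(float(value))).quantize(Decimal("0.1"), ROUND_HALF_UP))


def format_percent(value: float) -> str:
    """Report formatting: one-decimal value printed with two decimals."""
    if np.isnan(value):
        return "NA"
    return f"{round_percent(value):.2f}%"


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true (published) class, columns = predicted.

    Class order is high, medium, low (codes 0, 1, 2).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=CLASS_NAMES, columns=CLASS_NAMES)


def confusion_matrix(true, pred) -> ConfusionMatrix:
    """Count true-vs-predicted class pairs over a map collection."""
    true = [int(t) for t in true]
    pred = [int(p) for p in pred]
    if len(true) != len(pred):
        raise ValueError(f"length mismatch: {len(true)} true vs {len(pred)} predicted")
    if not true:
        return ConfusionMatrix(np.zeros((3, 3), dtype=np.int64))
    return ConfusionMatrix(_sk_confusion(true, pred, labels=[0, 1, 2]))


def combined_agreement(cm: ConfusionMatrix) -> float:
    """Percentage of maps on the diagonal, one-decimal rounding."""
    if cm.total == 0:
        raise MetricUndefinedError("combined agreement undefined for empty matrix")
    return round_percent(100.0 * np.trace(cm.counts) / cm.total)


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return float("nan")
    return round_percent(100.0 * num / den)


def partial_class_metrics(
    true_membership: np.ndarray, pred_membership: np.ndarray
) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV from (soft) class memberships.

    ``true_membership`` and ``pred_membership`` are (N, K) arrays of
    class weights per sample (rows may be one-hot).  Expected counts:
    ``TP_k = sum_i t_ik p_ik``, ``FP_k = sum_i (1 - t_ik) p_ik``, etc.
    """
    t = np.asarray(true_membership, dtype=float)
    p = np.asarray(pred_membership, dtype=float)
    if t.shape != p.shape or t.ndim != 2:
        raise ValueError("membership arrays must share an (N, K) shape")
    tp = (t * p).sum(axis=0)
    fp = ((1 - t) * p).sum(axis=0)
    fn = (t * (1 - p)).sum(axis=0)
    tn = ((1 - t) * (1 - p)).sum(axis=0)
    names = CLASS_NAMES if t.shape[1] == 3 else [str(k) for k in range(t.shape[1])]
    rows = {
        "sensitivity": [_ratio(tp[k], tp[k] + fn[k]) for k in range(t.shape[1])],
        "specificity": [_ratio(tn[k], tn[k] + fp[k]) for k in range(t.shape[1])],
        "ppv": [_ratio(tp[k], tp[k] + fp[k]) for k in range(t.shape[1])],
        "npv": [_ratio(tn[k], tn[k] + fn[k]) for k in range(t.shape[1])],
    }
    return pd.DataFrame(rows, index=names)


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class diagnostics from a crisp confusion matrix.

    Expands the matrix back to one-hot memberships and applies the
    partial-membership formulas, which reduce to one-vs-rest counts.
    """
    true_rows, pred_rows = [], []
    eye = np.eye(3)
    for i in range(3):
        for j in range(3):
            n = int(cm.counts[i, j])
            if n:
                true_rows.append(np.tile(eye[i], (n, 1)))
                pred_rows.append(np.tile(eye[j], (n, 1)))
    if not true_rows:
        raise MetricUndefinedError("class metrics undefined for empty matrix")
    return partial_class_metrics(np.vstack(true_rows), np.vstack(pred_rows))


def categorical_accuracy(
    pred_labels: np.ndarray, true_labels: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Fraction of (in-mask) voxels whose predicted class equals the label."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    if mask is None:
        mask = np.ones(pred.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pred.shape:
            raise ValueError("mask shape must match label shape")
    n = int(mask.sum())
    if n == 0:
        raise MetricUndefinedError("accuracy undefined over an empty mask")
    return float((pred[mask] == true[mask]).sum() / n)


def default_resolution_grid() -> np.ndarray:
    """1.5 to 15.0 Angstrom in 0.5 steps (28 resolutions)."""
    return np.round(np.arange(1.5, 15.0 + 1e-9, 0.5), 1)


@dataclass
class BoundaryScanResult:
    """Predicted class per simulated resolution, plus the change points.

    ``boundaries`` lists each resolution at which the predicted class
    first differs from the previous grid point's class.
    """

    resolutions: np.ndarray
    classes: list[ResolutionClass3]
    boundaries: list[float] = field(init=False)

    def __post_init__(self) -> None:
        self.resolutions = np.asarray(self.resolutions, dtype=float)
        if np.any(np.diff(self.resolutions) <= 0):
            raise ValueError("resolutions must be strictly increasing")
        self.boundaries = [
            float(r)
            for r, prev, cur in zip(
                self.resolutions[1:], self.classes[:-1], self.classes[1:]
            )
            if cur != prev
        ]


def net_classifier(net, batch_size: int = 8):
    """Wrap a trained global network as a (map, resolution) -> class callable."""
    from .models import predict

    def classify(density_map, resolution):
        del resolution  # the network sees only the map
        return ResolutionClass3(int(predict(net, density_map.data[None], batch_size)[0]))

    return classify


def boundary_scan(
    model,
    resolutions: np.ndarray | None = None,
    structure_source=None,
    box: int = 64,
    voxel_size: float = 1.0,
    n_atoms: int = 300,
    seed: int = 0,
) -> BoundaryScanResult:
    """Locate the resolutions where a classifier switches class.

    Simulates one normalized map per grid resolution — a distinct
    random structure each, unless ``structure_source(index, resolution)``
    supplies models — and records the predicted class.  ``model`` is
    either a trained global network or a callable
    ``(density_map, resolution) -> class``.
    """
    if resolutions is None:
        resolutions = default_resolution_grid()
    resolutions = np.asarray(resolutions, dtype=float)
    if np.any(np.diff(resolutions) <= 0):
        raise ValueError("resolutions must be strictly increasing")
    classify = model if callable(model) else net_classifier(model)
    classes = []
    import warnings

    for i, r in enumerate(resolutions):
        if structure_source is not None:
            structure = structure_source(i, r)
        else:
            structure = make_synthetic_model(
                n_atoms, extent=0.7 * box * voxel_size, seed=seed + i
            )
        with warnings.catch_warnings():
            # sub-voxel sigma warnings are expected on the fine end of the grid
            warnings.simplefilter("ignore", UserWarning)
            density_map = minmax_normalize(
                simulate_map(structure, SimulationSpec(float(r), box, voxel_size))
            )
        classes.append(ResolutionClass3(int(classify(density_map, float(r)))))
    return BoundaryScanResult(resolutions, classes)


def cross_evaluate(models: dict, eval_sets: dict) -> pd.DataFrame:
    """Accuracy grid: rows = evaluation sets, columns = models.

    Incompatible model/set pairs yield NaN cells rather than aborting
    the grid.
    """
    from .models import predict

    grid = pd.DataFrame(index=list(eval_sets), columns=list(models), dtype=float)
    for set_name, (x, y) in eval_sets.items():
        for model_name, net in models.items():
            try:
                pred = predict(net, x)
                if getattr(net, "task", "global") == "voxel":
                    from .preprocess import BACKGROUND

                    acc = categorical_accuracy(pred, y, mask=np.asarray(y) != BACKGROUND)
                else:
                    acc = categorical_accuracy(pred, np.asarray(y))
                grid.loc[set_name, model_name] = acc
            except (ValueError, MetricUndefinedError):
                grid.loc[set_name, model_name] = float("nan")
    return grid
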