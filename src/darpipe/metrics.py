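"""Imbalance-aware multi-class evaluation.

Confusion matrices (rows = actual, columns = predicted, fixed 8-class
order), per-class precision/recall/F1, micro accuracy, macro (unweighted
class means) and support-weighted aggregates, plus the feature-set ablation
experiment.  Zero-division convention: a class with no predictions or no
support scores 0 (with a warning) — required for rare-class ablations.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import CLASSES


@dataclasses.dataclass
class ConfusionMatrix:
    """8x8 (or k x k) counts of actual vs predicted classes."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError("counts must be a k x k non-negative matrix")

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("actual").to_csv(path)


@dataclasses.dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics."""

    per_class: pd.DataFrame  # index class; precision, recall, f1, support
    micro_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="index"),
            "micro_accuracy": self.micro_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion(actual: Sequence[str], predicted: Sequence[str],
              class_order: Sequence[str] = CLASSES) -> ConfusionMatrix:
    """Count actual-vs-predicted label pairs over a fixed class order."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    lut = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in lut:
            raise ValueError(f"unknown actual label {a!r}")
        if p not in lut:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[lut[a], lut[p]] += 1
    return ConfusionMatrix(tuple(class_order), counts)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Precision, recall and F1 per class from a confusion matrix."""
    diag = np.diag(cm.counts).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    row = cm.counts.sum(axis=1).astype(float)
    empty = (row == 0) & (col == 0)
    if empty.any():
        warnings.warn(
            "class(es) with no support and no predictions scored as 0: "
            + ", ".join(np.asarray(cm.classes)[empty]))
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1e-300), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1e-300), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1,
         "support": row.astype(int)},
        index=list(cm.classes))


def aggregate_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Micro accuracy plus macro and support-weighted aggregates.

    For single-label multi-class data the support-weighted recall equals the
    micro accuracy (every row contributes its own class's recall weight).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pc = per_class_metrics(cm)
    support = pc["support"].to_numpy(dtype=float)
    w = support / support.sum()
    return MetricsReport(
        per_class=pc,
        micro_accuracy=float(np.trace(cm.counts) / cm.total),
        macro_precision=float(pc["precision"].mean()),
        macro_recall=float(pc["recall"].mean()),
        macro_f1=float(pc["f1"].mean()),
        weighted_precision=float((w * pc["precision"]).sum()),
        weighted_recall=float((w * pc["recall"]).sum()),
        weighted_f1=float((w * pc["f1"]).sum()),
    )


def evaluate(actual, predicted, class_order: Sequence[str] = CLASSES) -> MetricsReport:
    """Convenience: confusion + aggregate metrics in one call."""
    return aggregate_metrics(confusion(actual, predicted, class_order))


#: Feature-set ablation combinations (every combo includes movement/timing).
ABLATION_COMBOS = {
    "ALL": ("movement_timing", "habitat", "history"),
    "MT+habitat": ("movement_timing", "habitat"),
    "MT+history": ("movement_timing", "history"),
    "MT": ("movement_timing",),
}


def ablation_run(
    features: pd.DataFrame,
    combos: Mapping[str, Sequence[str]] | Sequence[str],
    candidate,
    params: Mapping,
    split_indices,
    seed: int = 0,
) -> dict[str, MetricsReport]:
    """Refit one candidate (fixed hyperparameters) per feature-set combo.

    Uses a single fixed train/validation/test split so combos differ only in
    the feature columns available; returns a test-set report per combo.
    """
    from .features import FEATURE_NAMES, FEATURE_SET_OF
    from .models import fit_with_params, predict

    if not isinstance(combos, Mapping):
        combos = {name: ABLATION_COMBOS[name] for name in combos}
    for name, sets in combos.items():
        if "movement_timing" not in sets:
            raise ValueError(
                f"combo {name!r} lacks the movement/timing set; every "
                "combination must include it")
    train = features.iloc[split_indices.train]
    test = features.iloc[split_indices.test]
    reports: dict[str, MetricsReport] = {}
    for name, sets in combos.items():
        cols = [c for c in FEATURE_NAMES
                if c in features.columns and FEATURE_SET_OF[c] in sets]
        model = fit_with_params(candidate, params, train, seed=seed,
                                feature_cols=cols)
        pred, _ = predict(model, test)
        reports[name] = evaluate(test["label"], pred)
    return reports


def ablation_table(reports: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """Class-F1-by-combo matrix with a weighted-F1 summary row."""
    cols = {}
    for name, rep in reports.items():
        col = rep.per_class["f1"].copy()
        col.loc["Weighted-F1"] = rep.weighted_f1
        cols[name] = col
    return pd.DataFrame(cols)


def plot_confusion(cm: ConfusionMatrix, path) -> None:
    """Heatmap of the confusion matrix (optional report artefact)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("Predicted class")
    ax.set_ylabel("Actual class")
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
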