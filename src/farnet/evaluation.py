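"""Multilabel evaluation: per-label AP and mAP, micro/macro-F1,
precision/recall at a confidence threshold, and the label-wise
prediction-confidence grid.

AP is the area under the precision–recall curve computed as the mean of the
running precision at each positive in the confidence-ranked list (stable sort,
descending).  mAP is the arithmetic mean of per-label APs.  Binarization for
the thresholded metrics is strict: predicted positive iff confidence >
threshold (default 0.5), so a confidence exactly at the threshold counts as
negative.  A 0/0 precision or recall is reported as 0 and flagged undefined,
keeping aggregate means well-defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "precision_recall",
    "average_precision",
    "map_score",
    "f1_scores",
    "confidence_grid",
    "evaluate",
]

DEFAULT_GRID_LABELS = ("r", "mr", "c", "p")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-label TP/FP/FN/TN at a stated threshold; arrays of shape (C,)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        totals = self.tp + self.fp + self.fn + self.tn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-label counts must sum to the same sample total")


def confusion_counts(y_true, confidence, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize at the threshold (strict >) and count per label."""
    y = np.asarray(y_true, dtype=bool)
    c = np.asarray(confidence, dtype=float)
    if y.shape != c.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs confidences {c.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    pred = c > threshold
    return ConfusionCounts(
        tp=(pred & y).sum(axis=0),
        fp=(pred & ~y).sum(axis=0),
        fn=(~pred & y).sum(axis=0),
        tn=(~pred & ~y).sum(axis=0),
        threshold=threshold,
    )


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    undefined = den == 0
    out = np.divide(num, den, out=np.zeros(np.shape(den), dtype=float), where=~undefined)
    return out, undefined


def precision_recall(counts: ConfusionCounts) -> dict[str, np.ndarray]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN); 0/0 → 0 with a flag."""
    precision, p_undef = _safe_ratio(counts.tp, counts.tp + counts.fp)
    recall, r_undef = _safe_ratio(counts.tp, counts.tp + counts.fn)
    return {
        "precision": precision,
        "recall": recall,
        "precision_undefined": p_undef,
        "recall_undefined": r_undef,
    }


def average_precision(scores, y_true) -> float:
    """Every-point AP: mean of running precision at each positive, scores
    ranked descending with stable tie order."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("average precision is undefined without positive samples")
    order = np.argsort(-scores, kind="stable")
    ranked = y[order].astype(float)
    cum_tp = np.cumsum(ranked)
    ranks = np.arange(1, len(ranked) + 1)
    return float((cum_tp[ranked == 1] / ranks[ranked == 1]).mean())


def map_score(per_label_aps: Sequence[float]) -> float:
    """Arithmetic mean of per-label APs, as a percentage."""
    aps = np.asarray(per_label_aps, dtype=float)
    if aps.size == 0:
        raise ValueError("need at least one per-label AP")
    return float(aps.mean() * 100)


def f1_scores(counts: ConfusionCounts) -> tuple[float, float]:
    """(micro-F1, macro-F1): micro pools TP/FP/FN globally, macro averages
    per-label F1 (0/0 F1 counted as 0)."""
    tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
    micro = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = 2 * counts.tp + counts.fp + counts.fn
    per_label, _ = _safe_ratio(2 * counts.tp, denom)
    return float(micro), float(per_label.mean())


def confidence_grid(
    confidences,
    label_names: Sequence[str],
    selected: Sequence[str] = DEFAULT_GRID_LABELS,
    figure_path: str | Path | None = None,
):
    """N×k matrix of per-label confidences plus an optional pairwise scatter
    figure (k×k panels) for visualizing class separability."""
    conf = np.asarray(confidences, dtype=float)
    label_names = list(label_names)
    for name in selected:
        if name not in label_names:
            raise KeyError(f"unknown label {name!r}; vocabulary is {label_names}")
    cols = [label_names.index(name) for name in selected]
    grid = conf[:, cols]
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        k = len(selected)
        fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k), squeeze=False)
        for i in range(k):
            for j in range(k):
                ax = axes[i][j]
                if i == j:
                    ax.hist(grid[:, i], bins=20, range=(0, 1), color="#705040")
                else:
                    ax.scatter(grid[:, j], grid[:, i], s=4, alpha=0.4, color="#a03020")
                    ax.set_xlim(0, 1)
                    ax.set_ylim(0, 1)
                if i == k - 1:
                    ax.set_xlabel(selected[j])
                if j == 0:
                    ax.set_ylabel(selected[i])
        fig.tight_layout()
        fig.savefig(figure_path, dpi=110)
        plt.close(fig)
    return grid


@dataclass
class EvalReport:
    """Per-label AP, mAP, micro/macro-F1 and thresholded precision/recall,
    all as percentages."""

    label_names: tuple[str, ...]
    ap_pct: dict[str, float]
    map_pct: float
    micro_f1_pct: float
    macro_f1_pct: float
    precision_pct: dict[str, float]
    recall_pct: dict[str, float]
    threshold: float
    undefined: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.label_names),
            "ap_pct": self.ap_pct,
            "map_pct": self.map_pct,
            "micro_f1_pct": self.micro_f1_pct,
            "macro_f1_pct": self.macro_f1_pct,
            "precision_pct": self.precision_pct,
            "recall_pct": self.recall_pct,
            "threshold": self.threshold,
            "undefined": self.undefined,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_table(self) -> str:
        """Text table mirroring the per-label AP / summary layout."""
        header = f"{'label':>8} {'AP%':>8} {'prec%':>8} {'recall%':>8}"
        rows = [
            f"{name:>8} {self.ap_pct[name]:>8.2f} "
            f"{self.precision_pct[name]:>8.2f} {self.recall_pct[name]:>8.2f}"
            for name in self.label_names
        ]
        summary = (
            f"mAP {self.map_pct:.2f}%   micro-F1 {self.micro_f1_pct:.2f}%   "
            f"macro-F1 {self.macro_f1_pct:.2f}%   (threshold {self.threshold})"
        )
        return "\n".join([header, *rows, summary])


def evaluate(
    y_true,
    confidences,
    label_names: Sequence[str],
    threshold: float = 0.5,
) -> EvalReport:
    """Full report from targets and per-label confidences.

    Labels with no positive sample in ``y_true`` are excluded from the mAP
    mean (their AP is undefined) and flagged.
    """
    y = np.asarray(y_true)
    conf = np.asarray(confidences, dtype=float)
    counts = confusion_counts(y, conf, threshold)
    pr = precision_recall(counts)
    names = tuple(label_names)
    ap_pct: dict[str, float] = {}
    undefined: dict[str, list[str]] = {"ap": [], "precision": [], "recall": []}
    for i, name in enumerate(names):
        if y[:, i].sum() == 0:
            ap_pct[name] = 0.0
            undefined["ap"].append(name)
        else:
            ap_pct[name] = average_precision(conf[:, i], y[:, i]) * 100
        if pr["precision_undefined"][i]:
            undefined["precision"].append(name)
        if pr["recall_undefined"][i]:
            undefined["recall"].append(name)
    defined_aps = [ap_pct[n] / 100 for n in names if n not in undefined["ap"]]
    micro, macro = f1_scores(counts)
    return EvalReport(
        label_names=names,
        ap_pct=ap_pct,
        map_pct=map_score(defined_aps),
        micro_f1_pct=micro * 100,
        macro_f1_pct=macro * 100,
        precision_pct={n: pr["precision"][i] * 100 for i, n in enumerate(names)},
        recall_pct={n: pr["recall"][i] * 100 for i, n in enumerate(names)},
        threshold=threshold,
        undefined=undefined,
    )
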