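"""Dice / IoU scoring, dataset-level aggregation, error maps, and
trainable-parameter accounting.

Scores follow the standard overlap definitions

    Dice = 2|P∩G| / (|P| + |G|),     IoU = |P∩G| / |P∪G|,

with the empty-vs-empty convention scoring 1 (perfect agreement). Dataset
aggregation is pooled ("micro") by default: per class, pixel counts are
summed over the whole test set before scoring, which is stable on slices
where a small class is absent; per-slice averaging is available as a switch.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Module

__all__ = [
    "MetricReport",
    "count_trainable",
    "dice_from_counts",
    "dice_score",
    "error_map",
    "evaluate_dataset",
    "iou_from_counts",
    "iou_score",
    "sweep_report",
]


def dice_from_counts(intersection: int, n_pred: int, n_true: int) -> float:
    if n_pred + n_true == 0:
        return 1.0
    return 2.0 * intersection / (n_pred + n_true)


def iou_from_counts(intersection: int, n_pred: int, n_true: int) -> float:
    union = n_pred + n_true - intersection
    if union == 0:
        return 1.0
    return intersection / union


def _counts(pred_mask: np.ndarray, true_mask: np.ndarray) -> tuple[int, int, int]:
    p = np.asarray(pred_mask).astype(bool)
    g = np.asarray(true_mask).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    return int((p & g).sum()), int(p.sum()), int(g.sum())


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice coefficient of two binary masks (1.0 when both are empty)."""
    return dice_from_counts(*_counts(pred_mask, true_mask))


def iou_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Jaccard index of two binary masks (1.0 when both are empty)."""
    return iou_from_counts(*_counts(pred_mask, true_mask))


@dataclass
class MetricReport:
    per_class: dict  # class -> {"dice": float, "iou": float}
    mean_dice: float
    mean_iou: float
    n_items: int
    dispersion: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"{'class':>8}  {'IoU':>8}  {'Dice':>8}"]
        for c, row in sorted(self.per_class.items()):
            lines.append(f"{c:>8}  {row['iou']:8.4f}  {row['dice']:8.4f}")
        lines.append(f"{'mean':>8}  {self.mean_iou:8.4f}  {self.mean_dice:8.4f}")
        return "\n".join(lines)


def evaluate_dataset(
    predictions,
    ground_truths,
    classes: list[int] | None = None,
    include_background: bool = False,
    mode: str = "pooled",
) -> MetricReport:
    """Score aligned label-map pairs.

    ``classes`` defaults to all labels present in the ground truth. The mean
    row covers foreground classes only (class 0 excluded unless
    ``include_background``); binary tasks therefore report the foreground.
    ``mode``: 'pooled' (default) sums pixel counts over the set before
    scoring; 'per_slice' averages per-pair scores.
    """
    predictions = list(predictions)
    ground_truths = list(ground_truths)
    if len(predictions) != len(ground_truths):
        raise ValueError("prediction/ground-truth counts differ")
    if not predictions:
        raise ValueError("empty evaluation set")
    if mode not in ("pooled", "per_slice"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if classes is None:
        labels = set()
        for g in ground_truths:
            labels.update(np.unique(g).tolist())
        classes = sorted(int(c) for c in labels)
    per_class = {}
    for c in classes:
        if mode == "pooled":
            inter = npred = ntrue = 0
            for p, g in zip(predictions, ground_truths):
                i, np_, nt = _counts(np.asarray(p) == c, np.asarray(g) == c)
                inter, npred, ntrue = inter + i, npred + np_, ntrue + nt
            d = dice_from_counts(inter, npred, ntrue)
            j = iou_from_counts(inter, npred, ntrue)
        else:
            ds, js = [], []
            for p, g in zip(predictions, ground_truths):
                i, np_, nt = _counts(np.asarray(p) == c, np.asarray(g) == c)
                ds.append(dice_from_counts(i, np_, nt))
                js.append(iou_from_counts(i, np_, nt))
            d, j = float(np.mean(ds)), float(np.mean(js))
        per_class[c] = {"dice": d, "iou": j}
    fg = [c for c in classes if include_background or c != 0]
    report_classes = fg if fg else classes
    return MetricReport(
        per_class=per_class,
        mean_dice=float(np.mean([per_class[c]["dice"] for c in report_classes])),
        mean_iou=float(np.mean([per_class[c]["iou"] for c in report_classes])),
        n_items=len(predictions),
    )


def error_map(pred_labels: np.ndarray, true_labels: np.ndarray) -> np.ndarray:
    """Binary grid of mislabelled pixels (True where prediction != truth)."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("shape mismatch")
    return pred_labels != true_labels


def write_error_map(err: np.ndarray, path) -> None:
    """Write a binary mislabel grid as an image (.png) or NIfTI overlay."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        from .volume_io import Volume, write_volume

        grid = err.astype(np.uint8)
        if grid.ndim == 2:
            grid = grid[..., None]
        write_volume(Volume(grid), path)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, (err.astype(np.uint8) * 255))


def count_trainable(model) -> int:
    """Number of trainable parameters.

    Accepts a Module (counts non-frozen entries) or an iterable of
    (size, trainable) pairs.
    """
    if isinstance(model, Module):
        return model.n_parameters(trainable_only=True)
    return sum(int(size) for size, trainable in model if trainable)


def sweep_report(grid_results: dict) -> dict:
    """Mean and sample STD of IoU/Dice across an experiment grid.

    ``grid_results``: method -> list of (iou, dice) pairs, one per grid
    point (strides, sample sizes, seeds ...). STD is the n-1 sample
    standard deviation; undefined (None) for a single grid point.
    """
    out = {}
    for method, pairs in grid_results.items():
        if len(pairs) < 1:
            raise ValueError(f"no grid points for {method}")
        arr = np.asarray(pairs, dtype=np.float64)
        entry = {
            "mean_iou": float(arr[:, 0].mean()),
            "mean_dice": float(arr[:, 1].mean()),
            "n_points": int(len(pairs)),
        }
        if len(pairs) >= 2:
            entry["std_iou"] = float(arr[:, 0].std(ddof=1))
            entry["std_dice"] = float(arr[:, 1].std(ddof=1))
        else:
            entry["std_iou"] = entry["std_dice"] = None
        out[method] = entry
    return out


def sweep_report_text(grid_results: dict) -> str:
    rep = sweep_report(grid_results)
    lines = [f"{'method':>16}  {'mean IoU':>9}  {'mean Dice':>9}  {'STD IoU':>8}  {'STD Dice':>8}"]
    for method, e in rep.items():
        si = "n/a" if e["std_iou"] is None else f"{e['std_iou']:.4f}"
        sd = "n/a" if e["std_dice"] is None else f"{e['std_dice']:.4f}"
        lines.append(
            f"{method:>16}  {e['mean_iou']:9.4f}  {e['mean_dice']:9.4f}  {si:>8}  {sd:>8}"
        )
    return "\n".join(lines)
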