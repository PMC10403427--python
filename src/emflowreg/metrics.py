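"""Registration evaluation: NCC, label Dice, top-k Dice, endpoint error.

The headline label metric follows the standard protocol for this problem:
the k (default 50) nonzero labels with the largest area on the *first*
ground-truth section are selected, and each selected neurite's Dice is
computed over the full 3-D extent of the stack, so axial breaks caused by
misregistration depress the score even when individual sections overlap
well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .flow import FlowField
from .stack_io import LabelStack

__all__ = ["EvalReport", "ncc", "dice", "top_k_dice", "endpoint_error"]


@dataclass
class EvalReport:
    """Flat container for the evaluation outputs."""

    ncc_per_pair: list = field(default_factory=list)
    dice_per_label: dict = field(default_factory=dict)
    top_k_mean_dice: Optional[float] = None
    top_k_used: Optional[int] = None
    epe: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "ncc_per_pair": [float(v) for v in self.ncc_per_pair],
            "dice_per_label": {int(k): float(v) for k, v in self.dice_per_label.items()},
            "top_k_mean_dice": self.top_k_mean_dice,
            "top_k_used": self.top_k_used,
            "epe": self.epe,
        }


def ncc(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Zero-normalized cross-correlation in [−1, 1] over ``mask`` (all
    pixels by default).  Raises on fewer than two valid pixels or zero
    variance, where the score is undefined."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape mismatch")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("NCC needs at least two valid pixels")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da * da) * np.sum(db * db))
    if denom == 0:
        raise ValueError("NCC undefined: zero variance in at least one image")
    return float(np.clip(np.sum(da * db) / denom, -1.0, 1.0))


def dice(label_a: np.ndarray, label_b: np.ndarray, id: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of one label id's binary masks; 0 by
    definition when exactly one mask is empty.  ``id`` must occur in at
    least one map."""
    a = np.asarray(label_a) == id
    b = np.asarray(label_b) == id
    if a.shape != b.shape:
        raise ValueError("label map shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError(f"label {id} absent from both maps")
    return 2.0 * int((a & b).sum()) / (na + nb)


def top_k_dice(
    gt: LabelStack, result_labels: LabelStack, k: int = 50
) -> tuple[float, int]:
    """Mean whole-volume Dice of the k largest-area nonzero labels on the
    first ground-truth section.

    Ties in the area ranking break by ascending label id.  If fewer than k
    labels exist, all are used; the second return value records how many.
    """
    if gt.data.shape != result_labels.data.shape:
        raise ValueError("ground-truth and result label shapes differ")
    first = gt[0]
    ids, areas = np.unique(first[first > 0], return_counts=True)
    if len(ids) == 0:
        raise ValueError("first ground-truth section has no labels")
    order = np.lexsort((ids, -areas))  # area desc, id asc on ties
    selected = ids[order][:k]
    scores = [dice(gt.data, result_labels.data, int(i)) for i in selected]
    return float(np.mean(scores)), int(len(selected))


def endpoint_error(
    est: FlowField, gt: FlowField, mask: Optional[np.ndarray] = None
) -> float:
    """Mean Euclidean distance between estimated and ground-truth
    displacement vectors (EPE, px) over ``mask``."""
    if est.shape != gt.shape:
        raise ValueError("flow shapes differ")
    err = np.hypot(est.dy - gt.dy, est.dx - gt.dx)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != err.shape:
            raise ValueError("mask shape mismatch")
        err = err[mask]
    return float(err.mean())
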