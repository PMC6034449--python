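"""Precision / recall / F1 evaluation and interpolated PR curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryMask

__all__ = ["EvalResult", "PRCurve", "pixel_metrics", "interpolated_pr"]


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with the derived precision, recall and F1.

    Conventions for degenerate cases: precision is 0 when nothing is
    predicted positive, and F1 is 0 when precision + recall = 0, so every
    quantity is always defined.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalResult":
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        return cls(tp=int(tp), fp=int(fp), fn=int(fn),
                   precision=precision, recall=recall, f1=f1)


def _mask_array(mask) -> np.ndarray:
    arr = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
    if arr.dtype != bool:
        raise ValueError("masks must be boolean")
    return arr


def pixel_metrics(predicted, truth) -> EvalResult:
    """Pixel-level confusion of a predicted mask against ground truth."""
    pred = _mask_array(predicted)
    true = _mask_array(truth)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    return EvalResult.from_counts(tp, fp, fn)


@dataclass(frozen=True)
class PRCurve:
    """Ordered (recall, interpolated precision) pairs; precision is
    non-increasing in recall by construction."""

    recall: np.ndarray
    precision: np.ndarray

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recall.tolist(), self.precision.tolist()))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"recall": self.recall,
                             "precision": self.precision})


def interpolated_pr(points) -> PRCurve:
    """Interpolated precision at each measured recall level.

    At recall r the curve takes the highest precision achieved at any recall
    >= r (closing the strict inequality so the curve is defined at its own
    support), which removes the saw-tooth of raw PR points.  Idempotent on
    already non-increasing input.
    """
    pts = [(float(r), float(p)) for r, p in points]
    if not pts:
        raise ValueError("no PR points supplied")
    recalls = np.array(sorted({r for r, _ in pts}))
    precisions = np.empty_like(recalls)
    for i, r in enumerate(recalls):
        precisions[i] = max(p for rr, p in pts if rr >= r)
    return PRCurve(recall=recalls, precision=precisions)
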