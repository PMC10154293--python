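"""Object-level detection scoring with partial-overlap matching.

A ground-truth object counts as detected (TP) when at least one
predicted object overlaps it by at least one pixel; otherwise it is
missed (FN).  A predicted object that overlaps no ground-truth object is
false (FP); one that overlaps any truth object is never false, and
multiple predictions on the same truth object inflate neither TP nor FP.
This truth-side counting keeps ``TP + FN`` equal to the number of
annotated objects.  Sensitivity is TP/(TP+FN), precision TP/(TP+FP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ductseg.synthetic import GroundTruth, rasterize, RING_BOUNDARY

__all__ = [
    "DetectionCounts",
    "match",
    "sensitivity",
    "precision",
    "duct_truth_labels",
    "boundary_truth_labels",
]

ObjectSet = "np.ndarray | Sequence[np.ndarray]"


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


def _as_masks(objs) -> list[np.ndarray]:
    """Normalise a label map or a sequence of boolean masks to mask list."""
    if isinstance(objs, np.ndarray) and objs.ndim == 2:
        if objs.dtype == bool:  # a single mask
            return [objs]
        labels = np.unique(objs)
        return [objs == v for v in labels if v > 0]
    return [np.asarray(m, dtype=bool) for m in objs]


def match(pred, truth) -> DetectionCounts:
    """Count TP/FN/FP between predicted and ground-truth object sets.

    Either argument may be an integer label map (objects are labels > 0)
    or a sequence of boolean masks, all in the same coordinate frame.
    """
    pred_masks = _as_masks(pred)
    truth_masks = _as_masks(truth)
    shapes = {m.shape for m in pred_masks} | {m.shape for m in truth_masks}
    if len(shapes) > 1:
        raise ValueError(f"coordinate frame mismatch: shapes {shapes}")
    tp = 0
    pred_hit = np.zeros(len(pred_masks), dtype=bool)
    for t in truth_masks:
        overlapped = False
        for j, p in enumerate(pred_masks):
            if (t & p).any():
                overlapped = True
                pred_hit[j] = True
        tp += overlapped
    fn = len(truth_masks) - tp
    fp = int((~pred_hit).sum())
    return DetectionCounts(tp=tp, fn=fn, fp=fp)


def sensitivity(c: DetectionCounts) -> float:
    """SEN = TP / (TP + FN); undefined without ground-truth objects."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no ground-truth objects")
    return c.tp / (c.tp + c.fn)


def precision(c: DetectionCounts) -> float:
    """PREC = TP / (TP + FP); undefined without predictions."""
    if c.tp + c.fp == 0:
        raise ZeroDivisionError("precision undefined: no predicted objects")
    return c.tp / (c.tp + c.fp)


def duct_truth_labels(gt: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Label map of ground-truth duct disks (one label per duct)."""
    out = np.zeros(shape, dtype=np.int64)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    for i, (cr, cc, r) in enumerate(gt.duct_disks, start=1):
        out[(rows - cr) ** 2 + (cols - cc) ** 2 <= r * r] = i
    return out


def boundary_truth_labels(gt: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Label map of ground-truth ring-boundary bands (one label per boundary)."""
    mask = rasterize(
        GroundTruth(duct_disks=(), boundary_columns=gt.boundary_columns,
                    ring_extents=gt.ring_extents,
                    boundary_thickness_px=gt.boundary_thickness_px,
                    height_px=gt.height_px),
        shape,
    )
    out = np.zeros(shape, dtype=np.int64)
    half = (gt.boundary_thickness_px - 1) // 2
    for i, c in enumerate(gt.boundary_columns, start=1):
        lo = c - half
        band = np.zeros(shape, dtype=bool)
        band[:, lo:lo + gt.boundary_thickness_px] = True
        out[band & (mask == RING_BOUNDARY)] = i
    return out
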