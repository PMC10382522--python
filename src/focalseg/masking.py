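"""Binarization of focus-score maps and mask arithmetic.

Otsu's method picks the histogram threshold that maximizes the
between-class variance of the focus-score distribution, splitting each
fused map into in-focus foreground and out-of-focus background.  The
resulting binary masks are the weak labels for the surrogate model and
the cookie cutters used to extract in-focus voxels from the raw stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .focusmap import FocalStack, FocusScoreMap

__all__ = ["InFocusMask", "otsu_threshold", "apply_masks", "iou", "mean_iou"]


@dataclass
class InFocusMask:
    """Per-slice boolean mask marking in-focus pixels."""

    values: np.ndarray
    slice_index: int = 0
    origin: str = "rule_based"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != np.bool_:
            raise ValueError("mask values must be boolean")
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")


def otsu_threshold(score_map: FocusScoreMap, nbins: int = 256) -> tuple:
    """Otsu-binarize a focus-score map.

    Returns ``(threshold, mask)`` where the threshold maximizes the
    between-class variance of the ``nbins``-bin histogram and the mask
    marks values strictly above it.  A constant map is degenerate: the
    threshold equals the constant and the mask is all false.
    """
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    values = score_map.values
    if float(values.min()) == float(values.max()):
        thr = float(values.min())
    else:
        thr = float(threshold_otsu(values, nbins=nbins))
    mask = InFocusMask(values > thr, slice_index=score_map.slice_index, origin="rule_based")
    return thr, mask


def apply_masks(stack: FocalStack, masks: list) -> FocalStack:
    """Zero out masked-out voxels; masked-in voxels are preserved bit-exactly."""
    if len(masks) != stack.n_slices:
        raise ValueError(f"{len(masks)} masks for {stack.n_slices} slices")
    out = stack.voxels.copy()
    for z, m in enumerate(masks):
        if m.values.shape != stack.voxels.shape[1:]:
            raise ValueError(f"mask {z} shape {m.values.shape} != slice shape {stack.voxels.shape[1:]}")
        out[z][~m.values] = 0
    return FocalStack(out, stack.pixel_size_um, stack.z_step_um, stack.source_path)


def iou(pred: InFocusMask, truth: InFocusMask) -> float:
    """Intersection over union of two binary masks.

    Defined as 1.0 when both masks are empty, so a correctly all-false
    prediction on a fully out-of-focus slice scores perfectly.
    """
    a, b = pred.values, truth.values
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def mean_iou(preds: list, truths: list) -> float:
    """Mean per-slice IoU over paired mask lists."""
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equally many non-empty prediction and truth masks")
    return float(np.mean([iou(p, t) for p, t in zip(preds, truths)]))
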