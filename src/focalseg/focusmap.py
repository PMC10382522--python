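"""Sliding-window focus-score maps for focal stacks.

A square perception window is slid across each slice of a focal stack
with a fixed stride; the focus score of the pixels inside the window is
written over the window's footprint, and overlapping contributions are
combined (pixelwise max by default).  Repeating the scan over a grid of
window sizes and strides yields several raw maps per slice with
different spatial perceptions; these are min-max normalized and fused
by a pixelwise maximum projection into one focus-score map per slice,
bounded in [0, 1].

Whole-slice axial profiles (one score per slice, min-max normalized
across the stack) rank how sensitively each focus measure tracks the
focal plane along Z.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .metrics import _SOBEL_X, _SOBEL_Y, METRICS, MetricParams, compute_score

__all__ = [
    "FocalStack",
    "ScanConfig",
    "FocusScoreMap",
    "scan_slice",
    "fuse_configs",
    "focus_map_stack",
    "axial_profile",
]


@dataclass
class FocalStack:
    """A 3-D grayscale intensity grid (Z slices x H rows x W cols).

    ``pixel_size_um`` and ``z_step_um`` carry the physical sampling; the
    defaults mirror a stereomicroscope focal-stack acquisition with
    0.79 um lateral sampling and 8.55 um between focal planes.
    """

    voxels: np.ndarray
    pixel_size_um: float = 0.79
    z_step_um: float = 8.55
    source_path: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError(f"expected a Z x H x W stack, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(np.asarray(self.voxels, dtype=np.float64))):
            raise ValueError("stack contains non-finite values")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


@dataclass
class ScanConfig:
    """Parameters of the multi-scale sliding-window scan.

    The scan runs every (window_size, stride) pair in the cross product
    of ``window_sizes`` and ``strides``; window sizes larger than the
    slice are clamped to ``min(H, W)``.

    The default window/stride ladder suits the ~2048-px micrographs it
    was designed on.  Windows should scale with the field of view —
    :meth:`for_shape` builds a ladder spanning 1/16 to 1/4 of the
    shorter image side with strides of a quarter window, which is the
    recommended configuration for the 256-px synthetic stacks.

    Overlapping window contributions are averaged by default
    (``overlap_rule="mean"``), which centres the score transition on
    the true in-focus boundary; ``"max"`` keeps the sharpest window's
    score over its whole footprint, which favours recall over boundary
    precision.
    """

    metric: str = "stddev"
    window_sizes: tuple = (64, 128, 256)
    strides: tuple = (16, 32, 64, 128)
    metric_params: MetricParams = field(default_factory=MetricParams)
    overlap_rule: str = "mean"
    normalize_per_config: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.overlap_rule not in ("max", "mean"):
            raise ValueError("overlap_rule must be 'max' or 'mean'")
        if any(w < 1 for w in self.window_sizes) or any(s < 1 for s in self.strides):
            raise ValueError("window sizes and strides must be positive")

    @classmethod
    def for_shape(cls, shape: tuple, **kwargs) -> "ScanConfig":
        """Scan grid scaled to an image shape.

        Three window sizes spanning 1/16, 1/8 and 1/4 of the shorter
        side, strides of 1/4 to 2x of each window size (cross product),
        e.g. windows (16, 32, 64) with strides (4, 8, 16, 32) on a
        256 x 256 slice.
        """
        base = max(8, 1 << (min(shape) // 16).bit_length() - 1)
        return cls(window_sizes=(base, base * 2, base * 4), strides=(base // 4, base // 2, base, base * 2), **kwargs)

    def grid(self, shape: tuple) -> list:
        """(window, stride) pairs for a slice shape, windows clamped."""
        limit = min(shape)
        sizes = sorted({min(w, limit) for w in self.window_sizes})
        return list(itertools.product(sizes, self.strides))

    def digest(self) -> str:
        key = (
            f"{self.metric}|{tuple(self.window_sizes)}|{tuple(self.strides)}|"
            f"{self.overlap_rule}|{self.normalize_per_config}|{self.metric_params}"
        )
        return hashlib.sha1(key.encode()).hexdigest()[:12]


@dataclass
class FocusScoreMap:
    """Per-slice 2-D float map of focus scores aligned to the image grid."""

    values: np.ndarray
    slice_index: int = 0
    config_digest: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("focus-score map must be 2-D")


def _anchors(extent: int, window: int, stride: int) -> list:
    """Anchor offsets: 0, stride, 2*stride, ... plus one flush with the border."""
    last = extent - window
    pos = list(range(0, last + 1, stride))
    if pos[-1] != last:
        pos.append(last)
    return pos


def _box_sums(field: np.ndarray, rows, cols, h: int, w: int) -> np.ndarray:
    """Sums of ``field`` over h x w boxes anchored at rows x cols.

    Uses a zero-padded integral image; summation-order differences from
    a direct per-window sum are at the level of float64 rounding.
    """
    ii = np.zeros((field.shape[0] + 1, field.shape[1] + 1))
    np.cumsum(np.cumsum(field, axis=0), axis=1, out=ii[1:, 1:])
    r = np.asarray(rows)[:, None]
    c = np.asarray(cols)[None, :]
    return ii[r + h, c + w] - ii[r, c + w] - ii[r + h, c] + ii[r, c]


def _window_scores(img: np.ndarray, ws: int, rows, cols, metric: str, params: MetricParams) -> np.ndarray:
    """Focus score of every ws x ws window anchored on rows x cols.

    Derivative- and statistic-based metrics reduce to box sums of
    global elementwise maps, which makes the scan independent of the
    number of windows; histogram- and wavelet-based metrics fall back
    to a per-window loop.
    """
    min_ws = {"variance": 1, "stddev": 1, "brenner": 2, "smd": 2, "vollath": 2}.get(metric, 3)
    if metric in ("entropy", "dwt") or ws < min_ws:
        out = np.empty((len(rows), len(cols)))
        for a, r in enumerate(rows):
            for b, c in enumerate(cols):
                out[a, b] = compute_score(img[r : r + ws, c : c + ws], metric, params)
        return out
    if metric == "variance":
        # shift by the global mean to limit cancellation in E[x^2]-mu^2
        shifted = img - img.mean()
        n = ws * ws
        s1 = _box_sums(shifted, rows, cols, ws, ws)
        s2 = _box_sums(shifted * shifted, rows, cols, ws, ws)
        return s2 / n - np.square(s1 / n)
    if metric == "stddev":
        lag1 = img[:, :-1] * img[:, 1:]
        edge2 = img * img
        n = ws * ws
        inner = _box_sums(lag1, rows, np.asarray(cols), ws, ws - 1)
        last_col = _box_sums(edge2, rows, np.asarray(cols) + ws - 1, ws, 1)
        mu = _box_sums(img, rows, cols, ws, ws) / n
        return inner + last_col - n * mu * mu
    if metric == "brenner":
        d2 = np.square(img[:, 1:] - img[:, :-1])
        if params.brenner_theta > 0:
            d2 = np.where(d2 >= params.brenner_theta, d2, 0.0)
        return _box_sums(d2, rows, cols, ws, ws - 1)
    if metric == "smd":
        dx = np.abs(img[1:, :] - img[:-1, :])
        dy = np.abs(img[:, 1:] - img[:, :-1])
        return _box_sums(dx, rows, cols, ws - 1, ws) + _box_sums(dy, rows, cols, ws, ws - 1)
    if metric == "vollath":
        lag1 = img[:, :-1] * img[:, 1:]
        out = _box_sums(lag1, rows, cols, ws, ws - 1)
        if ws > 2:
            lag2 = img[:, :-2] * img[:, 2:]
            out = out - _box_sums(lag2, rows, cols, ws, ws - 2)
        return out
    if metric == "tenengrad":
        sx = convolve2d(img, _SOBEL_X, mode="valid")
        sy = convolve2d(img, _SOBEL_Y, mode="valid")
        g2 = sx * sx + sy * sy
        # valid Sobel positions inside a window start one pixel in
        return _box_sums(g2, np.asarray(rows), np.asarray(cols), ws - 2, ws - 2)
    if metric == "laplacian":
        k = np.asarray(params.laplacian_kernel, dtype=np.float64)
        lx = np.abs(convolve2d(img, k[np.newaxis, :], mode="valid"))
        ly = np.abs(convolve2d(img, k[:, np.newaxis], mode="valid"))
        return _box_sums(lx, np.asarray(rows), np.asarray(cols), ws, ws - 2) + _box_sums(
            ly, np.asarray(rows), np.asarray(cols), ws - 2, ws
        )
    raise ValueError(f"unknown focus metric {metric!r}")


def scan_slice(
    slice_2d: np.ndarray,
    window_size: int,
    stride: int,
    metric: str = "stddev",
    params: MetricParams | None = None,
    overlap_rule: str = "max",
) -> FocusScoreMap:
    """Raw (un-normalized) focus-score map of one slice.

    The window anchors on a lattice with the same stride in both axes
    plus a final anchor flush with each border; each window's scalar
    score is painted over its footprint and overlaps combine per
    ``overlap_rule``.  When ``stride > window_size`` the lattice can
    leave gaps between windows; uncovered pixels keep a score of 0.
    """
    img = np.asarray(slice_2d, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("slice must be 2-D")
    h, w = img.shape
    if window_size > min(h, w):
        raise ValueError(f"window {window_size} exceeds slice extent {min(h, w)}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    params = params or MetricParams()

    rows = _anchors(h, window_size, stride)
    cols = _anchors(w, window_size, stride)
    scores = _window_scores(img, window_size, rows, cols, metric, params)
    if overlap_rule == "max":
        acc = np.full((h, w), -np.inf)
        for a, r in enumerate(rows):
            for b, c in enumerate(cols):
                patch = acc[r : r + window_size, c : c + window_size]
                np.maximum(patch, scores[a, b], out=patch)
        acc[np.isneginf(acc)] = 0.0
    elif overlap_rule == "mean":
        acc = np.zeros((h, w))
        count = np.zeros((h, w))
        for a, r in enumerate(rows):
            for b, c in enumerate(cols):
                acc[r : r + window_size, c : c + window_size] += scores[a, b]
                count[r : r + window_size, c : c + window_size] += 1.0
        np.divide(acc, count, out=acc, where=count > 0)
    else:
        raise ValueError("overlap_rule must be 'max' or 'mean'")
    return FocusScoreMap(acc, slice_index=0, config_digest=f"{metric}-w{window_size}-s{stride}")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def fuse_configs(maps: list) -> FocusScoreMap:
    """Min-max normalize each raw map, then take the pixelwise maximum.

    Raw scores from different window sizes live on incomparable scales
    (sums grow with window area), so each map is normalized to [0, 1]
    before the maximum projection.  A constant (degenerate) map
    normalizes to all zeros.
    """
    if not maps:
        raise ValueError("fuse_configs needs at least one map")
    shape = maps[0].values.shape
    idx = maps[0].slice_index
    for m in maps:
        if m.values.shape != shape:
            raise ValueError("all maps must share the same shape")
        if m.slice_index != idx:
            raise ValueError("all maps must belong to the same slice")
    fused = np.zeros(shape)
    for m in maps:
        np.maximum(fused, _minmax(m.values), out=fused)
    return FocusScoreMap(fused, slice_index=idx, config_digest="fused")


def focus_map_stack(stack: FocalStack, config: ScanConfig) -> list:
    """Fused, normalized focus-score map for every slice of a stack.

    Slices are processed independently: for each slice every
    (window_size, stride) pair of the config grid is scanned and the
    resulting raw maps are fused.
    """
    out = []
    pairs = config.grid(stack.voxels.shape[1:])
    for z in range(stack.n_slices):
        maps = []
        for window, stride in pairs:
            m = scan_slice(
                stack.voxels[z],
                window,
                stride,
                metric=config.metric,
                params=config.metric_params,
                overlap_rule=config.overlap_rule,
            )
            m.slice_index = z
            maps.append(m)
        fused = fuse_configs(maps)
        fused.config_digest = config.digest()
        out.append(fused)
    return out


def axial_profile(stack: FocalStack, metric: str = "stddev", params: MetricParams | None = None) -> np.ndarray:
    """Whole-slice focus score per slice, min-max normalized across Z.

    The sharpest slice maps to 1 and the blurriest to 0; a stack of
    identical scores returns all zeros.  Needs at least 2 slices.
    """
    if stack.n_slices < 2:
        raise ValueError("axial_profile needs at least 2 slices")
    scores = np.array(
        [compute_score(stack.voxels[z], metric, params or MetricParams()) for z in range(stack.n_slices)]
    )
    return _minmax(scores)
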