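"""Rule-based focus measures.

Nine scalar focus scores computed from a single 2-D grayscale window.
All of them are designed to be large when the imaged content is sharp
(in focus) and small when it is blurred, exploiting the loss of
high-frequency content, contrast and histogram spread that defocus
causes.  Grouped by design:

* derivative-based: :func:`brenner`, :func:`tenengrad`,
  :func:`laplacian`, :func:`smd`, :func:`vollath`
* statistic-based: :func:`stddev_corr`, :func:`variance`
* histogram-based: :func:`entropy`
* wavelet-based: :func:`dwt_ratio`

Every function accepts a 2-D array-like of finite intensities and
computes in double precision regardless of the input dtype.  The
coordinate convention is row-major with ``x`` the column (horizontal)
index and ``y`` the row (vertical) index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import convolve2d

__all__ = [
    "MetricParams",
    "InvalidWindowError",
    "brenner",
    "tenengrad",
    "laplacian",
    "smd",
    "vollath",
    "stddev_corr",
    "variance",
    "entropy",
    "dwt_ratio",
    "METRICS",
    "compute_score",
]


class InvalidWindowError(ValueError):
    """Raised when a window is too small for the requested focus measure."""


@dataclass
class MetricParams:
    """Tunable parameters shared by the focus measures.

    Attributes
    ----------
    brenner_theta:
        Threshold on the squared horizontal difference in the Brenner
        gradient; squared differences below it are excluded.  Must be
        >= 0.  Default 0 (no thresholding).
    entropy_bins:
        Number of equal-width histogram bins for the entropy measure.
        Must be >= 2.  Default 256.
    wavelet:
        PyWavelets family identifier for the wavelet-based measure.
        Default orthonormal Haar.
    laplacian_kernel:
        Second-derivative kernel applied per axis.  Default is the
        separable 1-D ``[1, -2, 1]`` stencil.
    """

    brenner_theta: float = 0.0
    entropy_bins: int = 256
    wavelet: str = "haar"
    laplacian_kernel: tuple = (1.0, -2.0, 1.0)

    def __post_init__(self) -> None:
        if self.brenner_theta < 0:
            raise ValueError("brenner_theta must be >= 0")
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")


def _as_window(window) -> np.ndarray:
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 2 or w.size == 0:
        raise InvalidWindowError(f"expected a non-empty 2-D window, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise InvalidWindowError("window contains non-finite values")
    return w


def brenner(window, theta: float = 0.0) -> float:
    """Brenner gradient: sum of squared lag-1 horizontal differences.

    Terms enter the sum only when the squared difference is >= ``theta``.
    Requires at least 2 columns.
    """
    w = _as_window(window)
    if w.shape[1] < 2:
        raise InvalidWindowError("brenner needs at least 2 columns")
    d2 = np.square(np.diff(w, axis=1))
    return float(d2[d2 >= theta].sum())


_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


def tenengrad(window) -> float:
    """Tenengrad: sum of squared Sobel gradient magnitudes.

    The 3x3 Sobel kernels are applied only where they fit entirely
    inside the window (valid-region convolution, no padding).
    """
    w = _as_window(window)
    if w.shape[0] < 3 or w.shape[1] < 3:
        raise InvalidWindowError("tenengrad needs a window of at least 3x3")
    sx = convolve2d(w, _SOBEL_X, mode="valid")
    sy = convolve2d(w, _SOBEL_Y, mode="valid")
    return float(np.sum(sx * sx + sy * sy))


def laplacian(window, kernel=(1.0, -2.0, 1.0)) -> float:
    """Sum of absolute 1-D second differences along each axis.

    The x-term needs >= 3 columns and the y-term >= 3 rows; each term
    is computed only where its stencil fits (valid region).  A window
    smaller than 3 in both directions is rejected.
    """
    w = _as_window(window)
    k = np.asarray(kernel, dtype=np.float64)
    n = k.size
    if w.shape[1] < n and w.shape[0] < n:
        raise InvalidWindowError("laplacian needs at least 3 rows or 3 columns")
    total = 0.0
    if w.shape[1] >= n:
        lx = convolve2d(w, k[np.newaxis, :], mode="valid")
        total += float(np.abs(lx).sum())
    if w.shape[0] >= n:
        ly = convolve2d(w, k[:, np.newaxis], mode="valid")
        total += float(np.abs(ly).sum())
    return total


def smd(window) -> float:
    """Sum-modulus-difference: absolute lag-1 differences along both axes."""
    w = _as_window(window)
    if w.shape[0] < 2 and w.shape[1] < 2:
        raise InvalidWindowError("smd needs at least 2 rows or 2 columns")
    sx = float(np.abs(np.diff(w, axis=0)).sum())
    sy = float(np.abs(np.diff(w, axis=1)).sum())
    return sx + sy


def vollath(window) -> float:
    """Vollath F4 autocorrelation measure.

    Difference between the lag-1 and lag-2 horizontal autocorrelation
    sums; the lag-2 sum is empty for a 2-column window.  May be
    negative for adversarial inputs.
    """
    w = _as_window(window)
    if w.shape[1] < 2:
        raise InvalidWindowError("vollath needs at least 2 columns")
    lag1 = float(np.sum(w[:, :-1] * w[:, 1:]))
    lag2 = float(np.sum(w[:, :-2] * w[:, 2:])) if w.shape[1] > 2 else 0.0
    return lag1 - lag2


def stddev_corr(window, valid_only: bool = False) -> float:
    """Contrast statistic based on the lag-1 horizontal autocorrelation.

    Computes ``sum(i(x, y) * i(x+1, y)) - H*W*mu**2``.  By default the
    ``x+1`` access at the last column is resolved by replicate-edge
    padding, which makes a constant window score exactly 0 and turns
    the measure into a pure contrast statistic.  With
    ``valid_only=True`` the last column is dropped from the sum instead
    and the mean term is scaled to the number of summed terms.
    """
    w = _as_window(window)
    mu = w.mean()
    if valid_only:
        n = w.shape[0] * max(w.shape[1] - 1, 0)
        return float(np.sum(w[:, :-1] * w[:, 1:]) - n * mu * mu)
    shifted = np.concatenate([w[:, 1:], w[:, -1:]], axis=1)
    return float(np.sum(w * shifted) - w.size * mu * mu)


def variance(window) -> float:
    """Mean squared deviation from the window mean."""
    w = _as_window(window)
    return float(np.mean(np.square(w - w.mean())))


def entropy(window, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram.

    8/16-bit integer windows are binned over their dtype's full range
    so that the score is comparable across windows from the same image;
    float and wide-integer windows use their observed min-max range.  ``0 * log 0`` is
    taken as 0, so a constant window scores 0.
    """
    if bins < 2:
        raise ValueError("entropy needs at least 2 bins")
    raw = np.asarray(window)
    w = _as_window(window)
    if raw.dtype.kind in "ui" and raw.dtype.itemsize <= 2:
        info = np.iinfo(raw.dtype)
        lo, hi = float(info.min), float(info.max) + 1.0
    else:
        lo, hi = float(w.min()), float(w.max())
        if lo == hi:
            return 0.0
    counts, _ = np.histogram(w, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / w.size
    return float(-np.sum(p * np.log2(p)))


def dwt_ratio(window, wavelet: str = "haar") -> float:
    """Ratio of high-pass to low-pass energy in a one-level 2-D DWT.

    The high-pass norm concatenates the LH, HL and HH detail bands;
    both norms are L2.  Returns 0 when the window is identically zero.
    """
    w = _as_window(window)
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise InvalidWindowError("dwt_ratio needs a window of at least 2x2")
    ll, (lh, hl, hh) = pywt.dwt2(w, wavelet)
    high = float(np.sqrt(np.sum(lh * lh) + np.sum(hl * hl) + np.sum(hh * hh)))
    low = float(np.sqrt(np.sum(ll * ll)))
    if low == 0.0:
        return 0.0 if high == 0.0 else float("inf")
    return high / low


def compute_score(window, metric: str, params: MetricParams | None = None) -> float:
    """Dispatch a focus measure by name (see :data:`METRICS`)."""
    p = params or MetricParams()
    try:
        fn = METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown focus metric {metric!r}; choose from {sorted(METRICS)}") from None
    return fn(window, p)


METRICS = {
    "brenner": lambda w, p: brenner(w, p.brenner_theta),
    "tenengrad": lambda w, p: tenengrad(w),
    "laplacian": lambda w, p: laplacian(w, p.laplacian_kernel),
    "smd": lambda w, p: smd(w),
    "vollath": lambda w, p: vollath(w),
    "stddev": lambda w, p: stddev_corr(w),
    "variance": lambda w, p: variance(w),
    "entropy": lambda w, p: entropy(w, p.entropy_bins),
    "dwt": lambda w, p: dwt_ratio(w, p.wavelet),
}
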