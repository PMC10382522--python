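"""Independent literal-loop oracles used to cross-check the implementation.

Each focus measure is re-derived here as a direct, unvectorized
transcription of its defining sum, sharing no code with the package.
"""

import math

import numpy as np
import pywt


def brenner_loop(win, theta=0.0):
    w = np.asarray(win, dtype=float)
    h, n = w.shape
    total = 0.0
    for y in range(h):
        for x in range(n - 1):
            d2 = (w[y, x + 1] - w[y, x]) ** 2
            if d2 >= theta:
                total += d2
    return total


def tenengrad_loop(win):
    w = np.asarray(win, dtype=float)
    h, n = w.shape
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    total = 0.0
    for y in range(1, h - 1):
        for x in range(1, n - 1):
            sx = sy = 0.0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    # convolution flips the kernel
                    sx += kx[1 - dy][1 - dx] * w[y + dy, x + dx]
                    sy += kx[1 - dx][1 - dy] * w[y + dy, x + dx]
            total += sx * sx + sy * sy
    return total


def laplacian_loop(win):
    w = np.asarray(win, dtype=float)
    h, n = w.shape
    total = 0.0
    for y in range(h):
        for x in range(1, n - 1):
            total += abs(w[y, x - 1] - 2 * w[y, x] + w[y, x + 1])
    for y in range(1, h - 1):
        for x in range(n):
            total += abs(w[y - 1, x] - 2 * w[y, x] + w[y + 1, x])
    return total


def smd_loop(win):
    w = np.asarray(win, dtype=float)
    h, n = w.shape
    total = 0.0
    for y in range(1, h):
        for x in range(n):
            total += abs(w[y, x] - w[y - 1, x])
    for y in range(h):
        for x in range(1, n):
            total += abs(w[y, x] - w[y, x - 1])
    return total


def vollath_loop(win):
    w = np.asarray(win, dtype=float)
    h, n = w.shape
    lag1 = sum(w[y, x] * w[y, x + 1] for y in range(h) for x in range(n - 1))
    lag2 = sum(w[y, x] * w[y, x + 2] for y in range(h) for x in range(n - 2))
    return lag1 - lag2


def stddev_corr_loop(win):
    w = np.asarray(win, dtype=float)
    h, n = w.shape
    mu = w.mean()
    total = 0.0
    for y in range(h):
        for x in range(n):
            nxt = w[y, x + 1] if x + 1 < n else w[y, x]  # replicate edge
            total += w[y, x] * nxt
    return total - h * n * mu * mu


def variance_loop(win):
    w = np.asarray(win, dtype=float)
    mu = w.mean()
    return sum((v - mu) ** 2 for v in w.ravel()) / w.size


def entropy_loop(win, bins=256):
    raw = np.asarray(win)
    w = raw.astype(float)
    if raw.dtype.kind in "ui" and raw.dtype.itemsize <= 2:
        info = np.iinfo(raw.dtype)
        lo, hi = float(info.min), float(info.max) + 1.0
    else:
        lo, hi = w.min(), w.max()
        if lo == hi:
            return 0.0
    width = (hi - lo) / bins
    counts = [0] * bins
    for v in w.ravel():
        idx = min(int((v - lo) / width), bins - 1)
        counts[idx] += 1
    total = 0.0
    for c in counts:
        if c:
            p = c / w.size
            total -= p * math.log2(p)
    return total


def dwt_ratio_loop(win, wavelet="haar"):
    ll, (lh, hl, hh) = pywt.dwt2(np.asarray(win, dtype=float), wavelet)
    high = math.sqrt(sum(v * v for band in (lh, hl, hh) for v in band.ravel()))
    low = math.sqrt(sum(v * v for v in ll.ravel()))
    if low == 0.0:
        return 0.0 if high == 0.0 else float("inf")
    return high / low


LOOP_ORACLES = {
    "brenner": lambda w, p: brenner_loop(w, p.brenner_theta),
    "tenengrad": lambda w, p: tenengrad_loop(w),
    "laplacian": lambda w, p: laplacian_loop(w),
    "smd": lambda w, p: smd_loop(w),
    "vollath": lambda w, p: vollath_loop(w),
    "stddev": lambda w, p: stddev_corr_loop(w),
    "variance": lambda w, p: variance_loop(w),
    "entropy": lambda w, p: entropy_loop(w, p.entropy_bins),
    "dwt": lambda w, p: dwt_ratio_loop(w, p.wavelet),
}


def otsu_exhaustive(values, nbins=256):
    """Brute-force Otsu: maximize between-class variance over all bins."""
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    n = values.size
    best_var, best_thr = -1.0, centers[0]
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum() / n
        w1 = 1.0 - w0
        if w0 == 0.0 or w1 == 0.0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / (counts[: k + 1].sum())
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / (counts[k + 1 :].sum())
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[k]
    return best_thr


def scan_slice_loop(img, ws, stride, score_fn, rule="mean"):
    """Brute-force sliding-window placement with flush border anchors."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape

    def anchors(extent):
        pos = list(range(0, extent - ws + 1, stride))
        if pos[-1] != extent - ws:
            pos.append(extent - ws)
        return pos

    if rule == "max":
        acc = np.full((h, w), -np.inf)
        for r in anchors(h):
            for c in anchors(w):
                s = score_fn(img[r : r + ws, c : c + ws])
                acc[r : r + ws, c : c + ws] = np.maximum(acc[r : r + ws, c : c + ws], s)
        acc[np.isneginf(acc)] = 0.0
        return acc
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for r in anchors(h):
        for c in anchors(w):
            s = score_fn(img[r : r + ws, c : c + ws])
            acc[r : r + ws, c : c + ws] += s
            cnt[r : r + ws, c : c + ws] += 1
    return np.divide(acc, cnt, out=acc, where=cnt > 0)
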