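"""Independent brute-force oracles used to validate the image primitives.

Everything here is deliberately naive (direct definitions, python loops)
and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_median_filter(gray: np.ndarray, kernel: int) -> np.ndarray:
    """Direct neighborhood median with edge replication."""
    pad = kernel // 2
    padded = np.pad(gray, pad, mode="edge")
    out = np.empty_like(gray)
    for r in range(gray.shape[0]):
        for c in range(gray.shape[1]):
            out[r, c] = np.median(padded[r : r + kernel, c : c + kernel])
    return out


def brute_dilate(mask: np.ndarray, kernel: int) -> np.ndarray:
    """Minkowski sum of the set with a centered kernel x kernel square."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    half = kernel // 2
    lo = -half
    hi = kernel - half - 1  # even kernels extend one step further positive
    for r, c in zip(*np.nonzero(mask)):
        for dr in range(lo, hi + 1):
            for dc in range(lo, hi + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    out[rr, cc] = True
    return out


def brute_erode(mask: np.ndarray, kernel: int) -> np.ndarray:
    """Pixels whose whole kernel x kernel neighborhood is inside the set
    (out-of-frame treated as background, matching zero-padded erosion)."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    half = kernel // 2
    lo = -half
    hi = kernel - half - 1
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in range(lo, hi + 1):
                for dc in range(lo, hi + 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out


def brute_cht_peaks(
    gray: np.ndarray,
    r_min: int,
    r_max: int,
    vote_threshold_frac: float,
    min_center_distance: float,
):
    """Exhaustive (a, b, R) accumulator circle detection, naive scalar code.

    The full 3-D accumulator is materialized: every edge pixel (same
    gradient-hysteresis edge rule the detector documents: Otsu high
    threshold, half that low) casts one vote along +/- its gradient
    direction at every candidate radius, with plain python loops and scalar
    arithmetic.  Peaks come out of the accumulator by the documented rules:
    radius-summed center plane, 3x3 consolidation, greedy non-maximum
    suppression, a radius from the vote-weighted mean of the center's
    accumulator column (bins holding >= half the peak), and acceptance when
    the peak bin reaches vote_threshold_frac * 2 * pi * R.
    """
    from scipy import ndimage as ndi
    from skimage.filters import apply_hysteresis_threshold, threshold_otsu

    g = gray.astype(np.float32)
    gx = ndi.sobel(g, axis=1, mode="nearest")
    gy = ndi.sobel(g, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    if mag.max() <= 0:
        return []
    high = threshold_otsu(mag)
    edges = apply_hysteresis_threshold(mag, high / 2.0, high)
    ey, ex = np.nonzero(edges)
    h, w = gray.shape

    # full 3-D accumulator acc[R - r_min][b][a], one vote at a time
    n_r = r_max - r_min + 1
    acc = np.zeros((n_r, h, w), dtype=np.int64)
    for x, y in zip(ex.tolist(), ey.tolist()):
        theta = math.atan2(float(gy[y, x]), float(gx[y, x]))
        for ri in range(n_r):
            radius = r_min + ri
            for sign in (1.0, -1.0):
                a = float(np.rint(x - sign * radius * math.cos(theta)))
                b = float(np.rint(y - sign * radius * math.sin(theta)))
                if 0 <= a < w and 0 <= b < h:
                    acc[ri, int(b), int(a)] += 1

    combined = acc.sum(axis=0).astype(float)
    combined = ndi.uniform_filter(combined, size=3, mode="constant") * 9.0
    floor = vote_threshold_frac * 2.0 * math.pi * r_min
    cand = [
        (combined[b, a], b, a)
        for b, a in zip(*np.nonzero(combined >= floor))
    ]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    peaks = []
    for votes, b, a in cand:
        if all(math.hypot(b - pb, a - pa) >= min_center_distance
               for _, pb, pa in peaks):
            peaks.append((votes, b, a))

    out = []
    for _, b, a in peaks:
        # 3x3-consolidated accumulator column at this center
        col = acc[:, max(b - 1, 0) : b + 2, max(a - 1, 0) : a + 2].sum(axis=(1, 2))
        peak = int(col.max())
        if peak == 0:
            continue
        strong = col >= 0.5 * peak
        radii = r_min + np.arange(n_r)
        r = float((radii[strong] * col[strong]).sum() / col[strong].sum())
        r = int(round(min(max(r, r_min), r_max)))
        if peak >= vote_threshold_frac * 2.0 * math.pi * r:
            out.append((a, b, r))
    return out


def draw_annulus(
    shape: tuple[int, int],
    center: tuple[int, int],
    radius: float,
    thickness: float = 3.0,
    level: int = 40000,
    background: int = 2000,
) -> np.ndarray:
    """Clean bright ring (mid-line at ``radius``) on a flat background."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - center[0], yy - center[1])
    img = np.full(shape, background, dtype=np.uint16)
    img[np.abs(d - radius) <= thickness / 2.0] = level
    return img
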