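"""Droplet detection with a Circular Hough Transform (CHT).

Trapped water-in-oil droplets appear in brightfield as bright circular rims
of roughly known radius (25-50 um; the trap array holds them on a hexagonal
lattice with 360 um pitch).  Detection proceeds in three stages:

1. median smoothing of the grayscale overlay to suppress shot noise,
2. a gradient-voting CHT: edge pixels (gradient-magnitude hysteresis with
   Otsu-derived thresholds) cast votes along +/- the local gradient
   direction for every candidate radius; accumulator peaks whose support
   reaches ``vote_threshold_frac`` of the ideal perimeter ``2*pi*R`` become
   droplets,
3. trap-lattice deduplication: multiple detections falling inside one trap
   are collapsed to the highest-vote member, and retained neighbor spacings
   can be checked against the 360 +/- 10 um lattice pitch.

Voting over all radii shares a single 2-D center accumulator; the radius of
each accepted center is then recovered from the radial histogram of its
supporting edge pixels.  This is algebraically the same peak set as
per-radius accumulators but avoids materializing a 3-D array.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, threshold_otsu

log = logging.getLogger(__name__)


@dataclass
class DropletParams:
    """Tunable parameters of the droplet detector.

    All physical lengths are microns and are converted to pixels through
    ``microns_per_pixel`` (default 1.0, the calibration at which 25-50 um
    droplet radii and a 360 um trap pitch correspond to the pixel scales
    used throughout).
    """

    microns_per_pixel: float = 1.0
    r_min_um: float = 25.0
    r_max_um: float = 50.0
    median_kernel: int = 3
    vote_threshold_frac: float = 0.4
    radius_step: int = 1
    min_center_distance: float | None = None  # px; default 2 * r_min_px
    trap_spacing_um: float = 360.0
    trap_spacing_tol_um: float = 10.0
    validate_lattice: bool = False

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if not 0 < self.r_min_um < self.r_max_um:
            raise ValueError("require 0 < r_min < r_max")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")
        if not 0 < self.vote_threshold_frac <= 1:
            raise ValueError("vote_threshold_frac must be in (0, 1]")
        if self.radius_step < 1:
            raise ValueError("radius_step must be >= 1")
        if self.trap_spacing_tol_um >= self.trap_spacing_um:
            raise ValueError("trap spacing tolerance must be below the spacing")
        if self.r_min_px < 2:
            raise ValueError("r_min must be at least 2 px at this calibration")

    @property
    def r_min_px(self) -> int:
        return int(round(self.r_min_um / self.microns_per_pixel))

    @property
    def r_max_px(self) -> int:
        return int(round(self.r_max_um / self.microns_per_pixel))

    @property
    def min_center_distance_px(self) -> float:
        if self.min_center_distance is not None:
            return float(self.min_center_distance)
        return 2.0 * self.r_min_px

    @property
    def trap_spacing_px(self) -> float:
        return self.trap_spacing_um / self.microns_per_pixel

    @property
    def trap_spacing_tol_px(self) -> float:
        return self.trap_spacing_tol_um / self.microns_per_pixel


@dataclass
class Droplet:
    """One detected droplet: integer-pixel center (x=col, y=row), radius, votes."""

    x: int
    y: int
    radius: int
    votes: int
    droplet_id: int = -1

    @property
    def center(self) -> tuple[int, int]:
        return (self.x, self.y)


@dataclass
class DropletMap:
    """All droplets detected in one image (``n_droplets == len(droplets)``)."""

    droplets: list[Droplet] = field(default_factory=list)
    image_index: int = 0

    @property
    def n_droplets(self) -> int:
        return len(self.droplets)

    def __iter__(self):
        return iter(self.droplets)

    def __len__(self) -> int:
        return len(self.droplets)


def median_smooth(gray: np.ndarray, kernel: int) -> np.ndarray:
    """Median-filter a grayscale image with a square kernel.

    Borders are edge-replicated; the value range is trivially preserved.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("median_smooth expects a 2-D grayscale image")
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("median kernel must be odd and positive")
    if kernel > min(gray.shape):
        raise ValueError("median kernel larger than the image")
    return ndi.median_filter(gray, size=kernel, mode="nearest")


def _gradient_edges(gray: np.ndarray):
    """Edge pixels by gradient-magnitude hysteresis (high = Otsu, low = high/2).

    Returns (rows, cols, gx, gy) of edge pixels; empty arrays for a flat image.
    """
    g = gray.astype(np.float32)
    gx = ndi.sobel(g, axis=1, mode="nearest")
    gy = ndi.sobel(g, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    if mag.max() <= 0:
        empty = np.empty(0)
        return empty.astype(int), empty.astype(int), empty, empty
    high = threshold_otsu(mag)
    if high <= 0:
        empty = np.empty(0)
        return empty.astype(int), empty.astype(int), empty, empty
    edges = apply_hysteresis_threshold(mag, high / 2.0, high)
    rows, cols = np.nonzero(edges)
    return rows, cols, gx[rows, cols], gy[rows, cols]


def _greedy_nms(
    candidates: np.ndarray, votes: np.ndarray, min_distance: float
) -> list[int]:
    """Greedy non-maximum suppression: highest votes first, ties broken by
    smaller (row, col); returns indices of the accepted candidates."""
    order = np.lexsort((candidates[:, 1], candidates[:, 0], -votes))
    kept: list[int] = []
    kept_pos: list[np.ndarray] = []
    min_sq = min_distance * min_distance
    for i in order:
        pos = candidates[i].astype(np.float64)
        if all(np.sum((pos - q) ** 2) >= min_sq for q in kept_pos):
            kept.append(int(i))
            kept_pos.append(pos)
    return kept


def _refine_radius(
    dists: np.ndarray, r_min: int, r_max: int, step: int
) -> tuple[int, int]:
    """Radius and vote count from the radial histogram of edge distances.

    Bright rims a few pixels thick produce two thin edge rings (inner and
    outer); the vote-weighted mean over all radius bins holding at least
    half the peak support recovers the mid-rim radius to ~1 px.
    """
    lo, hi = r_min - 2, r_max + 2
    sel = (dists >= lo - 0.5) & (dists < hi + 0.5)
    if not sel.any():
        return 0, 0
    bins = np.round((dists[sel] - lo) / step).astype(int)
    counts = np.bincount(bins, minlength=int((hi - lo) / step) + 1)
    peak = int(counts.max())
    strong = counts >= 0.5 * peak
    radii = lo + step * np.arange(counts.size)
    r = float(np.sum(radii[strong] * counts[strong]) / np.sum(counts[strong]))
    r = min(max(r, r_min), r_max)
    return int(round(r)), peak


def circular_hough_transform(
    gray_smoothed: np.ndarray, params: DropletParams, image_index: int = 0
) -> DropletMap:
    """Detect circles of radius r_min..r_max px by gradient-voting CHT.

    Every edge pixel votes along +/- its gradient direction at each
    candidate radius; votes from all radii accumulate in one (a, b) center
    plane.  3x3-consolidated peaks separated by ``min_center_distance`` are
    accepted greedily by decreasing votes, then each center's radius is
    recovered from its radial edge histogram and the peak must reach
    ``vote_threshold_frac * 2 * pi * R`` supporting edge pixels.
    """
    gray = np.asarray(gray_smoothed)
    h, w = gray.shape
    rows, cols, gx, gy = _gradient_edges(gray)
    if rows.size == 0:
        return DropletMap(image_index=image_index)

    theta = np.arctan2(gy, gx)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    radii = np.arange(params.r_min_px, params.r_max_px + 1, params.radius_step)

    acc = np.zeros(h * w, dtype=np.float32)
    for sign in (1.0, -1.0):
        # candidate centers for all (edge pixel, radius) pairs at once
        a = np.rint(cols[None, :] - sign * radii[:, None] * cos_t[None, :])
        b = np.rint(rows[None, :] - sign * radii[:, None] * sin_t[None, :])
        ok = (a >= 0) & (a < w) & (b >= 0) & (b < h)
        idx = (b[ok].astype(np.int64) * w + a[ok].astype(np.int64))
        np.add.at(acc, idx, 1.0)
    acc = acc.reshape(h, w)
    acc_box = ndi.uniform_filter(acc, size=3, mode="constant") * 9.0

    floor = params.vote_threshold_frac * 2.0 * math.pi * params.r_min_px
    cand_r, cand_c = np.nonzero(acc_box >= floor)
    if cand_r.size == 0:
        return DropletMap(image_index=image_index)
    cand = np.stack([cand_r, cand_c], axis=1)
    cand_votes = acc_box[cand_r, cand_c]
    kept = _greedy_nms(cand, cand_votes, params.min_center_distance_px)

    droplets: list[Droplet] = []
    for i in kept:
        cy, cx = int(cand[i, 0]), int(cand[i, 1])
        d = np.hypot(cols - cx, rows - cy)
        radius, votes = _refine_radius(
            d, params.r_min_px, params.r_max_px, params.radius_step
        )
        if radius <= 0:
            continue
        if votes < params.vote_threshold_frac * 2.0 * math.pi * radius:
            continue
        droplets.append(Droplet(x=cx, y=cy, radius=radius, votes=votes))

    droplets.sort(key=lambda d: (d.y, d.x))
    for i, d in enumerate(droplets):
        d.droplet_id = i
    return DropletMap(droplets=droplets, image_index=image_index)


def deduplicate_trap_droplets(
    dmap: DropletMap, params: DropletParams
) -> DropletMap:
    """Collapse multiple detections per trap; optionally check lattice pitch.

    Detections whose centers lie within ``2 * r_max_px`` of each other can
    only be one physical trapped droplet, so each such group keeps its
    highest-vote member.  With ``validate_lattice`` enabled, the retained
    nearest-neighbor distances are compared against the hexagonal trap
    pitch (360 +/- 10 um); violations are logged, not removed, since a
    partially filled array legitimately breaks equidistance.
    """
    drops = list(dmap.droplets)
    if len(drops) <= 1:
        return DropletMap(droplets=[replace(d) for d in drops],
                          image_index=dmap.image_index)

    group_radius = 2.0 * params.r_max_px
    pos = np.array([[d.y, d.x] for d in drops], dtype=np.float64)
    n = len(drops)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pos[i] - pos[j])) < group_radius:
                parent[find(i)] = find(j)

    best: dict[int, Droplet] = {}
    for i, d in enumerate(drops):
        root = find(i)
        cur = best.get(root)
        if cur is None or (d.votes, -d.y, -d.x) > (cur.votes, -cur.y, -cur.x):
            best[root] = d

    kept = sorted((replace(d) for d in best.values()), key=lambda d: (d.y, d.x))
    for i, d in enumerate(kept):
        d.droplet_id = i

    if params.validate_lattice and len(kept) > 1:
        spacing, tol = params.trap_spacing_px, params.trap_spacing_tol_px
        pts = np.array([[d.y, d.x] for d in kept], dtype=np.float64)
        for i, d in enumerate(kept):
            dists = np.hypot(*(pts - pts[i]).T)
            dists[i] = np.inf
            nn = dists.min()
            if not (spacing - tol <= nn <= spacing + tol):
                log.info(
                    "droplet %d at (%d, %d): nearest-neighbor distance %.0f px "
                    "outside trap pitch %.0f +/- %.0f px",
                    d.droplet_id, d.x, d.y, nn, spacing, tol,
                )
    return DropletMap(droplets=kept, image_index=dmap.image_index)


def detect_droplets(
    gray: np.ndarray, params: DropletParams, image_index: int = 0
) -> DropletMap:
    """Full droplet stage: median smoothing, CHT, trap deduplication."""
    smoothed = median_smooth(gray, params.median_kernel)
    dmap = circular_hough_transform(smoothed, params, image_index=image_index)
    return deduplicate_trap_droplets(dmap, params)
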