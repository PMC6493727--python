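"""Detection of fluorescent contours (cells, nanoparticle clusters) by color.

Each fluorophore class is defined by an inclusive 8-bit B,G,R color window
(live cells green, dead cells red, dual-signal "dying" cells yellow, and
Eu- or Tb-doped nanoparticle clusters magenta / blue, chosen off the
GFP/RFP hues so trackers never collide with cells).  Per class the stages
are: color mask -> masked grayscale (Rec. 601 luminance, median smoothed)
-> Canny edges -> dilation -> erosion -> interior fill -> random-walker
splitting of touching objects -> contour extraction with convex-hull
adjustment -> area thresholding (>= 130 px^2 for cells, >= 150 px^2 for NP
clusters, both inclusive).  Parallel class passes are finally reconciled so
one physical object is reported once, with the dual-signal class taking
precedence over single-channel ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import canny as _skimage_canny
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours
from skimage.segmentation import random_walker

from .image_io import OverlayImage, luminance
from .droplet_detection import median_smooth

log = logging.getLogger(__name__)

#: Cell-type classes (count toward droplet occupancy) vs nanoparticle classes.
CELL_CLASSES = frozenset({"live", "dead", "overlap"})
NP_CLASSES = frozenset({"eu_np", "tb_np"})

#: Conflict precedence, best first: a region seen by several class passes is
#: reported once under the highest-precedence class (dual-signal "overlap"
#: cells must not be double-counted as live and dead).
CLASS_PRECEDENCE = ("overlap", "dead", "live", "eu_np", "tb_np", "custom")

#: Default inclusive 8-bit (B, G, R) color windows per class.
DEFAULT_BOUNDARIES: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "live": ((0, 51, 0), (153, 255, 153)),
    "dead": ((0, 0, 51), (153, 153, 255)),
    "overlap": ((0, 51, 51), (153, 255, 255)),
    "eu_np": ((51, 0, 51), (255, 102, 255)),
    "tb_np": ((51, 0, 0), (255, 51, 51)),
}


@dataclass
class ColorBoundary:
    """Inclusive 8-bit B,G,R color window for one fluorophore class."""

    class_label: str
    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo, up = tuple(self.lower), tuple(self.upper)
        if len(lo) != 3 or len(up) != 3:
            raise ValueError("boundaries must be B,G,R triples")
        for c, (a, b) in enumerate(zip(lo, up)):
            if not (0 <= a <= b <= 255):
                raise ValueError(
                    f"channel {c}: need 0 <= lower <= upper <= 255, got {a}..{b}"
                )
        self.lower, self.upper = lo, up

    @classmethod
    def default(cls, class_label: str) -> "ColorBoundary":
        lo, up = DEFAULT_BOUNDARIES[class_label]
        return cls(class_label, lo, up)


def default_boundaries(classes=None) -> dict[str, ColorBoundary]:
    """The per-class default color windows as ColorBoundary objects."""
    names = classes if classes is not None else DEFAULT_BOUNDARIES.keys()
    return {name: ColorBoundary.default(name) for name in names}


@dataclass
class ContourParams:
    """Tunable parameters of the contour detector (pixel units)."""

    canny_t_min: float | None = None  # None -> Otsu-derived
    canny_t_max: float | None = None
    canny_sigma: float = 1.0
    morph_kernel: int = 3
    dilate_iters: int = 1
    erode_iters: int = 1
    min_area_cell: int = 130
    min_area_np: int = 150
    hull_defect_depth: float = 3.0
    merge_radius: float = 5.0
    rw_beta: float = 130.0
    label_projection_radius: float = 3.0

    def __post_init__(self) -> None:
        if (
            self.canny_t_min is not None
            and self.canny_t_max is not None
            and self.canny_t_min >= self.canny_t_max
        ):
            raise ValueError("canny_t_min must be below canny_t_max")
        if self.morph_kernel < 1:
            raise ValueError("morph_kernel must be >= 1")
        if self.min_area_cell <= 0 or self.min_area_np <= 0:
            raise ValueError("minimum areas must be positive")

    def min_area_for(self, class_label: str) -> int:
        return self.min_area_np if class_label in NP_CLASSES else self.min_area_cell

    @property
    def marker_min_distance(self) -> int:
        # minimum separation of segmentation markers ~ radius of the
        # smallest admissible cell
        return max(3, int(math.sqrt(self.min_area_cell / math.pi)))


@dataclass
class Contour:
    """One detected fluorescent region.

    ``pixels`` is an ``(N, 2)`` array of (row, col) coordinates; ``area``
    is the pixel count; ``centroid`` is (x, y); ``boundary`` is the traced
    outer polygon as (x, y) vertices (replaced by its convex hull when the
    deepest convexity defect exceeds the configured depth).
    """

    contour_id: int
    class_label: str
    pixels: np.ndarray
    centroid: tuple[float, float]
    boundary: np.ndarray
    image_index: int = 0

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


def build_color_mask(img: OverlayImage | np.ndarray, boundary: ColorBoundary) -> np.ndarray:
    """Boolean mask of pixels inside the class color window.

    The 8-bit window is lifted into the 16-bit domain by x257 (matching the
    bit-depth normalization), and membership is the inclusive componentwise
    interval test on all three channels.
    """
    px = img.pixels if isinstance(img, OverlayImage) else np.asarray(img)
    lo = np.array(boundary.lower, dtype=np.uint32) * 257
    up = np.array(boundary.upper, dtype=np.uint32) * 257
    return np.all((px >= lo) & (px <= up), axis=-1)


def masked_grayscale(
    img: OverlayImage | np.ndarray, mask: np.ndarray, kernel: int = 3
) -> np.ndarray:
    """Luminance grayscale of the masked image, median smoothed.

    Pixels outside the mask are zeroed before smoothing, so only
    color-positive signal survives into edge detection.
    """
    px = img.pixels if isinstance(img, OverlayImage) else np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != px.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} != image shape {px.shape[:2]}")
    gray = luminance(px)
    gray[~mask] = 0
    return median_smooth(gray, kernel)


def canny_edges(
    gray: np.ndarray,
    t_min: float | None = None,
    t_max: float | None = None,
    sigma: float = 1.0,
) -> np.ndarray:
    """Canny edge map (Gaussian smoothing, Sobel gradient, non-maximum
    suppression, hysteresis between t_min and t_max).

    With thresholds left unset, the high threshold is the Otsu level of the
    Sobel gradient magnitude and the low threshold is half of it.
    """
    gray = np.asarray(gray, dtype=np.float32)
    if t_min is not None and t_max is not None and t_min >= t_max:
        raise ValueError("t_min must be below t_max")
    if t_min is None or t_max is None:
        gx = ndi.sobel(gray, axis=1, mode="nearest")
        gy = ndi.sobel(gray, axis=0, mode="nearest")
        mag = np.hypot(gx, gy)
        if mag.max() <= 0:
            return np.zeros(gray.shape, dtype=bool)
        high = float(threshold_otsu(mag))
        t_max = high if t_max is None else t_max
        t_min = high / 2.0 if t_min is None else t_min
        if t_min >= t_max:  # degenerate Otsu split
            t_min = t_max / 2.0
    return _skimage_canny(
        gray, sigma=sigma, low_threshold=t_min, high_threshold=t_max
    )


def _square(kernel: int) -> np.ndarray:
    return np.ones((kernel, kernel), dtype=bool)


def morph_dilate(mask: np.ndarray, kernel: int = 3, iters: int = 1) -> np.ndarray:
    """Minkowski dilation with a square structuring element."""
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    if iters < 1:
        return np.asarray(mask, dtype=bool)
    return ndi.binary_dilation(mask, structure=_square(kernel), iterations=iters)


def morph_erode(mask: np.ndarray, kernel: int = 3, iters: int = 1) -> np.ndarray:
    """Minkowski erosion with a square structuring element."""
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    if iters < 1:
        return np.asarray(mask, dtype=bool)
    return ndi.binary_erosion(mask, structure=_square(kernel), iterations=iters)


def fill_interior(mask: np.ndarray) -> np.ndarray:
    """Fill the interior of closed edge contours."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def segment_touching(
    mask: np.ndarray,
    params: ContourParams | None = None,
    intensity: np.ndarray | None = None,
) -> np.ndarray:
    """Split touching objects in a filled foreground mask by random walker.

    Markers are the local maxima of the Euclidean distance transform
    (minimum separation = radius of the smallest admissible cell); each
    multi-marker connected component is segmented by random-walker
    probabilities so every foreground pixel gets exactly one label.
    Single-marker components keep a single label, so the solver only runs
    where objects actually touch.
    """
    params = params or ContourParams()
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    comp, n_comp = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    slices = ndi.find_objects(comp)
    next_label = 1
    for ci, sl in enumerate(slices, start=1):
        sub = comp[sl] == ci
        dist = ndi.distance_transform_edt(sub)
        peaks = peak_local_max(
            dist,
            min_distance=params.marker_min_distance,
            labels=sub,
            exclude_border=False,
        )
        if len(peaks) <= 1:
            labels[sl][sub] = next_label
            next_label += 1
            continue
        markers = np.zeros(sub.shape, dtype=np.int32)
        markers[~sub] = -1
        for k, (pr, pc) in enumerate(peaks, start=1):
            markers[pr, pc] = k
        if intensity is not None:
            data = intensity[sl].astype(np.float64)
        else:
            data = dist
        span = data.max() - data.min()
        data = (data - data.min()) / span if span > 0 else np.zeros_like(data)
        try:
            rw = random_walker(data, markers, beta=params.rw_beta, mode="cg_j")
        except Exception:  # singular system on tiny crops: keep one object
            log.warning("random walker failed on a %s crop; keeping one label",
                        sub.shape)
            labels[sl][sub] = next_label
            next_label += 1
            continue
        for k in range(1, len(peaks) + 1):
            sel = sub & (rw == k)
            if sel.any():
                labels[sl][sel] = next_label
                next_label += 1
    return labels


def project_labels_to_mask(
    labels: np.ndarray, mask: np.ndarray, radius: float = 3.0
) -> np.ndarray:
    """Extend segmentation labels onto nearby color-mask pixels.

    Edge tracing and morphology localize objects to within a pixel or two of
    the fluorescence-positive region; the final pixel membership of each
    contour is the color mask itself, partitioned by the nearest label
    within ``radius`` px.  Mask pixels farther than that from any label
    (isolated speckle) are dropped.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    if not labels.any():
        return np.zeros(labels.shape, dtype=np.int32)
    dist, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    out = np.zeros(labels.shape, dtype=np.int32)
    take = mask & (dist <= radius)
    out[take] = labels[ir[take], ic[take]]
    return out


def _hull_boundary_xy(points_xy: np.ndarray) -> np.ndarray:
    hull = ConvexHull(points_xy)
    return points_xy[hull.vertices]


def _deepest_defect(points_xy: np.ndarray, hull_xy: np.ndarray) -> float:
    """Deepest deviation of boundary points from the convex hull (px)."""
    # distance from each point to the nearest hull edge; hull vertices -> 0
    depths = np.full(points_xy.shape[0], np.inf)
    n = hull_xy.shape[0]
    for i in range(n):
        p0, p1 = hull_xy[i], hull_xy[(i + 1) % n]
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        if seg_len2 == 0:
            d = np.hypot(*(points_xy - p0).T)
        else:
            t = np.clip(((points_xy - p0) @ seg) / seg_len2, 0.0, 1.0)
            proj = p0 + t[:, None] * seg
            d = np.hypot(*(points_xy - proj).T)
        depths = np.minimum(depths, d)
    return float(depths.max()) if depths.size else 0.0


def extract_contours(
    labels: np.ndarray,
    class_label: str,
    params: ContourParams | None = None,
    image_index: int = 0,
    offset: tuple[int, int] = (0, 0),
) -> list[Contour]:
    """One Contour per label: pixel set, area, centroid, traced boundary.

    The outer boundary is traced at the 0.5 iso-level of the label mask; if
    its deepest convexity defect exceeds ``hull_defect_depth``, the boundary
    polygon is replaced by the convex hull (pixel set and area unchanged).
    ``offset`` shifts reported coordinates when labels come from a crop.
    """
    params = params or ContourParams()
    labels = np.asarray(labels)
    out: list[Contour] = []
    if not labels.any():
        return out
    r_off, c_off = offset
    for val in np.unique(labels):
        if val == 0:
            continue
        sel = labels == val
        rows, cols = np.nonzero(sel)
        pixels = np.stack([rows + r_off, cols + c_off], axis=1)
        centroid = (float(cols.mean() + c_off), float(rows.mean() + r_off))
        # trace the outer boundary on a padded crop
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        crop = np.pad(sel[r0 : r1 + 1, c0 : c1 + 1], 1)
        traces = find_contours(crop.astype(float), 0.5)
        if traces:
            tr = max(traces, key=len)  # outer boundary = longest trace
            boundary = np.stack(
                [tr[:, 1] - 1 + c0 + c_off, tr[:, 0] - 1 + r0 + r_off], axis=1
            )
        else:
            boundary = np.array([[centroid[0], centroid[1]]])
        if boundary.shape[0] >= 4:
            try:
                hull = _hull_boundary_xy(boundary)
                if _deepest_defect(boundary, hull) > params.hull_defect_depth:
                    boundary = hull
            except (QhullError, ValueError):
                pass  # degenerate (collinear) boundary: keep the trace
        out.append(
            Contour(
                contour_id=len(out),
                class_label=class_label,
                pixels=pixels,
                centroid=centroid,
                boundary=boundary,
                image_index=image_index,
            )
        )
    return out


def filter_by_area(contours: list[Contour], min_area: int) -> list[Contour]:
    """Retain contours with area >= min_area (inclusive); log removals as debris."""
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    kept = [c for c in contours if c.area >= min_area]
    removed = len(contours) - len(kept)
    if removed:
        log.debug("area filter (>= %d px^2): removed %d debris contour(s)",
                  min_area, removed)
    return kept


def resolve_class_conflicts(
    per_class_sets: list[list[Contour]], merge_radius: float = 5.0
) -> list[Contour]:
    """Merge duplicate detections of one region across class passes.

    Contours from different passes whose centroids fall within
    ``merge_radius`` are the same physical object; the class precedence
    overlap > dead > live > eu_np > tb_np decides which detection survives.
    The result carries unique ids, ordered by centroid (y, x).
    """
    rank = {name: i for i, name in enumerate(CLASS_PRECEDENCE)}
    pool = [c for cs in per_class_sets for c in cs]
    pool.sort(key=lambda c: (rank.get(c.class_label, len(rank)),
                             c.centroid[1], c.centroid[0]))
    accepted: list[Contour] = []
    for c in pool:
        cx, cy = c.centroid
        if any(
            math.hypot(cx - a.centroid[0], cy - a.centroid[1]) < merge_radius
            for a in accepted
        ):
            continue
        accepted.append(c)
    accepted.sort(key=lambda c: (c.centroid[1], c.centroid[0]))
    for i, c in enumerate(accepted):
        c.contour_id = i
    return accepted


def detect_class_contours(
    img: OverlayImage,
    boundary: ColorBoundary,
    params: ContourParams | None = None,
    image_index: int = 0,
) -> list[Contour]:
    """Full per-class pass: mask, masked grayscale, Canny, dilation, erosion,
    fill, random-walker splitting, contour extraction.

    Processing after the full-frame color mask runs on padded bounding boxes
    of the mask's connected components — the fluorescent foreground is a
    small fraction of the frame, so this keeps the per-image cost
    proportional to the signal, not the sensor.  Area filtering is applied
    separately (`filter_by_area`) so debris removal stays observable.
    """
    params = params or ContourParams()
    mask = build_color_mask(img, boundary)
    if not mask.any():
        return []
    comp, n_comp = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    slices = ndi.find_objects(comp)
    pad = params.morph_kernel * max(params.dilate_iters, params.erode_iters) + 4
    h, w = mask.shape
    contours: list[Contour] = []
    for ci, sl in enumerate(slices, start=1):
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, h)
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, w)
        sub_mask = comp[r0:r1, c0:c1] == ci
        sub_img = img.pixels[r0:r1, c0:c1]
        gray = masked_grayscale(sub_img, sub_mask, kernel=3)
        edges = canny_edges(
            gray, params.canny_t_min, params.canny_t_max, sigma=params.canny_sigma
        )
        shaped = morph_erode(
            morph_dilate(edges, params.morph_kernel, params.dilate_iters),
            params.morph_kernel,
            params.erode_iters,
        )
        filled = fill_interior(shaped)
        labels = segment_touching(filled, params, intensity=None)
        labels = project_labels_to_mask(
            labels, sub_mask, radius=params.label_projection_radius
        )
        if not labels.any():
            # edge tracing lost a small/faint object entirely: fall back to
            # the color-mask component itself as a single region
            labels = sub_mask.astype(np.int32)
        contours.extend(
            extract_contours(
                labels,
                boundary.class_label,
                params,
                image_index=image_index,
                offset=(r0, c0),
            )
        )
    for i, c in enumerate(contours):
        c.contour_id = i
    return contours
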