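"""Per-contour intracellular fluorescence statistics.

For every detected cell the mean, minimum, maximum and variance of the
16-bit grayscale values inside its pixel set are tabulated (range
0-65535), the mean is normalized against an image-level background
estimate, and an 8-bit-binned (256-bin) histogram of the 16-bit values can
be produced for distribution inspection.

Intensity is measured on the fluorescence channel(s) that define the
contour's class window — e.g. the green channel for live/FAM signal, red
for RFP — not on the composite luminance, so single-channel uptake signals
are not diluted by the other channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour_detection import Contour
from .droplet_detection import DropletMap
from .image_io import OverlayImage

#: (B, G, R) weights of the fluorescence grayscale used per class.
CLASS_CHANNEL_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "live": (0.0, 1.0, 0.0),
    "dead": (0.0, 0.0, 1.0),
    "overlap": (0.0, 0.5, 0.5),
    "eu_np": (0.5, 0.0, 0.5),
    "tb_np": (1.0, 0.0, 0.0),
    "custom": (0.114, 0.587, 0.299),
}

FREE_FLOATING = -1


@dataclass
class IntensityRecord:
    """Intensity statistics of one contour (16-bit gray units)."""

    contour_id: int
    mean: float
    min: float
    max: float
    variance: float
    n_pixels: int
    normalized_mean: float = float("nan")
    droplet_id: int = FREE_FLOATING
    image_index: int = 0
    class_label: str = "custom"


@dataclass
class BackgroundModel:
    """Image-level background estimate used for normalization."""

    background_level: float
    method: str
    n_pixels_used: int

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.n_pixels_used <= 0:
            raise ValueError("background must be estimated from >= 1 pixel")


def fluorescence_gray(
    img: OverlayImage | np.ndarray, class_label: str = "custom"
) -> np.ndarray:
    """Class-specific fluorescence grayscale (float64, 16-bit scale)."""
    px = img.pixels if isinstance(img, OverlayImage) else np.asarray(img)
    wb, wg, wr = CLASS_CHANNEL_WEIGHTS.get(
        class_label, CLASS_CHANNEL_WEIGHTS["custom"]
    )
    return (
        wb * px[..., 0].astype(np.float64)
        + wg * px[..., 1].astype(np.float64)
        + wr * px[..., 2].astype(np.float64)
    )


def contour_intensity_stats(
    gray16: np.ndarray, contour: Contour, variance_mode: str = "population"
) -> IntensityRecord:
    """Mean / min / max / variance of the grayscale inside a contour.

    Variance is the population variance (divide by n) by default;
    ``variance_mode="sample"`` divides by n - 1 instead.
    """
    if contour.pixels.shape[0] == 0:
        raise ValueError("contour has an empty pixel set")
    rows, cols = contour.pixels[:, 0], contour.pixels[:, 1]
    h, w = np.asarray(gray16).shape
    if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
        raise ValueError("contour pixels fall outside the image")
    values = np.asarray(gray16, dtype=np.float64)[rows, cols]
    ddof = 0 if variance_mode == "population" else 1
    if variance_mode not in ("population", "sample"):
        raise ValueError("variance_mode must be 'population' or 'sample'")
    var = float(values.var(ddof=ddof)) if values.size > ddof else 0.0
    return IntensityRecord(
        contour_id=contour.contour_id,
        mean=float(values.mean()),
        min=float(values.min()),
        max=float(values.max()),
        variance=var,
        n_pixels=int(values.size),
        image_index=contour.image_index,
        class_label=contour.class_label,
    )


def estimate_background(
    gray16: np.ndarray, droplets: DropletMap, contours: list[Contour]
) -> BackgroundModel:
    """Median background: in-droplet pixels outside every contour.

    Falls back to the whole-image non-contour median when no droplets were
    detected.  Fails if nothing is eligible (the frame is wall-to-wall
    signal), since a background level of unknown provenance would silently
    corrupt every normalized value downstream.
    """
    gray = np.asarray(gray16, dtype=np.float64)
    h, w = gray.shape
    contour_mask = np.zeros((h, w), dtype=bool)
    for c in contours:
        contour_mask[c.pixels[:, 0], c.pixels[:, 1]] = True
    if len(droplets) > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        inside = np.zeros((h, w), dtype=bool)
        for d in droplets:
            # interior only: stay clear of the bright rim
            inside |= (xx - d.x) ** 2 + (yy - d.y) ** 2 <= (d.radius - 2) ** 2
        eligible = inside & ~contour_mask
        method = "median of in-droplet non-contour pixels"
    else:
        eligible = ~contour_mask
        method = "median of non-contour pixels (no droplets detected)"
    n = int(eligible.sum())
    if n == 0:
        raise ValueError("no pixels eligible for background estimation")
    return BackgroundModel(
        background_level=float(np.median(gray[eligible])),
        method=method,
        n_pixels_used=n,
    )


def normalize_intensity(
    record: IntensityRecord, bg: BackgroundModel, mode: str = "ratio"
) -> IntensityRecord:
    """Normalize the contour mean against the background level.

    ``ratio`` (default) divides by the background, making values unitless
    and comparable across experiments; ``subtract`` removes the background
    level instead.
    """
    if mode not in ("ratio", "subtract"):
        raise ValueError("mode must be 'ratio' or 'subtract'")
    if mode == "ratio":
        if bg.background_level <= 0:
            raise ValueError(
                "background level is zero; configure a noise floor or use "
                "mode='subtract'"
            )
        record.normalized_mean = record.mean / bg.background_level
    else:
        record.normalized_mean = record.mean - bg.background_level
    return record


def intensity_histogram(
    gray16: np.ndarray, contour: Contour
) -> tuple[np.ndarray, IntensityRecord]:
    """256-bin (8-bit-binned) histogram of the contour's 16-bit values.

    Bin ``k`` covers values ``[256 k, 256 (k + 1))`` so bin counts always
    sum to the contour pixel count; 0 falls in the first bin and 65535 in
    the last.  Returns the counts plus the 16-bit min/max/variance record
    used to annotate the plot.
    """
    record = contour_intensity_stats(gray16, contour)
    rows, cols = contour.pixels[:, 0], contour.pixels[:, 1]
    values = np.asarray(gray16, dtype=np.float64)[rows, cols]
    counts, _ = np.histogram(values, bins=256, range=(0.0, 65536.0))
    return counts, record
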