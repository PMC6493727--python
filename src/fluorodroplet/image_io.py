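"""Batch reading of microscopy image folders and tabular export of results.

Overlaid brightfield + fluorescence micrographs arrive as 8- or 16-bit
TIFF/PNG/GIF/JPEG/BMP files.  Everything downstream works in a single
16-bit, 3-channel (B, G, R) processing domain, so loaders normalize bit
depth (8-bit values are scaled by 257 so that 255 maps exactly to 65535)
and channel layout here, once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

#: Extensions the batch loader accepts (lower-case, no dot).
SUPPORTED_EXTENSIONS = frozenset({"tiff", "tif", "png", "gif", "jpeg", "jpg", "bmp"})


@dataclass
class OverlayImage:
    """A 16-bit, 3-channel (B, G, R) overlay micrograph.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array of ``uint16`` intensities in channel order B, G, R.
    source_path
        Where the image came from ("<synthetic>" for generated scenes).
    bit_depth_original
        Bit depth of the file on disk (8 or 16).
    """

    pixels: np.ndarray
    source_path: str = "<memory>"
    bit_depth_original: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint16:
            raise ValueError(f"pixels must be uint16, got {px.dtype}")
        if self.bit_depth_original not in (8, 16):
            raise ValueError("bit_depth_original must be 8 or 16")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ImageBatch:
    """An ordered (lexicographic by filename) list of overlay images."""

    images: list[OverlayImage] = field(default_factory=list)
    folder: str = ""

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    def __getitem__(self, i: int) -> OverlayImage:
        return self.images[i]


def normalize_bit_depth(raw_pixels: np.ndarray, depth: int) -> np.ndarray:
    """Map raw pixel data into the 16-bit processing domain.

    8-bit values ``v`` become ``v * 257`` so that 0 -> 0 and 255 -> 65535
    (the scaling preserves both extremes exactly, unlike ``v * 256``);
    16-bit data passes through unchanged.
    """
    raw = np.asarray(raw_pixels)
    if depth == 8:
        if raw.max(initial=0) > 255:
            raise ValueError("8-bit data contains values above 255")
        return (raw.astype(np.uint32) * 257).astype(np.uint16)
    if depth == 16:
        if raw.max(initial=0) > 65535:
            raise ValueError("16-bit data contains values above 65535")
        return raw.astype(np.uint16)
    raise ValueError(f"unsupported bit depth {depth}")


def _to_bgr3(arr: np.ndarray) -> np.ndarray:
    """Convert a decoded (RGB-native) array to H x W x 3 in B, G, R order."""
    if arr.ndim == 2:  # grayscale -> replicate
        return np.stack([arr, arr, arr], axis=-1)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            return arr[:, :, ::-1]  # RGB -> BGR
    raise ValueError(f"cannot interpret image of shape {arr.shape}")


def load_image(path: str | Path) -> OverlayImage:
    """Load a single image file as a 16-bit B,G,R overlay image.

    Animated GIFs contribute only their first frame; the analysis is
    single-frame throughout.
    """
    path = Path(path)
    ext = path.suffix.lower().lstrip(".")
    if ext in ("tiff", "tif"):
        arr = tifffile.imread(path)
    elif ext == "gif":
        arr = iio.imread(path, index=0)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 4:  # multi-frame container: first frame only
        arr = arr[0]
    depth = 8 if arr.dtype == np.uint8 else 16
    pixels = normalize_bit_depth(_to_bgr3(arr), depth)
    return OverlayImage(pixels=pixels, source_path=str(path), bit_depth_original=depth)


def load_image_batch(
    folder: str | Path, extensions: Iterable[str] | None = None
) -> ImageBatch:
    """Load every matching image in ``folder``, sorted lexicographically.

    Undecodable files are skipped with a warning; the call fails only if the
    folder is missing, no file matches, or every matching file fails to decode.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"input folder does not exist: {folder}")
    exts = {e.lower().lstrip(".") for e in (extensions or SUPPORTED_EXTENSIONS)}
    bad = exts - SUPPORTED_EXTENSIONS
    if bad:
        raise ValueError(f"unsupported extensions: {sorted(bad)}")
    paths = sorted(
        p for p in folder.iterdir()
        if p.is_file() and p.suffix.lower().lstrip(".") in exts
    )
    if not paths:
        raise FileNotFoundError(f"no images found in {folder}")
    images: list[OverlayImage] = []
    for p in paths:
        try:
            images.append(load_image(p))
        except Exception as exc:  # noqa: BLE001 - per-file skip is the contract
            log.warning("skipping undecodable file %s: %s", p, exc)
    if not images:
        raise RuntimeError(f"all {len(paths)} candidate images failed to decode")
    return ImageBatch(images=images, folder=str(folder))


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of a B,G,R image, rounded, as uint16."""
    px = np.asarray(pixels, dtype=np.float64)
    gray = 0.114 * px[..., 0] + 0.587 * px[..., 1] + 0.299 * px[..., 2]
    return np.rint(gray).astype(np.uint16)


def export_table(
    table: pd.DataFrame, path: str | Path, dialect: str = "csv"
) -> Path:
    """Write a result table as comma- (csv) or tab-delimited (txt) text.

    Floats are rendered with 6 significant digits so that read-back
    round-trips to that precision.  A header row is always written.
    """
    if dialect not in ("csv", "txt"):
        raise ValueError(f"dialect must be 'csv' or 'txt', got {dialect!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if dialect == "csv" else "\t"
    table.to_csv(path, sep=sep, index=False, float_format="%.6g")
    return path
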