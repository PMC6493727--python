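"""End-to-end batch pipeline: configuration, per-image processing, export.

Per image the stages are: load/normalize, grayscale + median smoothing,
CHT droplet detection, trap deduplication, per-class contour passes with
area thresholding and conflict resolution, contour-to-droplet assignment,
occupancy classification, and intensity quantification.  Images are
processed independently (no state is carried between frames), so per-image
rows are invariant to processing order and re-runs are byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contour_detection import (
    CELL_CLASSES,
    ColorBoundary,
    Contour,
    ContourParams,
    default_boundaries,
    detect_class_contours,
    filter_by_area,
    resolve_class_conflicts,
)
from .droplet_detection import DropletMap, DropletParams, detect_droplets
from .encapsulation import (
    EncapsulationRecord,
    PopulationSummary,
    assign_contours_to_droplets,
    classify_occupancy,
    co_encapsulation_table,
)
from .image_io import OverlayImage, export_table, load_image_batch, luminance
from .intensity_quant import (
    FREE_FLOATING,
    IntensityRecord,
    contour_intensity_stats,
    estimate_background,
    fluorescence_gray,
    normalize_intensity,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one batch run."""

    input_dir: str = ""
    output_dir: str = "fluorodroplet_out"
    extensions: list[str] = field(
        default_factory=lambda: ["tiff", "tif", "png", "gif", "jpeg", "jpg", "bmp"]
    )
    droplet: DropletParams = field(default_factory=DropletParams)
    contour: ContourParams = field(default_factory=ContourParams)
    boundaries: dict[str, ColorBoundary] = field(default_factory=default_boundaries)
    variance_mode: str = "population"
    normalize_mode: str = "ratio"
    export_dialect: str = "csv"
    debug_overlays: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.variance_mode not in ("population", "sample"):
            raise ValueError("variance_mode must be 'population' or 'sample'")
        if self.normalize_mode not in ("ratio", "subtract"):
            raise ValueError("normalize_mode must be 'ratio' or 'subtract'")
        if self.export_dialect not in ("csv", "txt"):
            raise ValueError("export_dialect must be 'csv' or 'txt'")


_DROPLET_KEYS = {
    "microns_per_pixel": "microns_per_pixel",
    "r_min_um": "r_min_um",
    "r_max_um": "r_max_um",
    "median_kernel": "median_kernel",
    "vote_threshold_frac": "vote_threshold_frac",
    "radius_step": "radius_step",
    "min_center_distance": "min_center_distance",
    "trap_spacing_um": "trap_spacing_um",
    "trap_tol_um": "trap_spacing_tol_um",
    "validate_lattice": "validate_lattice",
}
_CONTOUR_KEYS = {
    "canny_t_min": "canny_t_min",
    "canny_t_max": "canny_t_max",
    "canny_sigma": "canny_sigma",
    "morph_kernel": "morph_kernel",
    "dilate_iters": "dilate_iters",
    "erode_iters": "erode_iters",
    "min_area_cell": "min_area_cell",
    "min_area_np": "min_area_np",
    "hull_defect_depth": "hull_defect_depth",
    "merge_radius": "merge_radius",
    "rw_beta": "rw_beta",
}
_TOP_KEYS = {
    "input_dir", "output_dir", "extensions", "variance_mode",
    "normalize_mode", "export_dialect", "debug_overlays", "log_level",
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file; unset keys take the documented
    defaults (25/50 um radii, 130/150 px^2 areas, published color windows,
    360 um trap pitch).  Unknown keys warn; invalid values raise."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a YAML mapping")
    if overrides:
        data.update(overrides)

    droplet_kwargs, contour_kwargs, top_kwargs = {}, {}, {}
    boundaries = default_boundaries()
    for key, value in data.items():
        if key in _DROPLET_KEYS:
            droplet_kwargs[_DROPLET_KEYS[key]] = value
        elif key in _CONTOUR_KEYS:
            contour_kwargs[_CONTOUR_KEYS[key]] = value
        elif key in _TOP_KEYS:
            top_kwargs[key] = value
        elif key == "boundaries":
            if not isinstance(value, dict):
                raise ValueError("'boundaries' must map class -> {lower, upper}")
            boundaries = {}
            for cls, spec in value.items():
                boundaries[cls] = ColorBoundary(
                    cls, tuple(spec["lower"]), tuple(spec["upper"])
                )
        else:
            log.warning("unknown config key %r ignored", key)
    try:
        return RunConfig(
            droplet=DropletParams(**droplet_kwargs),
            contour=ContourParams(**contour_kwargs),
            boundaries=boundaries,
            **top_kwargs,
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


@dataclass
class ImageResult:
    """Everything the pipeline extracted from one image."""

    image_index: int
    source_path: str
    droplet_map: DropletMap
    contours: list[Contour]
    records: list[EncapsulationRecord]
    free_contour_ids: list[int]
    summary: PopulationSummary
    intensity: list[IntensityRecord]
    elapsed_s: float = 0.0


def process_image(
    img: OverlayImage, config: RunConfig | None = None, image_index: int = 0
) -> ImageResult:
    """Run the full pipeline on one overlay image."""
    config = config or RunConfig()
    t0 = time.perf_counter()

    gray = luminance(img.pixels)
    droplet_map = detect_droplets(gray, config.droplet, image_index=image_index)

    per_class: list[list[Contour]] = []
    for cls in sorted(config.boundaries):
        boundary = config.boundaries[cls]
        contours = detect_class_contours(
            img, boundary, config.contour, image_index=image_index
        )
        contours = filter_by_area(contours, config.contour.min_area_for(cls))
        per_class.append(contours)
    contours = resolve_class_conflicts(per_class, config.contour.merge_radius)

    records, free_ids = assign_contours_to_droplets(droplet_map, contours)
    records, summary = classify_occupancy(records, n_free_contours=len(free_ids))

    contour_droplet: dict[int, int] = {}
    for rec in records:
        for cid, _ in rec.contained_contours:
            contour_droplet[cid] = rec.droplet_id

    intensity: list[IntensityRecord] = []
    bg_cache: dict[str, object] = {}
    gray_cache: dict[str, np.ndarray] = {}
    for c in contours:
        cls = c.class_label
        if cls not in gray_cache:
            gray_cache[cls] = fluorescence_gray(img, cls)
        fgray = gray_cache[cls]
        rec = contour_intensity_stats(fgray, c, variance_mode=config.variance_mode)
        rec.droplet_id = contour_droplet.get(c.contour_id, FREE_FLOATING)
        if cls not in bg_cache:
            try:
                bg_cache[cls] = estimate_background(fgray, droplet_map, contours)
            except ValueError:
                bg_cache[cls] = None
        bg = bg_cache[cls]
        if bg is not None:
            rec = normalize_intensity(rec, bg, mode=config.normalize_mode)
        intensity.append(rec)

    elapsed = time.perf_counter() - t0
    log.info(
        "image %d: %d droplets | live %d dead %d overlap %d | SCE %d MCE %d | "
        "free %d | %.2f s",
        image_index, summary.n_droplets, summary.n_live, summary.n_dead,
        summary.n_overlap, summary.n_sce, summary.n_mce,
        summary.n_free_contours, elapsed,
    )
    return ImageResult(
        image_index=image_index,
        source_path=img.source_path,
        droplet_map=droplet_map,
        contours=contours,
        records=records,
        free_contour_ids=free_ids,
        summary=summary,
        intensity=intensity,
        elapsed_s=elapsed,
    )


def results_tables(results: list[ImageResult]) -> dict[str, pd.DataFrame]:
    """Collect per-image results into the five output tables."""
    drop_rows, cont_rows, enc_rows, int_rows, sum_rows = [], [], [], [], []
    total = PopulationSummary()
    for res in results:
        for d in res.droplet_map:
            drop_rows.append(
                {"image_index": res.image_index, "droplet_id": d.droplet_id,
                 "x": d.x, "y": d.y, "radius_px": d.radius, "votes": d.votes}
            )
        free = set(res.free_contour_ids)
        cmap = {
            cid: rec.droplet_id
            for rec in res.records
            for cid, _ in rec.contained_contours
        }
        for c in res.contours:
            cont_rows.append(
                {"image_index": res.image_index, "contour_id": c.contour_id,
                 "class_label": c.class_label, "area": c.area,
                 "x": c.centroid[0], "y": c.centroid[1],
                 "droplet_id": cmap.get(c.contour_id, FREE_FLOATING),
                 "free_floating": c.contour_id in free}
            )
        enc = co_encapsulation_table(res.records)
        enc_rows.append(enc)
        for r in res.intensity:
            int_rows.append(
                {"image_index": res.image_index, "contour_id": r.contour_id,
                 "class_label": r.class_label, "droplet_id": r.droplet_id,
                 "n_pixels": r.n_pixels, "mean": r.mean, "min": r.min,
                 "max": r.max, "variance": r.variance,
                 "normalized_mean": r.normalized_mean}
            )
        s = res.summary
        sum_rows.append(
            {"image_index": res.image_index, "n_droplets": s.n_droplets,
             "n_empty": s.n_empty, "n_sce": s.n_sce, "n_mce": s.n_mce,
             "n_live": s.n_live, "n_dead": s.n_dead, "n_overlap": s.n_overlap,
             "n_eu_np": s.n_eu_np, "n_tb_np": s.n_tb_np,
             "n_free_contours": s.n_free_contours, "n_tracked": s.n_tracked,
             "viability": s.viability}
        )
        total = total + s
    sum_rows.append(
        {"image_index": "total", "n_droplets": total.n_droplets,
         "n_empty": total.n_empty, "n_sce": total.n_sce, "n_mce": total.n_mce,
         "n_live": total.n_live, "n_dead": total.n_dead,
         "n_overlap": total.n_overlap, "n_eu_np": total.n_eu_np,
         "n_tb_np": total.n_tb_np, "n_free_contours": total.n_free_contours,
         "n_tracked": total.n_tracked, "viability": total.viability}
    )
    enc_df = (
        pd.concat(enc_rows, ignore_index=True)
        if enc_rows
        else co_encapsulation_table([])
    )
    return {
        "droplets": pd.DataFrame(
            drop_rows, columns=["image_index", "droplet_id", "x", "y",
                                "radius_px", "votes"]
        ),
        "contours": pd.DataFrame(
            cont_rows, columns=["image_index", "contour_id", "class_label",
                                "area", "x", "y", "droplet_id", "free_floating"]
        ),
        "encapsulation": enc_df,
        "intensity": pd.DataFrame(
            int_rows, columns=["image_index", "contour_id", "class_label",
                               "droplet_id", "n_pixels", "mean", "min", "max",
                               "variance", "normalized_mean"]
        ),
        "summary": pd.DataFrame(sum_rows),
    }


def _save_debug_overlay(img: OverlayImage, res: ImageResult, path: Path) -> None:
    """8-bit overlay PNG: droplet rims green, centers orange, contours outlined."""
    import imageio.v3 as iio
    from skimage.draw import circle_perimeter, disk as draw_disk

    rgb = (img.pixels[:, :, ::-1] // 257).astype(np.uint8)
    h, w = rgb.shape[:2]
    for d in res.droplet_map:
        rr, cc = circle_perimeter(d.y, d.x, d.radius, shape=(h, w))
        rgb[rr, cc] = (0, 255, 0)
        rr, cc = draw_disk((d.y, d.x), 3, shape=(h, w))
        rgb[rr, cc] = (255, 165, 0)
    outline = {"live": (255, 0, 0), "dead": (0, 0, 255), "overlap": (160, 32, 240),
               "eu_np": (255, 255, 0), "tb_np": (255, 165, 0)}
    for c in res.contours:
        color = outline.get(c.class_label, (255, 255, 255))
        pts = np.rint(c.boundary).astype(int)
        rr = np.clip(pts[:, 1], 0, h - 1)
        cc = np.clip(pts[:, 0], 0, w - 1)
        rgb[rr, cc] = color
    iio.imwrite(path, rgb)


def run_pipeline(config: RunConfig) -> list[ImageResult]:
    """Process a folder of images and write the output tables.

    Writes droplets / contours / encapsulation / intensity / summary tables
    into ``config.output_dir``.  Raises on fatal errors (missing folder,
    empty batch, invalid parameters); callers map these to exit codes.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    batch = load_image_batch(config.input_dir, config.extensions)
    log.info("loaded %d images from %s", len(batch), config.input_dir)
    results = [
        process_image(img, config, image_index=i) for i, img in enumerate(batch)
    ]
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if config.export_dialect == "csv" else "txt"
    for name, table in results_tables(results).items():
        export_table(table, out_dir / f"{name}.{ext}", config.export_dialect)
    if config.debug_overlays:
        dbg = out_dir / "overlays"
        dbg.mkdir(exist_ok=True)
        for res, img in zip(results, batch):
            _save_debug_overlay(img, res, dbg / f"overlay_{res.image_index:04d}.png")
    return results
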