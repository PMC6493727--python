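"""Ground-truthed synthetic droplet-array scenes.

The generator emulates the imaging side of a droplet trapping array:
aqueous droplets (bright brightfield rims, radius 25-50 um) sit on a
hexagonal trap lattice with 360 um pitch; fluorescent cells, nanoparticle
clusters and sub-threshold debris are rendered as filled colored disks
inside (or, for free-floating cells, outside) the droplets; Gaussian read
noise is added and the frame is quantized to 16-bit.  Every placement is
recorded in a ground-truth table so each pipeline stage can be scored
exactly.

Object colors are drawn from the interior 50% of each class's 8-bit color
window, further clipped to the sub-region that no other class window
covers, so class assignment of a rendered object is unambiguous (real
fluorophores are spectrally separated the same way; windows that overlap
on paper never overlap in signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contour_detection import CELL_CLASSES, DEFAULT_BOUNDARIES, NP_CLASSES
from .image_io import OverlayImage, export_table
from .intensity_quant import CLASS_CHANNEL_WEIGHTS

#: 8-bit (B, G, R) sampling boxes per class: interior 50% of the class
#: window, clipped where windows overlap so each color maps to one class.
CLASS_RENDER_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "live": ((38, 115), (102, 204), (38, 50)),
    "dead": ((38, 50), (38, 50), (102, 204)),
    "overlap": ((38, 115), (103, 204), (102, 204)),
    "eu_np": ((154, 204), (26, 76), (102, 204)),
    "tb_np": ((102, 204), (13, 38), (13, 38)),
}


@dataclass
class SceneSpec:
    """Study conditions of one synthetic scene (lengths in um, areas in px^2)."""

    image_size: tuple[int, int] = (1024, 1024)
    microns_per_pixel: float = 1.0
    trap_spacing_um: float = 360.0
    trap_radius_um: float = 35.0
    droplet_radius_range_um: tuple[float, float] = (25.0, 50.0)
    occupancy_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.2, 1: 0.5, 2: 0.2, 3: 0.1}
    )
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"live": 0.6, "dead": 0.3, "overlap": 0.1}
    )
    np_class_mix: dict[str, float] = field(
        default_factory=lambda: {"eu_np": 0.5, "tb_np": 0.5}
    )
    co_encapsulation_rate: float = 0.0
    cell_area_mean: float = 140.0
    cell_area_sd: float = 10.0
    cell_area_floor: int = 132
    np_area_mean: float = 170.0
    np_area_sd: float = 10.0
    np_area_floor: int = 152
    debris_rate: float = 0.4
    debris_area_range: tuple[int, int] = (20, 90)
    free_cell_rate: float = 0.05
    background_level: float = 5000.0
    droplet_interior_offset: float = 800.0
    rim_level: float = 45000.0
    rim_thickness: float = 3.0
    noise_sigma: float = 800.0
    max_traps: int | None = None  # cap the lattice at its first N sites
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (
            ("occupancy_distribution", self.occupancy_distribution),
            ("class_mix", self.class_mix),
            ("np_class_mix", self.np_class_mix),
        ):
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} probabilities must sum to 1 (got {total})")
        lo, hi = self.droplet_radius_range_um
        if not 0 < lo < hi:
            raise ValueError("droplet radius range must satisfy 0 < min < max")
        if self.debris_area_range[1] >= self.cell_area_floor:
            raise ValueError("debris areas must stay below the cell area floor")

    @property
    def r_min_px(self) -> int:
        return int(round(self.droplet_radius_range_um[0] / self.microns_per_pixel))

    @property
    def r_max_px(self) -> int:
        return int(round(self.droplet_radius_range_um[1] / self.microns_per_pixel))

    @property
    def trap_spacing_px(self) -> float:
        return self.trap_spacing_um / self.microns_per_pixel


@dataclass
class TruthObject:
    """One rendered object: a cell, an NP cluster, or debris."""

    kind: str  # cell | np | debris
    class_label: str
    x: float
    y: float
    area: int
    droplet_id: int  # -1 when free-floating
    true_mean_intensity: float


@dataclass
class GroundTruth:
    """Everything the generator placed in one scene."""

    droplets: list[tuple[int, int, int]] = field(default_factory=list)  # (x, y, r)
    objects: list[TruthObject] = field(default_factory=list)
    image_index: int = 0

    def cells(self, in_droplet_only: bool = True) -> list[TruthObject]:
        return [
            o for o in self.objects
            if o.kind == "cell" and (not in_droplet_only or o.droplet_id >= 0)
        ]

    def nps(self) -> list[TruthObject]:
        return [o for o in self.objects if o.kind == "np"]

    def class_counts(self) -> dict[str, int]:
        """In-droplet cell/NP counts per class."""
        counts: dict[str, int] = {}
        for o in self.objects:
            if o.kind in ("cell", "np") and o.droplet_id >= 0:
                counts[o.class_label] = counts.get(o.class_label, 0) + 1
        return counts

    def occupancy_counts(self) -> dict[str, int]:
        per_droplet = self._per_droplet()
        out = {"empty": 0, "single_cell": 0, "multi_cell": 0}
        for cells, _ in per_droplet.values():
            key = "empty" if cells == 0 else "single_cell" if cells == 1 else "multi_cell"
            out[key] += 1
        return out

    def subpopulation_counts(self) -> dict[str, int]:
        per_droplet = self._per_droplet()
        out = {"empty": 0, "cell_only": 0, "np_only": 0, "co_sc": 0, "co_mc": 0}
        for cells, nps in per_droplet.values():
            if cells == 0 and nps == 0:
                out["empty"] += 1
            elif cells > 0 and nps == 0:
                out["cell_only"] += 1
            elif cells == 0:
                out["np_only"] += 1
            elif cells == 1:
                out["co_sc"] += 1
            else:
                out["co_mc"] += 1
        return out

    def _per_droplet(self) -> dict[int, tuple[int, int]]:
        per: dict[int, tuple[int, int]] = {i: (0, 0) for i in range(len(self.droplets))}
        for o in self.objects:
            if o.droplet_id < 0 or o.kind == "debris":
                continue
            c, n = per[o.droplet_id]
            per[o.droplet_id] = (c + 1, n) if o.kind == "cell" else (c, n + 1)
        return per


def _lattice_sites(spec: SceneSpec) -> list[tuple[int, int]]:
    """Hexagonal trap centers that fit the frame with a full-droplet margin."""
    h, w = spec.image_size
    margin = spec.r_max_px + int(spec.rim_thickness) + 5
    dy = spec.trap_spacing_px * math.sin(math.pi / 3.0)
    sites: list[tuple[int, int]] = []
    row = 0
    y = float(margin)
    while y <= h - margin:
        x0 = margin + (spec.trap_spacing_px / 2.0 if row % 2 else 0.0)
        x = x0
        while x <= w - margin:
            sites.append((int(round(x)), int(round(y))))
            x += spec.trap_spacing_px
        y += dy
        row += 1
    return sites


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    sel = dy * dy + dx * dx <= radius * radius
    return np.stack([dy[sel], dx[sel]], axis=1)


def _disk_for_area(target_area: float, floor: int) -> np.ndarray:
    """Pixel offsets of a rasterized disk with >= floor pixels, near target_area."""
    radius = math.sqrt(target_area / math.pi)
    offs = _disk_offsets(radius)
    while offs.shape[0] < floor:
        radius += 0.15
        offs = _disk_offsets(radius)
    return offs

def _sample_color(rng: np.random.Generator, class_label: str) -> np.ndarray:
    """16-bit B,G,R color drawn from the class render box."""
    box = CLASS_RENDER_RANGES[class_label]
    color8 = np.array([rng.uniform(lo, hi) for lo, hi in box])
    return color8 * 257.0


def _true_mean(color16: np.ndarray, class_label: str) -> float:
    w = np.array(CLASS_CHANNEL_WEIGHTS[class_label])
    return float(w @ color16)


def _choice(rng: np.random.Generator, probs: dict) -> object:
    keys = sorted(probs.keys(), key=str)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate_scene(spec: SceneSpec, image_index: int = 0) -> tuple[OverlayImage, GroundTruth]:
    """Render one scene and its ground truth; fully determined by spec.seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    sites = _lattice_sites(spec)
    if spec.max_traps is not None:
        sites = sites[: spec.max_traps]
    if not sites:
        raise ValueError(
            f"trap lattice (pitch {spec.trap_spacing_px:.0f} px) does not fit a "
            f"{h}x{w} image"
        )
    img = np.full((h, w, 3), spec.background_level, dtype=np.float32)
    truth = GroundTruth(image_index=image_index)
    placed: list[tuple[float, float, float]] = []  # (y, x, object radius)
    min_gap = 5.0

    # droplets: dark-ish interior disk plus a bright rim annulus at radius R
    droplet_geom: list[tuple[int, int, int]] = []
    for cx, cy in sites:
        radius = int(rng.integers(spec.r_min_px, spec.r_max_px + 1))
        droplet_geom.append((cx, cy, radius))
        truth.droplets.append((cx, cy, radius))
        half = spec.rim_thickness / 2.0
        offs = _disk_offsets(radius + half)
        d = np.hypot(offs[:, 0], offs[:, 1])
        rows, cols = offs[:, 0] + cy, offs[:, 1] + cx
        interior = d <= radius - half
        rim = d > radius - half
        img[rows[interior], cols[interior]] = (
            spec.background_level + spec.droplet_interior_offset
        )
        img[rows[rim], cols[rim]] = spec.rim_level

    def try_place(offs: np.ndarray, inside_of: tuple[int, int, int] | None,
                  max_tries: int = 200) -> tuple[int, int] | None:
        obj_r = math.sqrt(offs.shape[0] / math.pi)
        for _ in range(max_tries):
            if inside_of is not None:
                dx_, dy_, dr = inside_of
                rad = dr - obj_r - spec.rim_thickness - 4.0
                if rad <= 1:
                    return None
                rho = math.sqrt(rng.uniform(0, 1)) * rad
                phi = rng.uniform(0, 2 * math.pi)
                px, py = dx_ + rho * math.cos(phi), dy_ + rho * math.sin(phi)
            else:
                px = rng.uniform(10 + obj_r, w - 10 - obj_r)
                py = rng.uniform(10 + obj_r, h - 10 - obj_r)
                # stay clear of every droplet (rim included)
                if any(
                    math.hypot(px - gx, py - gy) < gr + obj_r + 8
                    for gx, gy, gr in droplet_geom
                ):
                    continue
            px, py = int(round(px)), int(round(py))
            if all(
                math.hypot(py - qy, px - qx) >= obj_r + qr + min_gap
                for qy, qx, qr in placed
            ):
                placed.append((py, px, obj_r))
                return px, py
        return None

    def render_object(kind: str, class_label: str, area_mean: float,
                      area_sd: float, floor: int,
                      droplet: tuple[int, int, int] | None,
                      droplet_id: int) -> None:
        target = rng.normal(area_mean, area_sd)
        target = min(max(target, float(floor)), area_mean + 3 * area_sd)
        offs = _disk_for_area(target, floor)
        pos = try_place(offs, droplet)
        if pos is None:
            return
        px, py = pos
        color = _sample_color(rng, class_label)
        img[offs[:, 0] + py, offs[:, 1] + px] = color
        truth.objects.append(
            TruthObject(
                kind=kind,
                class_label=class_label,
                x=float(px),
                y=float(py),
                area=int(offs.shape[0]),
                droplet_id=droplet_id,
                true_mean_intensity=_true_mean(color, class_label),
            )
        )

    for did, geom in enumerate(droplet_geom):
        n_cells = int(_choice(rng, spec.occupancy_distribution))
        for _ in range(n_cells):
            cls = str(_choice(rng, spec.class_mix))
            render_object("cell", cls, spec.cell_area_mean, spec.cell_area_sd,
                          spec.cell_area_floor, geom, did)
        if spec.co_encapsulation_rate > 0 and rng.uniform() < spec.co_encapsulation_rate:
            n_np = 1 if rng.uniform() < 0.7 else 2
            for _ in range(n_np):
                cls = str(_choice(rng, spec.np_class_mix))
                render_object("np", cls, spec.np_area_mean, spec.np_area_sd,
                              spec.np_area_floor, geom, did)
        if rng.uniform() < spec.debris_rate:
            cls = str(_choice(rng, spec.class_mix))
            lo, hi = spec.debris_area_range
            area = float(rng.integers(lo, hi + 1))
            offs = _disk_for_area(area, floor=max(5, int(lo)))
            pos = try_place(offs, geom)
            if pos is not None:
                px, py = pos
                color = _sample_color(rng, cls)
                img[offs[:, 0] + py, offs[:, 1] + px] = color
                truth.objects.append(
                    TruthObject("debris", cls, float(px), float(py),
                                int(offs.shape[0]), did, _true_mean(color, cls))
                )

    n_free = rng.poisson(spec.free_cell_rate * len(droplet_geom))
    for _ in range(int(n_free)):
        cls = str(_choice(rng, spec.class_mix))
        render_object("cell", cls, spec.cell_area_mean, spec.cell_area_sd,
                      spec.cell_area_floor, None, -1)

    if spec.noise_sigma > 0:
        img += rng.standard_normal(img.shape, dtype=np.float32) * spec.noise_sigma
    pixels = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return (
        OverlayImage(pixels=pixels, source_path="<synthetic>", bit_depth_original=16),
        truth,
    )


def generate_batch(
    spec: SceneSpec, n_images: int, base_seed: int | None = None
) -> tuple[list[OverlayImage], list[GroundTruth]]:
    """Generate a folder-like batch; image i uses seed base_seed + i."""
    base = spec.seed if base_seed is None else base_seed
    images, truths = [], []
    for i in range(n_images):
        img, truth = generate_scene(replace(spec, seed=base + i), image_index=i)
        images.append(img)
        truths.append(truth)
    return images, truths


def truth_tables(truths: list[GroundTruth]) -> dict[str, pd.DataFrame]:
    """Ground truth as tables mirroring the pipeline output schemas."""
    drop_rows, obj_rows, sum_rows = [], [], []
    for t in truths:
        for did, (x, y, r) in enumerate(t.droplets):
            drop_rows.append(
                {"image_index": t.image_index, "droplet_id": did,
                 "x": x, "y": y, "radius_px": r}
            )
        for o in t.objects:
            obj_rows.append(
                {"image_index": t.image_index, "kind": o.kind,
                 "class_label": o.class_label, "x": o.x, "y": o.y,
                 "area": o.area, "droplet_id": o.droplet_id,
                 "true_mean_intensity": o.true_mean_intensity}
            )
        occ = t.occupancy_counts()
        cls = t.class_counts()
        sum_rows.append(
            {"image_index": t.image_index, "n_droplets": len(t.droplets),
             "n_empty": occ["empty"], "n_sce": occ["single_cell"],
             "n_mce": occ["multi_cell"],
             **{f"n_{name}": cls.get(name, 0)
                for name in ("live", "dead", "overlap", "eu_np", "tb_np")}}
        )
    return {
        "droplets": pd.DataFrame(
            drop_rows, columns=["image_index", "droplet_id", "x", "y", "radius_px"]
        ),
        "objects": pd.DataFrame(
            obj_rows, columns=["image_index", "kind", "class_label", "x", "y",
                               "area", "droplet_id", "true_mean_intensity"]
        ),
        "summary": pd.DataFrame(
            sum_rows, columns=["image_index", "n_droplets", "n_empty", "n_sce",
                               "n_mce", "n_live", "n_dead", "n_overlap",
                               "n_eu_np", "n_tb_np"]
        ),
    }


def write_truth(
    truths: GroundTruth | list[GroundTruth], out_dir: str | Path
) -> dict[str, Path]:
    """Write ground-truth CSVs (droplets / objects / summary) for comparison."""
    if isinstance(truths, GroundTruth):
        truths = [truths]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in truth_tables(truths).items():
        paths[name] = export_table(table, out_dir / f"truth_{name}.csv", "csv")
    return paths


def _agreement(auto: float, true: float) -> float:
    """Percent count agreement, 100 * (1 - |auto - true| / true), clipped at 0."""
    if true == 0:
        return 100.0 if auto == 0 else 0.0
    return max(0.0, 100.0 * (1.0 - abs(auto - true) / true))


@dataclass
class AgreementReport:
    """Pipeline-vs-truth scores for one image set."""

    categories: dict[str, tuple[int, int, float]]  # name -> (truth, auto, agreement)
    precision: dict[str, float]
    recall: dict[str, float]
    intensity_similarity: float
    n_matched_cells: int
    n_true_cells: int
    n_true_droplets: int

    def agreement(self, name: str) -> float:
        return self.categories[name][2]

    def mean_agreement(self, names: list[str] | None = None) -> float:
        names = names or list(self.categories)
        return float(np.mean([self.categories[n][2] for n in names]))


def _greedy_match(
    truth_pts: np.ndarray, auto_pts: np.ndarray, match_radius: float
) -> list[tuple[int, int]]:
    """Greedy nearest-pair matching within match_radius; returns index pairs."""
    if len(truth_pts) == 0 or len(auto_pts) == 0:
        return []
    d = np.hypot(
        truth_pts[:, None, 0] - auto_pts[None, :, 0],
        truth_pts[:, None, 1] - auto_pts[None, :, 1],
    )
    pairs: list[tuple[int, int]] = []
    d = d.copy()
    while True:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > match_radius:
            break
        pairs.append((int(i), int(j)))
        d[i, :] = np.inf
        d[:, j] = np.inf
        if np.isinf(d).all():
            break
    return pairs


def score_against_truth(
    results: list, truths: list[GroundTruth], match_radius: float = 6.0
) -> AgreementReport:
    """Score pipeline outputs against ground truth over an image set.

    ``results`` are per-image pipeline results (aligned with ``truths``)
    carrying ``contours``, ``records``, ``summary`` and ``intensity``
    attributes.  Counts are compared per category with the percent-agreement
    formula 100*(1-|auto-truth|/truth); objects are additionally matched by
    class and centroid proximity for precision/recall, and matched cells are
    compared on mean intensity.
    """
    from .encapsulation import subpopulation_counts  # local: avoid cycle at import

    if len(results) != len(truths):
        raise ValueError("results and truths must be aligned, one per image")

    truth_tot: dict[str, int] = {}
    auto_tot: dict[str, int] = {}

    def bump(d: dict[str, int], key: str, n: int) -> None:
        d[key] = d.get(key, 0) + n

    match_per_class: dict[str, int] = {}
    truth_per_class: dict[str, int] = {}
    auto_per_class: dict[str, int] = {}
    intensity_scores: list[float] = []
    n_true_cells = 0

    for res, truth in zip(results, truths):
        bump(truth_tot, "droplets", len(truth.droplets))
        bump(auto_tot, "droplets", res.droplet_map.n_droplets)
        occ = truth.occupancy_counts()
        bump(truth_tot, "sce", occ["single_cell"])
        bump(truth_tot, "mce", occ["multi_cell"])
        bump(truth_tot, "empty", occ["empty"])
        bump(auto_tot, "sce", res.summary.n_sce)
        bump(auto_tot, "mce", res.summary.n_mce)
        bump(auto_tot, "empty", res.summary.n_empty)
        cls_counts = truth.class_counts()
        for name in ("live", "dead", "overlap", "eu_np", "tb_np"):
            bump(truth_tot, name, cls_counts.get(name, 0))
            bump(auto_tot, name, getattr(res.summary, f"n_{name}"))
        for key, n in truth.subpopulation_counts().items():
            bump(truth_tot, f"subpop_{key}", n)
        for key, n in subpopulation_counts(res.records).items():
            bump(auto_tot, f"subpop_{key}", n)

        # object-level matching, per class
        auto_mean = {r.contour_id: r.mean for r in res.intensity}
        for cls in sorted({o.class_label for o in truth.objects if o.kind != "debris"}):
            t_objs = [o for o in truth.objects
                      if o.class_label == cls and o.kind != "debris"]
            a_objs = [c for c in res.contours if c.class_label == cls]
            t_pts = np.array([[o.x, o.y] for o in t_objs], dtype=float).reshape(-1, 2)
            a_pts = np.array([[c.centroid[0], c.centroid[1]] for c in a_objs],
                             dtype=float).reshape(-1, 2)
            pairs = _greedy_match(t_pts, a_pts, match_radius)
            bump(match_per_class, cls, len(pairs))
            bump(truth_per_class, cls, len(t_objs))
            bump(auto_per_class, cls, len(a_objs))
            if cls in CELL_CLASSES:
                n_true_cells += len(t_objs)
                for ti, ai in pairs:
                    true_mu = t_objs[ti].true_mean_intensity
                    auto_mu = auto_mean.get(a_objs[ai].contour_id)
                    if auto_mu is not None and true_mu > 0:
                        intensity_scores.append(
                            max(0.0, 100.0 * (1.0 - abs(auto_mu - true_mu) / true_mu))
                        )

    categories = {
        name: (truth_tot.get(name, 0), auto_tot.get(name, 0),
               _agreement(auto_tot.get(name, 0), truth_tot.get(name, 0)))
        for name in sorted(set(truth_tot) | set(auto_tot))
    }
    precision = {
        cls: (match_per_class.get(cls, 0) / auto_per_class[cls]
              if auto_per_class.get(cls) else 0.0)
        for cls in auto_per_class
    }
    recall = {
        cls: (match_per_class.get(cls, 0) / truth_per_class[cls]
              if truth_per_class.get(cls) else 0.0)
        for cls in truth_per_class
    }
    return AgreementReport(
        categories=categories,
        precision=precision,
        recall=recall,
        intensity_similarity=(
            float(np.mean(intensity_scores)) if intensity_scores else float("nan")
        ),
        n_matched_cells=len(intensity_scores),
        n_true_cells=n_true_cells,
        n_true_droplets=truth_tot.get("droplets", 0),
    )


# ---------------------------------------------------------------------------
# Study-condition presets


def counting_scene_spec(seed: int = 0) -> SceneSpec:
    """Viability-counting conditions: live/dead/overlap mix, debris, noise."""
    return SceneSpec(seed=seed)


def tracking_scene_spec(seed: int = 0) -> SceneSpec:
    """Droplet-tracking conditions: RFP-type (red-window) cells co-encapsulated
    with Eu- and Tb-doped NP clusters at ~0.3 co-encapsulation rate."""
    return SceneSpec(
        occupancy_distribution={0: 0.25, 1: 0.5, 2: 0.25},
        class_mix={"dead": 1.0},
        co_encapsulation_rate=0.3,
        seed=seed,
    )


def intensity_scene_spec(seed: int = 0) -> SceneSpec:
    """Peptide-uptake conditions: green-window cells with per-cell known mean
    intensity; read noise ~3% of the mid-range signal."""
    return SceneSpec(
        occupancy_distribution={0: 0.15, 1: 0.7, 2: 0.15},
        class_mix={"live": 1.0},
        noise_sigma=1200.0,
        seed=seed,
    )
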