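"""Joining droplet and contour center maps into encapsulation tables.

A contour belongs to a droplet when its centroid lies within the droplet's
detected radius (the scan range is bounded by the 25-50 um droplet radii);
contours inside no droplet are free-floating debris/cells drifting in the
device and are excluded from population statistics.  Droplet occupancy
(empty / single-cell / multi-cell) counts only cell-type contours —
nanoparticle trackers never contribute to occupancy — and a droplet holding
at least one cell and one NP cluster is "tracked" (co-encapsulated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .contour_detection import CELL_CLASSES, NP_CLASSES, Contour
from .droplet_detection import DropletMap

OCCUPANCY_EMPTY = "empty"
OCCUPANCY_SINGLE = "single_cell"
OCCUPANCY_MULTI = "multi_cell"


@dataclass
class EncapsulationRecord:
    """One droplet's contents: contained contours, occupancy class, tracking."""

    droplet_id: int
    contained_contours: list[tuple[int, str]] = field(default_factory=list)
    occupancy: str = OCCUPANCY_EMPTY
    tracked: bool = False
    image_index: int = 0

    @property
    def n_cells(self) -> int:
        return sum(1 for _, cls in self.contained_contours if cls in CELL_CLASSES)

    @property
    def n_nps(self) -> int:
        return sum(1 for _, cls in self.contained_contours if cls in NP_CLASSES)

    def n_of_class(self, class_label: str) -> int:
        return sum(1 for _, cls in self.contained_contours if cls == class_label)


@dataclass
class PopulationSummary:
    """Per-image (or pooled) droplet-population counts.

    The identities ``n_droplets == n_empty + n_sce + n_mce`` and
    ``assigned + free == total contours`` hold by construction.
    """

    n_droplets: int = 0
    n_empty: int = 0
    n_sce: int = 0
    n_mce: int = 0
    n_live: int = 0
    n_dead: int = 0
    n_overlap: int = 0
    n_eu_np: int = 0
    n_tb_np: int = 0
    n_free_contours: int = 0
    n_tracked: int = 0

    @property
    def n_cells(self) -> int:
        return self.n_live + self.n_dead + self.n_overlap

    @property
    def viability(self) -> float:
        total = self.n_cells
        return self.n_live / total if total else float("nan")

    def __add__(self, other: "PopulationSummary") -> "PopulationSummary":
        return PopulationSummary(
            **{
                f: getattr(self, f) + getattr(other, f)
                for f in self.__dataclass_fields__
            }
        )


def assign_contours_to_droplets(
    droplets: DropletMap, contours: list[Contour]
) -> tuple[list[EncapsulationRecord], list[int]]:
    """Assign each contour to at most one droplet by the containment test.

    A contour is contained in droplet ``d`` iff the Euclidean distance from
    its centroid to ``d``'s center is at most ``d``'s detected radius.  When
    several droplets contain it (overlapping detections should already have
    been deduplicated), the nearest center wins, ties going to the lower
    droplet id.  Returns the per-droplet records plus the ids of
    free-floating contours, which are excluded from population counts.
    """
    records = [
        EncapsulationRecord(droplet_id=d.droplet_id, image_index=droplets.image_index)
        for d in droplets
    ]
    by_id = {r.droplet_id: r for r in records}
    free: list[int] = []
    for c in contours:
        cx, cy = c.centroid
        best_id, best_dist = None, math.inf
        for d in droplets:
            dist = math.hypot(cx - d.x, cy - d.y)
            if dist <= d.radius and (
                dist < best_dist
                or (dist == best_dist and (best_id is None or d.droplet_id < best_id))
            ):
                best_id, best_dist = d.droplet_id, dist
        if best_id is None:
            free.append(c.contour_id)
        else:
            by_id[best_id].contained_contours.append((c.contour_id, c.class_label))
    return records, free


def classify_occupancy(
    records: list[EncapsulationRecord], n_free_contours: int = 0
) -> tuple[list[EncapsulationRecord], PopulationSummary]:
    """Set occupancy / tracked flags in place and build the population summary.

    Occupancy counts cell-class contours only (0 -> empty, 1 -> single-cell,
    >= 2 -> multi-cell); a droplet holding only NP clusters is still "empty"
    of cells but remains a distinct NP-only subpopulation in the
    co-encapsulation table.
    """
    summary = PopulationSummary(
        n_droplets=len(records), n_free_contours=n_free_contours
    )
    for rec in records:
        n_cells = rec.n_cells
        rec.occupancy = (
            OCCUPANCY_EMPTY
            if n_cells == 0
            else OCCUPANCY_SINGLE if n_cells == 1 else OCCUPANCY_MULTI
        )
        rec.tracked = n_cells >= 1 and rec.n_nps >= 1
        if rec.occupancy == OCCUPANCY_EMPTY:
            summary.n_empty += 1
        elif rec.occupancy == OCCUPANCY_SINGLE:
            summary.n_sce += 1
        else:
            summary.n_mce += 1
        summary.n_live += rec.n_of_class("live")
        summary.n_dead += rec.n_of_class("dead")
        summary.n_overlap += rec.n_of_class("overlap")
        summary.n_eu_np += rec.n_of_class("eu_np")
        summary.n_tb_np += rec.n_of_class("tb_np")
        summary.n_tracked += int(rec.tracked)
    return records, summary


def co_encapsulation_table(records: list[EncapsulationRecord]) -> pd.DataFrame:
    """Per-droplet cell/NP census with the co-encapsulation (tracked) flag."""
    rows = []
    for rec in records:
        rows.append(
            {
                "droplet_id": rec.droplet_id,
                "image_index": rec.image_index,
                "occupancy": rec.occupancy,
                "n_live": rec.n_of_class("live"),
                "n_dead": rec.n_of_class("dead"),
                "n_overlap": rec.n_of_class("overlap"),
                "n_eu_np": rec.n_of_class("eu_np"),
                "n_tb_np": rec.n_of_class("tb_np"),
                "n_cells": rec.n_cells,
                "n_nps": rec.n_nps,
                "tracked": rec.tracked,
            }
        )
    columns = [
        "droplet_id", "image_index", "occupancy", "n_live", "n_dead",
        "n_overlap", "n_eu_np", "n_tb_np", "n_cells", "n_nps", "tracked",
    ]
    return pd.DataFrame(rows, columns=columns)


def subpopulation_counts(records: list[EncapsulationRecord]) -> dict[str, int]:
    """Droplet subpopulations for tracking runs: empty / cell-only / NP-only /
    co-encapsulated single cell / co-encapsulated multiple cells."""
    counts = {"empty": 0, "cell_only": 0, "np_only": 0, "co_sc": 0, "co_mc": 0}
    for rec in records:
        cells, nps = rec.n_cells, rec.n_nps
        if cells == 0 and nps == 0:
            counts["empty"] += 1
        elif cells > 0 and nps == 0:
            counts["cell_only"] += 1
        elif cells == 0:
            counts["np_only"] += 1
        elif cells == 1:
            counts["co_sc"] += 1
        else:
            counts["co_mc"] += 1
    return counts
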