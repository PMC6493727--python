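"""Synthetic-benchmark runs used for validation.

Each benchmark regenerates a seeded synthetic study (scene conditions in
`synthetic_scenes`), runs the full pipeline with default parameters, and
scores the outputs against ground truth with the percent-agreement metric
100*(1-|auto-truth|/truth).  They are the quantitative self-checks of the
package: counting (viability categories), tracking (droplet subpopulations
with NP co-encapsulation) and intensity (per-cell mean fluorescence).
"""

from __future__ import annotations

import numpy as np

from .pipeline import ImageResult, RunConfig, process_image
from .synthetic_scenes import (
    AgreementReport,
    GroundTruth,
    SceneSpec,
    counting_scene_spec,
    generate_batch,
    intensity_scene_spec,
    score_against_truth,
    tracking_scene_spec,
)

#: Agreement categories reported per benchmark.
COUNTING_CATEGORIES = ["live", "dead", "overlap", "sce", "mce"]
TRACKING_CATEGORIES = [
    "subpop_empty", "subpop_cell_only", "subpop_np_only",
    "subpop_co_sc", "subpop_co_mc",
]


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k * 7_919 + 17) % (2**31 - 1))


def _run_set(
    spec: SceneSpec, n_images: int, config: RunConfig | None = None
) -> tuple[list[ImageResult], list[GroundTruth]]:
    config = config or RunConfig()
    images, truths = generate_batch(spec, n_images)
    results = [
        process_image(img, config, image_index=i) for i, img in enumerate(images)
    ]
    return results, truths


def counting_benchmark(
    seed: int = 1, n_sets: int = 3, n_images: int = 30
) -> list[AgreementReport]:
    """Triplicate viability-counting study (~30 images, >= 275 cells per set).

    Returns one agreement report per replicate; the headline number is the
    mean over `COUNTING_CATEGORIES` (in-droplet live/dead/overlap cells and
    single-/multi-cell encapsulation counts).
    """
    reports = []
    for k in range(n_sets):
        spec = counting_scene_spec(seed=_derive_seed(seed, k))
        results, truths = _run_set(spec, n_images)
        reports.append(score_against_truth(results, truths))
    return reports


def tracking_benchmark(
    seed: int = 1, n_runs: int = 2, n_images: int = 88
) -> list[AgreementReport]:
    """Duplicate droplet-tracking study (~790 droplets per run).

    Red-window cells plus Eu/Tb NP clusters at ~0.3 co-encapsulation rate;
    scored on the droplet subpopulation table (empty / cell-only / NP-only /
    co-encapsulated single cell / co-encapsulated multiple cells).
    """
    reports = []
    for k in range(n_runs):
        spec = tracking_scene_spec(seed=_derive_seed(seed, 100 + k))
        results, truths = _run_set(spec, n_images)
        reports.append(score_against_truth(results, truths))
    return reports


def intensity_benchmark(seed: int = 1, n_images: int = 20) -> AgreementReport:
    """Peptide-uptake intensity study (>= 142 cells of known mean intensity).

    The score is the mean per-cell relative agreement between the measured
    and rendered mean fluorescence over all matched cells.
    """
    spec = intensity_scene_spec(seed=_derive_seed(seed, 200))
    results, truths = _run_set(spec, n_images)
    return score_against_truth(results, truths)


def counting_similarity(reports: list[AgreementReport]) -> float:
    """Mean counting agreement (%) across replicates and categories."""
    return float(np.mean([r.mean_agreement(COUNTING_CATEGORIES) for r in reports]))


def tracking_similarity(reports: list[AgreementReport]) -> float:
    """Mean subpopulation-table agreement (%) across runs and categories."""
    return float(np.mean([r.mean_agreement(TRACKING_CATEGORIES) for r in reports]))
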