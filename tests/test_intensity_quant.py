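import numpy as np
import pytest

from fluorodroplet.contour_detection import Contour
from fluorodroplet.droplet_detection import Droplet, DropletMap
from fluorodroplet.intensity_quant import (
    BackgroundModel,
    contour_intensity_stats,
    estimate_background,
    fluorescence_gray,
    intensity_histogram,
    normalize_intensity,
)


def _contour_from_values(values, start_col=0):
    """A 1-row contour whose pixels carry the given values in a test image."""
    values = np.asarray(values, dtype=np.float64)
    gray = np.zeros((3, start_col + len(values) + 2))
    gray[1, start_col : start_col + len(values)] = values
    pixels = np.stack(
        [np.ones(len(values), dtype=int),
         np.arange(start_col, start_col + len(values))], axis=1
    )
    contour = Contour(0, "live", pixels, (0.0, 1.0), np.zeros((1, 2)))
    return gray, contour


class TestStats:
    def test_uniform_contour(self):
        gray, contour = _contour_from_values([1000] * 6)
        rec = contour_intensity_stats(gray, contour)
        assert (rec.mean, rec.min, rec.max, rec.variance) == (1000, 1000, 1000, 0)

    def test_closed_form_four_pixels(self):
        gray, contour = _contour_from_values([0, 0, 100, 100])
        rec = contour_intensity_stats(gray, contour)
        assert rec.mean == 50
        assert rec.min == 0 and rec.max == 100
        assert rec.variance == 2500
        assert rec.n_pixels == 4

    def test_variance_matches_two_pass_oracle(self, rng):
        values = rng.integers(0, 65536, size=200)
        gray, contour = _contour_from_values(values)
        rec = contour_intensity_stats(gray, contour)
        mu = sum(values) / len(values)
        two_pass = sum((v - mu) ** 2 for v in values) / len(values)
        assert rec.variance == pytest.approx(two_pass, rel=1e-6)
        assert rec.min <= rec.mean <= rec.max

    def test_sample_variance_mode(self):
        gray, contour = _contour_from_values([0, 0, 100, 100])
        rec = contour_intensity_stats(gray, contour, variance_mode="sample")
        assert rec.variance == pytest.approx(10000 / 3)

    def test_empty_pixel_set_fatal(self):
        contour = Contour(0, "live", np.zeros((0, 2), dtype=int), (0.0, 0.0),
                          np.zeros((1, 2)))
        with pytest.raises(ValueError):
            contour_intensity_stats(np.zeros((4, 4)), contour)


class TestBackground:
    def _droplet(self):
        return DropletMap(droplets=[Droplet(x=20, y=20, radius=15, votes=50,
                                            droplet_id=0)])

    def test_in_droplet_background(self):
        gray = np.full((40, 40), 9999.0)
        yy, xx = np.mgrid[0:40, 0:40]
        gray[np.hypot(xx - 20, yy - 20) <= 13] = 400.0
        pix = np.stack([np.full(9, 20), np.arange(16, 25)], axis=1)
        contour = Contour(0, "live", pix, (20.0, 20.0), np.zeros((1, 2)))
        gray[pix[:, 0], pix[:, 1]] = 2000.0
        bg = estimate_background(gray, self._droplet(), [contour])
        assert bg.background_level == 400.0

    def test_fallback_without_droplets(self):
        gray = np.full((10, 10), 250.0)
        bg = estimate_background(gray, DropletMap(), [])
        assert bg.background_level == 250.0
        assert "no droplets" in bg.method

    def test_median_of_three(self):
        gray = np.full((10, 10), 0.0)
        gray[0, :3] = [300.0, 400.0, 500.0]
        pix = np.stack([np.repeat(np.arange(1, 10), 10),
                        np.tile(np.arange(10), 9)], axis=1)
        contour = Contour(0, "live", pix, (5.0, 5.0), np.zeros((1, 2)))
        gray2 = gray.copy()
        bg = estimate_background(gray2[:1, :3], DropletMap(), [])
        assert bg.background_level == 400.0

    def test_all_contour_image_fatal(self):
        pix = np.stack(np.nonzero(np.ones((4, 4), dtype=bool)), axis=1)
        contour = Contour(0, "live", pix, (2.0, 2.0), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            estimate_background(np.zeros((4, 4)), DropletMap(), [contour])


class TestNormalization:
    def _rec(self, mean):
        gray, contour = _contour_from_values([mean] * 4)
        return contour_intensity_stats(gray, contour)

    def test_ratio(self):
        rec = normalize_intensity(
            self._rec(1000), BackgroundModel(500.0, "fixed", 10)
        )
        assert rec.normalized_mean == 2.0

    def test_identity_at_background(self):
        rec = normalize_intensity(
            self._rec(500), BackgroundModel(500.0, "fixed", 10)
        )
        assert rec.normalized_mean == 1.0

    def test_zero_background_fatal(self):
        with pytest.raises(ValueError, match="noise floor"):
            normalize_intensity(self._rec(100), BackgroundModel(0.0, "fixed", 1))

    def test_subtract_mode(self):
        rec = normalize_intensity(
            self._rec(1000), BackgroundModel(400.0, "fixed", 10), mode="subtract"
        )
        assert rec.normalized_mean == 600.0

    def test_scale_equivariance_of_ratio(self):
        for k in (2, 5):
            rec1 = normalize_intensity(
                self._rec(1200), BackgroundModel(300.0, "fixed", 10)
            )
            reck = normalize_intensity(
                self._rec(1200 * k), BackgroundModel(300.0 * k, "fixed", 10)
            )
            assert reck.normalized_mean == pytest.approx(rec1.normalized_mean)


class TestHistogram:
    def test_uniform_single_bin(self):
        gray, contour = _contour_from_values([3000] * 12)
        counts, rec = intensity_histogram(gray, contour)
        assert counts.sum() == 12
        assert (counts > 0).sum() == 1
        assert counts[3000 // 256] == 12

    def test_counts_conserved(self, rng):
        values = rng.integers(0, 65536, size=333)
        gray, contour = _contour_from_values(values)
        counts, _ = intensity_histogram(gray, contour)
        assert counts.sum() == 333
        assert counts.size == 256

    def test_extreme_values_hit_edge_bins(self):
        gray, contour = _contour_from_values([0, 65535])
        counts, rec = intensity_histogram(gray, contour)
        assert counts[0] == 1 and counts[255] == 1
        assert rec.min == 0 and rec.max == 65535


class TestFluorescenceChannels:
    def test_live_uses_green(self):
        px = np.zeros((1, 1, 3), dtype=np.uint16)
        px[0, 0] = (100, 20000, 300)
        assert fluorescence_gray(px, "live")[0, 0] == 20000

    def test_dead_uses_red(self):
        px = np.zeros((1, 1, 3), dtype=np.uint16)
        px[0, 0] = (100, 200, 31000)
        assert fluorescence_gray(px, "dead")[0, 0] == 31000

    def test_mean_recovery_on_noisy_synthetic_cells(self):
        """Measured means stay within 3*sigma/sqrt(n) of the rendered truth
        for >= 95% of cells."""
        from fluorodroplet.pipeline import process_image
        from fluorodroplet.synthetic_scenes import (
            generate_batch, intensity_scene_spec, score_against_truth,
        )

        spec = intensity_scene_spec(seed=99)
        images, truths = generate_batch(spec, 2)
        hits = total = 0
        for img, truth in zip(images, truths):
            res = process_image(img)
            by_id = {r.contour_id: r for r in res.intensity}
            for o in truth.cells():
                best = min(
                    res.contours,
                    key=lambda c: (c.centroid[0] - o.x) ** 2
                    + (c.centroid[1] - o.y) ** 2,
                    default=None,
                )
                if best is None:
                    continue
                rec = by_id[best.contour_id]
                total += 1
                tol = 3 * spec.noise_sigma / np.sqrt(rec.n_pixels)
                hits += abs(rec.mean - o.true_mean_intensity) <= tol
        assert total >= 10
        assert hits / total >= 0.95
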