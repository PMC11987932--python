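"""Synthetic tissue generation and ground-truth cytometry."""

import math

import numpy as np
import pytest

from mrcytometry import substrate as sub
from mrcytometry.substrate import (
    DEFAULT_PROFILES,
    PathologyProfile,
    Substrate,
    generate_substrate,
    ground_truth_metrics,
)


@pytest.fixture(scope="module")
def small_normal():
    return generate_substrate("normal", size_px=300, resolution=0.5, seed=11)


def circles_substrate(specs, size_px=200, resolution=0.5):
    """Substrate from explicit (cy, cx, d) circle specs in µm."""
    lab = np.zeros((size_px, size_px), dtype=np.int32)
    yy, xx = np.mgrid[:size_px, :size_px]
    for k, (cy, cx, d) in enumerate(specs, start=1):
        r_px = d / 2.0 / resolution
        mask = (yy + 0.5 - cy / resolution) ** 2 + (
            xx + 0.5 - cx / resolution
        ) ** 2 <= r_px * r_px
        lab[mask] = k
    return Substrate(lab, resolution)


class TestGeneration:
    def test_deterministic_for_seed(self):
        a = generate_substrate("HCC", size_px=200, resolution=0.5, seed=5)
        b = generate_substrate("HCC", size_px=200, resolution=0.5, seed=5)
        c = generate_substrate("HCC", size_px=200, resolution=0.5, seed=6)
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)

    def test_no_two_cells_overlap(self, small_normal):
        """Brute-force pairwise check on the placed disks."""
        c, r = small_normal.centers, small_normal.radii
        dist = np.sqrt(np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1))
        min_sep = r[:, None] + r[None, :] - small_normal.resolution
        np.fill_diagonal(dist, np.inf)
        assert np.all(dist >= min_sep - 1e-9)

    def test_diameters_within_profile_bounds(self, small_normal):
        prof = DEFAULT_PROFILES["normal"]
        d = 2 * small_normal.radii
        assert np.all(d >= prof.diameter_low - 1e-9)
        assert np.all(d <= prof.diameter_high + 1e-9)

    def test_area_fraction_below_packing_bound(self):
        for name in DEFAULT_PROFILES:
            s = generate_substrate(name, size_px=256, resolution=0.5, seed=0)
            assert s.intracellular_fraction < sub.PACKING_BOUND

    def test_hcc_doubles_normal_cell_density(self):
        """Tumour cell count per mm² ~2x normal parenchyma (±25%)."""
        ratios = []
        for seed in (0, 1, 2):
            n = generate_substrate("normal", size_px=400, resolution=0.5, seed=seed)
            h = generate_substrate("HCC", size_px=400, resolution=0.5, seed=seed)
            ratios.append(
                ground_truth_metrics(h).cellularity
                / ground_truth_metrics(n).cellularity
            )
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.25)

    def test_unreachable_fraction_flagged(self):
        prof = PathologyProfile("jam", 20.0, 20.0, 0.80)
        s = generate_substrate(prof, size_px=200, resolution=0.5, seed=0,
                               max_attempts=2000)
        assert s.saturated

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            PathologyProfile("bad", 20.0, 10.0, 0.5)
        with pytest.raises(ValueError):
            PathologyProfile("bad", 10.0, 20.0, 0.95)


class TestGroundTruth:
    def test_single_circle(self):
        # one 20 µm cell in a 100x100 µm field = 100 cells/mm²
        s = circles_substrate([(50.0, 50.0, 20.0)])
        m = ground_truth_metrics(s)
        assert m.n_cells == 1
        assert m.mean_diameter_number == pytest.approx(20.0, abs=2 * s.resolution)
        assert m.cellularity == pytest.approx(100.0)

    def test_identical_circles_have_equal_means(self):
        s = circles_substrate(
            [(25, 25, 14), (25, 75, 14), (75, 25, 14), (75, 75, 14)]
        )
        m = ground_truth_metrics(s)
        assert m.mean_diameter_number == pytest.approx(
            m.mean_diameter_volume_weighted, rel=1e-12
        )

    def test_volume_weighting_favours_large_cells(self):
        s = circles_substrate(
            [(25, 25, 10), (25, 75, 20), (75, 25, 10), (75, 75, 20)]
        )
        m = ground_truth_metrics(s)
        assert m.mean_diameter_number == pytest.approx(15.0, abs=0.5)
        # area weighting: (10³+20³)/(10²+20²) = 18
        assert m.mean_diameter_volume_weighted == pytest.approx(18.0, abs=0.5)
        assert m.mean_diameter_volume_weighted > m.mean_diameter_number

    def test_recovers_placed_diameters(self, small_normal):
        """Equivalent diameters agree with the generator's disks to ~1 px."""
        m = ground_truth_metrics(small_normal)
        placed = 2 * small_normal.radii
        # compare against interior cells only, as the metrics do
        labels = small_normal.labels
        border = set(np.concatenate([
            labels[0], labels[-1], labels[:, 0], labels[:, -1]
        ]).tolist())
        interior = [k for k in range(1, int(labels.max()) + 1)
                    if k not in border]
        expected = placed[np.array(interior) - 1].mean()
        assert m.mean_diameter_number == pytest.approx(
            expected, abs=2 * small_normal.resolution
        )

    def test_empty_substrate(self):
        s = Substrate(np.zeros((200, 200), dtype=np.int32), 0.5)
        m = ground_truth_metrics(s)
        assert m.empty and m.n_cells == 0 and m.area_fraction == 0.0

    def test_volume_weighted_at_least_number_weighted(self):
        for seed in range(3):
            s = generate_substrate("CRN", size_px=256, resolution=0.5, seed=seed)
            m = ground_truth_metrics(s)
            assert m.mean_diameter_volume_weighted >= m.mean_diameter_number


class TestIO:
    @pytest.mark.parametrize("suffix", [".tif", ".png"])
    def test_round_trip(self, tmp_path, suffix):
        s = generate_substrate("HCC", size_px=160, resolution=0.5, seed=3,
                               kappa=0.02)
        path = tmp_path / f"sub{suffix}"
        sub.save_label_image(s, path)
        loaded = sub.load_label_image(path)
        assert np.array_equal(loaded.labels, s.labels)
        assert loaded.resolution == s.resolution
        assert loaded.kappa == s.kappa

    def test_field_size_from_resolution(self):
        s = Substrate(np.zeros((2000, 2000), dtype=np.int32), 0.5)
        assert s.field_size_um == (1000.0, 1000.0)
        assert s.field_area_mm2 == pytest.approx(1.0)

    def test_missing_resolution_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "x.tif", np.zeros((64, 64), np.uint16))
        with pytest.raises(ValueError, match="resolution"):
            sub.load_label_image(tmp_path / "x.tif")

    def test_non_integer_image_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            Substrate(np.zeros((64, 64)), 0.5)
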