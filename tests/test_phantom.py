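"""Phantom generator: geometry oracle, determinism, dataset manifests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dsca.phantom import (PhantomConfig, analytic_polygon_area,
                          generate_dataset, generate_phantom, generate_samples)
from dsca.quant import calculate_area


def polygon_perimeter(poly):
    closed = np.vstack([poly, poly[:1]])
    return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))


class TestPolygonArea:
    def test_unit_square(self):
        assert analytic_polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == 1.0

    def test_circle_approximation_matches_closed_form(self):
        # regular 4096-gon of radius 10 vs pi r^2
        theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        poly = 10.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        assert abs(analytic_polygon_area(poly) - 100 * np.pi) < 0.01

    def test_orientation_invariance(self):
        poly = [(0, 0), (4, 0), (4, 2), (0, 2)]
        assert analytic_polygon_area(poly) == analytic_polygon_area(poly[::-1]) == 8.0

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            analytic_polygon_area([(0, 0), (1, 1)])

    def test_agrees_with_shapely(self):
        from shapely.geometry import Polygon

        rng = np.random.default_rng(4)
        theta = np.sort(rng.uniform(0, 2 * np.pi, 50))
        r = rng.uniform(1, 3, 50)
        poly = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert analytic_polygon_area(poly) == pytest.approx(Polygon(poly).area, rel=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    def test_area_scales_quadratically(self, scale):
        poly = np.array([(0.0, 0.0), (3.0, 0.0), (2.0, 2.0), (0.0, 1.0)])
        base = analytic_polygon_area(poly)
        assert analytic_polygon_area(poly * scale) == pytest.approx(base * scale ** 2)


class TestGeneratePhantom:
    def test_unperturbed_is_circle_with_target_area(self):
        config = PhantomConfig(image_size=64, perturb_amplitude=0.0,
                               noise_sigma=0.0, seed=1)
        s = generate_phantom(config, "P0000", 0)
        # circle: all boundary radii equal; analytic area equals the polygon's
        center = s.boundary_polygon.mean(axis=0)
        radii = np.hypot(*(s.boundary_polygon - center).T)
        assert radii.std() / radii.mean() < 1e-6
        assert radii.mean() == pytest.approx(np.sqrt(s.analytic_area_mm2 / np.pi), rel=1e-4)
        lo, hi = config.area_range_mm2
        assert lo <= s.analytic_area_mm2 <= hi

    def test_noise_free_intensities_are_exact(self):
        config = PhantomConfig(image_size=64, noise_sigma=0.0, seed=2)
        s = generate_phantom(config, "P0001", 1)
        levels = config.intensity_levels
        assert np.all(s.image[s.mask == 1] == levels["dural_sac"])
        outside = s.image[s.mask == 0]
        # T1-like contrast gap between sac and its surroundings
        assert outside.min() - s.image[s.mask == 1].max() >= 50

    def test_determinism(self):
        config = PhantomConfig(image_size=64, seed=3)
        a = generate_phantom(config, "P0007", 2)
        b = generate_phantom(config, "P0007", 2)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
        assert a.analytic_area_mm2 == b.analytic_area_mm2

    def test_mask_matches_image_shape(self, small_phantom_config):
        s = generate_phantom(small_phantom_config, "P0002", 0)
        assert s.image.shape == s.mask.shape == (64, 64)
        assert s.image.min() >= 0 and s.image.max() <= 255

    def test_pixelization_bound_on_seeded_cohort(self):
        """Rasterized area converges to the shoelace area within P * s^2."""
        config = PhantomConfig(image_size=96, n_patients=25,
                               slices_per_patient=(4, 4), seed=42)
        n = 0
        for s in generate_samples(config):
            raster = calculate_area(s.mask, s.pixel_spacing_mm)
            bound = polygon_perimeter(s.boundary_polygon) * s.pixel_spacing_mm ** 2
            assert abs(raster - s.analytic_area_mm2) <= bound
            n += 1
        assert n == 100

    def test_excessive_perturbation_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(perturb_amplitude=1.2)

    def test_inverted_contrast_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(intensity_levels={"dural_sac": 200.0,
                                            "epidural_fat": 190.0,
                                            "background": 110.0})


class TestGenerateDataset:
    def test_manifest_contents(self, tmp_path):
        config = PhantomConfig(image_size=64, n_patients=10,
                               slices_per_patient=(4, 4), seed=5)
        manifest = generate_dataset(config, tmp_path / "d")
        assert len(manifest) == 40
        assert manifest["patient_id"].nunique() == 10
        lo, hi = config.area_range_mm2
        assert manifest["analytic_area_mm2"].between(lo, hi).all()
        assert (tmp_path / "d" / manifest.iloc[0]["image_path"]).exists()
        assert (tmp_path / "d" / manifest.iloc[0]["mask_path"]).exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        config = PhantomConfig(image_size=64, n_patients=3, seed=6)
        generate_dataset(config, tmp_path / "a")
        generate_dataset(config, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
               (tmp_path / "b" / "manifest.csv").read_bytes()

    def test_mask_files_exercise_binarization(self, tmp_path):
        from PIL import Image

        config = PhantomConfig(image_size=64, n_patients=3, seed=7)
        manifest = generate_dataset(config, tmp_path / "d")
        arr = np.asarray(Image.open(tmp_path / "d" / manifest.iloc[0]["mask_path"]))
        assert set(np.unique(arr)) <= {0, 255}

    def test_dicom_roundtrip_carries_spacing(self, tmp_path):
        from dsca.io_prep import read_image_file

        config = PhantomConfig(image_size=64, n_patients=3, seed=8)
        manifest = generate_dataset(config, tmp_path / "d", file_format="dicom")
        arr, spacing = read_image_file(tmp_path / "d" / manifest.iloc[0]["image_path"])
        assert spacing == pytest.approx(config.pixel_spacing_mm)
        assert arr.shape == (64, 64)
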