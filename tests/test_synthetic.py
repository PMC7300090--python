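import numpy as np
import pytest

from stromaquant import synthetic
from stromaquant.errors import PlacementError
from stromaquant.fibers import angular_statistics
from stromaquant.ihc import deconvolve_stains, rgb_to_od


def small_fiber_spec(**kw):
    defaults = dict(n_fibers=20, image_hw=(256, 256), seed=0)
    defaults.update(kw)
    return synthetic.FiberFieldSpec(**defaults)


class TestFiberGenerator:
    def test_deterministic(self):
        a, _ = synthetic.generate_fiber_image(small_fiber_spec(seed=5))
        b, _ = synthetic.generate_fiber_image(small_fiber_spec(seed=5))
        assert np.array_equal(a.pixels, b.pixels)

    def test_zero_fibers_background_only(self):
        img, truth = synthetic.generate_fiber_image(small_fiber_spec(n_fibers=0))
        assert len(truth.fibers) == 0
        assert img.pixels.max() < 0.1  # noise floor only

    def test_single_fiber_echoed_exactly(self):
        spec = small_fiber_spec(
            n_fibers=1,
            angle_mu_deg=0.0,
            angle_kappa=1e9,
            length_mu_log=np.log(100.0),
            length_sigma_log=1e-9,
            width_mu_log=np.log(6.0),
            width_sigma_log=1e-9,
        )
        _, truth = synthetic.generate_fiber_image(spec)
        (f,) = truth.fibers
        assert f.length_px == pytest.approx(100.0, rel=1e-6)
        assert f.width_px == pytest.approx(6.0, rel=1e-6)
        assert min(f.angle_deg, 180 - f.angle_deg) < 0.01
        assert f.polyline.shape == (2, 2)

    def test_von_mises_circular_mean_near_mu(self):
        spec = synthetic.FiberFieldSpec(
            n_fibers=500, angle_mu_deg=90.0, angle_kappa=8.0, image_hw=(1024, 1024), seed=3
        )
        _, truth = synthetic.generate_fiber_image(spec)
        mean, _, _ = angular_statistics(truth.fibers)
        assert abs(mean - 90.0) < 3.0

    def test_ground_truth_moments_converge(self):
        """At n=2000 the sampled length/width medians track the model medians within 5%."""
        spec = synthetic.FiberFieldSpec(n_fibers=2000, image_hw=(2048, 2048), seed=4)
        _, truth = synthetic.generate_fiber_image(spec)
        assert np.median(truth.fibers.lengths_px) == pytest.approx(
            np.exp(spec.length_mu_log), rel=0.05
        )
        assert np.median(truth.fibers.widths_px) == pytest.approx(
            np.exp(spec.width_mu_log), rel=0.05
        )

    def test_angles_in_axial_range(self):
        _, truth = synthetic.generate_fiber_image(small_fiber_spec(n_fibers=200, seed=8))
        angles = truth.fibers.angles_deg
        assert np.all((angles >= 0) & (angles < 180))

    def test_hue_follows_width_rule(self):
        _, truth = synthetic.generate_fiber_image(small_fiber_spec(bundling=0.7, seed=2))
        for f, hue in zip(truth.fibers, truth.fiber_hues_deg):
            assert hue == pytest.approx(synthetic.hue_from_width(f.width_px, 0.7))


class TestIhcGenerator:
    def test_deterministic(self):
        spec = synthetic.IhcFieldSpec(n_cells=30, image_hw=(256, 256), seed=9)
        a, _ = synthetic.generate_ihc_image(spec)
        b, _ = synthetic.generate_ihc_image(spec)
        assert np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("p,expected", [(0.0, 0), (1.0, 50)])
    def test_positive_fraction_extremes(self, p, expected):
        spec = synthetic.IhcFieldSpec(n_cells=50, positive_fraction=p, seed=1)
        _, truth = synthetic.generate_ihc_image(spec)
        assert sum(c.is_positive for c in truth.cells) == expected

    def test_tumor_labels_match_fraction(self):
        spec = synthetic.IhcFieldSpec(n_cells=100, tumor_fraction=0.6, seed=2)
        _, truth = synthetic.generate_ihc_image(spec)
        assert sum(c.is_tumor for c in truth.cells) == 60

    def test_noise_free_density_recovery(self):
        """-log of the image projected on the stain basis inverts the forward model."""
        spec = synthetic.IhcFieldSpec(
            n_cells=20, marker="ECadherin", positive_fraction=0.5,
            noise_sd_od=0.0, image_hw=(256, 256), seed=6,
        )
        img, _ = synthetic.generate_ihc_image(spec)
        dens = deconvolve_stains(rgb_to_od(img), spec.stain_vectors)
        od = rgb_to_od(img)
        recomposed = (
            dens.hematoxylin[..., None] * spec.stain_vectors.matrix[0]
            + dens.dab[..., None] * spec.stain_vectors.matrix[1]
            + dens.vector_red[..., None] * spec.stain_vectors.matrix[2]
        )
        assert np.abs(recomposed - od).max() < 1e-6
        assert dens.clipped_fraction < 1e-9

    def test_overcrowded_field_raises(self):
        with pytest.raises(PlacementError, match="larger frame"):
            synthetic.generate_ihc_image(
                synthetic.IhcFieldSpec(n_cells=500, image_hw=(128, 128), seed=0)
            )

    def test_cells_do_not_overlap(self):
        spec = synthetic.IhcFieldSpec(n_cells=80, seed=3)
        _, truth = synthetic.generate_ihc_image(spec)
        centers = np.array([c.center_rc for c in truth.cells])
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).transpose(2, 0, 1))
        d[np.diag_indices(len(centers))] = np.inf
        assert d.min() > 2 * spec.cell_radius_px


class TestSpheroidGenerator:
    def test_plain_disk_area(self):
        ((img, truth),) = synthetic.generate_spheroid_series([100.0], 0, (256, 256), 1)
        mask = ~np.all(img.pixels == 1.0, axis=-1)
        assert mask.sum() == pytest.approx(np.pi * 50**2, rel=0.02)
        assert truth.spheroid_diameter_px == 100.0

    def test_series_monotone(self):
        series = synthetic.generate_spheroid_series([100.0, 80.0, 60.0], 0, (256, 256), 1)
        diams = [t.spheroid_diameter_px for _, t in series]
        assert diams == sorted(diams, reverse=True)

    def test_protrusions_add_area(self):
        ((plain, _),) = synthetic.generate_spheroid_series([100.0], 0, (256, 256), 1)
        ((spiky, _),) = synthetic.generate_spheroid_series([100.0], 8, (256, 256), 1)
        area = lambda im: (~np.all(im.pixels == 1.0, axis=-1)).sum()
        assert area(spiky) > area(plain)


class TestVesselGenerator:
    def test_zero_vessels(self):
        _, truth = synthetic.generate_vessel_image(0, seed=0)
        assert truth.vessel_count == 0 and truth.lumen_areas_px == []

    def test_count_echoed(self):
        _, truth = synthetic.generate_vessel_image(35, image_hw=(700, 700), seed=1)
        assert truth.vessel_count == 35 and len(truth.lumen_areas_px) == 35

    def test_lumen_areas_match_rendered_masks(self):
        img, truth = synthetic.generate_vessel_image(4, (6.0, 14.0), (400, 400), seed=2)
        bright = img.pixels.max(axis=-1) > 0.92
        from skimage.measure import label

        labels = label(bright)
        areas = sorted(np.bincount(labels.ravel())[1:])
        for measured, known in zip(areas, sorted(truth.lumen_areas_px)):
            assert measured == pytest.approx(known, rel=0.05)


class TestTrichromeGenerator:
    def test_exact_pixel_counts(self):
        _, truth = synthetic.generate_trichrome_image(0.3, 0.2, (256, 256), 0)
        assert truth.pixel_counts["blue"] == round(0.3 * 65536)
        assert truth.pixel_counts["red"] == round(0.2 * 65536)

    def test_half_half_leaves_no_unstained(self):
        _, truth = synthetic.generate_trichrome_image(0.5, 0.5, (128, 128), 0)
        assert truth.pixel_counts["unstained"] == 0

    def test_zero_zero_all_unstained(self):
        img, truth = synthetic.generate_trichrome_image(0.0, 0.0, (128, 128), 0)
        assert truth.pixel_counts["unstained"] == 128 * 128
        assert np.unique(img.pixels.reshape(-1, 3), axis=0).shape[0] == 1

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError):
            synthetic.generate_trichrome_image(0.7, 0.7)
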