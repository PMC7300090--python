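import numpy as np
import pytest

from stromaquant import synthetic
from stromaquant.core_io import AnalysisConfig, StainVectorSet
from stromaquant.errors import InsufficientDataError, StromaQuantError
from stromaquant.ihc import (
    deconvolve_stains,
    gate_tumor_cells,
    rgb_to_od,
    score_area_fraction,
    score_caspase,
    score_marker,
    score_membrane,
    score_nuclear,
    segment_cells,
    tumor_region_mask,
)


def analyzed_field(marker="Ki67", p=0.3, n=100, noise=0.0, seed=0, **spec_kw):
    spec = synthetic.IhcFieldSpec(
        n_cells=n, marker=marker, positive_fraction=p, noise_sd_od=noise,
        seed=seed, **spec_kw,
    )
    img, truth = synthetic.generate_ihc_image(spec)
    dens = deconvolve_stains(rgb_to_od(img), spec.stain_vectors)
    cells = gate_tumor_cells(segment_cells(dens), dens.vector_red)
    return cells, dens, truth


class TestOpticalDensity:
    def test_analytic_values(self):
        px = np.full((16, 16, 3), np.exp(-1.0))
        assert rgb_to_od(px) == pytest.approx(1.0)
        assert rgb_to_od(np.ones((16, 16, 3))).max() == 0.0

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(1 / 255, 1.0, (16, 16, 3))
        assert np.abs(np.exp(-rgb_to_od(px)) - px).max() < 1e-9


class TestDeconvolution:
    def test_pure_dab_recovered(self):
        sv = StainVectorSet()
        od = np.zeros((16, 16, 3)) + 0.8 * sv.matrix[1]
        dens = deconvolve_stains(od, sv)
        assert np.abs(dens.dab - 0.8).max() < 1e-6
        assert np.abs(dens.hematoxylin).max() < 1e-6
        assert np.abs(dens.vector_red).max() < 1e-6

    def test_white_image_zero_density(self):
        dens = deconvolve_stains(rgb_to_od(np.ones((16, 16, 3))))
        assert dens.hematoxylin.max() == dens.dab.max() == dens.vector_red.max() == 0.0

    def test_two_stain_mixture_exact(self):
        sv = StainVectorSet()
        rng = np.random.default_rng(1)
        h = rng.uniform(0, 1, (32, 32))
        v = rng.uniform(0, 1, (32, 32))
        od = h[..., None] * sv.matrix[0] + v[..., None] * sv.matrix[2]
        dens = deconvolve_stains(od, sv)
        assert np.abs(dens.hematoxylin - h).max() < 1e-6
        assert np.abs(dens.vector_red - v).max() < 1e-6
        assert np.abs(dens.dab).max() < 1e-6

    def test_ill_conditioned_basis_rejected(self):
        near_singular = StainVectorSet(
            vectors=np.array([[1.0, 0, 0], [1.0, 1e-5, 0], [0, 0, 1.0]])
        )
        with pytest.raises(StromaQuantError, match="condition number"):
            deconvolve_stains(np.zeros((4, 4, 3)), near_singular)


class TestSegmentCells:
    def test_cell_count_recovered(self):
        cells, _, truth = analyzed_field(n=50, seed=4, image_hw=(400, 400))
        assert abs(len(cells) - 50) <= 1

    def test_empty_field(self):
        from stromaquant.ihc import StainDensities

        zeros = np.zeros((64, 64))
        with pytest.warns(UserWarning):
            cells = segment_cells(StainDensities(zeros, zeros, zeros))
        assert cells == []

    def test_touching_nuclei_split_by_watershed(self):
        from stromaquant.ihc import StainDensities

        hema = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        for cr, cc in ((32, 27), (32, 37)):  # overlapping disks, radius 5
            hema[(yy - cr) ** 2 + (xx - cc) ** 2 <= 25] = 0.8
        cells = segment_cells(StainDensities(hema, np.zeros_like(hema), np.zeros_like(hema)))
        assert len(cells) == 2

    def test_compartments_disjoint_and_contained(self):
        cells, _, _ = analyzed_field(n=30, seed=5, image_hw=(300, 300))
        for c in cells:
            overlap = (
                (c.nucleus_mask & c.ring_mask)
                | (c.nucleus_mask & c.cytoplasm_mask)
                | (c.ring_mask & c.cytoplasm_mask)
            )
            assert not overlap.any()
            union = c.nucleus_mask | c.ring_mask | c.cytoplasm_mask
            assert not (union & ~c.cell_mask).any()


class TestGating:
    def test_tumor_fraction_recovered(self):
        cells, _, truth = analyzed_field(n=100, seed=6, tumor_fraction=0.6)
        frac = np.mean([c.is_tumor for c in cells])
        assert frac == pytest.approx(0.6, abs=0.05)

    def test_threshold_extremes(self):
        cells, dens, _ = analyzed_field(n=30, seed=7, image_hw=(300, 300))
        cfg_inf = AnalysisConfig(ck18_od_threshold=np.inf)
        assert sum(c.is_tumor for c in gate_tumor_cells(cells, dens.vector_red, cfg_inf)) == 0
        cfg_zero = AnalysisConfig(ck18_od_threshold=0.0)
        gated = gate_tumor_cells(cells, dens.vector_red, cfg_zero)
        assert all(c.is_tumor for c in gated)


class TestScoringRules:
    @pytest.mark.parametrize(
        "marker,p",
        [("Ki67", 0.3), ("bCatenin", 0.5), ("ECadherin", 0.4), ("CD44", 0.3),
         ("CD133", 0.5), ("Caspase3", 0.5)],
    )
    def test_fraction_recovered_noise_free(self, marker, p):
        cells, dens, _ = analyzed_field(marker=marker, p=p, n=100, seed=11)
        score = score_marker(cells, dens, marker)
        assert score.positive_fraction == pytest.approx(p, abs=0.04)

    def test_ncad_nuclear_only_branch(self):
        """N-cadherin positives carrying only nuclear DAB still score positive."""
        cells, dens, _ = analyzed_field(
            marker="NCadherin", p=0.4, n=100, seed=12, ncad_nuclear_fraction=1.0
        )
        score = score_marker(cells, dens, "NCadherin")
        assert score.positive_fraction == pytest.approx(0.4, abs=0.04)
        assert score.rule == "membrane_or_nuclear"

    def test_all_negative_field_scores_zero(self):
        cells, dens, _ = analyzed_field(marker="Ki67", p=0.0, n=50, seed=13, image_hw=(400, 400))
        assert score_nuclear(cells, dens.dab, "Ki67").positive_fraction == 0.0

    def test_zero_threshold_scores_all_positive(self):
        cells, dens, _ = analyzed_field(marker="Ki67", p=0.0, n=50, noise=0.02,
                                        seed=14, image_hw=(400, 400))
        cfg = AnalysisConfig(od_positive_threshold={m: 0.0 for m in AnalysisConfig().od_positive_threshold})
        assert score_nuclear(cells, dens.dab, "Ki67", cfg).positive_fraction == 1.0

    def test_zero_completeness_accepts_partial_rings(self):
        cells, dens, _ = analyzed_field(marker="ECadherin", p=0.0, n=50, seed=15,
                                        image_hw=(400, 400),
                                        membrane_completeness_of_negatives=0.5)
        cfg = AnalysisConfig(membrane_completeness_min=0.0)
        score = score_membrane(cells, dens.dab, "ECadherin", cfg)
        assert score.positive_fraction == 1.0

    def test_area_fraction_constructed_mask(self):
        tumor = np.zeros((100, 100), bool)
        tumor[:80, :] = True
        dab = np.zeros((100, 100))
        dab[:20, :] = 0.6  # exactly 25% of the tumor region
        score = score_area_fraction(tumor, dab)
        assert score.positive_fraction == pytest.approx(0.25, abs=0.01)
        assert score_area_fraction(tumor, np.zeros((100, 100))).positive_fraction == 0.0

    def test_area_fraction_empty_mask_raises(self):
        with pytest.raises(InsufficientDataError):
            score_area_fraction(np.zeros((32, 32), bool), np.zeros((32, 32)))

    def test_caspase_extremes(self):
        cells, dens, _ = analyzed_field(marker="Caspase3", p=1.0, n=50, seed=16,
                                        image_hw=(400, 400))
        assert score_caspase(cells, dens.dab).positive_fraction == 1.0

    def test_no_tumor_cells_flagged(self):
        cells, dens, _ = analyzed_field(marker="Ki67", p=0.5, n=30, seed=17,
                                        tumor_fraction=0.0, image_hw=(300, 300))
        score = score_nuclear(cells, dens.dab, "Ki67")
        assert np.isnan(score.positive_fraction) and score.flag is not None

    def test_ungated_cells_rejected(self):
        from stromaquant.ihc import StainDensities

        spec = synthetic.IhcFieldSpec(n_cells=10, image_hw=(200, 200), seed=18)
        img, _ = synthetic.generate_ihc_image(spec)
        dens = deconvolve_stains(rgb_to_od(img), spec.stain_vectors)
        cells = segment_cells(dens)  # not gated
        with pytest.raises(StromaQuantError, match="gated"):
            score_nuclear(cells, dens.dab, "Ki67")


class TestThresholdMonotonicity:
    @pytest.mark.parametrize("marker", ["Ki67", "ECadherin", "FAK"])
    def test_raising_threshold_never_raises_fraction(self, marker):
        cells, dens, _ = analyzed_field(marker=marker, p=0.5, n=100, noise=0.02, seed=19)
        rng = np.random.default_rng(0)
        thresholds = np.sort(rng.uniform(0.0, 0.8, 20))
        fractions = []
        for t in thresholds:
            cfg = AnalysisConfig(
                od_positive_threshold={m: float(t) for m in AnalysisConfig().od_positive_threshold}
            )
            if marker == "FAK":
                mask = tumor_region_mask(cells, dens.shape)
                fractions.append(score_area_fraction(mask, dens.dab, cfg).positive_fraction)
            else:
                fractions.append(score_marker(cells, dens, marker, cfg).positive_fraction)
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


def test_gate_consistency():
    """Scored cells equal gated tumor cells minus the edge-excluded tally."""
    cells, dens, _ = analyzed_field(marker="ECadherin", p=0.4, n=100, seed=20)
    n_tumor = sum(c.is_tumor for c in cells)
    score = score_membrane(cells, dens.dab, "ECadherin")
    assert score.n_cells_considered == n_tumor - score.n_excluded
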