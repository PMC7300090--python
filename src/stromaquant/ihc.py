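"""Stain deconvolution and per-cell marker scoring for dual-chromogen IHC.

Chromogen amounts add linearly in optical density (Beer-Lambert), so a
pixel's OD triple is the stain densities times the unit stain vectors;
deconvolution inverts that 3x3 system per pixel.  Cells are segmented from
the hematoxylin density (Otsu threshold, hole filling, watershed split on
the distance transform), nuclei are expanded to the configured cell radius
capped by neighbors, and a membrane ring of fixed thickness is taken just
inside each cell boundary.

Tumor cells are gated by Vector Red (the CK-18 epithelial label), and DAB
marker expression is scored per the marker's rule: nuclear positivity
(Ki67, beta-catenin), complete membrane localization (E-cadherin, CD44,
CD133; >= 95% of 36 angular sectors by default), membrane-or-nuclear
(N-cadherin), membrane+cytoplasmic (Caspase3), or stained area fraction of
the tumor region (FAK).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk, erosion, remove_small_objects
from skimage.segmentation import expand_labels, watershed

from stromaquant.core_io import (
    AnalysisConfig,
    MARKERS,
    RasterImage,
    StainVectorSet,
)
from stromaquant.errors import InsufficientDataError, StromaQuantError

__all__ = [
    "StainVectorSet",
    "StainDensities",
    "CellRecord",
    "MarkerScore",
    "rgb_to_od",
    "deconvolve_stains",
    "segment_cells",
    "gate_tumor_cells",
    "tumor_region_mask",
    "score_nuclear",
    "score_membrane",
    "score_area_fraction",
    "score_caspase",
    "score_marker",
]

NUCLEAR_RULE_MARKERS = ("Ki67", "bCatenin")
MEMBRANE_RULE_MARKERS = ("ECadherin", "NCadherin", "CD44", "CD133")

# minimum hematoxylin OD for a pixel to be considered nuclear at all; keeps
# Otsu from splitting pure background noise into spurious "nuclei"
_NUCLEUS_OD_FLOOR = 0.1


@dataclass
class StainDensities:
    """Per-pixel stain density maps (OD units along each unit stain vector)."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    vector_red: np.ndarray
    clipped_fraction: float = 0.0

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape


@dataclass
class CellRecord:
    """One segmented cell with its subcellular compartment masks.

    Masks are stored locally within ``bbox`` (a pair of slices into the
    frame); compartments are disjoint and contained in ``cell_mask``:
    the membrane ring is the band of ``ring_thickness`` px just inside the
    cell boundary (minus any nucleus overlap), cytoplasm is the remainder.
    """

    cell_id: int
    centroid_rc: tuple[float, float]
    bbox: tuple[slice, slice]
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    ring_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    touches_border: bool = False
    is_tumor: bool | None = None
    marker_call: bool | float | None = None
    mean_od: dict = field(default_factory=dict)

    def mean_density(self, density_map: np.ndarray, compartment: str) -> float:
        """Mean stain density over one compartment ('nucleus', 'cell', 'ring', 'cytoplasm')."""
        mask = {
            "nucleus": self.nucleus_mask,
            "cell": self.cell_mask,
            "ring": self.ring_mask,
            "cytoplasm": self.cytoplasm_mask,
        }[compartment]
        if not mask.any():
            return 0.0
        return float(density_map[self.bbox][mask].mean())


@dataclass
class MarkerScore:
    """Positivity score for one marker over the gated tumor cells.

    For ``rule='area_fraction'`` (FAK), ``positive_fraction`` is the stained
    area fraction of the tumor region and the cell counts are zero.
    """

    marker: str
    rule: str
    n_cells_considered: int
    n_positive: int
    positive_fraction: float
    n_excluded: int = 0
    flag: str | None = None


# ---------------------------------------------------------------------------
# deconvolution


def rgb_to_od(image: RasterImage | np.ndarray) -> np.ndarray:
    """Beer-Lambert inversion: OD = -log(transmittance), zeros clipped to 1/255."""
    px = image.pixels if isinstance(image, RasterImage) else np.asarray(image, np.float64)
    return -np.log(np.clip(px, 1.0 / 255.0, 1.0))


def deconvolve_stains(od: np.ndarray, vectors: StainVectorSet | None = None) -> StainDensities:
    """Project per-pixel OD onto the stain basis (exact 3x3 inverse).

    Negative densities are clipped to zero; the clipped fraction of total
    density mass is reported.  An ill-conditioned basis raises.
    """
    vectors = vectors or StainVectorSet()
    cond = vectors.condition_number
    if cond >= 1e3:
        raise StromaQuantError(
            f"stain vector matrix is ill-conditioned (condition number {cond:.3g})"
        )
    inv = np.linalg.inv(vectors.matrix)
    dens = od @ inv  # (..., 3) in stain order hematoxylin, dab, vector_red
    neg = np.clip(-dens, 0.0, None).sum()
    total = np.abs(dens).sum()
    clipped = float(neg / total) if total > 0 else 0.0
    dens = np.clip(dens, 0.0, None)
    return StainDensities(
        hematoxylin=dens[..., 0],
        dab=dens[..., 1],
        vector_red=dens[..., 2],
        clipped_fraction=clipped,
    )


# ---------------------------------------------------------------------------
# segmentation


def segment_cells(densities: StainDensities, config: AnalysisConfig | None = None) -> list[CellRecord]:
    """Segment nuclei from hematoxylin density and build cell geometry.

    Nuclei: Otsu threshold (with an OD floor), hole filling, small-object
    removal, watershed split on the distance transform.  Each nucleus is
    expanded to the configured cell radius, capped where neighbors meet.
    """
    config = config or AnalysisConfig()
    hema = densities.hematoxylin
    if hema.max() <= _NUCLEUS_OD_FLOOR:
        warnings.warn("segment_cells: no nuclear signal above the OD floor", stacklevel=2)
        return []
    thr = max(float(threshold_otsu(hema)), _NUCLEUS_OD_FLOOR)
    fg = hema > thr
    fg = ndi.binary_fill_holes(fg)
    min_area = max(9, int(0.3 * np.pi * config.nucleus_radius_px**2))
    fg = remove_small_objects(fg, max_size=min_area - 1)
    if not fg.any():
        warnings.warn("segment_cells: no nuclei found", stacklevel=2)
        return []
    dist = ndi.distance_transform_edt(fg)
    min_dist = max(2, int(round(0.8 * config.nucleus_radius_px)))
    peaks = peak_local_max(dist, min_distance=min_dist, labels=sk_label(fg), exclude_border=False)
    markers = np.zeros_like(fg, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    nuclei = watershed(-dist, markers, mask=fg)
    expand = max(config.cell_radius_px - config.nucleus_radius_px, 1.0)
    cells_lab = expand_labels(nuclei, distance=expand)

    records: list[CellRecord] = []
    h, w = fg.shape
    footprint = disk(config.ring_thickness_px)
    for lab, sl in enumerate(ndi.find_objects(cells_lab), start=1):
        if sl is None:
            continue
        cell_local = cells_lab[sl] == lab
        nuc_local = nuclei[sl] == lab
        padded = np.pad(cell_local, config.ring_thickness_px + 1)
        eroded = erosion(padded, footprint)[
            config.ring_thickness_px + 1 : -(config.ring_thickness_px + 1),
            config.ring_thickness_px + 1 : -(config.ring_thickness_px + 1),
        ]
        ring_local = cell_local & ~eroded & ~nuc_local
        cyto_local = cell_local & ~ring_local & ~nuc_local
        rr, cc = np.nonzero(cell_local)
        centroid = (float(rr.mean() + sl[0].start), float(cc.mean() + sl[1].start))
        touches = (
            sl[0].start == 0 and cell_local[0].any()
        ) or (
            sl[0].stop == h and cell_local[-1].any()
        ) or (
            sl[1].start == 0 and cell_local[:, 0].any()
        ) or (
            sl[1].stop == w and cell_local[:, -1].any()
        )
        records.append(
            CellRecord(
                cell_id=lab,
                centroid_rc=centroid,
                bbox=sl,
                nucleus_mask=nuc_local,
                cell_mask=cell_local,
                ring_mask=ring_local,
                cytoplasm_mask=cyto_local,
                touches_border=bool(touches),
            )
        )
    return records


def gate_tumor_cells(
    cells: Sequence[CellRecord],
    vector_red: np.ndarray,
    config: AnalysisConfig | None = None,
) -> list[CellRecord]:
    """Set ``is_tumor`` on each cell from its mean Vector Red density (CK-18 gate)."""
    config = config or AnalysisConfig()
    for cell in cells:
        mean_vr = cell.mean_density(vector_red, "cell")
        cell.mean_od[("vector_red", "cell")] = mean_vr
        cell.is_tumor = mean_vr > config.ck18_od_threshold
    return list(cells)


def tumor_region_mask(cells: Sequence[CellRecord], shape: tuple[int, int]) -> np.ndarray:
    """Union of the gated tumor cells' masks."""
    mask = np.zeros(shape, dtype=bool)
    for cell in cells:
        if cell.is_tumor:
            mask[cell.bbox] |= cell.cell_mask
    return mask


# ---------------------------------------------------------------------------
# scoring rules


def _gated(cells: Sequence[CellRecord]) -> list[CellRecord]:
    if any(c.is_tumor is None for c in cells):
        raise StromaQuantError("cells must be gated (gate_tumor_cells) before scoring")
    return [c for c in cells if c.is_tumor]


def _fraction_score(marker, rule, n_considered, n_positive, n_excluded=0) -> MarkerScore:
    if n_considered == 0:
        return MarkerScore(marker, rule, 0, 0, float("nan"), n_excluded,
                           flag="no tumor cells; fraction undefined")
    return MarkerScore(marker, rule, n_considered, n_positive,
                       n_positive / n_considered, n_excluded)


def score_nuclear(
    cells: Sequence[CellRecord],
    dab: np.ndarray,
    marker: str,
    config: AnalysisConfig | None = None,
) -> MarkerScore:
    """Nuclear positivity: mean DAB density over the nucleus above threshold."""
    if marker not in NUCLEAR_RULE_MARKERS:
        raise ValueError(f"{marker!r} is not scored by the nuclear rule")
    config = config or AnalysisConfig()
    thr = config.od_positive_threshold[marker]
    tumor = _gated(cells)
    n_pos = 0
    for cell in tumor:
        call = cell.mean_density(dab, "nucleus") > thr
        cell.marker_call = call
        n_pos += call
    return _fraction_score(marker, "nuclear", len(tumor), n_pos)


def _membrane_completeness(
    cell: CellRecord, dab: np.ndarray, thr: float, n_sectors: int
) -> float:
    """Fraction of angular membrane sectors whose mean DAB density exceeds thr."""
    rr, cc = np.nonzero(cell.ring_mask)
    if rr.size == 0:
        return 0.0
    rr = rr + cell.bbox[0].start
    cc = cc + cell.bbox[1].start
    theta = np.degrees(np.arctan2(rr - cell.centroid_rc[0], cc - cell.centroid_rc[1])) % 360.0
    sectors = np.minimum((theta / 360.0 * n_sectors).astype(int), n_sectors - 1)
    vals = dab[rr, cc]
    n_hot = 0
    for s in range(n_sectors):
        sel = sectors == s
        if sel.any() and vals[sel].mean() > thr:
            n_hot += 1
    return n_hot / n_sectors


def score_membrane(
    cells: Sequence[CellRecord],
    dab: np.ndarray,
    marker: str,
    config: AnalysisConfig | None = None,
) -> MarkerScore:
    """Complete-membrane positivity over angular sectors of the ring.

    A cell is positive when at least ``membrane_completeness_min`` of the
    ``n_membrane_sectors`` angular sectors show mean DAB density above the
    marker threshold.  N-cadherin is additionally positive on the nuclear
    rule (nuclear signal indicates cytoplasmic expression not yet at the
    membrane).  Cells touching the frame border have degenerate rings and
    are excluded (tallied in ``n_excluded``).
    """
    if marker not in MEMBRANE_RULE_MARKERS:
        raise ValueError(f"{marker!r} is not scored by the membrane rule")
    config = config or AnalysisConfig()
    thr = config.od_positive_threshold[marker]
    tumor = _gated(cells)
    usable = [c for c in tumor if not c.touches_border and c.ring_mask.any()]
    n_excluded = len(tumor) - len(usable)
    n_pos = 0
    for cell in usable:
        completeness = _membrane_completeness(cell, dab, thr, config.n_membrane_sectors)
        call = completeness >= config.membrane_completeness_min
        if marker == "NCadherin" and not call:
            call = cell.mean_density(dab, "nucleus") > thr
        cell.marker_call = call
        n_pos += call
    rule = "membrane_or_nuclear" if marker == "NCadherin" else "membrane_complete"
    return _fraction_score(marker, rule, len(usable), n_pos, n_excluded)


def score_area_fraction(
    tumor_mask: np.ndarray,
    dab: np.ndarray,
    config: AnalysisConfig | None = None,
    marker: str = "FAK",
) -> MarkerScore:
    """Stained area fraction: tumor pixels with DAB density above threshold."""
    config = config or AnalysisConfig()
    tumor_mask = np.asarray(tumor_mask, bool)
    n_tumor = int(tumor_mask.sum())
    if n_tumor == 0:
        raise InsufficientDataError("area fraction undefined for an empty tumor mask")
    thr = config.od_positive_threshold[marker]
    frac = float((dab[tumor_mask] > thr).sum() / n_tumor)
    return MarkerScore(marker, "area_fraction", 0, 0, frac)


def score_caspase(
    cells: Sequence[CellRecord],
    dab: np.ndarray,
    config: AnalysisConfig | None = None,
) -> MarkerScore:
    """Caspase-3 positivity: mean DAB over membrane ring plus cytoplasm."""
    config = config or AnalysisConfig()
    thr = config.od_positive_threshold["Caspase3"]
    tumor = _gated(cells)
    n_pos = 0
    for cell in tumor:
        sl = cell.bbox
        mask = cell.ring_mask | cell.cytoplasm_mask
        mean = float(dab[sl][mask].mean()) if mask.any() else 0.0
        call = mean > thr
        cell.marker_call = call
        n_pos += call
    return _fraction_score("Caspase3", "membrane_cytoplasmic", len(tumor), n_pos)


def score_marker(
    cells: Sequence[CellRecord],
    densities: StainDensities,
    marker: str,
    config: AnalysisConfig | None = None,
) -> MarkerScore:
    """Dispatch to the marker's scoring rule (see module docstring)."""
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    config = config or AnalysisConfig()
    if marker in NUCLEAR_RULE_MARKERS:
        return score_nuclear(cells, densities.dab, marker, config)
    if marker in MEMBRANE_RULE_MARKERS:
        return score_membrane(cells, densities.dab, marker, config)
    if marker == "Caspase3":
        return score_caspase(cells, densities.dab, config)
    mask = tumor_region_mask(cells, densities.shape)
    return score_area_fraction(mask, densities.dab, config)
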