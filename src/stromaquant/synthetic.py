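"""Synthetic histology generators with exhaustive ground truth.

Every downstream stage is validated by parameter recovery against fields
generated here: polarized-light PSR fiber fields whose hue encodes bundling,
Masson's trichrome blue/red fields with exact pixel counts, dual-chromogen
IHC fields composed through a Beer-Lambert optical-density mixing model with
per-cell positivity labels, and H&E-like spheroid and vessel geometries.

All generators are deterministic: an identical spec (including its seed)
produces a bit-identical image and ground truth.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from stromaquant.core_io import Modality, RasterImage, StainVectorSet
from stromaquant.errors import PlacementError
from stromaquant.fibers import Fiber, FiberSet, fold_axial
from stromaquant.errors import StromaQuantError

__all__ = [
    "FiberFieldSpec",
    "IhcFieldSpec",
    "SyntheticCell",
    "GroundTruth",
    "hue_from_width",
    "generate_fiber_image",
    "generate_ihc_image",
    "generate_spheroid_series",
    "generate_vessel_image",
    "generate_trichrome_image",
]

# reference widths (px) anchoring the width -> hue bundling map
HUE_WIDTH_MIN = 2.0
HUE_WIDTH_MAX = 12.0

# optical densities (along the unit stain vectors) used to paint compartments
NUCLEUS_HEMATOXYLIN_OD = 0.8
TUMOR_VECTOR_RED_OD = 0.5
MARKER_DAB_OD = 0.6
CASPASE_DAB_OD = 0.5

NUCLEAR_MARKERS = ("Ki67", "bCatenin")
MEMBRANE_MARKERS = ("ECadherin", "NCadherin", "CD44", "CD133")


@dataclass
class FiberFieldSpec:
    """Parameters of a synthetic polarized-light PSR fiber field.

    Angles follow either an axial-uniform model on [0, 180) or an axial
    von Mises model (``mu_deg`` center, concentration ``kappa``); lengths and
    widths are lognormal in pixels.  ``bundling`` in [0, 1] scales how
    strongly fiber width shifts the rendered hue from green toward red.
    """

    n_fibers: int = 500
    angle_model: str = "von_mises_axial"  # or "uniform_axial"
    angle_mu_deg: float = 90.0
    angle_kappa: float = 8.0
    length_mu_log: float = float(np.log(60.0))
    length_sigma_log: float = 0.4
    width_mu_log: float = float(np.log(6.0))
    width_sigma_log: float = 0.25
    bundling: float = 0.5
    background_noise_sd: float = 0.01
    image_hw: tuple[int, int] = (2048, 2048)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.angle_model not in ("uniform_axial", "von_mises_axial"):
            raise ValueError(f"unknown angle model {self.angle_model!r}")
        if self.angle_kappa < 0:
            raise ValueError("kappa must be >= 0")
        if min(self.image_hw) < 64:
            raise ValueError("image_hw must be at least 64 x 64")
        if not 0.0 <= self.bundling <= 1.0:
            raise ValueError("bundling must be in [0, 1]")


@dataclass
class IhcFieldSpec:
    """Parameters of a synthetic dual-chromogen IHC field.

    Cells are disks on a jittered grid (center spacing > 2 x cell radius, so
    segmentation is unambiguous and scoring tests isolate the scoring rules).
    Tumor cells carry Vector Red over the whole cell (the CK-18 gate);
    marker-positive tumor cells carry DAB in the compartment the marker's
    scoring rule reads (nuclear for Ki67/bCatenin; complete membrane ring for
    ECadherin/CD44/CD133; membrane or nuclear for NCadherin; cytoplasm plus
    membrane for Caspase3; for FAK ``positive_fraction`` is instead the DAB
    area fraction painted over the tumor region).  Marker-negative tumor
    cells receive at most ``membrane_completeness_of_negatives`` of the ring.
    """

    n_cells: int = 200
    tumor_fraction: float = 1.0
    marker: str = "Ki67"
    positive_fraction: float = 0.3
    membrane_completeness_of_negatives: float = 0.5
    nucleus_radius_px: float = 5.0
    cell_radius_px: float = 12.0
    ring_thickness_px: float = 3.0
    ncad_nuclear_fraction: float = 0.5
    stain_vectors: StainVectorSet = field(default_factory=StainVectorSet)
    noise_sd_od: float = 0.0
    image_hw: tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_px >= self.cell_radius_px:
            raise ValueError("nucleus radius must be smaller than cell radius")
        if not 0.0 <= self.membrane_completeness_of_negatives < 1.0:
            raise ValueError("membrane_completeness_of_negatives must be in [0, 1)")
        for name in ("tumor_fraction", "positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticCell:
    """Ground-truth record of one rendered cell."""

    cell_id: int
    center_rc: tuple[float, float]
    nucleus_radius_px: float
    cell_radius_px: float
    is_tumor: bool
    is_positive: bool
    membrane_completeness: float
    nuclear_branch: bool = False  # NCadherin positives rendered nuclearly


@dataclass
class GroundTruth:
    """Everything a generator knows about what it drew, plus the spec echo."""

    spec: object
    fibers: FiberSet | None = None
    fiber_hues_deg: list[float] | None = None
    cells: list[SyntheticCell] | None = None
    fak_area_fraction: float | None = None
    spheroid_diameter_px: float | None = None
    protrusion_count: int | None = None
    vessel_count: int | None = None
    lumen_areas_px: list[int] | None = None
    pixel_counts: dict[str, int] | None = None


# ---------------------------------------------------------------------------
# drawing primitives


def _capsule_coverage(shape, p0, p1, width):
    """Anti-aliased coverage of a straight capsule; returns (slices, coverage)."""
    h, w = shape
    r = width / 2.0 + 1.5
    rmin = max(int(np.floor(min(p0[0], p1[0]) - r)), 0)
    rmax = min(int(np.ceil(max(p0[0], p1[0]) + r)) + 1, h)
    cmin = max(int(np.floor(min(p0[1], p1[1]) - r)), 0)
    cmax = min(int(np.ceil(max(p0[1], p1[1]) + r)) + 1, w)
    if rmin >= rmax or cmin >= cmax:
        return None, None
    rows = np.arange(rmin, rmax, dtype=np.float64)[:, None]
    cols = np.arange(cmin, cmax, dtype=np.float64)[None, :]
    d = np.array(p1, dtype=np.float64) - np.array(p0, dtype=np.float64)
    denom = float(d @ d)
    if denom == 0:
        t = np.zeros((rows.size, cols.size))
    else:
        t = ((rows - p0[0]) * d[0] + (cols - p0[1]) * d[1]) / denom
        t = np.clip(t, 0.0, 1.0)
    proj_r = p0[0] + t * d[0]
    proj_c = p0[1] + t * d[1]
    dist = np.hypot(rows - proj_r, cols - proj_c)
    cov = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
    return (slice(rmin, rmax), slice(cmin, cmax)), cov


def _disk_coords(shape, center, radius):
    """Integer (rows, cols) of a filled disk clipped to the frame."""
    h, w = shape
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 1, h)
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 1, w)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    inside = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
    rr, cc = np.nonzero(inside)
    return rr + r0, cc + c0


def hue_from_width(width_px: float, bundling: float) -> float:
    """Deterministic bundling-hue rule: thin fibers green (160 deg), thick red (10 deg)."""
    t = np.clip(
        bundling * (width_px - HUE_WIDTH_MIN) / (HUE_WIDTH_MAX - HUE_WIDTH_MIN), 0.0, 1.0
    )
    return float(160.0 - 150.0 * t)


# ---------------------------------------------------------------------------
# fiber fields


def _sample_axial_angles(spec: FiberFieldSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.angle_model == "uniform_axial":
        return rng.uniform(0.0, 180.0, spec.n_fibers)
    if spec.angle_kappa == 0:
        return rng.uniform(0.0, 180.0, spec.n_fibers)
    doubled = rng.vonmises(np.radians(2.0 * spec.angle_mu_deg), spec.angle_kappa, spec.n_fibers)
    return np.asarray(fold_axial(np.degrees(doubled) / 2.0))


def generate_fiber_image(spec: FiberFieldSpec) -> tuple[RasterImage, GroundTruth]:
    """Render straight anti-aliased fiber capsules on a near-black field.

    Each fiber's HSV hue follows :func:`hue_from_width`; overlaps compose by
    channel-wise maximum so crossings stay in gamut.  Ground truth echoes
    every capsule (two-point polyline, angle, length, width) and its hue.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_hw
    img = np.clip(
        np.abs(rng.normal(0.0, spec.background_noise_sd, (h, w)))[:, :, None]
        * np.ones(3),
        0.0,
        1.0,
    )
    angles = _sample_axial_angles(spec, rng)
    lengths = rng.lognormal(spec.length_mu_log, spec.length_sigma_log, spec.n_fibers)
    widths = np.maximum(rng.lognormal(spec.width_mu_log, spec.width_sigma_log, spec.n_fibers), 1.0)
    fibers: list[Fiber] = []
    hues: list[float] = []
    for k in range(spec.n_fibers):
        ang = float(angles[k])
        half = lengths[k] / 2.0
        dvec = np.array([-np.sin(np.radians(ang)), np.cos(np.radians(ang))])
        for attempt in range(100):
            center = rng.uniform([0, 0], [h, w])
            p0 = center - half * dvec
            p1 = center + half * dvec
            sl, cov = _capsule_coverage((h, w), p0, p1, widths[k])
            if sl is not None and cov.max() > 0:
                break
        else:
            raise StromaQuantError("could not place fiber inside the frame in 100 attempts")
        hue = hue_from_width(float(widths[k]), spec.bundling)
        rgb = np.array(colorsys.hsv_to_rgb(hue / 360.0, 0.9, 1.0))
        img[sl] = np.maximum(img[sl], cov[:, :, None] * rgb)
        fibers.append(
            Fiber(
                polyline=np.array([p0, p1]),
                length_px=float(lengths[k]),
                width_px=float(widths[k]),
                angle_deg=ang,
                source={"fiber_id": k},
            )
        )
        hues.append(hue)
    image = RasterImage(np.clip(img, 0.0, 1.0), modality=Modality.PSR)
    truth = GroundTruth(spec=spec, fibers=FiberSet(fibers), fiber_hues_deg=hues)
    return image, truth


# ---------------------------------------------------------------------------
# IHC fields


def _grid_centers(spec: IhcFieldSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_hw
    margin = spec.cell_radius_px + 2.0
    pitch = 2.0 * spec.cell_radius_px + 4.0
    n_rows = int((h - 2 * margin) // pitch) + 1
    n_cols = int((w - 2 * margin) // pitch) + 1
    if n_rows * n_cols < spec.n_cells:
        raise PlacementError(
            f"cannot place {spec.n_cells} cells of radius {spec.cell_radius_px} in a "
            f"{h} x {w} frame without overlap; use a larger frame"
        )
    rows = margin + pitch * np.arange(n_rows)
    cols = margin + pitch * np.arange(n_cols)
    sites = np.array([(r, c) for r in rows for c in cols if r <= h - margin and c <= w - margin])
    if len(sites) < spec.n_cells:
        raise PlacementError("cannot place cells without overlap; use a larger frame")
    chosen = rng.choice(len(sites), size=spec.n_cells, replace=False)
    jitter = rng.uniform(-1.5, 1.5, (spec.n_cells, 2))
    return sites[np.sort(chosen)] + jitter


def _ring_arc_coords(shape, center, r_out, thickness, start_deg, sweep_deg):
    """Pixels of an annulus arc of the given angular sweep (degrees)."""
    rr, cc = _disk_coords(shape, center, r_out)
    rad = np.hypot(rr - center[0], cc - center[1])
    on_ring = rad > r_out - thickness
    rr, cc = rr[on_ring], cc[on_ring]
    if sweep_deg >= 360.0:
        return rr, cc
    theta = np.degrees(np.arctan2(rr - center[0], cc - center[1])) % 360.0
    rel = (theta - start_deg) % 360.0
    keep = rel < sweep_deg
    return rr[keep], cc[keep]


def generate_ihc_image(spec: IhcFieldSpec) -> tuple[RasterImage, GroundTruth]:
    """Compose a dual-chromogen IHC field through the Beer-Lambert model.

    Per-pixel optical density is the sum of per-stain density maps times the
    unit stain vectors; Gaussian OD noise (sd ``noise_sd_od``) is added, the
    result clipped at zero, and transmitted RGB is exp(-OD) channel-wise.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_hw
    centers = _grid_centers(spec, rng)
    n = spec.n_cells
    n_tumor = int(round(spec.tumor_fraction * n))
    tumor_ids = np.sort(rng.choice(n, size=n_tumor, replace=False))
    is_tumor = np.zeros(n, dtype=bool)
    is_tumor[tumor_ids] = True
    if spec.marker == "FAK":
        is_positive = np.zeros(n, dtype=bool)  # FAK is area-based, not per-cell
    else:
        n_pos = int(round(spec.positive_fraction * n_tumor))
        pos_ids = tumor_ids[np.sort(rng.choice(n_tumor, size=n_pos, replace=False))] if n_tumor else []
        is_positive = np.zeros(n, dtype=bool)
        is_positive[pos_ids] = True

    hema = np.zeros((h, w))
    dab = np.zeros((h, w))
    vred = np.zeros((h, w))
    cells: list[SyntheticCell] = []
    shape = (h, w)
    r_cell = spec.cell_radius_px
    r_nuc = spec.nucleus_radius_px
    thick = spec.ring_thickness_px
    for k in range(n):
        center = tuple(centers[k])
        nr, nc = _disk_coords(shape, center, r_nuc)
        hema[nr, nc] = NUCLEUS_HEMATOXYLIN_OD
        completeness = 0.0
        nuclear_branch = False
        if is_tumor[k]:
            cr, cc = _disk_coords(shape, center, r_cell)
            vred[cr, cc] = TUMOR_VECTOR_RED_OD
            if spec.marker in NUCLEAR_MARKERS:
                if is_positive[k]:
                    dab[nr, nc] = MARKER_DAB_OD
            elif spec.marker in MEMBRANE_MARKERS:
                start = float(rng.uniform(0.0, 360.0))
                if is_positive[k]:
                    if spec.marker == "NCadherin" and rng.uniform() < spec.ncad_nuclear_fraction:
                        nuclear_branch = True
                        dab[nr, nc] = MARKER_DAB_OD
                    else:
                        completeness = 1.0
                        ar, ac = _ring_arc_coords(shape, center, r_cell, thick, start, 360.0)
                        dab[ar, ac] = MARKER_DAB_OD
                else:
                    completeness = spec.membrane_completeness_of_negatives
                    if completeness > 0:
                        sweep = 360.0 * completeness
                        ar, ac = _ring_arc_coords(shape, center, r_cell, thick, start, sweep)
                        dab[ar, ac] = MARKER_DAB_OD
            elif spec.marker == "Caspase3":
                if is_positive[k]:
                    # diffuse cytoplasm + membrane: whole cell minus nucleus
                    body = np.hypot(cr - center[0], cc - center[1]) > r_nuc
                    dab[cr[body], cc[body]] = CASPASE_DAB_OD
            elif spec.marker != "FAK":
                raise ValueError(f"unknown marker {spec.marker!r}")
        cells.append(
            SyntheticCell(
                cell_id=k,
                center_rc=(float(center[0]), float(center[1])),
                nucleus_radius_px=r_nuc,
                cell_radius_px=r_cell,
                is_tumor=bool(is_tumor[k]),
                is_positive=bool(is_positive[k]),
                membrane_completeness=completeness if is_tumor[k] else 0.0,
                nuclear_branch=nuclear_branch,
            )
        )

    fak_fraction = None
    if spec.marker == "FAK":
        tumor_mask = np.zeros(shape, dtype=bool)
        for k in tumor_ids:
            cr, cc = _disk_coords(shape, tuple(centers[k]), r_cell)
            tumor_mask[cr, cc] = True
        n_tumor_px = int(tumor_mask.sum())
        n_paint = int(round(spec.positive_fraction * n_tumor_px))
        if n_paint > 0:
            blob_field = ndi.gaussian_filter(rng.standard_normal(shape), sigma=6.0)
            tr, tc = np.nonzero(tumor_mask)
            order = np.argsort(blob_field[tr, tc], kind="stable")[:n_paint]
            dab[tr[order], tc[order]] = MARKER_DAB_OD
        fak_fraction = (n_paint / n_tumor_px) if n_tumor_px else 0.0

    vectors = spec.stain_vectors.matrix
    od = (
        hema[:, :, None] * vectors[0]
        + dab[:, :, None] * vectors[1]
        + vred[:, :, None] * vectors[2]
    )
    if spec.noise_sd_od > 0:
        od = od + rng.normal(0.0, spec.noise_sd_od, od.shape)
    od = np.clip(od, 0.0, None)
    image = RasterImage(np.exp(-od), modality=Modality.IHC)
    truth = GroundTruth(spec=spec, cells=cells, fak_area_fraction=fak_fraction)
    return image, truth


# ---------------------------------------------------------------------------
# spheroids and vessels

SPUR_WIDTH_PX = 3.0
SPUR_LENGTH_PX = 20.0
TISSUE_RGB = np.array([0.78, 0.45, 0.55])  # eosin-like pink
VESSEL_BG_RGB = np.array([0.85, 0.72, 0.78])
VESSEL_WALL_RGB = np.array([0.55, 0.25, 0.35])
LUMEN_RGB = np.array([0.97, 0.96, 0.97])


def generate_spheroid_series(
    diameters_px: Sequence[float],
    protrusion_count: int = 0,
    image_hw: tuple[int, int] = (512, 512),
    seed: int = 0,
) -> list[tuple[RasterImage, GroundTruth]]:
    """Render one filled tissue disk per frame, with optional thin radial spurs.

    Spurs emulate migratory protrusions and are excluded from the
    ground-truth diameter, which is the disk diameter alone.
    """
    rng = np.random.default_rng(seed)
    h, w = image_hw
    out = []
    for d in diameters_px:
        if d >= min(h, w):
            raise ValueError(f"diameter {d} does not fit in a {h} x {w} frame")
        center = (h / 2.0, w / 2.0)
        mask = np.zeros((h, w), dtype=bool)
        rr, cc = _disk_coords((h, w), center, d / 2.0)
        mask[rr, cc] = True
        offset = float(rng.uniform(0.0, 360.0))
        for k in range(protrusion_count):
            ang = np.radians(offset + 360.0 * k / max(protrusion_count, 1))
            u = np.array([np.sin(ang), np.cos(ang)])
            p0 = np.array(center) + (d / 2.0 - 2.0) * u
            p1 = np.array(center) + (d / 2.0 + SPUR_LENGTH_PX) * u
            sl, cov = _capsule_coverage((h, w), p0, p1, SPUR_WIDTH_PX)
            if sl is not None:
                mask[sl] |= cov > 0.5
        img = np.ones((h, w, 3))
        img[mask] = TISSUE_RGB
        image = RasterImage(img, modality=Modality.HE)
        truth = GroundTruth(
            spec={"diameter_px": float(d), "protrusion_count": protrusion_count,
                  "image_hw": (h, w), "seed": seed},
            spheroid_diameter_px=float(d),
            protrusion_count=protrusion_count,
        )
        out.append((image, truth))
    return out


def generate_vessel_image(
    n_vessels: int,
    lumen_radius_range: tuple[float, float] = (6.0, 14.0),
    image_hw: tuple[int, int] = (512, 512),
    seed: int = 0,
    wall_thickness_px: float = 4.0,
) -> tuple[RasterImage, GroundTruth]:
    """Render stained vessel walls (annuli) with bright lumens on pink tissue.

    Ground truth stores the count and each lumen's rendered pixel area.
    """
    rng = np.random.default_rng(seed)
    h, w = image_hw
    lo, hi = lumen_radius_range
    img = np.ones((h, w, 3)) * VESSEL_BG_RGB
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    margin = hi + wall_thickness_px + 2.0
    min_sep = 2.0 * (hi + wall_thickness_px) + 4.0
    for _ in range(n_vessels):
        r = float(rng.uniform(lo, hi))
        for attempt in range(200):
            cand = (float(rng.uniform(margin, h - margin)), float(rng.uniform(margin, w - margin)))
            if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep for c in centers):
                centers.append(cand)
                radii.append(r)
                break
        else:
            raise PlacementError(
                f"could not place {n_vessels} vessels without overlap; use a larger frame"
            )
    areas: list[int] = []
    for center, r in zip(centers, radii):
        wr, wc = _disk_coords((h, w), center, r + wall_thickness_px)
        img[wr, wc] = VESSEL_WALL_RGB
        lr, lc = _disk_coords((h, w), center, r)
        img[lr, lc] = LUMEN_RGB
        areas.append(int(len(lr)))
    image = RasterImage(img, modality=Modality.HE)
    truth = GroundTruth(
        spec={"n_vessels": n_vessels, "lumen_radius_range": (lo, hi),
              "image_hw": (h, w), "seed": seed},
        vessel_count=n_vessels,
        lumen_areas_px=areas,
    )
    return image, truth


# ---------------------------------------------------------------------------
# trichrome fields

TRICHROME_BLUE_RGB = np.array([0.05, 0.05, 0.85])
TRICHROME_RED_RGB = np.array([0.85, 0.05, 0.05])
# near-white unstained tissue: below the white-value threshold so it counts
# in the tissue denominator, but far too unsaturated to read as blue or red
TRICHROME_UNSTAINED_RGB = np.array([0.94, 0.93, 0.92])


def generate_trichrome_image(
    blue_fraction: float,
    red_fraction: float,
    image_hw: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[RasterImage, GroundTruth]:
    """Assign exact counts of blue / red / unstained tissue pixels, clustered.

    Pixel counts are exact (``round(fraction * H * W)``); the remainder is
    near-white unstained tissue, so the generated fractions are directly the
    colored-over-tissue ratios.  Spatial clustering into blobs comes from
    ranking a smoothed random field.
    """
    if blue_fraction + red_fraction > 1.0 + 1e-12:
        raise ValueError("blue_fraction + red_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    h, w = image_hw
    n = h * w
    n_blue = int(round(blue_fraction * n))
    n_red = int(round(red_fraction * n))
    if n_blue + n_red > n:
        n_red = n - n_blue
    blob_field = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    order = np.argsort(blob_field.ravel(), kind="stable")
    img = np.ones((h, w, 3)) * TRICHROME_UNSTAINED_RGB
    flat = img.reshape(-1, 3)
    flat[order[:n_blue]] = TRICHROME_BLUE_RGB
    flat[order[n_blue : n_blue + n_red]] = TRICHROME_RED_RGB
    image = RasterImage(img, modality=Modality.TRICHROME)
    truth = GroundTruth(
        spec={"blue_fraction": blue_fraction, "red_fraction": red_fraction,
              "image_hw": (h, w), "seed": seed},
        pixel_counts={"blue": n_blue, "red": n_red, "unstained": n - n_blue - n_red},
    )
    return image, truth
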