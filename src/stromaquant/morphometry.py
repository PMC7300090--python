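"""Spheroid size tracking and vessel counting.

The spheroid "average diameter" is the mean, over equally spaced
directions, of the length of the chord through the component centroid,
after a morphological opening that suppresses thin migratory protrusions.
Vessel lumens are bright connected components whose boundary is mostly
adjacent to stained (non-bright) wall pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.measure import label as sk_label, perimeter_crofton
from skimage.morphology import disk, opening

from stromaquant.core_io import AnalysisConfig, RasterImage, RegionMask
from stromaquant.errors import InsufficientDataError

__all__ = [
    "SpheroidMeasurement",
    "VesselStats",
    "tissue_mask",
    "measure_spheroid",
    "track_growth",
    "count_vessels",
]


@dataclass
class SpheroidMeasurement:
    """Size and shape of one spheroid section at one timepoint."""

    timepoint: float
    diameter_px: float
    diameter_um: float
    area_px: float
    circularity: float
    label: str = ""
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")
        if not 0.0 < self.circularity <= 1.05:
            raise ValueError(f"circularity {self.circularity} outside (0, 1.05]")


@dataclass
class VesselStats:
    """Count of vessel lumens and their areas."""

    vessel_count: int
    lumen_areas_px: list[float]

    def __post_init__(self) -> None:
        if self.vessel_count != len(self.lumen_areas_px):
            raise ValueError("vessel_count must equal the number of lumen areas")


def tissue_mask(image: RasterImage, white_value_min: float = 0.92) -> RegionMask:
    """Non-white (tissue) pixels of a brightfield image."""
    hsv = rgb2hsv(image.pixels)
    mask = (hsv[:, :, 2] < white_value_min) | (hsv[:, :, 1] > 0.15)
    return RegionMask(mask, label="tissue")


def _mean_chord_diameter(mask: np.ndarray, centroid: tuple[float, float], n_dirs: int) -> float:
    """Mean in-mask length of the chord through the centroid over n directions."""
    h, w = mask.shape
    t_max = float(np.hypot(h, w)) / 2.0
    step = 0.5
    t = np.arange(-t_max, t_max + step, step)
    total = 0.0
    for theta in np.linspace(0.0, np.pi, n_dirs, endpoint=False):
        dr, dc = -np.sin(theta), np.cos(theta)
        rr = np.round(centroid[0] + t * dr).astype(int)
        cc = np.round(centroid[1] + t * dc).astype(int)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        total += mask[rr[ok], cc[ok]].sum() * step
    return total / n_dirs


def measure_spheroid(
    mask: RegionMask | np.ndarray,
    config: AnalysisConfig | None = None,
    timepoint: float = 0.0,
    label: str = "",
) -> SpheroidMeasurement:
    """Measure a spheroid section from its tissue mask.

    The mask is opened with a disk (default radius 3 px) to suppress thin
    protrusions; if more than one sufficiently large component remains, the
    largest is used and the result flagged.  Diameter is the mean centroid
    chord over ``n_diameter_directions``; circularity is 4*pi*A/P^2 with a
    Crofton perimeter estimate.
    """
    config = config or AnalysisConfig()
    pixels = mask.pixels if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if not pixels.any():
        raise InsufficientDataError("spheroid measurement undefined for an empty mask")
    opened = opening(pixels, disk(config.spheroid_opening_radius_px))
    if not opened.any():
        raise InsufficientDataError("mask vanished under opening; no spheroid present")
    labels = sk_label(opened)
    sizes = np.bincount(labels.ravel())[1:]
    flag = None
    big = np.flatnonzero(sizes >= config.spheroid_min_area_px)
    if big.size == 0:
        flag = "no component above the minimum area; largest used"
        keep = int(np.argmax(sizes)) + 1
    elif big.size > 1:
        flag = f"{big.size} components above the minimum area; largest used"
        keep = int(np.argmax(sizes)) + 1
    else:
        keep = int(big[0]) + 1
    comp = labels == keep
    rr, cc = np.nonzero(comp)
    centroid = (float(rr.mean()), float(cc.mean()))
    diameter = _mean_chord_diameter(comp, centroid, config.n_diameter_directions)
    area = float(comp.sum())
    perim = float(perimeter_crofton(comp, directions=4))
    circ = min(4.0 * np.pi * area / perim**2, 1.05) if perim > 0 else 1.05
    return SpheroidMeasurement(
        timepoint=timepoint,
        diameter_px=diameter,
        diameter_um=diameter * config.pixel_size_um,
        area_px=area,
        circularity=circ,
        label=label,
        flag=flag,
    )


def track_growth(series: list[SpheroidMeasurement]) -> pd.DataFrame:
    """Tabulate diameter against timepoint with fold-change from the first.

    Unordered timepoints are sorted with a warning.
    """
    if len(series) < 2:
        raise InsufficientDataError("growth tracking requires at least two timepoints")
    times = [m.timepoint for m in series]
    if times != sorted(times):
        warnings.warn("timepoints were unordered; sorting", stacklevel=2)
        series = sorted(series, key=lambda m: m.timepoint)
    first = series[0].diameter_px
    return pd.DataFrame(
        {
            "timepoint": [m.timepoint for m in series],
            "label": [m.label for m in series],
            "diameter_px": [m.diameter_px for m in series],
            "diameter_um": [m.diameter_um for m in series],
            "area_px": [m.area_px for m in series],
            "fold_change": [m.diameter_px / first for m in series],
        }
    )


def count_vessels(image: RasterImage, config: AnalysisConfig | None = None) -> VesselStats:
    """Count bright vessel lumens enclosed by stained walls.

    Candidate lumens are bright connected components (HSV value above
    ``lumen_value_min``) whose area lies within the configured bounds and
    whose boundary is at least ``lumen_boundary_adjacency_min`` adjacent to
    non-bright (stained) pixels.
    """
    config = config or AnalysisConfig()
    hsv = rgb2hsv(image.pixels)
    bright = hsv[:, :, 2] > config.lumen_value_min
    labels = sk_label(bright)
    areas: list[float] = []
    stained = ~bright
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        pad = (slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, labels.shape[0])),
               slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, labels.shape[1])))
        comp = labels[pad] == lab
        area = float(comp.sum())
        if not config.lumen_area_min_px <= area <= config.lumen_area_max_px:
            continue
        boundary = ndi.binary_dilation(comp) & ~comp
        n_boundary = int(boundary.sum())
        if n_boundary == 0:
            continue
        adjacency = float((boundary & stained[pad]).sum() / n_boundary)
        if adjacency >= config.lumen_boundary_adjacency_min:
            areas.append(area)
    return VesselStats(vessel_count=len(areas), lumen_areas_px=areas)
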