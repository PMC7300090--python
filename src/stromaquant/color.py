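"""Hue-based quantification: PSR bundling profiles and trichrome ratios.

Picrosirius-red birefringence hue encodes collagen bundling: red/orange
signal marks thick, mature bundles; yellow/green marks thin, reticular
fibers.  The hue profile counts masked pixels into configurable hue bins;
hues outside every bin (the cyan-magenta range, which genuine birefringence
does not produce) are tallied separately and excluded from the fractions.

Masson's trichrome renders collagen blue and cytoplasm/muscle red; the
trichrome ratio counts blue and red pixels against all (non-white) tissue
pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from stromaquant.core_io import AnalysisConfig, Modality, RasterImage, RegionMask

__all__ = ["HueProfile", "TrichromeRatio", "hue_profile", "trichrome_ratio"]


@dataclass
class HueProfile:
    """Pixel counts and fractions of birefringent signal per hue bin."""

    counts: dict[str, int]
    fractions: dict[str, float]
    total_birefringent_px: int
    out_of_bin_px: int = 0
    empty: bool = False

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("hue bin counts must be nonnegative")

    @property
    def red_orange_fraction(self) -> float:
        """Combined mature-bundle fraction (red + orange bins)."""
        return self.fractions.get("red", 0.0) + self.fractions.get("orange", 0.0)


@dataclass
class TrichromeRatio:
    """Blue (collagen) and red (cytoplasm/muscle) pixel ratios over tissue."""

    blue_px: int
    red_px: int
    tissue_px: int
    blue_fraction: float
    red_fraction: float
    empty: bool = False

    def __post_init__(self) -> None:
        if self.blue_px + self.red_px > self.tissue_px:
            raise ValueError("blue_px + red_px cannot exceed tissue_px")


def hue_profile(
    image: RasterImage,
    mask: RegionMask,
    config: AnalysisConfig | None = None,
) -> HueProfile:
    """Bin the hue of masked birefringent pixels into the configured windows.

    Fractions are counts over the total of binned pixels; out-of-bin hues
    are reported but excluded.  An empty mask yields an all-zero profile
    flagged ``empty``.
    """
    config = config or AnalysisConfig()
    if image.modality != Modality.PSR:
        warnings.warn(f"expected PSR modality, got {image.modality}", stacklevel=2)
    names = config.hue_bin_names()
    if not mask.pixels.any():
        warnings.warn("hue_profile: empty mask", stacklevel=2)
        return HueProfile({n: 0 for n in names}, {n: 0.0 for n in names}, 0, 0, empty=True)
    hsv = rgb2hsv(image.pixels[mask.pixels])
    hue_deg = hsv[:, 0] * 360.0
    counts = {n: 0 for n in names}
    assigned = np.zeros(hue_deg.shape, dtype=bool)
    for name, lo, hi in config.hue_bins:
        sel = (hue_deg >= lo) & (hue_deg < hi)
        counts[name] += int(sel.sum())
        assigned |= sel
    total = int(assigned.sum())
    out_of_bin = int(hue_deg.size - total)
    if total == 0:
        return HueProfile(counts, {n: 0.0 for n in names}, 0, out_of_bin, empty=True)
    fractions = {n: counts[n] / total for n in names}
    return HueProfile(counts, fractions, total, out_of_bin)


def _in_hue_window(hue_deg: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo <= hi:
        return (hue_deg >= lo) & (hue_deg < hi)
    return (hue_deg >= lo) | (hue_deg < hi)  # window wraps through 0


def trichrome_ratio(
    image: RasterImage,
    config: AnalysisConfig | None = None,
) -> TrichromeRatio:
    """Count blue and red pixels against all tissue (non-white) pixels.

    Tissue pixels have HSV value below the white threshold or saturation
    above the tissue minimum; blue/red classification additionally requires
    saturation above the color minimum and hue inside the stain's window.
    """
    config = config or AnalysisConfig()
    if image.modality != Modality.TRICHROME:
        warnings.warn(f"expected TRICHROME modality, got {image.modality}", stacklevel=2)
    hsv = rgb2hsv(image.pixels)
    hue_deg = hsv[:, :, 0] * 360.0
    sat = hsv[:, :, 1]
    val = hsv[:, :, 2]
    tissue = (val < config.trichrome_white_value_min) | (
        sat > config.trichrome_tissue_saturation_min
    )
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        warnings.warn("trichrome_ratio: no tissue pixels", stacklevel=2)
        return TrichromeRatio(0, 0, 0, 0.0, 0.0, empty=True)
    saturated = sat > config.trichrome_color_saturation_min
    blue = tissue & saturated & _in_hue_window(hue_deg, config.trichrome_blue_hue)
    red = tissue & saturated & _in_hue_window(hue_deg, config.trichrome_red_hue) & ~blue
    n_blue, n_red = int(blue.sum()), int(red.sum())
    return TrichromeRatio(n_blue, n_red, n_tissue, n_blue / n_tissue, n_red / n_tissue)
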