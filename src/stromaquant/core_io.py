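"""Raster containers, configuration, and file I/O.

All images are carried as ``RasterImage`` objects: H x W x 3 float arrays in
[0, 1], row-major with the origin at the top-left and 0-based indices.
Physical units are derived as ``px * pixel_size_um``; when no pixel size is
known the default of 1 um/px keeps every output valid in pixel units.
"""

from __future__ import annotations

import dataclasses
import enum
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from stromaquant.errors import ConfigError, UnsupportedFormatError

__all__ = [
    "Modality",
    "RasterImage",
    "RegionMask",
    "StainVectorSet",
    "AnalysisConfig",
    "MARKERS",
    "read_image",
    "write_image",
    "write_results",
    "load_config",
    "save_config",
]


class Modality(str, enum.Enum):
    """Stain/imaging modality of a micrograph."""

    PSR = "PSR"          # picrosirius red under crossed polarizers
    TRICHROME = "TRICHROME"  # Masson's trichrome brightfield
    IHC = "IHC"          # chromogenic immunohistochemistry
    HE = "HE"            # hematoxylin & eosin brightfield


#: Markers whose scoring rules the IHC module implements.
MARKERS = (
    "Ki67",
    "bCatenin",
    "ECadherin",
    "NCadherin",
    "FAK",
    "CD44",
    "CD133",
    "Caspase3",
)


@dataclass
class RasterImage:
    """An RGB micrograph with pixel-size metadata.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Float values in [0, 1] (rescaled from integer bit depth on read).
    pixel_size_um : float
        Micrometres per pixel; 1.0 when unknown.
    source_path : str
        Provenance of the raster, empty for in-memory images.
    modality : Modality
        Stain/imaging modality.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    source_path: str = ""
    modality: Modality = Modality.PSR

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"RasterImage requires an H x W x 3 array, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < 16 or w < 16:
            raise ValueError(f"RasterImage requires H, W >= 16, got {h} x {w}")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("RasterImage pixel values must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the raster."""
        return self.pixels.shape[:2]


@dataclass
class RegionMask:
    """A boolean region of interest paired with a raster of the same H x W."""

    pixels: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("RegionMask requires a 2-D boolean array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())


@dataclass
class StainVectorSet:
    """Unit RGB optical-density directions for the three chromogens.

    ``vectors`` rows are (hematoxylin, dab, vector_red); each row is
    renormalized to unit length on construction.  The row matrix must be
    invertible (condition number < 1e3) for deconvolution.
    """

    names: tuple[str, str, str] = ("hematoxylin", "dab", "vector_red")
    vectors: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.650, 0.704, 0.286],   # hematoxylin
                [0.269, 0.568, 0.778],   # DAB
                [0.095, 0.708, 0.700],   # Vector Red
            ]
        )
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.shape != (3, 3):
            raise ValueError("StainVectorSet requires a 3 x 3 matrix")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be nonzero")
        self.vectors = v / norms[:, None]
        self.names = tuple(self.names)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StainVectorSet):
            return NotImplemented
        return self.names == other.names and np.allclose(
            self.vectors, other.vectors, atol=1e-12
        )

    @property
    def matrix(self) -> np.ndarray:
        """Row matrix of unit stain vectors (stains x RGB)."""
        return self.vectors

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.vectors))

    def index(self, name: str) -> int:
        return self.names.index(name)


def _default_hue_bins() -> list[tuple[str, float, float]]:
    # Conventional picrosirius-red hue windows; red wraps around 0 degrees.
    return [
        ("red", 0.0, 25.0),
        ("orange", 25.0, 45.0),
        ("yellow", 45.0, 70.0),
        ("green", 70.0, 160.0),
        ("red", 335.0, 360.0),
    ]


def _default_od_thresholds() -> dict[str, float]:
    return {m: 0.15 for m in MARKERS}


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline with documented defaults.

    Hue bins are (name, lo_deg, hi_deg) half-open intervals covering part of
    [0, 360); a name may appear more than once (the red bin wraps around 0).
    Thresholds apply to deconvolved stain densities in OD units.
    """

    hue_bins: list[tuple[str, float, float]] = field(default_factory=_default_hue_bins)
    # half-intensity threshold: for an in-focus bright object on a dark
    # field the 0.5-value level set tracks the object boundary, so mask
    # width is unbiased; lower it for dim acquisitions
    birefringence_value_min: float = 0.5
    birefringence_saturation_min: float = 0.2
    stain_vectors: StainVectorSet = field(default_factory=StainVectorSet)
    od_positive_threshold: dict[str, float] = field(default_factory=_default_od_thresholds)
    membrane_completeness_min: float = 0.95
    pixel_size_um: float = 1.0
    seed: int = 0
    # fiber extraction
    min_fiber_length_px: float = 15.0
    gap_max_px: float = 10.0
    merge_angle_max_deg: float = 20.0
    min_component_px: int = 9
    # cell geometry for IHC scoring
    nucleus_radius_px: float = 5.0
    cell_radius_px: float = 12.0
    ring_thickness_px: int = 3
    n_membrane_sectors: int = 36
    ck18_od_threshold: float = 0.15
    # morphometry
    spheroid_opening_radius_px: int = 3
    spheroid_min_area_px: float = 100.0
    n_diameter_directions: int = 36
    lumen_value_min: float = 0.92
    lumen_area_min_px: float = 20.0
    lumen_area_max_px: float = 100000.0
    lumen_boundary_adjacency_min: float = 0.7
    # trichrome thresholds
    trichrome_white_value_min: float = 0.95
    trichrome_tissue_saturation_min: float = 0.1
    trichrome_color_saturation_min: float = 0.2
    trichrome_blue_hue: tuple[float, float] = (180.0, 260.0)
    trichrome_red_hue: tuple[float, float] = (300.0, 20.0)  # wraps through 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check the config invariants, raising ConfigError on violation."""
        arcs: list[tuple[str, float, float]] = []
        for name, lo, hi in self.hue_bins:
            lo, hi = float(lo), float(hi)
            if not (0.0 <= lo < hi <= 360.0):
                raise ConfigError(f"hue bin {name!r} [{lo}, {hi}) is not within [0, 360]")
            arcs.append((name, lo, hi))
        for i, (na, la, ha) in enumerate(arcs):
            for nb, lb, hb in arcs[i + 1 :]:
                if la < hb and lb < ha:
                    raise ConfigError(
                        f"hue bins {na!r} [{la}, {ha}) and {nb!r} [{lb}, {hb}) overlap"
                    )
        scalar_thresholds = {
            "birefringence_value_min": self.birefringence_value_min,
            "birefringence_saturation_min": self.birefringence_saturation_min,
            "ck18_od_threshold": self.ck18_od_threshold,
        }
        for key, val in scalar_thresholds.items():
            if val < 0:
                raise ConfigError(f"threshold {key} must be >= 0, got {val}")
        for marker, val in self.od_positive_threshold.items():
            if val < 0:
                raise ConfigError(
                    f"od_positive_threshold[{marker!r}] must be >= 0, got {val}"
                )
        if not 0.0 <= self.membrane_completeness_min <= 1.0:
            raise ConfigError("membrane_completeness_min must be in [0, 1]")
        if not isinstance(self.stain_vectors, StainVectorSet):
            self.stain_vectors = StainVectorSet(**self.stain_vectors)

    def hue_bin_names(self) -> list[str]:
        """Bin names in first-appearance order (duplicates collapsed)."""
        seen: list[str] = []
        for name, _, _ in self.hue_bins:
            if name not in seen:
                seen.append(name)
        return seen


# ---------------------------------------------------------------------------
# image I/O


def read_image(
    path: str | os.PathLike,
    modality: Modality | str = Modality.PSR,
    pixel_size_um: float = 1.0,
) -> RasterImage:
    """Read an 8- or 16-bit RGB/grayscale TIFF or PNG as a [0, 1] float raster.

    Grayscale is promoted to three identical channels; integer values are
    rescaled by the bit-depth maximum (255 or 65535).
    """
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures vary by backend
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise UnsupportedFormatError(
            f"{path!r}: unsupported bit depth {arr.dtype}; expected uint8 or uint16"
        )
    px = arr.astype(np.float64) / scale
    if px.ndim == 2:
        px = np.repeat(px[:, :, None], 3, axis=2)
    elif px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]  # drop alpha
    elif px.ndim != 3 or px.shape[2] != 3:
        raise UnsupportedFormatError(
            f"{path!r}: unsupported channel layout with shape {arr.shape}"
        )
    return RasterImage(px, pixel_size_um=pixel_size_um, source_path=path, modality=modality)


def write_image(image: RasterImage, path: str | os.PathLike) -> None:
    """Write a raster as 16-bit TIFF (.tif/.tiff) or 16-bit PNG (.png)."""
    path = os.fspath(path)
    data = np.round(np.clip(image.pixels, 0.0, 1.0) * 65535.0).astype(np.uint16)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, data, photometric="rgb")
    elif path.lower().endswith(".png"):
        iio.imwrite(path, data)
    else:
        raise UnsupportedFormatError(f"unsupported output format for {path!r}")


def read_mask(path: str | os.PathLike, label: str = "roi") -> RegionMask:
    """Read a single-channel TIFF/PNG as a boolean mask (nonzero = True)."""
    arr = iio.imread(os.fspath(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return RegionMask(arr > 0, label=label)


def write_mask(mask: RegionMask, path: str | os.PathLike) -> None:
    iio.imwrite(os.fspath(path), (mask.pixels.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# tabular results


def write_results(
    records: Sequence[Mapping] | pd.DataFrame,
    path: str | os.PathLike,
    columns: Iterable[str] | None = None,
) -> None:
    """Write result rows as CSV with a header, preserving input order.

    Floats are serialized with 8 significant digits so re-reading reproduces
    values; two runs on the same input produce byte-identical files.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=list(columns) if columns else None)
    df.to_csv(os.fspath(path), index=False, float_format="%.8g", lineterminator="\n")


# ---------------------------------------------------------------------------
# configuration files (YAML)


def _config_to_plain(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    d["stain_vectors"] = {
        "names": list(config.stain_vectors.names),
        "vectors": config.stain_vectors.vectors.tolist(),
    }
    d["hue_bins"] = [[name, float(lo), float(hi)] for name, lo, hi in config.hue_bins]
    d["trichrome_blue_hue"] = list(config.trichrome_blue_hue)
    d["trichrome_red_hue"] = list(config.trichrome_red_hue)
    return d


def save_config(config: AnalysisConfig, path: str | os.PathLike) -> None:
    """Serialize a config to YAML (keys sorted for determinism)."""
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(_config_to_plain(config), fh, sort_keys=True)


def load_config(path: str | os.PathLike | None = None) -> AnalysisConfig:
    """Load a YAML config; missing keys are filled from the defaults.

    An absent path or an empty file yields the full default configuration.
    Invariants (disjoint hue bins, nonnegative thresholds) are validated.
    """
    raw: dict = {}
    if path is not None:
        with open(os.fspath(path)) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {path!r} must be a mapping")
            raw = loaded
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "stain_vectors" in kwargs:
        sv = kwargs["stain_vectors"]
        kwargs["stain_vectors"] = StainVectorSet(
            names=tuple(sv["names"]), vectors=np.array(sv["vectors"])
        )
    if "hue_bins" in kwargs:
        kwargs["hue_bins"] = [
            (str(b[0]), float(b[1]), float(b[2])) for b in kwargs["hue_bins"]
        ]
    for key in ("trichrome_blue_hue", "trichrome_red_hue"):
        if key in kwargs:
            kwargs[key] = tuple(float(x) for x in kwargs[key])
    return AnalysisConfig(**kwargs)
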