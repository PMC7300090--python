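"""Collagen fiber extraction and distribution statistics for PSR images.

Fibers are bright birefringent structures on a dark field.  Extraction is a
fixed, open skeleton-tracing algorithm: threshold in HSV, skeletonize, split
at branch points, discard short segments, merge collinear segments across
small gaps, then measure per-fiber angle (total-least-squares orientation,
axial in [0, 180)), arc length, and width (mean of twice the Euclidean
distance transform along the skeleton).

Orientation statistics are axial: angles are doubled before vector
averaging, so the resultant length R is 1 for perfectly aligned fibers and
0 for an isotropic (or orthogonally balanced) field; circular variance is
1 - R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps
from scipy.spatial import cKDTree
from skimage.color import rgb2hsv
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_objects, skeletonize

from stromaquant.core_io import AnalysisConfig, Modality, RasterImage, RegionMask
from stromaquant.errors import InsufficientDataError
from stromaquant.stats import StatResult, GroupSummary, mean_sem

__all__ = [
    "Fiber",
    "FiberSet",
    "DistributionSummary",
    "segment_birefringent",
    "extract_fibers",
    "angular_statistics",
    "summarize_distribution",
    "compare_distributions",
]


def fold_axial(angle_deg) -> np.ndarray | float:
    """Fold an orientation into the axial range [0, 180)."""
    folded = np.mod(angle_deg, 180.0)
    # np.mod can round a tiny negative remainder up to exactly 180.0
    return np.where(folded >= 180.0, 0.0, folded)[()]


def axial_difference(a_deg: float, b_deg: float) -> float:
    """Smallest difference between two undirected orientations (<= 90 deg)."""
    d = abs(fold_axial(a_deg) - fold_axial(b_deg))
    return min(d, 180.0 - d)


def orientation_of_points(coords: np.ndarray) -> float:
    """Total-least-squares orientation of (row, col) points, in [0, 180).

    Angles are measured from the +column axis, counterclockwise with rows
    increasing downward (i.e. image convention: 0 deg horizontal, 90 deg
    vertical).
    """
    pts = np.asarray(coords, dtype=np.float64)
    x = pts[:, 1]
    y = -pts[:, 0]  # flip rows so angles read counterclockwise
    x = x - x.mean()
    y = y - y.mean()
    cov = np.array([[np.dot(x, x), np.dot(x, y)], [np.dot(x, y), np.dot(y, y)]])
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, np.argmax(evals)]
    return float(fold_axial(np.degrees(np.arctan2(vy, vx))))


@dataclass
class Fiber:
    """One traced fiber: a polyline in (row, col) pixel coordinates."""

    polyline: np.ndarray
    length_px: float
    width_px: float
    angle_deg: float
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=np.float64)
        if not 0.0 <= self.angle_deg < 180.0:
            raise ValueError(f"angle_deg {self.angle_deg} outside [0, 180)")
        if self.width_px <= 0:
            raise ValueError("width_px must be positive")


@dataclass
class FiberSet:
    """A collection of fibers with their sample/region/condition labels."""

    fibers: list[Fiber] = field(default_factory=list)
    source: dict = field(default_factory=dict)
    pooled: bool = False

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([f.angle_deg for f in self.fibers])

    @property
    def lengths_px(self) -> np.ndarray:
        return np.array([f.length_px for f in self.fibers])

    @property
    def widths_px(self) -> np.ndarray:
        return np.array([f.width_px for f in self.fibers])

    @classmethod
    def pool(cls, sets: Iterable["FiberSet"]) -> "FiberSet":
        """Concatenate fiber sets, stamping each fiber with its set's source."""
        fibers: list[Fiber] = []
        for fs in sets:
            for f in fs.fibers:
                src = dict(fs.source)
                src.update(f.source)
                fibers.append(Fiber(f.polyline, f.length_px, f.width_px, f.angle_deg, src))
        return cls(fibers=fibers, source={}, pooled=True)


@dataclass
class DistributionSummary:
    """Tukey box-plot summary: quartiles, 1.5*IQR whiskers, outliers, mean/SEM."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    mean: float
    sem: float
    sem_defined: bool


# ---------------------------------------------------------------------------
# segmentation


def segment_birefringent(image: RasterImage, config: AnalysisConfig | None = None) -> RegionMask:
    """Mask the bright birefringent (collagen) signal of a polarized PSR image.

    Foreground pixels exceed both the HSV value and saturation thresholds;
    connected components smaller than ``min_component_px`` are removed.
    """
    config = config or AnalysisConfig()
    if image.modality != Modality.PSR:
        warnings.warn(f"expected PSR modality, got {image.modality}", stacklevel=2)
    hsv = rgb2hsv(image.pixels)
    mask = (hsv[:, :, 2] > config.birefringence_value_min) & (
        hsv[:, :, 1] > config.birefringence_saturation_min
    )
    if config.min_component_px > 1:
        # drop components smaller than min_component_px (max_size removes <=)
        mask = remove_small_objects(mask, max_size=config.min_component_px - 1)
    if not mask.any():
        warnings.warn("birefringence mask is empty", stacklevel=2)
    return RegionMask(mask, label="birefringent")


# ---------------------------------------------------------------------------
# skeleton tracing


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _trace_path(coords: np.ndarray) -> np.ndarray:
    """Order the pixels of one skeleton segment along its longest path."""
    if len(coords) == 1:
        return coords
    index = {tuple(p): i for i, p in enumerate(map(tuple, coords))}
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    adj[i].append(j)

    def bfs(start: int) -> tuple[int, dict[int, int]]:
        parent = {start: -1}
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in parent:
                        parent[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, parent

    u, _ = bfs(0)
    v, parent = bfs(u)
    path = [v]
    while parent[path[-1]] != -1:
        path.append(parent[path[-1]])
    return coords[np.array(path[::-1])]


def _segment_polylines(mask: np.ndarray, min_length: float) -> list[np.ndarray]:
    """Skeletonize, cut at branch points, and return ordered pixel polylines."""
    skel = skeletonize(mask)
    if not skel.any():
        return []
    neighbors = ndi.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    branch = skel & (neighbors >= 3)
    cut = skel & ~branch
    labels = sk_label(cut, connectivity=2)
    polylines = []
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        local = np.argwhere(labels[sl] == lab)
        coords = local + np.array([sl[0].start, sl[1].start])
        path = _trace_path(coords)
        if _arc_length(path) >= min_length:
            polylines.append(path)
    return polylines


def _arc_length(polyline: np.ndarray) -> float:
    if len(polyline) < 2:
        return 0.0
    steps = np.diff(np.asarray(polyline, dtype=np.float64), axis=0)
    return float(np.sqrt((steps**2).sum(axis=1)).sum())


def _merge_segments(
    polylines: list[np.ndarray], gap_max: float, angle_max: float
) -> list[np.ndarray]:
    """Join segment pairs with close endpoints and near-collinear orientations.

    Candidate connections (endpoint distance <= gap_max, axial orientation
    difference < angle_max, and — for non-touching endpoints — connector
    direction consistent with both orientations) are accepted greedily by
    increasing orientation difference; each endpoint joins at most once and
    cycles are rejected, so accepted connections chain segments into paths.
    """
    n = len(polylines)
    if n < 2:
        return polylines
    angles = [orientation_of_points(p) for p in polylines]
    endpoints = np.array(
        [[p[0], p[-1]] for p in polylines], dtype=np.float64
    )  # (n, 2, 2)
    flat = endpoints.reshape(-1, 2)  # endpoint k of fiber k//2? no: index = 2*i + e
    tree = cKDTree(flat)
    pairs = tree.query_pairs(gap_max, output_type="ndarray")
    candidates = []
    for a, b in pairs:
        i, ei = divmod(int(a), 2)
        j, ej = divmod(int(b), 2)
        if i == j:
            continue
        dang = axial_difference(angles[i], angles[j])
        if dang >= angle_max:
            continue
        gap_vec = flat[b] - flat[a]
        gap = float(np.hypot(*gap_vec))
        if gap > 2.0:
            conn = fold_axial(np.degrees(np.arctan2(-gap_vec[0], gap_vec[1])))
            if (
                axial_difference(conn, angles[i]) >= angle_max
                or axial_difference(conn, angles[j]) >= angle_max
            ):
                continue
        candidates.append((dang, i, ei, j, ej))
    candidates.sort(key=lambda t: (t[0], t[1], t[3], t[2], t[4]))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used: set[tuple[int, int]] = set()
    links: list[tuple[int, int, int, int]] = []
    for _, i, ei, j, ej in candidates:
        if (i, ei) in used or (j, ej) in used:
            continue
        ri, rj = find(i), find(j)
        if ri == rj:
            continue  # would close a cycle
        parent[ri] = rj
        used.add((i, ei))
        used.add((j, ej))
        links.append((i, ei, j, ej))
    if not links:
        return polylines

    # assemble chains: each segment has <= 1 link per endpoint
    link_of: dict[tuple[int, int], tuple[int, int]] = {}
    for i, ei, j, ej in links:
        link_of[(i, ei)] = (j, ej)
        link_of[(j, ej)] = (i, ei)
    linked_ids = {i for i, _, _, _ in links} | {j for _, _, j, _ in links}
    merged: list[np.ndarray] = [p for k, p in enumerate(polylines) if k not in linked_ids]
    visited: set[int] = set()
    for start in sorted(linked_ids):
        if start in visited:
            continue
        # find a free endpoint of this chain to start the walk
        node, end = start, 0
        seen_walk = set()
        while (node, end) in link_of and (node, end) not in seen_walk:
            seen_walk.add((node, end))
            node, other_end = link_of[(node, end)]
            end = 1 - other_end  # continue from the far endpoint
        chain = []
        cur, entry = node, end  # entry endpoint has no link; traverse toward other end
        while True:
            visited.add(cur)
            poly = polylines[cur]
            chain.append(poly if entry == 0 else poly[::-1])
            exit_end = 1 - entry
            nxt = link_of.get((cur, exit_end))
            if nxt is None:
                break
            cur, nxt_end = nxt
            entry = nxt_end
        merged.append(np.vstack(chain))
    return merged


def extract_fibers(
    mask: RegionMask | np.ndarray,
    config: AnalysisConfig | None = None,
    source: dict | None = None,
) -> FiberSet:
    """Trace individual fibers from a birefringence mask.

    Steps: (1) skeletonize; (2) cut the skeleton at branch points; (3) drop
    segments shorter than ``min_fiber_length_px``; (4) merge segment pairs
    whose endpoints lie within ``gap_max_px`` and whose orientations differ
    by less than ``merge_angle_max_deg``; (5) measure each retained fiber.
    Width is the mean over skeleton pixels of twice the distance transform
    of the original mask.  Deterministic: identical mask, identical output.
    """
    config = config or AnalysisConfig()
    pixels = mask.pixels if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if not pixels.any():
        return FiberSet(source=source or {})
    polylines = _segment_polylines(pixels, config.min_fiber_length_px)
    polylines = _merge_segments(polylines, config.gap_max_px, config.merge_angle_max_deg)
    edt = ndi.distance_transform_edt(pixels)
    fibers = []
    for poly in polylines:
        length = _arc_length(poly)
        if length < config.min_fiber_length_px:
            continue
        rr = np.clip(np.round(poly[:, 0]).astype(int), 0, pixels.shape[0] - 1)
        cc = np.clip(np.round(poly[:, 1]).astype(int), 0, pixels.shape[1] - 1)
        width = float(2.0 * edt[rr, cc].mean())
        if width <= 0:
            continue
        fibers.append(
            Fiber(poly, length, width, orientation_of_points(poly), dict(source or {}))
        )
    return FiberSet(fibers=fibers, source=source or {})


# ---------------------------------------------------------------------------
# statistics


def angular_statistics(
    fibers: FiberSet | Sequence[float],
) -> tuple[float, float, float]:
    """Axial circular statistics of fiber orientations.

    Angles are doubled onto the full circle, vector-averaged, and the mean
    halved back.  Returns ``(circular_mean_deg, resultant_R, circular_variance)``
    with R in [0, 1]: near 0 for isotropic fields, near 1 for aligned ones.
    """
    angles = fibers.angles_deg if isinstance(fibers, FiberSet) else np.asarray(fibers, float)
    if angles.size == 0:
        raise InsufficientDataError("angular statistics undefined for an empty set")
    doubled = np.radians(2.0 * angles)
    c, s = np.cos(doubled).mean(), np.sin(doubled).mean()
    r = float(np.hypot(c, s))
    mean = float(fold_axial(np.degrees(np.arctan2(s, c)) / 2.0))
    return mean, r, 1.0 - r


def summarize_distribution(values: Sequence[float]) -> DistributionSummary:
    """Tukey box-plot summary of a pooled measurement distribution.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme data points within 1.5*IQR of the quartiles;
    points beyond are listed as outliers.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise InsufficientDataError("summary undefined for an empty sample")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    whisker_lo = float(inside.min()) if inside.size else float(q1)
    whisker_hi = float(inside.max()) if inside.size else float(q3)
    outliers = np.sort(arr[(arr < lo_fence) | (arr > hi_fence)])
    ms = mean_sem(arr)
    return DistributionSummary(
        n=int(arr.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=whisker_lo,
        whisker_hi=whisker_hi,
        outliers=outliers,
        mean=ms.mean,
        sem=ms.sem,
        sem_defined=ms.sem_defined,
    )


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sample Kolmogorov-Smirnov comparison of measurement distributions.

    D is the supremum distance between the two empirical CDFs; the p-value
    is scipy's default (exact for small samples, asymptotic otherwise).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 5 or b.size < 5:
        raise InsufficientDataError(
            f"KS comparison requires n >= 5 per sample (got {a.size}, {b.size})"
        )
    res = sps.ks_2samp(a, b)
    groups = [
        GroupSummary("a", int(a.size), float(a.mean()), float(np.std(a, ddof=1) / np.sqrt(a.size))),
        GroupSummary("b", int(b.size), float(b.mean()), float(np.std(b, ddof=1) / np.sqrt(b.size))),
    ]
    return StatResult(
        "two-sample KS",
        groups,
        float(res.statistic),
        float(res.pvalue),
        extra={"n_a": int(a.size), "n_b": int(b.size), "D": float(res.statistic)},
    )
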