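# Methods

`stromaquant` quantifies tumor-microenvironment architecture and tumor-cell
phenotype from brightfield and polarized-light micrographs. This note
records the models and procedures the package implements, the parameters
that matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was open.

## Image model and conventions

Images are H x W x 3 arrays of reflectance/transmittance in [0, 1],
row-major, origin top-left, 0-based. Physical lengths are `px *
pixel_size_um`; the default pixel size is 1 um/px, so with no calibration
every output remains valid in pixel units. Four modalities are carried as
metadata: PSR (picrosirius red under crossed polarizers), TRICHROME
(Masson's), IHC (chromogenic), and HE.

## Collagen fiber architecture

**Segmentation.** Birefringent collagen is bright and saturated on a dark
field. The foreground mask takes pixels with HSV value above
`birefringence_value_min` (default 0.5) and saturation above
`birefringence_saturation_min` (default 0.2), then removes connected
components under `min_component_px` (9 px). The 0.5 value default is the
half-intensity level set: for an in-focus bright structure the 50% contour
tracks the geometric boundary, which keeps downstream width measurements
unbiased. Dim acquisitions should lower it via the config.

**Fiber tracing.** Individual fibers come from a fixed, open skeleton
algorithm: (1) skeletonize the mask; (2) cut the skeleton at branch points
(pixels with three or more skeleton neighbors); (3) drop segments with arc
length under `min_fiber_length_px` (15 px); (4) merge segment pairs whose
endpoints lie within `gap_max_px` (10 px) and whose orientations differ by
less than `merge_angle_max_deg` (20 deg); (5) measure each retained fiber.
Merging re-joins fibers split by crossings. Candidate connections are
accepted greedily by increasing orientation difference, each endpoint joins
at most once, cycles are rejected, and — for endpoint gaps above 2 px —
the connector direction must itself be collinear (within the same angle
bound) with both segments, which prevents close parallel fibers from being
fused while still chaining multi-split fibers back together.

**Per-fiber measures.** Length is the polyline arc length. Width is the
mean over skeleton pixels of twice the Euclidean distance transform of the
mask — exact for the straight-capsule geometry of the synthetic oracle.
Orientation is the total-least-squares (principal-axis) line through the
polyline, folded into [0, 180) since fibers are undirected.

**Axial statistics.** Orientations are doubled onto the full circle before
vector averaging; the resultant length R is 1 for perfect alignment and 0
for isotropy (or an orthogonally balanced field), circular variance is
1 − R, and the circular mean is halved back into [0, 180).

**Distribution summaries.** Tukey box summaries: quartiles by linear
interpolation, whiskers at the most extreme data inside 1.5 x IQR of the
quartiles, points beyond listed as outliers; mean and SEM (sd with ddof=1
over sqrt(n); a single value reports SEM 0 with a flag). Distributions are
compared with the two-sample Kolmogorov–Smirnov test (scipy's exact/asymp
switch). The source material describes "Kolmogorov-Smirnov chi-square"
tests, an ambiguous phrase; the standard two-sample KS test is what is
implemented.

## Hue analysis

Masked pixel hues (degrees) are counted into configurable half-open bins;
the defaults are the conventional picrosirius windows red [0, 25) U [335,
360), orange [25, 45), yellow [45, 70), green [70, 160). Hues in the
cyan–magenta range fall outside every bin; genuine birefringence does not
produce them, so they are tallied separately and excluded from the
fractions rather than force-assigned, keeping the four fractions
interpretable. Fractions are invariant to uniform brightness scaling
because value scaling leaves hue untouched.

Trichrome ratios count blue (hue [180, 260)) and red (hue [300, 360) U
[0, 20), both at saturation > 0.2) pixels against all tissue pixels
(value < 0.95 or saturation > 0.1). The windows separate aniline blue from
Biebrich scarlet unambiguously on synthetic fields and are configurable.

## IHC deconvolution and scoring

**Beer–Lambert mixing.** Chromogen amounts add linearly in optical density
OD = −log(transmittance); a pixel's OD triple is the stain density vector
times the 3 x 3 matrix of unit stain vectors. Defaults (RGB OD,
renormalized): hematoxylin (0.650, 0.704, 0.286), DAB (0.269, 0.568,
0.778), Vector Red (0.095, 0.708, 0.700). Deconvolution applies the exact
matrix inverse per pixel, clips negative densities to zero, and reports the
clipped mass fraction; a basis with condition number >= 1e3 is refused.

**Cell geometry.** Nuclei are segmented from the hematoxylin density by
Otsu's threshold (with a 0.1 OD floor so pure noise is never split into
objects), hole filling, small-object removal, and a watershed split on the
distance transform. Each nucleus is expanded to `cell_radius_px` (default
12 px), capped where neighbors meet; the membrane ring is the
`ring_thickness_px` (3 px) band just inside the cell boundary, and
cytoplasm is the remainder. Compartments are disjoint by construction.

**Gating and rules.** Tumor cells are gated by mean Vector Red density
over the cell (the CK-18 epithelial label) above `ck18_od_threshold`
(0.15). Marker rules, each thresholding deconvolved DAB density at the
marker's `od_positive_threshold` (default 0.15, one global value per
marker, no per-image adaptation — this keeps scoring deterministic and
monotone in the threshold):

- **Ki67, beta-catenin** — positive if the mean nuclear DAB exceeds the
  threshold.
- **E-cadherin, CD44, CD133** — the ring is divided into 36 angular
  sectors about the centroid; completeness is the fraction of sectors whose
  mean DAB exceeds the threshold; positive at completeness >=
  `membrane_completeness_min` (0.95). "Complete membrane localization" has
  no published metric; sector coverage is the standard operationalization
  and is directly testable.
- **N-cadherin** — the membrane rule, or else the nuclear rule (nuclear
  signal indicates cytoplasmic protein not yet at the membrane).
- **Caspase-3** — mean DAB over ring plus cytoplasm.
- **FAK** — stained area fraction of the tumor region (tumor pixels with
  DAB above threshold over all tumor pixels).

Cells touching the frame border have degenerate rings; membrane scoring
excludes them and reports the excluded tally, so scored cells always equal
gated tumor cells minus exclusions.

The FAK rule is the only per-pixel rule and is therefore the most
noise-sensitive: the DAB and Vector Red vectors are ~13 degrees apart, so
additive OD noise of sd 0.02 appears on the DAB density with sd ~0.09
(amplification = the norm of the inverse-matrix column, ~4.6), and the
Gaussian tail above the 0.15 threshold contributes a ~4.7% false-positive
area on unstained tumor pixels. Compartment-mean rules average this noise
away and recover generated fractions essentially exactly.

## Morphometry

**Spheroid diameter.** The tissue mask is opened with a disk of radius 3
px to suppress thin migratory protrusions, the largest sufficiently large
component is kept (flagged if it was not unique), and the "average
diameter" is the mean, over 36 equally spaced directions, of the in-mask
length of the chord through the component centroid (sampled at 0.5 px).
For a disk this is the diameter in every direction; the published scripts
behind the measurement are unavailable, so this centroid-chord definition
is declared rather than inferred, and area plus circularity (4*pi*A/P^2,
Crofton perimeter) are reported alongside so an area-equivalent diameter
can be derived if preferred. The measure is rotation-invariant within 2%.

**Vessels.** Candidate lumens are bright connected components (value >
0.92) with area in [20, 1e5] px whose boundary is at least 70% adjacent to
stained (non-bright) pixels — an operational definition of an
annulus-enclosed lumen, exact on noise-free synthetic fields up to 50
non-overlapping vessels. Full histologic vessel recognition is out of
scope.

## Group statistics

Two groups: Student's t-test (equal variances; Welch and paired variants
by flag). Three or more: one-way ANOVA with Tukey HSD pairwise post-hoc
comparisons. No correction is applied across separate analyses beyond
Tukey within an ANOVA. Both the KS test and the ANOVA hold their nominal
5% type-I error on null simulations (the acceptance script measures the
rates).

## Synthetic generators: what they emulate and what they do not

All generators are deterministic given their spec (including its seed) and
store exhaustive ground truth, so every stage is validated by parameter
recovery rather than by eye.

- **Fiber fields** render straight anti-aliased capsules (axial-uniform or
  axial von Mises angles; lognormal lengths and widths, defaults: median 60
  px length with sigma_log 0.4, median 6 px width with sigma_log 0.25,
  500 fibers on 2048 x 2048 — a sparse field at ~4% coverage) on a
  near-black field. Hue encodes bundling by the invertible rule
  `hue = 160 − 150 * clip(bundling * (w − 2)/(12 − 2), 0, 1)` (thin →
  green 160, thick → red 10; the 2 and 12 px anchors bracket the width
  model). Fibers are straight because curvature is not among the measured
  quantities; real fibers curve, branch and vary in intensity, so recovery
  here demonstrates the estimator, not robustness to stain artifacts.
- **IHC fields** place disk cells on a jittered grid with center spacing
  above twice the cell radius, guaranteeing segmentability so scoring
  tests isolate the scoring rules from segmentation hardness. Painted
  densities: hematoxylin 0.8 (nuclei), Vector Red 0.5 (tumor cells), DAB
  0.6 (0.5 for the diffuse Caspase-3 pattern). Negative cells for membrane
  markers carry a partial ring arc (default 50% of the circumference).
  Real tissue has touching cells, anisotropic shapes and uneven staining;
  those failure modes are not exercised.
- **Trichrome fields** assign exact pixel counts of saturated blue, red,
  and near-white unstained tissue (value 0.94, below the 0.95 white
  threshold so it counts in the tissue denominator), clustered into blobs
  by ranking a smoothed random field.
- **Spheroids and vessels** are disks with optional thin radial spurs
  (width 3 px, length 20 px) and annulus-walled bright lumens with
  non-overlapping placement.

## Problem sizes and degenerate inputs

The validation suite uses 500-fiber fields at 2048 x 2048, 200-cell IHC
fields at 512 x 512 (32 marker-fraction combinations), 35-vessel frames at
700 x 700 and 500-replicate null calibrations; these sizes give stable
recovery statistics while keeping a full run in minutes on one CPU.
Degenerate inputs follow one rule: empty masks and empty fields flow
through as empty results with warnings, while statistics that would be
mathematically undefined (empty samples, zero tumor cells, empty tumor
region) raise explicit errors or return flagged NaN fractions.

## Known limitations

- The fiber extractor is a functional replacement for curvelet-based
  tracing; it reports the same distributional quantities but makes no
  attempt to match any particular tool's fiber counts on real slides.
- Hue windows, OD thresholds and stain vectors are declared defaults, not
  values fitted to clinical material; analyses of real slides should
  calibrate them via the config file.
- Whole-slide formats, ICC color management, fluorescence quantification
  and curved-fiber metrics are out of scope.
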