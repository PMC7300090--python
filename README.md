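# stromaquant

Quantification of tumor-microenvironment histology: collagen fiber
architecture from picrosirius-red (PSR) polarized-light images, hue-based
collagen bundling, Masson's trichrome blue/red ratios, dual-chromogen IHC
stain deconvolution with per-cell subcellular marker scoring, and
spheroid/vessel morphometry. It is aimed at groups studying how stromal
collagen organization shapes tumor phenotype (e.g. colorectal cancer
spheroids in engineered collagen constructs) who need the image-analysis
half of that workflow as open, tested, scriptable code instead of
proprietary pipelines.

Because such studies rarely deposit raw images, the package ships a
synthetic-histology generator with exhaustive ground truth; every analysis
stage is validated by parameter recovery against it.

## What it computes

- **Fiber architecture** — bright birefringent collagen is masked in HSV,
  skeleton-traced into individual fibers, and each fiber gets an arc
  length, a width (mean of twice the distance transform along the
  skeleton) and an axial orientation in [0, 180). Orientation statistics
  are circular on doubled angles: resultant length R in [0, 1]
  (R ≈ 0 isotropic, R ≈ 1 aligned), circular variance 1 − R. Distributions
  are summarized as Tukey box statistics and compared with the two-sample
  Kolmogorov–Smirnov test.
- **Hue profiles** — masked PSR pixels binned into red / orange / yellow /
  green hue windows; red+orange fraction tracks collagen bundling.
- **IHC scoring** — Beer–Lambert deconvolution (OD = −log T, per-pixel
  3×3 inverse of unit stain vectors for hematoxylin / DAB / Vector Red),
  watershed cell segmentation, CK-18/Vector-Red tumor gating, then
  per-marker rules: nuclear (Ki67, β-catenin), complete-membrane over 36
  angular sectors (E-cadherin, CD44, CD133), membrane-or-nuclear
  (N-cadherin), membrane+cytoplasm (Caspase-3), stained area fraction
  (FAK).
- **Morphometry** — spheroid "average diameter" (mean centroid chord over
  36 directions after an opening that removes thin protrusions) and counts
  of bright-lumen vessels enclosed by stained walls.
- **Statistics** — Student's t-test / one-way ANOVA with Tukey HSD,
  mean ± SEM summaries, and JSON/CSV report bundling.

See `docs/methods.md` for the full model description and defaults.

## Worked example

Generate a synthetic polarized-light fiber field (500 fibers, axial von
Mises orientations centered on 90° with concentration κ = 8, lognormal
widths/lengths) and recover its architecture:

```python
import numpy as np
from stromaquant import synthetic
from stromaquant.fibers import angular_statistics, extract_fibers, segment_birefringent

spec = synthetic.FiberFieldSpec(n_fibers=500, angle_mu_deg=90.0, angle_kappa=8.0, seed=1)
image, truth = synthetic.generate_fiber_image(spec)
fibers = extract_fibers(segment_birefringent(image))
mean_deg, R, circ_var = angular_statistics(fibers)
print(f"n={len(fibers)}  mean={mean_deg:.1f} deg  R={R:.3f}")
print(f"median length {np.median(fibers.lengths_px):.1f} px, "
      f"median width {np.median(fibers.widths_px):.2f} px")
```

```
n=488  mean=90.4 deg  R=0.927
median length 58.1 px, median width 6.02 px
```

The generating model had a 90° mean, 60 px median length and 6 px median
width: the circular mean is recovered within half a degree and the medians
within a few percent, and R ≈ 0.93 correctly reports a strongly aligned
field (an isotropic field of the same size gives R ≈ 0.04).

The same works from the shell:

```sh
stromaquant simulate fibers --n-fibers 500 --kappa 8 --seed 1 --out field.tif
stromaquant fibers --image field.tif --out fibers.csv
stromaquant simulate ihc --marker ki67 --positive-fraction 0.3 --seed 5 --out ihc.tif
stromaquant ihc --image ihc.tif --marker ki67 --out score.json
```

`fibers.csv` holds one row per fiber (angle, length, width, in px and µm);
`score.json` reports the recovered Ki67-positive fraction of gated tumor
cells (0.30 for the field above) plus a per-cell CSV.

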