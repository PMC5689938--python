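# petrad

Reproducibility analysis of radiomic features extracted from masked 3D
PET-SUV volumes. `petrad` extracts a fixed catalogue of 79 radiomic
features from tumor regions of interest and quantifies how stable each
feature is under three sources of variation:

* **SM** — segmentation method: three correlated mask variants per case
  (labels `MTV1`, `MTV2`, `GBSV`);
* **GL** — gray-level discretization: fixed-bin-count re-binning of the
  ROI SUV range at 32 / 64 / 128 / 256 levels (reference 64);
* **RA** — reconstruction style: four image variants per case with
  different smoothing/noise profiles (labels `OSEM`, `FOREIR`,
  `FOREFBP`, `3DRP`; `OSEM` is the identity reference).

Because no patient data is bundled, a phantom module generates synthetic
cases with the statistical structure the analysis expects: ellipsoidal
tumors carrying a tunable Gaussian-random-field texture, boundary-jittered
mask variants constrained to pairwise Dice >= 0.75, and smoothing/noise
image variants in which the `3DRP`-like profile is the most divergent.

## Feature catalogue (79)

| family | count | notes |
|---|---|---|
| GLCM   | 26 | symmetric co-occurrence matrix pooled over the 13 unique one-voxel 3D directions |
| GLRLM  | 11 | run-length matrix summed over the same 13 directions |
| GLSZM  | 11 | size zones = 26-connected equal-level components |
| NGTDM  | 5  | 7x7 in-plane neighborhood, in-mask neighbors only |
| Shape  | 6  | volume, sphericity, spherical disproportionality, convexity (solidity), eccentricity, surface/volume |
| Intensity / IVH | 20 | first-order moments on raw SUVs, discretized-histogram entropy/uniformity, V10/50/90 and I10/50/90 |

Agreement statistics follow the Bland-Altman scheme on per-case
percentage differences `d = (f_m - f_n) / ((f_m + f_n)/2) * 100`:
`URL/LRL = mean(d) +/- 1.96 SD(d)`, a reproducibility gate
(`|mean d| <= 25` and `SD <= 35`), and a High / Intermediate / Low / NR
band from `max(|URL|, |LRL|)` (<=30 / <=45 / <=50 / otherwise).
Reliability uses the two-way random-effects, absolute-agreement,
single-measurement ICC with an F-based 95% CI; *precision* is the CI
half-width x 100.

## Command-line use

```bash
# synthetic cohort (NIfTI volumes/masks + manifest.json)
petrad phantom generate --out data/ --cases 10 --seed 1

# 79 features for every (mask, gray level, recon) combination the design needs
petrad extract --data data/ --out features.csv

# pair statistics, classification bands, ICC + precision
petrad repro --features features.csv --out report/

# color-coded reproducibility map
petrad report --report report/ --out figures/

# or everything in one step
petrad study --cases 10 --seed 1 --out study/
```

Volumes are read/written as NIfTI-1 (`.nii`/`.nii.gz`) or NRRD
(`.nrrd`); feature tables are long-format CSV
(`case_id, segmentation, gray_level, recon, feature_name, value`)
with a JSON mirror.

## Python API

```python
from petrad import StudyConfig, run_study

report = run_study(StudyConfig(n_cases=10, seed=1))
report.pair_stats          # per feature x pair: |d|, SD, LRL, URL, class
report.icc                 # per feature x parameter: ICC, 95% CI, precision
report.reproducible_sets   # per parameter + cross-parameter intersection
```

## Conventions worth knowing

* ROI-wise discretization: `bin_size = (SUVmax - SUVmin) / Ng` over
  in-mask voxels; levels `min(Ng, floor((v - min)/bin_size) + 1)`;
  a constant ROI maps to level 1 with a warning.
* GLCM/GLRLM pool one matrix over all 13 directions (per-direction
  aggregation is switchable via the `directions` argument).
* Sphericity is evaluated on a lightly smoothed marching-cubes mesh
  (area and enclosed volume), keeping it in (0, 1]; a voxel-face area
  cross-check is exposed as `voxel_face_surface_area`.
* `Ix` is the minimum intensity of the hottest x% of the ROI volume and
  is therefore non-increasing in x; `Vx` uses the relative-intensity
  axis `min + x% * range` and is non-increasing in x.
* All randomness flows through explicit integer seeds; identical
  (config, seed) reproduce reports bit-for-bit on one platform.
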