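# Methods

This note documents the models, parameter choices and numerical
conventions behind `voxfpar`, and what the synthetic-stand experiments do
and do not demonstrate about real data.

## 1. The measurement model

### PAR balances

Six quantum-sensor components per tree (incident/reflected at canopy top,
mid-canopy and base, averaged over four cardinal directions) enter two
whole-canopy balances:

* **`paper` mode (default)** — `APAR = PAR_ci − PAR_cr − (PAR_gi − PAR_gr)
  − (PAR_mi − PAR_mr)`. This three-layer form subtracts both the middle
  and ground net fluxes from the top net flux. It is kept as the default
  for fidelity to the field protocol this package implements, but it is
  not a standard two-level radiative balance: when much of the canopy's
  flux passes the mid-canopy sensor, the middle net flux is subtracted a
  second time and fPAR can go negative. Such records are **flagged
  invalid, never clipped**.
* **`two_layer` mode** — `APAR = (PAR_ci − PAR_cr) − (PAR_gi − PAR_gr)`,
  the standard top-minus-bottom balance, always in [0, 1] for physically
  ordered components.

### Per-stratum fPAR

The field protocol yields one six-component record per tree, but three
stratum labels are needed. The layer strategy used here takes net-flux
differences between adjacent sensor levels: with net fluxes
`F_c, F_m, F_g` (incident minus reflected at ~20, ~10, ~4 m),

    upper  = (F_c − F_m) / PAR_ci
    middle = (F_m − F_g) / PAR_ci
    lower  = F_g · (1 − τ_floor) / PAR_ci

`τ_floor` (default 0) is the fraction of below-base flux *not* credited to
the lower stratum. With the default, the lower stratum absorbs everything
that passes the base sensor; the three strata then sum to whole-canopy
two-layer fPAR. A consequence worth stating plainly: in a *thin* canopy
most light reaches the base sensor, so the lower stratum is credited with
more absorption than the upper one. The familiar ordering
upper ≥ middle ≥ lower therefore holds only for sufficiently absorbing
canopies — for the layer spacing used here, roughly when the optical depth
between the middle and base sensors exceeds ln 2. The simulator's default
parameterization satisfies this with margin (see §3); the package does not
enforce the ordering for arbitrary configurations.

### Stratum thresholds

Voxels are assigned to strata by centroid height `Z = (k + 0.5)·dz`
against fixed cut points (default 15 m / 7 m, the published zoning;
boundaries are lower-edge inclusive: `Z ≥ 15` is upper, `7 ≤ Z < 15`
middle). Percentile-derived thresholds (default 75th/40th of
LiDAR-derived tree heights, linear-interpolation percentiles) are
available via config; for the tightly height-clustered synthetic stands
the fixed zoning is the sensible default, since percentiles of a
near-degenerate height distribution land both cut points inside the upper
crown. Three zonings (labeling 15/7 m; validation 15–20/10–15/0–5 m;
5-m profile bins) are kept distinct and never merged.

## 2. LiDAR processing and fusion

* **Ground classification**: per-cell (default 2 m) minimum plus a
  tolerance band (default 0.3 m ≈ 6 vertical-noise standard deviations at
  the default simulation noise; large enough that the cell minimum — a
  low-order statistic of hundreds of returns — does not truncate the
  ground-return distribution). Suited to the near-planar orchard terrain
  in scope; no slope-adaptive filtering is attempted.
* **Normalization**: heights above a bilinearly interpolated per-cell mean
  ground surface; points below −0.1 m are dropped, small negatives clamped
  to 0.
* **CHM**: per-cell maximum of normalized heights; half-open, lower-edge
  inclusive binning with the origin floored to the cell grid (no
  double-counting at edges); empty cells are NaN.
* **Segmentation**: Gaussian smoothing (default σ = 1 cell), local maxima
  above `min_height` (default 2 m) separated by `min_distance` (default
  3 cells) as markers, watershed on the inverted smoothed CHM within the
  above-threshold mask. Plateau and tie cases resolve to the
  lexicographically smallest cell, so segmentation is deterministic.
* **Voxelization**: half-open floor binning; the per-column top point is
  the highest return, ties to the smallest point index. Default
  resolution 0.25 m × 0.25 m × 2 m: the centimetre-scale horizontal
  resolution used over multi-hectare stands implies ~10⁹ columns and is
  impractical (and unnecessary) at desk scale; it remains available via
  config.
* **Reflectance propagation**: nearest-neighbour sampling of the pixel
  containing the transformed top point — no interpolation, matching the
  "pixel at that exact location" convention. Columns outside the raster
  are flagged and excluded from training.
* **Co-registration**: 2-D affine least squares on control-point pairs
  (≥ 3, non-collinear), RMSE reported over the pairs. The synthetic
  pipeline renders the orthomosaic in the cloud frame, so the identity
  transform applies there.

## 3. The synthetic stand

The simulator generates the study conditions: a 6 × 8 m lattice (≤ 10 %
positional jitter) of cone-crowned trees, 20 half-sib families assigned in
randomized blocks, LiDAR returns sampled on crown surfaces (density
proportional to local cone radius), in crown interiors and on the ground,
plus each tree's exact apex.

Key defaults, chosen once as a plausible mid-rotation slash-pine orchard:

| parameter | default | rationale |
| --- | --- | --- |
| height | N(18 m, 0.4 m), clipped ±3σ | a uniform, evenly managed stand |
| crown | cone, apex at `h`, base at `0.2 h`, radius `0.12 h` | conifer silhouette; closed-form footprint and leaf-area integrals |
| LAI | `3.0 · (h/18) · (1 ± 3 %)` | constant nominal leaf-area density (~0.21 m²/m³) so vertical optical depth per metre is comparable across trees |
| extinction | `k_eff = 0.9 · (0.75 + 0.5 · chl)` | mid-range conifer extinction, modulated by chlorophyll so that absorption and the red-edge signature share a common driver |
| chlorophyll | family N(0.5, 0.10) + tree N(0, 0.05), clipped [0.05, 0.95] | heritable (family-level) plus individual variation |
| albedo | 0.05 per level | typical canopy PAR reflectance |
| PAR noise | multiplicative N(0, 0.05) per reading | quantum-sensor repeatability across the four directions |

Leaf area is uniform over the crown's vertical extent, giving analytic
cumulative leaf area `L(z)` and transmittance `exp(−k_eff·L(z))`. The
noiseless per-stratum absorbed fractions recorded as scene truth equal
exactly what the ground-truthing module recovers from noiseless,
zero-albedo sensor components (verified to 1e-9 in the tests). Under the
defaults, the worst-case optical depth between the middle and base sensors
is `0.9 · 0.775 · 1.125 · 0.94 ≈ 0.74 > ln 2`, so the stratum ordering
upper ≥ middle ≥ lower holds for every tree deterministically.

### The reflectance model

Pixels inside a crown footprint mix the tree's foliage spectrum with a
fixed background spectrum by the local cover fraction `f = 1 − d/r`
(1 at the stem, 0 at the crown edge); background pixels are pure
background. Two deliberate design choices shape what the inversion can
learn, and both are documented here because they determine which indices
carry information:

1. **Chlorophyll acts only on the red-edge band**:
   `R730 = 0.42 − 0.16·chl`, with blue/green/red/NIR fixed at
   0.04/0.08/0.06/0.52 (plus small per-tree green/red brightness jitter,
   σ = 6 %, uncorrelated with any canopy property — fine-scale BRDF and
   shadowing variation). NIR/red-edge ratios are therefore strictly
   increasing in chlorophyll.
2. **The background contrasts with foliage only in the red edge**: it is
   modeled as a regularly mown, largely senescent understory —
   photosynthetically inactive but structurally vegetated — whose
   spectrum (0.06, 0.08, 0.06, **0.50**, 0.52) matches foliage in the
   structural bands and has a flattened red edge (R730 near the NIR
   plateau, as chlorophyll-free vegetation does).

Together these place the canopy–background contrast that encodes crown
geometry, and the chlorophyll signal that drives absorption, in the same
chlorophyll-sensitive band. This is the regime the package is designed to
emulate: in dense, clumped conifer canopies, retrieval skill comes from
red-edge information rather than broad greenness, and the simulator makes
that mechanism explicit rather than incidental. The consequence — red-edge
indices (RECI, NDRE, LCI) dominating variable importance while the
NDVI-family broadband indices are uninformative — is a *designed* property
of the forward model, verified by the parameter-recovery test, not an
empirical discovery about any particular dataset.

What the simulator does **not** emulate: multiple scattering, BRDF and
solar-geometry effects, within-crown needle clumping, shadowing between
crowns, seasonal phenology beyond a per-date chlorophyll multiplier,
off-nadir view angles, and non-planar terrain beyond a gentle plane.
Passing tests therefore demonstrate the correctness of the processing
chain and the identifiability of the inversion under the stated forward
model — not retrieval accuracy on field data.

## 4. Models and evaluation

* Final hyperparameters are the published values (RF 300 trees, mtry 6;
  XGBoost eta 0.01, 500 rounds, depth 6; SVM C 10, γ 0.1; PLSR 10
  components). SVR's `epsilon` is not published; 0.01 is used because
  labels are fractions in [0, 1] and the library default tube of 0.1
  would swallow most of the signal.
* SVM and PLSR consume standardized predictors (statistics from the
  calibration split only, inside the pipeline); tree ensembles take raw
  indices. Grid search, when enabled, scans small grids centered on the
  final values and minimizes mean CV RMSE (ties to the first candidate).
* All splits and CV folds are **grouped by tree**: no tree contributes
  rows to both sides of any split, mitigating the spatial/temporal
  leakage inherent in voxel-level data. Folds partition a per-repeat
  shuffle of the tree list.
* Permutation importance: mean RMSE increase over `n_repeats` shuffles of
  one column, on held-out data. With correlated predictors the importance
  of a signal is shared across its carriers (two duplicated columns split
  the mass); rankings should be read cluster-wise.
* Predictions are clipped to [0, 1] with a flag; rows with missing
  predictors get missing predictions, never imputed values.

## 5. Statistics

* One-way ANOVA by the classical between/within decomposition; zero
  within-group variance yields F = ∞ (p = 0) for unequal means and F = 0
  for equal ones.
* Duncan's multiple range test: means sorted descending; span `p` uses
  protection level `α_p = 1 − (1−α)^(p−1)` and critical range
  `r_p = q(1−α_p, p, df₂)·√(MS_within/n_h)` with `n_h` the harmonic mean
  group size (standard unequal-n extension). A span is homogeneous if its
  range is below `r_p` or it lies inside a homogeneous longer span;
  letters are the maximal homogeneous spans. Studentized-range quantiles
  come from `scipy.stats.studentized_range` (agreeing with published
  tables to better than 1e-6) and are cached process-wide because a single
  quantile evaluation is expensive.
* Monthly series keep gaps as missing values; nothing is interpolated.

## 6. Problem sizes

The test-suite and acceptance experiments use desk-scale stands: 48 trees
(6 × 8) for parameter recovery and gradient experiments, 10–20 trees for
unit fixtures, 40 pts/m² LiDAR density, 0.1 m orthomosaic GSD, 0.25 m
horizontal voxels. Statistical calibration uses 100 replicates for layer-
effect power and 1000 for the family type-I rate. These sizes are the
package's defaults for synthetic work; all are config keys.

## 7. Known limitations

* The `paper`-mode APAR balance can be negative by construction; users
  wanting a strict radiative balance should select `two_layer`.
* Reflectance is top-of-canopy only; voxel predictors within a column are
  identical, so vertical structure in predictions comes entirely from the
  stratum-labeled training scheme, not from observed within-canopy
  optics.
* The LAS reader/writer covers LAS 1.2 point format 0 (coordinates,
  classification, return number) — sufficient for local-frame UAV clouds,
  not a general LAS implementation.
* Duncan's test inherits the usual criticisms of multiple range tests
  (no strong familywise error control); it is provided because it is the
  field's customary post-hoc display, not as a recommendation.
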