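# Methods

`hipfe` reproduces, on synthetic data, the analysis chain of a prospective
fracture-prediction study in postmenopausal women: 3D densitometric femur
images → finite-element (FE) femoral strength and hip structural parameters
→ fracture adjudication → survival, reclassification and anatomical-map
statistics.  Because the underlying cohort data are not shareable, every
input is produced by a first-class synthetic generator whose defaults are
calibrated to the published control-group marginals; the statistical
machinery then has to *recover* the effect sizes that the generator plants.

## Femur phantom

The phantom is an analytic union of four solids — a sphere (femoral head),
a frustum (neck), a cylinder (proximal shaft) and an ellipsoid (greater
trochanter) — rasterised at 0.75 mm isotropic spacing with voxel values in
mg/cm³ of volumetric BMD (vBMD).  A Euclidean distance transform from the
periosteal surface splits bone into a cortical shell of region-dependent
thickness and a trabecular interior; anatomical regions (neck, trochanter,
shaft; the head sits outside the densitometric ROIs, as in DXA hip
analysis) are attributed by nearest solid.  The canonical periosteal mesh
is extracted once per configuration by marching cubes on a 2 mm grid, so
all subjects share vertex count and ordering (free canonical
correspondence).

Two anatomically motivated refinements matter mechanically:

* **Calcar asymmetry.** Neck cortical thickness varies azimuthally as
  `cth_neck · (1 + 0.7 cos φ)` with φ = 0 at the inferior-medial (calcar)
  side.  The thick calcar and thin superior cortex are what differentiate
  stance (calcar in compression) from fall loading (superior cortex in
  compression).
* **Shell closure bound.** A shell thinner than one voxel diagonal cannot
  separate interior from background on a grid, so local thickness is
  clamped at √3·spacing (≈1.3 mm at the default spacing).  This is the
  phantom's floor on the superior neck cortex — thinner than the clamp in
  life — and one reason the stance/fall strength contrast is much weaker
  than in real femurs (see Limitations).

A single latent factor q ("bone quality", population SD units) scales
trabecular vBMD, cortical vBMD and cortical thickness via `exp(s·q)` with
sensitivities chosen from the coefficient of variation of the corresponding
published control marginals (0.21, 0.08, 0.08).  A smooth multiplicative
Gaussian field (4 % SD, 4 mm correlation length) adds within-bone texture.
Defaults were calibrated once so that the q = 0 phantom reproduces the
control-group targets: projected total-hip aBMD 0.84 g/cm² (target 0.849),
total-hip trabecular vBMD 166–169 mg/cm³ (target 162), femoral-neck
trabecular vBMD 203 mg/cm³ (target 202), FN cortical thickness 1.86 mm,
and FE fall strength 3530 N (target 3563 N).

## Structural parameters

* **Compartment statistics** — BMC, mean vBMD and volume per compartment
  (trabecular/cortical/integral) and region (neck/trochanter/shaft/total
  hip), by direct voxel sums (float64 accumulation).
* **Vertex-wise cortical measures** — rays marched along the inward vertex
  normal in quarter-voxel steps; cortical thickness (CTh) is the length of
  the first contiguous cortical segment, cortical vBMD its mean image
  value, and surface BMD their unit-consistent product
  (sBMD [mg/cm²] = Ct.vBMD [mg/cm³] × CTh [cm]).  Rays that miss cortex
  within 3 mm are flagged missing and excluded from region averages.
* **Cross sections** — a 2D resampling of the image on a plane
  perpendicular to the neck axis at mid-neck (FN) or to the shaft axis at
  the neck-base level (IT), at half-voxel pixels staggered off voxel
  boundaries.  Density is looked up nearest-neighbour (linear interpolation
  smears the periosteal edge and biases the moments).  SA is the bone
  area; CSA and the polar CSMI are weighted by w = vBMD/1000 mg·cm⁻³ (the
  hip-structural-analysis convention of normalising by fully mineralised
  cortical density); Z = CSMI/d_max with d_max the largest distance from
  the density-weighted centroid to the periosteal contour.  Only the
  connected patch containing the section center is used, because a neck
  plane can also clip the trochanter.  On a digitized annulus at 0.5 mm
  the moments converge to the closed forms within 2 %.
* **Projection** — posterior-anterior aBMD as ROI BMC divided by the
  silhouette area along the neck/shaft-plane normal; BMC is conserved by
  construction.
* **T-scores** — young-adult references (TH 0.9402/0.1200 g/cm²,
  FN 0.8514/0.1125 g/cm²) recovered by inverting two published
  (aBMD, T-score) pairs per site and frozen in `REFERENCE_CURVES`.

## Finite-element strength

The vBMD image is block-averaged to 3 mm isotropic voxels; every voxel
with modulus above a 0.1 MPa floor becomes an 8-node trilinear hexahedron
(full 2×2×2 Gauss integration), and only the largest connected component
is kept.  The material is elastic-perfectly-plastic with von Mises yield:
BV/TV = min(1, vBMD/1200 mg·cm⁻³), E = E₀·(BV/TV)^1.6, σ_y = 0.007·E,
ν = 0.3.  E₀ = 7360 MPa is the single constant calibrated so the mean
phantom reaches the control-group mean fall strength; the exponent, yield
strain and tissue density are representative of published laws.  An
optional isotropic damage variable (exponential stiffness reduction with
accumulated plastic strain) exists and is off by default — the strength
criterion is reachable without softening.

Load cases:

* **Fall** — the bone is rigidly re-posed so the shaft axis makes 10° with
  the horizontal, the neck/shaft plane is vertical and the head lies above
  the greater trochanter (GT).  A polyurethane padding cap (E = 40 MPa) is
  grown above the femoral head and below the GT; the GT pad rests on a
  rigid support (fixed), the distal shaft face is fully constrained, and
  all head-cap top nodes move together vertically downward (rigid-cup
  kinematic coupling to a head reference point).
* **Stance** — the bone is rotated in the neck/shaft plane until the head
  center sits vertically above the distal shaft center, so the vertical
  driven displacement acts along the mechanical axis of the (truncated)
  femur, the physiologic direction of the single-leg-stance joint load.
  Head cap as above; distal face fixed; no GT support.

The solve is displacement-controlled and quasi-static: equal increments to
the target displacement of 4 % of the head-center–GT distance, full Newton
with the consistent (radial-return) tangent, a backtracking line search on
the residual norm (perfect plasticity chatters under undamped Newton), a
relative residual tolerance of 10⁻⁶ and a sparse direct factorisation that
is refreshed only when the contraction ratio degrades (stale-Jacobian
iterations are far cheaper than refactorisation).  Strength is the total
reaction at the driven nodes at the target displacement; with equal
increments the last step lands on it exactly and intermediate crossings
are interpolated linearly.  The default is 20 increments; tests use 8–10
after verifying the result changes by < 0.1 % (3827.8 N vs 3828.7 N on the
default phantom).

Rigid re-posing resamples the image trilinearly (masks nearest-neighbour)
onto a grid whose origin is snapped to the 3 mm FE pitch, and successive
rigid moves are composed onto the source image so any chain of poses costs
exactly one resampling pass; both choices are what make strength invariant
to the phantom's initial orientation (pre-rotating a phantom changes the
solved strength by zero to machine precision).

Exactness anchors: a homogeneous column with lateral-free ends reproduces
E·A·u/L and the plastic plateau σ_y·A to machine precision (a uniform
uniaxial state is representable by trilinear hexes), force curves scale
exactly linearly with (E, σ_y), and the consistent tangent matches finite
differences of the stress update to ~10⁻⁶ relative.

## Cohort generator

Subject parameters are drawn from a single-factor Gaussian model
`X = μ + σ(λq + √(1−λ²)ε)` with the published control-group (mean, SD) per
parameter and loading λ = 0.837 for all bone parameters (pairwise r ≈ 0.7,
the assumed strength–aBMD correlation; the source prints no correlation
matrix, so this is configuration, not an empirical claim).  Age and BMI
load zero.  T-scores are derived from the drawn aBMD through the frozen
references, not sampled separately.  Follow-up is truncated normal
(5.7 ± 1.5 y, floor 0.5 y).

Outcomes follow an exponential proportional-hazards model: the hazard is
`h₀·exp(β·(−z))` with z the in-sample standardized fall strength, i.e. the
risk is multiplied by exp(β) per SD *decrease*; h₀ is calibrated by root
finding so the expected event fraction matches the target (100/740
low-trauma fractures, with 44/100 of events being major osteoporotic
fractures).  MOF membership among LT events is tilted by
`exp((β_MOF−β_LT)(−z))` so MOF ⊆ LT holds exactly while the planted MOF
effect (HR 1.50/SD) exceeds the LT effect (1.32/SD).  Event sites follow
the published MOF composition (forearm 19, humerus 16, proximal femur 5,
vertebra 4 of 44); the non-MOF site split is configuration.  All
randomness derives from one master seed through named substreams, so
cohort tables are bit-reproducible.

A deterministic roster fixture reproduces the recruitment-flow arithmetic
(833 recruited; 9 missing DXA, 34 lost to follow-up, 50 traumatic
fractures; 740 analysed; 100 LT / 44 MOF) for the adjudication rules.

## Statistics

* Group comparisons: two-sided Mann–Whitney U (p = 1 on fully tied input).
* Cox models: lifelines partial likelihood with Efron tie handling;
  continuous predictors standardized in-sample and sign-flipped so HR > 1
  means risk per SD decrease; Wald CIs.  Binary threshold models
  (T-score ≤ −2.5 at FN/TH/either, strength < 3000/2600 N) guard against
  monotone likelihood (|log HR| > 8 raises).
* Harrell's C: in-repo vectorized pair counting (usable pair: the shorter
  time carries an event; score ties count ½), cross-checked against brute
  force and lifelines; CI by leave-one-subject-out jackknife over pair
  sums; two correlated C indices are compared by a paired jackknife z
  test.
* NRI: nested logistic models (statsmodels) — outcome ~ T-score flag +
  follow-up duration, plus the fragile-strength flag in the extended model
  — with subjects binned against fixed predicted-probability cutoffs (15 %
  MOF, 20 % LT).  Two-category NRI with the standard asymptotic SE and
  normal p.  If the added flag duplicates the existing one the nested
  models are identical and NRI is exactly 0 (no fit of the degenerate
  design).  The sweep covers 2300–3000 N in 100 N steps × {FN, TH} ×
  {LT, MOF}, uncorrected for multiplicity.
* Surface maps: per-vertex Welch t tests (Mann–Whitney available) on the
  canonical mesh, relative (% of control) and absolute difference maps,
  significance mask at p ≤ 0.05 without correction (an FDR option
  exists).  Per-subject vertex maps at cohort scale come from the latent
  factor plus independent vertex noise — a fast surrogate for ray-casting
  every subject's image, which remains available through the phantom path.

## Problem sizes

The default test and pipeline sizes are chosen for a single workstation
core: cohort statistics at n = 300–740; hazard-recovery and null
calibration at 100–500 replicate fits; whole-bone FE on the default
phantom (~5700 elements at 3 mm) for the calibration pair and on a
two-thirds-scale geometry for monotonicity and frame-indifference checks;
the acceptance script averages 120 replicate Cox fits per target.

## Limitations

* The stance/fall strength ratio of the mean phantom is only ≈1.1, far
  below the published ≈1.85: with an isotropic material, a uniform-density
  trabecular interior and a diagonal-clamped superior cortex, the phantom
  cannot reproduce the full mechanical contrast between load cases.  The
  cohort table therefore plants the stance marginal (6583 ± 1574 N)
  directly; FE stance strength is validated only for ordering
  (stance > fall) and monotonicity.
* Periosteal geometry is identical across subjects (only densities and
  cortical thickness vary with the latent factor), so cross-sectional
  geometry varies through density weighting alone, and canonical mesh
  correspondence is exact by construction rather than by registration.
* One latent factor induces a single correlation scale (r ≈ 0.7) among all
  bone parameters; real inter-parameter correlation structure is richer.
  Passing recovery tests therefore demonstrates correctness of the
  estimators under a proportional-hazards, single-factor world, not
  robustness to real-data violations (non-proportional hazards, competing
  risks, measurement error).
* The FE model is small-strain, contact-free and rate-independent; padding
  is elastic; damage is off by default.
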