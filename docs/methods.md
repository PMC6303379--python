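# Methods

## The measurement chain

The package models a planted soil core imaged by µCT: an 8/16-bit
grayscale volume with isotropic voxels (axis order fixed as (z, y, x),
slice index = z, 0-based). Segmentation assigns each voxel to one of three
exhaustive classes — pore (air, low attenuation), solid matrix, root
(intermediate attenuation). All subsequent geometry is computed on that
label volume:

1. **Distance shells.** An exact Euclidean distance transform gives each
   voxel its distance (µm) to the nearest root voxel; shells are half-open
   bands [d, d+1) mm from the root surface. A voxel at exactly 1 mm
   belongs to the 1–2 mm shell. Shells partition the soil out to the outer
   band edge; the root itself is excluded everywhere (also from porosity
   denominators).
2. **Rhizosheath boundary.** Replicate shell porosities (one value per
   core per shell — voxels within a core are not independent observations)
   enter a one-way ANOVA followed by Tukey HSD. The boundary is the outer
   edge of the maximal prefix of shells such that *every* shell inside the
   prefix is significantly higher (α = 0.05) than *every* shell beyond it.
   Shells inside the prefix need not differ from each other, so a 0–2 mm
   elevation yields a 2 mm boundary; if no shell is elevated the boundary
   is 0 and the result is flagged "no rhizosheath detected". Bulk soil is
   defined as the band from the boundary to twice the boundary.
3. **Connectivity.** The Γ-indicator: percentage of pore volume in the
   largest connected pore cluster, 26-connectivity by default
   (6-connectivity selectable). Computed on the middle 100 slices
   (z ∈ [z/2 − 50, z/2 + 50)); stacks shorter than 100 slices are used
   whole with a warning. By default the statistic is restricted to the
   extracted region within that window. The source imaging practice this
   reimplements never defined its connectivity statistic; the Γ-indicator
   is the standard choice in soil µCT and reproduces near-100 % values for
   well-connected pore systems.
4. **Unplanted controls** have no root to anchor shells, so a central 1 mm
   region is used: a full-width slab of ⌊1 mm / voxel⌋ slices at mid-z by
   default, a 1 mm-diameter axial cylinder as an option.

## Segmentation

Pore thresholding is Otsu's method on the gray histogram (or a fixed
threshold); the boundary value itself is classified pore. Root extraction
is deliberately transparent, since the plug-in it replaces is a black box:
seeded region growing over an intensity window (default ±25 gray on an
8-bit scale, roughly ±2.2 effective class SDs) centred on the median gray
of the seed's 3×3×3 neighbourhood, then 3D morphological closing (ball
radius 2 voxels, fills interior noise holes) and opening (same radius,
strips attached surface fuzz); morphology is computed on an edge-padded
array so roots meeting a volume face are not eroded. A grown region
exceeding 20 % of the volume (configurable) aborts with a leak error — on
a volume without an intermediate gray class the seed's component is
essentially the whole matrix, which this guard catches. Root overrides
pore where both masks claim a voxel. No despeckling or minimum-object-size
filtering is applied by default.

## Synthetic phantoms

Phantoms exist to give every geometric operation a voxel-exact ground
truth. The root is a solid tube (optionally tapered, with straight lateral
branches) of intermediate gray; root hairs are not rendered — they sit
below the ~16 µm voxel size the phantom emulates. Pores are overlapping
spheres: the volume is pre-partitioned into the requested distance-band
regions (plus far field), sphere centres are drawn uniformly within a
region and sphere voxels are clipped to it, and spheres are added until
the region's pore count reaches its target. Clipping makes each band's
achieved porosity exact up to the last sphere (well under ±1 porosity
point at desk scale) at the cost of slightly unphysical pore truncation at
band boundaries. A target that stops progressing (region saturated, or the
sphere budget exhausted) raises an error naming the band. Gray rendering:
pore 60 ± 10, solid 160 ± 10, root 110 ± 10 on the 8-bit scale plus
additive Gaussian noise (SD 5) — a bimodal-plus-intermediate histogram like
real soil µCT. No gray-level histograms were available to validate these
defaults, and no beam hardening, ring artefacts or partial-volume physics
are simulated.

Consequences worth noting: (i) a single large region redistributes sphere
coverage towards its interior (edge depletion), so the full study pipeline
assigns every analysis band its own generator region; (ii) phantom
replicates are nearly identical — far more alike than real cores — so the
study emulation draws each replicate's porosity targets from a normal
distribution (SD 0.005 porosity fraction) to give the ANOVA a realistic
error term. Passing tests therefore demonstrate correctness of the
measurement chain, not robustness to real-scan artefacts (beam hardening,
partial volume, water films).

Desk-scale test phantoms use 64 µm voxels on ~(64, 112, 112) grids so that
0–3 mm shells fit in memory and seconds; the spec-level default of
400³ voxels at 16 µm (a 6.4 mm cube, 0–6 mm shells) is supported but not
exercised routinely.

## MicroResp conversion

The assay chain is: per-well time-zero normalisation
`Ai = A_t6 × (plate mean A_t0 / A_t0)`; rational calibration
`%CO₂ = A + B/(1 + D·Ai)` (clipped at 0; a non-positive denominator is an
error); ideal-gas conversion
`rate = Δ%CO₂/100 × V_headspace(µl) × (44/22.414) × (12/44) × 273/(273+T)
/ m_soil(g) × 24/t(h)` in µg CO₂-C g⁻¹ d⁻¹ (1 g/l ≡ 1 µg/µl, so µl
headspace gives µg directly). Defaults: 0.5 g soil, 900 µl headspace
(1200 µl well minus soil), 6 h at 25 °C. The calibration constants default
to standard published cresol-red gel values (A = −0.2265, B = −1.606,
D = −6.771) but are assay-specific configuration — absolute rates are only
as good as the user's own gel calibration, and the rate is linear in
Δ%CO₂ and inversely proportional to soil mass and incubation time by
construction. A negative CO₂ increment (colour/evaporative drift) is
clipped to zero with a warning. Plates are read in long format
(well, role, timepoint, a570); ambient wells define the reference %CO₂
(0.04 % if absent).

## Statistics

Two-way ANOVA uses Type-II sums of squares (equal to Type-I/III on the
balanced n = 4 design, still well-defined on unbalanced synthetic data),
with empty cells reported by name and an all-equal response flagged rather
than producing infinite F. Tukey HSD p-values come from the studentized
range; the compact letter display uses the insert-and-absorb algorithm
with letters ordered by group mean descending, and the result is verified
internally (significant pairs share no letter, non-significant pairs share
one) before being returned. Box-Cox chooses λ on a grid over [−3, 3] in
steps of 0.01 by profile log-likelihood; λ = 0 is the log branch, and
non-positive data are refused with a shift suggestion. The pipeline's
convention for "transform when necessary" is Shapiro normality of ANOVA
residuals at p < 0.05. Percent change is `100·(rhizo − bulk)/bulk`,
signed. α = 0.05 throughout.

When recomputing the source study's "high carbon increased X by N %"
claims from its printed means, the comparison baseline is the mean of the
no-carbon and moderate-carbon treatment means.

## Path models

Only recursive models (DAGs over observed variables, uncorrelated
equation errors) are supported — no latent variables, no modification
indices, no bootstrap. Variables are standardized internally; carbon
enters as an ordinal 1/2/3 score (a single carbon node; a two-indicator
0/1 dummy coding is available as an option). Estimation is equation-wise
least squares on the sample covariance, which coincides with ML for this
model class; an independent numerical minimiser of the ML discrepancy is
used as a test oracle, not as the estimator. The implied covariance is
Σ̂ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ with a saturated exogenous block, and fit indices
are F_ML = log|Σ̂| + tr(SΣ̂⁻¹) − log|S| − p, χ² = (n−1)F_ML (exactly 0 with
df = 0 for saturated models), GFI = 1 − tr[(Σ̂⁻¹(S−Σ̂))²]/tr[(Σ̂⁻¹S)²],
RMSEA = √(max(χ²−df, 0)/(df(n−1))). Degrees of freedom are
p(p+1)/2 − (#edges + #endogenous + exogenous (co)variances).

One semantic choice matters for nested comparisons: a parentless variable
is exogenous (freely correlated with other exogenous variables) unless the
model declares its exogenous set explicitly, in which case an undeclared
parentless variable keeps residual-only variance and zero model-implied
covariance with the rest — deleting an edge then tightens the model
instead of silently freeing a covariance. Standard errors are
normal-theory OLS values on the standardized data with two-sided normal
p-values; n below 5× the free parameter count triggers a small-sample
warning (the emulated study scale, n = 12 per scenario, is such a case and
its fit indices are reported for illustration only).

Model comparison ranks by χ² p-value (descending), then RMSEA, then GFI,
flagging χ² p > 0.05 as "acceptable".

## Synthetic tables

Replicate tables are generated from a linear recursive DAG: endogenous
variables are weighted sums of their *standardized* parents plus Gaussian
noise, with residual variance chosen to complete each variable to
approximately unit variance, so generating weights are directly
recoverable as standardized regression slopes. The design mirrors the
emulated experiment: cultivar × carbon (scored 1/2/3) × replicate, n = 4
per cell by default. A second generator produces the
cultivar × carbon × zone measurement table with additive factor effects
(exact null when no effects are set), used for ANOVA calibration and
letter-display demonstrations.

## Numerical and degenerate-input conventions

* Gray thresholding: "≤ threshold is pore"; Otsu on a constant volume is
  an error.
* Distance bands: half-open; ties at a band edge go outward.
* Connectivity ties for largest cluster resolve by component label order
  (deterministic given the labelling).
* χ² is clipped at 0 (F_ML can be −1e−15 numerically); residual variances
  are floored at 1e−12; singular sample covariances are refused.
* All randomness flows from explicit integer seeds; identical seeds give
  bit-identical phantoms, tables and pipeline CSVs.

## Known limitations

* No pore-size distributions, tortuosity or permeability; no mesh export.
* The phantom generator validates geometry and statistics, not image
  physics; segmentation performance on real scans will be worse than the
  Dice ≥ 0.98 achieved on phantoms.
* Absolute MicroResp rates require a user calibration; only the functional
  form and unit pipeline are verifiable here.
* The published study's absolute porosity/connectivity/respiration means
  are not reproducible without its raw scans; its percent-change claims,
  recomputed from the printed means, are the only direct numerical
  contact points.
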