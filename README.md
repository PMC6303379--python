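# rhizoct

Rhizosheath extraction and pore-geometry analysis for X-ray microtomography
(µCT) of rooted soil, with the downstream statistics of a
rhizosphere-function experiment: MicroResp respiration conversion,
ANOVA/Tukey treatment summaries, and recursive path models (SEM) linking
carbon addition, root traits, pore geometry and soil function.

It is aimed at soil/rhizosphere scientists who scan planted soil cores and
want a scriptable, tested replacement for the usual chain of FIJI macros:
segment pores and root, profile porosity in distance shells around the
root surface, locate the rhizosheath statistically, and quantify region
porosity and pore connectivity — plus the tabular statistics that follow.

## What it computes

* **Distance-shell porosity profile.** With pore/solid/root labels and an
  exact Euclidean distance transform `d(x)` from the root surface, the soil
  is partitioned into half-open shells `[k, k+1)` mm (default 0–6 mm) and
  porosity `φ_k = 100 · pores_k / (pores_k + solids_k)` is computed per
  shell, per replicate core.
* **Rhizosheath boundary.** One-way ANOVA of `φ_k` across shells
  (replicates as observations) with Tukey HSD; the rhizosheath is the
  maximal prefix of shells each significantly higher (α = 0.05) than every
  subsequent shell. The rhizosheath (0..b) and bulk (b..2b) regions are
  then extracted; unplanted controls use a central 1 mm core instead.
* **Pore connectivity.** The Γ-indicator on the middle 100 slices:
  `Γ = 100 · |largest 26-connected pore cluster| / |pore voxels|` within
  the analysed region.
* **MicroResp rates.** Per-well time-zero normalisation
  `A_i = A6_i · (mean A0 / A0_i)`, calibration `%CO₂ = A + B/(1 + D·A_i)`,
  and ideal-gas conversion to µg CO₂-C g⁻¹ d⁻¹.
* **Treatment statistics.** Two-way ANOVA (Type-II SS), Tukey HSD with
  compact letter displays, Box-Cox by profile likelihood, and
  rhizosheath-vs-bulk percent changes `100·(rhizo − bulk)/bulk`.
* **Path models.** Recursive SEM by ML on the sample covariance:
  standardized path coefficients (equation-wise least squares, which is ML
  for recursive models with uncorrelated errors) and fit indices
  χ² = (n−1)·F_ML, GFI, RMSEA.

Because raw µCT scans of this kind are rarely shareable, the package ships
a synthetic-data layer: rooted-soil phantoms with voxel-exact ground truth
(controllable porosity per distance band around the root) and replicate
tables with known ANOVA effects and path coefficients. Every stage is
tested against those ground truths or independent oracles (analytic
annulus volumes, brute-force Otsu, BFS flood fill, a numerical ML
discrepancy minimiser).

## Worked example

```python
from rhizoct.phantom import PhantomSpec, generate_phantom
from rhizoct import geometry as geo

profiles = []
for rep in range(4):
    spec = PhantomSpec(shape=(64, 112, 112), voxel_size=64.0, root_radius=500.0,
                       porosity_profile=[(0.0, 1.0, 0.28)], far_porosity=0.24,
                       pore_radius_range=(128.0, 256.0), seed=100 + rep)
    volume, truth = generate_phantom(spec)
    profiles.append(geo.shell_profile(truth, (0.0, 1.0, 2.0, 3.0), sample_id=f"r{rep}"))

det = geo.detect_rhizosheath(profiles)
print(det.boundary_mm, det.status)
print(det.band_means.round(2))
```

prints

```
1.0 ok
band
0-1mm    28.08
1-2mm    24.41
2-3mm    25.07
Name: porosity_pct, dtype: float64
```

i.e. the 0–1 mm shell porosity (28.1 %) is significantly above the deeper
shells (24–25 %), so the detected rhizosheath boundary is 1 mm — the
generator's ground truth. The `analysis/` scripts run the full emulated
study (`01_simulate_study.py`: phantoms → segmentation → shells → ANOVA →
SEM, writing `results/study/`), the boundary-recovery study (`02`), the
published-table percent-change reanalysis (`03`) and the three scenario
path models (`04`). The same stages are available from a shell via the
`rhizoct` CLI (`simulate`, `segment`, `geometry`, `respiration`, `stats`,
`sem`, `run-all`).

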