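# cropsar

Multi-temporal crop classification from dual-polarization SAR and
multispectral optical imagery, as a tested, reusable Python pipeline.

**Who it is for.** Agricultural remote-sensing practitioners who classify
crop types (here: an 8-class paddy-rice landscape — rice, soybean, ramie,
corn, grassland, water, forest, building) from a season of C-band VV/VH
SAR acquisitions and cloud-screened optical surface-reflectance scenes,
and who want every stage — polarimetric decomposition, feature fusion,
random-forest classification, accuracy assessment — reproducible and unit
tested.  Because no public scene archive is bundled, the package ships a
synthetic scene generator that emulates the full acquisition season, so
the complete pipeline runs and is validated without any download.

## The model at the core

Per acquisition date, the dual-pol observable is the 2×2 Hermitian
covariance **C2** with elements C11 = ⟨|S_VV|²⟩, C22 = ⟨|S_VH|²⟩,
C12 = ⟨S_VV S*_VH⟩.  After multi-looking and a 9×9 boxcar speckle filter,
seven SAR features are computed per pixel:

* **Backscatter intensities** VV_dB, VH_dB = 10·log₁₀(C11), 10·log₁₀(C22).
* **Eigen-decomposition (Cloude–Pottier-style H/A/α).**  With eigenvalues
  λ₁ ≥ λ₂ ≥ 0 and pseudo-probabilities P_i = λ_i/(λ₁+λ₂):
  H = −Σ P_i log₂ P_i ∈ [0,1], A = (λ₁−λ₂)/(λ₁+λ₂) ∈ [0,1],
  α = P₁α₁ + P₂α₂ ∈ [0°, 90°] with α_i = arccos |u_i(1)|.
* **Model-based volume/polarized decomposition.**  The Stokes vector
  s = [C11+C22, C11−C22, 2 Re C12, −2 Im C12] is modelled as an
  unpolarized random-dipole-cloud volume term plus a fully polarized term,
  s = m_v·s_v + m_s·s_p with s_v = [1, ½, 0, 0].  Since s_pᵀG s_p = 0 for
  G = diag(1,−1,−1,−1), the volume power solves
  a·m_v² + b·m_v + c = 0 with a = s_vᵀG s_v = ¾, b = −2(s₁ − ½s₂),
  c = s₁²−s₂²−s₃²−s₄², the physical root obeying energy conservation
  0 ≤ m_v ≤ s₁; the polarized power is m_s = s₁ − m_v.

Optical scenes (12 surface-reflectance bands at 10/20/60 m) are screened
at a strict <20% cloud fraction, resampled to the common 10 m grid and
stacked.  In the reference configuration 8 optical dates × 12 bands (96)
plus 12 SAR dates × 7 features (84) fuse into a 180-band cube.  A
150-tree random forest is trained on a per-class stratified 7:3 pixel
split; accuracy is assessed with producer's/user's accuracy, overall
accuracy and Cohen's kappa from the test-set confusion matrix, and class
separability with the Jeffries–Matusita distance JM = 2(1 − e^(−D_B)).

## Worked example

```python
import cropsar as cs
from cropsar.workbench import simulate_scenes

cfg = cs.ExperimentConfig(extent=(96, 96), seed=3)
lcmap, polygons, sar_scenes, optical_scenes = simulate_scenes(cfg)

sar_cube = cs.sar_feature_cube(sar_scenes, cfg.boxcar_window)   # 84 bands
optical_cube, screening = cs.optical_feature_cube(optical_scenes)  # 96 bands
fused = cs.fuse(optical_cube, sar_cube)                         # 180 bands

result = cs.CropClassifier(fused, polygons=polygons).fit(seed=3)
print(result.summary())
print(result.importance().head(3).round(3))
```

On the synthetic scene this prints a test-set report with
`OA 100.00` and `Kappa 1.00` (the default generator's eight classes are
fully separable once all 20 dates are fused — real scenes are not), and
the top of the date-aggregated, max-normalized feature importances:

```
         raw_importance  normalized_importance
feature
B8                0.183                  1.000
VH_dB             0.122                  0.666
B7                0.104                  0.566
```

The incremental temporal experiment shows the saturation behaviour that
motivates multi-temporal stacking; with the 84-band SAR feature cube
alone (`cs.temporal_experiment(sar_cube, polygons, seed=...)`), overall
accuracy grows from 76.5% with one date to 100% by mid-season, and the
SAR-only importance ranking puts `VH_dB`, `mv` and `VV_dB` first — the
volume power m_v carries most of the polarimetric information.

The same study runs from the shell:

```bash
cropsar -v full --seed 3 -o out/      # scenes -> cubes -> experiments -> CSVs
cropsar simulate --seed 3 -o scenes/  # just the synthetic scenes (TIFF/GeoJSON)
```

`out/` then holds the three per-prefix accuracy tables
(`experiment_optical.csv`, `experiment_sar_intensity.csv`,
`experiment_sar_features.csv`), the fused best-strategy confusion matrix,
accuracy report, classification map and SAR feature importances, the
cloud-screening report, a JM separability matrix and a JSON manifest with
seed, config digest and per-stage wall times.

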