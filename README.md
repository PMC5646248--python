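# starchlink

Multi-omics analysis of dietary **resistant starch (RS)** crossover cohorts.

Resistant starch escapes digestion in the small intestine and is fermented
by colonic microbes into short-chain fatty acids and other products. In a
crossover design, each subject contributes one fecal sample per diet —
baseline washout, low-RS (LRS), and high-RS (HRS) — measured on three omics
layers: 16S OTU counts, metaproteome spectral counts, and direct-infusion
FT-ICR-MS metabolite intensities. `starchlink` provides the full desk-side
analysis path for such cohorts, for microbiome researchers who want the
statistics without the original vendor tooling:

- **Per-layer preprocessing** — OTU depth/prevalence filters and
  proportional even-depth scaling; spectral-count normalization to the mean
  MS-run total, `SCᵢ′ = (Σⱼ Σₖ SCₖ / M) / (Σₖ SCₖ)ⱼ · SCᵢ`; FT-ICR-MS peak
  alignment at 1 ppm with S/N, occurrence and mass-defect filters; exact
  monoisotopic-mass and adduct arithmetic (AMP⁺ charge tags, [M−H]⁻) with
  external-calibration quantification of short-chain fatty acids.
- **Dose-response mapping** — per-subject Pearson correlation of feature
  abundance against the coded RS dose (baseline 0, LRS 0.05, HRS 1),
  averaged across subjects; Kruskal–Wallis + Nemenyi post-hoc diet tests;
  treemap-ready hierarchy tables.
- **OPLS-DA** — orthogonal PLS discriminant analysis with a single
  class-predictive component t[1], R²Y(cum), 7-fold cross-validated
  Q²(cum), CV-ANOVA model significance, and merged significant-feature
  bookkeeping across valid models.
- **CLR networks** — cross-omics association networks by context likelihood
  of relatedness: mutual information over equal-frequency discretized
  ranks, rectified background z-scores `z(i,j) = √(max(0,zᵢ)² + max(0,zⱼ)²)`,
  a Z ≥ 6.5 edge filter, the six-network intra/inter-layer merge rule, diet
  t-test node coloring, and module extraction.
- **Synthetic cohorts** — a generator with planted dose-linear effects,
  diet shifts, and cross-layer correlated modules, so every stage can be
  validated against known ground truth.

## Worked example

```python
from starchlink import (CohortDesign, PlantedEffect, generate_cohort,
                        dose_correlation, ClassDesign, fit_opls_da,
                        significant_features)

design = CohortDesign(n_subjects=23, seed=17)   # 23 subjects x 3 diets
effects = [PlantedEffect("metabolite", f"MET_{i+1:04d}", "hrs_shift", 2.0)
           for i in range(8)]
effects.append(PlantedEffect("metabolite", "MET_0009", "dose_linear", 2.0))
tables, meta, truth = generate_cohort(design, effects)

# which metabolites track the RS dose?
result = dose_correlation(tables["metabolite"], meta)
print(result.ranked().head(3))

# class discrimination baseline vs HRS on the metabolite layer
contrast = ClassDesign.from_meta(meta, ("baseline", "HRS"))
model = fit_opls_da(tables["metabolite"].data, contrast, n_orthogonal="auto")
print(f"R2Y={model.r2y_cum:.3f}  Q2={model.q2_cum:.3f}  p={model.cv_anova_p:.3g}")
selected, _ = significant_features([model], [tables["metabolite"].data])
print("selected:", len(selected))
```

prints

```
MET_0008    0.920053
MET_0002    0.893821
MET_0001    0.705523
dtype: float64
R2Y=0.998  Q2=0.596  p=1.15e-07
selected: 13
```

The planted diet-responsive metabolites top the averaged per-subject dose
correlation (mean r up to 0.92), the baseline-versus-HRS OPLS-DA model is
strongly cross-validated (Q² ≈ 0.6) and significant by CV-ANOVA, and the
merged feature selection recovers all nine planted features (13 selected of
150, including four false positives at the 0.05 feature-level cut).

Exact-mass arithmetic works standalone:

```sh
$ starchlink mass-calc C4H8O2 --ion amp     # AMP+-derivatized butyric acid
255.1497
$ starchlink mass-calc C12H24O2 --ion deprotonated   # C12:0 [M-H]-
199.17035
```

The full pipeline (synthetic or on-disk tables) runs from one YAML config:

```sh
starchlink run config.yaml    # writes stage outputs + manifest.json
```

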