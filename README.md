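# femri

Spatial quantification of iron-laden macrophages from multi-gradient-echo
(MGE) MRI and matched histology.

Tumor-associated macrophages (TAMs) take up iron — endogenously, and avidly
after injection of ultrasmall superparamagnetic iron oxide (USPIO)
nanoparticles — and concentrate it in rare, compact multicellular deposits
at the tumor margin. Each deposit spans only a few MRI pixels, so
conventional whole-ROI statistics over the tumor cross section dilute the
signal in the low-iron bulk of cancer cells and stroma. `femri` implements
the alternative: build a **parametric iron map** (FeMRI map) pixel by pixel,
then **count and size the localized high-iron pixel clusters** directly, and
score the same deposits in histology down to per-cell polarization
phenotypes.

## Method

1. **Relaxometry.** Each pixel of an MGE magnitude stack is fit to the
   monoexponential decay S(TE) = S₀·exp(−R₂\*·TE), giving effective
   transverse relaxation-rate maps R₂\* = 1/T₂\* (nonlinear least squares,
   log-linear initialized).
2. **Iron calibration.** Reference iron standards establish the linear
   relation R₂\* = m·C + b over the 0.0–0.3 mg iron(III) g⁻¹ working range;
   inverting it converts the R₂\* map into a concentration map
   C = (R₂\* − b)/m.
3. **Stratification and cluster analysis.** Pixels at or above the midpoint
   of the range (0.15 mg/g) form the high-iron stratum. Connected
   components of that stratum are the iron deposits; their count and areas
   (pixel count × pixel size²) are the localized observables. For
   comparison, the conventional whole-ROI distribution (clusters per
   concentration bin, frequency- and size-weighted medians) is computed from
   the same map.
4. **Histology mirror.** Prussian-blue-positive pixels detected in a
   full-resolution section are block-averaged 1:100 per axis to MRI pixel
   scale, discretized into individual deposits by watershed processing of
   the density map, and each deposit's iron⁺ macrophage count is scored from
   the full-resolution cell table. Polarization frequencies
   (M1-like AIF1⁺ vs M2-like CD206⁺, f_M1 = M1/(M1+M2)) and iron⁺-restricted
   subset frequencies (iron⁺X⁺/X⁺) complete the Fig-3-style readouts.
5. **Statistics.** Group comparisons use the two-tailed pooled-variance
   Student's *t*-test. A simulation harness contrasts the statistical yield
   of ROI medians against localized cluster counting on matched synthetic
   cohorts.

Because no public image data accompany the study design this package
targets, a first-class phantom module generates MGE series and histology
sections with known ground truth (deposit positions, iron levels, cell
tables), so every stage is testable end to end.

## Worked example

```sh
femri run-all --config examples/demo.cfg --outdir demo_out
```

simulates a 128×128 MGE series (16 echoes, 3–48 ms; 4.5 mm tumor disc with
30 planted deposits, 1 % noise) plus a 3×3 mm histology section with 12
iron⁺ colonies, runs both pipelines, and prints:

```json
{
  "mri": {
    "n_true_deposits": 30,
    "n_fitted_pixels": 6376,
    "median_r2star_s": 32.09,
    "median_iron_freq_mg_g": 0.0407,
    "median_iron_size_mg_g": 0.0299,
    "n_high_clusters": 30,
    "mean_high_cluster_area_mm2": 0.039
  },
  "histo": {
    "n_true_deposits": 12,
    "n_recovered_deposits": 12,
    "mean_cells_per_deposit": 15.67,
    "n_unassigned_cells": 4,
    "f_m1_pct": 42.36,
    "f_m2_pct": 57.64,
    "iron_cd68_pct": 8.78
  }
}
```

Reading this: the whole-ROI medians sit deep in the low-iron range
(~0.03–0.04 mg/g — the tumor bulk), while the localized analysis counts all
30 planted high-iron clusters at ~4 pixels (0.04 mm²) each; the histology
path recovers all 12 colonies with their cellularity, and the cohort's
polarization split lands at the configured 42/58 M1/M2 frequencies.
Intermediate rasters (R₂\*, T₂\*, FeMRI map, strata, deposit labels) and
tables are written to `demo_out/`, along with the fully resolved
configuration for bit-identical reruns.

Individual stages are also exposed (`femri simulate-mri`, `fit-relaxometry`,
`calibrate`, `map-iron`, `clusters`, `histo-deposits`, `polarization`,
`compare-groups`, `power-sim`) and as plain library functions.

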