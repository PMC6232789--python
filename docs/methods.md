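# Methods

This note documents the models, parameter choices and numerical conventions
behind `femri`, and what the synthetic phantoms do and do not establish
about real data.

## Signal model and relaxometry

Each pixel of a multi-gradient-echo magnitude series is modelled as a
monoexponential decay S(TE) = S₀·exp(−R₂\*·TE). Echo times are in ms and
rates are stored in s⁻¹; internally the fit works per ms and converts once
on output. The default echo schedule is 16 echoes at TE = 3, 6, …, 48 ms
(even 3 ms spacing starting at the increment — the standard MGE reading of
"evenly spaced 3 ms echoes").

The estimator is nonlinear least squares in (S₀, R₂\*), initialized from the
ordinary log-linear regression of ln S on TE and refined by a vectorized
damped Gauss–Newton iteration (per-pixel Levenberg-style damping factor,
step accepted only when it lowers the residual sum of squares; singular
2×2 normal systems — e.g. perfectly constant signal — leave the initial
estimate untouched). On noise-free data the log-linear start is already
exact, so the noiseless closed form is reproduced to machine precision; a
plain log-linear mode (`method="loglin"`) is provided because either
estimator is a defensible reading of "pixel-wise monoexponential fitting".
Negative fitted rates are clamped to 0 (physical non-negativity) with the
fit still marked valid.

Non-tissue pixels are screened by a first-echo signal threshold: pixels
below `min_signal_fraction` (default 0.05) of the masked 99th-percentile
first-echo signal are excluded from fitting. The 99th percentile, not the
maximum, anchors the reference so a single hot pixel cannot shift the
cutoff.

## Iron calibration and stratification

The relaxation rate of aqueous iron(III) standards is linear in
concentration over the working range, R₂\* = m·C + b. `fit_calibration` is
ordinary least squares (with r² reported); a non-positive slope is treated
as a calibration failure rather than silently inverted. Applying a
calibration inverts the line, C = (R₂\* − b)/m, and **clamps** to the
concentration range (default 0.0–0.3 mg/g): sub-intercept rates map to the
floor and supra-range rates saturate at the ceiling, mirroring how
parametric maps are displayed on a fixed scale. The high-iron stratum
starts at the midpoint of the range — 0.15 mg/g for the default range — and
the boundary is **inclusive** (a pixel exactly at 0.15 is high) so ties
resolve deterministically and in favor of deposit sensitivity.

The calibration constants themselves are study inputs, not constants of
nature; the phantom defaults (m = 400 s⁻¹ per mg/g, b = 20 s⁻¹) give tissue-
like T₂\* of ~31 ms at baseline iron and ~7 ms inside the strongest
deposits.

## Cluster quantification

Two routes quantify the same stratified map:

* **Whole-ROI distribution**: the concentration range is tiled by
  `n_bins` equal-width bins (default 15, i.e. 0.02 mg/g over 0–0.3; the
  width is configurable because no canonical value exists), the map is
  binarized per bin, and connected clusters are counted and sized. Summary
  medians are weighted medians of the per-cluster mean concentrations —
  count-weighted (each cluster once) for the frequency median,
  area-weighted for the size median. Per-cluster values rather than bin
  centers are used because bin centers quantize the median to the bin
  width, which destroys between-group contrasts smaller than one bin; the
  plain per-pixel median is also reported. The weighted median is the
  smallest value whose cumulative weight reaches half the total.
* **Localized analysis**: connected components of the high stratum within
  the tumor mask, counted and sized directly.

Connectivity defaults to 8-neighbor (the common particle-analysis
convention; 4-neighbor is exposed and equally tested), there is no minimum
cluster size by default, areas are always pixel_count × pixel_size², and
cluster ids are ordered by each component's lexicographically smallest
(row, col) pixel so output tables are reproducible. Slices are processed
independently; there is no 3-D merging.

## Histology mapping

Iron⁺ pixel detection uses blue chromaticity: a pixel is iron⁺ when
B/(R+G+B) ≥ 0.5 and its luminance is below 200 (ITU-R 601 weights), the
luminance cutoff rejecting bright, chromatically neutral slide background.
Class-label rasters (as produced by the phantom) bypass color logic.

Down-sampling to MRI scale is block averaging over factor×factor tiles
("1:100" is read per axis: ~1 µm/px histology → ~0.1 mm MRI pixels), which
conserves total iron area exactly when the raster dimensions are exact
multiples of the factor; otherwise a bilinear resample to the rounded
target shape is used and exact conservation is not guaranteed. The phantom
defaults are exact multiples.

Watershed discretization Gaussian-smooths the density map (σ = 1 low-res
pixel), thresholds at `min_density` = 0.01 to form the deposit foreground,
seeds at regional maxima (minimum separation 2 px) and applies a
marker-controlled watershed on the negated smoothed density so touching
deposits split at low-density necks; regions under `min_area` (default 1 px)
are dropped. The 0.01 threshold is set from the phantom geometry: a ~14-cell
colony of 10 µm-radius macrophages carries a smoothed peak density of
roughly 0.015–0.05 depending on how it straddles pixel boundaries, so 0.01
keeps small (Poisson-tail) colonies while staying above the level produced
by isolated single iron⁺ cells (~0.005).

Per-deposit cellularity assigns each full-resolution iron⁺ cell centroid to
the deposit label under it after coordinate down-scaling; cells over
background are counted as unassigned, cells outside the raster as skipped,
so assigned + unassigned + skipped always equals the iron⁺ cell total.

## Polarization statistics

f_M1 = N(AIF1⁺) / (N(AIF1⁺) + N(CD206⁺)) and f_M2 = 100 % − f_M1.
Double-positive AIF1⁺CD206⁺ cells count in both numerators and both
denominator terms (they are additionally reported as their own
iron⁺-restricted ratio); this choice is documented rather than forced
because the frequency formula names single markers only. Iron⁺ subset
frequencies are iron⁺X⁺/X⁺ for X ∈ {CD68, AIF1, CD206, AIF1⁺CD206⁺}; an
empty denominator makes that single ratio undefined (NaN) without
suppressing the others.

Group tests are two-tailed pooled-variance Student's *t* (not Welch,
matching the stated test), df = n₁+n₂−2. Zero pooled variance follows a
documented convention: p = 1 for equal means, p = 0 (infinite t of the
appropriate sign) otherwise. No multiple-testing correction is applied —
none is used in the comparison design this mirrors — and the report states
as much.

## Phantoms: what they emulate, and what they do not

**MRI phantom** (256×256 default at 0.1 mm pixels): a tumor disc of radius
5 mm with i.i.d. Gaussian baseline iron 0.03 ± 0.01 mg/g (placed well
inside the low stratum so the distribution maxima fall in the low range, as
in tissue), plus `n_deposits` compact blobs grown by seeded random walk to
a Poisson(4)-pixel target area, iron uniform in [0.15, 0.30] mg/g, confined
to a peripheral margin band (0.55–0.95 of the tumor radius) with a minimum
center spacing of 4 px; grown pixels may not touch another deposit even
diagonally, so planted deposit count equals high-cluster count by
construction. Noise is additive Gaussian on magnitude (the high-SNR Rician
approximation; full Rician available via a flag), and the background
outside the tumor is noise only.

**Histology phantom** (4000×4000 px at 1 µm/px — a 4×4 mm section rather
than a full 1 cm cross section, a deliberate size choice that keeps
multi-seed suites inexpensive while preserving the 1:100 scale relation):
iron⁺ macrophage colonies of Poisson(14) cells (10 µm cell radius, 15 µm
centroid spread) in the margin band with ≥ 500 µm spacing — the spacing is
what guarantees watershed separability, matching the premise that deposits
are spatially discrete — plus a diffuse background population (default
5000; real per-section denominators are not established, so this is an
order-of-magnitude stand-in) that is iron⁺ at the endogenous 0.41 % rate.
Marker flags: AIF1⁺CD206⁺ with probability `p_double`, otherwise
single-positive at relative weights `p_m1`:`p_m2` (default 42:58).

Neither phantom models partial-volume blur, susceptibility artifacts,
B₀/B₁ inhomogeneity, stain variability, cell-segmentation error, or
non-stationary deposit clustering. Passing tests therefore establish that
the *analysis* is correct and statistically calibrated under the stated
generative assumptions — not that the detection thresholds are optimal for
any particular scanner or stain.

## Cohort simulations

`compare_roi_vs_localized` plants a pure count effect: per-tumor deposit
counts Poisson with means 235/8 (control) and 748/8 (treated), 8 tumors per
group, while deposit size and iron-level distributions are shared. Each
tumor is a full 128×128 phantom (4.5 mm radius, 1 % noise) run through the
complete MRI pipeline; per-tumor metrics (ROI frequency- and size-medians,
high-cluster count, mean high-cluster area) are compared across groups per
replicate. The expected pattern — decisive significance for the localized
count, marginal for the ROI frequency median, none for the size metrics —
is asserted over 25 replicates. The standalone cohort simulations
(`simulate_deposit_count_test`, `simulate_shared_size_test`) strip this to
the count vectors and a shared lognormal size distribution (median 4 px,
log-sd 0.5 — a few MRI pixels, right-skewed as deposit areas are).

Randomness: every generator consumes a `numpy` Generator seeded from the
run seed; replicate and per-tumor streams are derived with `SeedSequence`
spawning so cohorts are independent yet fully reproducible. Identical
configuration + seed yields bit-identical rasters, tables and reports.

## Known limitations

* The calibration constants and watershed parameters ship as phantom-tuned
  defaults and must be re-measured/re-validated for real acquisitions.
* Whole-slide pyramid formats, DICOM, stain deconvolution beyond the blue-
  ratio rule, and MRI–histology co-registration are out of scope; the
  comparison between modalities is at the level of summary statistics.
* Cell identity in real RGB sections would require a segmentation step the
  package does not provide; it consumes cell tables (the phantom's ground
  truth, or an external cell caller's export).
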