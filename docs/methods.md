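# Methods

This note documents the models, parameter choices and numerical
conventions behind `osteoscreen`, and what the synthetic-data tests do and
do not demonstrate about real screens.

## Assay model

The analysis assumes 384-well plates (16 rows A–P × 24 columns) of
osteoblast monolayers, reverse-transfected with one siRNA pool per well
and differentiated for several days. Each well is imaged as several
fields (default 15, covering most of the well area) in two or three
channels: a nuclear DNA stain, the ELF 97 phosphatase substrate whose
fluorescent precipitate marks sites of ALP activity as punctate spots,
and optionally the proliferation marker Ki67. The screen runs in
triplicate plates; plate roles (library, Non-Targeting (NT) control,
positive controls Alpl/Il11/Sp7/Runx2, the Kif11 transfection control,
mock, untreated) come from a plate map.

## Segmentation operators

Two operator sets are provided; both report objects in calibrated units
(µm) via the image pixel size (default 1.29 µm/px, a 10× objective at 2×
binning — configurable, never hard-coded).

**Threshold pipeline.** Nuclei: Otsu's threshold computed in sliding
50-px tiles; tiles whose dynamic range is below 25 % of the global range
fall back to the global Otsu value (a per-tile Otsu on a pure-background
tile would split noise). Foreground components are hole-filled,
optionally split by distance-transform watershed (on by default; peaks
closer than 0.7× the minimum nuclear diameter are merged to avoid
over-splitting single nuclei), and gated on equivalent diameter
(4–21.22 µm). ALP spots: the ELF channel is background-corrected by
subtracting a median-filtered (window 2×10+1) and Gaussian-smoothed
background estimate, clipped at zero; spots are then connected components
above a single global threshold set at 2× the mode of the smoothed
intensity histogram — the "background" global-thresholding convention,
which assumes most pixels are background. The threshold is *estimated*
on a smoothed copy but *applied* to the unsmoothed corrected image:
smoothing tails would otherwise bridge nearby spots. No size gate is
applied in this mode.

**Round-object pipeline.** Each channel is background-corrected with a
white top-hat (disk structuring element; feature size 50 px for the
nuclear channel, 100 px for ELF 97 and Ki67; the spot stage applies an
additional top-hat of 10 px). Objects are connected components above an
intensity threshold (nuclei 200 a.u., spots 1000 a.u.) whose equivalent
diameter lies in the size window (nuclei 4–21.22 µm, spots 1.3–8 µm) and
whose circularity 4πA/P² is ≥ 0.6. The circularity cut-off implements
the "round object" notion and is configurable; single-pixel components,
whose perimeter is degenerate, count as round. Component membership is
decided by the pixel threshold; whether an instrument's round-object
detector gates on peak or mean intensity is not observable from the
analysis outputs, so the simpler convention is used and exposed.

Equivalent diameter is the diameter of the circle of equal area. Note a
resolution limit: at 1.29 µm/px a single-pixel object already has an
equivalent diameter of ~1.46 µm, so the 1.3 µm lower spot gate only bites
at finer pixel sizes.

**Ki67.** A nucleus is Ki67-positive when its mean intensity in the
(background-corrected) Ki67 channel is strictly above 300 a.u.

## Quantification

Per field: nuclei count, summed background-corrected ELF intensity over
spot pixels, spot area. Per well: cell number = sum of nuclei over
fields; ALP/cell = unweighted mean over fields of (spot-intensity sum /
nuclei count), **excluding fields with zero nuclei** (treating them as
zero would bias wells downward; dividing would be undefined); Ki67
fraction = pooled positives / pooled nuclei (pooling is unbiased under
varying field density, unlike averaging per-field fractions). A
mean-intensity variant of the ALP statistic (mean ELF intensity within
spot area instead of the sum) is available behind `alp_stat="mean"`; the
sum-based form is canonical.

## Normalization, testing, hit calling

Per plate, cell number and ALP/cell are expressed as percent of the NT
mean; log2(ALP/cell) is z-scored (sample sd) over the library + NT wells
of the plate. Kif11/mock/untreated wells are excluded from the z pool as
process controls, and positive controls as known extremes; the pool is
configurable. The NT wells' mean z (`z_NT`) is carried along: the final
hit criterion is `z ≥ z_NT + 1` (suppressors) or `z ≤ z_NT − 1`
(activators), centred on the controls rather than on zero — in a screen
where many knockdowns lower ALP, the NT controls sit visibly above the
plate mean (z_NT ≈ +0.45 in the simulated reference screen), and an
uncentred ±1 band would be asymmetric with respect to them.

Significance is an unpaired pooled-variance two-tailed t-test of the
gene's replicate log2 values against the NT wells. Raw log2 ALP values
are not comparable across replicate plates (plate-scale offsets), so the
test uses log2 of the percent-of-control values — identical to
re-centring each plate by its NT log2 mean — with NT wells pooled across
plates. p-values are used unadjusted at 0.05, reproducing the screen's
convention; a Benjamini–Hochberg option exists (`HitThresholds(adjust_p=True)`)
and is off by default — with 320 genes tested, the unadjusted criterion
is permissive, which is why the effect-size and z criteria do the real
filtering. Wells with ALP/cell = 0 receive half the smallest positive
ALP value on their plate as a pseudocount before the log and are flagged.

The viability filter excludes genes whose mean cell number falls below
60 % of NT *before* any ALP criterion is considered; hit categories
(suppressor / activator / excluded_viability / not_hit) are therefore
mutually exclusive and exhaustive. The boundary is inclusive: exactly
60 % passes.

`classify_table` applies only the ALP-threshold + p criteria; it exists
for candidate tables that are already post viability/z filtering, such as
the bundled 65-gene primary-screen candidate list.

## Synthetic screens

The simulator emulates the study conditions rather than arbitrary data:
wells seeded at 1800 cells grow to a baseline of 4000 cells by the
imaging endpoint (an assumption; the observed per-well scale of such
screens tops out near 6000, the default heat-map scale), distributed over
15 fields (default) of 696×520 px at 1.29 µm/px. Per-gene effects are
multiplicative: `viability_fraction` on expected cell number and
`alp_fold` on per-cell spot intensity. For Kif11 control wells the
knockdown kills only transfected, dividing cells, so the surviving
fraction is `(1 − transfection_efficiency) + transfection_efficiency ×
viability`; the default efficiency of 0.75 reproduces the ~75 % cell
loss that makes siKif11 a transfection readout.

Counts are Poisson around the expected value after a well-level
multiplicative lognormal factor (CV 0.10 by default — an assumed
triplicate-scale variability, not a measured one) applied independently
to the cell-number and ALP channels. Spots arrive at 1.5 per cell
(Poisson) with lognormal peak amplitudes (mean 3000 a.u., CV 0.25).
Setting `noise_cv = 0` switches the simulation to fully deterministic
expectations — the null-screen identity (every well exactly at baseline)
is part of the generator's contract. All randomness derives from
`(seed, replicate, well)`, so outputs are bit-identical across runs and
monotone in planted effects at fixed seed.

Rendering: nuclei and spots are disks with a raised-cosine edge of 1 px
(so thresholding recovers the planted radius to sub-pixel accuracy, and
tiny objects are not inflated), plus a constant background (100 a.u.) and
additive Gaussian read noise clipped at zero. Nuclei are placed by
rejection sampling with a minimum edge-to-edge margin (default 4 µm:
detection masks dilate up to ~0.5 px beyond the true edge, and 8-connected
labelling bridges gaps under 2 px, so smaller margins would merge objects
that were planted as separate). Ground truth records planted centers,
radii, per-spot rendered pixel sums, and Ki67 labels.

What the simulator does **not** model: optical PSF and focus variation,
overlapping/multi-layer cultures (excluded by design — the assay itself
requires monolayers), uneven illumination, plate-edge effects, and
spatial autocorrelation of biology within a plate. Passing tests
therefore demonstrate correctness of the measurement and statistics
given the assay's assumptions, not robustness to those artifacts.

## Problem sizes used in tests

Tests and the acceptance script run scaled-down studies: fields of
256–320 px, 60–800 cells per well, 1–10 fields, chosen so the whole suite
completes in a couple of minutes while every check remains a ratio or
count that is independent of absolute scale. The screen-scale
recovery study (320 genes, 65 planted effects, triplicate) runs on the
measurement-level simulator (`simulate_measurements`), which draws from
the same statistical model as the image path without rendering; the image
path itself is validated separately by exact segmentation-oracle
equivalence on 50 rendered fields. In a 40-seed development run the hit
caller recovered 100 % of planted effects with zero false positives
among 255 null genes; the transfection-control readout measured
75.0 ± 1.3 % cell loss over 10 seeds.

## Known limitations

* The background-global spot threshold assumes a well-corrected, mostly
  empty background; heavy confluent ALP staining would shift the
  histogram mode and the threshold with it.
* The adaptive-Otsu tiling can show tile-boundary threshold steps on
  images with strong low-frequency illumination gradients (the simulator
  does not generate these by default).
* The unadjusted p < 0.05 criterion is intentionally faithful to the
  screen's convention and is not a multiplicity-controlled error rate.
* 384-well geometry only; other plate formats are out of scope.
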