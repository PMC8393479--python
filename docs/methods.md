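# Methods

Models, parameter defaults, numerical choices, and known limitations of the
`cordleak` pipeline. All distances are micrometres; rasters are `(row, col)`
`float64`/`bool` arrays; areas are `pixel count × pixel_size_um²`.

## Units and morphology primitives

* `um_to_px` converts a physical distance to an integer pixel radius by
  rounding half away from zero, clipped below at 1 px, so a morphological
  radius requested in micrometres always has an effect at any sampling.
* `dilate`/`erode` implement Euclidean-disk morphology through the exact
  Euclidean distance transform (dilation: distance-to-mask ≤ r; erosion:
  distance-to-background > r, with a one-pixel false border so the frame
  edge counts as background). This produces the same pixel sets as
  structuring-element morphology with a discrete disk but stays O(pixels)
  for arbitrarily large radii — relevant for the 100 µm edge-exclusion
  margin, where a 201×201 structuring element is impractical.
* `threshold_relative(raster, region, k)` marks pixels above
  `median + k·MAD` of the region background; the background pool excludes
  the top intensity decile so bright objects cannot inflate their own
  threshold. Default `k = 3`.
* `adaptive_threshold(raster, window_um, k, valid=…)` marks pixels above the
  local mean + k·SD of a square window (uniform filter). The optional
  `valid` mask restricts the *statistics* to a pixel subset, implemented as
  ratios of weighted uniform filters; windows with no valid support carry
  zero statistics. Windows under 5 px are rejected; windows exceeding the
  frame fall back to the global threshold with a warning.
* `exclude_edge` erodes every region class by the margin; it is explicitly
  not idempotent, and the cumulative margin is tracked on the `RegionSet`.

## Synthetic section generator

The generator (`cordleak.synthetic`) exists because the post-mortem images
the analysis was designed for are not publicly deposited; it renders
sections in which every measured quantity is known exactly. **The generator
defaults are the study conditions** for all validation results quoted here.

Geometry: an elliptical cord (semi-axes 0.46 of the frame) holding a
two-lobed "butterfly" gray matter (lateral lobes plus a commissural bridge)
with labeled anterior horns in the ventral half of each lobe. This is
bookkeeping geometry, not anatomy.

Per channel (`SectionSpec` defaults in parentheses):

* **Vessels** (40 per 512×512 µm frame, radii uniform 3–12 µm): lectin
  rings of 3 µm rim width at amplitude 400; every lumen carries an
  intravascular hemoglobin pool at amplitude 300. Centers are
  rejection-sampled with a minimum separation of 8 µm inside the eroded
  tissue mask.
* **Leakage** (`leak_fraction` 0.3): `round(leak_fraction · n)` vessels,
  chosen uniformly, receive an extravascular halo
  `A·exp(−(d−r)/λ)` with amplitude `A = 150` at the rim and decay length
  `λ = 20 µm`, truncated at 6λ. The noise-free halo integral per
  compartment is recorded in the ground truth.
* **SMI-32 somata** (diameter 20 µm) and **pTDP-43 puncta** (diameters
  uniform 4–12 µm, straddling the 8 µm gate) are placed without overlap in
  the anterior horns.
* **Noise**: autofluorescence background 50 inside tissue, then
  Poisson shot noise (`counts = Poisson(gain·I)/gain`) and Gaussian read
  noise, both off by default and enabled for the noisy studies
  (`gain = 0.25`, `read SD = 5`).

Determinism: one `numpy` Generator seeded from `spec.seed` drives the whole
render; equal specs give bit-identical rasters.

CSF cohorts are log-normal per arm. Published medians and upper quartiles
(control 39.86 / 310.4 ng/mL; ALS 74.25 / 889.8 ng/mL) determine the
parameters through `µ = ln(median)`, `σ = ln(Q3/median)/z₀.₇₅` with
`z₀.₇₅ = 0.6744897501960817`. Values below the 6.25 ng/mL limit of
detection are censored *at* the LOD and flagged — never zeroed or halved —
preserving the rank statistics used downstream.

### Generator limitations

* Vessels are circular cross-sections; no longitudinal profiles, no
  tortuosity, no caliber variation along the section.
* Touching or overlapping structures are rendered as-is; two vessels closer
  than the lectin threshold resolves merge into one detected component (a
  resolution limit shared with the real assay, covered by a test).
* Halos are isotropic exponentials; real extravasation is anisotropic and
  follows tissue tracts.
* Region geometry is schematic. Horn areas (~1.1 × 10⁴ µm² at defaults) are
  two orders of magnitude below anatomical anterior horns; densities are
  internally consistent but not anatomically scaled.
* Somata and inclusions are uniform disks at constant amplitude; inclusion
  diameters at the 8 µm gate can rasterize one pixel either side of it, so
  count recovery at the gate is exact only to ±1.

## Vessel morphometry

Detection: `threshold_relative` on the lectin channel within tissue,
8-connected components, area window 10–10,000 µm², compartment assigned by
the centroid's region label (horn labels collapse to gray). Densities are
centroid counts per mm² of compartment.

Shells around the pooled vessel mask:

* perivascular — `dilate(vessel, 10) ∧ ¬erode(fill(vessel), 5)`; for an
  ideal disk of radius 10 µm the analytic area is `π(20² − 5²) ≈ 1178 µm²`;
* glia limitans — `dilate(vessel, 20) ∧ ¬fill(vessel)`; analytic
  `π(30² − 10²) ≈ 2513 µm²`.

Discretized areas match these within 5% at 1 µm/px. Per-vessel marker
means restrict each shell to the vessel's nearest-vessel (Voronoi) cell,
computed from the EDT index transform; a vessel with no qualifying pixels
(e.g. after an intensity-window filter) reports NaN, never zero.

## Hemoglobin scoring and leakage classification

**Scores.** Hemoglobin objects are `threshold_relative` components within
the compartment, minus the filled (intravascular) vessel mask, passing a
20 µm² minimum area. In gray matter an object is kept only if its minimum
EDT distance to the vasculature is ≤ 25 µm (the proximity radius is not a
published parameter; results should always be reported with the radius
used). The score is `Σ(I − background median) / compartment area (mm²)`.
By construction this is a *thresholded, background-subtracted* measure: on
rendered halos it recovers 60–85% of the raw halo integral (the exponential
tail below threshold is excluded) and is exact for compact objects fully
above threshold. The test suite pins both properties.

**Leakage mask** (`build_leakage_mask` defaults): the intravascular pool,
dilated by 3 µm, is removed; the remaining signal is smoothed with a
*masked* Gaussian (`G(I·w)/G(w)`, σ = 3 µm) so lumen intensity cannot bleed
outward; an adaptive threshold (window 200 µm, k = 1.5) whose statistics
run over extravascular tissue only is re-estimated 3 times with previously
detected pixels excluded, so extensive leakage cannot inflate its own
background estimate; morphological closing (4 µm) bridges gaps at excluded
lumens, patches under 250 µm² are swept, and holes are filled so a vessel
fully surrounded by halo sits inside the mask. A vessel is *leaked* when
its centroid lies in the mask (an overlap-fraction rule is available).

Validity regime: the construction assumes leakage is locally anomalous. At
leak fractions up to ~0.5 it reaches sensitivity ≥ 0.9 at specificity
≥ 0.9 (noise-free) and calls no vessels on null sections; with *ubiquitous*
leakage (fraction near 1) the local background estimate saturates and
sensitivity degrades — documented as out of scope.

## Neuropathology counts

SMI-32 somata: thresholded components in the pooled anterior horns with a
100–3,000 µm² soma-area window, reported as count and count per mm² of
horn. pTDP-43 inclusions: thresholded components whose equivalent diameter
`2√(area/π)` meets the 8 µm gate; touching inclusions are not split (no
watershed). Inclusion load is inclusions per neuron, NaN (with a warning)
when no neurons are present. A manual click list (CSV of points) flows
through the same normalization for comparison with the automated counts.

## ELISA standard curves

The calibrator series is fitted with the four-parameter logistic
`A(c) = d + (a−d)/(1 + (c/c₀)^b)` (`scipy.optimize.curve_fit`); fits that
fail or are non-monotone over the calibrated range fall back to a log-log
linear model. Inversion is closed-form
(`c = c₀·((a−d)/(A−d) − 1)^{1/b}`), returning NaN outside the invertible
range. Duplicates are averaged *before* inversion (the curve is nonlinear,
so the order matters); the estimate times the dilution factor (default
1:10) is the reported concentration, censored at the LOD as above.
Round-trip accuracy in range is at machine precision, tested to 0.5%.

## Cohort statistics

* Sections → one arithmetic mean per case and level (NaN sections dropped).
* Outlier screen: one-pass two-sided Grubbs at α = 0.2 on the control
  cohort's per-case means, critical value
  `((n−1)/√n)·√(t²/(n−2+t²))`, `t = t₁₋α/(2n), n−2`. At most one case is
  flagged per variable, and a flagged case is excluded from every
  subsequent table (the control n 5 → 4 bookkeeping).
* Mann–Whitney: exact enumeration when the smaller sample has ≤ 8 values
  and there are no ties, tie-corrected normal approximation otherwise; the
  exact branch is verified against exhaustive enumeration for all
  partitions with n₁+n₂ ≤ 10.
* Two-way ANOVA: `value ~ C(group, Sum) * C(level, Sum)`, Type III sums of
  squares (robust to the unbalanced 5-control/13-ALS design; equal to
  Type I when balanced, which is tested). Post-tests: Šidák-adjusted
  between-group contrasts at each level (family = number of levels) on the
  pooled cell residual mean square, and Tukey–Kramer studentized-range
  comparisons across levels within each group. A repeated-measures variant
  (`AnovaRM`) requires a complete within-subject design and refuses
  anything else. Empirical power of the group main effect is calibrated
  against the noncentral-F prediction in the test suite.

## Validation studies

`cordleak.studies` runs the full chain on rendered cohorts (study spec:
160×160 px at 2 µm/px, 12 vessels, leak fraction 0.25, Poisson gain 0.25,
read SD 5; pipeline with 10 µm edge margin and 150 µm leakage window):

* `leak_classification_accuracy` — pooled confusion counts of the
  leaked/non-leaked call against the generator's assignment, matching
  detections to rendered vessels by nearest center (KD-tree).
* `thoracic_detection_rate` — cohorts of 10 ALS cases × 3 levels × 2
  sections in which the thoracic halo amplitude is doubled (300 vs 150);
  a seed counts as detected when both thoracic-vs-other Tukey comparisons
  have adjusted p < 0.05 in the injected direction. 50 seeds by default.
* `null_false_positive_rate` — identical cohorts without an injected
  effect; a seed counts when *any* adjusted p < 0.05 appears in the level
  family (family-wise error proxy).

Representative results (seed 1 of `scripts/acceptance.py`): sensitivity
0.92 / specificity 1.00 noise-free; 50/50 seeds detect the thoracic
effect; null family-wise false-positive rate 0.04.
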