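# Methods

This note documents the measurement model, its parameters and defaults,
the synthetic data used to validate it, and the numerical and design
choices that were genuinely open.

## Measurement model

The object of measurement is the two-dimensional projected area of
anucleate red cells on a stained smear, in µm². The chain is
segmentation → single-cell location → RBC/nucleated classification →
per-cell area → per-subject aggregation. Key modeling assumptions:

- **Cells are the saturated objects.** Wright-Giemsa-stained cells are
  strongly colored against a pale background, so Otsu's threshold is
  computed on the HSV *saturation* channel (the channel is not dictated
  by the method description; saturation separates stain from background
  more robustly than value, which is perturbed by illumination).
- **Only outer contours count.** Interior holes (the RBC central pallor)
  are filled before contour tracing; a cell is its external boundary.
  Components are 8-connected.
- **S_mean-relative selection.** The per-image mean contour area S_mean
  (over non-pending contours) is the reference scale. The selection
  window (a·S_mean, b·S_mean) with a = 0.3, b = 5 is open at both ends;
  area ≥ b·S_mean is classified as a merged clump. "Convex edge shape"
  is operationalized as polygon area / convex-hull area ≥ 0.9, which
  accepts rasterized circles (ratio ≈ 0.99) and rejects fused-pair
  dumbbells (ratio ≈ 0.88–0.90). The 0.5–10 µm² band is read as: below
  0.5 µm² noise (discarded), [0.5, 10) µm² pending debris (excluded from
  S_mean and from measurement, never revisited).
- **One-pass classification.** Mg is the mean gray value over all
  effective single cells of the image — including nucleated ones — and
  classification uses this fixed Mg in a single pass (no iteration).
  A cell's G is averaged over its filled contour interior (not its
  bounding box), as the less background-contaminated reading. A ratio of
  exactly 0.8 classifies as RBC (documented tie-break; configurable).
- **Per-cell roundness.** P_mean is computed per cell from that cell's
  contour; the recall criterion requires *every* ratio r_i/r > 0.85,
  not the mean. S_r = S_i·P_mean² = π·(mean r_i)², which for a convex,
  nearly round contour approximates the enclosed area; for a perfect
  circle S_r = S_i. Only recall RBCs enter the smear average (the
  non-recall remainder are deformed or clipped cells); setting
  `area.include_non_recall` admits them.
- **Aggregation.** Per-subject mean/SD (sample SD, n−1) of S_r over
  pooled fields; CV = 100·SD/mean. The per-group summaries of a cohort
  are computed across subjects (that is what the subject counts refer
  to), not across pooled cells.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `calibration.microns_per_pixel` | 0.1 | µm/px | pixel pitch at the specimen; 0.1 is typical for 1000× oil immersion. All µm² thresholds are converted through it. |
| `segmentation.noise_floor_um2` | 0.5 | µm² | below: discard as noise |
| `segmentation.pending_ceiling_um2` | 10 | µm² | [floor, ceiling): pending debris |
| `segmentation.a`, `b` | 0.3, 5 | — | S_mean-relative selection window |
| `segmentation.convexity_min` | 0.9 | — | area / convex-hull-area cut |
| `segmentation.edge_refine` | on | — | boundary snap pass (below) |
| `classification.ratio_threshold` | 0.8 | — | G/Mg decision boundary |
| `area.roundness_min` | 0.85 | — | per-point r_i/r recall cut |
| `stats.alpha_normality` | 0.05 | — | Shapiro–Wilk / Levene dispatch level |

## Edge refinement

Whether edge-based segmentation is a separate pass or a refinement of the
threshold mask was an open design point; it is implemented as an optional
refinement (on by default, `--no-edge-refine` to disable): light
morphological closing, then the mask boundary is advanced as a whole
front — a boundary ring is peeled only while the majority of it lies off
any strong intensity edge ("strong" = Sobel magnitude above the Otsu
threshold of the gradient image). A mask already aligned with sharp edges
is a fixed point; a mask dilated into flat background shrinks back to
within one (8-connected) pixel of the true boundary. Ring-at-a-time
peeling means isolated noise dips in rim gradient cannot notch a contour,
which matters because a single notched point fails the all-points
roundness recall. Total foreground change is capped at 20% of the input
mask.

## Statistics

- Two-group comparison dispatch: both groups Shapiro–Wilk p > α and
  Levene (Brown–Forsythe) p > α → pooled t-test; normal but heteroscedastic
  → Welch's t-test (the "corrected" t-test); otherwise two-sided
  Mann–Whitney U with the tie-corrected normal approximation. Pairwise
  comparisons are reported unadjusted, with an optional Holm correction
  flag.
- CV is SD/mean × 100 throughout.
- Correlation: Pearson when both variables pass Shapiro–Wilk at α,
  otherwise Spearman.
- ROC: AUC via the Mann–Whitney rank identity with midranks; orientation
  is fixed at "higher score → case" and never flipped, so AUCs below 0.5
  are reported as such. The AUC p-value tests H0: AUC = 0.5 by the
  tie-corrected normal approximation (the null for reported AUC p-values
  is not otherwise identifiable). The combined marker is the fitted case
  probability of an unpenalized two-covariate logistic regression
  (maximum likelihood); under perfect separation the fit is redone
  without the separation guard and flagged — coefficients are then
  meaningless but the probability ordering, all the ROC consumes, is the
  separating one.

Note an inherent property of the dispatch rule: on exactly Gaussian
equal-variance input, p-values of the three gate tests are uniform, so
the pooled-t branch fires with probability ≈ 0.95³ ≈ 0.857 and a
t-family branch with ≈ 0.95² ≈ 0.90. Dispatch "accuracy" is therefore
meaningful as discrimination between distributional regimes (t-family on
Gaussian vs rank-sum on lognormal, ≈ 95% combined), not as a per-branch
hit rate that the rule itself caps below 0.95.

## Synthetic data

`generate_scene` renders 1000×-like fields: pale background
(245, 240, 240), anti-aliased elliptical RBCs (pale red (230, 160, 150),
default radius 3.75 ± 0.2 µm so mean true area ≈ 44.2 µm², mild
ellipticity ≤ 1.05, central pallor rendered as a lighter center),
nucleated cells (larger, purple nucleus (90, 60, 130) occupying ≥ 70% of
the cell so their mean gray is well below the RBC level), optional
touching pairs at center distance 0.95·(r₁+r₂) (fused dumbbells with
convexity just under the 0.9 cut), and additive Gaussian pixel noise
(SD 3). The default field is 640×640 px with 20 RBCs + 2 nucleated
cells, ≈ 25% areal density — a well-spread counting area; denser fields
fail placement by design rather than silently overlapping. Everything is
deterministic given the seed.

What the generator does *not* emulate: real stain variability and
illumination gradients, rouleaux, platelets, cell debris with complex
texture, biconcave 3-D shading, and focus blur. Passing tests therefore
demonstrate correctness of the measurement logic on well-formed smears,
not robustness to poor slide quality.

`generate_cohort` simulates the four-group study structure (normal 25,
AA 25, MDS 68, MA 64 subjects) with per-subject mean areas at the
reported group moments (44.19 ± 3.88, 43.47 ± 4.37, 45.86 ± 6.42,
52.87 ± 7.68 µm²), lognormal (moment-matched) for AA and MDS whose
clinical distributions were non-normal, and CBC indices drawn at the
reported group means/SDs *independently* of area — deliberately encoding
the observed absence of area–CBC correlation. An `area_mcv_correlation`
knob exists for power studies.

## Numerical choices

- Contours are traced at the 0.5 iso-level (sub-pixel); polygon areas by
  the shoelace formula, agreeing with pixel-fill counts within 5% for
  disks of radius ≥ 8 px.
- The minimum enclosing circle is Welzl's move-to-front construction in
  float64 (containment tolerance 1e-10·scale, radius exact to well under
  1e-6 px); collinear three-point supports fall back to the smallest
  covering two-point circle. The internal shuffle uses a fixed seed: it
  only affects expected runtime, never the result.
- r_i/r ratios are clipped to [0, 1] against float rounding; a ratio of
  exactly the roundness threshold fails (strict inequality).
- Degenerate inputs raise typed errors rather than returning sentinel
  values: constant channel at Otsu, empty candidate set at S_mean,
  non-positive Mg, < 3 distinct points at the enclosing circle, constant
  data at Shapiro–Wilk, single-class labels at ROC.
- SD of a single cell (n = 1) is undefined and reported as absent, as is
  the mean for zero qualifying cells; `run_measure` marks a subject
  failed only when no image of theirs is readable.

## Problem sizes in validation

The shipped validation uses 20-scene end-to-end runs (≈ 400 RBCs), 100
random point sets for the enclosing-circle oracle, 2000 replicates per
branch for type-I calibration, and 100 simulated cohorts (181 subjects
each) for the qualitative reproduction checks.

## Known limitations

- Merged clumps are excluded, not split; fields dominated by touching
  cells under-sample the RBC population (the measurement method shares
  this property).
- S_mean is per field; a field containing almost no real cells makes the
  reference scale meaningless and the field errors out as empty.
- The G/Mg rule assumes nucleated cells are a minority; a field that is
  mostly leukocytes would shift Mg enough to misclassify.
- `Sr` slightly underestimates the area of markedly elliptical cells
  (P_mean² under-corrects the enclosing circle of an ellipse); at the
  ellipticities of real RBC projections (≤ ~1.1) the bias is < 1%.
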