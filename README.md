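# rbcarea

Red-blood-cell (RBC) area morphometry from stained peripheral-blood-smear
microscope images, with the cohort-level statistics used to compare
anemic-disease groups.

## The problem

Aplastic anemia (AA), myelodysplastic syndrome (MDS) and megaloblastic
anemia (MA) are cytopenic diseases that can be hard to tell apart from
routine blood work, especially where cytogenetic and molecular testing is
unavailable. The mean two-dimensional area of RBCs on an ordinary
Wright-Giemsa-stained smear, measured automatically from 1000× microscope
fields, is an inexpensive morphometric marker: MA red cells are markedly
enlarged (macro-ovalocytes), so mean RBC area separates MA from normal
subjects and from AA/MDS, and combines with the mean corpuscular volume
(MCV) into a stronger two-marker classifier.

`rbcarea` implements the full measurement chain and the statistical
workflow, plus a synthetic smear/cohort generator with exhaustive ground
truth so every stage is testable without clinical material.

## The method

Per field of view (RGB image + µm/px calibration):

1. **Segmentation** — convert to HSV; Otsu's threshold on the saturation
   channel separates stained cells from the pale background; an optional
   edge-refinement pass snaps mask boundaries to strong gray-gradient
   edges.
2. **Single-cell location** — extract one outer contour per 8-connected
   component (interior holes such as central pallor are ignored). Contours
   below 0.5 µm² are noise; those in [0.5, 10) µm² are *pending* debris,
   excluded from everything. S_mean is the mean area of the remaining
   contours; a contour is an *effective* single cell if its area lies in
   (a·S_mean, b·S_mean) with a = 0.3, b = 5 and its outline is convex
   (area / convex-hull area ≥ 0.9). Contours at or above b·S_mean are
   merged multi-cell clumps and are excluded.
3. **RBC vs nucleated** — G is a cell's mean gray value (BT.601 luma), Mg
   the mean of G over all located single cells; G/Mg > 0.8 → RBC,
   otherwise nucleated (dark nucleus pulls G down).
4. **Area** — for each cell, the minimum enclosing circle (radius r) of
   the contour; with r_i the distances of contour points to the circle
   center, P_mean = mean(r_i / r). A *recall RBC* has every r_i/r > 0.85
   and circle area inside (a·S_mean, b·S_mean). Its area is

       S_i = π r²,   S_r = S_i · P_mean²

   and per-subject results are the mean ± SD (and CV = 100·SD/mean) of
   S_r over recall RBCs, pooled across that subject's fields.

Cohort statistics on per-subject mean areas: Shapiro–Wilk normality
dispatch (pooled t-test / Welch t-test / Wilcoxon rank-sum, with Levene's
test for variance homogeneity), Pearson-or-Spearman correlation against
CBC indices (MCV, MCH, MCHC, RDW), and ROC analysis per disease vs
normal: area alone, MCV alone, and the fitted case probability of a
two-covariate logistic model as the combined marker.

## Worked example

Generate a synthetic field, measure it, and run cohort statistics on a
simulated four-group cohort:

```bash
rbcarea synth scene --seed 11 --out scene.png
rbcarea measure scene.png --subject demo --out summary.csv
cat summary.csv
```

```
subject_id,n_rbc_measured,mean_area_um2,sd_area_um2,cv_percent,failed
demo,20,43.76760703593638,4.84444055688514,11.06855248656273,False
```

All 20 generated RBCs (drawn with radius 3.75 ± 0.2 µm, i.e. a true mean
area near π·3.75² ≈ 44.2 µm²) were located, classified and measured; the
recovered mean of 43.8 µm² reflects this particular field's random draw
of radii.

```bash
rbcarea synth cohort --seed 11 --out cohort.csv
rbcarea stats cohort.csv --out report.json
```

The JSON report contains every pairwise group comparison, per-group CVs,
area-vs-CBC correlations and the per-disease ROC triples. For this seed:
MA vs normal is compared by Welch's t-test (p ≈ 1.2e-10), and the MA ROC
AUCs are 0.831 (area), 0.999 (MCV) and 0.999 (combined predicted
probability) — the expected pattern: area alone is a good but imperfect
MA marker and combines cleanly with MCV.

The same operations are available as a library (`rbcarea.measure_image`,
`rbcarea.run_measure`, `rbcarea.run_stats`,
`rbcarea.synthetic.generate_scene`, ...).

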