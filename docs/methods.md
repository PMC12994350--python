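# Methods

## Problem

The tumor-stroma ratio (TSR) is a prognostic marker in rectal
adenocarcinoma: patients whose tumors contain a high proportion of
intratumoral stroma fare worse. The conventional assessment is visual — a
pathologist picks the stroma "hot-spot" (a 1.8 mm-diameter microscope field
at ×100 with tumor at all borders and high stroma content) and estimates,
in 10% increments, the fraction

    TSR = 100% × stroma area / (tumor area + stroma area)

inside the circle, excluding lumen, tears and other tissue types. Patients
are dichotomized at a cutoff (50% by convention, or the cohort median of
the automated scores) into *stroma-low* (TSR ≤ cutoff) and *stroma-high*
(TSR > cutoff). This package implements the semi-automatic counterpart:
multi-class tissue segmentation of the H&E raster, pixel counting inside
the expert-marked circle, dichotomization, and the statistical harness that
compares observers with the automated method (cross-tabulations, Cohen's
kappa, ICC) and evaluates prognostic value (Kaplan–Meier, log-rank, Cox).
Hot-spot *selection* remains manual by design; the method is
semi-automatic.

## Tissue classes and segmentation

Nine tissue classes are segmented: tumor, intratumoral stroma, necrosis,
muscle, healthy epithelium, fat, mucus, lymphocytes and blood
(erythrocytes). A tenth *background* code marks unstained glass/lumen and
is assigned only by masking — a pixel is background when its minimum RGB
channel is ≥ 220 (8-bit), cleaned by a 3×3 majority filter. This explicit
rule is needed because lumen appears inside hot-spots yet is not a class
the classifier predicts, and the visual protocol excludes it from the
ratio.

The classifier operates on 256×256-pixel patches. Rather than a
convolutional network, it is a compact multilayer perceptron (hidden
layers 64/32) over 16 engineered statistics of the patch's central block:
per-channel mean/std/median, dark- and white-pixel fractions, gradient
energy (mean/std), orientation anisotropy, and red–blue / red–green
offsets. Features are standardized with a floored std and clipped z-scores
so directions that are near-constant in training (e.g. white fraction)
cannot explode on unseen mixed blocks. Dense maps are produced by sliding
the patch window at stride 16 and painting each prediction onto the
patch's central 16×16 block; borders are covered by reflective padding.
The small block keeps boundary-straddling blocks rare, which matters for
TSR because misclassified boundary blocks are excluded from the
denominator. Training patches are labelled with the majority class of the
same central block and kept only when that class covers ≥ 90% of it
(mixed patches are ambiguous); classes are balance-sampled to prevent
majority collapse.

Training runs a fixed number of epochs (default 30, learning rate 0.01,
batch 128) over shuffled minibatches with a 20% held-out split; the
per-epoch loss and held-out accuracy are recorded, and a fixed seed makes
the fit bit-reproducible. Evaluation is pixel-wise over an annotated
region mask: one-vs-rest sensitivity and specificity per class plus
overall accuracy, from a confusion table whose rows are truth classes and
whose extra final column collects pixels the map coded background inside
tissue (a miss for their true class, a false positive for none).
Cross-validation is k-fold (default 5) over *slide* identifiers, never
patches, so no slide contributes to both sides of a fold; pooled metrics
sum the per-fold confusion tables. Both per-fold and pooled figures are
emitted since averaging conventions differ between studies.

## Hot-spot geometry and TSR

Physical units are primary: a hot-spot is a circle with center in mm on
the slide and diameter 1.8 mm by default; at the reference scanner
resolution of 0.455 µm/pixel that is 1800/0.455 ≈ 3956 ≈ 4000 pixels. A
pixel is inside the circle iff its center (i+0.5, j+0.5) lies within the
radius, boundary inclusive — an unambiguous rule whose area converges to
πr². Inside the circle, tumor and stroma pixels are counted; every other
class including background is *excluded*, and TSR follows the formula
above. A circle with no tumor and no stroma raises an error rather than
returning 0 or 100: the protocol requires tumor at the borders, so an
empty denominator marks an invalid hot-spot. Dichotomization is
inclusive-low (TSR ≤ cutoff → stroma-low) at either a fixed cutoff or the
sample median of the automated scores (mean-of-middle-two for even n),
which balances group sizes up to ties.

## Agreement statistics

Dichotomized labels from two raters are cross-tabulated 2×2 and summarised
by unweighted Cohen's kappa, κ = (p_o − p_e)/(1 − p_e), implemented from
the closed form with a large-sample asymptotic CI (reported, not used for
decisions). Continuous scores are compared with the intraclass correlation
via pingouin; the default variant is two-way random effects, absolute
agreement, single measure (ICC(A,1)), because raters here are
interchangeable measurement methods and a systematic offset between an
observer and the machine must count as disagreement; the consistency
variant ICC(C,1) is available by option. Associations between TSR and
categorical clinicopathological variables use the Mann–Whitney U test (two
levels) or Kruskal–Wallis (more), two-sided, α = 0.05.

## Survival harness

Covariates follow the conventional grouped coding for this cohort
structure: age continuous; male vs female; pT3–4 vs pT1–2 (the sparse pT1
and pT4 levels are merged with their neighbours); lymph-node metastases
(pN ≥ 1) vs none; poorly vs well/moderately differentiated; any adjuvant
therapy vs none; TSR group with stroma-low as reference. Kaplan–Meier
curves per group use lifelines, with a two-sided log-rank test; with zero
events the log-rank is undefined and p = 1 is reported with a warning.
Five-year rates read the product-limit curve at 5 years
(right-continuous); if follow-up ends earlier with patients at risk the
last estimate is returned with a warning. Cox proportional-hazards fits
report per-covariate hazard ratios with Wald 95% CIs and p-values. Ties
are handled by the Efron approximation by default (lifelines); the Breslow
option — the default of some commercial packages — is provided through the
statsmodels proportional-hazards fit, since lifelines implements Efron
only. The difference is immaterial for continuous simulated times.

## Synthetic fixtures: what they emulate and what they do not

No public image or patient-level data accompany the study design this
package targets, so every component is exercised on synthetic fixtures
with exact ground truth.

**Tiles.** Each class has a fixed procedural recipe (base hue + smoothed
noise + structural elements: dark nuclei blobs for tumor, anisotropic
fibrous strokes for stroma and muscle at orthogonal orientations, ring
structures for epithelium, pale membrane polygons for fat, dense dark dots
for lymphocytes, speckled grey-pink for necrosis, pale blue wisps for
mucus, saturated red for blood). Multi-class tiles partition the raster
into contiguous nearest-seed cells, redrawn until every class holds ≥ 2%
of the area (equal stripes as a deterministic fallback). The recipes are
deliberately separable by color/texture statistics — the point is a
learnable, fully labelled benchmark on CPU, not photorealism. Passing the
segmentation benchmark therefore shows the pipeline's plumbing and
training loop are correct, *not* that the classifier would reach
comparable accuracy on real whole-slide images, where class appearance
overlaps heavily and staining varies.

**Hot-spot scenes.** A circle inscribed in a square tile is filled with
tumor + stroma split by thresholding a smoothed noise field at the exact
quantile matching the target TSR (plus an optional share of other tissue
and background); region scale grows with the scene (σ = size/5) because
real hot-spot territories are large contiguous areas, not pixel salt. The
true TSR is recomputed from the emitted mask and is within 2 points of the
target by construction.

**Cohorts.** True TSR is drawn from a clipped normal (mean 55, sd 20 —
broad spread straddling both cutoffs); the two visual scores add
independent Gaussian noise (default sd 10 points, a free parameter since
no inter-observer noise magnitude is published) and round to 10%
increments; the automated score adds small unrounded noise (sd 2).
Consensus is the mean of the two visual scores then the cutoff — a
stand-in, since real consensus meetings are not modellable. Survival times
are exponential with the stroma-high group's hazard multiplied by the
configured hazard ratio (DSS baseline 0.06/yr, DFS 0.09/yr), censored by
an independent exponential (0.05/yr) capped at 12 years of follow-up;
recurrence is truncated at the end of disease-specific follow-up. The
clinicopathological covariates are drawn from the marginal frequencies of
a 129-patient rectal-cancer cohort. The generator satisfies the
proportional-hazards assumption exactly, so Cox recovery checks estimator
correctness, not robustness to model misspecification.

## Problem sizes used in tests

The cross-validated segmentation benchmark uses 10 synthetic slides × 9
single-class 384×384 tiles (stride-64 patch grids, ~81 patches/class/fold
arm, 20 epochs). Hazard-ratio recovery uses 50 simulated cohorts of n=500
at true HR 2.5; log-rank null calibration uses 200 cohorts of n=2000
without censoring; the end-to-end TSR recovery uses 512-pixel scenes.

## Known limitations

- The patch classifier's engineered features are tailored to the fixture
  textures; real H&E work would substitute a convolutional backbone behind
  the same training/inference interface.
- Stain normalization offers Reinhard-style LAB channel statistics and
  Macenko-style stain-vector deconvolution; both are standard stand-ins
  for whatever normalizer a deployment prefers, selectable in config, and
  can be fitted per slide or on a fixed template.
- Hot-spot selection is not automated; circles come from a spec file or
  CLI arguments.
- The kappa CI is the simple large-sample form; the ICC CI is pingouin's
  F-based interval. Neither drives any decision in the package.
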