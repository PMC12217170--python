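# Methods

`blcb` implements classification-based segmentation of the retinal
vascular tree: every pixel of a fundus photograph is classified as
vessel or non-vessel from the 64×64 intensity window centered on it,
and the per-pixel probabilities are reassembled into a map. The
package's core is the bi-level class-balancing scheme that decides
*which* pixels the classifier trains on.

## Pipeline

1. **Preprocessing** (`blcb.preprocess`). The green channel (highest
   vessel/background contrast of the RGB channels) is normalised by
   global contrast normalisation,
   `x' = s·(x − mean) / max(ε, sqrt(λ + var))` with `s = 1`,
   `λ = ε = 1e−8` over the whole image, min-max rescaled to [0, 1],
   passed through CLAHE (clip limit 2.0 in histogram-count units on an
   8×8 tile grid) and a gamma correction (`γ = 1.2`). The GCN rescale
   keeps stages composable (CLAHE needs a valid intensity range); the
   CLAHE and gamma values are conventional fundus-enhancement settings
   and are configurable — nothing downstream depends on their exact
   values. Order is fixed: GCN → CLAHE → gamma. Degenerate inputs:
   a constant image maps to zeros under GCN and is a CLAHE fixed point.

2. **Patch bookkeeping** (`blcb.patching`). An even-sized window has no
   central pixel; the convention here puts the focal pixel at local
   index (32, 32), i.e. reflect padding (mirror without edge repeat) of
   32 px top/left and 31 px bottom/right. Reflect padding avoids the
   artificial dark borders zero padding would create, which would bias
   window means near the image edge. Per-pixel records carry the window
   means of image and ground truth (`pm_image`, `pm_gt`), computed with
   integral-image sliding sums so no window is ever materialised during
   enumeration.

3. **Bi-level balancing** (`blcb.balancing`). Records are first split
   into vessel (α), partial background (β: non-vessel with
   `pm_image ≥ t`, default `t = 0.10`) and full background (γ: the
   near-black surround). Vessel membership defaults to the center-pixel
   label; a patch-mean mode (vessel iff `pm_gt ≥ v`) is available.
   *Level I* keeps α and draws `y = round(p·|α|)` records from β and
   `z = |α| − y` from γ (`p = 0.9`), seeded, without replacement.
   *Level II* first splits α into thick/thin via morphological opening
   of the ground truth with a radius-1 disk (which removes 1–2 px wide
   structures — exactly the thin class), keeps all thin records, draws
   `x = min(round(r·|thin|), |thick|)` thick records (`r = 1`), then
   rebalances the background against the reduced vessel set with the
   Level-I rule. Rounding is half-up; the remainder goes to γ so totals
   are exact. Shortfall rules: a deficit in β fills from γ and vice
   versa; an overall background deficit subsamples the vessel side
   (logged) so the vessel/non-vessel balance is always exact. One
   seeded generator per balance call over deterministically ordered
   catalogs makes every balanced set bit-reproducible.

4. **Classifier** (`blcb.cnn`). Three convolutional blocks of two
   sub-blocks (3×3 conv → batch norm → ReLU), each block closed by 2×2
   max pooling and dropout 0.25, filters doubling per block (F, 2F,
   4F; default F = 32); flatten; three dense blocks (256/128/64 with
   batch norm, ReLU, dropout 0.25); one sigmoid output — ten weighted
   layers in total. The network is implemented directly on numpy
   (shift-and-GEMM convolution, channels-last layout) with He
   initialisation, binary cross-entropy and Adam (lr 1e−3), all
   randomness drawn from a single seeded generator, so training is
   bit-reproducible on a fixed platform. Defaults: 80 epochs, batch 64.

   *Batch-norm recalibration.* Dropout inflates activation variance
   during training, so batch-norm running statistics collected then
   over-normalise at inference and systematically deflate the output
   probabilities (a known dropout/batch-norm interaction). After the
   last epoch the per-channel moments are therefore re-estimated over
   the training windows with dropout disabled ("precise BN") and
   installed as the inference statistics. Without this step a
   short-schedule model can rank pixels well yet push almost all
   probabilities below a fixed 0.5 threshold.

5. **Segmentation** (`blcb.segmentation`). The probability at (i, j) is
   the classifier output on the window centered there; maps keep the
   image's shape. Binarisation threshold defaults to 0.5 with ties
   counted as vessel; the probability map is preserved because ROC
   analysis needs continuous scores. Post-processing is one binary
   erosion with a 3×3 cross (zero-padded border), optional because
   erosion can delete one-pixel-wide vessels — the tension between
   noise removal and thin-vessel recall is inherent, so `--no-erode`
   is provided.

6. **Evaluation** (`blcb.evaluation`). Sensitivity = vessel recall,
   specificity = background recall, accuracy, and rank-based
   (Mann–Whitney) AUC with half credit for ties — identical to
   trapezoidal ROC integration. Metrics evaluate all pixels by default;
   a FOV mask restricts them when supplied. Undefined metrics (empty
   denominator) are flagged `None`, never silently NaN.

## Synthetic data

`blcb.synth` generates fundus-like images with exact ground truth: a
bright circular field of view with a radial illumination gradient and
Gaussian noise (σ = 0.03) on a near-black surround, and vessel trees
grown by a seeded branching random walk. Branches start 5–7 px wide at
the FOV margin, shrink by ×0.7 at each bifurcation, and terminate below
1 px or at the FOV edge; every stroked pixel records the maximum
stroking width, and the thick/thin truth is the width cut at 2 px
(matching what a radius-1 opening removes; a junction pixel stroked at
several widths counts as thick). The intensity image is rendered with a
softened vessel profile; masks are hard-rasterised so truth stays
binary. Defaults (256×256, 2 trees, contrast drop 0.35) give vessel
densities of roughly 5–15 % of the FOV with both width classes present —
in the range of real fundus annotations.

What the generator does *not* emulate: optic disc, macula, lesions,
color/texture variation between eyes, annotation noise. Passing tests
therefore validate the pipeline's mechanics and the balancing
algorithm's effect under controlled conditions; they do not certify
benchmark-level performance on real fundus datasets, which requires the
real images and full-scale training.

## Scaled-down balancing study

The three-arm ablation (`ablation_run`) trains otherwise-identical
classifiers on (a) a uniform subsample of all patches at natural class
proportions, (b) Level-I and (c) Level-II balanced sets, all capped to
the same patch budget by stratified (largest-remainder) subsampling so
the arms are budget-matched. The study sizes were chosen once for a
single-CPU desk run: 8 training / 2 test images of 256×256, a budget of
1 800 patches per arm, base filters F = 6 with dense widths (48, 24,
12), 5 epochs, batch 64, and per-test-image evaluation on a stratified
pixel sample (600 vessel pixels split evenly between thin and thick,
plus 600 background pixels) rather than a dense 65 536-pixel sweep —
sensitivity and specificity are per-class means, so a stratified sample
estimates them without bias, and thin-vessel sensitivity is reported
from the thin stratum. Metrics are averaged over test images per seed
and over three seeds per arm.

Expected qualitative outcome, mirroring the full-scale behaviour: the
unbalanced arm has high specificity but poor sensitivity (the classifier
favours the dominant background class); Level I raises sensitivity at
some cost in specificity; Level II further raises thin-vessel
sensitivity. Magnitudes are not comparable to full-scale training.

## Known limitations

- The numpy classifier is single-threaded and desk-scale; DRIVE-scale
  training (hundreds of thousands of patches, 80 epochs) is out of its
  intended range.
- Seed determinism holds for a fixed platform/BLAS; exact floats may
  differ across BLAS builds (losses agree to ~1e−6).
- The radius-1 opening misclassifies a small fraction of vessel pixels
  near junctions and on diagonal width-3 branches (measured ~99 %
  agreement with construction truth on synthetic trees).
- With `p = 0.9` and few full-background pixels in view, the γ quota
  silently shifts to β by the documented shortfall rule; the provenance
  counts record what was actually drawn.
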