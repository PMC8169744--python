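# Methods

`cacscore` implements fully automatic coronary artery calcium (CAC)
scoring for chest CT in two stages, plus a bucket classifier for non-gated
exams, a synthetic phantom generator that serves as an exact reference
standard, and the agreement statistics used to evaluate such systems.

## The scoring model

**Stage 1 — segmentation.** A convolutional encoder–decoder processes each
axial slice independently and emits, per pixel, the vector
(p_calc, p_lca, p_lad, p_lcx, p_rca): a logistic (sigmoid) calcium
probability and a softmax distribution over the four coronary territories
(left main, left anterior descending, left circumflex, right coronary), with
p_lca + p_lad + p_lcx + p_rca = 1 at every pixel. There is no explicit
"non-coronary calcium" class: aortic-wall and valvular calcifications must
be suppressed through low p_calc, which is exactly what the hard-negative
mining (below) trains. Both heads share the entire trunk and split only at
the final 1×1 projection.

The encoder is a stack of squeeze-and-excitation residual stages with
grouped 3×3 convolutions (SE-ResNeXt style). Stage plans (blocks per stage)
are (3,4,6,3) for the full 50-layer setting and (2,2,2,2)/(1,1,1,1) for
desk-scale variants; all share the output contract, which the tests enforce
for arbitrary weights. The decoder is 4 blocks, each "3×3 conv → 4×4
stride-2 transposed conv (2× upsampling) → 3×3 conv", so the output returns
exactly to input resolution. Three U-Net-style skip connections concatenate
encoder features into the decoder. Which encoder stages feed the skips is a
genuinely open design point; we take the three shallowest (full-resolution
stem, 1/2, 1/4), leaving the deepest decoder block unskipped — the
full-resolution skip is what lets the head commit to pixel-exact lesion
boundaries, and this choice is load-bearing for the overfitting smoke test.
Every convolution is followed by group normalization (the batch-independent
stand-in for the batch normalization the full-scale encoder family uses;
group count min(8, C)). The calcium-head bias is initialized to −4 so the
initial foreground probability matches the rarity of calcium rather than
starting at 0.5; with a Dice objective this avoids an early phase where the
gradient is dominated by a dense half-on background.

The network and its training loop are written directly on NumPy with a
small reverse-mode autograd (`_nn.py`): im2col convolutions, transposed
convolutions implemented as the exact adjoint of the strided convolution,
hand-derived backward passes validated against central finite differences
in the test suite. This keeps the package dependency-light and every
gradient auditable; it is a desk-scale engine, not a GPU trainer.

**Preprocessing.** Inputs are Hounsfield Units clipped to [−800, 1200] and
zero-centered. The centering constant is not uniquely determined by that
description; we use the fixed affine map x → (x − 200)/1000 (midpoint and
half-width of the clip window), deliberately image-independent so that
preprocessing is deterministic and monotone in HU. Slices are resampled to
the network size with linear interpolation (labels: nearest-neighbour), and
pixel spacing is rescaled by the same factor so physical areas survive the
round trip.

**Stage 2 — deterministic scoring.** Scoring always runs on the
original-resolution raw HU volume, never the preprocessed one: the Agatston
definition lives in HU, and clipping at 1200 would corrupt the density
weight of dense plaque. Per slice:

1. threshold p_calc > 0.5 (strict);
2. 8-connected components within the slice (never across slices);
3. per-pixel artery argmax, lesion label by plurality vote; ties broken by
   the larger summed probability mass, then fixed order LCA<LAD<LCX<RCA;
4. lesion area counts only pixels with attenuation > 130 HU (strict);
   the lesion score is area(mm²) × w(peak HU) with the standard density
   bins w = 1/2/3/4 for peak HU in (130,200)/[200,300)/[300,400)/[400,∞).

Scores are summed per artery and in total; the total maps to risk bucket
I–V for totals 0 / (0,10] / (10,100] / (100,400] / >400, and dichotomizes
at the clinical cutoffs {1, 10, 100, 400} as "score ≥ cutoff". "Scale the
area by the maximum attenuation" could also be read literally
(area × peak HU); that variant is exposed via
`ScoringConfig(literal_hu_weight=True)`, but the binned weight is the
default because the bucket boundaries (0–400) presuppose the conventional
scale. No minimum lesion area is applied by default
(`min_lesion_area_mm2=0`); the conventional ≥1 mm² filter is one config
field away.

A note on boundaries: the printed bucket convention (1–10, 11–100,
101–400) and the cutoff convention (≥10, ≥100, ≥400) disagree at the
boundary scores themselves (a score of exactly 100 is bucket III yet
positive at cutoff 100) and for fractional scores in (0, 1). The package
keeps both conventions as stated and the tests assert their equivalence
only away from those measure-zero disagreement points.

## Training procedure

Mini-batches (64 slices at full scale) are drawn without replacement per
epoch from an eligible pool that starts as the lesion-bearing slices only.
After every epoch the pool is expanded with calcium-free slices the model
misclassifies. "Misclassifies" is operationalized as: the *full* second
stage (0.5 threshold, components, HU>130 restriction, minimum area) yields
at least one lesion with a nonzero score — i.e. exactly the event that
would corrupt a patient's score, rather than any raw pixel probability.
The pool only grows, and re-adding is a no-op.

The loss is Dice loss on the calcium head (additive smoothing constant 1.0,
keeping empty-mask batches finite) plus cross-entropy on the vessel head
evaluated only on true-calcium pixels: vessel identity is undefined
elsewhere, and the softmax constraint forces *some* artery label at every
pixel, so unmasked supervision would be noise.

Optimization is Adam (β₁=0.9, β₂=0.999) with L2 regularization 1e-4 on all
parameters and two learning-rate groups: 1e-3 for randomly initialized
weights and 1e-4 for pretrained encoder weights (loadable from an `.npz`
archive; never bundled). The schedule is a linear warmup over 5k iterations
followed by cosine annealing over 300k, and the pretrained group evaluates
the same function delayed by 10k iterations (clamped at zero). A single
`scale_factor` multiplies all three counts so the identical shape runs at
desk scale; the schedule is iteration-based and independent of epoch
length. Divergence (non-finite loss) aborts with a diagnostic rather than
continuing.

## Non-gated post-processing

Non-gated chest CT is noisier (thicker effective slices, motion, varying
dose), so the summed score is not trusted directly. Each slice's predicted
lesions are summarized by four numbers: total calcified area (mm²), peak HU
within the predicted region, Σ(lesion area × lesion peak HU), and the
lesion count; an empty slice is (0,0,0,0) and the peak of an empty region
is defined as 0. The summaries of the 5 slices with the largest predicted
area (ties broken by smaller slice index) are concatenated into a
20-component exam vector, zero-padded when fewer than 5 slices bear
lesions. A multiclass gradient-boosted decision tree (200 trees, depth 3,
learning rate 0.1, fixed seed; scikit-learn backend) maps the vector to a
bucket I–V, trained against bucket labels from paired gated reference
scores. Binary calls at the clinical cutoffs derive from the predicted
bucket via the boundary mapping 1↔≥II, 10↔≥III, 100↔≥IV, 400↔V.

## The phantom generator

Phantoms make every stage testable with an exact, analytically known
reference. A phantom is a stack of axial slices (defaults: 512×512 pixels,
0.5 mm in-plane, 5 mm slice spacing — a calcium-scoring series geometry;
tests use 32–64 px versions of the same geometry): uniform soft-tissue
background (40 HU) with additive Gaussian noise (10 HU), four disjoint
vessel territories (quadrant-offset tubes through the stack — deliberately
schematic, so ground truth is unambiguous), and non-coronary distractors
(aortic wall, aortic-root cusps, mitral annulus) in a central zone disjoint
from every territory. Lesions are filled ellipses with uniform HU drawn
from a configurable window strictly above 130; placement enforces a ≥2 px
8-connectivity gap between all objects, so components never merge and
vessel-vote ties cannot arise by construction. If a territory cannot host
the request, generation fails loudly (`PlacementError`), never silently.

Noise is added after lesion insertion and the manifest records clean-volume
statistics, so the generator-side Agatston score — computed from the
manifest with an independently written copy of the formula — is exact. The
bucket-stratified cohort builder chooses lesion counts, radii and HU
windows per bucket such that the minimum and maximum attainable totals both
fall inside the target bucket whatever the random placements; stratified
cohorts therefore hit requested bucket counts exactly.

The gated→non-gated degradation applies in-plane Gaussian blur along a
motion axis, z-smoothing (thicker effective slices) and extra noise, while
the ground truth stays that of the paired gated phantom — mirroring the use
of gated scores as the reference standard for non-gated exams. With all
parameters zero the output equals the input bit for bit.

What the phantoms do *not* emulate: anatomy (vessel curvature, ostia),
contrast enhancement, beam hardening, partial-volume blur at lesion edges
in the *clean* volume, scanner spectra. Passing tests therefore demonstrate
the correctness of the pipeline's mechanics and the learnability of
high-contrast segmentation — not clinical performance on real exams.

## Evaluation statistics

Bland–Altman: bias = mean(predicted − reference), limits of agreement
bias ± 1.96·SD (SD with n−1), bias CI via SD/√n. Cohen's Kappa: unweighted,
on buckets, with the conventional bands (<0 poor, ≤0.2 slight, ≤0.4 fair,
≤0.6 moderate, ≤0.8 substantial, ≤1.0 almost perfect); perfect agreement
with one observed category is reported as 1.0. Two-sample
Kolmogorov–Smirnov via `scipy.stats.ks_2samp` with the asymptotic p-value.
Diagnostic metrics at each cutoff come from the 2×2 table; 95% CIs use the
Wald normal approximation clipped to [0,1] (Wilson intervals by flag); F1
is the harmonic mean of sensitivity and PPV; metrics with an empty
denominator are NaN and flagged `undefined` rather than silently replaced.
Confusion matrices are 5×5 with the reference on rows.

## Problem sizes used in tests and the acceptance script

Phantom cohorts of 50–60 exams at 64×64×8; oracle comparisons on 200
random ≤14×14 volumes; the training smoke test overfits a reduced model
(depth-10 encoder, 8 base channels) on one 5-slice 64×64 phantom for ~900
iterations (`scale_factor=0.003`), reaching hard Dice > 0.9 on CPU in about
two minutes. These sizes are the package's chosen desk-scale operating
points; every mechanism they exercise is size-independent.

## Known limitations

- The NumPy engine is single-device and desk-scale by design; full-scale
  (512², depth-50, 300k iterations) training is out of reach without a GPU
  framework, and no trained clinical weights ship with the package.
- Slice-wise (2-D) component analysis and no slice-thickness
  renormalization, matching the method being implemented; scores from thick
  slices are not comparable across protocols.
- The phantom's noise model is additive Gaussian; real CT noise is
  correlated and dose-dependent.
- Cohen's Kappa is unweighted; "partial agreement" is a display category,
  not a weighting scheme.
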