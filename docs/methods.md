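# Methods

## Problem and pipeline

The package studies screening for neonatal jaundice from a single RGB
photograph of a newborn's face with a color calibration card in frame. The
physiological signal is a yellow cast of skin and sclera that grows with the
bilirubin level; the diagnostic label is a threshold on transcutaneous
bilirubin, TCB ≥ 204 µmol/L → jaundiced. The pipeline is
simulate (or load) → white balance → segment ROIs → extract color means →
classify → compare models.

## Synthetic scene model

Real neonatal photographs cannot be redistributed, so all testing runs on a
generative stand-in that reproduces the statistical structure the analysis
relies on, not photographic realism.

A scene is a 256×256 RGB canvas with a face rectangle painted in a skin
color, two sclera ellipses, and a calibration card with four reference
patches (one pure white) on the chest. The color model is

- yellowing: the blue channel of skin and sclera is depressed by
  `jaundice_blue_drop · min(TCB/300, 1)`; red and green are untouched.
  In RGB, yellow is the complement of blue, so clinical yellowing is a blue
  deficit at roughly constant red/green. The shifted color is quantized to
  integers — ground-truth colors are 8-bit camera colors;
- illumination: a per-channel multiplicative gain in (0, 1], the same cast
  the calibration card is there to remove. Sampled gains are snapped to the
  1/255 grid so that an ideal white surface maps to an exact 8-bit level;
  with that convention the paint-then-recalibrate round trip provably loses
  at most one intensity unit to rounding for any gain ≥ 0.5 (two roundings
  of a ≤2× rescale). Off-grid gains are still accepted for user scenes;
- noise: additive i.i.d. Gaussian pixel noise (default σ = 10 intensity
  units, a realistic smartphone sensor level), then clip to [0, 255] and
  round half-up to uint8.

Landmarks follow the standard 0-based 68-point convention. The six contour
points of each eye are placed at 60° steps on a 1.03-scaled copy of the
painted sclera ellipse; with that geometry the rasterized convex hull of the
landmarks overlaps the painted ellipse with IoU ≈ 0.89 and contains almost
no non-sclera pixels (mean-color error < 2 intensity units). Both margins
are deterministic given the image size, because the landmark layout is.

Cohorts draw TCB uniformly from [0, 203] for healthy and [204, 300] for
jaundiced subjects, with an exact class count `round(n · fraction)`; the
default mix 24/68 ≈ 35 % jaundiced mirrors a realistic screening imbalance.
The default `jaundice_blue_drop` of 60 intensity units yields ≈ 30 units of
blue-channel separation between class mean colors. Everything is
reproducible bit-exactly from a seed.

What the generator deliberately does **not** model: skin-tone/melanin
variation, specular highlights, pose, occlusion (beyond a binary flag that
blanks the face, for error-path tests), shadows that vary across the face
(the illumination cast is global and diagonal), or landmark-detector error
(landmarks are ground truth). Passing tests therefore validate the
*pipeline's* correctness and statistical calibration, not clinical accuracy
on real neonates — the default cohorts are nearly separable by construction.

## White balancing

`[R,G,B] = diag(255/R′w, 255/G′w, 255/B′w)·[R′,G′,B′]`, with the patch mean
measured on the uncalibrated image. Output is rounded half-up and clipped to
[0, 255]; the product is computed as `(255·c)/mean` so exact halves stay
exact in floating point. Consequences tested as invariants: the white patch
maps to exactly (255,255,255), recalibration is idempotent, the transform is
monotone per channel, and saturated pixels are unrecoverable (no inpainting).
A zero channel mean raises rather than dividing by zero. Card localization is
taken as input (sidecar JSON or user annotation) — detecting a card in an
unconstrained photo is a separate problem this package does not solve.

## ROI rules

Forehead: columns spanning the eyebrow points 18–25, rows
`[y_min − 140, y_min − 20)` where `y_min` is the global minimum eyebrow row
— i.e. a 120-px-tall box starting 20 px above the brows, clipped to the
image; a fully clipped box is an error, mirroring how occluded faces should
be excluded rather than silently processed. Sclera: the filled convex hull
of the six eye points (right 36–41, left 42–47); the hull excludes eyelid
skin better than a bounding box. Collinear eye points raise a degenerate-ROI
error.

## Features

12 per region: per-channel means in RGB (0–255), YCbCr (full-range BT.601,
chroma centered at 128), CIELab (sRGB, D65; L 0–100, a/b signed) and HSV
(H in degrees, S/V in [0, 1]). Fixing the colorspace variants is what makes
features bit-reproducible; the named spaces admit several conventions.
Conversions run on real-valued pixels with no intermediate quantization.
Hue is averaged arithmetically like every other channel; that is safe for
skin/sclera hues (well inside 0–120°) and documented as incorrect for reds
straddling the 0°/360° wrap. The *eye* condition concatenates the two eyes
(24 features) rather than averaging them; *fusion* is skin‖left‖right (36).

## Classifiers

Hyperparameters are fixed, not searched: MLP 2×200 relu, Adam, batch 32, 50
epochs; SVM RBF C=1000 γ=0.7; CART gini unlimited depth; RF 100 trees. Two
backend notes, both deliberate:

- features are standardized (training-fold statistics) before SVM and MLP;
  an RBF kernel with γ=0.7 on raw 0–255 scales would zero out every
  off-diagonal kernel entry. Trees are scale-invariant and get raw features;
- the MLP configuration specifies dropout 0.5, which the sklearn backend
  does not implement; its default L2 penalty stands in. SVM probabilities
  come from an explicit Platt-style link — a logistic sigmoid fitted to the
  training margins — because libsvm's internal cross-validated estimates are
  not guaranteed monotone in the decision value on small or separable data,
  and the monotone-probability contract is part of the tested surface.

The transfer-learning branch is represented by its architecture contract
(224×224×3 input → convolutional backbone → 7×7×512 → global average
pooling → 512 → three dense layers with two 0.5-dropout layers → softmax)
and by its input pipeline: ROI crops composited on a fixed canvas (forehead
alone; two sclera crops side by side; or forehead above both scleras),
resized, with the minority class replicated under flips, ≤10° rotations and
brightness jitter until classes balance. Gradient training requires a
user-supplied convolutional backend; the package bundles none, so
`train_model` with kind `"deep"` raises.

## Evaluation protocol

Stratified k-fold (default k=5) is split **once per experiment**, shared by
every model and feature set, so per-fold differences are genuinely paired.
SMOTE runs inside each training fold only; oversampling before the split
leaks synthetic near-copies of test subjects into training, and that leaky
variant is kept behind `smote="pre_cv"` purely for protocol comparisons.
SMOTE itself is implemented in-package (the convex-combination contract is
part of the tested surface): each synthetic point is `x + t·(nb − x)` for a
uniform t and a nearest minority neighbor nb, with the neighbor count
reduced automatically for small minorities.

Metrics: accuracy; macro-averaged precision, recall and F1 (macro-recall
equals balanced accuracy; a `binary` switch reports jaundiced-class values
instead); AUC as the tie-aware pairwise probability, computed from
jaundiced-class scores. The paired comparison uses the k-fold
cross-validated paired t-test, `t = p̄√k / s_p` with k−1 df, two-sided, at
α = 0.05 and no multiple-comparison correction. Zero-variance differences
are reported explicitly (t=0, p=1 when means agree; ±∞ with a degenerate
flag otherwise). The corrected-variance (Nadeau–Bengio) test is a known
alternative that accounts for overlapping training sets; it is out of scope
here. The pairwise table covers model pairs within a feature set and
feature-set pairs for a fixed model.

## Problem sizes and numerical choices

Default experiment sizes — 50 scenes for calibration properties, 200-scene
cohorts for end-to-end recovery, 1000 random score pairs for the t-test
oracle and 5000 replicates for its null calibration — were chosen so the
whole suite and the acceptance script each run in well under a minute on one
CPU while keeping Monte-Carlo standard errors small (the null rejection rate
at 5000 replicates has SE ≈ 0.003). Rounding is half-up everywhere an image
is quantized, for cross-platform determinism. All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; derived seeds
stay below 2³¹.

## Known limitations

- Synthetic scenes are cartoons: conclusions about real-photo performance
  require real, IRB-approved data.
- The calibration model is diagonal (von Kries in device RGB); colored or
  spatially varying illumination violates it.
- Arithmetic hue averaging breaks near the red wrap-around.
- The deep branch trains nothing without an external backend.
- The forehead height/offset constants (120/20 px) are absolute pixel
  counts, appropriate for face images at roughly the default scale; very
  low-resolution images clip or degenerate.
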