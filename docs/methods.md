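# Methods

`apicalnet` implements a classical pipeline for detecting apical lesions
on periapical radiographs: frequency-domain sharpening, global
binarization, projection-profile tooth segmentation, database balancing,
and a small convolutional classifier. Because clinical periapical films
are protected material, the package ships a synthetic phantom generator
that reproduces the geometry the pipeline exploits; every stage is
developed and validated against those phantoms and their known ground
truth.

## Synthetic phantoms

A phantom film is a dark background (default intensity 60) carrying 2–5
bright, rounded-top vertical bars (teeth, intensities drawn per tooth
from 160–220 with a mild axial gradient), separated by full-height
low-intensity seams (default width 10 px, intensity 10). An optional
whole-film rotation (bilinear, background-filled) emulates misaligned
acquisitions, and additive Gaussian noise (default sd 5, clipped to
[0, 255]) keeps thresholding nontrivial. A lesion-class tooth carries a
filled ellipse at the root apex whose intensity is reduced by the lesion
contrast (default 90), mimicking the radiolucent area of apical
periodontitis. Ground truth records the inclusive column interval of
each tooth, the centre column of each seam, per-tooth labels, lesion
centres, and the applied rotation (all in the unrotated frame).

Defaults — 192×256 films, side margins 4% of the width, seams ≥ 6 px,
noise sd 5 — were chosen once to resemble the scale of intraoral films
digitised at modest resolution and are deliberately conservative: the
margins stay well inside the cut-line search margin (1/8 of the width),
and seam width comfortably exceeds the ~2 px residual smoothing of the
default sharpening (below).

What the phantoms do **not** model: overlapping or impacted teeth,
crowns/fillings/root canals, bone texture, exposure gradients, scatter,
and the soft, diffuse margins of real lesions. Passing tests therefore
demonstrate that the algorithms are implemented correctly and behave as
designed on well-formed inputs — not that the pipeline reaches clinical
accuracy on real films.

## Sharpening and binarization

The transfer function on the centred frequency rectangle is
`H(u,v) = 1 − exp(−D(u,v)² / (2·D0))` with `D` the Euclidean distance
from the rectangle centre (`D(u,v) = √((u−⌊M/2⌋)² + (v−⌊N/2⌋)²)`); a
`standard_gaussian` convention dividing by `2·D0²` is also available.
Filtering multiplies the centred spectrum by `H` and inverts the
transform; sharpening subtracts the filtered image from the original
(direction configurable), clipping to [0, 255].

An algebraic consequence worth stating: with this construction the
difference image equals a Gaussian low-pass of the original with
frequency sigma `√D0` (literal convention), i.e. a residual spatial blur
of roughly `N/(2π√D0)` px per N-px axis. The default `D0 = 240` keeps
that blur near 2 px on the default films — an order of magnitude below
the seam width — so interdental seams survive binarization. Small `D0`
values (say, ≤ 20) blur seams away entirely and will break segmentation;
the parameter is exposed for experimentation but the default is the
operating point.

The threshold is selected iteratively: `T0 = (Zmax + Zmin)/2`, then
`T_{k+1} = (mean(pixels ≤ T_k) + mean(pixels > T_k))/2` until the update
moves less than ε (default 0.5 intensity units; hard cap 100
iterations; pixels equal to the threshold join the low group — the
boundary rule is arbitrary but must be fixed for determinism). A
constant image is its own threshold. Binarization maps values strictly
above the threshold to 255.

## Tooth cropping

Columns of the binary film are summed; seams binarize to (near) zero,
so cutting at minimum-sum columns separates adjacent teeth. Details
that matter:

- The minimum search excludes `⌈W/8⌉` columns per side, otherwise dark
  film borders always win.
- After binarization whole runs of seam columns tie at zero. The cut
  goes to the middle of the tied run nearest the piece centre
  (remaining ties leftmost). Centering keeps the recursion balanced —
  peeling always at the leftmost seam leaves a left piece of about W/4
  on 4-tooth films, which the quarter-width rule (next) then rejects —
  and the middle of a seam is where a physical cutting line belongs.
- A cut is discarded, and the piece emitted whole, when (a) either
  output would be narrower than 1/4 of that piece's width, or (b) the
  chosen column is not actually dark (sum above 2% of the piece's
  tallest column). Rule (b) encodes the premise that cutting lines lie
  on seams: a bright "minimum" means the piece has no interior seam —
  typically a single tooth whose darkest interior column is the
  radiolucent lesion itself, which must not be cut through.
- Both pieces keep the cut column (inclusive intervals), so adjacent
  crops overlap by exactly one column and the crops tile the film.

Rotation is corrected beforehand by exhaustive search over ±10° in 1°
steps: each candidate rotation is binarized and scored by the minimum
column sum inside the bright content band (deepest valley), with the
widest run at the minimum breaking depth ties — seams are vertical
exactly when the valley is deepest and widest. Scoring inside the
content band is essential: rotation shifts content and otherwise
exposes empty border columns that tie at zero for every large angle.
Ties prefer 0°, then the smaller magnitude, then the negative angle;
since 0° is always a candidate, correction never worsens the valley.

Retouching zeroes all columns outside a band; the pipeline uses the
bright-content band of each crop so residual neighbour-tooth slivers
are masked.

## Database construction

Class balancing equalizes both classes at a target (default 230 per
class): minority classes are augmented round-robin over their originals,
majority classes subsampled without replacement, all seeded. The
augmentation draw applies, per enabled op: horizontal/vertical flips
(p = 0.5 each), rotation ±10°, zoom ±10% (centre crop/pad), translation
±10 px, contrast ±20% about the mean, brightness ±20 intensity units —
mild, label-preserving ranges; the apex stays in frame. Images are
standardized to 200×100 by unconditional bilinear resampling (no
letterboxing), and the 70/30 split takes the first ⌊0.7·N⌋ indices of a
seeded permutation, which on a 460-image database gives exactly 322/138.

Two pipeline orders are exposed. The default splits first and balances
only the training side, so augmented copies of one crop can never
appear on both sides of the split. `order="balance_first"` reproduces
the published arithmetic (balance the whole database to 460, then split
322/138) at the cost of possible augmentation leakage; the end-to-end
acceptance run uses this order because its printed counts are part of
what is being reproduced, and on phantoms the leakage does not change
the conclusion (the classes are separable by construction).

## The classifier

The network is an AlexNet-derived stack fixed at input 200×100×3
(grayscale crops replicated across channels):
conv 11×11/4 pad 5 → 48 maps (50×25) → ReLU → cross-channel LRN
(window 5, α = 1e-4, β = 0.75, k = 2) → max-pool 3×3/2 pad 1 (25×13) →
conv 3×3/2 pad 1 (13×7×48) → ReLU → LRN → max-pool 3×3/1 pad 1
(shape-preserving, 13×7×48) → FC 2184 → ReLU → dropout 0.5 → FC 2184 →
ReLU → dropout 0.5 → FC 2 → softmax. Kernel geometry is the unique
small set reproducing the declared shapes (note both pools need pad 1;
the second pool does not downsample). Every realized shape is asserted
against its declaration at build time.

Layers are implemented directly in numpy (float32, NCHW): convolution
and FC as im2col/BLAS matrix products, pooling as a running max over
kernel offsets with first-max tie routing in the backward pass, LRN with
shifted-slice window sums. The first convolution skips its input
gradient. Gradients were verified against central finite differences on
small configurations.

Training is mini-batch SGD with momentum 0.9, initial learning rate
6e-5, L2 weight decay 1e-4 (weights only; update
`v ← μv − η(∇L + λw)`, `w ← w + v`), mini-batch 128, up to 100 epochs,
optional global-L2-norm gradient clipping (off by default) and optional
validation-loss patience (off by default). Inputs are zero-centred by
the training-set mean image, which is stored with the model. Batches
are drawn from a seeded shuffle each epoch; the final partial batch is
kept so every epoch touches each sample exactly once. A log row
(epoch, iteration, elapsed time, mini-batch accuracy/loss, validation
accuracy/loss) is emitted at iteration 1, every 20 iterations, and at
the end.

Weights initialize with He (fan-in-scaled) Gaussians and zero biases,
seeded. A fixed-sd Gaussian is available per layer (`weight_sd`), but
at this learning rate a small fixed sd (e.g. 0.01) trains far too
slowly from scratch — the recipe was published for fine-tuning a
pretrained backbone, whereas this package always trains from scratch
(no pretrained weights are shipped or downloaded; the build accepts
externally supplied weights through the same save/load seam).

With everything seeded (init, shuffle, dropout) and single-threaded
BLAS, repeated runs are bitwise-reproducible; the determinism checks
compare repeated trainings at 1e-9.

## Problem sizes and acceptance checks

The end-to-end run generates 411 normal / 65 lesion crops, balances to
230/230 (460), splits 322/138, and trains the full network for 100
epochs (~300 iterations at batch 128); on one CPU core this takes a few
minutes and reaches ≥ 90% validation accuracy well before the epoch
cap (typically 100% by mid-training, since the phantom classes are
separable by construction). Oracle checks run at deliberately small
sizes where brute force is exact: the frequency filter is compared to
an explicit per-frequency DFT double loop on 8×8 images (agreement to
1e-8), and the iterative threshold to an exhaustive 256-value integer
scan over histograms of 16×16 images. Segmentation recovery is scored
over 50 seeded phantoms with 2–4 teeth and seams ≥ 6 px; the pipeline
recovers exactly k single-tooth crops in ≥ 95% of them (100% on the
development seeds).

## Known limitations

- The cutting algorithm assumes vertically separable teeth; overlapping
  crowns or contact points without a dark seam cannot be split.
- The quarter-width rule caps the usable teeth count per film at about
  four to five; beyond that, even perfect seams produce pieces the rule
  rejects.
- The residual-blur analysis of the sharpening step ties `D0` to film
  width; films much wider than the default need proportionally larger
  `D0`.
- Phantom realism is intentionally minimal (see above); no claim about
  clinical-film accuracy follows from these tests.
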