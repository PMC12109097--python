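# Methods

This note documents the model implemented by `pemt`, the choices made where
the design was open, and what the synthetic experiments do and do not show.

## The semi-supervised objective

Training minimises, over student weights θ,

```
L_total = L_s + λ(t) · L_u
```

* `L_s = CE + DiceLoss` on the labeled batch. CE is the pixel-mean negative
  log-likelihood (probabilities clipped at 1e−7 before the log); the Dice
  term uses soft probabilities on the foreground channel(s), one ratio per
  image and foreground class, smoothed by 1e−5 in numerator and denominator
  to avoid 0/0 on empty masks, then averaged. Both terms are averaged per
  image and then over the batch.
* `L_u` is the per-pixel channel-mean squared difference between the
  student's softmax output (input noise η₁, dropout active) and the
  teacher's (input noise η₂, dropout off), averaged over the pixels whose
  teacher uncertainty `u` is below the threshold τ(t):
  `Σ 1[u<τ]·d / Σ 1[u<τ]`, defined as 0 when the mask is empty. The teacher
  map enters as a constant: gradients flow only through the student. The
  consistency sum runs over labeled *and* unlabeled images (a config flag
  restricts it to unlabeled only).
* Input noises η₁, η₂ are additive Gaussian draws with σ = 0.1 clipped to
  ±0.2 (both config-exposed), the usual mean-teacher convention.

## Schedules

All schedules are driven by the optimizer iteration t (not epochs):

| quantity | form | default |
|---|---|---|
| consistency weight λ(t) | 0.1·exp(−5(1−t/t_max)²) | scale 0.1 |
| uncertainty threshold τ(t) | (0.75+0.25·e^(−5(1−t/t_max)))·ln 2 | — |
| teacher EMA decay α(t) | min(1−1/t, 0.99) | cap 0.99 |
| learning rate | 0.01 · 0.1^⌊t/2500⌋ | SGD, momentum 0.9, weight decay 1e−4 |

α(1) = 0, so the first teacher update copies the student exactly; before any
update the teacher is initialised as a clone of the student.

## Teacher/student weight coupling

`ema_update` is the plain convex combination. `pema_update` first performs
the EMA with the *unperturbed* current student, then adds
`β · mod(θ*, θ)` to the student; the perturbed student is what the next
gradient step trains. Momentum buffers are not touched by the perturbation.

The element-wise modulus is the *floored* modulus `a − b·⌊a/b⌋` (result sign
follows the divisor, magnitude strictly below |b|), so each weight's
perturbation is proportional to that weight's own magnitude — a "small
weight perturbation" at every scale of the network. Since weights can sit
near zero, divisors with |b| < 1e−8 yield a zero perturbation (the bound
forces a near-zero result there anyway, and a/b would overflow). A scalar
reference loop pins this convention in the tests. β is constant (default
0.001); it does not ramp.

One consequence worth knowing: because the residual's sign follows the
student weight, the perturbation is on average inflationary — it grows
weight magnitudes by roughly a factor (1 + β/2) per step. At β = 0.001 over
a few thousand iterations this is a mild, bounded drift; at β = 0.005 it is
the plausible mechanism for the degradation the β-sweep shows.

## Uncertainty maps

The teacher's predictive uncertainty is estimated from K = 8 stochastic
forward passes (dropout forced on, fresh input noise per pass — a config
flag freezes the noise across passes instead). The passes run as one batched
forward; the per-pixel, per-class mean p̄ of the K softmax outputs feeds:

* `eum(p̄) = −Σ_c p̄_c ln p̄_c` — predictive entropy, in [0, ln C];
* `rum(p̄, υ) = Σ_c p̄_c (1−p̄_c)^(υ−p̄_c)` — the residual-guided map, with
  υ = 2 by default.

Conventions: 0·ln 0 := 0 for the entropy; 0⁰ := 1 for the power (reachable
only when the exponent υ−p̄_c hits 0 at p̄_c ∈ {0,1}), which matches the
continuous limit of (1−p)^(1−p) and is one reason υ = 2 (whose exponent
never vanishes on [0,1]) is the default. Both maps are 0 on one-hot inputs
and peak at the uniform distribution.

A quantitative subtlety the implementation preserves rather than hides: at
υ = 2 and C = 2 the RUM maximum is 2·0.5·0.5^1.5 ≈ 0.354, *below* the
smallest value of the threshold schedule τ(0) ≈ 0.521. Under the default
schedules the RUM-gated mask therefore retains every pixel, and the
RUM-masked variant's trajectory coincides exactly with the unmasked
mean-teacher one (the test suite asserts this bitwise). At υ = 1 the maximum
is ≈ 0.707 > τ and masking activates. The same τ formula is applied to both
EUM and RUM; no RUM-specific rescaling is invented.

## Backbone

Both networks share a tiny functional 2D U-Net: one group-normalised 3x3
conv + ReLU per encoder level, 2x2 average-pool downsampling, a bottleneck
conv, and nearest-upsample + projected-additive-skip + conv decoder levels,
with a 1x1 classification head and channel softmax (default: base width 8,
depth 3, ~40k parameters). Dropout (rate 0.5) sits at the bottleneck and the
deepest decoder level, so Monte-Carlo passes perturb semantic features.
Weights are He-initialised float32; the forward pass runs on the package's
own reverse-mode autodiff core, which is gradient-checked against central
finite differences end to end.

Group normalisation (4 groups, per-channel affine) was chosen over batch
normalisation because batches are small and split labeled/unlabeled, and
because it has no running statistics — training and inference behave
identically and nothing needs transferring between student and teacher.
Normalisation also makes the features insensitive to the overall scale of
the conv weights, which matters for the pEMA: the modulus residual's mild
magnitude inflation (previous section) then perturbs effective *directions*
rather than the output scale. Additive skips (a 1x1 projection of the
upsampled features added to the encoder skip) halve the decoder's
convolution cost relative to channel concatenation at equal width, which is
what keeps full training runs in CPU minutes.

## Training loop

Each iteration draws equal labeled and unlabeled sub-batches (4+4 by
default) from infinite shuffled samplers, augments every image independently
(random multiples of 90° rotation and axis flips, applied jointly to image
and mask), takes one SGD step on the student, then applies the variant's
coupling: none (supervised), EMA (mt / uamt / uamt_rum) or pEMA (pemt), with
the uncertainty mask none / EUM / RUM / RUM respectively. Uncertainty and τ
are recomputed every iteration on the current batch.

Randomness is split into independent named streams (initialisation, data
order, student dropout, η₁, η₂, Monte-Carlo passes) spawned from the run
seed. Variants that share a seed therefore consume identical draws on the
paths they share, which makes the lattice equivalences exact and testable
bitwise: pemt(β=0) ≡ uamt_rum, uamt(τ=∞) ≡ mt, mt(λ≡0) ≡ supervised.

Checkpoints (HDF5) store the config, both weight sets, iteration, momentum
buffers and RNG states; training logs are CSV rows of
(t, lr, λ, τ, supervised, consistency, masked_fraction, total).

## Synthetic data

`generate_sample` renders, deterministically from (seed, index): 1–3
ellipse/annulus foreground structures (an annulus is a myocardium-like ring)
with radii 0.14–0.28 of the image side; 0–3 small bright distractor blobs
(radii 0.03–0.07) that share the foreground intensity but belong to the
background, so intensity alone cannot solve the task; per-sample background
level ~ U(0.1, 0.35) and foreground contrast ~ U(0.25, 0.6); Gaussian
boundary blur (σ 1.5 at the default 64px size); additive Gaussian noise
(σ 0.1); a smooth multiplicative bias field (±20%); and ±20% per-sample
jitter on blur and noise, emulating acquisition variability. Foreground
fraction is kept within (0.02, 0.5) by redrawing structures. A 4-class
"cardiac-like" mode (ring / inner disk / side blob) supports multi-class
tests. Ground truth of the unlabeled pool is stored only in a diagnostics
field that the trainer never reads.

What this generator does *not* emulate: real MRI texture and artefacts, 3D
context, anisotropic spacing, and inter-patient anatomy correlations.
Passing tests show the algorithmic machinery behaves as specified on data
with fuzzy boundaries, class imbalance and appearance variability — not that
the method reaches any particular accuracy on clinical data.

## Evaluation

DSC and JAC on binary masks (both-empty defined as perfect agreement);
surface metrics from 4-connected boundary pixels and Euclidean distance
transforms with pixel spacing applied: HD95 takes each directed distance
list's 95th percentile (linear interpolation) and then the maximum of the
two directions (exact Hausdorff via `percentile=100`); ASD is the
one-directional mean from prediction surface to reference surface. Surface
metrics are undefined for empty masks; such classes are excluded from the
macro averages (NaN if none remain). Multi-class reporting is one-vs-rest
per foreground class, macro-averaged.

## Scaled experiment sizes

The end-to-end experiments in the test suite and `scripts/acceptance.py`
run at 32×32 pixels (boundary blur 0.75, scaled with the image), 100
training images with 5% labeled, batch 4+4, 1000 iterations, three dataset
seeds in the tests and the `--seed`-derived dataset in the script; the
full-label learnability run uses the 64px default spec. These sizes keep a
complete variant-lattice comparison within minutes per run on one CPU core
while preserving the regime of interest (a label-starved baseline that has
not saturated). The lr decay interval stays at the 2500-iteration default,
so the learning rate is constant within these shorter runs.

## Known limitations

* The backbone is 2D; volumes must be processed slice-wise (a NIfTI/HDF5
  path is provided for that).
* The consistency target is a single noisy teacher pass, as the objective
  specifies; reusing the Monte-Carlo mean as the target would reduce its
  variance but changes the objective.
* At desk scale the separation between variants is of the order of a Dice
  point and depends on the sampled dataset's difficulty; claims at clinical
  scale require the real-data path and far longer schedules.
* The RUM/τ interaction described above means υ = 2 disables masking under
  the printed schedules; υ = 1 (or a rescaled τ) is required if active
  RUM-gating is wanted.
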