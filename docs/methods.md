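# Methods

## Registration model

The registrar treats an RGB colposcopy time sequence as three scalar
sequences and aligns each colour channel independently. For a fixed/moving
channel pair (f, m), an encoder–decoder CNN g_θ predicts a dense
displacement field u(p) = (dy, dx) in absolute pixels; the registered
channel is the backward warp m′(p) = m(p + u(p)) computed by bilinear
interpolation inside a differentiable spatial transform layer. Each of the
three branches has the same architecture but its own parameters, so the
channels may move independently; this preserves per-channel appearance at
the cost of possible sub-pixel channel desynchronisation (see
Limitations).

Architecture. The channel widths [16, 32, 32, 32, 32, 32, 32, 16] split
into a four-stage encoder and four-stage decoder. Encoder stages are 3×3
convolutions with stride 2 and leaky-ReLU (slope 0.2); decoder stages are
nearest-neighbour 2× upsampling followed by a 3×3 convolution over the
concatenation with the mirrored encoder activation (the outermost skip is
the 2-channel input itself); a final linear 3×3 convolution emits the
2-channel field at input resolution. Input dimensions must divide 2⁴ = 16;
the loader pads (symmetric, edge-replicate) and records the padding. The
output head is initialised with std 1e-5 and zero bias so an untrained
model predicts (essentially) the identity warp — training starts from "do
nothing" rather than from a random deformation.

The transform class is a free dense deformation, not a parametric
(affine/rigid) model: smoothness is imposed only through the loss. Dense
fields are strictly more expressive than the rigid motions of the phantom,
so phantom recovery is a fair but not trivial test.

## Losses

- Similarity (default `mse`): mean squared intensity difference on [0,1]
  intensities. Selectable `lncc`: the negated mean of the local normalized
  cross-correlation over odd square windows (default 9 px), computed from
  box-filtered moments with an epsilon-stabilised (1e-5) denominator and
  restricted to windows fully inside the image; −1 means perfect local
  correlation. LNCC is the robust choice when illumination varies strongly;
  MSE is the default because the phantom's jitter is mild and MSE is
  cheapest.
- Local spatial variation (smoothness): the mean of squared
  forward-difference gradients of u over both components and both axes.
  It is zero for any constant field, so pure translations are never
  penalised, and quadratic under field scaling.
- Total: Σ_channels [ sim + λ·smooth ], λ = `lambda_smooth`.

λ defaults to 0.1. The weight trades deformation freedom against
regularity: at λ = 1 the field is visibly over-damped on 64×64 phantoms
(pooled mask-overlap improvement ≈ +2%), while λ = 0.1 recovers most of
the imposed rigid motion (≈ +8%) without tearing artifacts; λ = 0.01
behaves similarly to 0.1 but leaves the field rougher. The value is a free
parameter of the package, exposed in `LossConfig`.

## Training scheme

Training is per sequence (misalignment is intra-sequence), unsupervised,
batch size one. The sequence is first expanded by photometric augmentation
(`per_frame_copies` copies per frame; colour shift, contrast, unsharp-mask
sharpening, Gaussian noise — never any spatial transform, so augmented
frames remain geometrically identical to their source). Each epoch walks a
freshly shuffled pool in disjoint (fixed, moving) pairs, reshuffling
within the epoch when the pool is spent, for exactly `steps_per_epoch`
steps; over accumulating epochs every pooled frame is visited in both
roles. The aggregated three-branch loss is backpropagated and parameters
updated with Adam. Everything — augmentation, initialisation, pair
sampling, updates — derives from one seed, making runs bit-reproducible.

Optimiser defaults: Adam, learning rate 1e-4 in the full-scale profile
(420 epochs × 1000 steps, intended for long-edge-1024 clinical frames on
accelerator hardware and never exercised by the tests). The desk profile —
the configuration the tests and the acceptance script actually run — uses
15 epochs × 60 steps at learning rate 2e-3 with one augmentation copy per
frame, sized so one RGB sequence of 17 64×64 frames trains in under a
minute on a single CPU while still recovering most of the phantom's
misalignment. The learning-rate difference reflects problem scale: 900
steps on a 64×64 phantom need larger steps than 420k steps on clinical
data.

The trainer's interface accepts only frames and configuration; ground
truth (transforms, masks) cannot leak into training by construction.

## Numerical engine

The network, warp and losses run on a small reverse-mode autodiff engine
over numpy arrays (`cervreg.nn`): convolution via im2col matrix
multiplication, nearest upsampling, channel concatenation, bilinear
grid-sampling with clamp-to-edge boundaries (gradient flows to both image
and field; the coordinate gradient is masked where sampling is clamped),
box filtering (self-adjoint under zero padding), elementwise arithmetic
and reductions, and Adam. Parameters are float32 for speed; gradient
checks run the same graph in float64 and agree with central finite
differences to ~1e-6 relative (asserted at 1e-3 in the tests). Bilinear
warping is piecewise-linear in the field, so gradient checks probe it away
from integer sampling coordinates where the kernel has kinks.

## Phantom generator

The phantom emulates the structure of a DYSIS-style acquisition: T = 17
same-size RGB frames of a bright elliptical cervix with a darker interior
os on a dark background, whose epithelium (cervix minus os) brightens over
time. The scene is analytic: region membership is an ellipse quadratic
form, edges are blended over a softness scale (default 2 px) with a
logistic profile, and every frame t > 1 evaluates the scene at rigidly
inverse-transformed coordinates (rotation about the image centre plus
translation, drawn uniformly within ±`max_rotation`, ±`max_translation`).
Because frames are rendered analytically rather than resampled, the
recorded transforms and rasterized masks are exact; warping frame t by the
closed-form inverse rigid field recovers frame 1 to within bilinear
interpolation error (mean absolute intensity difference below 0.01 on
noise-free, whitening-free phantoms), which is the oracle the acceptance
tests lean on.

Whitening follows a saturating-exponential profile w(t) = 1 +
r·(1 − e^{−(t−1)/τ}), τ = (T−1)/3, applied as an exponent on the
distance-to-white, I′ = 1 − (1 − I)^{w}: anchored at 1 for t = 1,
monotone, and intensity-bounded by construction. Per-frame photometric
jitter (global gain uniform within ±`illumination_jitter`, per-channel
colour gain within half that) and Gaussian noise (σ = `noise_sigma`)
complete the frame.

Defaults (64×64, cervix semi-axes 22×18 px, os 7×5 px, whitening rate 0.5,
translations ≤ 6 px, rotations ≤ 4°, jitter 0.05, noise 0.01) put the
unregistered mean Dice around 0.85 — comparable misalignment severity, at
desk scale, to the ≈0.79 reported for clinical sequences. No quantitative
description of clinical inter-frame motion exists, so these magnitudes are
chosen as plausible, not fitted.

What the phantom does *not* model: specular highlights, instruments,
occlusion, focus changes, non-rigid tissue deformation (an elastic
perturbation is deliberately left out of the default so oracles stay
exact), or realistic texture. Passing phantom tests therefore demonstrates
that the method recovers known rigid misalignment under photometric
nuisance on smooth-edged anatomy-like scenes; it does not certify clinical
performance.

## Evaluation

Registration quality is scored exactly as in the mask-overlap protocol:
Dice and IoU of each frame's cervix mask against the frame-1 mask, means
taken unweighted over frames 2..T, reported at full precision (the
published per-frame table in `cervreg.benchmark` rounds to 0.891 from the
table but 0.892 in the reported summary — full-precision means keep both
roundings inspectable). Since no learned segmenter is in scope, phantom
masks come from the ground truth transported through the predicted fields
with nearest-neighbour sampling (keeping masks strictly binary), using the
green channel's field by default (configurable via `channel_policy`). The
improvement statistic is 100·(D_reg − D_unreg)/D_unreg.

## Numerical and design choices

- Coordinates are row-major 0-based pixels; fields are (dy, dx) backward
  offsets in absolute pixels; rigid transforms act about the image centre.
- Out-of-bounds warp samples clamp to the border (no zero fill), so
  registered frames never acquire black corners.
- Registered intensities are clipped to [0,1]; frame 1 passes through
  byte-identical.
- Grayscale mode converts with BT.601 luminance (0.299, 0.587, 0.114).
- Degenerate inputs are rejected loudly: fewer than 2 frames, mixed frame
  sizes, dimensions not divisible by 16 (unpadded), non-finite fields or
  losses, empty reference masks, both-empty mask pairs.
- LNCC on constant windows is finite by the epsilon-stabilised denominator.

## Limitations

- Per-channel fields can disagree by design; mask transport must choose
  one field (default green). No cross-channel consistency is enforced or
  measured.
- The numpy engine is single-threaded and CPU-bound; the full-scale
  profile is provided for completeness but is impractical without porting
  the branch to an accelerator framework.
- The dense field has no diffeomorphic guarantee; large λ avoids folding
  in practice but nothing forbids it.
- Phantom realism is deliberately limited (see above); clinical claims
  require clinical data, which is restricted-access.
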