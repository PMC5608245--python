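# Methods

This note records the models, conventions, defaults, and design choices
behind `petsae`, and what the synthetic experiments do and do not show.

## Measurement model and simulator

Emission data follow the standard Poisson model: the counts in detector
bin *q* of frame *i* are `y_iq ~ Poisson(ȳ_iq)` with
`ȳ_iq = Σ_p G_qp x_ip`, where `x_i` is the activity image of frame *i*
and `G` is the system matrix.  The simulator realizes `G` as an exact
parallel-beam line-integral operator: entry (q, p) is the intersection
length of ray *q* with pixel *p*, computed by sorted grid-crossing
traversal.  Rays cover [0, π) uniformly in angle; radial offsets are
centered on the grid with spacing `max(rows, cols)/n_radial_bins`, so the
default geometry (bins = grid side) sends rays through pixel centers.
Pixel convention: unit pixels, origin at the image corner, pixel (r, c)
covering [r, r+1) × [c, c+1); offsets are measured from the grid center;
the field of view is the inscribed circle.  A ray lying exactly on a
shared pixel edge is attributed to the pixel on its positive side; the
default geometries never produce such rays.

No randoms, attenuation, scatter, or normalization effects are simulated,
so the Poisson model above holds exactly for the generated data.
Counting rate is interpreted as the total expected events of the whole
scan (a per-frame option exists): the noiseless sinogram series is
rescaled so its grand total equals the budget, and each bin is then
sampled independently.  The applied scale factor is retained so ground
truth can be expressed in the same count units as the reconstructions.

## Phantoms

A dynamic phantom is piecewise constant over labeled regions; each
region's value over time follows a configurable time-activity curve
(TAC): constant, mono-exponential washout `A e^{−λt}`, or gamma-variate
uptake `A t^α e^{−βt}` (peak-normalized to A).  TACs are evaluated at
frame midpoints, so the region mean at frame *i* equals the TAC value
exactly — phantoms double as exact ground truth.  Three geometry
families cover different patch statistics: scattered disjoint disks,
a brain-like rim/interior/blob layout, and a torso-like ellipse with
offset organs.  Default kinetics are seeded draws mixing washout
(λ ∈ [0.03, 0.12] s⁻¹) and uptake (α ∈ [1.5, 3], β ∈ [0.2, 0.5] s⁻¹)
with amplitudes in [2, 8]; frames default to uniform 1 s duration.
These synthetic objects reproduce the smooth-region / sharp-edge
structure that the patch model feeds on, but not anatomical texture,
partial-volume effects, or scanner physics — conclusions from them are
about the mechanism, not about clinical image quality.

## MLEM

Per frame, the classical multiplicative update

    x ← (x / s) ⊙ Gᵀ(y ⊘ Gx),   s = Gᵀ1,

run for a fixed 50 iterations by default (a relative-likelihood stopping
rule is available).  Initialization is the uniform image `Σy / Σs`,
strictly positive as the multiplicative form requires.  Bins with zero
forward projection are excluded from the ratio; voxels with zero
sensitivity are held at zero with a warning.  Each iteration provably
does not decrease the Poisson log-likelihood
`Σ_q y_q log ȳ_q − ȳ_q`, and under strictly positive sensitivity
preserves total counts; both properties are asserted by the test suite.

## Sparse autoencoder and its objective

Encoder `h = σ(W_e^T x + b_e)`, decoder `o = σ(W_d^T h + b_d)`, objective
on a batch

    (1/M) Σ_m ‖o_m − x_m‖² + α₁(‖W_e‖_F + ‖W_d‖_F) + α₂ KL(ρ̂ ‖ ρ₀),

with `ρ̂_j` the batch-mean activation of hidden unit *j* and the
Bernoulli KL summed over units (natural log; ρ̂ clipped to
(10⁻⁸, 1−10⁻⁸)).  Notes on conventions:

- The weight penalty uses the *unsquared* Frobenius norm by default, with
  gradient `W/‖W‖_F` (zero at W = 0); a squared variant is a config
  switch.  The RBM pretraining penalty is the squared norm.
- "Sparsity of the weight matrix" is realized as the batch-mean hidden
  activation — the only reading that makes the KL term trainable.
- Gradients are exact analytic backpropagation including the KL term's
  dependence on the encoder through ρ̂; they match central finite
  differences to better than 10⁻⁶ relative for every penalty
  combination (asserted over the full parameter space of a 12→8→12 net).

Defaults: α₁ = 10⁻⁴, α₂ = 0.1, ρ₀ = 0.05.  These are package choices;
larger α₂ visibly drives mean activations toward ρ₀ (a dedicated test
trains with α₂ = 1 and checks the mechanism).  Optimization is
mini-batch gradient descent with classical momentum 0.9; with small
datasets a heavy KL penalty can saturate all hidden units near zero,
from which backpropagation cannot recover — the fine-tuning stage
therefore matters most when pretraining data are scarce.

## RBM initialization

Each template's weights start from a Bernoulli RBM trained by CD-1 on
the template's input batch, treating [0, 1] values as Bernoulli
probabilities.  Energy uses the standard sign `E = −b·v − c·h − vᵀWh`,
making the factorized conditionals come out as logistic units; the
conditionals are verified against Bayes-rule computation on the
enumerated joint, and CD-1 is verified to increase an exactly enumerated
data likelihood on tiny machines.  One CD step samples binary hiddens in
the positive phase, reconstructs visibles mean-field, and uses hidden
probabilities at both ends of the gradient (the low-variance common
variant).  The mapping to the autoencoder is encoder ← (W, c),
decoder ← (Wᵀ, b), untied thereafter.

## Stacking, fine-tuning, patch sweep

Training rows concatenate the N = 3 window patches (frames i−1, i, i+1;
edge frames replicated at sequence boundaries) in temporal order,
row-major within a patch.  Inputs and labels share one affine
normalization to [0, 1]; in the pipeline its upper point is the maximum
of the ground truth and the 99.5th percentile of the MLEM images, so
isolated MLEM noise spikes do not compress the useful dynamic range
(spiked inputs clip at 1).  The stack is pretrained greedily, the
intermediate decoders are discarded, and a sigmoid output layer
(h_s → l·k) is appended whose bias starts at the logit of the mean label.
Fine-tuning is pure mean-squared-error backpropagation through all
layers (an output-layer-only mode exists), momentum 0.9, optional
per-epoch learning-rate decay.  The supervised label is the l×k patch of
the target frame, not the whole image: the sweep estimates one patch per
pixel position, which forces the patch-sized output reading.

Reconstruction sweeps every interior center position, predicts the patch,
de-normalizes, and aggregates.  Two modes:

- `overlap` (default): each pixel averages the predictions of all
  overlapping patches, Gaussian-weighted by the predicted pixel's offset
  from its patch center.  This is the standard overlap-averaging of
  patch-based restoration; averaging ~l·k independent predictions per
  pixel lowers variance without spatially blurring the estimate.
- `center`: the estimate at a position is the Gaussian-weighted average
  of the single predicted patch — one scalar per center.  This reading
  trades bias (it convolves the prediction with the kernel) for
  simplicity; it is kept as the literal per-center variant.

Kernel default σ = (patch side)/4, normalized to sum 1; σ→0 tends to a
delta at the center, σ→∞ to uniform weights.  The border band that no
full patch covers (width ⌊l/2⌋) is filled from the MLEM image of the
target frame, and the result is clipped at zero.

## Evaluation

Three indexes per ROI and frame: peak SNR `20 log₁₀(255/RMSE)` with both
images mapped so the truth maximum is 255 (a literal no-square-root
variant is available), mean relative bias `mean((u−û)/û)`, and
truth-normalized variance `mean(((u−ū)/û)²)` with ū the ROI mean of the
reconstruction.  Pixels with zero truth are excluded from the ratio
forms and their count reported.  The "Total" ROI is the union of all
labeled regions.

## Problem sizes and the headline experiment

The headline comparison trains on 12 simulated dynamic phantom sets and
evaluates on 4 held-out sets (64×64 grid, 9 frames, 5×10⁴ total counts
per scan, middle frame as target, dense stride-1 patch extraction,
147→200→100→49 network, 30 pretraining and 300 fine-tuning epochs at
learning rate 0.3, batch 128).  These sizes run in about seven minutes
on one CPU while leaving the mechanism intact; they are far below a
realistic training campaign (hundreds of simulated sets), so the
absolute metric values are not comparable to scanner studies — only the
MLEM versus MLEM+SAE contrast within the same conditions is meaningful.
At this count level (~1.4 expected events per pixel per frame) the fused
reconstruction typically gains 15–18 dB of Total-ROI SNR over per-frame
MLEM and reduces both bias magnitude and variance; a small residual
negative bias remains in hot regions, the familiar shrinkage of
minimum-MSE denoisers at extreme noise.  The counting-rate sweep
(5×10⁴…10⁶ events) reproduces the expected monotone improvement of
per-frame MLEM with dose.

## Numerical and degenerate-input conventions

- All randomness flows from one master seed through named substreams
  (phantom/i, poisson/i, pretrain, finetune); identical configs give
  bit-identical runs, and run directories store a config manifest.
- Sigmoids are evaluated in the numerically stable split form; the RBM
  enumeration oracle uses log-sum-exp.
- All-zero sinogram frames reconstruct to zero images; all-zero label
  maps degenerate to a whole-grid "Total" ROI; empty metric masks are
  skipped with a warning; training aborts with a diagnostic on
  non-finite loss.
- Even patch sides are rejected (no center pixel); the temporal window
  must be odd.

## Known limitations

2-D phantoms only; no scanner physics (randoms/scatter/attenuation,
detector blur, time of flight); the TV baseline of the wider literature
is not implemented; training at realistic corpus sizes is supported by
the same code paths but not exercised by the bundled experiments; the
fused estimate is produced per target frame rather than jointly across
frames.
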