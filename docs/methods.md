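# Methods

## Problem setting

Given one baseline medical image `x0` (a 2D radiograph-like array or a 3D
volume), a set of scalar clinical variables `m0` (categorical and
continuous, possibly missing), and ordinal severity labels `y0..yT` at the
baseline and T future horizons (possibly missing beyond the baseline), the
model predicts the whole trajectory at once as T+1 classification tasks.
The temporal structure lives in the transformer states rather than in a
recurrent scan, so the forecast is a single forward pass.

## Architecture

Three pre-norm transformer encoders cooperate:

* **Radiologist (R).** A small residual CNN turns the image into a grid of
  super-pixel (or super-voxel) feature vectors; each grid cell becomes one
  token of width CX (row-major order, recorded so attention maps can be
  folded back onto the grid).  R encodes `[CLS, s1..sN]`; the mean of its
  N+1 output states feeds a diagnosis head producing the baseline logits
  `f0R`.
* **Context (C).** Every clinical variable is one-hot encoded — continuous
  variables are quantized into 4 equal-width bins between the training-split
  minimum and maximum (half-open bins, closed at the top; out-of-range
  values clipped), and every variable carries one extra slot that encodes
  MISSING, so no imputation is performed.  A per-variable linear→GELU→
  layer-norm encoder maps each one-hot to width CM.  C encodes
  `[CLS, m1..mM]` and exposes only the CLS output `h̄C0` as the context
  vector.
* **General practitioner (P).** By default the context vector is
  concatenated channel-wise onto each of R's N+1 output states (width
  CX+CM); the alternative sequence-wise fusion projects `h̄C0` to CX and
  appends it as one extra token.  K learnable [CLS] tokens are prepended
  (K = T+1 by default, one per horizon; K = 1 routes a single token to all
  horizon heads); the first T+1 output states feed the prediction head(s)
  (layer-norm → linear → GELU → linear), either one head shared across
  horizons (requires equal class counts) or one per horizon.

Each encoder block follows `z = MSA(LN(h)) + h`, `h' = MLP(LN(z)) + z` with
per-layer Q/K/V projections of the block input (the standard pre-norm
vision-transformer convention), learnable positional embeddings, and
truncated-normal (sd 0.02) initialization of CLS/positional embeddings.
The MLP hidden width is `mlp_ratio * C` (default 4).

The diagnosis head of block R is implemented as the feed-forward trunk used
throughout the model (linear → GELU → layer norm at width CX) followed by a
final linear classifier.  Ending the head at the layer norm instead would
constrain the logits to zero mean and fixed norm — for a binary task the
output space degenerates to two points — which makes the L1 consistency
target pathological; the trunk+classifier form avoids this while keeping
the stated layer structure.

## Losses

With `g = exp(f)` and true class `c`, the temperature-scaled cross-entropy
at inverse temperature `τ ∈ (0, 1]` is CE evaluated on `τ·f`.  The reverse
Hölder inequality gives the upper bound implemented as the CLUB loss

    L_CLUB = τ·L_CE + (1 − τ)·log Nc,      τ ∈ [0, 1],

with equality iff τ = 1.  Its gradients are `∂L_CLUB/∂logits =
τ·∂L_CE/∂logits` and `∂L_CLUB/∂τ = L_CE − log Nc`, so each τ acts as a
learnable task weight that trades sharpness against calibration; both
identities are verified by finite differences in the test suite.

Per-task temperatures derive from unconstrained noise parameters σ_t via
`ρ_t = 1/(σ_t² + ε)`, `ρ̃ = softmax(ρ)`, `τ_t = ρ̃_t / max(ρ̃)`.  This keeps
every τ in (0, 1] with max(τ) = 1, prevents the all-equal-one collapse, and
is differentiable end to end (the max uses a subgradient at ties; no
stop-gradient is placed on the maximum).  Defaults: ε = 1e−6 (small enough
not to distort ρ for σ in [0.1, 10]), σ initialized to 1 for every task so
training starts at plain cross-entropy.  A `detach_tau` switch cuts the
gradient path from the loss into σ; because τ does not depend on the model
parameters and CE does not depend on σ, the two gradient identities above
hold either way, so the switch only freezes calibration learning and is
kept as a diagnostic.

The prognosis loss averages the per-task CLUB terms over observed targets
(indicator mask; the baseline target is always observed), per sample, then
over the samples with at least one observed target; a batch with none is an
error.  The consistency loss is the L1 distance between the two diagnosis
logit vectors `‖f0R − f0‖₁`, batch-averaged, applied to every sample
including those with masked follow-ups.  The total objective is
`L = L_prog + λ·L_cons` with λ = 0.5 by default.

## Synthetic cohorts

The generator produces the statistical structure the model assumes, so the
whole pipeline is testable without clinical data:

* **Images.** Two bright horizontal bands on a dark background; the
  inter-band gap shrinks strictly with the severity grade (mimicking
  joint-space narrowing), grades ≥ 2 add small bright blobs in the outer
  column thirds (mimicking osteophytes; the central third stays clean so
  the gap remains measurable), plus per-subject vertical jitter and
  optional Gaussian noise.  3D volumes extrude the same pattern along
  depth.  Rendering is deterministic given (severity, morphology seed,
  noise sd, size).
* **Trajectories.** A Markov chain over ordinal grades advancing one grade
  per step with a per-subject rate drawn from a configurable interval,
  absorbing at the top grade; `progressive=True` (default) forbids
  regression, otherwise the state may regress with probability 0.2·rate.
* **Covariates.** Two categorical (sex, injury history) and two continuous
  (age, body-mass index); BMI shifts the progression rate by
  `covariate_effect·(bmi_std − 0.5)`, so exactly one clinical variable is
  informative about progression and the fusion is ablatable.
* **Missingness.** Follow-up targets and covariates are masked
  independently at configurable rates; the baseline target is never masked,
  matching the training regime in which the current diagnosis is always
  supervised.

What the generator does **not** emulate: realistic radiographic texture and
anatomy, acquisition/site effects, label noise in the grading itself,
correlated (informative) missingness, and time-varying covariates.  Passing
tests therefore demonstrate that the architecture, losses, and evaluation
machinery behave as specified and that the model can recover a planted
multimodal signal — not clinical-grade performance on real cohorts.

## Training and evaluation

Adam (default lr 1e−4, matching the regime used for full-size imaging
backbones; the desk-scale reference experiment uses 1e−3, appropriate for
its width-32 model and 450 training subjects), batch size 32, no early
stopping (the checkpoint is the last epoch), all arithmetic in float64.
Cross-validation splits group by subject ID so augmented entries of one
subject never straddle a fold.  Evaluation computes balanced accuracy
(mean per-class recall over classes present in the labels), ECE
(10 equal-width confidence bins over (0, 1] by default), and Hand–Till
one-vs-one multiclass AUROC per horizon on observed targets only, then
averages over configurable horizon windows; class pairs with an absent
class are skipped with a warning.  An `exclude_top_baseline` flag drops
subjects already at the top grade at baseline, mirroring the clinical
practice of not forecasting knees that already reached the terminal
outcome.

## Reference experiment and problem sizes

The parameter-recovery experiment (`climat.experiments`) uses 600 subjects,
binary severity, T = 2, noiseless 64×64 images, one informative covariate,
width-32 model with block depths 2/2/2, K = T+1, common head, channel-wise
fusion, CLUB with λ = 0.5, 30 epochs, evaluated on a held-out quarter of
the subjects and averaged over 3 seeds.  These sizes keep a full
reproduction (tests plus acceptance script) in the minutes range on one CPU
core while leaving the recovered signal unambiguous: held-out horizon-0
balanced accuracy is essentially perfect and every horizon clearly beats a
permuted-label control.

## Design choices where the design was open

* **K = 1 routing:** the single CLS output feeds all T+1 heads.
* **Attention readout:** last-layer attention rows of the relevant CLS
  token, arithmetic mean over heads, renormalized over the token subset of
  one modality (CLS and cross-modal positions excluded) so maps are
  comparable across K.
* **Quantization ranges** come from the training split only and are stored
  in the fitted schema.
* **Out-of-range continuous values** are clipped into [vmin, vmax].
* **R/C depths** default to 2 each; P defaults to depth 4 (the depth its
  ablation favours), with 2 used in the desk-scale experiment.
* **Common vs separate heads:** a shared head requires equal class counts
  at every horizon; configurations violating this fail validation rather
  than silently padding classes.

## Known limitations

* Attention weights are a visualization, not a measure of importance: on
  small variable sets the context block extracts the informative covariate
  through its value path while keeping near-uniform attention, so the test
  suite measures covariate reliance by occlusion (masking a variable to
  MISSING at evaluation) instead of by attention mass.
* Backbones are randomly initialized and small; there is no pretraining or
  transfer, so absolute performance on realistic images is out of scope.
* The consistency term couples two heads trained at very different signal
  strengths; large λ can slow early training (visible in the loss logs as
  a consistency-dominated phase).
* Efficient-attention variants, GPU execution, and multi-image fusion are
  not implemented.
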