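# Methods

`cardiograph` models a patient's multimodal cardiovascular record — a
time-indexed sequence of physiological state vectors plus discrete
clinical events and intervention actions — as a typed temporal graph,
learns latent trajectories with a graph attention encoder and
bidirectional recurrent fusion, and shapes those trajectories with a
family of alignment and regularization objectives. This note documents
the model, the numerical choices, and the synthetic study conditions the
test suite runs under.

## Trajectory representation and graph construction

A trajectory holds strictly increasing timestamps (seconds), one state
vector `x_t ∈ R^d` per timestamp, and timestamped event/action records
with their own feature vectors and type labels. The graph places one node
per record, typed `state` / `event` / `action`, and three edge families:

* **Temporal backbone.** Consecutive state nodes are always connected by a
  bidirected pair, regardless of any window, so the graph is never
  disconnected in time and every state node has at least one neighbor.
* **Co-occurrence edges.** Any two nodes within `window` seconds are
  connected bidirectionally. Events and actions connect to each other by
  the same rule as to states.
* **Causal-prior edges.** A rule table (source kind/label pattern →
  destination kind/label pattern, maximum lag, weight) adds *directed*
  edges whenever a matching pair occurs within the lag, weighted
  `w · exp(-Δt / max_lag)` to encode pharmacodynamic delay. Labels match
  with shell-style wildcards. When a causal edge coincides with an existing
  temporal edge, the causal provenance wins (it carries strictly more
  information). Expert review of subgraphs is out of scope; the rule table
  is the machine-checkable stand-in for guideline knowledge.

Stored edge weights are used for provenance and filtering only; message
passing uses learned attention. `filter_edges` drops edges whose relevance
score falls below a threshold but never removes the backbone, and is
idempotent at a fixed threshold.

## Encoder

Node kind dispatches to one of three two-layer MLPs (tanh hidden layer,
hidden width D, Xavier-uniform init from a mandatory seed) mapping raw
features to `R^D`. Propagation layer `l` updates each node with neighbors
weighted by a softmax over its in-neighborhood of

    score(u→v) = −λ · |t_v − t_u| · ψᵀ[h_u ‖ h_v],

i.e. temporal decay and learned similarity couple multiplicatively inside
one exponent. This is implemented exactly as stated, including the
consequence that a *negative* similarity score increases the weight of
temporally distant neighbors; a `clamp_similarity` flag (default off)
clamps the similarity factor to be nonnegative for users who prefer the
strictly-decaying reading. Nodes with no in-neighbors keep their previous
embedding (the update rule is undefined for an empty neighborhood). The
activation defaults to tanh and is configurable.

Per-node embeddings are averaged over layers 1..L, and each state's fused
embedding adds a sigmoid-gated sum over all *strictly preceding*
event/action nodes (whether or not they are graph-connected to it). The
counterfactual simulation operator

    S(h, u, Δt) = h + η · exp(−λ_sim Δt) · tanh(W_s [h‖u] + b_s)

bounds the intervention effect by `η·exp(−λ_sim Δt)` in every coordinate,
so effects decay monotonically with elapsed time. Counterfactual states
are produced by applying `S` to the fused embedding at the intervention
time and re-running bi-temporal fusion with that single time step
replaced, holding all others fixed.

## Bi-temporal fusion and latent geometry

A learned query attention pool gives one trajectory-level vector; forward
and backward GRUs (standard update/reset/candidate gates, zero initial
state) give per-step contexts that are linearly fused and added back to
the fused embedding to yield the final state `s_t`. The latent-geometry
constraint — latent distance between two times should match the observed
physiological path length between them within a tolerance ε — is relaxed
to a squared hinge penalty (hard constraints are incompatible with
gradient training). Observed change is the discrete path length
`Σ ‖x_{i+1} − x_i‖₂` over samples in the window, a piecewise-linear
quadrature of `∫‖dx/dt‖ dt` that telescopes exactly on linear segments.
Constrained pairs are all consecutive pairs plus a seeded handful of
random non-adjacent pairs (default 4). A learnable positive scale on the
observed change is available (flag, default fixed at 1) because latent
and physical units need not agree. Multi-resolution consistency — named in
the source method but never given a formula — is realized by evaluating
the geometry penalty and arc-length term on the full sequence and on
strided subsequences (strides 1, 2, 4) with equal weights; this is an
interpretation, and is documented as such.

## Alignment objectives

* **Cross-patient alignment** compares two patients' latent sequences
  pointwise after linear interpolation onto a common 32-point
  normalized-time grid (the raw sum is undefined for different sampling).
  The interpolation is a constant matrix multiply, so gradients flow.
* **Soft alignment** uses a monotone nearest-normalized-time index map by
  default; learned warping (soft-DTW) is out of scope.
* **Clinical-prior loss** projects latent states through a learnable
  affine map and penalizes squared deviation from supplied prior targets;
  on synthetic data the noise-free generative skeleton serves as target.
* **Stage statistics** use contiguous equal-size segments (remainder to
  the last), population-normalized covariance; stage separation is
  `Σ exp(−‖μ_i − μ_j‖²)` and anchor separation is `Σ 1/(‖c_i − c_j‖² + ε)`
  — the two deliberately different functional forms are kept as printed.
* **Intervention orientation** compares the counterfactual-minus-factual
  latent effect to a registered expected-response field; the default field
  is `A · ‖u‖ · exp(−Δt/τ)` with a per-label fixed unit direction and
  τ = 2 s. Fields are structural priors, not learned.
* **Graph smoothness** is the Laplacian quadratic form of the undirected
  unit-weight support (equal to the explicit edge sum); a weighted variant
  sits behind a flag.

## Training

All learnable pieces — encoder MLPs and attention, GRUs, fusion, forecast
head, prior projection, event anchors, simulation operator — are trained
jointly with Adam (default lr 1e-3) on a weighted sum: prediction weight
1.0, every structural term 0.1 by default, scheduled by a piecewise-
constant curriculum (default: prediction-only before epoch 5, then full
weights; the last schedule entry with `epoch_start ≤ epoch` applies,
closed left endpoint). Inside the trainer every structural term is
averaged over its own constraint set (per finite-difference step, per
pair, per edge, per event) so the weights act on comparable, intensive
scales; the standalone loss functions return the unnormalized sums as
defined.

Forecasting defaults to a residual parameterization
`x̂_{t+h} = x_t + readout(s_t)` with a zero-initialized readout: the model
starts exactly at the persistence forecast and learns only the correction.
An `absolute` mode (`x̂ = readout(s_t)`) is available. MSE supervision is
the default; L1 is available, as is an optional Gaussian per-step loss
mask centered on a high-risk time (off by default).

The structural subsample (alignment pairs, geometry pairs, the
counterfactual-intervention subset, default 4 per optimizer step) is
drawn from a generator seeded by (run seed, batch index) only, so the
optimized objective is the same deterministic function at every epoch and
two runs with the same config and seed produce bit-identical loss
histories in the default single-threaded mode. A non-finite loss aborts
with the name of the offending component. Anomaly classification for
evaluation thresholds the forecast-residual norm (the method itself
defines no classification target); accuracy/recall/F1 come from
scikit-learn, RMSE from the continuous forecasts.

All differentiable computation runs on the package's own reverse-mode
autodiff core (`cardiograph.autodiff`): dense float64 tensors, a small
vectorized primitive set (including gather and segment-sum, which keep
graph attention O(edges) on the tape), and Adam. Gradients of every loss
term are verified against central differences in the test suite.

### Identifiability of the simulation operator

In `S`, the amplitude η and the saturation level of the tanh term enter
as a product, and the generative response is state-independent, so η
alone is not identifiable from responses. The recovery routine therefore
reports the *effective amplitude* `η_eff = η · mean‖tanh(W_s[h‖u]+b_s)‖₂`
together with the decay λ_sim. The synthetic kernel's direction is
unit-norm by construction, so η_eff estimates the kernel amplitude
directly.

## Synthetic study conditions

The generator is first-class, tested code and defines the conditions every
experiment runs under. Defaults: 50 patients × 100 steps at a 5 s sampling
interval, d = 6 channels (indices: 0 heart-rate proxy, 1 HRV proxy,
2 systolic-BP proxy, 3 sympathetic-tone proxy, rest generic). Dynamics are
a stable VAR(1): channel pairs (0,2) and (1,3) form damped 2×2 rotation
blocks (spectral radius 0.9, angle 0.35 rad — a baroreflex-like
oscillation with period ≈ 18 samples ≈ 90 s), remaining channels decay
geometrically, plus a small random coupling. Per-step Gaussian variability
(sd 0.05) lives in the transition — heart-rate variability is intrinsic
noise, not measurement error — and the noise-free skeleton of the same
recursion is retained as ground truth and prior target. Events fire
per-step with label-specific rates (default two labels at 0.02);
interventions (default one label at 0.015) inject the additive response
`η* exp(−λ* Δt) · direction` (defaults η* = 0.8, λ* = 0.5, unit direction)
into all subsequent states — deliberately the same amplitude-decay form as
the simulation operator, which makes parameter recovery well-posed.
Anomaly labels are a fixed threshold (0.25 ≈ two stationary standard
deviations) on channel 0 and are exactly re-derivable from the emitted
states. Patients alternate between a `typical` and an `asd_like`
condition; the latter shrinks HRV-channel variability and shifts the
sympathetic-proxy baseline — a *structural* emulation of reduced HRV with
sympathetic dominance, with no claim of clinical realism. The prior-rule
table links each intervention label to states within three decay time
constants (3/λ*).

What passing tests on this generator do **not** show: robustness to real
ECG/PPG morphology, missingness, nonstationary regimes, label noise, or
model misspecification of the intervention response — the generative
kernel matches the operator's functional form by design.

## Problem sizes and numerical choices

The full training check uses the default cohort (50 × 100, D = 16, L = 2,
20 epochs, batch size 5, 4 counterfactual interventions per step, all
objective terms active from epoch 0 with default weights); it verifies
that the 3-epoch moving average of the total loss is non-increasing over
the first ten epochs and that the final forecast MSE is strictly below
the last-value-carried-forward baseline. Attention softmaxes subtract the
per-neighborhood maximum before exponentiation; sigmoids use the
numerically stable split form; latent distances add 1e-300 under the
square root to avoid an undefined gradient at exactly coincident states;
gradient checks use central differences with step 1e-5 at relative
tolerance 1e-3. Checkpoints are versioned JSON holding every tensor plus
the config hash.

## Known limitations

* The encoder is bidirectional in time (co-occurrence edges and the
  backward GRU see the future), so `s_t` is a smoothing representation;
  forecasts are in-cohort reconstructions, not causal out-of-sample
  predictions.
* Cross-patient pairing uses cohort condition labels; without labels all
  patients form one group.
* Minibatch mode changes pair subsampling with batch composition;
  reproducibility is exact for a fixed batch size only.
* The attention exponent follows the printed multiplicative coupling; see
  `clamp_similarity` above for the alternative reading.
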