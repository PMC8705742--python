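# Methods

This note documents the models, algorithms and design choices behind
gaitkit: what each pipeline stage computes, which parameters matter and
why their defaults are what they are, what the synthetic benchmark does
and does not emulate, and the numerical decisions that make results
reproducible on one CPU.

## Data model

A tracklet is a contiguous, uniformly sampled sequence of COCO-17
skeletons of one tracked person, stored as a `(T, 17, 3)` array of
(x, y, confidence). Image coordinates are y-down pixels until
normalization; frame `k` occurs at time `k/fps` with 0-based indices.
Temporal resampling (`resample_tracklet`) interpolates trajectories
linearly at the new frame instants, clamping the tail to the final frame
so that resampling to double rate and back is an identity at the original
knots. Confidences are interpolated like coordinates and clamped to
[0, 1] — the simplest monotone choice.

## Curation filters

Four heuristics separate usable walking sequences from pose-estimation
failures and non-walkers. They run in a fixed order (length → mean
confidence → feet visibility → velocity) and each rejection is attributed
to the first failing stage, which makes reports reproducible and
additive: survivors + Σ rejections = input size always.

| filter | default | meaning |
|---|---|---|
| `min_length` | 54 frames | ≈ two full gait cycles at 24 fps |
| `max_length` | 1000 frames | very long tracks are usually loiterers; no principled cutoff exists, so it is configurable |
| `min_mean_confidence` | 0.60 (strict >) | mean over all frames and all 17 joints |
| `feet_conf_threshold` / `max_consecutive_low_feet` | 0.50 / 3 frames | per frame the feet confidence is min(left ankle, right ankle) — *both* feet must be visible; short occlusions are tolerated |
| `min_mean_velocity` | 0.01 units/frame | mean frame-to-frame displacement of ankles and knees, computed on *normalized* coordinates |

Two readings of the velocity rule are config-exposed: whether knees
contribute (`velocity_use_knees`, default on, since leg motion — feet and
knees — is what distinguishes walking) and the threshold itself. The
pipeline order is normalize → filter, so the unitless 0.01 threshold
applies to normalized displacements.

## Normalization

Per frame, every joint is zero-centered at the pelvis (hip midpoint) and
scaled per axis: x by the shoulder width |x_R.shoulder − x_L.shoulder|, y
by the torso length |y_neck − y_pelvis| (neck = shoulder midpoint; COCO-17
has neither pelvis nor neck, and the midpoint construction is the only one
consistent with the scaling identities). Denominators are per frame, not
per tracklet. The transform is idempotent and invariant under translation
and uniform scaling of the input; after it, the pelvis is exactly the
origin and shoulder width and torso length are exactly 1 — no absolute
position or stature information survives, which is the anonymization
property. Frames whose shoulder width or torso length falls below 1e-6
source units are degenerate; the default policy rejects the whole
tracklet, since per-frame scale factors from collapsed skeletons corrupt
the sequence.

## Augmentation

Contrastive training needs multiple views of the same walk. Each view is
produced by, in order: a pace change (linear time resampling by a factor
drawn from {0.25, 0.5, 0.75, 1, 1.25, 1.5, 1.75, 2}), a random contiguous
54-frame crop (sequences shorter than the crop are tiled from the start),
then independent draws of squeeze (x-scaling), mirror (x → −x with
left/right joint relabeling), temporal flip (reversal), and joint/frame
dropout (zeroing, never deletion, so the tensor shape stays `(3, 17, 54)`).
Pace precedes cropping so the emitted length is always exact. "Flip" and
"mirror" denote distinct transforms — temporal reversal and horizontal
reflection respectively — the conventional split. Dropout rates and the
squeeze range have no canonical values and are config-exposed
(defaults 0.1 and [0.8, 1.2]).

## Encoder

A spatio-temporal graph-convolutional network over the COCO skeleton
graph. The spatial operator is Λ^{−1/2}((A+I)⊗M)Λ^{−1/2} with A the
skeleton adjacency, I self-loops, Λ the degree matrix of A+I, and M a
learnable edge-importance mask initialized to ones (one mask per block,
elementwise, unconstrained). With M ≡ 1 the operator is the standard
symmetric normalization: symmetric, spectral radius ≤ 1. Each block
applies the spatial operator, a 1×Γ temporal convolution (whose channel
mixing is the graph layer's weight matrix), batch normalization, a
residual connection (1×1 strided convolution when shapes change), and a
ReLU. Statistics pooling over joints and frames (per-channel mean
concatenated with standard deviation — a plain mean cancels the
oscillatory components that carry gait amplitude; `pooling: "mean"`
restores the plain average) feeds a projection head of the standard
Linear → BatchNorm → ReLU → Linear form; embeddings are L2-normalized to
the unit sphere. The head's batch normalization is load-bearing at small
scale: without it a batch of near-identical skeleton inputs can share a
single active hidden unit, and with a zero output bias every normalized
embedding then collapses onto one point, a fixed point with exactly zero
gradient. Input channels are (x, y, confidence); a config flag drops
confidence.

Default block widths (64, 64, 64, 128, 128, 256, 256) with Γ = 9 follow
the original recipe for this architecture family; the experiments use
`EncoderConfig.small()` — three blocks (16, 32, 32), strides (1, 2, 2),
Γ = 5, 32-dimensional embeddings — which trains in minutes on one CPU.
There is no classification head, so the parameter count is independent of
how many tracklet or identity labels the training set carries.

### NumPy autodiff

The encoder and loss are built on a small reverse-mode automatic
differentiation core (`gaitkit.autodiff`): broadcast arithmetic, matmul,
ReLU/exp/log/sqrt, axis reductions, a skeleton graph convolution and the
1×Γ temporal convolution, plus an Adam optimizer with per-parameter
learning rates. All computation is float64; gradients are verified against
central finite differences in the test suite. Batch normalization is
composed from these primitives (batch statistics during training, running
averages at inference), so its gradients need no special casing.

## Contrastive training

The supervised contrastive loss over a multiviewed batch of 2N unit
embeddings z with labels ỹ:

L = mean_i [ −1/|P(i)| Σ_{p∈P(i)} log( exp(z_i·z_p/τ) / Σ_{a≠i} exp(z_i·z_a/τ) ) ]

where P(i) are same-label indices other than i. The log-sum-exp is
max-shifted with the shift zeroed on excluded entries, so the excluded
self-similarity (the largest entry at small τ) cannot overflow. Every
anchor must have ≥ 1 positive; a batch violating this is a construction
bug and raises. Useful analytic anchors: all-identical embeddings give
exactly log(2N−1) at any τ; a solved batch (positives coincident,
negatives orthogonal) gives ≤ (2N−2)·e^{−1/τ}, numerically 0 at τ = 0.01.

Pretraining uses tracklet ids as labels, N = 16 sources per batch with two
crops each, Adam at 1e-3 (3e-3 in the synthetic experiments), and a
constant learning-rate schedule by default — with few steps per epoch the
late low-rate phase of cosine decay measurably hurt final retrieval, so
cosine is available but not forced. τ defaults to 0.01; smaller
temperatures sharpen hard-negative weighting.

Fine-tuning reuses the same objective with identity labels on a
per-identity random fraction of runs (round(fraction·runs), minimum 1 —
at 10% of 12 runs that is one walk per person), with layer-wise learning
rates: the projection head at the base rate and each block group below it
decayed by 0.5 per level. Five reseeded repetitions are averaged wherever
run subsampling introduces randomness.

## Evaluation

Recognition is cosine nearest-neighbor retrieval (dot product on the unit
sphere), ties broken to the lowest gallery index for determinism. The
cross-view protocol scores, for each angle θ, the probes at θ against a
gallery of the evaluation identities at all other angles, and averages
over angles; train and evaluation identity sets are disjoint and a sample
is never in both roles. On label-shuffled embeddings the protocol sits at
the 1/#identities chance line. For stability, the experiment harnesses
embed each tracklet as the renormalized mean over four evenly spaced
deterministic crops, each rendered at three squeeze factors
(1.0, 0.65, 0.35) and mirrored — averaging over the augmentation orbit
marginalizes the viewpoint-dependent x-scale out of the embedding and is
the single most effective stabilizer of cross-view retrieval in these
experiments. The procedure is deterministic and applied identically to
gallery and probe; training is untouched. An optional t-SNE plot colors
embeddings by identity or viewpoint.

## Synthetic gait simulator

The simulator exists to make the pipeline testable end to end, not to be
biomechanically exact. Each identity is a parameter vector: cadence
~ N(0.9, 0.1) strides/s truncated above 0.5; ankle swing amplitude
~ N(0.35, 0.05) and knee ~ N(0.18, 0.04) normalized units; arm
counter-swing ~ N(0.25, 0.05); left/right leg phases π apart plus
N(0, 0.1) jitter; vertical pelvis bounce ~ N(0.05, 0.015) at twice the
cadence; bone lengths (legs, arms, hip width, head) jittered ±5% around a
canonical skeleton with torso ≡ 1 and shoulder width ≡ 1. Joint
trajectories are sinusoids of these parameters; arms counter-swing
against the legs; walking drift translates the whole body (normalization
removes it again).

Viewpoint: joints carry lateral (body-width) and sagittal
(walking-direction) components; the image x is f(θ)·lateral +
sin(θ)·sagittal with f mapping cos θ into [0.35, 1]. A literal cos θ
would collapse the shoulder width at 90°, and with it the normalization
denominator — real side-view 2D poses keep a nonzero apparent shoulder
width, which the floor emulates. The vertical axis is viewpoint-invariant.

Noise: additive Gaussian jitter (σ = 0.01 normalized units) smoothed with
a 9-frame moving average, emulating the temporally correlated jitter of
pose estimators. The window is a designed quantity: white noise of this
magnitude alone has mean frame-to-frame speed ≈ 1.77σ ≈ 0.018, above the
0.01 walking threshold, and normalization further inflates x-noise by
1/f(θ) at side views; a width-k moving average scales successive
differences by √2/k, and k = 9 keeps standing contaminants' measured leg
speed below ~0.0065 while clean walkers stay above ~0.012 — a two-sided
margin around the 0.01 threshold that makes the generator's ground-truth
verdicts exact. Confidences are N(0.85, 0.05) clipped to [0, 1];
"low-confidence" mode inserts a ≥ 4-frame block of ankle confidences in
[0.1, 0.45] (fails feet visibility), "standing" mode zeroes all
oscillation amplitudes (fails the velocity filter).

What passing tests on this simulator show: that curation, normalization,
the encoder, the loss, and the retrieval protocols do what they claim on
data whose ground truth is known exactly, and that identity information
present in kinematics is recoverable across viewpoints. What they do not
show: robustness to real pose-estimator failure modes (identity
switches, limb confusions, crowd occlusion), to non-sinusoidal gait
variability, or to appearance-driven confounds — none of which the
generator emulates.

## Scaled-down experiments

The experiment harnesses (`gaitkit.experiments`) run the recognition
protocols at CPU scale; all sizes are package choices:

* **Identity recovery** — pretrain on an uncooperative-style pool of 160
  walkers with *one tracklet each* (viewpoints round-robin, 200 epochs,
  10-epoch learning-rate warmup, gradient norm clipped at 5), then
  cross-view retrieval on the held-out identity half of a separate
  20-identity × 4-run × 2-viewpoint benchmark (chance 0.10), repeated
  over 3 seeds. Pool size matters twice over: more walkers give more
  negatives per batch and force a finer-grained identity code. The
  experiment encoder widens the embedding to 64 (projector 128): at
  temperature 0.01 the loss stops improving once the pool is separable,
  and a narrow embedding then drops identity-relevant kinematics
  (contrastive feature suppression); the wider code retains more of them.
* **Pretraining benefit** — a fresh 12-identity benchmark; fine-tune the
  recovery checkpoint vs a randomly initialized twin on a 10% run
  fraction (one run per identity) and compare mean cross-view accuracy
  over 5 reseeded repetitions.
* **Corpus-size trend** — pretraining pools of 10%, 50% and 100% of the
  walker pool; epochs scale inversely with the pool fraction (capped at
  4×) so optimization steps are comparable and the comparison isolates
  data diversity; 5 seeds.

The single-run pool structure is not incidental. Tracklet ids are the
contrastive classes, so two runs of the same person in the pretraining
pool are *negatives*: the loss then rewards whatever separates them —
viewpoint, noise realization, phase — which is precisely what cross-view
retrieval penalizes. Measured on this simulator, pretraining on a
multi-run pool caps cross-view rank-1 around 0.5–0.7 regardless of
training length, while the same recipe on a single-run pool of equal size
reaches 1.0. The uncooperative corpus this method is designed for has the
single-appearance structure by construction (each person passes the
camera once), which is why the objective aligns with identity there.

The experiments' augmentation recipe fixes pace at 1 and widens the
squeeze range to [~0, 1.2]: the squeeze must span — and exceed — the
full foreshortening ratio of the viewpoint model, so that matching the
two crops forces representations that survive near-total loss of the x
channel; this is exactly the invariance cross-view transfer needs, and
it is what makes the y-axis kinematics (which no augmentation and no
viewpoint ever touches) the load-bearing identity code. With the full
wide pace set and all dropouts active, the contrastive task at τ = 0.01
does not converge at these tiny data sizes; the recipe is deliberately
the minimal set that trains stably while enforcing view invariance.

## Known limitations

* The simulator's viewpoint model is a 2D foreshortening heuristic, not a
  camera projection; it exercises the cross-view protocol but does not
  reproduce perspective effects.
* Batch-norm statistics make the loss trace depend on batch composition;
  runs are reproducible only under a fixed seed and platform.
* The NumPy encoder trains small configurations in minutes but is not
  meant for corpus-scale pretraining; the architecture and training code
  are nonetheless complete and config-scalable.
* The curation thresholds are literal readings of their sources
  ("over 60%" strict, "≥ 54 frames" inclusive); boundary behavior is
  documented in the filter docstrings and pinned by tests.
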