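# Methods

## Problem

Predict whether a critically ill patient dies within seven days, from (a)
36 routine physiological indicators and (b) facial features extracted from
a patient image by an object detector.  The scientific question the
pipeline is built to answer is comparative: does the facial channel add
predictive value over the indicators alone?  Because cohorts of this kind
are private, the package treats the generative model of its synthetic data
as part of the method: every claim a green test establishes is a claim
about behaviour *under that stated world*, spelled out below.

## Detector

### Residual stem

The stem computes `G = ReLU(conv_c(x))`, adds a linear skip `conv_d(x)`,
and modulates the sum `s` with a gate derived from global average pooling:
`gate = W_p · GAP(s) + b_p`, output `Softplus(s ⊙ gate)`.  Two choices
deserve note:

* the pooled vector is *projected and broadcast back* rather than
  replacing the feature map — a literal pooling would destroy the spatial
  structure a detector needs;
* the gate is linear (no squashing): the defining equation multiplies the
  pooled projection directly.  `b_p` is initialised to 1 so the stem
  starts near an identity gate; with all parameters zero the output is
  `Softplus(0) = ln 2`, a closed-form anchor used by the tests.

Softplus keeps stem outputs strictly positive; it is used in the stem
only, the body uses ReLU.

### Body

Three stages of residual bottleneck blocks (1×1 → 3×3 stride-s → 1×1 with
projection skip), default widths 16/24/32 and depths 1/1/1 on top of a
stride-4 stem, yielding levels at strides 8/16/32.  No design-space search
is attempted; the body is deliberately small so a CPU can train it in
minutes.  Input sizes must be divisible by 32 so pyramid levels halve
exactly.

### Pyramid

Top-down pass `P_i = lateral(C_i) + Up(P_{i+1})` with cubic-convolution
upsampling (4-tap Catmull–Rom kernel, a = −0.5, half-pixel centres;
factors 2 and 3 supported).  Edge taps are clamped with weight
accumulation, and each interpolation row is normalised to sum exactly to
1, so constant maps are reproduced bit-exactly and the operator is linear.
The second, path-aggregation pass runs finest→coarsest with stride-2
convolutions (`F_i = conv(P_i) + downconv(F_{i−1})`); a config switch
(`second_pass_direction`) provides a top-down variant since the direction
is a genuinely open design choice.

### Head and training

A one-stage head (shared 3×3 tower, sigmoid-per-class and box branches)
rather than a two-stage RPN+RoI design: no proposal stage is specified
anywhere in the architecture this implements, and a one-stage head
exercises every pyramid component at desk scale.  Anchors: one scale per
level (16/32/64 px), aspects 0.35/0.6/1.0 (height/width — the lip targets
are wide and low).  Assignment: IoU ≥ 0.5 positive, ≤ 0.4 negative, best
anchor per ground-truth box force-matched.  Loss: focal (α = 0.25,
γ = 2) + smooth-L1 on standard box deltas, normalised by positive count;
classification bias initialised to prior 0.01.  Adam, lr 2e-3, batch 8,
500 steps.  Inference: score threshold 0.05, per-class greedy NMS at IoU
0.5, boxes clipped to the image, ties broken by input order so results
are deterministic.

## Classifier

The tabular vector (36 indicators; +7 facial features in the multimodal
arm) is mean-imputed and z-scored with training-split statistics, padded
to a multiple of T = 6 and split into T ordered groups ("pseudo-
timesteps").  There is no natural sequence in tabular data; the grouping
is an explicit modelling device, configurable via `n_timesteps`.

Stages (all per sample):

1. dense map `z_t = x_t ⊙ w_t + α_t` (elementwise; a matrix-product
   variant is selectable because the printed form is ambiguous);
2. LSTM over the T steps, hidden size 16, forget-gate bias 1;
3. attention: scalar score per hidden state, weights
   `softmax_t(tanh(score))` — nonnegative, summing to 1 per sample;
4. pooling `R = Σ_t a_t h_t`;
5. gate `σ(R ⊙ Linear(mean_t z_t))` multiplying the pooled vector (a
   variant gating the hidden trajectory is selectable — the gate's
   placement is an open design point);
6. residual branch `BatchNorm(ReLU(Linear(x))) + bias` added to the gated
   vector (batch statistics in training, running statistics with momentum
   0.1 at inference; a training batch of one is rejected as undefined);
7. linear head + sigmoid, threshold 0.5 for hard labels.

Training: binary cross-entropy, Adam lr 1e-2, batch 32, up to 80 epochs,
early stopping on validation AUC (patience 10) with accuracy as a
tie-break for checkpoint selection; the best state is restored.  All
randomness flows from one seed; identical seeds give identical metric
histories.

## Fusion

Facial features are hand-crafted detector summaries: eye/lip counts, mean
eye confidence, eye aspect ratio (height/width), inter-eye centre
distance and eye box area as image fractions, and the across-frame
standard deviation of the aspect ratio (zero with a single frame).
Missing features (no detections) carry explicit flags and are imputed to
training means.  Fusion is early concatenation after per-feature
z-scoring; both experiment arms share the identical train/validation
split and seed so the comparison isolates the facial channel.
Interpretable summaries were chosen over learned embeddings deliberately:
the fusion stage is then auditable and its null behaviour (γ = 0) exact.

## Metrics

Detection follows the COCO protocol: confidence-ordered greedy matching
to unmatched ground truth per IoU threshold, all-point interpolated AP,
averaging over the 0.50:0.95:0.05 grid and over classes; AP@0.5 is also
reported.  "Precision" is measured at an operating score threshold of 0.5
and IoU 0.5.  Classification AUC is the Mann–Whitney statistic (ties ½),
which equals trapezoidal ROC integration; confusion counts, accuracy,
precision, recall and F1 are computed at the configured threshold.

## Statistics

* Group comparison: Welch's t-test by default (robust to unequal
  variances; the test used by the study design is unnamed), Mann–Whitney
  as an option; no multiple-testing correction by default (rows are
  reported marginally), Benjamini–Hochberg available.
* Logistic regression: own IRLS implementation with step halving, so the
  log-likelihood trace is non-decreasing by construction and exposed for
  testing; SEs from observed information, Wald t and 95% CIs
  (B ± 1.96·SE), OR = exp(B), standardized Beta = B × sd(column).
  Zero-variance columns are dropped with a warning; quasi-separation is
  flagged and reported as non-converged.  statsmodels serves as an
  independent oracle in the tests, never as the implementation.
* Feature impact: permutation importance — mean |Δ predicted probability|
  under within-column shuffling, averaged over 10 permutations.  Chosen
  over gradient attribution because it is model-agnostic and cheap;
  constant columns have impact exactly 0.

## The stated synthetic world

**Images.**  Grey 96×96 canvases: low-frequency smoothed-noise background
(level 0.35), two ellipse eyes and one ellipse lip filled at background
+ 0.35 contrast, additive pixel noise sd 0.03.  Ground-truth boxes are
the exact ellipse bounding boxes.  The eye aspect ratio (height/width in
0.35–0.85) is an affine function of a per-patient scalar s ∈ [0, 1] — a
deliberately simple stand-in for "eye-movement variability", which the
underlying clinical construct never defines operationally.  What a green
detection test establishes is that the architecture can learn compact
high-contrast targets; nothing about photorealistic faces, pose,
illumination or occlusion robustness.

**Cohort.**  Indicators are independent normals with clinically plausible
means and 15% coefficients of variation; the death label follows
`Bernoulli(σ(intercept + β·x_std + γ·s_std))`.  The 13 significant
indicators carry ±β with the sign pattern of the reported group
differences (temperature, respiratory rate, Na, GCS, AST, BIL, PT, APTT,
FIB toward death; systolic pressure, MAP, BE, chronic health evaluation
toward survival).  Real indicators are correlated and non-normal; this
world tests the learning machinery, not clinical realism.

Two named regimes:

* *strong* (`strong_cohort_spec`): β-scale 2.0, γ = 0, intercept −0.5.
  The scale is set by an explicit design rule — the Bayes-optimal linear
  scorer should reach AUC ≈ 0.98 (Monte-Carlo at n = 4·10⁵ gives Bayes
  AUC 0.981, Bayes accuracy 0.925) — because the learnability check
  presumes a world where a strong signal genuinely exists.  A first
  guess of scale 1.2 was discarded after the same calculation showed its
  Bayes accuracy (0.881) makes the stated accuracy bound unattainable by
  any classifier.
* *multimodal* (`multimodal_cohort_spec`): β-scale 0.5, γ = 2.0 — a
  moderate clinical signal with a facial channel of comparable aggregate
  weight, so the unimodal-vs-multimodal gap is large relative to
  validation noise at n = 298.

## Numerical choices

* All tensors are float64; training is deterministic given the seed
  (single-threaded NumPy, one `default_rng` per run).
* Box convention: 0-based half-open corners; COCO x/y/w/h converted at
  the I/O boundary.
* Predicted log-size deltas are clamped at ±4 before decoding to avoid
  overflow from untrained heads.
* NMS suppresses at IoU strictly greater than the threshold; score ties
  resolve by input order.
* Constant-column z-scoring guards against floating-point dust
  (sd ≤ 1e−9·max(1, |mean|) is treated as zero and mapped to sd 1).
* Standardisation/imputation statistics always come from the training
  split; the tests assert invariance to the held-out split.

## Known limitations

* The detector is one-stage; the two-stage extension point exists only as
  a config flag.
* No instance masks: never part of the specified design.
* The synthetic facial channel is a single static geometric proxy; frame
  sequences are supported (per-frame features averaged + variability
  channel) but default to one frame.
* Logistic Wald CIs are symmetric; profile-likelihood CIs are not
  implemented.
* Tabular-to-sequence grouping is arbitrary (indicator order); the model
  is not invariant to indicator permutation across groups.
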