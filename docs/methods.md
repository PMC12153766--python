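# Methods

This note documents the models, defaults and design choices behind
pentrack: what is computed, why the defaults are what they are, and what
the synthetic experiments do and do not demonstrate.

## Motion model

Each track carries a constant-velocity Kalman filter over the 8-dim state
(c_x, c_y, a, h, vc_x, vc_y, va, vh): box center, aspect ratio w/h, height,
and per-frame velocities. The measurement is the first four components.
Process and measurement standard deviations scale with box height using the
conventional weights 1/20 (position) and 1/160 (velocity), both exposed in
`KalmanParams`. Scaling noise by height makes the filter gain
scale-invariant: a piglet near the camera and one far away are tracked with
the same relative stiffness.

Two deliberate deviations from the most common parameterization:

- **Diffuse velocity prior at initiation.** Velocity is completely
  unobserved when a track is born, so the initial velocity standard
  deviation is h/2 rather than a tightly scaled value. With a tight prior
  the filter needs ~20 updates to trust an observed velocity of a few
  px/frame; with the diffuse prior two or three updates pin it down and a
  noiseless constant-velocity target is predicted to well under 0.1 px by
  the tenth update. (The original SORT filter makes the same choice even
  more aggressively, with variances in the thousands.)
- **Frozen shape while coasting.** For tracks that missed their last
  update, the aspect/height velocities are zeroed before prediction.
  Extrapolating shape velocities through a long occlusion can drive the
  predicted height negative; position velocities keep extrapolating so the
  track continues along its path.

The filter is exact for noiseless constant-velocity targets (the estimation
error contracts geometrically once the model matches), and the covariance
stays symmetric positive-semidefinite through arbitrary predict/update
sequences; both are property-tested.

## Association cascade

Per frame, after predicting every live track:

| stage | candidates | cost | gate (default) |
|---|---|---|---|
| 1 | high-confidence detections × all live tracks | 1 − IoU | IoU ≥ 0.3 |
| 2 | stage-1 leftovers | center distance (px) | ≤ half the mean predicted-box diagonal |
| 3 | remaining tracks × low-confidence detections | λ(1 − IoU) + (1 − λ)·min(d_cos, 1) | cost ≤ 0.5 |

Defaults: τ_high = 0.6, τ_low = 0.1, λ = 0.5. Detections below τ_low are
dropped entirely. Every stage solves a gated minimum-cost bipartite
assignment via `scipy.optimize.linear_sum_assignment`; ineligible pairs are
replaced by a penalty that dominates any sum of eligible costs, so the
solution has maximum cardinality among eligible pairs and minimum total
cost at that cardinality. This construction also gives the monotonicity
property that admitting more low-confidence detections can never increase
the number of unmatched tracks.

Choices worth flagging:

- The stage-2 distance is kept in **raw pixels**, not normalized by image
  size; the adaptive gate (half the mean box diagonal of the candidate
  tracks) makes it scale-aware without an image-size dependence.
- The cosine term in stage 3 is clipped to [0, 1] so both cost terms share
  a scale and the gate stays interpretable; a detection without an
  embedding falls back to the pure IoU cost.
- Stage 2 considers only the unmatched *high*-confidence detections; the
  `stage2_include_low` switch admits low-confidence ones as well for the
  alternative reading of the pipeline.
- New tracks are born from unmatched high-confidence detections only
  (low-confidence detections may rescue existing tracks but never create
  one), the ByteTrack-family convention.

## Track lifecycle

tentative → confirmed after `n_init` = 3 consecutive hits; a tentative
track that misses a frame is removed immediately. A confirmed track that
misses becomes lost, keeps coasting (and stays eligible in all three
stages), and is removed after `max_age` = 30 consecutive missed frames —
one second at the 30 fps the recordings are standardized to. The
appearance template is an exponential moving average with α = 0.9 on the
unit sphere (renormalized after each blend), the standard JDE-family
smoothing. Emitted rows carry the matched detection's confidence.

With a noiseless detector the tentative phase serves no purpose (it exists
to suppress tracks born from false positives) and necessarily costs the
first `n_init` − 1 frames of every track; the noise-free demo and the
perfect-input check therefore run with `n_init` = 1, which is also the
configuration for pipelines that confirm instantly.

## Domain-aware attention

For a feature map F ∈ R^(C×H×W): g = avgpool(F); domain weights
s = softmax(W_C g) with W_C ∈ R^(3×C) (numerically stable via max
subtraction); three branch responses b_k = A_k g + c_k with A_k ∈ R^(C×C)
(an effective squeeze-and-excitation block is a single fully connected
layer on the pooled vector — no reduction ratio); combined response
r = Σ_k s_k b_k; output channel c is F[c]·σ(r_c).

The product of the domain-weight vector with the stacked branch outputs is
interpreted as a **convex combination of the three C-dim branch
descriptors** — the only reading that yields a C-vector consumable by the
per-channel sigmoid scaling. Branches carry no internal sigmoid; the single
saturation at the output avoids double squashing. Two consequences are
property-tested: the output is an elementwise strict shrinkage of the
input, and jointly permuting the branches with the rows of W_C leaves the
output unchanged. The operator is inference-only by design.

## Evaluation suite

- **CLEAR correspondence**: matches persist frame-to-frame while their IoU
  clears the threshold (default 0.5); the remainder is re-matched by
  minimum 1 − IoU assignment. An identity switch is counted when a
  ground-truth identity's matched hypothesis id differs from its most
  recent previous match, including across gaps.
- **MOTA** = 1 − (FN + FP + IDSW)/GT; unbounded below, 1 only for perfect
  tracking.
- **MOTP** is reported as the **mean IoU of matched pairs** (higher =
  better), consistent with how the benchmark tables rank it; the
  `--motp-as-distance` flag recovers the literal distance-ratio form with
  d = center distance in pixels.
- **IDF1** uses the optimal global bijection between ground-truth and
  hypothesis identities on per-frame IoU ≥ 0.5 co-occurrence counts.
- **HOTA** follows the canonical two-pass protocol: a global alignment
  score per identity pair, per-frame Hungarian matching on
  alignment-weighted IoU, then per-threshold DetA and AssA and the
  geometric mean √(DetA_α·AssA_α) averaged over α ∈ {0.05, …, 0.95}. The
  square-root form is the canonical definition; `--hota-no-sqrt` gives the
  plain product for comparison with sources that print the formula without
  it.
- **MT/ML** use the standard 80% / 20% coverage thresholds.

Frame-rate (FPS) and other hardware-dependent numbers are out of scope.

The oracle for the whole suite is an independently written naive reference
evaluator in the test suite: pure-Python loops, shapely-based rectangle
overlap, exhaustive permutation matching per frame, exhaustive bijection
enumeration for IDF1. Implementation and oracle agree to 1e−6 on twenty
tracked synthetic scenarios and to 1e−9 on HOTA fixtures.

## Synthetic pen scenarios

The generator emulates a fixed top-down pen camera. Ground truth: each of
n identities follows a reflected correlated random walk — persistent
heading plus Gaussian turning noise with standard deviation
(1 − persistence)·π, reflecting off walls — with a per-identity box size
drawn once (70–110 px wide, aspect 0.6–1.6, matching ~50 kg pigs seen
top-down at typical mounting heights). Occlusion episodes are injected as
Poisson-arriving chase intervals (rate `occlusion_rate`/100 per frame,
mean length 12 frames) during which one animal steers at another;
visibility is 1 minus the largest fraction of the animal's box covered by
any other box (2-D overlap only, no depth ordering — enough to trigger the
code paths stages 2 and 3 exist for).

Detector emulation: misses with probability interpolating base→occluded
by (1 − visibility); Gaussian box jitter; confidence drawn around a
visibility-interpolated mean (σ = 0.05), clipped to [0, 1]; Poisson false
positives placed uniformly with confidence ~0.3; embeddings are
unit-normalized identity prototypes plus visibility-dependent Gaussian
noise, with random embeddings on false positives. All draws come from one
seeded generator in a fixed order, so scenarios are bit-reproducible.

Preset conditions (chosen once as plausible for the two regimes):

- **day**: 6 animals, 300 frames, miss 2%→35%, confidence 0.88/0.45,
  embedding noise 0.08/0.25, 0.1 FP/frame.
- **night**: 10 animals (densest pens are recorded at night in the source
  footage), 300 frames, miss 12%→60%, confidence 0.62/0.32, embedding
  noise 0.25/0.5, 0.5 FP/frame.

What passing on this simulator shows: the association logic, lifecycle
management and metric implementations behave lawfully under controlled
degradation, and the low-confidence/fused stages measurably reduce identity
switches when occlusion and detector noise are heavy. What it does not
show: performance on real video — the simulator has no appearance drift,
no camera noise correlated in time, no detector biases (e.g. merged boxes
for touching animals), and its embeddings are idealized prototypes. Real
accuracy numbers require a trained detector and annotated footage.

## Recorded benchmark arithmetic

`pentrack.benchmarks` stores the published ablation grid of the tracker on
its ten-scene pig-pen video benchmark and recomputes the deltas the
headline claims rest on (cascade: +10.0 MOTA, +30.9 IDF1, +20.7 HOTA
points, switches 447→54; full model: +16.6 MOTA, +25.2 HOTA, switches
447→24, a 94.6% reduction). Those video-pipeline scores themselves are not
reproducible here — they depend on the trained detector and the real
footage — so only their internal arithmetic is asserted. Where recomputed
deltas differ from quoted prose (e.g. an IDF1 gain of 33.3 from the
one-decimal table vs. a quoted 33.2 computed before rounding, and two
per-scene HOTA deltas quoted with a dropped leading digit), the
table-derived values are used.

## Problem sizes

The test suite and the acceptance script use desk-scale runs chosen to
exercise every code path with comfortable margins: 200 random matrices up
to 6×6 for assignment optimality; 20 four-animal, 40-frame scenarios for
metric-oracle agreement; a 100-frame noise-free scenario for the
perfect-input law; the full 300-frame day/night presets, 20 seeds, for the
stage-3 ablation; 25 random instances (C ≤ 8, H, W ≤ 5) for the attention
laws.
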