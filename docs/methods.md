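# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Segmentation metrics

All five metrics derive from one pixelwise confusion pass between a
predicted and a ground-truth binary mask:

* DSC = 2|P∩Q| / (|P|+|Q|), JI = |P∩Q| / |P∪Q| (linked by
  DSC = 2·JI/(1+JI)),
* precision = TP/(TP+FP), sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP).

**Degenerate denominators.** Any ratio with a zero denominator — both masks
empty, no positive predictions, no true negatives — is defined as 1.0.
Tumor-free slices are common in abdominal CT; an empty prediction on an
empty truth is a correct answer and must not poison aggregates.
**Aggregation** is the per-case mean of metrics, not pooled confusion
counts; this is the dominant convention for reporting Dice. **Counting
unit** is the 2-D pixel: the networks are 2-D and operate per slice, so
per-slice pixel counts match the model even when masks come from a 3-D
label volume.

## GWBCO optimizer

A population of candidates maximizes a black-box fitness over a box
[l, u]. Defaults: population 50, 50 iterations, observation threshold
φ* = 0.9, movement factor K_m = 0.5, eyeing probability factor ρ_f = 1,
unit time step.

Per iteration: rank the population (alpha/beta/delta = three best, stable
ties by index), then for each candidate draw φ ~ U(0,1):

* **Encircle/attack (φ < φ\*).** Three coefficient sets are drawn
  (P = 2p·r₁ − p, Q = 2r₂ with r₁, r₂ ~ U(0,1)); p decays linearly from 2
  at iteration 0 to 0 at the final iteration. The candidate moves to the
  mean of the three leader-relative positions
  R_leader(1 − P·Q) + P·R_t, plus the eyeing displacement.
* **Eyeing.** From the candidate's own motion: speed V = ‖R_t − R_{t−1}‖/Δt,
  acceleration A = (V_new − V_old)/Δt, prey speed
  V_prey = √max(0, V² − 2·A·s) with s the last step length (the kinematic
  identity v² = u² − 2as; the radicand is clamped at zero so a hard
  acceleration never produces an imaginary speed). The scalar displacement
  V_prey·Δt − ½·A·Δt² is applied along the unit vector of the last
  movement; a stationary candidate gets zero displacement.
* **Observation (φ > φ\*).** R_{t+1} = R_g + K_m(R_prey − R_t). The prey
  position is identified with the current global-best position.

Conventions adopted where the method description is underdetermined:
r₁, r₂ are plain U(0,1) draws; φ is drawn independently per candidate per
iteration; initial velocities are zero, so initialization is uniform in the
box; positions are clamped (projected) into the box after every update; a
non-finite fitness demotes the candidate to the worst rank with a logged
warning instead of aborting. The best-ever position is tracked separately
(elitism), so the reported best fitness is non-decreasing — a property the
tests assert on every run.

Ablation switches expose the two ingredients separately: `eyeing=False,
observation=False` reduces an iteration to the plain pack update exactly
(asserted bitwise in the tests); `leader_mode="global_best"` replaces the
three-leader consensus with a global-best-only update while keeping eyeing
and observation, approximating a herding-only variant.

## Stage networks

Each stage maps a normalized H×W slice to an H×W logit map. Topology:
depth 4, two 3×3 'same' convolutions + ReLU per block, 2×2 max pooling,
base 8 features doubling per level (8→128 at the bottleneck), 2×2
up-convolutions, skip concatenation, final 1×1 convolution; He-normal
initialization under a fixed seed. 'Same' padding makes skip concatenation
crop-free and guarantees output size = input size for any input divisible
by 2⁴. The desk-scale default input is 64×64; 512×512 is configurable and
uses the identical topology. No batch normalization. Binarization
threshold 0.5 on sigmoid outputs.

The CNN engine is written in numpy: convolutions are einsum contractions
over sliding-window views, the 2×2 pool/up-conv exploit their
non-overlapping geometry, and every layer implements an analytic backward
pass (verified against central-difference gradients in the tests).

**Fusion.** Stage outputs merge into a {0,1,2} label map; tumor overrides
pancreas on overlap, and a tumor pixel outside the pancreas prediction is
kept rather than suppressed — suppression would hide exactly the false
positives one needs to see. The inverse mapping counts tumor pixels as
pancreas for stage-I ground truth (the tumor lies within the organ); a
strict `label == 1` mode is available.

**Parameter vectors.** Any subset of layers (named, or by block prefix)
flattens to a vector with a recorded layout; inject(extract(net)) is the
bit-exact identity and touches nothing outside the subset. Refinement
fitness uses a cached partial forward pass: activations upstream of the
refined layers are computed once per validation batch, so an inner fitness
call costs only the refined tail of the network.

## Training and refinement

* **Normalization:** per-image min–max to [0,1]; a constant image maps to
  zeros.
* **Split schedule:** shuffle once, then train fractions 0.4→0.8 in 0.1
  steps with nested training sets; the largest-train step is the reported
  model. Refinement fitness uses a held-out quarter of the training cases.
* **Loss:** pixelwise binary cross-entropy + soft Dice (smoothing 1.0).
  The Dice term counters the class imbalance that plain cross-entropy
  handles poorly on small organs. Optimizer: Adam, learning rate 1e-4,
  batch size 32. Full-scale defaults are 500 epochs evaluated every 100;
  the package's desk defaults are 50/10, and the acceptance experiments use
  15-epoch pre-training so the refinement step operates on a realistic
  partially-trained starting point.
* **Refinement:** subset = final decoder block + output convolution
  (~2 300 weights at base 8 — small enough that a 20×20 or 50×50 evaluation
  budget is meaningful; a configurable dimension cap warns on larger
  subsets). Search box half-width 0.5 around the pre-trained vector:
  weights of a trained network live at unit scale, so ±0.5 covers sign
  flips and large rescalings without being unbounded. Fitness = mean
  validation DSC after injection. Seeding the population with the
  pre-trained vector plus best-ever tracking guarantees
  final ≥ initial validation DSC. Refinement is applied per stage.

## Synthetic phantoms

Each case is an elongated ellipse "organ" (aspect ratio 2–3.5, smooth
low-harmonic boundary perturbation) covering 2–6% of a 64×64 slice, with a
tumor disc (radius 0.15–0.5 of the organ's minor axis) placed strictly
inside it via the distance transform; 10% of slices are tumor-free. Mean
intensities 0.2/0.6/0.8 (background/organ/tumor) with Gaussian noise
σ = 0.05, clipped to [0,1]. Everything is driven by a seeded generator and
is bit-reproducible.

The phantoms emulate only the statistical properties the method is
sensitive to: severe class imbalance, tumor-within-organ containment,
three-level contrast, noise. They do **not** model anatomy, Hounsfield
units, partial-volume effects, neighboring organs, or inter-slice
correlation — so passing tests demonstrate that the machinery (training,
injection, refinement, fusion, metrics) behaves correctly and that
refinement improves Dice on this family, not that the pipeline reaches any
particular accuracy on real CT.

## Problem sizes and known limitations

The acceptance experiments use 30 phantoms at 64×64 with base 8 features,
15-epoch pre-training and a 20×20 refinement budget per stage, repeated
over ten seeds — sizes chosen so the whole suite runs on a single CPU core
in minutes while every property under test (elitism, ablation direction,
convergence, round trips) remains meaningful. At these sizes absolute Dice
values are far below what full-scale training reaches; the tests therefore
assert properties and orderings, never benchmark numbers.

Known limitations: refinement on a handful of validation slices can
overfit them (test Dice improves on average but fluctuates per run); the
eyeing displacement direction is a modeling choice (the underlying
kinematics prescribe only a scalar); the cascade's stage II sees the whole
slice (no crop-cascade mode); 3-D context is ignored by design.
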