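# Methods

This note documents the models, defaults and numerical choices behind the
package, what the simulator does and does not emulate, and the known
limitations.

## Problem setting

A two-stage lung-nodule CADe system proposes candidate locations at high
sensitivity and then classifies a 30-mm cube around each candidate as
nodule or non-nodule.  The package implements the second stage with a
training strategy built for scarce clinical labels: supervised training on
labeled phantom-like scans, plus two mechanisms that bridge the
phantom-to-clinic gap — a rich augmentation menu and a semi-supervised
objective over unlabeled clinical-like scans.

## Scan simulation

**Phantom mode** renders a simplified thorax: air (−1000 HU) outside an
elliptic-cylinder chest wall (+40 HU, 4 mm thick), lung parenchyma
(−850 HU) inside, and a sparse branching tube tree (+50 HU, two roots,
two branch levels, 1.2 mm radius) standing in for a vascular insert.
Nodules come from four shape families — spherical, elliptical (axis ratios
0.6–1.0 rescaled so the mean axis equals the nominal diameter), lobulated
(3–6 spheres with radii 0.3–0.5 d offset up to 0.3 d) and spiculated
(0.35 d core plus 8–16 conical spikes) — at diameters 5–20 mm and
densities {−630, −10, 100} HU.  The lobulated/spiculated construction
rules are this package's own; only the family names and the diameter and
density inventory are externally fixed, and each mask is clipped to a
1.5 d bounding box.  The 48-piece inventory (4 shapes × 4 diameters ×
3 densities) is available as a catalogue, and the default dataset builder
cycles it over 569 scan layouts.  Nodules are blended in with a Gaussian
edge (σ = 0.7 voxel) emulating partial-volume averaging, and the
acquisition protocol is collapsed onto two knobs: additive Gaussian noise
(default 12 HU std) and slice thickness (default 2 mm).  There is no
physics-based projection/reconstruction; scanner kernels, dose and pitch
are out of scope.

**Clinical mode** keeps the same scaffold and adds what makes real scans
hard: band-limited parenchymal texture (σ ≈ 60 HU at difficulty 1),
denser bifurcating vessel trees, air-density airway tubes, scar-like
soft-tissue blobs placed in clear parenchyma, pleural-attached nodules, a
wider nodule density range (−400 to +150 HU) and occasional calcified
nodules (up to +400 HU).  A `difficulty` knob in [0, 1] scales all of
this; at 0 the output is distributionally close to phantom mode.  The knob
is *not* calibrated against any real dataset — it is a free parameter of
the study conditions.

A region-proposal emulator stands in for the first detection stage: each
truth is included with probability `sensitivity` (default 0.95) with a
center jitter up to 0.25·diameter, and the remaining candidates are placed
preferentially (70%) on bright structures — vessels, wall, mimics — the
way shape/intensity-based detectors fire.

All generators are pure functions of (parameters, seed); identical seeds
give bit-identical volumes.

## Preprocessing

Volumes are trilinearly resampled to (2, 0.625, 0.625) mm (grid anchored
at voxel (0,0,0), origin preserved), clipped to [−1000, 400] HU and
linearly mapped to [−1, 1].  The "30 mm ROI" is a 30-mm cube —
15 × 48 × 48 voxels at target spacing; the center voxel is the half-up
rounding of the continuous index, and out-of-volume regions pad with −1
(air).  Negatives are sampled uniformly over lung *tissue* — parenchyma
plus vessels and airway walls (−965 to 155 HU), excluding outside air and
the chest wall — under the constraint that the candidate's ROI box does
not intersect any truth's bounding sphere.  Sampling over tissue rather
than parenchyma only is deliberate: stage-1 candidates sit on bright
structures, and negatives drawn only from flat parenchyma would make the
training task unrealistically easy.  Class imbalance is handled by
repeating each positive ROI (250× in the reference configuration).

## Augmentations

Weak = per-axis flips plus integer translations up to 10% of the patch
extent (exactly invertible); strong = a weak augmentation followed by one
operator drawn uniformly from {in-plane rotation ≤ 30°·m, isotropic scale
1 ± 0.2 m, additive Gaussian noise σ ≤ 0.1 m (normalized units),
intensity scale/shift ± 0.2 m, Gaussian blur σ ≤ 1 voxel·m, cutout cube
≤ 25% extent}, with magnitude m ∈ [0, 1].  The labeled stream draws one
operator per sample uniformly from {identity} ∪ the full menu.  The
strong-operator menu is a reconstruction — only flip and translate are
externally named as the weak set — and is config-driven so it can be
edited without code changes.  Rotations are in-plane by default because
the 2 mm z-spacing makes through-plane interpolation lossy.  Every
operator preserves shape, label and the [−1, 1] range (values re-clipped).

## Network

Three conv blocks (two same-padded 3×3×3 convolutions + leaky ReLU each,
then 2× max pool and dropout 0.3) with 32/64/128 kernels, then global 3D
average pooling, two 128-node fully connected layers (leaky ReLU, dropout
0.9) and a single-logit sigmoid head — 6 convolutions and 2 hidden dense
layers in total.  Pooling uses floor division (z: 15 → 7 → 3 → 1), inside
each block the order is conv–act–conv–act–pool–dropout, the leaky slope is
fixed at 0.01, and confidence for the one-logit head is max(p, 1 − p).
The single-logit head (rather than a 2-way softmax) makes the binary task
explicit.

The engine is a compact numpy implementation: im2col + BLAS matmul
convolutions, explicit backward passes, Adam (β₁ = 0.9, β₂ = 0.999) with
*decoupled* weight decay applied to convolution kernels only
(default 1e-4).  Gradients are validated against central finite
differences; float32 arithmetic and max-pool kinks limit pointwise
agreement to a few percent, which the test tolerances reflect.

## Training objective

L = l_s + λ₁ l_u + λ₂ l_p with λ₁ = λ₂ = 0.5; all terms are focal losses
(α = 16, γ = 2, probabilities clamped at 1e-7).  Setting α = 1, γ = 0
recovers binary cross-entropy exactly (the γ — not α — must vanish for
the reduction; the package follows the mathematics).  Details that were
genuinely open and are fixed here:

* the consistency gate applies to max(p, 1 − p) of the *weak* view,
  computed without dropout and without gradient flow; gated samples
  contribute FL(p_strong, [p_weak ≥ 0.5]);
* l_u is the mean over gated samples and exactly 0 when none pass, so
  early training is driven by labeled data and the gate fraction is a
  logged diagnostic;
* pseudo-labels are assigned once, before training, by a teacher trained
  with λ₁ = λ₂ = 0 on phantom data only; thresholds ≤ 0.01 / ≥ 0.99;
  pseudo-labeled samples also remain in the consistency stream; l_p is
  evaluated on the strong view so one backward pass serves both terms;
* optimizer, learning rate (1e-3 reference / 3e-3 desk scale), batch
  sizes (32+32 reference / 16+16 desk), epochs and the 1:1
  labeled:unlabeled batch ratio are free constants exposed in
  `OptimConfig`.

The recorded total equals l_s + λ₁ l_u + λ₂ l_p at every step by
construction, and an empty unlabeled set reduces the loop bitwise to plain
supervised focal training.

## Evaluation

A candidate is a true positive iff its center lies within diameter/2 of a
truth center (the simulator annotates spherical extents); a truth counts
once however many candidates hit it; findings failing the consideration
filter (diameter > 3 mm, reader agreement ≥ 3) become ignore regions whose
hits count as neither TP nor FP.  FROC operating points are taken where
the FP count changes — at each distinct FP score, threshold-inclusive —
plus a zero-FP endpoint counting truths that out-score every FP; this
conservative convention credits a sensitivity gain only once the FP budget
accounts for all equally-scored false positives.  Sensitivity at arbitrary
rates interpolates linearly on the FP axis (a step-function mode is
available) and holds at the right end.  CPM = mean sensitivity at
{0.125, 0.25, 0.5, 1, 2, 4, 8} FP/scan.  Bootstrap CIs for CPM
differences resample *scans* with replacement (CPM is a scan-population
quantity), re-score both systems per replicate and take 2.5/97.5
percentiles of 1000 differences.

## Desk-scale study conditions

The study harness reproduces the two designs — the four-arm
±augmentation × ±unlabeled ablation and the dataset-enlargement sweep —
at sizes a single CPU handles in minutes:

* grids of 12 × 56 × 56 voxels at (4, 1.25, 1.25) mm → 30-mm ROIs of
  8 × 24 × 24 voxels; clinical nodule diameters restricted to 8–16 mm
  (a 5-mm nodule is barely one slice at 4-mm spacing);
* 10 phantom training scans (3 nodules, 30 negatives each, positives
  oversampled 10×), 10 clinical scans for the unlabeled stream (30
  candidate patches each), a frozen test set of 20 clinical scans × 30
  candidates (~55–60 considered truths, so sensitivity resolves in ~0.018
  steps — enough for paired CPM contrasts);
* a narrow network (4/8/16 conv kernels, 32/32 dense) with dropout
  0.1/0.3: the reference rates (0.3/0.9) are sized for 128-wide layers
  and a long schedule, and under them a 32-wide net trained for ~100
  steps cannot learn at all;
* 10 epochs × 12 steps, Adam at 3e-3, batches 16+16; "basic"
  augmentation is flip/translate/rotate, "full" is the whole menu.

Reference-scale constants (569 scans, 1000 negatives/scan, 250×
oversampling, the 32/64/128 network) remain the configuration defaults
and are what the pipeline-constants checks exercise.

What desk-scale results do and do not show: trained arms beat the
random-score baseline by a wide margin, and the augmentation and
unlabeled-data contrasts are assessed as *orderings over shared seeds*,
not magnitudes.  Both effects are small at this scale (CPM deltas on the
order of +0.01 against seed noise of similar size), so the harness reports
majorities over shared seeds together with bootstrap CIs rather than
claiming significance per seed.  Clinical-scale CPM values are not
expected to reproduce on synthetic data and the package makes no such
claim.

The simulator's negatives are easier than real hard mimics (no genuine
scar morphology, no respiratory or reconstruction artifacts), its nodules
are geometric idealizations, and its anatomy lacks airway/vessel trees
with realistic topology.  Passing tests therefore demonstrate the
*machinery* — losses, gating, pseudo-labeling, matching, FROC arithmetic,
bootstrap coverage — and directional behavior on a controlled benchmark,
not clinical performance.

## Degenerate inputs and tie-breaks

Nodule diameters below one voxel raise a degenerate-shape error;
overlapping layout nodules raise a layout error (bounding-sphere test at
0.75·(d₁+d₂), matching the 1.5 d mask boxes).  ROI centers more than one
ROI extent outside the volume are placement errors.  Negative sampling
retries in bounded rounds and fails loudly if the admissible region is too
small — at reduced grids this binds: a 30-mm exclusion box around each
truth needs an in-plane extent of ≥ ~80 mm to leave room, which sets the
(16, 128, 128) grid of the 569-scan pipeline check.  Ties in candidate→
truth matching go to the relatively closest truth; matching is
order-independent.  A bootstrap replicate that happens to contain no
truths falls back to the full scan set (rare at the sizes used).
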