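# Methods

This note documents the model, the synthetic benchmark, the numerical and
design choices made where the design was genuinely open, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The system classifies the direction of single-object, one-pixel motion
between two same-sized RGB frames into eight classes (the 3×3 neighbors of
a pixel, reading order, center skipped: 1=up-left … 8=down-right;
coordinates are 0-based with row 0 at top).

**Retinal front end.** Each channel is processed independently (the three
cone types are identified with the R/G/B planes). Two binary responses
are computed per pixel: the bipolar (vertical On–Off) response fires when
the intensity at a pixel changes between the frames by more than `ε_V`,
and the horizontal (horizontal On–Off) response fires when the center
intensity at time *t* matches a 3×3 neighbor's intensity at *t+Δt* to
within `ε_H` (both inequalities strict; a difference exactly at the
threshold falls on the "off" branch, which the defining strict
inequalities leave open). Only pixels whose full 3×3 neighborhood lies
inside the grid participate downstream — padding would fabricate
intensities, so border centers are excluded instead. The per-pixel input
vector takes slot 5 from the bipolar map and the other eight slots from
the horizontal maps.

**Dendritic ganglion neurons.** One four-layer neuron per (direction,
channel): sigmoidal synapses `S = σ((w x − q)/d)` on the binary inputs, a
multiplicative branch `b = Π S`, a weighted membrane sum `u = Σ v_j b_j`,
and a sigmoidal soma `O = σ(λ(u − θ))`. The (w, q) pair puts each synapse
in one of four states — excitatory, inhibitory, constant-1, constant-0 —
classified by thresholding its outputs at x=0 and x=1 at 0.5. With the
default structure (9 synapses, 1 branch, 8 directions, 3 channels) the
learnable parameters {w, q} number 9·2·8·3 = 432.

**LGN and readout.** A fixed neuron per direction multiplies the three
channel somas and thresholds the product, `M_m = σ(λ_m(O^R O^G O^B −
θ_m))`; activation requires all three channels. Direction evidence is
`D_m = Σ_{a,b} M_m(a,b)` over interior pixels, normalized to the simplex
by `D̄ = D/ΣD`, and the prediction is `argmax_m D_m` with ties broken
toward the smallest label.

**Learning.** Cross-entropy `E = −Σ T_m log D̄_m` minimized by plain
mini-batch gradient descent on w and q only. The default gradients are the
exact chain rule through every stage, including the normalization Jacobian
and the other-channel product in `∂M/∂O^c`; they are verified coordinate-
by-coordinate against a central-finite-difference oracle. A second mode,
`gradient_mode="paper_literal"`, implements a historically printed
simplification of this derivation verbatim: the normalization Jacobian is
collapsed to 1, the LGN derivative is evaluated at `(O − θ)` without the
other-channel product, and the soma derivative at `(v − θ)` instead of
`(u − θ)`. In that form the teacher factor `−T_m/D̄_m` is zero for every
direction except the true one, so only the true direction's neurons are
ever updated; the mode is exposed for comparison, trains poorly, and is
not the default. Sum normalization is likewise the default; a
`normalization="image_area"` mode (divide by the pixel count instead of
the direction total) is provided because the literal derivation implies
it, and the discrepancy between the two is surfaced here rather than
silently resolved.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `ε_V` | bipolar threshold (intensity units) | 0 | any integer change fires; tightest reading consistent with the binary worked example |
| `ε_H` | horizontal threshold | 1 | exact integer match |
| `d` | synapse distance (sigmoid temperature) | 0.5 | slope-2 synapses; steeper (0.2) sigmoids saturate almost everywhere and make SGD unstable |
| `v` | branch weight | 1 | single branch, not learned |
| `λ, θ` | soma slope/threshold | 5, 0.5 | midpoint of the membrane range u ∈ (0,1) |
| `λ_m, θ_m` | LGN slope/threshold | 5, 0.5 | same operating point on the channel product |
| `η` | learning rate | 10 | see "Loss scale" below |
| batch / epochs / patience | | 32 / 100 / 10 | plateau patience arms only after the loss first improves, so slow starts are not cut short |
| init | w, q | "gated" | see below |

## Initialization: the innate bipolar gate

Uniform w, q ~ U(−1, 1) is a dead zone: the product of nine mid-range
sigmoids is ≈ 0, every soma sits at the same floor, and gradients are
~1e-8 at any learning rate. Worse, a structural argument shows plain
uniform-style initializations cannot reach high accuracy at all: under sum
normalization, a response component that is *common to all eight direction
neurons* leaves `D̄` — and hence the loss — exactly unchanged at the
symmetric point `D_m = ΣD/8`. The all-background input pattern is such a
component, and the synapse that separates background from motion evidence
is the center (bipolar) one: background pixels have `x_5 = 0`, evidence
pixels `x_5 = 1`. Turning the center synapse excitatory therefore lies in
a flat direction of the loss, gradient descent never learns it, and
training plateaus around 90% with adjacent-direction confusion — even
though a hand-constructed parameter set with the gate (excitatory at the
center and at the slot matching each direction's displacement, constant-1
elsewhere) classifies every configuration perfectly.

The default initialization therefore encodes the gate innately: the
center synapse starts in its excitatory state and the surround synapses
start just inside constant-1 with small perturbations, so branches
transmit and the surround acquires direction selectivity through
learning. This mirrors the developmental account the model is built on:
On/Off-pathway segregation is genetically programmed and functional from
birth, while dendritic synaptic states are shaped by visual experience.
With the gate, background rows contribute no gradient and desk-scale
training reaches 100% train and held-out accuracy across a wide band of
learning rates. `scheme="uniform"` is retained for the untrained
chance-level control.

## Loss scale and the learning rate

With 900 interior pixels and an LGN floor of σ(−λθ) ≈ 0.076, the direction
sums carry a baseline of ≈ 68 per direction against evidence contributions
of a few units, compressing the achievable loss range to ≈ 0.1 nats. The
gradients inherit that compression, so the learning rate that moves
parameters at a useful pace is of order 10, not 0.01. Tiny datasets
(tens of pairs) additionally need smaller batches (more update steps per
epoch); the tests use batch 8 there. The smallest scale at which the
default optimizer reliably reaches 100% training accuracy is ≈ 80 balanced
pairs.

## Synthetic benchmark

The generator emulates: a single rigid 4-connected object (random seeded
accretion growth, one-cell margin to every edge so each of the 8 unit
shifts stays in bounds), object/background intensities from {dark = 0,
constant = one shared triplet with channels uniform on [1, 255], random =
i.i.d. uniform per pixel and channel}, a static background, and exact
one-pixel translation with the object's per-pixel colors moving rigidly.
In the constant-on-constant configuration (LL) the background triplet is
resampled if it equals the object's, since an invisible object has no
defined label. Defaults are the full benchmark conditions (32×32 frames,
8 configurations, sizes 1–128, 500 pairs per direction per size, i.e.
4000 pairs per configuration and size).

It does **not** emulate sub-pixel or multi-pixel motion, occlusion,
lighting drift, sensor noise, deformable or multiple objects, or textured
natural backgrounds. Passing tests therefore demonstrate the mechanism on
clean rigid translation only and say nothing about natural video.

## Numerical choices

- Pattern compression: interior pixels of one frame pair reduce to unique
  27-bit binary patterns with multiplicities; all sums over pixels are
  computed as count-weighted sums over unique patterns. This is an exact
  reformulation, not an approximation, and makes training ~20× faster.
- Cross-entropy clamps the true-class probability at 1e-12 (with a
  warning) so degenerate fields give a large finite loss.
- The finite-difference oracle uses central differences at step 1e-5;
  comparisons use relative error with an absolute floor of 1e-10, the
  rounding noise floor of the difference quotient at float64.
- Checkpoints serialize float64 exactly (JSON via repr round-trip).
- Argmax ties break toward the smallest direction label,
  deterministically.
- Stratified splits shuffle within (configuration, size, direction) strata
  and round the training share per stratum, keeping direction balance to
  within one pair; a split that would empty either side of a stratum is an
  error.

## Problem sizes used in tests and acceptance runs

Desk scale for both experiment protocols: object sizes {8, 16, 32}, 100
pairs per direction per size, three seeded repetitions (the ratio
protocol pools all eight configurations, 19 200 pairs; cross-configuration
runs train on one configuration's 2 400 pairs with a stratified 75:25
self-holdout). Full benchmark conditions remain available behind
`--paper-scale`.

## Known limitations

- **Transfer signature.** The gated solution keys on object-side
  (vacated-pixel) motion evidence, which survives random backgrounds, so a
  DL-trained model transfers to DR at ≈ 100% rather than degrading.
  Conversely a DR-trained model meets constant (dark or light) test
  backgrounds as out-of-distribution input — their all-ones horizontal
  surround pattern was never constrained during training — and its
  per-direction response bias, multiplied by ~870 background pixels,
  swamps the evidence (DR→LD ≈ 60%, and DR→DL in the same range).
  Ungated training dynamics produce a different signature; which solution
  family gradient descent finds is a property of the optimization, not of
  the architecture, whose hand-set ideal parameters classify every
  configuration perfectly.
- Very small datasets (≤ 40 pairs) are not reliably fit by plain SGD at
  any setting tried; no momentum or adaptive optimizer is provided by
  design.
- The center gate is learnable in principle but loss-neutral (see above);
  if it is destroyed by prolonged training on data where it is redundant,
  out-of-distribution robustness degrades. Early stopping on the loss
  plateau mitigates this.
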