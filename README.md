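# avsmotion

A biomimetic *artificial visual system* (AVS) that detects the direction of
object motion in pairs of RGB frames, built from dendritic neuron models of
the early visual pathway: cone-cell channel separation, bipolar and
horizontal-cell On–Off responses, learnable dendritic ganglion neurons, and
fixed LGN integration across color channels. It is aimed at researchers in
computational neuroscience and biologically inspired vision who want a
small, interpretable, fully testable alternative to CNNs for
motion-direction classification — the whole model has 432 learnable
parameters.

## The model

Given two frames `x(t)` and `x(t+Δt)` (8-bit RGB, same size), each pixel
`(a,b)` of each channel `c` is binarized by two retinal mechanisms over its
3×3 receptive field (slots `i = 1..9` in reading order, `i = 5` the
center):

- **bipolar (vertical On–Off):** `B(a,b)^c = 1` iff
  `|x(a,b)^c(t) − x(a,b)^c(t+Δt)| > ε_V` — a temporal change detector;
- **horizontal (horizontal On–Off):** `H(a,b)_i^c = 1` iff
  `|x(a,b)^c(t) − x'_i(t+Δt)| < ε_H` — a spatial match between the center
  at `t` and neighbor `i` at `t+Δt`.

The 9-vector `x_i` (slot 5 from `B`, others from `H`) feeds one **dendritic
ganglion neuron** per direction `m = 1..8` and channel:

```
S_ij = σ((w_ij x_i − q_ij) / d)      synapse (excitatory / inhibitory /
b_j  = Π_i S_ij                       constant-1 / constant-0 states)
u    = Σ_j v_j b_j                    branch product, membrane sum
O    = σ(λ (u − θ))                   soma
```

The **LGN** requires joint activation of all three channels,
`M_m(a,b) = σ(λ_m (O^R O^G O^B − θ_m))`, and the readout sums over the
image, `D_m = Σ_{a,b} M_m(a,b)`, normalizes `D̄ = D / Σ_m D_m` and takes
the argmax. Only `w` and `q` are learned — by plain gradient descent on
the cross-entropy `E = −Σ_m T_m log D̄_m` with the exact chain rule through
every layer (verified against a central-finite-difference oracle to 1e-6).

The package also contains the synthetic moving-object benchmark the model
is evaluated on: a connected object of 1–128 pixels on a 32×32 background,
each drawn from {dark, constant ("light"), random} intensity categories
(configurations DL, DR, LD, LL, LR, RD, RL, RR), translating by one pixel
in one of 8 directions between frames.

## Worked example

```python
import numpy as np
from avsmotion import (DatasetSpec, generate_dataset, encode_dataset,
                       TrainConfig, train_model, evaluate_accuracy,
                       LGNParams, forward_field, stratified_split)

spec = DatasetSpec(configurations=("DL",), object_sizes=(8, 16, 32),
                   pairs_per_direction=100, seed=0)
pairs, manifest = generate_dataset(spec)
print(f"{len(pairs)} frame pairs, directions 1..8 balanced:",
      manifest.direction.value_counts().nunique() == 1)

encoded = encode_dataset(pairs)
train_idx, test_idx = stratified_split(encoded.meta, 0.75,
                                       np.random.default_rng(0))
train_ds, test_ds = encoded.subset(train_idx), encoded.subset(test_idx)
params, history = train_model(train_ds, TrainConfig(seed=0))
print(f"trained for {len(history)} epochs, "
      f"final loss {history.train_loss.iloc[-1]:.4f}")

lgn = LGNParams()
print(f"train accuracy {evaluate_accuracy(params, lgn, train_ds):.3f}, "
      f"test accuracy {evaluate_accuracy(params, lgn, test_ds):.3f}")

field = forward_field(pairs[0].frame_t, pairs[0].frame_t1, params)
print(f"true direction {pairs[0].direction_label}, "
      f"predicted {field.prediction}, "
      f"normalized direction outputs {np.round(field.D_norm, 3)}")
```

prints

```
2400 frame pairs, directions 1..8 balanced: True
trained for 100 epochs, final loss 2.0021
train accuracy 1.000, test accuracy 1.000
true direction 1, predicted 1, normalized direction outputs [0.134 0.124 0.122 0.127 0.122 0.125 0.122 0.124]
```

The normalized outputs sit close to 1/8 because every pixel contributes a
floor response to every direction; the *argmax* — here direction 1
(up-left) — carries the decision, and the trained model separates it
cleanly (100% train and held-out accuracy on this high-contrast
configuration).

## Command line

```bash
avsmotion generate --out data/ --configs DL --sizes 8,16,32 --pairs-per-direction 100 --seed 0
avsmotion train --data data/ --out model.json --log training.csv
avsmotion eval --data data/ --checkpoint model.json
avsmotion xval --train-config DL --out xval.csv        # cross-configuration validation
avsmotion ratio --splits 75:25,50:50,10:90,5:95 --out ratio.csv
avsmotion inspect --data data/ --index 0 --out maps.png  # On-Off activation maps
```

`xval` and `ratio` default to desk scale (object sizes {8, 16, 32}, 100
pairs per direction, 3 seeds); `--paper-scale` restores the full benchmark
conditions (sizes 1–128, 500 pairs per direction, 5 seeds), which takes
hours rather than minutes.

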