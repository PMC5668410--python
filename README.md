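# frameindex

Coordinate-frame identification from multivariate activity patterns.

When the forearm rotates from a pronated (Pro) to a midway (Mid)
posture, the preferred directions of wrist muscles rotate with it, while
the world outside does not move.  A brain region that encodes an aiming
direction can therefore represent it in an **extrinsic** frame (fixed to
the world; unaffected by the posture change), a **joint-like** frame
(rotating the full 90° with the joint), or a **muscle-like** frame in
between.  `frameindex` estimates where a region's code sits on this
continuum — its *coordinate index* Δθ̂ — from trial-by-feature response
matrices (e.g. multi-voxel fMRI patterns) recorded under both postures,
and provides the surrounding analyses: cosine-tuning fits of muscle
activity, posture-generalization decoding profiles, and circular group
statistics.  A synthetic population-code generator with a known
ground-truth frame rotation makes the entire pipeline testable end to
end without any recordings.

## The model

The aiming direction θ is encoded as the unit vector
**v** = (cos θ, sin θ).  A single *common decoder* **w** (2 × N, N =
number of features) must decode **v** from the patterns of both
postures at once, with the Mid readout rotated by a candidate angle Δθ:

```
v = w r_Pro = R(Δθ) w r_Mid ,    R(Δθ) = [[cos Δθ, −sin Δθ],
                                          [sin Δθ,  cos Δθ]]
```

For each Δθ on a grid (−45°…315°, 5° steps), **w** is fitted by
penalized linear regression on the stacked two-posture design and
scored by the nested-cross-validated mean squared error of the
predicted aiming vector.  The minimizer of this error curve is the
coordinate index Δθ̂: 0° = extrinsic, 90° = joint-like, intermediate =
muscle-like.  Complementary analyses: an 8-way linear SVM yields
within- and across-posture generalization profiles and an asymmetry
index (mean predicted-label fraction at +45/+90/+135° offsets minus
that at −45/−90/−135°); cosine fits f(θ) = k·cos(θ − µ) + b of muscle
activations yield preferred-direction shifts whose circular mean
defines the muscle-like frame.  See `docs/methods.md` for the full
treatment.

## Worked example

```python
import numpy as np
from frameindex import (
    SyntheticConfig, generate_dataset, zscore_volumes,
    CoordinateFrameModel, group_coordinate_index,
)

# a simulated 12-participant study whose true frame rotation is the
# empirically reported muscle angle, 58.8 degrees
cfg = SyntheticConfig(delta_theta_true=58.8, seed=1)
data = zscore_volumes(generate_dataset(cfg))

res = CoordinateFrameModel(data.for_participant(0)).fit()
print(res.summary())
```

```
Coordinate-frame estimate (rotation-model common decoder)
---------------------------------------------------------
participant                     0
estimator                   ridge
grid                   -45..315 deg, 73 points
outer folds                     8
delta_theta_hat           60.0 deg
min CV error               0.0105
alpha range chosen            100 .. 100
```

The per-participant estimate lands on the grid point nearest the true
rotation (60.0° vs 58.8°); the minimum cross-validated squared error of
the 2-D aiming-vector prediction is 0.0105 (the error of an
uninformative decoder predicting the mean target is 1.0).  At the
group level:

```python
ests = [CoordinateFrameModel(data.for_participant(p)).fit().delta_theta_hat
        for p in data.participants()]
print(group_coordinate_index(ests, references=(0.0, 90.0)).summary_text())
```

```
Group coordinate index
----------------------
participants              12
mean +/- 95% CI         60.0 +/- 0.0 deg
resultant length       1.000
test vs    0.0 deg   p = 9.999e-05
test vs   90.0 deg   p = 9.999e-05
```

At this noise level every participant's estimate quantizes to the same
5° grid point (hence the zero-width CI; see the grid-quantization note
in `docs/methods.md`).  The group mean recovers the simulated
muscle-like frame and the
circular one-sample tests reject both the extrinsic (0°) and joint
(90°) reference frames — the signature of an intermediate coordinate
frame.

A full staged run (simulate → decode → estimate → report) is available
as a library call (`run_experiment(RunConfig(...))`) or from the shell:

```
frameindex run --config demo.yaml
```

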