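# trajscale

Neural-trajectory geometry and temporal-scaling analysis of motor-cortex
population dynamics.

When a monkey makes planar reaching movements, the condition-averaged
activity of a motor-cortex population traces a low-dimensional trajectory
through state space. `trajscale` tests how that trajectory encodes two
independently specifiable movement parameters:

- **direction** — different reach directions map to *different* trajectories,
  separating monotonically with angular difference;
- **duration / speed** — different movement speeds map to the *same*
  trajectory traversed at different rates (**temporal scaling**), rather than
  to different trajectories (**geometry**).

The package provides the full analysis chain and the models to probe it:

| stage | module | what it does |
|---|---|---|
| synthetic sessions | `trajscale.synth` | seeded sequential-reach sessions: direction-tuned, duration-rescaled latents, Poisson spikes, bell-profile kinematics, ground truth |
| preprocessing | `trajscale.preprocess` | Gaussian smoothing (σ = median pooled ISI), 8 cm/s movement segmentation, 8×4 direction/duration (or 8×2 speed) condition averages, soft-normalization |
| subspace | `trajscale.subspace` | `CommonSubspace` (PCA at 80 % variance, sklearn fit/transform), marginalized variance fractions per task variable |
| trajectory geometry | `trajscale.trajgeo` | 600-bin rescaling, concatenated R² with split-half ceilings and cross-direction floors, Hausdorff-distance contrasts, separation time courses |
| duration decoder | `trajscale.decoder` | `TemporalScalingDurationDecoder`: nearest-point time indices, slope-based relative speed v, Duration_sample = v·Duration_ref |
| E/I network | `trajscale.rnn` | stability-optimised 200-unit rate network; input-rotation (direction) and time-constant (duration) experiments |
| orchestration | `trajscale.pipeline`, `trajscale.cli` | seeded end-to-end runs with manifests, property-check suite, `trajscale` CLI |

## The statistics at the core

For trajectories X, Y rescaled to a common 600-bin base (dimensions
concatenated):

```
R²(X, Y) = 1 − Σ(X − Y)² / Σ(X − X̄)²
```

with X̄ the time-mean point of X. R² = 1 is perfect matching; 0 matches only
as well as X's mean point; negative values mean magnitude mismatch.

For trajectories of different lengths, the Hausdorff distance

```
d_H(X, Y) = max{ sup_x inf_y d(x, y), sup_y inf_x d(x, y) }
```

compares point sets without any temporal alignment.

The decoder assumes a sample and a same-direction reference share one curve:
each sample point S_t is matched to its nearest reference point
(idx_t = argmin_u d(R(u), S_t)); the slope v of sample time regressed on
matched reference time gives Duration_sample = v · Duration_ref, and the
movement duration follows by subtracting the epoch's constant non-movement
time (500 ms PMd, 450 ms M1, 800 ms for untrimmed epochs).

## Worked example

```python
import trajscale as ts

cfg = ts.GeneratorConfig(n_trials=150, balanced_conditions=True,
                         latent_seed=1, spike_seed=2)
session = ts.generate_session(cfg)

tensor, spec, events = ts.preprocess_session(session)
space = ts.CommonSubspace().fit(tensor)          # PCA at 80 % variance
trajs = {t.condition: t for t in space.transform(tensor)}

r2 = ts.trajgeo.pairwise_scaled_r2(trajs)["r2"].mean()
_, contrast = ts.distance_contrasts(trajs, "duration")
bench = ts.decoder_benchmark(trajs, region="full")

print(f"sigma = {spec.sigma_ms:.0f} ms, D = {space.D_}")
print(f"scaled R2 (same direction, across durations) = {r2:.2f}")
print(f"Hausdorff: durations {contrast['mean_a']:.2f} "
      f"< adjacent directions {contrast['mean_b']:.2f}, p = {contrast['p']:.1e}")
print(f"decoded movement duration, median relative error = "
      f"{bench['rel_error_movement'].median():.1%}")
```

prints (seeds as above):

```
sigma = 43 ms, D = 4
scaled R2 (same direction, across durations) = 0.92
Hausdorff: durations 0.33 < adjacent directions 0.92, p = 8.5e-46
decoded movement duration, median relative error = 6.4%
```

Read: smoothing lands in the tens of milliseconds; four principal components
capture 80 % of the condition-averaged variance; same-direction trajectories
of different durations are nearly identical after temporal rescaling
(R² → 1), and are several times closer in Hausdorff distance than
trajectories of adjacent directions — so duration barely moves the
trajectory while direction does; and a decoder that *assumes* temporal
scaling recovers movement durations to within a few percent.

The RNN side of the story:

```python
from trajscale import rnn
model = rnn.build_stabilized_network(n=200, seed=0)   # E/I, gradient-stabilized
sweep = rnn.timeconstant_experiment(model)            # tau = 160/200/240 ms
print(sweep["durations_ms"])                          # [1878.0, 2106.0, 2346.0]
```

Trajectory durations grow with the network time constant while the rescaled
trajectory shape is preserved (scaled R² ≈ 0.99 between the extreme-τ runs
vs ≈ 0.66 unscaled): direction (via input rotation) and duration (via τ) are
controlled by independent network parameters.

A CLI wraps the same stages: `trajscale synth`, `trajscale preprocess`,
`trajscale subspace`, `trajscale decode`, `trajscale rnn-build`,
`trajscale rnn-run`, `trajscale pipeline run`, `trajscale pipeline accept`.

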