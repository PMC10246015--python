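# Methods

`trajscale` analyses how the low-dimensional population dynamics of motor
cortex encode the spatial (direction) and temporal (duration/speed) parameters
of planar reaching movements. The central scientific question it
operationalises is whether movement speed is encoded by *different*
state-space trajectories (the geometry hypothesis) or by *how quickly a fixed
trajectory is traversed* (the temporal-scaling hypothesis). The package
implements the full analysis chain on real-format inputs, a synthetic-session
generator that embodies (or falsifies) the temporal-scaling structure, and an
excitatory/inhibitory rate-network model showing that the two parameters can
be controlled by independent network knobs.

## Preprocessing

Per-unit spike trains are smoothed with a Gaussian kernel whose standard
deviation σ is the median of the population's pooled inter-spike intervals
(per-unit-median-of-medians is exposed as an option; pooling was chosen for
robustness with sparse units). Rates are sampled every 10 ms by default (the
behavioural/neural sampling rates of the original recordings are not part of
the data contract, so these are declared package defaults).

Movements are segmented from hand kinematics: onset is the first upward
crossing of an 8 cm/s hand-speed threshold after a target appears (the task is
self-paced, so there is no go cue), refined to sub-sample precision by linear
interpolation; the end is the entry of the hand into the 2 cm acceptance
window centred on the target. Movements are binned into 8 directions × 4
durations (edges 200/300/400/500/600 ms; bins closed on the left, the last bin
closed on both sides, so rounding a duration to its bin's upper edge is well
defined — a 240 ms movement is treated as ending 300 ms after onset).
Direction bins are 45° sectors centred on the cardinal/diagonal directions
(the bin phase is configurable; the centred-on-0° convention is declared, not
inferred). Per condition, activity from 500 ms before onset to 300 ms after
the (rounded) movement end is averaged across movements. Units with fewer
than 5 estimated spikes across all condition epochs are discarded, and each
remaining unit is soft-normalized by (firing-rate range + 5), which bounds
every normalized range strictly below 1.

The speed variant restricts movements to a 4–6 cm distance window (to break
the strong speed–distance coupling), splits them at the session's median
maximum speed, linearly rescales each movement's epoch to the grand-median
duration (the reference duration is otherwise unspecified, so the median was
chosen), and averages into 8 directions × 2 speeds.

## Common subspace and marginalized variance

The common subspace is PCA fitted on all conditions' averaged, normalized
activity concatenated in time (no temporal rescaling is needed: PCA is
indifferent to trajectory length). The dimensionality D is the smallest
number of leading components explaining ≥ 80 % of variance. Centering uses
the grand mean over all conditions and times.

`marginalized_variance` linearly rescales every condition to 600 time bins
and decomposes the tensor X[direction, duration, unit, time] into additive
marginal means: condition-independent (time only), direction × time,
duration × time, and the interaction residual. On the balanced grid these
marginals are orthogonal, so their variances partition the total exactly
(fractions sum to 1). This is the marginalization step underlying demixed
PCA without the demixing projections — a deliberate simplification; the
package makes no claims that require the full demixed solver, only variance
fractions per task variable.

## Trajectory geometry

*Rescaling and similarity.* Trajectories are rescaled to 600 time bins by
linear interpolation. Similarity between two rescaled trajectories X, Y is
the coefficient of determination on the concatenated-dimension vectors,
R² = 1 − Σ(X−Y)² / Σ(X−X̄)², where X̄ is X's time-mean point taken per
dimension. The per-dimension mean (rather than a scalar grand mean) makes
R² invariant to a common rotation of both trajectories in the subspace, which
a geometry statistic should be; every 1-D reference value is unchanged by
this choice. R² = 1 is perfect matching, 0 matches as well as the baseline
mean point, negative values indicate magnitude mismatch. The statistic is
asymmetric in (X, Y); by convention the first argument supplies the baseline,
and pairwise summaries average both orderings.

A *ceiling* on attainable similarity is estimated by repeatedly splitting
each condition's movements into random halves, averaging and projecting each
half, and computing R² between the two split trajectories (floor(n/2)
repeats per condition, pooled across conditions). A *floor* is the R²
between unscaled equal-length trajectories of the same duration but different
directions.

*Distances.* The Hausdorff distance (maximum over either set of the minimum
Euclidean distance to the other) compares trajectories of different lengths
without any alignment. The duration contrast compares each trajectory's
distance to the 3 other durations of its direction (96 directed pairs)
against its distance to the 2 adjacent directions at the same duration (64
directed pairs), with a one-sided Welch t-test (the test's flavour is a
package choice; only "t-test" is inherited). The speed contrast is the same
construction over 2 speed bins (16 vs 32 directed pairs).

*Separation time course.* For the 8 same-duration direction trajectories on
a common time axis, the profile is the mean over all 28 pairs of the
pointwise distance, normalized by the maximum pointwise pairwise distance of
the population. Landmarks: the pre-onset minimum (ties resolved toward the
latest minimizer, i.e. the divergence point when the profile is flat before
separating), the global maximum (first maximizer), and the post-onset minimum
(earliest minimizer — the reconvergence point). Regional analysis epochs
(PMd: −450 ms to end+50 ms; M1: −250 ms to end+200 ms) are exposed as a trim
applied before the geometry statistics.

## Duration decoder

Under temporal scaling, a sample trajectory and a same-direction reference
trace the same curve, so each sample point has a nearest reference point
(Euclidean, ties to the smallest index). Regressing sample time on matched
reference time (OLS with intercept; the slope alone is the relative speed v —
the only orientation dimensionally consistent with
Duration_sample = v · Duration_ref) yields the predicted trajectory duration
v · Duration_ref, from which the movement duration follows by subtracting the
constant non-movement time inside the epoch: 500 ms for PMd-trimmed epochs,
450 ms for M1-trimmed epochs, 800 ms for untrimmed preprocessing epochs
(−500/+300 ms). The benchmark uses the 8 trajectories of the 300–400 ms bin
as references and decodes the other 24 conditions. Cross-direction
references are supported only as the falsification control: decode error
should grow with the angular difference between sample and reference.

## Synthetic sessions

The generator emulates the self-paced sequential-reach task: 4 targets per
trial in a 20 × 20 cm workspace, target distances 5–15 cm at arbitrary
angles, target appearance 196 ms after the previous target is reached,
≥ 100 ms holds. Hand speed follows a parabolic bell profile; movement
durations are sampled lognormally around 180 + 14·distance ms (σ_log = 0.16),
clipped to what the 8 cm/s threshold makes kinematically realizable. These
choices reproduce the recorded behaviour's structure: maximum speed strongly
correlated with distance (r ≈ 0.8) and duration only moderately so
(r ≈ 0.6), with long durations rarer than short ones. A `balanced_conditions`
mode instead cycles deterministically through the 32 direction × duration
bins (with centre-biased filler reaches when workspace geometry blocks a
pending bin) so that compact test sessions populate every condition; the
random mode remains the task-faithful default.

Latent structure: each movement's analysis epoch carries n_latents smooth
latent curves in epoch phase. Latent 0 is condition-invariant — a monotone
ramp plus a mild bump, untapered, which keeps the population state-space
curve injective (real condition-invariant components are similarly dominant
and directional in time; without an injective backbone, nearest-point
matching at the converged epoch edges would be degenerate by construction
rather than by data). Latents k ≥ 1 are sums of 2–4 Gaussian bumps with
amplitudes cosine-tuned to per-latent preferred directions and tapered to
zero at the epoch edges, producing monotone separation-vs-angle structure
and reconvergence at the epoch boundaries. With `temporal_scaling_exact`,
the latent phase spans the whole epoch (−500 ms to end+300 ms) and rescales
with its total length, so trajectories of different durations are exact time
rescalings; `geometry_perturbation` > 0 instead shifts bump centres and
amplitudes with duration, creating the falsifiable geometry alternative.
Because the *entire* epoch rescales, exactness holds on full epochs; regional
trims cut fixed-millisecond windows that correspond to slightly different
phase windows across durations, so synthetic decoding defaults to full epochs
with the 800 ms non-movement constant, while the PMd/M1 constants are
exercised on constructed cases.

Unit rates are `base_rate + rate_gain · (loading · latents)` with unit-norm
loading rows rescaled so each unit's peak latent drive is 1; rates then span
exactly [base−gain, base+gain] and positivity reduces to gain ≤ base (a
config whose rates would go negative is rejected). Defaults (40 units,
base 15 spikes/s, gain 13 spikes/s) put the pooled median-ISI σ at ~44 ms,
inside the 36–86 ms range of the recorded populations, with modulation depths
deep enough that condition averages over ~15–20 movements support decoding.
Spikes are Poisson-thinned at 1 ms resolution — finer than any smoothing
bandwidth used downstream. Inter-movement timing is stretched (≥ ~850 ms
between one movement's end and the next onset) so analysis epochs never
overlap; the real task is faster-paced, and this is the one deliberate
departure from its temporal statistics. Ground truth (onset, end, direction,
duration, scaling factor) is stored beside the data and never consumed by the
analysis stages.

What passing tests on these sessions do *not* show: the generator has no
inter-neuron noise correlations, no biomechanical arm model, no failed
trials, linear rate-latent coupling, and i.i.d. Poisson variability — so the
pipeline's performance here bounds only its behaviour under this noise model,
not under real recording artefacts.

## E/I rate network

The simulator integrates τ dx/dt = −x + p·I(t) + W·Δr(x) for n = 200 units
(100 excitatory / 100 inhibitory columns by sign), with the saturating rate
deviation Δr(x) = r0·tanh(x/r0) for x ≤ 0 and (rmax−r0)·tanh(x/(rmax−r0)) for
x > 0 (r0 = 5 Hz, rmax = 70 Hz; unit slope at 0). The input is a 1 s
saturating exponential ramp (200 ms constant) followed by a 200 ms decay with
a 0.1 ms constant, starting at t = 1 s in a 4 s simulation; the input
amplitude (default 5, dimensionless) is a free parameter chosen so rates stay
well inside (0, rmax). Integration is fixed-step explicit midpoint (RK2) at
dt = 0.5 ms; the stiff input decay is evaluated analytically, never
integrated. Halving dt changes trajectories by ~0.01 % RMS, and
small-amplitude simulations match a tightly-tolerated linear-ODE solution to
~0.02 % RMS.

Stabilization: initial weights are half-normal (excitatory) and
negative-half-normal (inhibitory), balanced in mean, scaled to an unstable
spectral abscissa ≈ 2.5. The default method performs gradient descent on the
smoothed spectral abscissa of W − I (the Lyapunov-based smoothed measure;
gradient Q·P/tr(QP) of the shifted Gramians, verified against finite
differences) over the inhibitory entries only, with Dale signs enforced by
clipping and a backtracking line search, until the abscissa falls below −0.2.
The descent anneals the smoothing ε when progress stalls; the occasional
initial draw that still stalls above the target is discarded and re-drawn
deterministically from the same seeded stream (most draws converge in a few
iterations). This yields stable, strongly non-normal networks with
inhibition fine-tuned against excitation. A crude fallback (`method="scale"`) shrinks the whole
matrix by the closed-form factor placing the abscissa at the target; pure
inhibitory-gain scaling cannot stabilize a dense random E/I matrix because
stronger inhibition also inflates the spectral bulk.

Direction analog: the input projection p (uniform on [−1, 1], or [0, 1] for
the excitatory-only variant) is rotated by a common angle in each consecutive
2-D coordinate plane (an exact isometry; rotations compose additively);
10 rotations span 360°, PCA across the 10 runs defines the output subspace,
and the mean pairwise trajectory distance grows monotonically with rotation
angle. Duration analog: with p fixed, the time constant is swept over
τ ∈ {160, 200, 240} ms; each trajectory's duration is the time from input
onset to its first re-entry — after the maximal excursion — into a hypersphere
centred on the mean pre-input state with radius the 20th percentile of
pairwise distances among trajectory points (within- and across-run distances
pooled; the percentile basis is ambiguous and this pooling is declared).
Durations increase strictly with τ. Shape preservation is quantified on the
autonomous segment of each trajectory (maximal excursion → return): the early
rise is locked to the input's absolute time course and is therefore shared,
not rescaled, across τ values; on the autonomous segment the rescaled R²
(~0.99) far exceeds the unscaled R² (~0.4–0.7).

## Numerical and design notes

- All RNG is through `numpy.random.Generator` with explicit seeds; the
  pipeline fans a single master seed out to named per-stage seeds recorded in
  the run manifest, and re-running a manifest's config reproduces outputs
  byte-for-byte.
- Nearest-point ties in the decoder go to the smallest reference index;
  decoder fits with non-positive v are flagged invalid rather than reported.
- Degenerate inputs raise informative errors: empty point sets (Hausdorff),
  constant baselines (R²), single-sample trajectories (rescaling), < 2 spikes
  (σ estimation), all-units-filtered tensors, unit mismatches in projection.
- Problem sizes in the test-suite and acceptance runs (e.g. 150-trial
  balanced sessions, 3 network realizations in the quick profile, 20 in the
  full profile) are the package's declared study sizes for synthetic
  verification; estimates stabilize well below these sizes.
- Known limitations: no dPCA demixing projections; no cross-population
  (CCA-style) statistics; no single-trial decoding; the RNN is one region,
  not a PMd–M1 pair.
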