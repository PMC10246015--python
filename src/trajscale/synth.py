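"""Synthetic motor-cortex session generator.

Emulates self-paced sequential-reach sessions: a monkey-style task where four
targets appear one after another in a 20 x 20 cm workspace, the hand moves
between them with bell-shaped speed profiles, and a population of units fires
Poisson spikes driven by low-dimensional latent trajectories.

The latent structure embodies the temporal-scaling hypothesis: each movement
direction has a fixed latent curve, and movements of different durations
traverse that same curve at a rate inversely proportional to the analysis-epoch
length (``temporal_scaling_exact``).  Setting ``geometry_perturbation > 0``
instead injects duration-dependent shape changes, giving a falsifiable
alternative for the downstream geometry statistics.

Ground truth (true onset/end, direction, duration, latent scaling factor) is
stored alongside the raw data and is never consumed by the analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

# Task constants (movement segmentation convention shared with preprocess)
ONSET_SPEED_THRESHOLD = 8.0     # cm/s, hand-speed threshold defining movement onset
TARGET_WINDOW_HALF_CM = 1.0     # acceptance window is a 2 cm square centred on target
TARGET_APPEAR_DELAY_S = 0.196   # next target appears 196 ms after reaching the previous
MIN_HOLD_S = 0.100              # required hold on a target

# Analysis epoch around each movement (ms): onset-500 .. end+300
PRE_EPOCH_MS = 500.0
POST_EPOCH_MS = 300.0

# Nominal reference epoch used to express the latent time-scaling factor:
# a 400 ms movement has epoch length 400 + 800 = 1200 ms.
REFERENCE_EPOCH_MS = 1200.0

SPIKE_DT_S = 0.001              # Poisson thinning resolution


class RateUnderflowError(ValueError):
    """Raised when the configured rate gain drives unit rates negative."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Defaults emulate the recorded populations: 24-95 units per population,
    reaches spanning 0-360 degrees, durations 200-600 ms, and pooled
    inter-spike-interval medians landing in the tens of milliseconds.
    """

    n_units: int = 40
    n_latents: int = 4
    n_trials: int = 100                      # trials of 4 reaches each
    direction_set: Sequence[float] | None = None   # None -> continuous U[0, 360)
    duration_range: tuple[float, float] = (220.0, 580.0)  # ms, measured onset->end
    workspace_extent: float = 20.0           # cm, square workspace side
    base_rate: float = 15.0                  # spikes/s baseline per unit
    rate_gain: float = 13.0                  # spikes/s peak latent modulation
    kinematics_rate: float = 100.0           # hand-position samples/s
    spike_seed: int = 0
    latent_seed: int = 1
    temporal_scaling_exact: bool = True
    geometry_perturbation: float = 0.0       # dimensionless; >0 breaks exact scaling
    balanced_conditions: bool = False        # cycle the 32 direction x duration bins

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_latents < 1:
            raise ValueError("n_latents must be >= 1")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        lo, hi = self.duration_range
        if not (200.0 <= lo < hi <= 600.0):
            raise ValueError("duration_range must lie within [200, 600] ms")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.direction_set is not None:
            angles = np.asarray(self.direction_set, dtype=float)
            if angles.size == 0 or np.any(angles < 0) or np.any(angles >= 360):
                raise ValueError("direction_set angles must lie in [0, 360)")
        if self.geometry_perturbation < 0:
            raise ValueError("geometry_perturbation must be >= 0")


@dataclass
class SessionRecording:
    """One synthetic population recording: spikes, kinematics, task events."""

    unit_spike_times: list[np.ndarray]       # seconds, non-decreasing per unit
    hand_times: np.ndarray                   # seconds, uniform
    hand_position: np.ndarray                # (n_samples, 2) cm
    target_events: pd.DataFrame              # trial, reach, t_appear, target_x/y
    ground_truth: pd.DataFrame | None        # per-movement truth (synthetic only)
    config: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        for i, st in enumerate(self.unit_spike_times):
            if st.size > 1 and np.any(np.diff(st) < 0):
                raise ValueError(f"spike times of unit {i} are not non-decreasing")


# ---------------------------------------------------------------------------
# Latent curve family
# ---------------------------------------------------------------------------

@dataclass
class LatentFamily:
    """Per-direction latent curves: sums of smooth bumps in trajectory phase.

    Latent 0 is condition-independent; latents k >= 1 are cosine-tuned to a
    preferred direction, so the separation between direction trajectories grows
    monotonically with angular difference.
    """

    centers: list[np.ndarray]        # bump centres in phase (0, 1), per latent
    widths: list[np.ndarray]
    amplitudes: list[np.ndarray]     # signed bump amplitudes
    preferred_dir_deg: np.ndarray    # per latent; latent 0 untuned
    loading: np.ndarray              # (n_units, n_latents), unit-norm rows

    @property
    def n_latents(self) -> int:
        return len(self.centers)


def _edge_taper(s: np.ndarray, frac: float = 0.12) -> np.ndarray:
    """Raised-cosine taper to zero over the first/last `frac` of phase."""
    t = np.ones_like(s)
    lo = s < frac
    hi = s > 1 - frac
    t[lo] = 0.5 * (1 - np.cos(np.pi * s[lo] / frac))
    t[hi] = 0.5 * (1 - np.cos(np.pi * (1 - s[hi]) / frac))
    return t


def make_latent_family(config: GeneratorConfig) -> LatentFamily:
    rng = np.random.default_rng(config.latent_seed)
    K = config.n_latents
    centers, widths, amps = [], [], []
    for _ in range(K):
        nb = int(rng.integers(2, 5))         # 2-4 bumps
        c = np.sort(rng.uniform(0.18, 0.82, nb))
        w = rng.uniform(0.06, 0.12, nb)
        a = rng.uniform(0.5, 1.0, nb) * rng.choice([-1.0, 1.0], nb)
        centers.append(c)
        widths.append(w)
        amps.append(a)
    # latent 0 carries the dominant condition-invariant component as a
    # monotone ramp (plus a mild bump), keeping the state-space curve
    # injective so nearest-point matching along it is well defined
    centers[0] = np.array([rng.uniform(0.4, 0.6)])
    widths[0] = np.array([rng.uniform(0.10, 0.16)])
    amps[0] = np.array([rng.uniform(0.25, 0.4) * rng.choice([-1.0, 1.0])])
    pref = (np.arange(K) * 360.0 / max(K - 1, 1) + rng.uniform(0, 30, K)) % 360.0
    pref[0] = np.nan                         # latent 0 is condition-independent
    loading = rng.normal(size=(config.n_units, K))
    loading /= np.linalg.norm(loading, axis=1, keepdims=True)
    family = LatentFamily(centers, widths, amps, pref, loading)

    # normalize each unit's latent drive to unit peak magnitude, so rates
    # span exactly [base_rate - rate_gain, base_rate + rate_gain] and the
    # positivity condition reduces to rate_gain <= base_rate
    phase = np.linspace(0.0, 1.0, 241)
    gp = 0.0 if config.temporal_scaling_exact else config.geometry_perturbation
    peak = np.zeros(config.n_units)
    durs = (400.0,) if gp == 0 else tuple(np.arange(200.0, 601.0, 40.0))
    for theta in np.arange(0.0, 360.0, 7.5):
        for dur in durs:
            lat = latent_curves(family, theta, phase, dur, gp)
            peak = np.maximum(peak, np.abs(loading @ lat.T).max(axis=1))
    loading /= (1.02 * np.maximum(peak, 1e-12))[:, None]
    return family


def latent_curves(
    family: LatentFamily,
    direction_deg: float,
    phase: np.ndarray,
    duration_ms: float = 400.0,
    geometry_perturbation: float = 0.0,
) -> np.ndarray:
    """Evaluate the latent curves for one direction at phases in [0, 1].

    Returns (len(phase), n_latents).  With ``geometry_perturbation = 0`` the
    curve depends only on direction, so movements of different durations are
    exact time-rescalings of one another.  With a positive perturbation, bump
    centres and amplitudes shift with movement duration, changing the
    trajectory's shape (the "geometry" alternative).
    """
    phase = np.asarray(phase, dtype=float)
    out = np.zeros((phase.size, family.n_latents))
    taper = _edge_taper(phase)
    dur_dev = (duration_ms - 400.0) / 200.0          # in [-1, 1] over 200-600 ms
    for k in range(family.n_latents):
        if k == 0 or np.isnan(family.preferred_dir_deg[k]):
            tune = 1.0
        else:
            dtheta = np.deg2rad(direction_deg - family.preferred_dir_deg[k])
            tune = np.cos(dtheta)
        c = family.centers[k]
        w = family.widths[k]
        a = family.amplitudes[k]
        if geometry_perturbation > 0:
            c = np.clip(c + geometry_perturbation * 0.15 * dur_dev
                        * np.sin(2 * np.pi * c), 0.05, 0.95)
            a = a * (1.0 + geometry_perturbation * 0.5 * dur_dev)
        bumps = np.sum(
            a[None, :] * np.exp(-0.5 * ((phase[:, None] - c[None, :]) / w[None, :]) ** 2),
            axis=1,
        )
        if k == 0:
            # condition-invariant ramp + mild bump, untapered: keeps the
            # population state-space curve injective over the epoch
            out[:, 0] = 1.1 * (phase - 0.5) + bumps
        else:
            out[:, k] = tune * bumps * taper
    return out


def unit_rates_for_epoch(
    family: LatentFamily,
    config: GeneratorConfig,
    direction_deg: float,
    duration_ms: float,
    phase: np.ndarray,
) -> np.ndarray:
    """Noise-free unit firing rates (n_units, len(phase)) on one epoch."""
    lat = latent_curves(
        family, direction_deg, phase, duration_ms,
        0.0 if config.temporal_scaling_exact else config.geometry_perturbation,
    )
    rates = config.base_rate + config.rate_gain * (family.loading @ lat.T)
    return rates


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _bell_speed(s: np.ndarray, distance: float, t_full: float) -> np.ndarray:
    """Parabolic bell speed profile: v(s) = 6 d/T s (1-s), peak 1.5 d/T."""
    return 6.0 * distance / t_full * s * (1 - s)


def _bell_path(s: np.ndarray, distance: float) -> np.ndarray:
    """Cumulative path length of the bell profile at phase s."""
    return distance * (3 * s**2 - 2 * s**3)


def generate_speed_profile(
    distance_cm: float, duration_ms: float, sample_rate: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Bell-shaped hand-speed profile covering `distance_cm` in `duration_ms`.

    Returns (times_s, speed_cm_s).  The time-integral of speed equals the
    distance to within 0.1 %.  Raises if the profile would be physiologically
    absurd (peak > 200 cm/s) or never crosses the 8 cm/s onset threshold.
    """
    if distance_cm <= 0 or duration_ms <= 0:
        raise ValueError("distance and duration must be positive")
    t_full = duration_ms / 1000.0
    peak = 1.5 * distance_cm / t_full
    if peak > 200.0:
        raise ValueError(
            f"infeasible profile: peak speed {peak:.1f} cm/s exceeds 200 cm/s")
    if peak <= ONSET_SPEED_THRESHOLD:
        raise ValueError(
            f"infeasible profile: peak speed {peak:.2f} cm/s never crosses "
            f"the {ONSET_SPEED_THRESHOLD} cm/s onset threshold")
    n = max(int(round(t_full * sample_rate)) + 1, 3)
    t = np.linspace(0.0, t_full, n)
    v = _bell_speed(t / t_full, distance_cm, t_full)
    return t, v


def _onset_phase(distance: float, t_full: float) -> float | None:
    """Phase where the bell profile first crosses the onset threshold."""
    q = ONSET_SPEED_THRESHOLD * t_full / (6.0 * distance)  # s(1-s) at crossing
    if q <= 0 or q > 0.25:
        return None
    return float((1 - np.sqrt(1 - 4 * q)) / 2)


def _entry_phase(distance: float, entry_radius: float) -> float:
    """Phase where the remaining distance to target equals `entry_radius`."""
    from scipy.optimize import brentq

    target = distance - entry_radius
    return float(brentq(lambda s: _bell_path(np.array([s]), distance)[0] - target,
                        1e-9, 1.0 - 1e-9, xtol=1e-12))


def _measured_duration_s(t_full: float, distance: float, s_end: float) -> float:
    s_on = _onset_phase(distance, t_full)
    if s_on is None:
        return 0.0
    return t_full * (s_end - s_on)


def _solve_full_duration(
    distance: float, entry_radius: float, target_measured_s: float
) -> tuple[float, float, float] | None:
    """Find the full profile duration whose measured (onset->entry) duration
    equals `target_measured_s`.  Returns (t_full, s_on, s_end) or None."""
    from scipy.optimize import brentq

    s_end = _entry_phase(distance, entry_radius)
    t_max = 1.5 * distance / ONSET_SPEED_THRESHOLD    # peak == threshold
    grid = np.linspace(0.05, t_max * 0.999, 60)
    meas = np.array([_measured_duration_s(t, distance, s_end) for t in grid])
    k = int(np.argmax(meas))
    if meas[k] < target_measured_s:
        return None
    # ascending branch: smallest t_full bracketing the target
    lo_idx = 0
    for i in range(k + 1):
        if meas[i] >= target_measured_s:
            lo_idx = i
            break
    a = grid[max(lo_idx - 1, 0)]
    b = grid[lo_idx] if meas[lo_idx] >= target_measured_s else grid[k]
    if a == b:
        a = grid[0] * 0.5
    t_full = float(brentq(
        lambda t: _measured_duration_s(t, distance, s_end) - target_measured_s,
        a, b, xtol=1e-9))
    s_on = _onset_phase(distance, t_full)
    return t_full, float(s_on), s_end


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

DURATION_BIN_EDGES_MS = np.array([200.0, 300.0, 400.0, 500.0, 600.0])


def _duration_bin(duration_ms: float) -> int:
    """0-3 for [200,300), [300,400), [400,500), [500,600]; -1 outside."""
    if duration_ms < 200.0 or duration_ms > 600.0:
        return -1
    return min(int((duration_ms - 200.0) // 100.0), 3)


def _reach_geometry(
    rng: np.random.Generator, pos: np.ndarray, ws: float,
    direction: float, distance: float,
) -> tuple[np.ndarray, float] | None:
    """Target position and acceptance-window entry radius, or None if the
    target falls outside the workspace."""
    u = np.array([np.cos(np.deg2rad(direction)), np.sin(np.deg2rad(direction))])
    target = pos + distance * u
    margin = 0.5
    if not (margin <= target[0] <= ws - margin
            and margin <= target[1] <= ws - margin):
        return None
    entry_r = TARGET_WINDOW_HALF_CM / max(abs(u[0]), abs(u[1]))
    return target, entry_r


def _sample_reach(
    rng: np.random.Generator, config: GeneratorConfig,
    pos: np.ndarray, pending: list[tuple[int, int]] | None,
) -> tuple[float, float, float, np.ndarray, tuple[float, float, float]]:
    """Sample a feasible reach from the current hand position.

    Returns (direction_deg, distance_cm, duration_ms, target,
    (t_full, s_on, s_end)).  Durations are tied to reach distance — longer
    movements require longer reaches, as in the recorded behaviour where
    maximum speed scales with distance — and a reach is only accepted if the
    bell profile can realize the requested onset-to-window-entry duration.
    In balanced mode the pending direction x duration bins are consumed in
    deficit order, falling back to whichever pending bin is feasible from the
    current position.
    """
    lo, hi = config.duration_range
    if pending is not None:
        counts: dict[tuple[int, int], int] = {}
        for b in pending:
            counts[b] = counts.get(b, 0) + 1
        order = sorted(counts, key=lambda b: -counts[b])
        for dbin, ubin in order:
            b_lo = max(200.0 + 100.0 * ubin + 12.0, lo)
            b_hi = min(300.0 + 100.0 * ubin - 12.0, hi)
            for _ in range(40):
                duration = rng.uniform(b_lo, max(b_hi, b_lo + 1.0))
                d_min = 12.5 * duration / 1000.0 + 1.8
                direction = (dbin * 45.0 + rng.uniform(-20.0, 20.0)) % 360.0
                distance = rng.uniform(d_min, min(14.5, d_min + 4.0))
                geo = _reach_geometry(rng, pos, config.workspace_extent,
                                      direction, distance)
                if geo is None:
                    continue
                target, entry_r = geo
                sol = _solve_full_duration(distance, entry_r, duration / 1000.0)
                if sol is not None:
                    pending.remove((dbin, ubin))
                    return direction, distance, duration, target, sol
        # no pending bin reachable from here: fall through to a filler reach
        # biased back toward the workspace centre (does not consume the queue)
    center_bias = pending is not None
    for _ in range(400):
        if center_bias:
            to_center = np.rad2deg(np.arctan2(
                config.workspace_extent / 2 - pos[1],
                config.workspace_extent / 2 - pos[0]))
            direction = float((to_center + rng.uniform(-60.0, 60.0)) % 360.0)
        elif config.direction_set is not None:
            direction = float(rng.choice(np.asarray(config.direction_set,
                                                    float)))
        else:
            direction = float(rng.uniform(0.0, 360.0))
        distance = float(rng.uniform(4.5, 14.5))
        geo = _reach_geometry(rng, pos, config.workspace_extent,
                              direction, distance)
        if geo is None:
            continue
        target, entry_r = geo
        # longest onset-to-entry duration this distance can realize given the
        # 8 cm/s threshold, and a lognormal duration rising mildly with
        # distance (keeps max speed strongly distance-scaled, duration only
        # moderately so, as in the recorded behaviour)
        dur_cap = (92.0 * distance - 155.0) * 0.95
        d_hi = min(hi, dur_cap)
        if d_hi <= lo + 5.0:
            continue
        mu = 180.0 + 14.0 * distance
        duration = float(np.clip(
            np.exp(rng.normal(np.log(mu), 0.16)) , lo, d_hi))
        sol = _solve_full_duration(distance, entry_r, duration / 1000.0)
        if sol is not None:
            return direction, distance, duration, target, sol
    raise RuntimeError("could not sample a feasible reach")


def generate_session(config: GeneratorConfig) -> SessionRecording:
    """Generate one seeded synthetic session.

    Two independent RNG streams: ``latent_seed`` drives latent structure and
    task randomness, ``spike_seed`` drives Poisson thinning, so the same task
    can be re-spiked independently.
    """
    family = make_latent_family(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.latent_seed, 7]))
    rng_spk = np.random.default_rng(config.spike_seed)
    kin_dt = 1.0 / config.kinematics_rate
    ws = config.workspace_extent

    pending = None
    if config.balanced_conditions:
        n_total = config.n_trials * 4
        bins = [(d, u) for d in range(8) for u in range(4)]
        pending = [bins[i % 32] for i in range(n_total)]
        rng.shuffle(pending)

    movements: list[dict] = []
    events: list[dict] = []
    pos = np.array([ws / 2, ws / 2])
    t = 0.5
    n_target = config.n_trials * 4
    m_idx = 0
    while (pending if config.balanced_conditions else m_idx < n_target):
        if m_idx >= 3 * n_target:
            raise RuntimeError("balanced sampling did not converge")
        trial, reach = divmod(m_idx, 4)
        direction, distance, duration_ms, target, sol = _sample_reach(
            rng, config, pos, pending)
        t_full, s_on, s_end = sol

        t_appear = t
        rt = rng.uniform(0.65, 0.85)     # self-paced reaction + hold margin
        move_start = t_appear + rt
        onset = move_start + t_full * s_on
        end = move_start + t_full * s_end

        events.append(dict(trial=trial, reach=reach, t_appear=t_appear,
                           target_x=target[0], target_y=target[1],
                           success=True))
        meas_dur_ms = (end - onset) * 1000.0
        epoch_ms = meas_dur_ms + PRE_EPOCH_MS + POST_EPOCH_MS
        movements.append(dict(
            trial=trial, reach=reach,
            move_start=move_start, t_full=t_full,
            onset=onset, end=end,
            direction_deg=direction,
            duration_ms=meas_dur_ms,
            distance_cm=float(_bell_path(np.array([s_end]), distance)[0]
                              - _bell_path(np.array([s_on]), distance)[0]),
            full_distance_cm=distance,
            max_speed_cm_s=1.5 * distance / t_full,
            start_x=pos[0], start_y=pos[1],
            target_x=target[0], target_y=target[1],
            scaling_factor=epoch_ms / REFERENCE_EPOCH_MS,
            duration_bin=_duration_bin(meas_dur_ms),
        ))
        m_idx += 1
        pos = target
        t = end + TARGET_APPEAR_DELAY_S
        if reach == 3:
            t += 0.5                          # inter-trial interval

    t_end = t + 1.0 if movements else 0.0
    times = np.arange(0.0, t_end, kin_dt)

    # hand position: hold at targets, bell-profile along each reach
    hand = np.empty((times.size, 2))
    cur = np.array([ws / 2, ws / 2])
    hand[:] = cur
    for mv in movements:
        u = np.array([mv["target_x"] - mv["start_x"],
                      mv["target_y"] - mv["start_y"]])
        d = np.linalg.norm(u)
        u = u / d if d > 0 else u
        i0 = int(np.searchsorted(times, mv["move_start"]))
        i1 = int(np.searchsorted(times, mv["move_start"] + mv["t_full"]))
        seg = times[i0:i1]
        s = np.clip((seg - mv["move_start"]) / mv["t_full"], 0.0, 1.0)
        path = _bell_path(s, mv["full_distance_cm"])
        start = np.array([mv["start_x"], mv["start_y"]])
        hand[i0:i1] = start[None, :] + path[:, None] * u[None, :]
        hand[i1:] = np.array([mv["target_x"], mv["target_y"]])

    # unit rates at 1 ms resolution, Poisson-thinned to spikes
    n_spike_bins = int(np.ceil(t_end / SPIKE_DT_S))
    rates = np.full((config.n_units, n_spike_bins), config.base_rate,
                    dtype=np.float32)
    spike_t = (np.arange(n_spike_bins) + 0.5) * SPIKE_DT_S
    for mv in movements:
        e0 = mv["onset"] - PRE_EPOCH_MS / 1000.0
        e1 = mv["end"] + POST_EPOCH_MS / 1000.0
        j0 = max(int(np.searchsorted(spike_t, e0)), 0)
        j1 = min(int(np.searchsorted(spike_t, e1)), n_spike_bins)
        if j1 <= j0:
            continue
        phase = (spike_t[j0:j1] - e0) / (e1 - e0)
        rates[:, j0:j1] += unit_rates_for_epoch(
            family, config, mv["direction_deg"], mv["duration_ms"], phase
        ).astype(np.float32) - config.base_rate

    if rates.size and float(rates.min()) < 0.0:
        raise RateUnderflowError(
            f"rate_gain={config.rate_gain} drives rates to {rates.min():.2f} "
            "spikes/s; reduce the gain or raise base_rate")

    unit_spikes: list[np.ndarray] = []
    if n_spike_bins:
        p_spike = rates * SPIKE_DT_S
        for uix in range(config.n_units):
            draws = rng_spk.random(n_spike_bins)
            unit_spikes.append(spike_t[draws < p_spike[uix]])
    else:
        unit_spikes = [np.empty(0) for _ in range(config.n_units)]

    gt = pd.DataFrame(movements) if movements else None
    ev = pd.DataFrame(events, columns=["trial", "reach", "t_appear",
                                       "target_x", "target_y", "success"])
    return SessionRecording(
        unit_spike_times=unit_spikes,
        hand_times=times,
        hand_position=hand,
        target_events=ev,
        ground_truth=gt,
        config=config,
    )


# ---------------------------------------------------------------------------
# Noise-free condition tensors (ground-truth shortcut for tests/oracles)
# ---------------------------------------------------------------------------

def ideal_condition_epoch(
    config: GeneratorConfig,
    family: LatentFamily,
    direction_deg: float,
    duration_ms: float,
    dt_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free unit rates on the analysis epoch of one condition.

    Returns (time_axis_ms relative to onset, rates (n_units, n_t))."""
    t_axis = np.arange(-PRE_EPOCH_MS, duration_ms + POST_EPOCH_MS + dt_ms / 2,
                       dt_ms)
    phase = (t_axis + PRE_EPOCH_MS) / (duration_ms + PRE_EPOCH_MS + POST_EPOCH_MS)
    rates = unit_rates_for_epoch(family, config, direction_deg, duration_ms,
                                 phase)
    return t_axis, rates


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_session(session: SessionRecording, out_dir: str | Path) -> Path:
    """Write a session to the documented plain-text layout.

    spikes.csv (unit, time_s), hand.csv (time_s, x_cm, y_cm),
    events.csv (trial table), ground_truth.csv, meta.json (config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [(u, t) for u, st in enumerate(session.unit_spike_times) for t in st]
    pd.DataFrame(rows, columns=["unit", "time_s"]).to_csv(
        out / "spikes.csv", index=False)
    pd.DataFrame({
        "time_s": session.hand_times,
        "x_cm": session.hand_position[:, 0],
        "y_cm": session.hand_position[:, 1],
    }).to_csv(out / "hand.csv", index=False)
    session.target_events.to_csv(out / "events.csv", index=False)
    if session.ground_truth is not None:
        session.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    meta = {"n_units": len(session.unit_spike_times)}
    if session.config is not None:
        cfg = asdict(session.config)
        if cfg["direction_set"] is not None:
            cfg["direction_set"] = list(map(float, cfg["direction_set"]))
        cfg["duration_range"] = list(cfg["duration_range"])
        meta["config"] = cfg
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def read_session(session_dir: str | Path) -> SessionRecording:
    """Read a session from the on-disk layout written by :func:`write_session`."""
    d = Path(session_dir)
    meta = json.loads((d / "meta.json").read_text())
    n_units = int(meta["n_units"])
    spikes = pd.read_csv(d / "spikes.csv")
    unit_spikes = [
        np.sort(spikes.loc[spikes["unit"] == u, "time_s"].to_numpy())
        for u in range(n_units)
    ]
    hand = pd.read_csv(d / "hand.csv")
    events = pd.read_csv(d / "events.csv")
    gt_path = d / "ground_truth.csv"
    gt = pd.read_csv(gt_path) if gt_path.exists() else None
    cfg = None
    if "config" in meta:
        c = dict(meta["config"])
        c["duration_range"] = tuple(c["duration_range"])
        cfg = GeneratorConfig(**c)
    return SessionRecording(
        unit_spike_times=unit_spikes,
        hand_times=hand["time_s"].to_numpy(),
        hand_position=hand[["x_cm", "y_cm"]].to_numpy(),
        target_events=events,
        ground_truth=gt,
        config=cfg,
    )
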