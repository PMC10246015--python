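"""Condition-averaged PSTH preprocessing.

Turns a raw session (spike times + hand kinematics + trial events) into
condition-averaged, soft-normalized firing-rate tensors:

1. Gaussian smoothing of spike trains, with the kernel width set to the median
   pooled inter-spike interval of the population.
2. Movement segmentation from hand speed (8 cm/s onset threshold; end =
   entry into the 2 cm target acceptance window).
3. Binning into 8 direction x 4 duration conditions (or 8 direction x 2
   maximum-speed conditions over a narrow 4-6 cm distance window).
4. Epoch extraction from 500 ms before onset to 300 ms after the rounded
   movement end, averaging across movements per condition.
5. Unit filtering (< 5 spikes across all condition epochs) and
   soft-normalization (divisor = firing-rate range + 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .synth import (
    ONSET_SPEED_THRESHOLD,
    TARGET_WINDOW_HALF_CM,
    PRE_EPOCH_MS,
    POST_EPOCH_MS,
    SessionRecording,
    DURATION_BIN_EDGES_MS,
    _duration_bin,
)

MIN_SPIKES = 5              # units with fewer total spikes are discarded
SOFT_NORM_CONST = 5.0       # spikes/s added to the range in the divisor
SPEED_DISTANCE_WINDOW_CM = (4.0, 6.0)


@dataclass
class SmoothingSpec:
    """Gaussian smoothing parameters: kernel sigma and rate sampling step."""

    sigma_ms: float
    rate_sample_interval_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_ms <= 0:
            raise ValueError("sigma must be positive")
        if self.rate_sample_interval_ms <= 0:
            raise ValueError("rate sample interval must be positive")


@dataclass
class MovementEvent:
    """One segmented reach with its condition labels."""

    onset_time: float            # s
    end_time: float              # s
    duration_ms: float
    direction_deg: float         # [0, 360)
    direction_bin: int           # 0-7
    duration_bin: int            # 0-3, -1 if outside [200, 600] ms
    max_speed: float             # cm/s
    distance: float              # cm, path length onset->end
    rounded_duration_ms: float   # upper edge of the duration bin
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not self.excluded and self.end_time <= self.onset_time:
            raise ValueError("movement end must follow onset")


@dataclass
class ConditionTensor:
    """Condition-averaged firing rates.

    ``values[i]`` is the (n_units, n_time) average for ``condition_labels[i]``;
    duration-scheme conditions keep their native epoch lengths, speed-scheme
    conditions share a common rescaled time base.  ``per_movement`` retains the
    single-movement epochs feeding each average (needed for split-half
    ceilings and spike-count unit filtering).
    """

    condition_labels: list[tuple[int, int]]   # (direction_bin, duration/speed bin)
    values: list[np.ndarray]
    time_axes: list[np.ndarray]               # ms relative to movement onset
    n_movements: list[int]
    scheme: str                               # "duration" | "speed"
    dt_ms: float
    normalization: dict | None = None
    per_movement: dict[tuple[int, int], list[np.ndarray]] = field(
        default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.values[0].shape[0]

    def as_dict(self) -> dict[tuple[int, int], np.ndarray]:
        return dict(zip(self.condition_labels, self.values))


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_spikes(
    spike_times: list[np.ndarray],
    spec: SmoothingSpec,
    t_start: float,
    t_end: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed firing rates on a uniform grid.

    Returns (times_s, rates) with rates of shape (n_units, n_t) in spikes/s.
    Each spike contributes unit mass, so the time-integral of a unit's rate
    matches its spike count away from the series edges.  Empty trains give
    all-zero rows.
    """
    dt = spec.rate_sample_interval_ms / 1000.0
    edges = np.arange(t_start, t_end + dt, dt)
    times = 0.5 * (edges[:-1] + edges[1:])
    sigma_bins = spec.sigma_ms / spec.rate_sample_interval_ms
    rates = np.zeros((len(spike_times), times.size))
    for i, st in enumerate(spike_times):
        if st.size == 0:
            continue
        counts, _ = np.histogram(st, bins=edges)
        rates[i] = gaussian_filter1d(counts.astype(float), sigma_bins,
                                     mode="constant") / dt
    return times, rates


def median_isi_sigma(
    spike_times: list[np.ndarray],
    pooling: str = "pooled",
    rate_sample_interval_ms: float = 10.0,
) -> SmoothingSpec:
    """Set the smoothing sigma to the median inter-spike interval.

    ``pooling="pooled"`` pools all within-unit ISIs across the population
    before taking the median; ``pooling="per_unit"`` takes per-unit medians
    first, then the median across units.  A sigma outside [1, 1000) ms raises
    a warning (it usually signals a pathologically sparse or dense recording).
    """
    isis = [np.diff(st) for st in spike_times if st.size >= 2]
    if not isis:
        raise ValueError("need at least 2 spikes in the population")
    if pooling == "pooled":
        sigma_ms = float(np.median(np.concatenate(isis)) * 1000.0)
    elif pooling == "per_unit":
        sigma_ms = float(np.median([np.median(x) for x in isis]) * 1000.0)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    if sigma_ms < 1.0 or sigma_ms >= 1000.0:
        warnings.warn(
            f"median-ISI sigma {sigma_ms:.1f} ms is outside [1, 1000) ms",
            stacklevel=2)
    return SmoothingSpec(sigma_ms=sigma_ms,
                         rate_sample_interval_ms=rate_sample_interval_ms)


# ---------------------------------------------------------------------------
# Movement segmentation
# ---------------------------------------------------------------------------

def _interp_crossing(t0: float, t1: float, v0: float, v1: float,
                     level: float) -> float:
    """Sub-sample linear interpolation of the time where v crosses `level`."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def direction_bin_of(direction_deg: float, phase_deg: float = 0.0) -> int:
    """8 equal 45-degree sectors centred on 0, 45, ... (+ optional phase)."""
    return int(np.round((direction_deg - phase_deg) / 45.0)) % 8


def segment_movements(
    hand_times: np.ndarray,
    hand_position: np.ndarray,
    target_events: pd.DataFrame,
    direction_bin_phase_deg: float = 0.0,
) -> list[MovementEvent]:
    """Segment one reach per successful target event.

    Onset is the first upward crossing of the 8 cm/s hand-speed threshold
    after the target appears (the task is self-paced, so there is no go cue);
    the crossing time is refined by linear interpolation between kinematic
    samples.  End is the entry of the hand into the 2 cm acceptance window
    centred on the target.  Reaches whose speed never crosses threshold, or
    whose duration falls outside [200, 600] ms, are flagged rather than
    dropped or fabricated.
    """
    events = target_events[target_events.get("success", True) == True]  # noqa: E712
    if hand_times.size < 3:
        raise ValueError("hand series too short to segment")
    vel = np.gradient(hand_position, hand_times, axis=0)
    speed = np.linalg.norm(vel, axis=1)

    out: list[MovementEvent] = []
    prev_target: np.ndarray | None = None
    prev_end_idx = 0
    for row in events.itertuples(index=False):
        target = np.array([row.target_x, row.target_y])
        i_app = int(np.searchsorted(hand_times, row.t_appear))
        start_idx = max(i_app, prev_end_idx)
        if prev_target is None or getattr(row, "reach", 1) == 0:
            origin = hand_position[min(i_app, len(hand_times) - 1)]
        else:
            origin = prev_target
        direction = float(np.rad2deg(np.arctan2(target[1] - origin[1],
                                                target[0] - origin[0])) % 360.0)

        seg = slice(start_idx, hand_times.size)
        above = speed[seg] >= ONSET_SPEED_THRESHOLD
        onset_rel = np.argmax(above) if above.any() else -1
        if onset_rel < 0:
            out.append(MovementEvent(
                onset_time=row.t_appear, end_time=row.t_appear + 1e-6,
                duration_ms=np.nan, direction_deg=direction,
                direction_bin=direction_bin_of(direction,
                                               direction_bin_phase_deg),
                duration_bin=-1, max_speed=float(speed[seg].max(initial=0.0)),
                distance=0.0, rounded_duration_ms=np.nan,
                excluded=True, exclusion_reason="no_threshold_crossing"))
            prev_target = target
            continue
        i_on = start_idx + int(onset_rel)
        if i_on > start_idx:
            onset_t = _interp_crossing(
                hand_times[i_on - 1], hand_times[i_on],
                speed[i_on - 1], speed[i_on], ONSET_SPEED_THRESHOLD)
        else:
            onset_t = float(hand_times[i_on])

        # window entry: max(|dx|, |dy|) <= 1 cm
        cheb = np.max(np.abs(hand_position[i_on:] - target[None, :]), axis=1)
        inside = cheb <= TARGET_WINDOW_HALF_CM
        end_rel = np.argmax(inside) if inside.any() else -1
        if end_rel < 0:
            out.append(MovementEvent(
                onset_time=onset_t, end_time=onset_t + 1e-6,
                duration_ms=np.nan, direction_deg=direction,
                direction_bin=direction_bin_of(direction,
                                               direction_bin_phase_deg),
                duration_bin=-1, max_speed=float(speed[i_on:].max(initial=0.0)),
                distance=0.0, rounded_duration_ms=np.nan,
                excluded=True, exclusion_reason="no_window_entry"))
            prev_target = target
            continue
        i_end = i_on + int(end_rel)
        if end_rel > 0:
            end_t = _interp_crossing(
                hand_times[i_end - 1], hand_times[i_end],
                cheb[end_rel - 1], cheb[end_rel], TARGET_WINDOW_HALF_CM)
        else:
            end_t = float(hand_times[i_end])

        duration_ms = (end_t - onset_t) * 1000.0
        dbin = _duration_bin(duration_ms)
        steps = np.linalg.norm(np.diff(hand_position[i_on:i_end + 1], axis=0),
                               axis=1)
        mv = MovementEvent(
            onset_time=onset_t, end_time=end_t, duration_ms=duration_ms,
            direction_deg=direction,
            direction_bin=direction_bin_of(direction, direction_bin_phase_deg),
            duration_bin=dbin,
            max_speed=float(speed[i_on:i_end + 1].max(initial=0.0)),
            distance=float(steps.sum()),
            rounded_duration_ms=(DURATION_BIN_EDGES_MS[dbin + 1]
                                 if dbin >= 0 else np.nan),
            excluded=dbin < 0,
            exclusion_reason="duration_out_of_range" if dbin < 0 else "")
        out.append(mv)
        prev_target = target
        prev_end_idx = i_end
    return out


# ---------------------------------------------------------------------------
# Condition averaging
# ---------------------------------------------------------------------------

def _extract_epoch(
    rate_times: np.ndarray, rates: np.ndarray,
    onset_s: float, rel_axis_ms: np.ndarray,
) -> np.ndarray:
    """Linear-interpolated (n_units, n_t) epoch of the rate series."""
    t_abs = onset_s + rel_axis_ms / 1000.0
    return np.stack([np.interp(t_abs, rate_times, rates[u])
                     for u in range(rates.shape[0])])


def condition_average(
    rate_times: np.ndarray,
    rates: np.ndarray,
    events: list[MovementEvent],
    scheme: str = "duration",
    dt_ms: float = 10.0,
    speed_distance_window_cm: tuple[float, float] = SPEED_DISTANCE_WINDOW_CM,
    keep_per_movement: bool = True,
) -> ConditionTensor:
    """Average smoothed rates across movements per condition.

    Duration scheme: 32 conditions (8 directions x 4 durations) with native
    epoch lengths (-500 ms to rounded duration + 300 ms).  Speed scheme:
    movements restricted to the 4-6 cm distance window, split at the median
    maximum speed, each movement's epoch linearly rescaled to the grand-median
    duration before averaging (8 directions x 2 speeds = 16 conditions).
    Empty conditions are omitted (marked missing), never zero-filled.
    """
    included = [e for e in events if not e.excluded]
    if scheme == "duration":
        groups: dict[tuple[int, int], list[MovementEvent]] = {}
        for e in included:
            groups.setdefault((e.direction_bin, e.duration_bin), []).append(e)
        labels, values, axes, counts = [], [], [], []
        per_movement: dict[tuple[int, int], list[np.ndarray]] = {}
        for (dbin, ubin), evs in sorted(groups.items()):
            rounded = DURATION_BIN_EDGES_MS[ubin + 1]
            axis = np.arange(-PRE_EPOCH_MS, rounded + POST_EPOCH_MS + dt_ms / 2,
                             dt_ms)
            epochs = [_extract_epoch(rate_times, rates, e.onset_time, axis)
                      for e in evs]
            labels.append((dbin, ubin))
            values.append(np.mean(epochs, axis=0))
            axes.append(axis)
            counts.append(len(evs))
            if keep_per_movement:
                per_movement[(dbin, ubin)] = epochs
        if not labels:
            raise ValueError("all conditions are empty")
        return ConditionTensor(labels, values, axes, counts, "duration",
                               dt_ms, per_movement=per_movement)

    if scheme == "speed":
        lo, hi = speed_distance_window_cm
        subset = [e for e in included if lo <= e.distance <= hi]
        if not subset:
            raise ValueError("no movements inside the distance window")
        med_speed = float(np.median([e.max_speed for e in subset]))
        ref_dur = float(np.median([e.duration_ms for e in subset]))
        axis = np.arange(-PRE_EPOCH_MS, ref_dur + POST_EPOCH_MS + dt_ms / 2,
                         dt_ms)
        groups2: dict[tuple[int, int], list[np.ndarray]] = {}
        for e in subset:
            sbin = int(e.max_speed > med_speed)
            native = np.arange(-PRE_EPOCH_MS,
                               e.duration_ms + POST_EPOCH_MS + dt_ms / 2, dt_ms)
            ep = _extract_epoch(rate_times, rates, e.onset_time, native)
            # rescale this movement's epoch to the reference duration
            src = np.linspace(0.0, 1.0, native.size)
            dst = np.linspace(0.0, 1.0, axis.size)
            scaled = np.stack([np.interp(dst, src, ep[u])
                               for u in range(ep.shape[0])])
            groups2.setdefault((e.direction_bin, sbin), []).append(scaled)
        labels, values, axes, counts = [], [], [], []
        per_movement = {}
        for lab, eps in sorted(groups2.items()):
            labels.append(lab)
            values.append(np.mean(eps, axis=0))
            axes.append(axis)
            counts.append(len(eps))
            if keep_per_movement:
                per_movement[lab] = eps
        return ConditionTensor(labels, values, axes, counts, "speed",
                               dt_ms, per_movement=per_movement)

    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Unit filtering and soft-normalization
# ---------------------------------------------------------------------------

def filter_and_normalize(
    tensor: ConditionTensor,
    min_spikes: int = MIN_SPIKES,
    soft_norm_const: float = SOFT_NORM_CONST,
) -> ConditionTensor:
    """Drop near-silent units and soft-normalize the rest.

    A unit's total spike count is estimated as the time-integral of its rate
    over every movement epoch feeding the averages (falling back to the
    count-weighted condition averages when single-movement epochs were not
    kept).  Units with fewer than `min_spikes` are discarded.  Each remaining
    unit is divided by (its firing-rate range across all conditions and times
    + `soft_norm_const`), which bounds every normalized range strictly
    below 1.
    """
    dt_s = tensor.dt_ms / 1000.0
    n_units = tensor.n_units
    spikes = np.zeros(n_units)
    if tensor.per_movement:
        for eps in tensor.per_movement.values():
            for ep in eps:
                spikes += ep.sum(axis=1) * dt_s
    else:
        for val, n in zip(tensor.values, tensor.n_movements):
            spikes += val.sum(axis=1) * dt_s * n
    keep = np.flatnonzero(spikes >= min_spikes)
    if keep.size == 0:
        raise ValueError("all units fall below the minimum spike count")

    stacked = np.hstack([v[keep] for v in tensor.values])
    rng_ = stacked.max(axis=1) - stacked.min(axis=1)
    divisor = rng_ + soft_norm_const
    values = [v[keep] / divisor[:, None] for v in tensor.values]
    per_movement = {
        lab: [ep[keep] / divisor[:, None] for ep in eps]
        for lab, eps in tensor.per_movement.items()
    }
    return ConditionTensor(
        condition_labels=list(tensor.condition_labels),
        values=values,
        time_axes=[a.copy() for a in tensor.time_axes],
        n_movements=list(tensor.n_movements),
        scheme=tensor.scheme,
        dt_ms=tensor.dt_ms,
        normalization={
            "kept_units": keep,
            "divisor": divisor,
            "estimated_spikes": spikes,
            "soft_norm_const": soft_norm_const,
        },
        per_movement=per_movement,
    )


def preprocess_session(
    session: SessionRecording,
    scheme: str = "duration",
    sigma_override_ms: float | None = None,
    rate_dt_ms: float = 10.0,
    direction_bin_phase_deg: float = 0.0,
) -> tuple[ConditionTensor, SmoothingSpec, list[MovementEvent]]:
    """Full preprocessing chain for one session."""
    if sigma_override_ms is not None:
        spec = SmoothingSpec(sigma_override_ms, rate_dt_ms)
    else:
        spec = median_isi_sigma(session.unit_spike_times,
                                rate_sample_interval_ms=rate_dt_ms)
    t0 = float(session.hand_times[0])
    t1 = float(session.hand_times[-1])
    rate_times, rates = smooth_spikes(session.unit_spike_times, spec, t0, t1)
    events = segment_movements(session.hand_times, session.hand_position,
                               session.target_events,
                               direction_bin_phase_deg)
    tensor = condition_average(rate_times, rates, events, scheme=scheme,
                               dt_ms=rate_dt_ms)
    tensor = filter_and_normalize(tensor)
    return tensor, spec, events
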