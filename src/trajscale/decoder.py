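"""Temporal-scaling duration decoder.

Under the temporal-scaling hypothesis a sample trajectory and a same-direction
reference trajectory trace the same curve in state space, so each sample point
has a well-defined nearest reference point.  Plotting sample time against the
matched reference time gives a line whose slope is the relative traversal
speed v; the sample's full trajectory duration is then v times the reference
trajectory duration, and the movement duration follows by subtracting the
constant non-movement time inside the epoch (500 ms for PMd, 450 ms for M1,
800 ms for untrimmed preprocessing epochs).

Conventions (the verbal description of the regression is ambiguous): the
predictor is the matched reference index converted to ms, the response is the
sample time, an intercept is included, and v is the slope alone — the only
orientation dimensionally consistent with Duration_sample = v * Duration_ref.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .subspace import NeuralTrajectory
from .trajgeo import NON_MOVEMENT_TIME_MS

REFERENCE_DURATION_BIN = 1      # 300-400 ms movements serve as references


@dataclass
class TimeIndexTrace:
    """Nearest-reference-point indices for each sample point."""

    sample_times_ms: np.ndarray
    matched_indices: np.ndarray      # integer reference time indices
    match_distances: np.ndarray      # subspace units
    reference_dt_ms: float
    n_reference: int

    def __post_init__(self) -> None:
        if self.matched_indices.shape != self.sample_times_ms.shape:
            raise ValueError("trace arrays must share a length")
        if self.matched_indices.size and (
                self.matched_indices.min() < 0
                or self.matched_indices.max() >= self.n_reference):
            raise ValueError("matched indices outside the reference")


@dataclass
class DecoderResult:
    """Outcome of decoding one sample trajectory."""

    v: float                                 # relative traversal speed
    predicted_trajectory_duration_ms: float
    predicted_movement_duration_ms: float
    fit_r2: float
    reference_condition: tuple | str
    sample_condition: tuple | str
    valid: bool = True
    reason: str = ""


def match_indices(sample: NeuralTrajectory,
                  reference: NeuralTrajectory) -> TimeIndexTrace:
    """For each sample point, the index of the Euclidean-nearest reference
    point (ties broken to the smallest index)."""
    if sample.points.size == 0 or reference.points.size == 0:
        raise ValueError("trajectories must be non-empty")
    if sample.points.shape[1] != reference.points.shape[1]:
        raise ValueError("sample and reference must share subspace dimension")
    D = cdist(sample.points, reference.points)
    idx = np.argmin(D, axis=1)              # first minimum = smallest index
    return TimeIndexTrace(
        sample_times_ms=sample.time_axis_ms - sample.time_axis_ms[0],
        matched_indices=idx,
        match_distances=D[np.arange(D.shape[0]), idx],
        reference_dt_ms=reference.dt_ms,
        n_reference=reference.points.shape[0])


def relative_speed(trace: TimeIndexTrace) -> tuple[float, float, float]:
    """Relative speed v between sample and reference.

    OLS of sample time (response) on matched reference time (predictor, the
    matched indices converted to ms); returns (v, intercept, fit_r2)."""
    if trace.sample_times_ms.size < 3:
        raise ValueError("need at least 3 matched points")
    x = trace.matched_indices * trace.reference_dt_ms
    y = trace.sample_times_ms
    if np.ptp(x) == 0:
        raise ValueError("matched indices have zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot else 1.0
    return float(slope), float(intercept), r2


def decode_duration(
    sample: NeuralTrajectory,
    reference: NeuralTrajectory,
    region: str = "full",
    non_movement_time_ms: float | None = None,
) -> DecoderResult:
    """Predict a sample trajectory's movement duration from a reference.

    predicted trajectory duration = v * reference trajectory duration;
    predicted movement duration subtracts the region's non-movement time.
    A non-positive v marks the decode invalid (the trajectories are not
    consistent traversals of one curve)."""
    nmt = (NON_MOVEMENT_TIME_MS[region]
           if non_movement_time_ms is None else non_movement_time_ms)
    trace = match_indices(sample, reference)
    try:
        v, _, r2 = relative_speed(trace)
    except ValueError as exc:
        return DecoderResult(np.nan, np.nan, np.nan, np.nan,
                             reference.condition, sample.condition,
                             valid=False, reason=str(exc))
    ref_traj_ms = reference.duration_ms
    pred_traj = v * ref_traj_ms
    result = DecoderResult(
        v=v,
        predicted_trajectory_duration_ms=pred_traj,
        predicted_movement_duration_ms=pred_traj - nmt,
        fit_r2=r2,
        reference_condition=reference.condition,
        sample_condition=sample.condition,
    )
    if v <= 0:
        result.valid = False
        result.reason = "non-positive relative speed"
    return result


class TemporalScalingDurationDecoder(BaseEstimator):
    """Nearest-point time-warp decoder of movement duration.

    Parameters
    ----------
    region : "PMd" | "M1" | "full"
        Selects the constant non-movement time subtracted from the predicted
        trajectory duration (500 / 450 / 800 ms).
    non_movement_time_ms : float, optional
        Explicit override of the region preset.

    ``fit`` takes the reference trajectories (one per direction bin, by
    convention the 300-400 ms duration bin); ``predict`` decodes sample
    trajectories against the same-direction reference.
    """

    def __init__(self, region: str = "full",
                 non_movement_time_ms: float | None = None):
        self.region = region
        self.non_movement_time_ms = non_movement_time_ms

    def _nmt(self) -> float:
        if self.non_movement_time_ms is not None:
            return self.non_movement_time_ms
        return NON_MOVEMENT_TIME_MS[self.region]

    def fit(self, references: list[NeuralTrajectory], y=None
            ) -> "TemporalScalingDurationDecoder":
        refs: dict[int, NeuralTrajectory] = {}
        for r in references:
            dbin = r.condition[0] if isinstance(r.condition, tuple) else 0
            refs[int(dbin)] = r
        if not refs:
            raise ValueError("no reference trajectories given")
        self.references_ = refs
        return self

    def predict(self, samples: list[NeuralTrajectory],
                cross_direction: bool = False,
                reference_bin: int | None = None) -> pd.DataFrame:
        """Decode each sample; returns one row per sample trajectory.

        With ``cross_direction`` the reference from ``reference_bin`` is used
        regardless of the sample's direction (control mode)."""
        rows = []
        for s in samples:
            dbin = s.condition[0] if isinstance(s.condition, tuple) else 0
            key = reference_bin if cross_direction else int(dbin)
            if key not in self.references_:
                raise ValueError(f"missing reference for direction bin {key}")
            res = decode_duration(s, self.references_[key],
                                  non_movement_time_ms=self._nmt())
            rows.append(dict(
                sample_condition=s.condition,
                reference_condition=res.reference_condition,
                v=res.v, fit_r2=res.fit_r2,
                predicted_trajectory_ms=res.predicted_trajectory_duration_ms,
                predicted_movement_ms=res.predicted_movement_duration_ms,
                valid=res.valid, reason=res.reason))
        return pd.DataFrame(rows)


def decoder_benchmark(
    trajectories: dict[tuple[int, int], NeuralTrajectory],
    region: str = "full",
    non_movement_time_ms: float | None = None,
    reference_bin: int = REFERENCE_DURATION_BIN,
    true_movement_ms: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Decode all non-reference conditions against same-direction references.

    The 8 trajectories of `reference_bin` (300-400 ms movements) are the
    references; the remaining 24 conditions are decoded.  Reports per-sample
    relative errors of trajectory duration, and of movement duration when
    the true movement durations per duration bin are supplied (defaults to
    the rounded bin edges 300/400/500/600 ms).
    """
    if true_movement_ms is None:
        true_movement_ms = {0: 300.0, 1: 400.0, 2: 500.0, 3: 600.0}
    refs = {d: t for (d, u), t in trajectories.items() if u == reference_bin}
    missing = [d for d, _ in trajectories if d not in refs]
    if missing:
        raise ValueError(
            f"missing reference condition for direction bins {sorted(set(missing))}")
    nmt = (NON_MOVEMENT_TIME_MS[region]
           if non_movement_time_ms is None else non_movement_time_ms)
    rows = []
    for (d, u), sample in sorted(trajectories.items()):
        if u == reference_bin:
            continue
        res = decode_duration(sample, refs[d], non_movement_time_ms=nmt)
        true_traj = sample.duration_ms
        true_move = true_movement_ms.get(u, np.nan)
        rows.append(dict(
            direction_bin=d, duration_bin=u, v=res.v, fit_r2=res.fit_r2,
            predicted_trajectory_ms=res.predicted_trajectory_duration_ms,
            true_trajectory_ms=true_traj,
            rel_error_trajectory=abs(res.predicted_trajectory_duration_ms
                                     - true_traj) / true_traj,
            predicted_movement_ms=res.predicted_movement_duration_ms,
            true_movement_ms=true_move,
            rel_error_movement=abs(res.predicted_movement_duration_ms
                                   - true_move) / true_move,
            valid=res.valid))
    return pd.DataFrame(rows)
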