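"""Trajectory-geometry statistics.

Separation time courses and their timing landmarks, temporal rescaling to a
common 600-bin base, the concatenated coefficient of determination between
rescaled trajectories (with split-half ceilings and cross-direction floors),
and Hausdorff-distance contrasts across duration, direction, and speed.

All distances are Euclidean in the fitted D-dimensional subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import ttest_ind

from .subspace import CommonSubspace, NeuralTrajectory

N_SCALE_BINS = 600

# Analysis epochs (ms relative to movement onset / end) inside which direction
# coding is sustained in each region; applied before the geometry statistics.
REGION_EPOCHS = {
    "PMd": (-450.0, 50.0),    # epoch start; offset past movement end
    "M1": (-250.0, 200.0),
    "full": (None, None),     # keep the full preprocessing epoch
}

# Non-movement time inside each region's trajectory epoch (pre + post), ms.
NON_MOVEMENT_TIME_MS = {"PMd": 500.0, "M1": 450.0, "full": 800.0}


@dataclass
class ScaledTrajectory:
    """A trajectory linearly rescaled to a fixed number of time bins."""

    points: np.ndarray                 # (n_bins, D)
    source_condition: tuple | str
    original_duration_ms: float

    def __post_init__(self) -> None:
        if self.points.ndim != 2:
            raise ValueError("points must be (n_bins, D)")


@dataclass
class SeparationProfile:
    """Mean pairwise distance between direction trajectories over time."""

    time_axis_ms: np.ndarray
    mean_distance: np.ndarray          # normalized by the population max
    t_min_pre_ms: float
    t_max_ms: float
    t_min_post_ms: float
    degenerate: bool = False


def trim_trajectory(traj: NeuralTrajectory, region: str = "full",
                    movement_end_ms: float | None = None) -> NeuralTrajectory:
    """Trim a trajectory to a region's analysis epoch.

    ``movement_end_ms`` defaults to epoch_end - 300 ms (the post-movement
    margin of the preprocessing epoch)."""
    start, post = REGION_EPOCHS[region]
    if start is None:
        return traj
    if movement_end_ms is None:
        movement_end_ms = traj.time_axis_ms[-1] - 300.0
    mask = (traj.time_axis_ms >= start) & (
        traj.time_axis_ms <= movement_end_ms + post)
    return NeuralTrajectory(points=traj.points[mask], dt_ms=traj.dt_ms,
                            condition=traj.condition,
                            time_axis_ms=traj.time_axis_ms[mask])


# ---------------------------------------------------------------------------
# Temporal rescaling and concatenated R^2
# ---------------------------------------------------------------------------

def rescale_trajectory(traj: NeuralTrajectory | np.ndarray,
                       n_bins: int = N_SCALE_BINS) -> ScaledTrajectory:
    """Linearly interpolate a trajectory onto `n_bins` time bins.

    Endpoints are preserved exactly and every output point lies on the
    segment between its bracketing input samples."""
    if isinstance(traj, NeuralTrajectory):
        pts = traj.points
        cond = traj.condition
        dur = traj.duration_ms
    else:
        pts = np.asarray(traj, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        cond = "array"
        dur = float(pts.shape[0])
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 samples to rescale")
    src = np.linspace(0.0, 1.0, pts.shape[0])
    dst = np.linspace(0.0, 1.0, n_bins)
    out = np.stack([np.interp(dst, src, pts[:, d])
                    for d in range(pts.shape[1])], axis=1)
    return ScaledTrajectory(points=out, source_condition=cond,
                            original_duration_ms=dur)


def _as_points(x) -> np.ndarray:
    if isinstance(x, (ScaledTrajectory, NeuralTrajectory)):
        return x.points
    a = np.asarray(x, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def scaled_r2(X, Y) -> float:
    """Coefficient of determination between two equal-shape trajectories.

    Both are collapsed into single vectors with all dimensions concatenated;
    R^2 = 1 - sum((X-Y)^2) / sum((X - Xbar)^2), where Xbar is X's time-mean
    point (per-dimension mean, so the statistic is invariant to a common
    rotation of both trajectories in the subspace).  R^2 = 1 means perfect
    matching, 0 matches only as well as X's mean point, negative worse than
    that baseline.  Asymmetric: the FIRST argument supplies the baseline
    mean; for pairwise summaries report the mean of both orderings.
    """
    x = _as_points(X)
    y = _as_points(Y)
    if x.shape != y.shape:
        raise ValueError("trajectories must share dimensionality and bins")
    denom = float(np.sum((x - x.mean(axis=0)) ** 2))
    if denom == 0:
        raise ValueError("baseline trajectory is constant (zero variance)")
    return 1.0 - float(np.sum((x - y) ** 2)) / denom


def symmetric_scaled_r2(X, Y) -> float:
    return 0.5 * (scaled_r2(X, Y) + scaled_r2(Y, X))


def pairwise_scaled_r2(
    trajectories: dict[tuple[int, int], NeuralTrajectory],
    n_bins: int = N_SCALE_BINS,
) -> pd.DataFrame:
    """Mean symmetric R^2 between rescaled same-direction trajectory pairs."""
    scaled = {lab: rescale_trajectory(t, n_bins)
              for lab, t in trajectories.items()}
    rows = []
    dirs = sorted({d for d, _ in scaled})
    for d in dirs:
        durs = sorted(u for dd, u in scaled if dd == d)
        for i, u1 in enumerate(durs):
            for u2 in durs[i + 1:]:
                rows.append(dict(direction_bin=d, bin_a=u1, bin_b=u2,
                                 r2=symmetric_scaled_r2(scaled[(d, u1)],
                                                        scaled[(d, u2)])))
    return pd.DataFrame(rows)


def lower_limit_r2(
    trajectories: dict[tuple[int, int], NeuralTrajectory],
) -> pd.DataFrame:
    """Floor: R^2 between UNSCALED equal-length trajectories of the same
    duration bin but different directions."""
    rows = []
    durs = sorted({u for _, u in trajectories})
    for u in durs:
        labs = sorted(lab for lab in trajectories if lab[1] == u)
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                ta, tb = trajectories[a], trajectories[b]
                n = min(ta.points.shape[0], tb.points.shape[0])
                r2 = 0.5 * (scaled_r2(ta.points[:n], tb.points[:n])
                            + scaled_r2(tb.points[:n], ta.points[:n]))
                rows.append(dict(duration_bin=u, dir_a=a[0], dir_b=b[0], r2=r2))
    return pd.DataFrame(rows)


def within_bin_ceiling(
    tensor_per_movement: dict[tuple[int, int], list[np.ndarray]],
    space: CommonSubspace,
    seed: int = 0,
    n_bins: int = N_SCALE_BINS,
) -> tuple[float, pd.DataFrame]:
    """Split-half ceiling on trajectory similarity.

    For every condition with >= 4 movements: randomly split the movements into
    two equal halves, average each half, project into the common subspace,
    rescale to `n_bins`, and compute the symmetric R^2 between the two
    split trajectories.  Repeated floor(n/2) times per condition; values are
    pooled across conditions into a per-population mean.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lab, epochs in sorted(tensor_per_movement.items()):
        n = len(epochs)
        if n < 4:
            continue
        half = n // 2
        arr = np.stack(epochs)
        for rep in range(half):
            perm = rng.permutation(n)
            a = arr[perm[:half]].mean(axis=0)
            b = arr[perm[half:2 * half]].mean(axis=0)
            ta = rescale_trajectory(space.project_points(a), n_bins)
            tb = rescale_trajectory(space.project_points(b), n_bins)
            rows.append(dict(direction_bin=lab[0], other_bin=lab[1],
                             repeat=rep, r2=symmetric_scaled_r2(ta, tb)))
    if not rows:
        raise ValueError("no condition has >= 4 movements to split")
    df = pd.DataFrame(rows)
    return float(df["r2"].mean()), df


# ---------------------------------------------------------------------------
# Hausdorff distances and contrasts
# ---------------------------------------------------------------------------

def hausdorff(X, Y) -> float:
    """Symmetric Hausdorff distance between two point sets.

    max over each set of the minimum Euclidean distance to the other set;
    a metric on compact point sets (zero iff equal as sets, symmetric,
    triangle inequality).
    """
    x = np.atleast_2d(_as_points(X))
    y = np.atleast_2d(_as_points(Y))
    if x.size == 0 or y.size == 0:
        raise ValueError("point sets must be non-empty")
    return max(directed_hausdorff(x, y)[0], directed_hausdorff(y, x)[0])


def _welch_summary(a: np.ndarray, b: np.ndarray,
                   alternative: str = "two-sided") -> dict:
    res = ttest_ind(a, b, equal_var=False, alternative=alternative)
    return dict(statistic=float(res.statistic), p=float(res.pvalue),
                dof=float(res.df), n_a=int(len(a)), n_b=int(len(b)),
                mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
                alternative=alternative)


def distance_contrasts(
    trajectories: dict[tuple[int, int], NeuralTrajectory],
    contrast: str = "duration",
    split_distances: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Hausdorff-distance contrast tables with a Welch t-test summary.

    ``duration``: each trajectory vs the 3 other durations of its direction
    (96 directed pairs over the 8 x 4 grid) against each trajectory vs its 2
    adjacent directions at the same duration (64 directed pairs); one-sided
    test that duration distances are smaller.  The factor composition
    3 (duration-bin combinations) x 2 (adjacent bins) x 4 x 8 = 192 is
    reported for bookkeeping.

    ``speed``: same-direction high-vs-low speed distances against
    adjacent-direction distances at the same speed (2 x 2 x 8 = 32 on the
    direction side).

    ``within_bin``: requires ``split_distances`` (Hausdorff distances between
    split-half trajectories of one direction and duration); one-sided test of
    different-duration distances against them.
    """
    labs = set(trajectories)
    dirs = sorted({d for d, _ in labs})
    n_dirs = len(dirs)

    def H(a, b):
        return hausdorff(trajectories[a], trajectories[b])

    if contrast in ("duration", "within_bin"):
        durs = sorted({u for _, u in labs})
        missing = [(d, u) for d in dirs for u in durs if (d, u) not in labs]
        if missing:
            raise ValueError(f"missing conditions: {missing}")
        rows = []
        for d in dirs:
            for u in durs:
                for u2 in durs:
                    if u2 != u:
                        rows.append(dict(kind="duration", direction_bin=d,
                                         bin_a=u, bin_b=u2,
                                         distance=H((d, u), (d, u2))))
        for d in dirs:
            for u in durs:
                for step in (-1, 1):
                    d2 = dirs[(dirs.index(d) + step) % n_dirs]
                    rows.append(dict(kind="adjacent_direction",
                                     direction_bin=d, bin_a=u, bin_b=u,
                                     distance=H((d, u), (d2, u))))
        df = pd.DataFrame(rows)
        dur = df.loc[df.kind == "duration", "distance"].to_numpy()
        adj = df.loc[df.kind == "adjacent_direction", "distance"].to_numpy()
        if contrast == "duration":
            summary = _welch_summary(dur, adj, alternative="less")
            summary["n_composition"] = (len(durs) - 1) * 2 * len(durs) * n_dirs
            return df, summary
        if split_distances is None:
            raise ValueError("within_bin contrast needs split_distances")
        summary = _welch_summary(dur, np.asarray(split_distances, float),
                                 alternative="greater")
        return df, summary

    if contrast == "speed":
        speeds = sorted({u for _, u in labs})
        if speeds != [0, 1]:
            raise ValueError("speed contrast needs speed bins {0, 1}")
        missing = [(d, s) for d in dirs for s in speeds if (d, s) not in labs]
        if missing:
            raise ValueError(f"missing conditions: {missing}")
        rows = []
        for d in dirs:
            for s, s2 in ((0, 1), (1, 0)):
                rows.append(dict(kind="speed", direction_bin=d,
                                 bin_a=s, bin_b=s2,
                                 distance=H((d, s), (d, s2))))
        for d in dirs:
            for s in speeds:
                for step in (-1, 1):
                    d2 = dirs[(dirs.index(d) + step) % n_dirs]
                    rows.append(dict(kind="adjacent_direction",
                                     direction_bin=d, bin_a=s, bin_b=s,
                                     distance=H((d, s), (d2, s))))
        df = pd.DataFrame(rows)
        spd = df.loc[df.kind == "speed", "distance"].to_numpy()
        adj = df.loc[df.kind == "adjacent_direction", "distance"].to_numpy()
        summary = _welch_summary(spd, adj, alternative="less")
        summary["n_composition"] = 2 * 2 * n_dirs
        return df, summary

    raise ValueError(f"unknown contrast {contrast!r}")


# ---------------------------------------------------------------------------
# Separation time course (direction coding landmarks)
# ---------------------------------------------------------------------------

def separation_profile(
    trajectories: list[NeuralTrajectory],
    onset_ms: float = 0.0,
) -> SeparationProfile:
    """Mean pointwise pairwise distance across direction trajectories.

    All trajectories must share one time axis.  The profile is the mean over
    all direction pairs of the pointwise Euclidean distance, normalized by
    the maximum pointwise pairwise distance of the population.  Landmarks:
    the pre-onset minimum (ties broken toward the latest minimizer — the
    divergence point when the profile is flat before separating), the global
    maximum, and the post-onset minimum (ties broken toward the earliest
    minimizer — the reconvergence point).
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    lens = {t.points.shape[0] for t in trajectories}
    if len(lens) != 1:
        raise ValueError("trajectories must share a common time axis")
    axis = trajectories[0].time_axis_ms
    P = np.stack([t.points for t in trajectories])   # (n_traj, n_t, D)
    n = P.shape[0]
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(np.linalg.norm(P[i] - P[j], axis=1))
    D = np.stack(dists)                              # (n_pairs, n_t)
    max_dist = float(D.max())
    degenerate = max_dist <= 1e-12
    profile = D.mean(axis=0) / (max_dist if not degenerate else 1.0)

    pre = np.flatnonzero(axis <= onset_ms)
    post = np.flatnonzero(axis >= onset_ms)
    if pre.size == 0 or post.size == 0:
        raise ValueError("onset must lie inside the epoch")
    pre_min = np.flatnonzero(profile[pre] == profile[pre].min())
    t_min_pre = float(axis[pre[pre_min[-1]]])
    t_max = float(axis[int(np.argmax(profile))])
    post_min = np.flatnonzero(profile[post] == profile[post].min())
    t_min_post = float(axis[post[post_min[0]]])
    return SeparationProfile(
        time_axis_ms=axis, mean_distance=profile,
        t_min_pre_ms=t_min_pre, t_max_ms=t_max, t_min_post_ms=t_min_post,
        degenerate=degenerate)


def distance_vs_angle(
    trajectories: dict[tuple[int, int], NeuralTrajectory],
    duration_bin: int = 0,
) -> pd.DataFrame:
    """Mean pointwise distance between same-duration direction trajectories
    as a function of their angular difference (45-degree bins)."""
    labs = sorted(lab for lab in trajectories if lab[1] == duration_bin)
    rows = []
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            dbin = abs(a[0] - b[0])
            dbin = min(dbin, 8 - dbin)
            d = np.linalg.norm(trajectories[a].points
                               - trajectories[b].points, axis=1).mean()
            rows.append(dict(angle_deg=45 * dbin, distance=float(d)))
    df = pd.DataFrame(rows)
    return df.groupby("angle_deg", as_index=False)["distance"].mean()
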