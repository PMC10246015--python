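"""Common low-dimensional subspace and marginalized variance fractions.

The common subspace is fitted by PCA across all conditions' averaged neural
activity, concatenated in time — no temporal rescaling is needed since PCA is
agnostic to trajectory length.  The retained dimensionality D is the smallest
number of components explaining at least 80 % of the variance (3-11 on the
recorded populations).

``marginalized_variance`` reports how total variance splits across
condition-independent, direction, duration, and interaction marginals after
rescaling every condition to 600 time bins.  This is the balanced
marginalization decomposition underlying demixed PCA, without the demixing
projections — a deliberately simple, documented approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .preprocess import ConditionTensor


@dataclass
class NeuralTrajectory:
    """A D-dimensional trajectory with its time base and condition label."""

    points: np.ndarray            # (n_time, D)
    dt_ms: float
    condition: tuple[int, int] | str
    time_axis_ms: np.ndarray      # relative to movement onset

    def __post_init__(self) -> None:
        if self.points.ndim != 2:
            raise ValueError("points must be (n_time, D)")
        if np.any(~np.isfinite(self.points)):
            raise ValueError("trajectory contains missing samples")

    @property
    def epoch(self) -> tuple[float, float]:
        return float(self.time_axis_ms[0]), float(self.time_axis_ms[-1])

    @property
    def duration_ms(self) -> float:
        return float(self.time_axis_ms[-1] - self.time_axis_ms[0])


class CommonSubspace(BaseEstimator, TransformerMixin):
    """PCA-defined common subspace across all condition averages.

    Parameters
    ----------
    var_threshold : float, default 0.80
        Retain the smallest number of leading components whose cumulative
        explained-variance fraction reaches this threshold.

    Attributes (after ``fit``)
    --------------------------
    basis_ : (n_units, D) orthonormal loading matrix.
    mean_vector_ : (n_units,) grand mean over all conditions and times.
    D_ : retained dimensionality.
    variance_explained_ : per-component variance fractions (full spectrum).
    """

    def __init__(self, var_threshold: float = 0.80):
        self.var_threshold = var_threshold

    def fit(self, tensor: ConditionTensor, y=None) -> "CommonSubspace":
        X = np.hstack(tensor.values).T        # (total_time, n_units)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 units to fit a subspace")
        pca = PCA(svd_solver="full")
        pca.fit(X)
        ratios = pca.explained_variance_ratio_
        cum = np.cumsum(ratios)
        D = int(np.searchsorted(cum, self.var_threshold) + 1)
        self.mean_vector_ = pca.mean_
        self.basis_ = pca.components_[:D].T   # (n_units, D)
        self.D_ = D
        self.variance_explained_ = ratios
        self.n_units_ = X.shape[1]
        return self

    def transform(self, tensor: ConditionTensor) -> list[NeuralTrajectory]:
        """Project each condition average into the fitted subspace."""
        if tensor.n_units != self.n_units_:
            raise ValueError(
                f"unit mismatch: subspace fitted on {self.n_units_} units, "
                f"tensor has {tensor.n_units}")
        out = []
        for lab, val, axis in zip(tensor.condition_labels, tensor.values,
                                  tensor.time_axes):
            pts = (val.T - self.mean_vector_) @ self.basis_
            out.append(NeuralTrajectory(points=pts, dt_ms=tensor.dt_ms,
                                        condition=lab, time_axis_ms=axis))
        return out

    def project_points(self, rates: np.ndarray) -> np.ndarray:
        """Project raw (n_units, n_time) rates; returns (n_time, D)."""
        return (rates.T - self.mean_vector_) @ self.basis_


def fit_common_subspace(tensor: ConditionTensor,
                        var_threshold: float = 0.80) -> CommonSubspace:
    return CommonSubspace(var_threshold=var_threshold).fit(tensor)


def project(tensor: ConditionTensor,
            space: CommonSubspace) -> list[NeuralTrajectory]:
    return space.transform(tensor)


def _rescale_to_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Linear interpolation of (n_units, n_t) to (n_units, n_bins)."""
    src = np.linspace(0.0, 1.0, values.shape[1])
    dst = np.linspace(0.0, 1.0, n_bins)
    return np.stack([np.interp(dst, src, row) for row in values])


def marginalized_variance(tensor: ConditionTensor,
                          n_bins: int = 600) -> dict[str, float]:
    """Variance fractions per task-variable marginal.

    Requires the full 8 x 4 duration-scheme grid.  Every condition is
    linearly rescaled to ``n_bins`` time bins; the data tensor
    X[direction, duration, unit, time] is decomposed into additive marginal
    means — condition-independent (time only), direction x time,
    duration x time, and the interaction residual — whose variances
    partition the total exactly (fractions sum to 1).
    """
    labels = set(tensor.condition_labels)
    dirs = sorted({d for d, _ in labels})
    durs = sorted({u for _, u in labels})
    missing = [(d, u) for d in dirs for u in durs if (d, u) not in labels]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    if tensor.scheme != "duration" or len(dirs) < 2 or len(durs) < 2:
        raise ValueError("marginalized_variance needs the full "
                         "direction x duration grid")
    lut = tensor.as_dict()
    X = np.stack([
        np.stack([_rescale_to_bins(lut[(d, u)], n_bins) for u in durs])
        for d in dirs
    ])  # (n_dir, n_dur, n_units, n_bins)

    grand = X.mean(axis=(0, 1, 3), keepdims=True)          # per-unit mean
    Xc = X - grand
    m_time = Xc.mean(axis=(0, 1), keepdims=True)           # condition-indep.
    m_dir = Xc.mean(axis=1, keepdims=True) - m_time        # direction x time
    m_dur = Xc.mean(axis=0, keepdims=True) - m_time        # duration x time
    resid = Xc - m_time - m_dir - m_dur

    total = float(np.sum(Xc**2))
    if total == 0:
        raise ValueError("tensor has zero variance")

    def frac(M: np.ndarray) -> float:
        return float(np.sum(np.broadcast_to(M, X.shape) ** 2) / total)

    return {
        "condition_independent": frac(m_time),
        "direction": frac(m_dir),
        "duration": frac(m_dur),
        "interaction": frac(resid),
    }
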