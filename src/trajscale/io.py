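"""HDF5 containers for condition tensors and fitted subspaces."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .preprocess import ConditionTensor
from .subspace import CommonSubspace


def save_condition_tensor(tensor: ConditionTensor, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["scheme"] = tensor.scheme
        f.attrs["dt_ms"] = tensor.dt_ms
        for lab, val, axis, n in zip(tensor.condition_labels, tensor.values,
                                     tensor.time_axes, tensor.n_movements):
            g = f.create_group(f"condition_{lab[0]}_{lab[1]}")
            g.attrs["label"] = list(lab)
            g.attrs["n_movements"] = n
            g.create_dataset("values", data=val)
            g.create_dataset("time_axis_ms", data=axis)
        if tensor.normalization is not None:
            g = f.create_group("normalization")
            for k, v in tensor.normalization.items():
                if np.isscalar(v):
                    g.attrs[k] = v
                else:
                    g.create_dataset(k, data=np.asarray(v))


def load_condition_tensor(path: str | Path) -> ConditionTensor:
    labels, values, axes, counts = [], [], [], []
    norm = None
    with h5py.File(path, "r") as f:
        scheme = f.attrs["scheme"]
        dt_ms = float(f.attrs["dt_ms"])
        for name in sorted(k for k in f if k.startswith("condition_")):
            g = f[name]
            labels.append(tuple(int(x) for x in g.attrs["label"]))
            values.append(g["values"][()])
            axes.append(g["time_axis_ms"][()])
            counts.append(int(g.attrs["n_movements"]))
        if "normalization" in f:
            g = f["normalization"]
            norm = {k: g.attrs[k] for k in g.attrs}
            norm.update({k: g[k][()] for k in g})
    return ConditionTensor(labels, values, axes, counts, str(scheme), dt_ms,
                           normalization=norm)


def save_subspace(space: CommonSubspace, path: str | Path,
                  config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["var_threshold"] = space.var_threshold
        f.attrs["D"] = space.D_
        f.attrs["config_hash"] = config_hash
        f.create_dataset("basis", data=space.basis_)
        f.create_dataset("mean_vector", data=space.mean_vector_)
        f.create_dataset("variance_explained", data=space.variance_explained_)


def load_subspace(path: str | Path) -> CommonSubspace:
    space = CommonSubspace()
    with h5py.File(path, "r") as f:
        space.var_threshold = float(f.attrs["var_threshold"])
        space.D_ = int(f.attrs["D"])
        space.basis_ = f["basis"][()]
        space.mean_vector_ = f["mean_vector"][()]
        space.variance_explained_ = f["variance_explained"][()]
        space.n_units_ = space.basis_.shape[0]
    return space
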