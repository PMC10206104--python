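"""Matrix and result I/O.

Text dialect: plain TSV, no header, one row per node, '.' decimal,
scientific notation allowed — bit-exact and diff-able.  Binary results and
fitted weights go to HDF5.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import Connectome, CouplingWeights, SimulationResult

__all__ = ["read_matrix", "write_matrix", "read_connectome",
           "save_weights", "load_weights", "save_result", "load_config"]


def read_matrix(path) -> np.ndarray:
    """Read a header-free TSV matrix (or an HDF5 file's first dataset)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            key = next(iter(f.keys()))
            return f[key][()]
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_matrix(path, M: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(M), delimiter="\t", fmt="%.17g")


def read_connectome(path) -> Connectome:
    return Connectome(read_matrix(path))


def save_weights(path, W: CouplingWeights, C: Connectome | None = None,
                 **attrs) -> None:
    """Persist fitted weights (datasets w_LRE, w_FFI, J, optionally C)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("w_LRE", data=W.w_LRE)
        f.create_dataset("w_FFI", data=W.w_FFI)
        f.create_dataset("J", data=W.J)
        if C is not None:
            f.create_dataset("C", data=C.C)
        for k, v in attrs.items():
            f.attrs[k] = v


def load_weights(path) -> CouplingWeights:
    with h5py.File(path, "r") as f:
        return CouplingWeights(f["w_LRE"][()], f["w_FFI"][()], f["J"][()])


def save_result(path, res: SimulationResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("bold", data=res.bold)
        f.create_dataset("currents_E", data=res.currents_E)
        f.create_dataset("rates_E", data=res.rates_E)
        f.attrs["dt"] = res.dt
        f.attrs["tr"] = res.tr
        f.attrs["seed"] = res.seed


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}
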