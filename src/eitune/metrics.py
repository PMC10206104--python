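"""Functional-connectivity and synaptic-input summary metrics.

FC is the matrix of pairwise Pearson correlations between regional BOLD
series; mean FC averages its strictly-upper-triangle entries.  Input
summaries quantify the amplitude and synchrony of excitatory synaptic
currents, the quantities that link E/I-balance to circuit behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Connectome, CouplingWeights, DMFParams, DMFSimulator
from .fic import FICParams

__all__ = ["FCMatrix", "InputSummary", "compute_fc", "mean_fc",
           "input_summary", "two_node_sweep", "ratio_to_weights",
           "TwoNodeSweepResult"]


@dataclass
class FCMatrix:
    """Symmetric correlation matrix with unit diagonal."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=np.float64)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("FC must be square")
        self.rho = r

    @property
    def n(self) -> int:
        return self.rho.shape[0]


@dataclass
class InputSummary:
    mean_amplitude: float
    mean_correlation: float


def compute_fc(bold: np.ndarray) -> FCMatrix:
    """Pairwise Pearson correlations of the rows of ``bold`` (node x TR)."""
    bold = np.atleast_2d(np.asarray(bold, dtype=np.float64))
    if bold.shape[1] < 2:
        raise ValueError("need at least 2 TRs to compute FC")
    sd = bold.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance BOLD series at node {bad[0]}")
    rho = np.corrcoef(bold)
    np.fill_diagonal(rho, 1.0)
    return FCMatrix(np.clip(rho, -1.0, 1.0))


def mean_fc(fc: FCMatrix | np.ndarray) -> float:
    """Average of the strictly-upper-triangle FC entries."""
    rho = fc.rho if isinstance(fc, FCMatrix) else np.asarray(fc)
    n = rho.shape[0]
    if n < 2:
        raise ValueError("mean FC requires at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(rho[iu].mean())


def input_summary(currents_E: np.ndarray) -> InputSummary:
    """Grand-mean amplitude and mean pairwise correlation of I_E series."""
    cur = np.atleast_2d(np.asarray(currents_E, dtype=np.float64))
    if cur.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    amp = float(cur.mean())
    if cur.shape[0] < 2:
        return InputSummary(amp, 1.0)
    if np.any(cur.std(axis=1) == 0):
        raise ValueError("constant current series: correlation undefined")
    rho = np.corrcoef(cur)
    iu = np.triu_indices(cur.shape[0], k=1)
    return InputSummary(amp, float(rho[iu].mean()))


def ratio_to_weights(q: float) -> tuple[float, float]:
    """Map an E/I-ratio q to (w_LRE, w_FFI) under w_LRE + w_FFI = 1,
    so that w_LRE / w_FFI = q (total long-range input held constant)."""
    if q <= 0:
        raise ValueError("E/I-ratio must be positive")
    return q / (1.0 + q), 1.0 / (1.0 + q)


@dataclass
class TwoNodeSweepResult:
    """Repeat-averaged tuning curves over an E/I-ratio grid."""

    ratios: np.ndarray
    fc: np.ndarray
    input_correlation: np.ndarray
    input_amplitude: np.ndarray
    input_variance: np.ndarray
    J_mean: np.ndarray


def two_node_sweep(ratio_grid, *, fic: bool = True, repeats: int = 1,
                   seed: int = 0, params: DMFParams | None = None,
                   burn_in_ms: float = 300_000.0,
                   measure_ms: float = 300_000.0,
                   coupling: float = 1.0) -> TwoNodeSweepResult:
    """FC / input-current tuning curves of the two-node network versus
    E/I-ratio, with w_LRE + w_FFI = 1 per connection.

    With FIC active the FC-vs-ratio curve is monotonically increasing;
    without FIC it is not.  Metrics are averaged over ``repeats`` seeds.
    """
    ratios = np.asarray(ratio_grid, dtype=np.float64)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    conn = Connectome.two_node(coupling)
    out = {k: np.zeros(ratios.size) for k in
           ("fc", "ic", "amp", "var", "J")}
    for qi, q in enumerate(ratios):
        w_lre, w_ffi = ratio_to_weights(q)
        for rep in range(repeats):
            W = CouplingWeights.default(2)
            W.w_LRE[:] = [[0.0, w_lre], [w_lre, 0.0]]
            W.w_FFI[:] = [[0.0, w_ffi], [w_ffi, 0.0]]
            sim = DMFSimulator(conn, params, W,
                               seed=seed + 7919 * rep + 104729 * qi)
            sim.run(burn_in_ms, fic=fic)
            res = sim.run(measure_ms, fic=fic)
            out["fc"][qi] += compute_fc(res.bold).rho[0, 1]
            s = input_summary(res.currents_E)
            out["ic"][qi] += s.mean_correlation
            out["amp"][qi] += s.mean_amplitude
            out["var"][qi] += float(res.currents_E.var(axis=1).mean())
            out["J"][qi] += float(W.J.mean())
    for v in out.values():
        v /= repeats
    return TwoNodeSweepResult(ratios, out["fc"], out["ic"], out["amp"],
                              out["var"], out["J"])
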