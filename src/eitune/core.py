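"""Dynamic mean-field brain network model with tunable long-range E/I balance.

Each node holds one excitatory and one inhibitory population (reduced
Wong–Wang dynamics).  Long-range coupling through the structural connectome
C is split into two pathways with independent per-connection multipliers:
w_LRE scales excitatory-to-excitatory (long-range excitation) and w_FFI
scales excitatory-to-inhibitory coupling (feedforward inhibition).  Local
inhibitory feedback J_i is regulated online by feedback inhibition control
(:mod:`eitune.fic`), and excitatory gating drives a Balloon–Windkessel
hemodynamic model (:mod:`eitune.hemodynamics`) sampled once per TR.

Currents (nA), one node i:

    I_E_i = W_E*I_0 + w_plus*J_NMDA*S_E_i
            + J_NMDA * sum_j w_LRE_ij * C_ij * S_E_j - J_i * S_I_i
    I_I_i = W_I*I_0 + J_NMDA*S_E_i
            + J_NMDA * sum_j w_FFI_ij * C_ij * S_E_j - S_I_i

rates through the sigmoidal transfer r(I) = (a*I-b)/(1-exp(-d*(a*I-b))),
and gating by Euler–Maruyama integration of

    dS_E/dt = -S_E/tau_E + (1 - S_E)*gamma_E*r_E + sigma*nu(t)
    dS_I/dt = -S_I/tau_I + gamma_I*r_I + sigma*nu(t)

with independent standard-normal draws per population and step, scaled by
sigma*sqrt(dt), and gating clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit

from .fic import FICParams, apply_fic
from .hemodynamics import (HemodynamicError, HemodynamicState, HemoParams,
                           _bold_readout, _hemo_step)

__all__ = [
    "Connectome", "DMFParams", "CouplingWeights", "NetworkState",
    "SimulationResult", "SimulationError", "transfer_rate",
    "synaptic_currents", "integrate_step", "DMFSimulator", "simulate",
]


class SimulationError(RuntimeError):
    """Raised when the network state becomes non-finite or unphysical."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Connectome:
    """Square nonnegative structural coupling matrix with zero diagonal.

    Self-coupling is expressed by the local recurrence w_plus, never by C.
    """

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=np.float64)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.all(np.isfinite(C)):
            raise ValueError("connectome contains non-finite entries")
        if np.any(C < 0):
            raise ValueError("connectome entries must be nonnegative")
        if np.any(np.diag(C) != 0):
            raise ValueError("connectome diagonal must be zero")
        self.C = np.ascontiguousarray(C)

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    @classmethod
    def two_node(cls, coupling: float = 1.0) -> "Connectome":
        """The reduced two-node network: C_12 = C_21 = coupling."""
        C = np.array([[0.0, coupling], [coupling, 0.0]])
        return cls(C)


@dataclass
class DMFParams:
    """Dynamic mean-field constants (canonical values, all overridable).

    Gains a_* in Hz/nA, thresholds b_* in Hz, shapes d_* in s, time
    constants tau_* in ms, saturation rates gamma_* in 1/ms per Hz,
    currents in nA.
    """

    W_E: float = 1.0
    W_I: float = 0.7
    I_0: float = 0.382
    w_plus: float = 1.4
    J_NMDA: float = 0.15
    a_E: float = 310.0
    b_E: float = 125.0
    d_E: float = 0.16
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 100.0
    tau_I: float = 10.0
    gamma_E: float = 0.641e-3
    gamma_I: float = 1.0e-3
    sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be positive")
        if self.a_E <= 0 or self.a_I <= 0 or self.d_E <= 0 or self.d_I <= 0:
            raise ValueError("transfer gains and shapes must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def as_tuple(self) -> tuple:
        return (self.W_E, self.W_I, self.I_0, self.w_plus, self.J_NMDA,
                self.a_E, self.b_E, self.d_E, self.a_I, self.b_I, self.d_I,
                self.tau_E, self.tau_I, self.gamma_E, self.gamma_I, self.sigma)


@dataclass
class CouplingWeights:
    """Per-connection long-range multipliers and per-node local inhibition.

    Defaults are the untuned state w_LRE = 1, w_FFI = 0 everywhere and
    J_i = 1 nA.
    """

    w_LRE: np.ndarray
    w_FFI: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.w_LRE = np.ascontiguousarray(self.w_LRE, dtype=np.float64)
        self.w_FFI = np.ascontiguousarray(self.w_FFI, dtype=np.float64)
        self.J = np.ascontiguousarray(self.J, dtype=np.float64)
        n = self.J.shape[0]
        if self.w_LRE.shape != (n, n) or self.w_FFI.shape != (n, n):
            raise ValueError("weight matrices must be n x n matching J")
        for name, a in (("w_LRE", self.w_LRE), ("w_FFI", self.w_FFI),
                        ("J", self.J)):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(a < 0):
                raise ValueError(f"{name} entries must be nonnegative")

    @classmethod
    def default(cls, n_nodes: int) -> "CouplingWeights":
        return cls(np.ones((n_nodes, n_nodes)), np.zeros((n_nodes, n_nodes)),
                   np.ones(n_nodes))

    def copy(self) -> "CouplingWeights":
        return CouplingWeights(self.w_LRE.copy(), self.w_FFI.copy(),
                               self.J.copy())


@dataclass
class NetworkState:
    """Instantaneous state of all populations."""

    S_E: np.ndarray
    S_I: np.ndarray
    I_E: np.ndarray
    I_I: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    t: float = 0.0


@dataclass
class SimulationResult:
    """TR-sampled output of one simulation run.

    ``bold`` holds the hemodynamic readout at every TR; ``currents_E``,
    ``rates_E``, ``rates_I`` are window averages over the preceding TR;
    ``gating_E`` samples S_E at the TR boundary.  ``drive`` optionally holds
    the per-step net synaptic drive (Eq.-11-style bracket, i.e. I_E without
    the external W_E*I_0 term) of requested nodes at full dt resolution.
    """

    bold: np.ndarray
    currents_E: np.ndarray
    rates_E: np.ndarray
    rates_I: np.ndarray
    gating_E: np.ndarray
    seed: int
    dt: float
    tr: float
    drive: Optional[np.ndarray] = None
    drive_nodes: Optional[np.ndarray] = None

    @property
    def n_tr(self) -> int:
        return self.bold.shape[1]


# ---------------------------------------------------------------------------
# elementary operations


@njit(cache=True)
def _transfer(x, d):  # pragma: no cover - jitted
    # x = a*I - b; removable singularity at x = 0 with limit 1/d.
    # expm1 keeps the quotient accurate arbitrarily close to the pole.
    if abs(d * x) < 1e-12:
        return 1.0 / d + 0.5 * x
    return x / (-np.expm1(-d * x))


def transfer_rate(I, a: float, b: float, d: float):
    """Sigmoidal current-to-rate transfer (aI-b)/(1-exp(-d(aI-b))) in Hz.

    Continuous through the removable singularity at aI = b where the value
    is 1/d.  Accepts scalars or arrays.
    """
    if a <= 0 or d <= 0:
        raise ValueError("gain a and shape d must be positive")
    I = np.asarray(I, dtype=np.float64)
    if not np.all(np.isfinite(I)):
        raise ValueError("input current must be finite")
    x = a * I - b
    # np.where evaluates both branches; the singular branch may warn.
    # expm1 keeps the quotient accurate arbitrarily close to the pole.
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        out = np.where(np.abs(d * x) < 1e-12, 1.0 / d + 0.5 * x,
                       x / (-np.expm1(-d * x)))
    if out.ndim == 0:
        return float(out)
    return out


def synaptic_currents(state: NetworkState, params: DMFParams, C: Connectome,
                      W: CouplingWeights):
    """Input currents (I_E, I_I) in nA for the given gating state."""
    Cm = C.C if isinstance(C, Connectome) else np.asarray(C, dtype=np.float64)
    n = Cm.shape[0]
    S_E = np.asarray(state.S_E, dtype=np.float64)
    S_I = np.asarray(state.S_I, dtype=np.float64)
    if S_E.shape != (n,) or S_I.shape != (n,) or W.J.shape != (n,):
        raise ValueError("state/weight dimensions do not match the connectome")
    p = params
    I_E = (p.W_E * p.I_0 + p.w_plus * p.J_NMDA * S_E
           + p.J_NMDA * ((W.w_LRE * Cm) @ S_E) - W.J * S_I)
    I_I = (p.W_I * p.I_0 + p.J_NMDA * S_E
           + p.J_NMDA * ((W.w_FFI * Cm) @ S_E) - S_I)
    return I_E, I_I


def integrate_step(state: NetworkState, params: DMFParams, C: Connectome,
                   W: CouplingWeights, dt: float,
                   noise: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> NetworkState:
    """One Euler–Maruyama step; ``noise`` is a pair of standard-normal
    vectors (E, I), or None for the deterministic drift."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params
    I_E, I_I = synaptic_currents(state, p, C, W)
    r_E = transfer_rate(I_E, p.a_E, p.b_E, p.d_E)
    r_I = transfer_rate(I_I, p.a_I, p.b_I, p.d_I)
    n = I_E.shape[0]
    if noise is None:
        nu_E = nu_I = np.zeros(n)
    else:
        nu_E, nu_I = noise
    sq = np.sqrt(dt)
    S_E = (state.S_E + dt * (-state.S_E / p.tau_E
                             + (1.0 - state.S_E) * p.gamma_E * r_E)
           + p.sigma * sq * nu_E)
    S_I = (state.S_I + dt * (-state.S_I / p.tau_I + p.gamma_I * r_I)
           + p.sigma * sq * nu_I)
    np.clip(S_E, 0.0, 1.0, out=S_E)
    np.clip(S_I, 0.0, 1.0, out=S_I)
    new = NetworkState(S_E, S_I, I_E, I_I, np.atleast_1d(r_E),
                       np.atleast_1d(r_I), state.t + dt)
    return new


# ---------------------------------------------------------------------------
# jitted inner loop (one TR chunk per call)


@njit(cache=True)
def _run_chunk(S_E, S_I, hs, hf, hv, hq, C, w_LRE, w_FFI, J, p, hp,
               dt, n_steps, noise_E, noise_I, drive_idx, drive_out,
               acc):  # pragma: no cover - jitted
    """Integrate ``n_steps`` of the coupled system, accumulating window
    averages into ``acc`` rows (r_E, r_I, I_E) and capturing per-step drive
    for the nodes in ``drive_idx``.  Returns (err, step, node)."""
    (W_E, W_I, I_0, w_plus, J_NMDA, a_E, b_E, d_E, a_I, b_I, d_I,
     tau_E, tau_I, gamma_E, gamma_I, sigma) = p
    n = S_E.shape[0]
    M_E = w_LRE * C
    M_I = w_FFI * C
    sq = np.sqrt(dt)
    ext_E = W_E * I_0
    ext_I = W_I * I_0
    I_E = np.empty(n)
    I_I = np.empty(n)
    r_E = np.empty(n)
    r_I = np.empty(n)
    for t in range(n_steps):
        lr_E = M_E @ S_E
        lr_I = M_I @ S_E
        for i in range(n):
            I_E[i] = (ext_E + w_plus * J_NMDA * S_E[i]
                      + J_NMDA * lr_E[i] - J[i] * S_I[i])
            I_I[i] = ext_I + J_NMDA * S_E[i] + J_NMDA * lr_I[i] - S_I[i]
            r_E[i] = _transfer(a_E * I_E[i] - b_E, d_E)
            r_I[i] = _transfer(a_I * I_I[i] - b_I, d_I)
            if not (np.isfinite(I_E[i]) and np.isfinite(I_I[i])):
                return 1, t, i
            acc[0, i] += r_E[i]
            acc[1, i] += r_I[i]
            acc[2, i] += I_E[i]
        for k in range(drive_idx.shape[0]):
            drive_out[k, t] = I_E[drive_idx[k]] - ext_E
        for i in range(n):
            S_E[i] += (dt * (-S_E[i] / tau_E
                             + (1.0 - S_E[i]) * gamma_E * r_E[i])
                       + sigma * sq * noise_E[t, i])
            S_I[i] += (dt * (-S_I[i] / tau_I + gamma_I * r_I[i])
                       + sigma * sq * noise_I[t, i])
            if S_E[i] < 0.0:
                S_E[i] = 0.0
            elif S_E[i] > 1.0:
                S_E[i] = 1.0
            if S_I[i] < 0.0:
                S_I[i] = 0.0
            elif S_I[i] > 1.0:
                S_I[i] = 1.0
        err = _hemo_step(hs, hf, hv, hq, S_E, dt / 1000.0, hp)
        if err != 0:
            return 2, t, -1
    return 0, -1, -1


# ---------------------------------------------------------------------------
# simulator


class DMFSimulator:
    """Stateful network simulator; successive :meth:`run` calls continue the
    same trajectory (gating, hemodynamics, J, noise stream).

    Parameters
    ----------
    C : Connectome or array
    params : DMFParams, optional
    weights : CouplingWeights, optional (shared, mutated by FIC/tuning hooks)
    dt, tr : step and sampling period in ms
    seed : RNG seed; identical seed and inputs give identical output
    """

    def __init__(self, C, params: DMFParams | None = None,
                 weights: CouplingWeights | None = None, *,
                 dt: float = 1.0, tr: float = 720.0, seed: int = 0,
                 hemo_params: HemoParams | None = None,
                 fic_params: FICParams | None = None,
                 init_gating: tuple[np.ndarray, np.ndarray] | None = None):
        self.connectome = C if isinstance(C, Connectome) else Connectome(C)
        n = self.connectome.n_nodes
        self.params = params or DMFParams()
        self.weights = weights if weights is not None else CouplingWeights.default(n)
        if self.weights.J.shape[0] != n:
            raise ValueError("weights do not match connectome size")
        if not (tr >= dt > 0):
            raise ValueError("require tr >= dt > 0")
        self.dt = float(dt)
        self.tr = float(tr)
        self.steps_per_tr = int(round(tr / dt))
        if abs(self.steps_per_tr * dt - tr) > 1e-9 * tr:
            raise ValueError("dt must divide tr")
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self.hemo_params = hemo_params or HemoParams()
        self.fic_params = fic_params or FICParams()
        if init_gating is None:
            jitter = self.rng.uniform(-0.01, 0.01, size=(2, n))
            self.S_E = np.full(n, 0.1) + jitter[0]
            self.S_I = np.full(n, 0.1) + jitter[1]
        else:
            self.S_E = np.array(init_gating[0], dtype=np.float64)
            self.S_I = np.array(init_gating[1], dtype=np.float64)
        self.hemo = HemodynamicState.baseline(n)
        self.t = 0.0
        self.tr_count = 0

    @property
    def n_nodes(self) -> int:
        return self.connectome.n_nodes

    def run(self, duration: float, *, fic: bool = False,
            hook: Optional[Callable] = None,
            capture_drive_nodes: Optional[Sequence[int]] = None
            ) -> SimulationResult:
        """Integrate ``duration`` ms (rounded down to whole TRs).

        Once per TR the FIC update is applied (if ``fic``) using rates
        averaged over the TR window, and ``hook(sim, bold_sample)`` is
        invoked with the newest BOLD sample — the hook may mutate
        ``self.weights`` (online tuning).
        """
        if duration < self.tr:
            raise ValueError("duration must cover at least one TR")
        n = self.n_nodes
        n_chunks = int(duration // self.tr)
        steps = self.steps_per_tr
        if capture_drive_nodes is None:
            drive_idx = np.empty(0, dtype=np.int64)
        else:
            drive_idx = np.asarray(capture_drive_nodes, dtype=np.int64)
            if np.any(drive_idx < 0) or np.any(drive_idx >= n):
                raise ValueError("drive node index out of range")
        drive_all = (np.empty((drive_idx.shape[0], n_chunks * steps))
                     if drive_idx.size else None)
        bold = np.empty((n, n_chunks))
        currents = np.empty((n, n_chunks))
        rates_E = np.empty((n, n_chunks))
        rates_I = np.empty((n, n_chunks))
        gating = np.empty((n, n_chunks))
        ptup = self.params.as_tuple()
        htup = self.hemo_params.as_tuple()
        h = self.hemo
        acc = np.empty((3, n))
        bold_sample = np.empty(n)
        drive_chunk = np.empty((drive_idx.shape[0], steps))
        for k in range(n_chunks):
            noise = self.rng.standard_normal((2, steps, n))
            acc[:] = 0.0
            err, step, node = _run_chunk(
                self.S_E, self.S_I, h.s, h.f, h.v, h.q,
                self.connectome.C, self.weights.w_LRE, self.weights.w_FFI,
                self.weights.J, ptup, htup, self.dt, steps,
                noise[0], noise[1], drive_idx, drive_chunk, acc)
            if err == 1:
                raise SimulationError(
                    f"non-finite current at step {step} of TR "
                    f"{self.tr_count + k}, node {node}")
            if err == 2:
                raise HemodynamicError(
                    f"hemodynamic state left physical domain at step {step} "
                    f"of TR {self.tr_count + k}; use a smaller dt")
            acc /= steps
            _bold_readout(h.v, h.q, htup, bold_sample)
            bold[:, k] = bold_sample
            rates_E[:, k] = acc[0]
            rates_I[:, k] = acc[1]
            currents[:, k] = acc[2]
            gating[:, k] = self.S_E
            if drive_all is not None:
                drive_all[:, k * steps:(k + 1) * steps] = drive_chunk
            if fic:
                apply_fic(self.weights.J, (acc[1], acc[0]), self.fic_params)
            if hook is not None:
                hook(self, bold[:, k])
        self.t += n_chunks * self.tr
        self.tr_count += n_chunks
        return SimulationResult(bold, currents, rates_E, rates_I, gating,
                                self.seed, self.dt, self.tr,
                                drive=drive_all,
                                drive_nodes=(drive_idx if drive_idx.size
                                             else None))


def simulate(C, params: DMFParams | None = None,
             W: CouplingWeights | None = None, *, duration: float,
             dt: float = 1.0, tr: float = 720.0, seed: int = 0,
             fic: bool = False, fic_params: FICParams | None = None,
             tuning_hook: Optional[Callable] = None,
             capture_drive_nodes: Optional[Sequence[int]] = None
             ) -> SimulationResult:
    """Convenience one-shot simulation (see :class:`DMFSimulator`)."""
    if not (duration >= tr >= dt > 0):
        raise ValueError("require duration >= tr >= dt > 0")
    sim = DMFSimulator(C, params, W, dt=dt, tr=tr, seed=seed,
                       fic_params=fic_params)
    return sim.run(duration, fic=fic, hook=tuning_hook,
                   capture_drive_nodes=capture_drive_nodes)
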