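"""Balloon–Windkessel hemodynamic forward model.

Converts excitatory synaptic gating into BOLD signal via the classic
four-variable balloon model (vasodilatory signal ``s``, inflow ``f``,
venous volume ``v``, deoxyhemoglobin ``q``) with a static nonlinear
readout.  One independent hemodynamic unit per network node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["HemoParams", "HemodynamicState", "bold_from_gating", "HemodynamicError"]


class HemodynamicError(RuntimeError):
    """Raised when the hemodynamic ODEs leave their physical domain."""


@dataclass
class HemoParams:
    """Balloon–Windkessel constants (rates in 1/s, times in s).

    kappa    : vasodilatory signal decay rate
    gamma_h  : flow-dependent elimination rate
    tau_h    : hemodynamic transit time
    alpha    : Grubb's vessel stiffness exponent
    rho_h    : resting oxygen extraction fraction
    V0       : resting venous blood volume fraction
    k1,k2,k3 : BOLD readout coefficients (k1=7*rho_h, k2=2, k3=2*rho_h-0.2)
    """

    kappa: float = 0.65
    gamma_h: float = 0.41
    tau_h: float = 0.98
    alpha: float = 0.32
    rho_h: float = 0.34
    V0: float = 0.02
    k1: float = field(default=7.0 * 0.34)
    k2: float = 2.0
    k3: float = field(default=2.0 * 0.34 - 0.2)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("kappa", "gamma_h", "tau_h", "rho_h", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_tuple(self) -> tuple:
        return (self.kappa, self.gamma_h, self.tau_h, self.alpha,
                self.rho_h, self.V0, self.k1, self.k2, self.k3)


@dataclass
class HemodynamicState:
    """Per-node hemodynamic state; baseline is s=0, f=v=q=1."""

    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @classmethod
    def baseline(cls, n_nodes: int) -> "HemodynamicState":
        return cls(np.zeros(n_nodes), np.ones(n_nodes),
                   np.ones(n_nodes), np.ones(n_nodes))


@njit(cache=True)
def _hemo_step(s, f, v, q, z, dt_s, hp):  # pragma: no cover - jitted
    """One explicit-Euler step of the balloon ODEs; returns 0 or error code 2."""
    kappa, gamma_h, tau_h, alpha, rho_h, _V0, _k1, _k2, _k3 = hp
    ia = 1.0 / alpha
    for i in range(s.shape[0]):
        fi = f[i]
        vi = v[i]
        if fi <= 0.0 or vi <= 0.0:
            return 2
        ds = z[i] - kappa * s[i] - gamma_h * (fi - 1.0)
        df = s[i]
        dv = (fi - vi ** ia) / tau_h
        dq = (fi * (1.0 - (1.0 - rho_h) ** (1.0 / fi)) / rho_h
              - q[i] * vi ** (ia - 1.0)) / tau_h
        s[i] += dt_s * ds
        f[i] += dt_s * df
        v[i] += dt_s * dv
        q[i] += dt_s * dq
    return 0


@njit(cache=True)
def _bold_readout(v, q, hp, out):  # pragma: no cover - jitted
    _kappa, _gamma_h, _tau_h, _alpha, _rho_h, V0, k1, k2, k3 = hp
    for i in range(v.shape[0]):
        out[i] = V0 * (k1 * (1.0 - q[i]) + k2 * (1.0 - q[i] / v[i])
                       + k3 * (1.0 - v[i]))


@njit(cache=True)
def _bold_series(S_E, dt_s, sample_every, hp, bold):  # pragma: no cover
    n, n_t = S_E.shape
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    out = np.empty(n)
    k = 0
    for t in range(n_t):
        err = _hemo_step(s, f, v, q, S_E[:, t], dt_s, hp)
        if err != 0:
            return t
        if (t + 1) % sample_every == 0:
            _bold_readout(v, q, hp, out)
            bold[:, k] = out
            k += 1
    return -1


def bold_from_gating(S_E_series: np.ndarray, dt: float, tr: float,
                     params: HemoParams | None = None) -> np.ndarray:
    """Integrate the balloon model driven by gating ``S_E_series`` (node x time).

    ``dt`` and ``tr`` are in ms; ``dt`` must divide ``tr``.  Returns the BOLD
    signal sampled every ``tr`` ms, shape (n_nodes, n_TR).  Deterministic.
    """
    params = params or HemoParams()
    S = np.ascontiguousarray(np.atleast_2d(np.asarray(S_E_series, dtype=np.float64)))
    if not np.all(np.isfinite(S)):
        raise ValueError("gating series contains non-finite values")
    if dt <= 0 or tr <= 0:
        raise ValueError("dt and tr must be positive")
    sample_every = int(round(tr / dt))
    if abs(sample_every * dt - tr) > 1e-9 * tr or sample_every < 1:
        raise ValueError("dt must divide tr")
    n_tr = S.shape[1] // sample_every
    bold = np.empty((S.shape[0], n_tr))
    bad = _bold_series(S, dt / 1000.0, sample_every, params.as_tuple(), bold)
    if bad >= 0:
        raise HemodynamicError(
            f"blood flow or volume became non-positive at step {bad}; "
            "use a smaller dt")
    return bold
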