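"""Feedback inhibition control (FIC).

Homeostatic inhibitory synaptic plasticity: the local inhibitory-to-excitatory
weight J_i of every node is nudged once per update interval so that the
long-term average firing rate of the excitatory population settles at the
target rate rho_0 (4 Hz).  The rule is Hebbian with a presynaptic gate:

    delta_J = eta_FIC * (pre * post - rho_0 * pre)

with ``pre`` the window-averaged inhibitory rate and ``post`` the excitatory
rate of the same node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FICParams", "fic_delta", "apply_fic"]


@dataclass
class FICParams:
    """eta_FIC: learning rate; rho_0: target excitatory rate (Hz);
    update_interval: ms between updates; J_min: lower clamp (nA)."""

    eta_FIC: float = 0.001
    rho_0: float = 4.0
    update_interval: float = 720.0
    J_min: float = 0.001

    def __post_init__(self) -> None:
        if self.eta_FIC <= 0:
            raise ValueError("eta_FIC must be positive")
        if self.rho_0 <= 0:
            raise ValueError("rho_0 must be positive")
        if self.update_interval <= 0:
            raise ValueError("update_interval must be positive")


def fic_delta(pre, post, p: FICParams | None = None):
    """Weight change (nA) for presynaptic rate ``pre`` and postsynaptic rate
    ``post`` (Hz); positive when post exceeds the target, zero when pre is 0."""
    p = p or FICParams()
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if np.any(pre < 0) or np.any(post < 0):
        raise ValueError("firing rates must be nonnegative")
    return p.eta_FIC * (pre * post - p.rho_0 * pre)


def apply_fic(J: np.ndarray, window_rates, p: FICParams | None = None) -> np.ndarray:
    """Update all J_i simultaneously from window-averaged (pre, post) rates,
    clamping at J_min.  Returns the updated vector (also modified in place)."""
    p = p or FICParams()
    pre, post = window_rates
    delta = fic_delta(pre, post, p)
    np.maximum(J + delta, p.J_min, out=J)
    return J
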