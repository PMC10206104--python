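"""Frontoparietal winner-take-all circuit for decision-making and WM.

Four reduced NMDA-gating populations — two stimulus-selective pools in
posterior parietal cortex (A_PPC, B_PPC) and two in prefrontal cortex
(A_PFC, B_PFC).  Same-selectivity pools excite each other within and
across areas; opposite-selectivity pools inhibit each other (effective
cross-inhibition through local interneurons).  Each pool follows

    dS/dt = -S/tau + gamma * (1 - S) * r(I),
    I_i   = sum_j J[i, j] * S_j + I_0 + I_app_i + I_noise_i,
    r(I)  = (a*I - b) / (1 - exp(-c*(a*I - b)))

with AMPA-like input noise from an Ornstein–Uhlenbeck process (Euler–
Maruyama, time constant tau_AMPA).  Evidence enters as external currents
to the two PPC pools, I_e*(1 +/- c'/100); a decision is registered when a
PFC pool's rate crosses the threshold (40 Hz), and the time from stimulus
onset to crossing is the integration time.  A brief stimulus to one PPC
pool can also induce persistent activity (working memory), which a later
distractor to the rival pool may or may not disrupt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .core import _transfer

__all__ = ["DMParams", "NoiseSpec", "DMTrialResult", "DMExperimentResult",
           "WMOutcome", "build_couplings", "ou_noise", "evidence_input",
           "dm_trial", "dm_experiment", "wm_trial", "bifurcation_map",
           "A_PPC", "B_PPC", "A_PFC", "B_PFC"]

A_PPC, B_PPC, A_PFC, B_PFC = 0, 1, 2, 3


def build_couplings(j_self: float = 0.35, j_cross: float = 0.11,
                    j_ff: float = 0.09, j_ff_cross: float = 0.0,
                    j_fb: float = 0.04, j_fb_cross: float = 0.0
                    ) -> np.ndarray:
    """4x4 synaptic coupling matrix J[target, source] (nA).

    Within each area: self-excitation ``j_self`` and cross-inhibition
    ``-j_cross``.  Between areas: same-selectivity excitation (``j_ff``
    PPC->PFC, ``j_fb`` PFC->PPC) and opposite-selectivity inhibition.
    """
    J = np.zeros((4, 4))
    for a_, b_ in ((A_PPC, B_PPC), (A_PFC, B_PFC)):
        J[a_, a_] = J[b_, b_] = j_self
        J[a_, b_] = J[b_, a_] = -j_cross
    # PPC -> PFC
    J[A_PFC, A_PPC] = J[B_PFC, B_PPC] = j_ff
    J[A_PFC, B_PPC] = J[B_PFC, A_PPC] = -j_ff_cross
    # PFC -> PPC
    J[A_PPC, A_PFC] = J[B_PPC, B_PFC] = j_fb
    J[A_PPC, B_PFC] = J[B_PPC, A_PFC] = -j_fb_cross
    return J


@dataclass
class DMParams:
    """Circuit constants.

    J_syn[i, j] couples source pool j to target pool i (nA); a (Hz/nA),
    b (Hz), c (s) shape the transfer function; tau is the NMDA gating
    time constant (ms), gamma its saturation rate (per Hz, seconds
    convention); tau_AMPA (ms) and sigma_noise (nA) parametrize the OU
    input noise; I_e and c_prime define the evidence currents; a decision
    needs a PFC rate above ``threshold`` (Hz) within ``trial_max`` (ms).
    """

    J_syn: np.ndarray = field(default_factory=build_couplings)
    I0_dm: float = 0.323
    a: float = 270.0
    b: float = 108.0
    c: float = 0.154
    tau: float = 60.0
    gamma: float = 0.641
    tau_AMPA: float = 2.0
    sigma_noise: float = 0.02
    threshold: float = 40.0
    I_e: float = 0.0118
    c_prime: float = 6.4
    trial_max: float = 3000.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        self.J_syn = np.ascontiguousarray(self.J_syn, dtype=np.float64)
        if self.J_syn.shape != (4, 4):
            raise ValueError("J_syn must be 4x4")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.tau <= 0 or self.tau_AMPA <= 0:
            raise ValueError("time constants must be positive")
        if self.trial_max <= 0:
            raise ValueError("trial_max must be positive")
        if not (0 < self.dt < self.tau_AMPA):
            raise ValueError("require 0 < dt < tau_AMPA")

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_max / self.dt))


@dataclass
class NoiseSpec:
    """OU-input statistics: per-area mean offsets (nA) and within-area
    noise correlations in [0, 1]."""

    mean_ppc: float = 0.0
    mean_pfc: float = 0.0
    corr_ppc: float = 0.0
    corr_pfc: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("corr_ppc", "corr_pfc"):
            c = getattr(self, nm)
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"{nm} must lie in [0, 1]")
        if not (np.isfinite(self.mean_ppc) and np.isfinite(self.mean_pfc)):
            raise ValueError("noise means must be finite")


@dataclass
class DMTrialResult:
    decision: str                      # "A", "B" or "none"
    integration_time: float            # ms; NaN when no decision
    trajectories: Optional[np.ndarray] = None  # (4, n_steps) rates


@dataclass
class DMExperimentResult:
    percent_correct: float
    mean_integration_time: float       # ms over decided trials; NaN if none
    n_decided: int
    n_trials: int


@dataclass
class WMOutcome:
    regime: str                        # "no_induction", "disrupted", "robust"


@njit(cache=True)
def _ou_pair(white_sh, white_a, white_b, dt, tau, sigma, corr,
             mean):  # pragma: no cover - jitted
    """Two OU series whose white-noise drives share a sqrt(corr) common
    component; Euler–Maruyama per Eq-of-motion tau*dI = -I dt + eta*sqrt(tau
    sigma^2) dW."""
    n = white_sh.shape[0]
    out = np.empty((2, n))
    sc = np.sqrt(corr)
    si = np.sqrt(1.0 - corr)
    g = np.sqrt(dt / tau) * sigma
    xa = 0.0
    xb = 0.0
    k = dt / tau
    for t in range(n):
        ea = sc * white_sh[t] + si * white_a[t]
        eb = sc * white_sh[t] + si * white_b[t]
        xa += -xa * k + g * ea
        xb += -xb * k + g * eb
        out[0, t] = xa + mean
        out[1, t] = xb + mean
    return out


def ou_noise(duration: float, dt: float, tau_AMPA: float,
             sigma_noise: float, corr: float, mean: float,
             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two correlated OU current series (nA) of length duration/dt.

    The white-noise drives share a common component so their empirical
    correlation approaches ``corr``; each series is offset by ``mean``.
    """
    if not (0.0 <= corr <= 1.0):
        raise ValueError("corr must lie in [0, 1]")
    if not (0 < dt < tau_AMPA):
        raise ValueError("require 0 < dt < tau_AMPA")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((3, n))
    out = _ou_pair(w[0], w[1], w[2], dt, tau_AMPA, sigma_noise, corr, mean)
    return out[0], out[1]


def evidence_input(I_e: float, c_prime: float) -> tuple[float, float]:
    """Evidence currents to (A_PPC, B_PPC): I_e*(1 + c'/100) to the favored
    pool A and I_e*(1 - c'/100) to B."""
    if I_e < 0:
        raise ValueError("I_e must be nonnegative")
    return I_e * (1.0 + c_prime / 100.0), I_e * (1.0 - c_prime / 100.0)


@njit(cache=True)
def _race(J, I0, a, b, c, tau, gamma_ms, dt, inputs, threshold,
          record, rates_out):  # pragma: no cover - jitted
    """Integrate the 4-pool circuit; returns (winner, step).

    winner: 0/1 = A/B PFC pool first above threshold, -1 = none,
    -2 = non-finite state (step reported).  Tie at one step goes to the
    pool with the higher rate; an exact tie is no decision.
    """
    n_steps = inputs.shape[1]
    S = np.full(4, 0.1)
    I = np.empty(4)
    r = np.empty(4)
    winner = -1
    win_step = -1
    for t in range(n_steps):
        for i in range(4):
            tot = I0 + inputs[i, t]
            for j in range(4):
                tot += J[i, j] * S[j]
            I[i] = tot
            if not np.isfinite(tot):
                return -2, t
            r[i] = _transfer(a * tot - b, c)
            if record:
                rates_out[i, t] = r[i]
        if winner < 0:
            a_hit = r[2] >= threshold
            b_hit = r[3] >= threshold
            if a_hit or b_hit:
                if a_hit and b_hit:
                    if r[2] > r[3]:
                        winner, win_step = 0, t
                    elif r[3] > r[2]:
                        winner, win_step = 1, t
                    # exact tie: no decision, race continues
                elif a_hit:
                    winner, win_step = 0, t
                else:
                    winner, win_step = 1, t
                if winner >= 0 and not record:
                    return winner, win_step
        for i in range(4):
            S[i] += dt * (-S[i] / tau + gamma_ms * (1.0 - S[i]) * r[i])
            if S[i] < 0.0:
                S[i] = 0.0
            elif S[i] > 1.0:
                S[i] = 1.0
    return winner, win_step


def _trial_inputs(p: DMParams, noise: NoiseSpec, n_steps: int,
                  rng: np.random.Generator, evidence: bool = True,
                  ) -> np.ndarray:
    """External input series (4, n_steps): evidence plus OU noise."""
    w = rng.standard_normal((6, n_steps))
    ppc = _ou_pair(w[0], w[1], w[2], p.dt, p.tau_AMPA, p.sigma_noise,
                   noise.corr_ppc, noise.mean_ppc)
    pfc = _ou_pair(w[3], w[4], w[5], p.dt, p.tau_AMPA, p.sigma_noise,
                   noise.corr_pfc, noise.mean_pfc)
    inputs = np.empty((4, n_steps))
    inputs[A_PPC] = ppc[0]
    inputs[B_PPC] = ppc[1]
    inputs[A_PFC] = pfc[0]
    inputs[B_PFC] = pfc[1]
    if evidence:
        ia, ib = evidence_input(p.I_e, p.c_prime)
        inputs[A_PPC] += ia
        inputs[B_PPC] += ib
    return inputs


def _run_race(p: DMParams, inputs: np.ndarray,
              record: bool = False) -> DMTrialResult:
    gamma_ms = p.gamma / 1000.0
    rates = np.empty((4, inputs.shape[1])) if record else np.empty((1, 1))
    winner, step = _race(p.J_syn, p.I0_dm, p.a, p.b, p.c, p.tau, gamma_ms,
                         p.dt, inputs, p.threshold, record, rates)
    if winner == -2:
        raise RuntimeError(f"non-finite circuit state at step {step}")
    decision = {0: "A", 1: "B", -1: "none"}[winner]
    it = (step + 1) * p.dt if winner >= 0 else float("nan")
    return DMTrialResult(decision, it, rates if record else None)


def dm_trial(p: DMParams, noise: NoiseSpec | np.ndarray, seed: int = 0,
             record: bool = False) -> DMTrialResult:
    """One decision trial.

    ``noise`` is either a :class:`NoiseSpec` (isolated circuit: evidence +
    OU noise generated from ``seed``) or a prebuilt (4, n_steps) external
    drive series (multiscale coupling), used as-is.
    """
    if isinstance(noise, NoiseSpec):
        rng = np.random.default_rng(seed)
        inputs = _trial_inputs(p, noise, p.n_steps, rng)
    else:
        inputs = np.ascontiguousarray(noise, dtype=np.float64)
        if inputs.ndim != 2 or inputs.shape[0] != 4:
            raise ValueError("external drive must have shape (4, n_steps)")
        if inputs.shape[1] < p.n_steps:
            raise ValueError("external drive shorter than trial_max")
    return _run_race(p, inputs, record)


def dm_experiment(p: DMParams, noise: NoiseSpec, n_trials: int,
                  seed: int = 0) -> DMExperimentResult:
    """Repeat the decision task; a correct decision is one for option A
    (the pool receiving the higher evidence).

    percent_correct counts A-decisions over *all* trials; integration
    time is averaged over decided trials only.  Per-trial seeds derive
    from the master seed, so results are reproducible.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(n_trials)]
    n_a = 0
    n_dec = 0
    t_sum = 0.0
    for rng in rngs:
        inputs = _trial_inputs(p, noise, p.n_steps, rng)
        res = _run_race(p, inputs)
        if res.decision != "none":
            n_dec += 1
            t_sum += res.integration_time
            if res.decision == "A":
                n_a += 1
    mean_t = t_sum / n_dec if n_dec else float("nan")
    return DMExperimentResult(100.0 * n_a / n_trials, mean_t, n_dec,
                              n_trials)


# ---------------------------------------------------------------------------
# working memory protocol


def _wm_params(p: DMParams, J_S: float) -> DMParams:
    """Shift within-area self/cross couplings so that net recurrent
    strength (self minus cross) equals J_S, split symmetrically."""
    J = p.J_syn.copy()
    j_s0 = J[A_PPC, A_PPC]
    j_c0 = J[A_PPC, B_PPC]
    delta = J_S - (j_s0 - j_c0)
    for a_, b_ in ((A_PPC, B_PPC), (A_PFC, B_PFC)):
        J[a_, a_] = J[b_, b_] = j_s0 + delta / 2.0
        J[a_, b_] = J[b_, a_] = j_c0 - delta / 2.0
    q = DMParams(**{**p.__dict__, "J_syn": J})
    return q


def wm_trial(p: DMParams, J_S: float, I_app: float,
             input_amplitude: float = 0.0, seed: int = 0, *,
             stim_ms: float = 250.0, stim_onset_ms: float = 500.0,
             distractor_delay_ms: float = 1500.0,
             duration_ms: float = 4000.0,
             memory_rate: float = 20.0, margin_rate: float = 10.0,
             record: bool = False) -> WMOutcome:
    """Working-memory induction/distraction trial.

    A target boxcar stimulus (amplitude ``I_app``) drives A_PPC; a
    distractor of the same amplitude drives B_PPC ``distractor_delay_ms``
    later.  OU noise with mean ``input_amplitude`` feeds all pools.
    Memory is present when A_PPC's mean rate over the last 500 ms before
    the distractor exceeds ``memory_rate`` and the rival's by
    ``margin_rate``; the regime is then robust or disrupted according to
    the same criterion over the final 500 ms.
    """
    q = _wm_params(p, J_S)
    n_steps = int(round(duration_ms / q.dt))
    rng = np.random.default_rng(seed)
    spec = NoiseSpec(mean_ppc=input_amplitude, mean_pfc=input_amplitude)
    inputs = _trial_inputs(q, spec, n_steps, rng, evidence=False)
    i0 = int(round(stim_onset_ms / q.dt))
    i1 = i0 + int(round(stim_ms / q.dt))
    d0 = i0 + int(round(distractor_delay_ms / q.dt))
    d1 = d0 + int(round(stim_ms / q.dt))
    inputs[A_PPC, i0:i1] += I_app
    inputs[B_PPC, d0:d1] += I_app
    gamma_ms = q.gamma / 1000.0
    rates = np.empty((4, n_steps))
    winner, step = _race(q.J_syn, q.I0_dm, q.a, q.b, q.c, q.tau, gamma_ms,
                         q.dt, inputs, np.inf, True, rates)
    if winner == -2:
        raise RuntimeError(f"non-finite circuit state at step {step}")
    half_s = int(round(500.0 / q.dt))

    def memory(window: slice) -> bool:
        ra = rates[A_PPC, window].mean()
        rb = rates[B_PPC, window].mean()
        return ra > memory_rate and (ra - rb) > margin_rate

    induced = memory(slice(d0 - half_s, d0))
    if not induced:
        return WMOutcome("no_induction")
    held = memory(slice(n_steps - half_s, n_steps))
    return WMOutcome("robust" if held else "disrupted")


def bifurcation_map(p: DMParams, J_S_grid, I_app_grid,
                    input_amplitude: float = 0.0,
                    seeds=(0, 1, 2)) -> np.ndarray:
    """Majority WM regime over seeds at each (J_S, I_app) grid point.

    Returns an object array of regime strings, shape
    (len(J_S_grid), len(I_app_grid)).
    """
    J_S_grid = np.atleast_1d(np.asarray(J_S_grid, dtype=np.float64))
    I_app_grid = np.atleast_1d(np.asarray(I_app_grid, dtype=np.float64))
    if J_S_grid.size == 0 or I_app_grid.size == 0:
        raise ValueError("grids must be nonempty")
    out = np.empty((J_S_grid.size, I_app_grid.size), dtype=object)
    for i, js in enumerate(J_S_grid):
        for j, ia in enumerate(I_app_grid):
            votes = [wm_trial(p, js, ia, input_amplitude, seed=s).regime
                     for s in seeds]
            out[i, j] = max(set(votes), key=votes.count)
    return out
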