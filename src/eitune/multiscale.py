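"""Coupling fitted large-scale models to the decision circuit.

The net synaptic drive of a chosen PFC and PPC node (local recurrent
excitation plus long-range input minus local inhibition, i.e. the
excitatory input current without its constant external term) is extracted
at circuit resolution, range-normalized across a cohort of models so that
the 10th–90th percentile band of per-region mean amplitudes maps onto the
current range the circuit operates in ([a_MJW, b_MJW] = [-0.006, 0.001]
nA), and injected into both pools of the corresponding circuit module in
place of the OU noise mean — each pool keeping its own independent OU
noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (Connectome, CouplingWeights, DMFParams, DMFSimulator,
                   SimulationResult)
from .dm import A_PFC, A_PPC, B_PFC, B_PPC, DMExperimentResult, DMParams, \
    _ou_pair, _run_race, evidence_input

__all__ = ["CouplingSpec", "region_drive", "drive_from_gating",
           "cohort_range", "normalize_drive", "multiscale_dm"]


@dataclass
class CouplingSpec:
    """Range-normalization spec for large-scale -> circuit coupling.

    pfc_regions / ppc_regions list candidate node indices; [a_MJW, b_MJW]
    is the target current band (nA); lo_pct/hi_pct are the cohort
    percentiles defining the per-region source band.
    """

    pfc_regions: tuple = ()
    ppc_regions: tuple = ()
    a_MJW: float = -0.006
    b_MJW: float = 0.001
    lo_pct: float = 10.0
    hi_pct: float = 90.0

    def __post_init__(self) -> None:
        if not self.a_MJW < self.b_MJW:
            raise ValueError("require a_MJW < b_MJW")
        if not (0.0 <= self.lo_pct < self.hi_pct <= 100.0):
            raise ValueError("require 0 <= lo_pct < hi_pct <= 100")
        if set(self.pfc_regions) & set(self.ppc_regions):
            raise ValueError("PFC and PPC region lists must be disjoint")


def drive_from_gating(S_E: np.ndarray, S_I_node: np.ndarray,
                      C: Connectome, W: CouplingWeights,
                      params: DMFParams, node: int) -> np.ndarray:
    """Net synaptic drive of ``node`` from gating series (oracle path):
    w_plus*J_NMDA*S_E_i + J_NMDA*sum_j w_LRE_ij*C_ij*S_E_j - J_i*S_I_i,
    excluding the external W_E*I_0 term."""
    p = params
    Cm = C.C if isinstance(C, Connectome) else C
    row = W.w_LRE[node] * Cm[node]
    return (p.w_plus * p.J_NMDA * S_E[node]
            + p.J_NMDA * (row @ S_E) - W.J[node] * S_I_node)


def region_drive(sim: SimulationResult, node: int) -> np.ndarray:
    """Per-step drive series (nA) of ``node`` captured during simulation.

    Requires the simulation to have been run with
    ``capture_drive_nodes`` including ``node``.
    """
    if sim.drive is None or sim.drive_nodes is None:
        raise ValueError(
            "simulation was run without drive capture; pass "
            "capture_drive_nodes=[...] to simulate/run")
    where = np.where(sim.drive_nodes == node)[0]
    if where.size == 0:
        raise ValueError(f"node {node} was not captured "
                         f"(captured: {sim.drive_nodes.tolist()})")
    return sim.drive[where[0]]


def cohort_range(drives, spec: CouplingSpec) -> tuple[float, float]:
    """(a_BNM, b_BNM): lo/hi percentiles (linear interpolation) of one
    region's mean drive amplitudes over the cohort."""
    x = np.asarray(drives, dtype=np.float64)
    if x.size < 2:
        raise ValueError("cohort needs at least 2 models")
    a, b = np.percentile(x, [spec.lo_pct, spec.hi_pct])
    if b <= a:
        raise ValueError("degenerate cohort: zero spread in drive amplitudes")
    return float(a), float(b)


def normalize_drive(x: np.ndarray, a_BNM: float, b_BNM: float,
                    spec: CouplingSpec) -> np.ndarray:
    """Affine range normalization of a drive series into [a_MJW, b_MJW]:
    values outside the source band map linearly beyond the target bounds
    (no clipping).  The circuit's own OU noise is added downstream."""
    if b_BNM <= a_BNM:
        raise ValueError("require b_BNM > a_BNM")
    x = np.asarray(x, dtype=np.float64)
    return ((spec.b_MJW - spec.a_MJW) * (x - a_BNM) / (b_BNM - a_BNM)
            + spec.a_MJW)


def _zero_order_hold(x: np.ndarray, factor: int) -> np.ndarray:
    return np.repeat(x, factor)


def _model_drives(conn: Connectome, W: CouplingWeights,
                  params: DMFParams | None, ppc_node: int, pfc_node: int,
                  duration_ms: float, seed: int,
                  burn_in_ms: float = 28_800.0):
    """Simulate one fitted model (J frozen) capturing per-step drives of
    the two chosen nodes; returns (ppc_drive, pfc_drive) at large-scale dt.
    """
    sim = DMFSimulator(conn, params, W.copy(), seed=seed)
    sim.run(burn_in_ms, fic=False)
    res = sim.run(duration_ms, fic=False,
                  capture_drive_nodes=[ppc_node, pfc_node])
    return region_drive(res, ppc_node), region_drive(res, pfc_node), res


def multiscale_dm(models, spec: CouplingSpec, pfc_node: int, ppc_node: int,
                  p: DMParams | None = None, n_trials: int = 100,
                  seed: int = 0, *, params: DMFParams | None = None
                  ) -> list[DMExperimentResult]:
    """Drive the circuit with each fitted model's normalized regional
    drives and run decision experiments.

    ``models`` is a sequence of (Connectome, CouplingWeights) fitted
    models.  Both pools of the PPC module receive the same normalized
    PPC-node drive plus independent OU noise; likewise for PFC.  Evidence
    currents are added to the PPC pools as in the isolated circuit.
    """
    p = p or DMParams()
    if spec.pfc_regions and pfc_node not in spec.pfc_regions:
        raise ValueError(f"pfc_node {pfc_node} not in spec.pfc_regions")
    if spec.ppc_regions and ppc_node not in spec.ppc_regions:
        raise ValueError(f"ppc_node {ppc_node} not in spec.ppc_regions")
    dmf = params or DMFParams()
    hold = int(round(1.0 / p.dt))  # large-scale dt (1 ms) -> circuit dt
    need_ms = n_trials * p.trial_max
    dur = float(int(np.ceil(need_ms / 720.0)) * 720.0)
    ppc_all, pfc_all = [], []
    for k, (conn, W) in enumerate(models):
        d_ppc, d_pfc, _ = _model_drives(conn, W, dmf, ppc_node, pfc_node,
                                        dur, seed + 7919 * k)
        ppc_all.append(d_ppc)
        pfc_all.append(d_pfc)
    a_ppc, b_ppc = cohort_range([d.mean() for d in ppc_all], spec)
    a_pfc, b_pfc = cohort_range([d.mean() for d in pfc_all], spec)
    ia, ib = evidence_input(p.I_e, p.c_prime)
    n_steps = p.n_steps
    results = []
    for k in range(len(ppc_all)):
        z_ppc = _zero_order_hold(
            normalize_drive(ppc_all[k], a_ppc, b_ppc, spec), hold)
        z_pfc = _zero_order_hold(
            normalize_drive(pfc_all[k], a_pfc, b_pfc, spec), hold)
        rng = np.random.default_rng(seed + 104729 * k + 1)
        n_a = 0
        n_dec = 0
        t_sum = 0.0
        for trial in range(n_trials):
            lo = trial * n_steps
            seg_ppc = z_ppc[lo:lo + n_steps]
            seg_pfc = z_pfc[lo:lo + n_steps]
            w = rng.standard_normal((6, n_steps))
            ou_ppc = _ou_pair(w[0], w[1], w[2], p.dt, p.tau_AMPA,
                              p.sigma_noise, 0.0, 0.0)
            ou_pfc = _ou_pair(w[3], w[4], w[5], p.dt, p.tau_AMPA,
                              p.sigma_noise, 0.0, 0.0)
            inputs = np.empty((4, n_steps))
            inputs[A_PPC] = seg_ppc + ou_ppc[0] + ia
            inputs[B_PPC] = seg_ppc + ou_ppc[1] + ib
            inputs[A_PFC] = seg_pfc + ou_pfc[0]
            inputs[B_PFC] = seg_pfc + ou_pfc[1]
            res = _run_race(p, inputs)
            if res.decision != "none":
                n_dec += 1
                t_sum += res.integration_time
                if res.decision == "A":
                    n_a += 1
        mean_t = t_sum / n_dec if n_dec else float("nan")
        results.append(DMExperimentResult(100.0 * n_a / n_trials, mean_t,
                                          n_dec, n_trials))
    return results
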