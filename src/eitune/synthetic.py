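"""Synthetic connectomes, ground-truth target FCs, and cohorts.

Stands in for tractography-derived structural connectomes and empirical FC:
connectomes are random connected weighted graphs (log-normal weights,
row-sum normalized), and target FCs are generated by simulating the model
itself with randomized ground-truth E/I-ratios, so that a perfect fit is
achievable by construction.  Cohorts scale the generating E/I-ratios to
span a controlled range of mean FC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Connectome, CouplingWeights, DMFSimulator, DMFParams
from .fic import FICParams
from .metrics import compute_fc
from .tuning import TargetFC

__all__ = ["SynthSpec", "gen_connectome", "gen_ground_truth_fc", "gen_cohort"]


@dataclass
class SynthSpec:
    """n_nodes; density of nonzero off-diagonal entries; log-normal weight
    law (mu, sigma_w); symmetric flag; seed."""

    n_nodes: int = 30
    density: float = 0.12
    weight_law: tuple[float, float] = (0.0, 0.5)
    symmetric: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")


def gen_connectome(spec: SynthSpec) -> Connectome:
    """Random connected symmetric connectome: a random spanning tree
    guarantees connectedness, extra edges are added up to ``density``,
    weights are log-normal, and the matrix is normalized so the maximum
    row sum is 1."""
    n = spec.n_nodes
    rng = np.random.default_rng(spec.seed)
    n_pairs = n * (n - 1) // 2
    n_edges = int(round(spec.density * n_pairs))
    if n_edges < n - 1:
        raise ValueError(
            f"density {spec.density} gives {n_edges} edges; at least "
            f"{n - 1} are needed to connect {n} nodes")
    order = rng.permutation(n)
    edges = set()
    for k in range(1, n):  # random spanning tree
        a = order[k]
        b = order[rng.integers(0, k)]
        edges.add((min(a, b), max(a, b)))
    iu = np.triu_indices(n, k=1)
    all_pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    rng.shuffle(all_pairs)
    for pair in all_pairs:
        if len(edges) >= n_edges:
            break
        edges.add(pair)
    mu, sigma_w = spec.weight_law
    C = np.zeros((n, n))
    for (a, b) in sorted(edges):
        w = rng.lognormal(mu, sigma_w)
        C[a, b] = w
        C[b, a] = w
    # symmetric Sinkhorn balancing: equalizes total coupling per node
    # (the usual input normalization for connectomes), then exact scaling
    # so the maximum row sum is 1
    for _ in range(50):
        d = C.sum(axis=1)
        C /= np.sqrt(np.outer(d, d))
    C /= C.sum(axis=1).max()
    return Connectome(C)


def _random_ratio_weights(C: np.ndarray, rng: np.random.Generator,
                          ratio_sigma: float, ratio_scale: float,
                          coupling_scale: float) -> CouplingWeights:
    """Ground-truth weights: per-connection E/I-ratios are log-normal
    (median ``ratio_scale``), symmetrized, split as
    w_LRE + w_FFI = coupling_scale so long-range input stays bounded."""
    n = C.shape[0]
    logq = rng.normal(np.log(ratio_scale), ratio_sigma, size=(n, n))
    logq = (logq + logq.T) / 2.0
    q = np.exp(logq)
    w_lre = coupling_scale * q / (1.0 + q)
    w_ffi = coupling_scale / (1.0 + q)
    mask = C > 0
    w_lre = np.where(mask, w_lre, 0.0)
    w_ffi = np.where(mask, w_ffi, 0.0)
    return CouplingWeights(w_lre, w_ffi, np.ones(n))


def gen_ground_truth_fc(C: Connectome, seed: int = 0, *,
                        ratio_sigma: float = 2.0, ratio_scale: float = 6.0,
                        coupling_scale: float = 1.0,
                        params: DMFParams | None = None,
                        burn_in_ms: float = 480_000.0,
                        duration_ms: float = 10_800_000.0,
                        max_extra_burns: int = 3
                        ) -> tuple[TargetFC, CouplingWeights]:
    """Simulate the model with randomized ground-truth weights and return
    the resulting FC as fitting target, plus the generating weights
    (with FIC-converged J)."""
    rng = np.random.default_rng(seed)
    W = _random_ratio_weights(C.C, rng, ratio_sigma, ratio_scale,
                              coupling_scale)
    fp = FICParams()
    sim = DMFSimulator(C, params, W, seed=seed)
    for attempt in range(1 + max_extra_burns):
        res = sim.run(burn_in_ms, fic=True)
        tail = res.rates_E[:, res.n_tr // 2:].mean(axis=1)
        if np.all(np.abs(tail - fp.rho_0) < 0.5):
            break
    else:
        raise RuntimeError(
            "FIC did not converge while generating the target FC; "
            f"final mean rates: {np.round(tail, 2)}")
    res = sim.run(duration_ms, fic=True)
    fc = compute_fc(res.bold).rho
    return TargetFC(fc), W


def gen_cohort(K: int, spec: SynthSpec, heterogeneity: float = 0.8,
               seed: int = 0, *, shared_connectome: bool = False,
               **gen_kwargs) -> list[tuple[Connectome, TargetFC,
                                           CouplingWeights]]:
    """K synthetic models whose generating E/I-ratio medians increase
    across the cohort, so mean target FC spans a controlled range.

    Returns (connectome, target FC, ground-truth weights) per model;
    extra keyword arguments are forwarded to :func:`gen_ground_truth_fc`.
    """
    if K < 2:
        raise ValueError("a cohort needs at least 2 models")
    offsets = (np.linspace(-heterogeneity, heterogeneity, K)
               if heterogeneity > 0 else np.zeros(K))
    cohort = []
    conn = gen_connectome(spec) if shared_connectome else None
    for k in range(K):
        if not shared_connectome:
            sub = SynthSpec(spec.n_nodes, spec.density, spec.weight_law,
                            spec.symmetric, seed=seed + 1009 * k)
            conn = gen_connectome(sub)
        target, W = gen_ground_truth_fc(
            conn, seed=seed + 1009 * k + 1,
            ratio_scale=float(6.0 * np.exp(offsets[k])), **gen_kwargs)
        cohort.append((conn, target, W))
    return cohort
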