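"""Mesoscopic stochastic simulation of the lattice network.

Each cell is one well-mixed voxel of volume ``V`` (um^3) carrying integer
molecule counts of the five species plus a transport pseudo-species
``D_in``.  Within a voxel the nine mass-action/Hill reactions mirror the
deterministic model with concentrations replaced by counts and the Hill
constants volume-scaled to molecule units (``K [uM] * V [um^3] * 602.214``
molecules).  Cell-to-cell signalling is a species-changing transport
process: Dll1 spawns the pseudo-species ``D -> D + D_in`` at rate
``alpha_N D``, and ``D_in`` in voxel ``k`` converts into Notch in a
neighbouring voxel ``l`` at rate ``alpha_N q_kl D_in`` with ``q_kl`` the
signalling proportion (1/6 between hexagonal neighbours).  On lattices
with zero boundary conditions the proportion aimed at missing neighbours
is routed to a sink, so the expected signal matches the deterministic
boundary treatment.

Trajectories are statistically exact realisations of the jump process
(direct-method stochastic simulation with per-voxel propensity grouping
and localised updates), generated by a compiled kernel and deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import HexLattice
from .params import SPECIES, ModelParameters
from . import ode_grid
from ._ssa import ssa_core

__all__ = [
    "MOLECULES_PER_UM_UM3",
    "ReactionNetwork",
    "CountTrajectory",
    "build_network",
    "synthetic_initial_counts",
    "ssa_simulate",
    "counts_to_concentration",
    "volume_scan",
]

#: Molecules per voxel for a 1 uM solution in a 1 um^3 voxel
#: (Avogadro x 1e-6 mol/L x 1e-15 L/um^3).
MOLECULES_PER_UM_UM3 = 602.214076

#: Count-vector species order (the five concentrations plus transport).
COUNT_SPECIES = (*SPECIES, "Din")


@dataclass
class ReactionNetwork:
    """Reaction channels and transport topology at a fixed voxel volume.

    Intra-voxel channels, with counts ``(D, N, M, P, n, Din)``:

    ======  ==========================  ============================
    index   reaction                    propensity
    ======  ==========================  ============================
    0       n -> n + D                  alpha_D n
    1       N -> N + M                  alpha_M N / (1 + (P/(K_M V))^k)
    2       M -> M + P                  alpha_P M
    3       0 -> n                      alpha_n V / (1 + (P/(K_n V))^h)
    4..8    X -> 0 for X in D,N,M,P,n   mu_X X
    9       D -> D + D_in               alpha_N D
    10      D_in(k) -> N(l) / sink      alpha_N c_k D_in
    ======  ==========================  ============================

    where ``c_k = max(sum_l q_kl, 1)`` and the sink absorbs the proportion
    ``1 - sum_l q_kl`` lost over a zero-flux boundary.
    """

    params: ModelParameters
    volume: float
    KM_V: float
    Kn_V: float
    an_V: float
    trans_ptr: np.ndarray | None = None
    trans_idx: np.ndarray | None = None
    trans_cum: np.ndarray | None = None
    out_factor: np.ndarray | None = None

    @property
    def has_transport(self) -> bool:
        return self.trans_ptr is not None

    def q(self, k: int) -> tuple[np.ndarray, np.ndarray, float]:
        """Transport proportions from voxel ``k``: (targets, q_kl, sink)."""
        if not self.has_transport:
            raise ValueError("network was built without a lattice")
        lo, hi = self.trans_ptr[k], self.trans_ptr[k + 1]
        cum = self.trans_cum[lo:hi] * self.out_factor[k]
        qs = np.diff(np.concatenate([[0.0], cum]))
        sink = max(0.0, 1.0 - qs.sum())
        return self.trans_idx[lo:hi], qs, sink

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        """The eleven per-voxel channel propensities at integer ``counts``."""
        D, N, M, P, n, Din = (float(c) for c in np.asarray(counts))
        p = self.params
        hill_M = 1.0 + (P / self.KM_V) ** p.k
        hill_n = 1.0 + (P / self.Kn_V) ** p.h
        return np.array(
            [
                p.alpha_D * n,
                p.alpha_M * N / hill_M,
                p.alpha_P * M,
                self.an_V / hill_n,
                p.mu_D * D,
                p.mu_N * N,
                p.mu_M * M,
                p.mu_P * P,
                p.mu_n * n,
                p.alpha_N * D,
                p.alpha_N * Din,
            ]
        )


@dataclass
class CountTrajectory:
    """Time-sampled integer counts, shape ``(n_times, n_voxels, 6)``."""

    t: np.ndarray
    X: np.ndarray
    volume: float
    lattice: HexLattice
    params: ModelParameters
    seed: int | None = None

    def counts(self, species: str) -> np.ndarray:
        return self.X[:, :, COUNT_SPECIES.index(species)]

    def concentrations(self, species: str) -> np.ndarray:
        """Per-voxel uM time series of one species."""
        return counts_to_concentration(self.counts(species), self.volume)

    def stationary_mean(self, species: str, frac: float = 0.2) -> np.ndarray:
        """Per-voxel time-averaged concentration over the final ``frac`` of
        the horizon (the stationary window)."""
        n = max(int(round(frac * self.t.size)), 1)
        return self.concentrations(species)[-n:].mean(axis=0)


def build_network(
    params: ModelParameters, volume: float, lattice: HexLattice | None = None
) -> ReactionNetwork:
    """Assemble the reaction channels (and transport, if a lattice is given)."""
    if volume <= 0:
        raise ValueError("voxel volume must be positive")
    net = ReactionNetwork(
        params=params,
        volume=volume,
        KM_V=params.K_M * volume * MOLECULES_PER_UM_UM3,
        Kn_V=params.K_n * volume * MOLECULES_PER_UM_UM3,
        an_V=params.alpha_n * volume * MOLECULES_PER_UM_UM3,
    )
    if lattice is not None:
        _attach_transport(net, lattice)
    return net


def _attach_transport(net: ReactionNetwork, lattice: HexLattice) -> None:
    # q_kl = weight with which voxel l receives signal from voxel k, i.e.
    # the columns of the lattice weight matrix.
    W = lattice.weights.tocsc()
    K = lattice.n_nodes
    ptr = np.zeros(K + 1, dtype=np.int64)
    idx_all, cum_all, factors = [], [], np.ones(K)
    for k in range(K):
        col = W.getcol(k).tocoo()
        mask = col.row != k  # self-weights carry no transport
        targets, qs = col.row[mask], col.data[mask]
        total = qs.sum()
        c_k = max(total, 1.0)
        factors[k] = c_k
        cum = np.cumsum(qs) / c_k
        idx_all.append(targets.astype(np.int64))
        cum_all.append(cum)
        ptr[k + 1] = ptr[k] + targets.size
    net.trans_ptr = ptr
    net.trans_idx = np.concatenate(idx_all) if idx_all else np.zeros(0, dtype=np.int64)
    net.trans_cum = np.concatenate(cum_all) if cum_all else np.zeros(0)
    net.out_factor = factors


def counts_to_concentration(counts, volume: float):
    """Convert molecule counts in a voxel of ``volume`` um^3 to uM."""
    return np.asarray(counts, dtype=float) / (volume * MOLECULES_PER_UM_UM3)


def synthetic_initial_counts(
    lattice: HexLattice,
    volume: float,
    seed: int,
    params: ModelParameters | None = None,
    reference=None,
) -> np.ndarray:
    """Uniform random initial molecule counts, shape ``(n_voxels, 6)``.

    Concentration-scale initial data (uniform on ``[0, reference]`` per
    species) is converted to molecules by stochastic rounding (floor plus
    a Bernoulli on the fractional part), which preserves the expected
    concentration exactly.  The transport pseudo-species starts at zero.
    """
    ss = np.random.SeedSequence(seed)
    conc_seed, round_seed = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(2))
    conc = ode_grid.synthetic_initial_conditions(lattice, reference, conc_seed, params=params)
    mols = conc * volume * MOLECULES_PER_UM_UM3
    rng = np.random.default_rng(round_seed)
    base = np.floor(mols)
    counts = base + (rng.random(mols.shape) < (mols - base))
    out = np.zeros((lattice.n_nodes, 6), dtype=np.int64)
    out[:, :5] = counts.astype(np.int64)
    return out


def ssa_simulate(
    lattice: HexLattice,
    network: ReactionNetwork,
    init: np.ndarray,
    t_end: float,
    seed: int,
    output_dt: float = 10.0,
) -> CountTrajectory:
    """Exact stochastic realisation of the reaction-transport process.

    Uses the direct method with per-voxel propensity grouping, a binary
    tree over voxel totals and localised propensity updates, which is
    statistically identical to next-subvolume-method simulation.  Counts
    are sampled on a uniform output grid.
    """
    init = np.asarray(init)
    if init.shape != (lattice.n_nodes, 6):
        raise ValueError(f"init must have shape ({lattice.n_nodes}, 6)")
    if np.any(init < 0) or not np.issubdtype(init.dtype, np.integer):
        raise ValueError("initial counts must be non-negative integers")
    if not network.has_transport:
        network = build_network(network.params, network.volume, lattice)
    p = network.params
    out_times = np.arange(0.0, t_end + 0.5 * output_dt, output_dt)
    kernel_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF)
    X_out, n_events = ssa_core(
        init.astype(np.int64),
        out_times,
        float(p.alpha_D), float(p.alpha_N), float(p.alpha_M), float(p.alpha_P),
        float(network.an_V),
        float(p.mu_D), float(p.mu_N), float(p.mu_M), float(p.mu_P), float(p.mu_n),
        float(network.KM_V), float(network.Kn_V), int(p.k), int(p.h),
        network.trans_ptr, network.trans_idx, network.trans_cum, network.out_factor,
        kernel_seed,
    )
    if n_events < 0:
        raise RuntimeError("internal SSA consistency failure (negative count reached)")
    return CountTrajectory(
        t=out_times, X=X_out, volume=network.volume, lattice=lattice,
        params=p, seed=seed,
    )


def volume_scan(
    lattice: HexLattice,
    params: ModelParameters,
    volumes,
    replicates: int,
    seed: int,
    *,
    t_end: float = 3000.0,
    output_dt: float = 10.0,
    stationary_frac: float = 0.2,
    level: float = 0.95,
):
    """Stationary patterning summaries for a sequence of voxel volumes.

    For each volume, ``replicates`` independent seeded realisations are
    run; the per-cell stationary Hes1 protein concentrations feed the
    high/low classification, bimodality summary and the pooled patterning
    coefficient.  Returns a list of per-volume dictionaries.
    """
    from . import patterning

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    volumes = np.atleast_1d(np.asarray(volumes, dtype=float))
    if np.any(volumes <= 0):
        raise ValueError("volumes must be positive")
    ss = np.random.SeedSequence(seed)
    results = []
    for vol, child in zip(volumes, ss.spawn(len(volumes))):
        net = build_network(params, float(vol), lattice)
        rep_states = []
        for rep_seed in child.spawn(replicates):
            s_init, s_run = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in rep_seed.spawn(2))
            init = synthetic_initial_counts(lattice, float(vol), s_init, params=params)
            traj = ssa_simulate(lattice, net, init, t_end, s_run, output_dt=output_dt)
            rep_states.append(traj.stationary_mean("P", frac=stationary_frac))
        estimate = patterning.estimate_pattern_quality(rep_states, lattice, level=level)
        _, bimodal = patterning.classify_high_low(np.concatenate(rep_states))
        results.append(
            {
                "volume": float(vol),
                "replicates": replicates,
                "stationary_states": rep_states,
                "patterning": estimate,
                "bimodal": bimodal,
            }
        )
    return results
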