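"""Deterministic, seedable generators of study networks and flow tables.

Everything here is a pure function of its arguments (including the seed):
scale-free pairs emulating the reference study conditions, closed-form star
and clique toys used as exact oracles, and synthetic two-group flow tables
with a known generative truth for the directed/Markov-chain machinery.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .networks import NodeNetwork

__all__ = [
    "make_scale_free_pair",
    "make_star",
    "make_clique",
    "make_chain",
    "make_two_group_flow",
    "DEFAULT_SEED_A",
    "DEFAULT_SEED_B",
]

# Default seeds for the reference scale-free pair.  They are chosen so the
# two leading eigenvalues are close (delta_lam ~ 0.07 at N=250, m=3), the
# regime in which the out-of-equilibrium transient is long and the
# strong/weak competition is interesting; very different eigenvalues make
# the relaxation essentially instantaneous.
DEFAULT_SEED_A = 5
DEFAULT_SEED_B = 30


def make_scale_free_pair(
    N: int = 250,
    m: int = 3,
    seedA: int = DEFAULT_SEED_A,
    seedB: int = DEFAULT_SEED_B,
) -> tuple[NodeNetwork, NodeNetwork]:
    """Two preferential-attachment (Barabasi-Albert) networks of N nodes.

    The construction seeds growth with an ``m``-clique, so the link count
    is ``m*(m-1)/2 + (N-m)*m`` (744 for N=250, m=3).  With those defaults
    the leading eigenvalue falls in roughly [9, 12] across seeds.

    The returned pair is *not* reordered: whether A is the strong network
    depends on the seeds.  The defaults give ``lam_A1 > lam_B1``.
    """
    if N < m + 1:
        raise ValueError(f"need N >= m+1, got N={N}, m={m}")
    # growth needs an initial graph with at least one link: K_2 for m = 1
    seed_graph = nx.complete_graph(max(m, 2))
    gA = nx.barabasi_albert_graph(N, m, seed=seedA, initial_graph=seed_graph)
    gB = nx.barabasi_albert_graph(N, m, seed=seedB, initial_graph=seed_graph)
    return (
        NodeNetwork.from_graph(gA, label=f"BA(N={N},m={m},seed={seedA})"),
        NodeNetwork.from_graph(gB, label=f"BA(N={N},m={m},seed={seedB})"),
    )


def make_star(k_leaves: int) -> NodeNetwork:
    """Star with node 0 at the centre and ``k`` leaves.

    Closed forms: ``lam1 = sqrt(k)``, centre centrality ``1/sqrt(2)``,
    leaf centrality ``1/sqrt(2k)``.
    """
    if k_leaves < 1:
        raise ValueError("star needs at least one leaf")
    return NodeNetwork.from_graph(nx.star_graph(k_leaves), label=f"star({k_leaves})")


def make_clique(n: int) -> NodeNetwork:
    """Complete graph K_n: ``lam1 = n-1``, uniform centralities ``1/sqrt(n)``."""
    if n < 2:
        raise ValueError("clique needs at least two nodes")
    return NodeNetwork.from_graph(nx.complete_graph(n), label=f"K{n}")


def make_chain(n: int) -> NodeNetwork:
    """Path graph on n nodes: ``lam1 = 2 cos(pi/(n+1))``."""
    if n < 2:
        raise ValueError("chain needs at least two nodes")
    return NodeNetwork.from_graph(nx.path_graph(n), label=f"chain({n})")


def make_two_group_flow(
    nA: int,
    nB: int,
    inter_scale: float,
    periods: int,
    ar_coefficient: float = 0.0,
    seed: int = 0,
    sigma: float = 0.2,
    asymmetry: float = 0.1,
):
    """Synthetic yearly flow tables with two groups of nodes.

    Each table is a square matrix of directed flows (``entries[i, j]`` =
    flow from node i to node j).  Intra-group flows are dense positive
    draws held fixed across periods.  Inter-group flows are scaled by
    ``inter_scale`` overall and are asymmetric by design: the A -> B block
    is further down-weighted by ``asymmetry`` and follows a stationary
    log-AR(1) process with the given coefficient across periods, while the
    B -> A block is steady.

    This emulates a strong group that leaks little of its outflow (so its
    internal block keeps the larger leading eigenvalue) interacting with a
    leakier weak group.  The directed connection strength is proportional
    to the strong side's outward leak, so the strength series inherits the
    AR(1) generative truth and its magnitude is controlled by
    ``asymmetry`` -- small values place the tables in the perturbative
    regime where (strength, x) points collapse on the diagonal.

    Returns a list of :class:`FlowTable` (one per period).
    """
    from .flows import FlowTable

    if inter_scale < 0:
        raise ValueError("inter_scale must be nonnegative")
    if periods < 1:
        raise ValueError("need at least one period")
    rng = np.random.default_rng(seed)
    n = nA + nB

    def dense_block(rows: int, cols: int) -> np.ndarray:
        return rng.uniform(0.5, 1.5, size=(rows, cols))

    intra_A = dense_block(nA, nA)
    intra_B = dense_block(nB, nB)
    np.fill_diagonal(intra_A, 0.0)
    np.fill_diagonal(intra_B, 0.0)
    pattern_AB = dense_block(nA, nB)
    pattern_BA = dense_block(nB, nA)

    # stationary log-AR(1) process for the strong side's outward leak
    rho = ar_coefficient
    z = np.empty(periods)
    z[0] = rng.normal(0.0, sigma / np.sqrt(max(1.0 - rho**2, 1e-12)))
    for t in range(1, periods):
        z[t] = rho * z[t - 1] + sigma * rng.normal()

    labels = [f"A{i}" for i in range(nA)] + [f"B{j}" for j in range(nB)]
    groups = {lab: ("A" if lab.startswith("A") else "B") for lab in labels}
    tables = []
    for t in range(periods):
        entries = np.zeros((n, n))
        entries[:nA, :nA] = intra_A
        entries[nA:, nA:] = intra_B
        entries[:nA, nA:] = inter_scale * asymmetry * np.exp(z[t]) * pattern_AB
        entries[nA:, :nA] = inter_scale * pattern_BA
        tables.append(FlowTable(entries=entries, node_labels=labels, group_map=groups))
    return tables
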