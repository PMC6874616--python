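"""Directed generalisation: weighted flow networks as Markov chains.

A square table of directed flows (e.g. monetary flows between economic
sectors) is normalised into a column-stochastic transition matrix, making
the linear spreading process a finite Markov chain whose stationary state
is the Perron eigenvector.  For a partition of the nodes into a group and
the rest, the directed normalised connection strength

    (u^L_B P u_A) / (lam_A1 - lam_B1)

uses the left eigenvector of the weak side and only the links flowing from
the strong to the weak side; to first order in the coupling it equals the
stationary population distribution x, so (strength, x) points collapse on
the diagonal of the flux diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.csgraph as csgraph

from .networks import (
    DegenerateSpectrumError,
    EigenData,
    NodeNetwork,
    ReducibleSystemError,
)
from .spectral import leading_eigenpair

__all__ = [
    "FlowTable",
    "GroupPartitionResult",
    "StationaryState",
    "flow_to_transition",
    "group_vs_rest",
    "equilibria_series",
    "stationary_state",
]


@dataclass
class FlowTable:
    """Square nonnegative matrix of directed flows between labelled nodes.

    ``entries[i, j]`` is the flow from node i to node j per period.
    ``group_map`` assigns each node label to a group (e.g. a country).
    Nodes with zero total outflow are legal at construction but rejected by
    the normalisation step.
    """

    entries: np.ndarray
    node_labels: list[str]
    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("flow table must be square")
        if np.any(e < 0):
            raise ValueError("flows must be nonnegative")
        if len(self.node_labels) != e.shape[0]:
            raise ValueError("node_labels length must match the table size")
        self.entries = e

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]

    def group_indices(self, group_id: str) -> np.ndarray:
        idx = [
            k
            for k, lab in enumerate(self.node_labels)
            if self.group_map.get(lab) == group_id
        ]
        return np.asarray(idx, dtype=int)


def flow_to_transition(table: FlowTable, row_stochastic: bool = False) -> np.ndarray:
    """Column-stochastic transition matrix from a flow table.

    ``M[i, j]`` is the fraction of node j's total outflow directed to node
    i, so every column sums to one and ``n(t) = M n(t-1)`` conserves the
    total population (the closed-model reading: demand consumes its own
    output).  ``row_stochastic=True`` returns the transposed convention
    instead.
    """
    L = table.entries
    outflow = L.sum(axis=1)
    dead = np.flatnonzero(outflow == 0)
    if dead.size:
        names = [table.node_labels[k] for k in dead]
        raise ValueError(f"nodes with zero total outflow: {names}")
    M = (L / outflow[:, None]).T
    return M.T if row_stochastic else M


@dataclass
class StationaryState:
    """Stationary distribution of the chain with a periodicity flag."""

    distribution: np.ndarray
    periodic: bool


def stationary_state(M: np.ndarray, tol: float = 1e-12) -> StationaryState:
    """Leading right eigenvector of an irreducible chain, normalised to sum 1.

    Periodic chains (e.g. a 2-node swap) have no limiting distribution in
    the usual sense; the Perron vector is still returned, flagged periodic.
    Reducible chains raise with the communicating classes listed.
    """
    M = np.asarray(M, dtype=float)
    n_comp, labels = csgraph.connected_components(
        (M != 0).astype(np.int8), directed=True, connection="strong"
    )
    if n_comp != 1:
        classes = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        raise ReducibleSystemError(
            f"chain is reducible: {n_comp} communicating classes {classes}"
        )
    net = NodeNetwork(weights=M, directed=True, allow_self_loops=True)
    eig = leading_eigenpair(net)
    vals = np.linalg.eigvals(M)
    lam1 = np.max(vals.real)
    periodic = int(np.sum(np.abs(np.abs(vals) - abs(lam1)) < 1e-8)) > 1
    v = eig.u1
    return StationaryState(distribution=v / v.sum(), periodic=periodic)


def _dual_left(eig: EigenData) -> np.ndarray:
    """Left Perron vector rescaled to be biorthonormal with the right one.

    With w = u_left / (u_left . u_right) the first-order expansion
    coefficient of a perturbed eigenvector on mode u is exactly
    (w V u_source) / dlam, which is what makes the strength and the
    measured x comparable without spurious overlap factors.  For symmetric
    matrices w reduces to the unit-norm eigenvector itself.
    """
    overlap = float(eig.u1_left @ eig.u1)
    if overlap == 0.0:
        raise DegenerateSpectrumError("defective leading eigenpair (zero overlap)")
    return eig.u1_left / overlap


@dataclass
class GroupPartitionResult:
    """Spectral comparison of one group of nodes against all the rest.

    ``strength`` is the directed normalised connection strength between the
    strong and weak sides; ``x_eq`` the stationary population distribution
    measured on the full chain.  ``group_is_strong`` records the ordering.
    """

    strong: EigenData
    weak: EigenData
    group_is_strong: bool
    strength: float
    x_eq: float

    @property
    def x_eq_point(self) -> tuple[float, float]:
        return (self.strength, self.x_eq)


def group_vs_rest(table: FlowTable, group_id: str) -> GroupPartitionResult:
    """Directed connection strength and stationary x for group-vs-rest.

    Splits the normalised chain into the group's internal block and the
    complement's internal block (inter-group entries zeroed, matching the
    isolated-network convention), labels strong/weak by the blocks' leading
    eigenvalues, and evaluates

        strength = (w^L_B  V_{A->B}  u_A) / (lam_A - lam_B)

    where ``V_{A->B}`` holds only the transition entries that move
    population from the strong side into the weak side and ``w^L_B`` is the
    weak block's dual-normalised left eigenvector.  ``x_eq`` projects the
    full chain's stationary state on the two blocks' eigenvectors.
    """
    g = table.group_indices(group_id)
    if g.size == 0 or g.size == table.n_nodes:
        raise ValueError(f"group {group_id!r} must be a nonempty proper subset")
    r = np.setdiff1d(np.arange(table.n_nodes), g)
    M = flow_to_transition(table)

    def block_eigen(idx: np.ndarray) -> EigenData:
        net = NodeNetwork(
            weights=M[np.ix_(idx, idx)], directed=True, allow_self_loops=True
        )
        return leading_eigenpair(net)

    eig_g, eig_r = block_eigen(g), block_eigen(r)
    if np.isclose(eig_g.lam1, eig_r.lam1, rtol=0, atol=1e-12):
        raise DegenerateSpectrumError(
            f"leading eigenvalues tie ({eig_g.lam1} vs {eig_r.lam1})"
        )
    group_is_strong = eig_g.lam1 > eig_r.lam1
    eig_a, idx_a = (eig_g, g) if group_is_strong else (eig_r, r)
    eig_b, idx_b = (eig_r, r) if group_is_strong else (eig_g, g)
    dlam = eig_a.lam1 - eig_b.lam1

    # links from the strong to the weak side: population leaving A-columns
    # into B-rows of the column-stochastic chain
    V_ab = M[np.ix_(idx_b, idx_a)]
    w_b = _dual_left(eig_b)
    strength = float(w_b @ V_ab @ eig_a.u1) / dlam

    stat = stationary_state(M)
    n = stat.distribution
    w_a = _dual_left(eig_a)
    num = float(n[idx_b] @ w_b)
    den = float(n[idx_a] @ w_a)
    x_eq = np.inf if den == 0.0 else num / den
    return GroupPartitionResult(
        strong=eig_a,
        weak=eig_b,
        group_is_strong=group_is_strong,
        strength=strength,
        x_eq=x_eq,
    )


def equilibria_series(
    tables: list[FlowTable], group_id: str
) -> tuple[list[GroupPartitionResult], float, dict]:
    """Per-period (strength, x) points and the lag-1 strength correlation.

    Pearson correlation between the connection-strength series and its
    one-period lag; a constant series (zero variance) returns 1.0 with a
    flag, reading perfect persistence into an unchanging coupling.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 periods")
    points = [group_vs_rest(tb, group_id) for tb in tables]
    s = np.array([p.strength for p in points])
    flags = {"constant_series": False}
    if np.std(s[:-1]) == 0.0 or np.std(s[1:]) == 0.0:
        flags["constant_series"] = True
        corr = 1.0
    else:
        corr = float(np.corrcoef(s[:-1], s[1:])[0, 1])
    return points, corr, flags
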