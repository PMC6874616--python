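"""Core domain types: single networks, connector-link configurations.

A :class:`NodeNetwork` holds the weighted link structure of one network
together with lazily computed spectral data (leading eigenvalue and
eigenvector-centrality vector).  A :class:`ConnectorConfig` describes the
inter-network links -- the only links the steering strategies are allowed
to touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NodeNetwork",
    "ConnectorConfig",
    "EigenData",
    "InterfluxError",
    "ConvergenceError",
    "DegenerateSpectrumError",
    "ReducibleSystemError",
    "OutOfRegimeError",
    "UndefinedStateError",
]


class InterfluxError(Exception):
    """Base class for all library-specific errors."""


class ConvergenceError(InterfluxError):
    """An iterative eigensolver failed to reach the requested residual."""


class DegenerateSpectrumError(InterfluxError):
    """The two networks have (numerically) tied leading eigenvalues.

    The perturbative theory requires a strict strong/weak ordering
    lambda_A1 > lambda_B1; callers may relabel the networks and retry.
    """


class ReducibleSystemError(InterfluxError):
    """The coupled (or flow) matrix is reducible where irreducibility is needed."""


class OutOfRegimeError(InterfluxError):
    """Inputs outside the perturbative regime of the closed-form theory.

    Raised when (eps*F)^2 >= lambda_B1 * (lambda_A1 - lambda_B1), which makes
    the contraction factor K non-positive and the first-order formulas
    meaningless.
    """


class UndefinedStateError(InterfluxError):
    """A population state on which the requested observable is undefined."""


@dataclass(frozen=True)
class EigenData:
    """Perron (leading) eigendata of a single network.

    Attributes
    ----------
    lam1:
        Largest eigenvalue of the network's matrix.  For an adjacency
        matrix this grows with the number and weight of links, so the
        network with the larger ``lam1`` is called *strong*.
    u1:
        Right leading eigenvector -- the eigenvector centrality.  Entrywise
        nonnegative, unit Euclidean norm.
    u1_left:
        Left leading eigenvector (same normalisation).  Equal to ``u1``
        for undirected networks.
    lam2:
        Second eigenvalue, when a dense solve produced it (oracle use).
    degenerate:
        True when the network had no links and the eigenvector is an
        arbitrary (uniform) choice for the zero matrix.
    """

    lam1: float
    u1: np.ndarray
    u1_left: np.ndarray
    lam2: float | None = None
    degenerate: bool = False


@dataclass
class NodeNetwork:
    """One network: an ``N x N`` nonnegative weight matrix plus metadata.

    Parameters
    ----------
    weights:
        Square nonnegative matrix of link weights; ``weights[i, j]`` is the
        weight of the link feeding node ``i`` from node ``j`` (symmetric for
        undirected networks).
    directed:
        Whether the matrix is allowed to be asymmetric.
    label:
        Free-text name used in logs and exports.
    allow_self_loops:
        Permit nonzero diagonal entries (used e.g. for flow tables with
        self-consumption).
    """

    weights: np.ndarray
    directed: bool = False
    label: str = ""
    allow_self_loops: bool = False
    _eigen: EigenData | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise ValueError("network must have at least one node")
        if np.any(w < 0):
            raise ValueError("link weights must be nonnegative")
        if not self.allow_self_loops and np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed (set allow_self_loops=True)")
        if not self.directed and not np.allclose(w, w.T, rtol=0, atol=0):
            raise ValueError("undirected network requires a symmetric weight matrix")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_graph(cls, graph: nx.Graph, label: str = "") -> "NodeNetwork":
        """Build from a networkx graph; nodes are relabelled 0..N-1 in sorted order."""
        nodes = sorted(graph.nodes())
        w = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
        return cls(weights=w, directed=graph.is_directed(), label=label)

    def to_graph(self) -> nx.Graph:
        cls = nx.DiGraph if self.directed else nx.Graph
        return nx.from_numpy_array(self.weights, create_using=cls)

    def eigen(self, tol: float = 1e-10) -> EigenData:
        """Leading eigendata, computed on first use and cached."""
        if self._eigen is None:
            from .spectral import leading_eigenpair

            self._eigen = leading_eigenpair(self, tol=tol)
        return self._eigen

    def scaled(self, c: float) -> "NodeNetwork":
        """A copy with every link weight multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return NodeNetwork(
            weights=c * self.weights,
            directed=self.directed,
            label=self.label,
            allow_self_loops=self.allow_self_loops,
        )


@dataclass(frozen=True)
class ConnectorConfig:
    """A set of connector links between networks A and B with common weight eps.

    ``pairs`` lists ``(i, j)`` node indices, ``i`` in A and ``j`` in B.  An
    empty pair list is valid and describes two disconnected networks.
    """

    pairs: tuple[tuple[int, int], ...]
    epsilon: float
    label: str = ""

    def __init__(self, pairs, epsilon: float, label: str = "") -> None:
        pairs = tuple((int(i), int(j)) for i, j in pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate connector pairs")
        if any(i < 0 or j < 0 for i, j in pairs):
            raise ValueError("connector indices must be nonnegative")
        if not epsilon > 0:
            raise ValueError("connector weight epsilon must be positive")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "epsilon", float(epsilon))
        object.__setattr__(self, "label", label)

    def validate_against(self, n_a: int, n_b: int) -> None:
        for i, j in self.pairs:
            if i >= n_a or j >= n_b:
                raise ValueError(
                    f"connector pair ({i}, {j}) out of range for sizes ({n_a}, {n_b})"
                )

    def with_epsilon(self, epsilon: float) -> "ConnectorConfig":
        return ConnectorConfig(self.pairs, epsilon, label=self.label)
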