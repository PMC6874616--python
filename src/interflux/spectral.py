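"""Eigenvalue/eigenvector machinery and the closed-form scalar theory inputs.

All observables of the closed-form theory reduce to a handful of scalars
computed here: the leading eigenvalues ``lam_A1 > lam_B1`` of the two
isolated networks, the connection strength ``eps * F`` (connector weight
times the summed products of the connector nodes' eigenvector centralities)
and the constants ``K`` and ``L`` that govern the relaxation of the
population distribution ``x(t)`` towards its equilibrium
``x_eq = eps*F / (lam_A1 - lam_B1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph as csgraph

from .networks import (
    ConnectorConfig,
    ConvergenceError,
    DegenerateSpectrumError,
    EigenData,
    NodeNetwork,
    ReducibleSystemError,
)

__all__ = [
    "leading_eigenpair",
    "left_leading_eigenvector",
    "connection_strength",
    "analytic_equilibrium",
    "theory_constants",
    "exact_equilibrium",
    "embed_pair",
    "TheorySummary",
]

#: Below this size a failed power iteration falls back to a dense solve.
DENSE_FALLBACK_N = 500


def _perron_power(M: np.ndarray, tol: float, max_iter: int) -> tuple[float, np.ndarray] | None:
    """Shifted power iteration for the Perron eigenpair of a nonnegative matrix.

    The shift ``sigma > 0`` makes the Perron root strictly dominant even for
    bipartite (periodic) structures, whose spectrum is symmetric about zero.
    Returns None on non-convergence.
    """
    n = M.shape[0]
    scale = np.abs(M).sum(axis=1).max()  # inf-norm bound on the spectrum
    if scale == 0.0:
        return 0.0, np.full(n, 1.0 / np.sqrt(n))
    sigma = 0.2 * scale
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(max_iter):
        w = M @ v + sigma * v
        nw = np.linalg.norm(w)
        if nw == 0.0:  # nilpotent corner case
            return 0.0, v
        v_new = w / nw
        lam = v_new @ (M @ v_new)
        if np.linalg.norm(M @ v_new - lam * v_new, ord=np.inf) <= tol * max(1.0, abs(lam)):
            v = v_new
            break
        v = v_new
    else:
        return None
    v = np.abs(v)  # Perron vector is nonnegative; clean rounding signs
    nv = np.linalg.norm(v)
    v = v / nv
    lam = v @ (M @ v)
    return float(lam), v


def _perron_dense(M: np.ndarray, symmetric: bool) -> tuple[float, np.ndarray, float]:
    """Dense solve of the eigenpair with the largest real eigenvalue."""
    if symmetric:
        vals, vecs = np.linalg.eigh(M)
        order = np.argsort(vals.real)[::-1]
    else:
        vals, vecs = scipy.linalg.eig(M)
        order = np.argsort(vals.real)[::-1]
    k = order[0]
    lam1 = float(vals[k].real)
    v = np.real(vecs[:, k])
    if np.sum(v) < 0:
        v = -v
    v = np.abs(v)
    v = v / np.linalg.norm(v)
    lam2 = float(vals[order[1]].real) if M.shape[0] > 1 else None
    return lam1, v, lam2


def leading_eigenpair(
    net: NodeNetwork, tol: float = 1e-10, max_iter: int = 100_000
) -> EigenData:
    """Perron eigenpair (eigenvector centrality) of one network.

    The returned eigenvector is entrywise nonnegative with unit Euclidean
    norm and satisfies ``||M u1 - lam1 u1||_inf <= tol`` (scaled by the
    eigenvalue magnitude).  An all-zero weight matrix yields ``lam1 = 0``
    with a uniform vector flagged as degenerate.

    Strategy: shifted power iteration; on non-convergence a dense solve is
    used for networks below 500 nodes, otherwise a convergence error is
    raised.
    """
    M = net.weights
    n = net.n_nodes
    if not M.any():
        u = np.full(n, 1.0 / np.sqrt(n))
        return EigenData(lam1=0.0, u1=u, u1_left=u.copy(), degenerate=n > 1)

    lam2 = None
    res = _perron_power(M, tol, max_iter)
    if res is None:
        if n > DENSE_FALLBACK_N:
            raise ConvergenceError(
                f"power iteration did not reach residual {tol} in {max_iter} "
                f"iterations on a {n}-node network"
            )
        lam1, u1, lam2 = _perron_dense(M, symmetric=not net.directed)
    else:
        lam1, u1 = res

    if net.directed:
        res_l = _perron_power(M.T, tol, max_iter)
        if res_l is None:
            if n > DENSE_FALLBACK_N:
                raise ConvergenceError("left eigenvector power iteration did not converge")
            _, u1_left, _ = _perron_dense(M.T, symmetric=False)
        else:
            _, u1_left = res_l
    else:
        u1_left = u1.copy()
    return EigenData(lam1=lam1, u1=u1, u1_left=u1_left, lam2=lam2)


def left_leading_eigenvector(
    net: NodeNetwork, tol: float = 1e-10, max_iter: int = 100_000
) -> np.ndarray:
    """Left Perron vector (unit norm, nonnegative); equals ``u1`` when undirected."""
    return leading_eigenpair(net, tol=tol, max_iter=max_iter).u1_left


def connection_strength(
    uA1: np.ndarray, uB1: np.ndarray, cfg: ConnectorConfig
) -> tuple[float, float]:
    """Connection strength of a connector configuration.

    ``F`` is the sum over connector links of the products of the two
    endpoints' eigenvector centralities, measured on each network in
    isolation; the connection strength proper is ``eps * F``.  Central-to-
    central (CC) links give large ``F``, peripheral-to-peripheral (PP)
    links give small ``F``.

    Returns ``(F, eps_F)``; an empty pair list gives ``(0, 0)``.
    """
    F = float(sum(uA1[i] * uB1[j] for i, j in cfg.pairs))
    return F, cfg.epsilon * F


def analytic_equilibrium(lamA1: float, lamB1: float, eps_F: float) -> float:
    """First-order equilibrium population distribution ``x_eq = eps*F / dlam``.

    ``x_eq = 0`` (all population fills the strong network A) iff the
    networks are disconnected or connected only through zero-centrality
    nodes.  Requires the strict strong/weak ordering ``lamA1 > lamB1``.
    """
    if not lamA1 > lamB1:
        raise DegenerateSpectrumError(
            f"analytic equilibrium requires lamA1 > lamB1, got {lamA1} <= {lamB1}"
        )
    return eps_F / (lamA1 - lamB1)


def theory_constants(
    lamA1: float, lamB1: float, eps_F: float, x0: float
) -> tuple[float, float]:
    """The relaxation constants ``(K, L)`` of the closed-form ``x(t)``.

    ``K = (lamB1*dlam - (eps F)^2) / (lamA1*dlam + (eps F)^2)`` is the
    per-step contraction factor (``0 < K < 1`` in the perturbative regime);
    ``L = (x0*dlam - eps F) / (dlam + x0*eps F)`` encodes the initial
    condition and vanishes exactly at equilibrium.
    """
    if not lamA1 > lamB1:
        raise DegenerateSpectrumError(
            f"theory constants require lamA1 > lamB1, got {lamA1} <= {lamB1}"
        )
    dlam = lamA1 - lamB1
    K = (lamB1 * dlam - eps_F**2) / (lamA1 * dlam + eps_F**2)
    denom = dlam + x0 * eps_F
    if denom == 0.0:
        raise ValueError("invalid input: dlam + x0*eps_F = 0")
    L = (x0 * dlam - eps_F) / denom
    return K, L


def embed_pair(netA: NodeNetwork, netB: NodeNetwork, left: bool = False):
    """Isolated leading eigenvectors of A and B embedded in the joint space.

    A's vector is padded with zeros on B's indices and vice versa; all dot
    products of the theory are taken in this embedded ``N_A + N_B`` space.
    """
    nA, nB = netA.n_nodes, netB.n_nodes
    eA, eB = netA.eigen(), netB.eigen()
    vA = eA.u1_left if left else eA.u1
    vB = eB.u1_left if left else eB.u1
    uA = np.concatenate([vA, np.zeros(nB)])
    uB = np.concatenate([np.zeros(nA), vB])
    return uA, uB


def exact_equilibrium(sys) -> float:
    """Exact equilibrium ``x`` from the Perron eigenvector of the coupled matrix.

    Computes the leading eigenvector of the full coupled transition matrix
    and projects it on the embedded isolated eigenvectors.  Agrees with
    :func:`analytic_equilibrium` to second order in the connector weight.

    Parameters
    ----------
    sys : CoupledSystem
        Connected (irreducible) coupled system.
    """
    T = sys.matrix
    if not sys.cfg.pairs:
        raise ReducibleSystemError(
            "coupled matrix is block-diagonal (no connector links); "
            "analyse the two networks separately"
        )
    n_comp, _ = csgraph.connected_components(
        (T != 0).astype(np.int8), directed=True, connection="strong"
    )
    if n_comp != 1:
        raise ReducibleSystemError(
            "coupled matrix is reducible; exact equilibrium is not unique"
        )
    net_t = NodeNetwork(
        weights=T,
        directed=sys.net_a.directed or sys.net_b.directed,
        allow_self_loops=True,
        label="coupled",
    )
    uT = leading_eigenpair(net_t).u1
    uA_emb, uB_emb = embed_pair(sys.net_a, sys.net_b)
    num = float(uT @ uB_emb)
    den = float(uT @ uA_emb)
    if den == 0.0:
        return np.inf
    return num / den


@dataclass(frozen=True)
class TheorySummary:
    """All scalars of the closed-form theory for one fixed connector config.

    Built by :func:`summarize`; consumed by the analytic ``x(t)`` and flux
    formulas.  ``a = eps_F / delta_lam`` is the normalised connection
    strength, the natural horizontal axis of the population flux diagram.
    """

    lamA1: float
    lamB1: float
    delta_lam: float
    F: float
    eps_F: float
    a: float
    K: float
    L: float
    x0: float
    x_eq: float

    @classmethod
    def from_scalars(
        cls, lamA1: float, lamB1: float, eps_F: float, x0: float, F: float | None = None
    ) -> "TheorySummary":
        dlam = lamA1 - lamB1
        K, L = theory_constants(lamA1, lamB1, eps_F, x0)
        return cls(
            lamA1=lamA1,
            lamB1=lamB1,
            delta_lam=dlam,
            F=eps_F if F is None else F,
            eps_F=eps_F,
            a=eps_F / dlam,
            K=K,
            L=L,
            x0=x0,
            x_eq=analytic_equilibrium(lamA1, lamB1, eps_F),
        )


def summarize(
    netA: NodeNetwork, netB: NodeNetwork, cfg: ConnectorConfig, x0: float
) -> TheorySummary:
    """Assemble the :class:`TheorySummary` for two networks and a connector config.

    Requires ``netA`` to be the strong network (larger leading eigenvalue);
    raises :class:`DegenerateSpectrumError` otherwise so the caller may
    relabel.
    """
    lamA1 = netA.eigen().lam1
    lamB1 = netB.eigen().lam1
    F, eps_F = connection_strength(netA.eigen().u1, netB.eigen().u1, cfg)
    ts = TheorySummary.from_scalars(lamA1, lamB1, eps_F, x0, F=F)
    return ts
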