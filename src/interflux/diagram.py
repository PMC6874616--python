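"""The population flux diagram.

The plane (a, x) -- normalised connection strength eps*F/dlam on the
horizontal axis, population distribution x on the vertical -- condenses
the whole steering problem: under a fixed connector configuration the
system moves vertically towards the equilibrium curve x_eq(a) ~ a, while
rewiring the connector links moves it horizontally at constant x.  This
module builds |flux| grids over (a, x0) by direct simulation or from the
closed-form theory, traces exact equilibrium curves, and converts
schedules of rewirings into vertical/horizontal diagram paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import build_coupled_matrix
from .networks import ConnectorConfig, NodeNetwork
from .spectral import TheorySummary, connection_strength, exact_equilibrium, embed_pair
from .theory import flux_of_t

__all__ = [
    "FluxGrid",
    "DiagramPath",
    "PathSegment",
    "realize_connection",
    "realize_equilibrium",
    "compute_flux_grid",
    "equilibrium_curve",
    "trace_path",
    "plot_flux_diagram",
]


@dataclass
class FluxGrid:
    """|flux| over a grid of (normalised connection strength, x0).

    ``flux_abs[k, l]`` is |dx/dt| at evaluation time ``t`` for
    ``a_values[k]`` and ``x0_values[l]``.  ``missing`` flags cells whose
    target ``a`` could not be realized with the available connector links
    under the epsilon cap (numeric method only).
    """

    a_values: np.ndarray
    x0_values: np.ndarray
    flux_abs: np.ndarray
    t: float
    method: str
    missing: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, a in enumerate(self.a_values):
            for l, x0 in enumerate(self.x0_values):
                rows.append((a, x0, self.flux_abs[k, l], self.t, self.method))
        return pd.DataFrame(rows, columns=["a", "x0", "flux_abs", "t", "method"])


@dataclass(frozen=True)
class PathSegment:
    """One segment of a diagram path: vertical (dynamics) or horizontal (rewiring)."""

    kind: str  # "vertical" | "horizontal"
    start_a: float
    start_x: float
    end_a: float
    end_x: float
    t_start: int
    t_end: int


@dataclass
class DiagramPath:
    """Contiguous alternation of vertical and horizontal segments."""

    segments: list[PathSegment] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.kind, s.start_a, s.start_x, s.end_a, s.end_x)
                for s in self.segments
            ],
            columns=["type", "start_a", "start_x", "end_a", "end_x"],
        )


def realize_connection(
    netA: NodeNetwork,
    netB: NodeNetwork,
    a_target: float,
    eps_cap: float = 1.0,
    pair_sample: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ConnectorConfig | None, bool]:
    """Choose a single connector link realizing a normalised strength ``a``.

    Mirrors the dual tuning mechanism of the study: the link (hence F, a
    product of the endpoints' centralities) sets the coarse scale and the
    weight eps is scaled so eps*F/dlam matches ``a_target`` exactly.  Among
    candidate pairs the one with the smallest F still reaching the target
    under the eps cap is chosen.  Returns ``(config, exact)``;
    ``config=None`` for ``a_target = 0`` (no link) and ``exact=False``
    when even the maximal-F link cannot reach the target (cell flagged
    missing by callers).
    """
    if a_target < 0:
        raise ValueError("a_target must be nonnegative")
    dlam = netA.eigen().lam1 - netB.eigen().lam1
    if dlam <= 0:
        raise ValueError("netA must be the strong network")
    if a_target == 0.0:
        return None, True
    uA, uB = netA.eigen().u1, netB.eigen().u1
    target_F = a_target * dlam / eps_cap  # minimal F usable under the cap
    if pair_sample is not None:
        rng = rng or np.random.default_rng(0)
        ii = rng.integers(0, netA.n_nodes, size=pair_sample)
        jj = rng.integers(0, netB.n_nodes, size=pair_sample)
        F_cand = uA[ii] * uB[jj]
        ok = F_cand >= target_F
        if ok.any():
            k = np.flatnonzero(ok)[np.argmin(F_cand[ok])]
        else:
            k = int(np.argmax(F_cand))
        i, j = int(ii[k]), int(jj[k])
    else:
        F_all = np.outer(uA, uB)
        ok = F_all >= target_F
        if ok.any():
            masked = np.where(ok, F_all, np.inf)
            i, j = np.unravel_index(int(np.argmin(masked)), F_all.shape)
        else:
            i, j = np.unravel_index(int(np.argmax(F_all)), F_all.shape)
    F = float(uA[i] * uB[j])
    eps = a_target * dlam / F
    exact = eps <= eps_cap * (1 + 1e-12)
    eps = min(eps, eps_cap)
    return ConnectorConfig([(int(i), int(j))], eps, label=f"a={a_target:.4g}"), exact


def realize_equilibrium(
    netA: NodeNetwork,
    netB: NodeNetwork,
    x_target: float,
    eps_cap: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> ConnectorConfig | None:
    """Connector config whose *exact* equilibrium sits at ``x_target``.

    The first-order equilibrium is x_eq = a, but the exact curve bends
    below the diagonal at strong coupling (two-mode closed form
    ``x_eq(a) = (sqrt(1/4 + a^2) - 1/2)/a``).  This solves for the ``a``
    whose realized configuration has ``exact_equilibrium == x_target``, by
    secant iteration seeded with the two-mode inverse ``a = x/(1 - x^2)``.
    """
    if not 0.0 < x_target < 1.0:
        raise ValueError("holdable targets must lie in (0, 1)")
    from .dynamics import build_coupled_matrix as _build

    def x_eq_of(a: float) -> float:
        cfg, exact = realize_connection(netA, netB, a, eps_cap=eps_cap)
        if cfg is None or not exact:
            raise ValueError(f"target a={a} unreachable under the epsilon cap")
        return exact_equilibrium(_build(netA, netB, cfg))

    a0 = x_target / (1.0 - x_target**2)
    a1 = a0 * 1.05
    f0, f1 = x_eq_of(a0) - x_target, x_eq_of(a1) - x_target
    for _ in range(max_iter):
        if abs(f1) <= tol:
            break
        if f1 == f0:
            break
        a0, a1, f0 = a1, a1 - f1 * (a1 - a0) / (f1 - f0), f1
        a1 = max(a1, 1e-12)
        f1 = x_eq_of(a1) - x_target
    cfg, _ = realize_connection(netA, netB, a1, eps_cap=eps_cap)
    return cfg


def _batch_x_series(
    M: np.ndarray, N0: np.ndarray, t_max: int, uA: np.ndarray, uB: np.ndarray
) -> np.ndarray:
    """x(t) for a batch of initial columns, renormalizing each step."""
    n = N0.copy()
    xs = np.empty((t_max + 1, N0.shape[1]))
    with np.errstate(divide="ignore"):
        xs[0] = (uB @ n) / (uA @ n)
    for t in range(1, t_max + 1):
        n = M @ n
        n = n / n.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore"):
            xs[t] = (uB @ n) / (uA @ n)
    return xs


def compute_flux_grid(
    netA: NodeNetwork,
    netB: NodeNetwork,
    t: int,
    a_values: np.ndarray | None = None,
    x0_values: np.ndarray | None = None,
    method: str = "numeric",
    eps_cap: float = 1.0,
) -> FluxGrid:
    """|flux| at time ``t`` over a grid of (a, x0).

    Numeric method: for each ``a`` a connector link is realized
    (:func:`realize_connection`), every ``x0`` defines an independent
    two-eigenvector initial state, the coupled system is simulated to
    ``t + 1`` and the forward difference |x(t+1) - x(t)| recorded.
    Analytic method: |dx/dt| from the closed-form flux at the same (a, x0).

    Grid defaults: 25 points with a in [0, 1] and x0 in [0, 2.5].
    """
    if a_values is None:
        a_values = np.linspace(0.0, 1.0, 25)
    if x0_values is None:
        x0_values = np.linspace(0.0, 2.5, 25)
    a_values = np.asarray(a_values, float)
    x0_values = np.asarray(x0_values, float)
    lamA, lamB = netA.eigen().lam1, netB.eigen().lam1
    dlam = lamA - lamB

    flux = np.empty((len(a_values), len(x0_values)))
    missing = np.zeros_like(flux, dtype=bool)
    if method == "analytic":
        for k, a in enumerate(a_values):
            for l, x0 in enumerate(x0_values):
                ts = TheorySummary.from_scalars(lamA, lamB, a * dlam, x0)
                flux[k, l] = abs(flux_of_t(ts, t))
        return FluxGrid(a_values, x0_values, flux, t, "analytic")
    if method != "numeric":
        raise ValueError(f"unknown method {method!r}")

    uA_emb, uB_emb = embed_pair(netA, netB)
    nA, nB = netA.n_nodes, netB.n_nodes
    # independent initial states: one column per x0
    cA = 1.0 / np.sqrt(1.0 + x0_values**2)
    N0 = np.outer(uA_emb, cA) + np.outer(uB_emb, cA * x0_values)
    for k, a in enumerate(a_values):
        cfg, exact = realize_connection(netA, netB, a, eps_cap=eps_cap)
        if cfg is None:
            M = np.zeros((nA + nB, nA + nB))
            M[:nA, :nA] = netA.weights
            M[nA:, nA:] = netB.weights
        else:
            M = build_coupled_matrix(netA, netB, cfg).matrix
        if not exact:
            missing[k, :] = True
        xs = _batch_x_series(M, N0, t + 1, uA_emb, uB_emb)
        flux[k, :] = np.abs(xs[t + 1] - xs[t])
    return FluxGrid(a_values, x0_values, flux, t, "numeric", missing=missing)


def equilibrium_curve(
    netA: NodeNetwork, netB: NodeNetwork, configs: list[ConnectorConfig]
) -> list[tuple[float, float]]:
    """Exact equilibria (a, x_eq_exact) for a list of connector configs.

    The analytic counterpart is the diagonal x = a; the exact curve
    deviates from it by O(eps^2).
    """
    uA, uB = netA.eigen().u1, netB.eigen().u1
    dlam = netA.eigen().lam1 - netB.eigen().lam1
    points = []
    for cfg in configs:
        _, eps_F = connection_strength(uA, uB, cfg)
        sys_c = build_coupled_matrix(netA, netB, cfg)
        points.append((eps_F / dlam, exact_equilibrium(sys_c)))
    return sorted(points)


def trace_path(
    netA: NodeNetwork,
    netB: NodeNetwork,
    n0: np.ndarray,
    schedule,
    steps: int,
) -> DiagramPath:
    """Convert a run under a rewiring schedule into a diagram path.

    Emits one vertical segment per constant-config stretch (the dynamics
    moving x towards that config's equilibrium) and one horizontal segment
    per rewiring instant (a jumps at frozen x).
    """
    from .strategies import evolve_schedule

    traj = evolve_schedule(netA, netB, schedule, n0, steps)
    uA, uB = netA.eigen().u1, netB.eigen().u1
    dlam = netA.eigen().lam1 - netB.eigen().lam1

    def a_of(cfg: ConnectorConfig | None) -> float:
        if cfg is None or not cfg.pairs:
            return 0.0
        _, eps_F = connection_strength(uA, uB, cfg)
        return eps_F / dlam

    segments: list[PathSegment] = []
    times = [t for t, _ in schedule.entries]
    configs = [c for _, c in schedule.entries]
    bounds = times + [steps]
    prev_a = None
    for k, cfg in enumerate(configs):
        t0, t1 = bounds[k], min(bounds[k + 1], steps)
        if t1 <= t0:
            break
        a_k = a_of(cfg)
        i0 = int(np.flatnonzero(traj.t == t0)[0])
        i1 = int(np.flatnonzero(traj.t == t1)[0])
        x_start, x_end = float(traj.x[i0]), float(traj.x[i1])
        if prev_a is not None and a_k != prev_a:
            segments.append(
                PathSegment("horizontal", prev_a, x_start, a_k, x_start, t0, t0)
            )
        segments.append(PathSegment("vertical", a_k, x_start, a_k, x_end, t0, t1))
        prev_a = a_k
    return DiagramPath(segments=segments)


def plot_flux_diagram(
    grid: FluxGrid,
    curve: list[tuple[float, float]] | None = None,
    paths: list[DiagramPath] | None = None,
    out_path: str | None = None,
):
    """Minimal diagram rendering: |flux| heat map, equilibrium curve, paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(
        grid.a_values, grid.x0_values, grid.flux_abs.T, shading="nearest", cmap="viridis"
    )
    fig.colorbar(mesh, ax=ax, label=f"|flux| at t={grid.t} ({grid.method})")
    if curve:
        aa, xx = zip(*curve)
        ax.plot(aa, xx, "k-", lw=1.5, label="exact equilibria")
        ax.plot(aa, aa, "k--", lw=1.0, label="analytic x = a")
    if paths:
        for p in paths:
            for s in p.segments:
                ax.plot([s.start_a, s.end_a], [s.start_x, s.end_x], "w-", lw=1.2)
    ax.set_xlabel("normalised connection strength a")
    ax.set_ylabel("population distribution x")
    if curve:
        ax.legend(loc="upper left", fontsize=8)
    if out_path:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
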