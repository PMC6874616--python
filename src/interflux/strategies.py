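"""Connector-link selection and real-time rewiring strategies.

Static placements (CC/PP/CP/PC by eigenvector-centrality rank), the
heuristic CC->PP swap (fast approach under a central-central link, then
rewire to peripheral-peripheral once the flux dies down to keep the strong
network's optimal asymptote), exhaustive n-step lookahead over all single
connector links, and alternating schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    CoupledSystem,
    PopulationState,
    Trajectory,
    build_coupled_matrix,
    evolve,
)
from .networks import ConnectorConfig, NodeNetwork
from .spectral import exact_equilibrium

__all__ = [
    "StrategySpec",
    "RewiringSchedule",
    "select_static",
    "run_heuristic_swap",
    "exhaustive_lookahead",
    "run_exhaustive_strategy",
    "alternating_equilibrium",
    "run_reach_and_hold",
    "evolve_schedule",
]

#: Cap on horizon * N_A * N_B for the lookahead search.
LOOKAHEAD_BUDGET_CAP = 5_000_000


@dataclass(frozen=True)
class StrategySpec:
    """Declarative description of a strategy, as used in run-config files.

    ``kind`` is one of static, heuristic_swap, exhaustive, alternating,
    custom_schedule; ``params`` holds kind-specific settings (connection
    mode, swap threshold, lookahead horizon, objective, link budget).
    """

    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = ("static", "heuristic_swap", "exhaustive", "alternating", "custom_schedule")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "exhaustive" and self.params.get("horizon", 1) < 1:
            raise ValueError("exhaustive lookahead needs horizon >= 1")
        if self.kind == "heuristic_swap" and self.params.get("threshold", 1.0) <= 0:
            raise ValueError("heuristic swap needs threshold > 0")


@dataclass
class RewiringSchedule:
    """Ordered list of (activation time, connector config), starting at t=0."""

    entries: list[tuple[int, ConnectorConfig]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.entries]
        if not self.entries or times[0] != 0:
            raise ValueError("schedule must start at t=0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")

    def config_at(self, t: int) -> ConnectorConfig:
        cfg = self.entries[0][1]
        for t0, c in self.entries:
            if t0 <= t:
                cfg = c
            else:
                break
        return cfg


def _rank_order(u: np.ndarray, highest: bool) -> np.ndarray:
    """Node indices by centrality rank; ties broken by ascending node index."""
    # stable sort on (-u, index) or (u, index)
    key = -u if highest else u
    return np.argsort(key, kind="stable")


def select_static(
    netA: NodeNetwork,
    netB: NodeNetwork,
    mode: str,
    k_links: int = 1,
    epsilon: float = 1.0,
) -> ConnectorConfig:
    """Static connector placement by centrality rank.

    CC pairs the k most central nodes of each network in rank order, PP the
    k most peripheral, CP/PC mix one end of each ranking.  Centralities are
    those of the isolated networks; ties break by ascending node index.
    """
    mode = mode.upper()
    if mode not in ("CC", "PP", "CP", "PC"):
        raise ValueError(f"unknown connection mode {mode!r}")
    if k_links < 1:
        raise ValueError("k_links must be >= 1")
    if k_links > min(netA.n_nodes, netB.n_nodes):
        raise ValueError("k_links exceeds the smaller network size")
    uA = netA.eigen().u1
    uB = netB.eigen().u1
    ranksA = _rank_order(uA, highest=mode[0] == "C")
    ranksB = _rank_order(uB, highest=mode[1] == "C")
    pairs = [(int(ranksA[k]), int(ranksB[k])) for k in range(k_links)]
    return ConnectorConfig(pairs=pairs, epsilon=epsilon, label=mode)


def run_heuristic_swap(
    netA: NodeNetwork,
    netB: NodeNetwork,
    n0: np.ndarray | PopulationState,
    threshold: float = 1e-4,
    max_steps: int = 5000,
    epsilon: float = 1.0,
) -> tuple[Trajectory, RewiringSchedule, dict]:
    """CC until the flux dies down, then PP (the CC->PP heuristic).

    Evolves under the central-central link; once the per-step |x(t+1)-x(t)|
    falls below ``threshold`` (the system is close to the CC equilibrium)
    the single connector is rewired to peripheral-peripheral, which slowly
    drains the remaining population into the strong network.

    Returns the trajectory, the realized schedule, and an info dict with
    the swap time (``swapped=False`` flags that the threshold was never
    reached within ``max_steps``).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cfg_cc = select_static(netA, netB, "CC", epsilon=epsilon)
    cfg_pp = select_static(netA, netB, "PP", epsilon=epsilon)
    sys_cc = build_coupled_matrix(netA, netB, cfg_cc)

    state = n0 if isinstance(n0, PopulationState) else PopulationState(np.asarray(n0, float))
    parts: list[Trajectory] = []
    swap_t = None
    traj = None
    for t in range(max_steps):
        traj_step = evolve(sys_cc, state, steps=1, config_id="CC")
        state = traj_step.final_state
        parts.append(traj_step)
        if abs(traj_step.x[1] - traj_step.x[0]) < threshold:
            swap_t = t + 1
            break
    if swap_t is not None and swap_t < max_steps:
        sys_pp = sys_cc.with_config(cfg_pp)
        tail = evolve(sys_pp, state, steps=max_steps - swap_t, config_id="PP")
        parts.append(tail)
        schedule = RewiringSchedule([(0, cfg_cc), (swap_t, cfg_pp)])
    else:
        schedule = RewiringSchedule([(0, cfg_cc)])
    traj = Trajectory.concatenate(parts)
    traj.metadata["strategy"] = "heuristic CC->PP"
    info = {"swapped": swap_t is not None, "swap_time": swap_t, "threshold": threshold}
    return traj, schedule, info


class _LookaheadWorkspace:
    """Precomputed per-network quantities for the single-link lookahead.

    For a candidate link (i, j) with weight eps the coupled matrix differs
    from the block-diagonal M0 by a rank-2 update, so the state after h
    steps stays in the span of {M0^k n0} and the columns {M_A^k e_i},
    {M_B^k e_j}.  Only three families of scalars enter the objective:
    diag(M_A^k) (feedback of a column onto its own node), the column sums
    of M_A^k (mass each column injects into A), and the same for B.  This
    evaluates P_A after h steps for all N_A*N_B candidate links at once,
    exactly (same arithmetic as literally simulating every candidate).
    """

    def __init__(self, netA: NodeNetwork, netB: NodeNetwork, horizon: int):
        self.nA, self.nB = netA.n_nodes, netB.n_nodes
        self.h = horizon
        MA, MB = netA.weights, netB.weights
        self.MA, self.MB = MA, MB
        powA = [np.eye(self.nA)]
        powB = [np.eye(self.nB)]
        for _ in range(horizon):
            powA.append(MA @ powA[-1])
            powB.append(MB @ powB[-1])
        self.diagA = np.array([np.diag(P) for P in powA])  # (h+1, nA)
        self.diagB = np.array([np.diag(P) for P in powB])
        self.colsumA = np.array([P.sum(axis=0) for P in powA])  # (h+1, nA)
        self.colsumB = np.array([P.sum(axis=0) for P in powB])

    def p_a_scores(self, n: np.ndarray, epsilon: float) -> np.ndarray:
        """P_A after h steps for every candidate link, as an (nA, nB) array."""
        h, nA, nB = self.h, self.nA, self.nB
        baseA = np.empty((h + 1, nA))
        baseB = np.empty((h + 1, nB))
        baseA[0], baseB[0] = n[:nA], n[nA:]
        for k in range(h):
            baseA[k + 1] = self.MA @ baseA[k]
            baseB[k + 1] = self.MB @ baseB[k]
        # cA[k], cB[k]: coefficients of M_A^k e_i and M_B^k e_j for every
        # candidate (i, j); shapes broadcast against (nA, nB)
        zero = np.zeros((1, 1))
        cA = [zero] * (h + 1)
        cB = [zero] * (h + 1)
        for t in range(h):
            # entries of n(t) at the two candidate endpoints
            n_p = baseA[t][:, None] + sum(
                cA[k] * self.diagA[k][:, None] for k in range(h + 1)
            )
            n_q = baseB[t][None, :] + sum(
                cB[k] * self.diagB[k][None, :] for k in range(h + 1)
            )
            cA = [epsilon * n_q] + cA[:-1]
            cB = [epsilon * n_p] + cB[:-1]
        massA = baseA[h].sum() + sum(
            cA[k] * self.colsumA[k][:, None] for k in range(h + 1)
        )
        massB = baseB[h].sum() + sum(
            cB[k] * self.colsumB[k][None, :] for k in range(h + 1)
        )
        return massA / (massA + massB)


def _naive_single_link_scores(
    netA: NodeNetwork, netB: NodeNetwork, n: np.ndarray, epsilon: float, horizon: int
) -> np.ndarray:
    """Literal enumeration: simulate every candidate link for h steps."""
    nA, nB = netA.n_nodes, netB.n_nodes
    scores = np.empty((nA, nB))
    for i in range(nA):
        for j in range(nB):
            sys_ij = build_coupled_matrix(netA, netB, ConnectorConfig([(i, j)], epsilon))
            v = n.copy()
            for _ in range(horizon):
                v = sys_ij.matrix @ v
            scores[i, j] = v[:nA].sum() / v.sum()
    return scores


def exhaustive_lookahead(
    netA: NodeNetwork,
    netB: NodeNetwork,
    n: np.ndarray,
    horizon: int,
    epsilon: float = 1.0,
    objective: str = "max_PA",
    budget_cap: int = LOOKAHEAD_BUDGET_CAP,
) -> ConnectorConfig:
    """Best single connector link by simulating ``horizon`` steps ahead.

    Scores every candidate link in N_A x N_B by the chosen objective
    evaluated on the state after ``horizon`` steps (default: the strong
    network's population share P_A) and returns the argmax; ties break
    deterministically by (node index in A, node index in B).

    Objectives: ``max_PA``, ``min_PA``, ``max_abs_flux`` (largest one-step
    |x| change at the horizon).
    """
    if not 1 <= horizon <= 20:
        raise ValueError("horizon must be in 1..20")
    nA, nB = netA.n_nodes, netB.n_nodes
    if horizon * nA * nB > budget_cap:
        raise ValueError(
            f"lookahead budget {horizon * nA * nB} exceeds cap {budget_cap}; "
            "sample candidate links instead"
        )
    n = np.asarray(n, dtype=float)
    if objective in ("max_PA", "min_PA"):
        ws = _LookaheadWorkspace(netA, netB, horizon)
        scores = ws.p_a_scores(n, epsilon)
        if objective == "min_PA":
            scores = -scores
    elif objective == "max_abs_flux":
        from .spectral import embed_pair

        uA, uB = embed_pair(netA, netB)
        scores = np.empty((nA, nB))
        for i in range(nA):
            for j in range(nB):
                sys_ij = build_coupled_matrix(netA, netB, ConnectorConfig([(i, j)], epsilon))
                v = n.copy()
                for _ in range(horizon):
                    v = sys_ij.matrix @ v
                    v = v / v.sum()
                w = sys_ij.matrix @ v
                x1 = (w @ uB) / (w @ uA)
                x0 = (v @ uB) / (v @ uA)
                scores[i, j] = abs(x1 - x0)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    flat = np.argmax(scores)  # first occurrence = smallest (i, j): deterministic
    i, j = np.unravel_index(flat, scores.shape)
    return ConnectorConfig([(int(i), int(j))], epsilon, label=f"lookahead_h{horizon}")


def run_exhaustive_strategy(
    netA: NodeNetwork,
    netB: NodeNetwork,
    n0: np.ndarray | PopulationState,
    steps: int,
    horizon: int = 5,
    epsilon: float = 1.0,
    objective: str = "max_PA",
    reoptimize_every: int = 1,
) -> tuple[Trajectory, RewiringSchedule]:
    """Run the exhaustive lookahead strategy over time.

    Every ``reoptimize_every`` steps the best single link for the current
    state is recomputed and the system advances one step under it.
    """
    state = n0 if isinstance(n0, PopulationState) else PopulationState(np.asarray(n0, float))
    cfg = exhaustive_lookahead(netA, netB, state.n, horizon, epsilon, objective)
    sys_cur = build_coupled_matrix(netA, netB, cfg)
    entries = [(0, cfg)]
    parts = []
    for t in range(steps):
        if t > 0 and t % reoptimize_every == 0:
            new_cfg = exhaustive_lookahead(netA, netB, state.n, horizon, epsilon, objective)
            if new_cfg.pairs != cfg.pairs:
                cfg = new_cfg
                sys_cur = sys_cur.with_config(cfg)
                entries.append((t, cfg))
        part = evolve(sys_cur, state, steps=1, config_id=f"exh{cfg.pairs[0]}")
        state = part.final_state
        parts.append(part)
    traj = Trajectory.concatenate(parts)
    traj.metadata["strategy"] = f"exhaustive lookahead h={horizon}"
    return traj, RewiringSchedule(entries)


def evolve_schedule(
    netA: NodeNetwork,
    netB: NodeNetwork,
    schedule: RewiringSchedule,
    n0: np.ndarray | PopulationState,
    steps: int,
) -> Trajectory:
    """Evolve under a rewiring schedule; each config takes effect at the
    start of its activation step."""
    state = n0 if isinstance(n0, PopulationState) else PopulationState(np.asarray(n0, float))
    times = [t for t, _ in schedule.entries] + [steps]
    parts = []
    for k, (t0, cfg) in enumerate(schedule.entries):
        t1 = min(times[k + 1], steps)
        if t1 <= t0:
            break
        sys_k = build_coupled_matrix(netA, netB, cfg)
        part = evolve(sys_k, state, steps=t1 - t0, config_id=cfg.label or f"cfg{k}")
        state = part.final_state
        parts.append(part)
    return Trajectory.concatenate(parts)


def alternating_equilibrium(
    sys: CoupledSystem,
    cfg1: ConnectorConfig,
    cfg2: ConnectorConfig,
    max_steps: int = 20000,
    tol: float = 1e-10,
) -> float:
    """Limiting x under strict alternation of two connector configs.

    Switches between ``cfg1`` and ``cfg2`` every step and returns the limit
    of x over the even-step subsequence.  The limit coincides (to second
    order in eps) with the exact equilibrium of the union configuration in
    which every link of both configs carries half its weight.
    """
    if cfg1.pairs == cfg2.pairs and cfg1.epsilon == cfg2.epsilon:
        return exact_equilibrium(sys.with_config(cfg1))
    if cfg1.epsilon != cfg2.epsilon:
        raise ValueError("alternating configs must share the same epsilon")
    sys1 = sys.with_config(cfg1)
    sys2 = sys.with_config(cfg2)
    uA, uB = sys.embedded_eigenvectors()
    n = sys.equilibrium_initial_state(1.0)
    from .dynamics import distribution_x

    x_prev = distribution_x(n, uA, uB)
    for t in range(1, max_steps + 1):
        M = sys1.matrix if (t - 1) % 2 == 0 else sys2.matrix
        n = M @ n
        n = n / n.sum()
        if t % 2 == 0:
            x = distribution_x(n, uA, uB)
            if abs(x - x_prev) < tol:
                return x
            x_prev = x
    raise RuntimeError(
        f"alternating evolution did not settle within {max_steps} steps "
        f"(last even-step x = {x_prev})"
    )


def run_reach_and_hold(
    netA: NodeNetwork,
    netB: NodeNetwork,
    n0: np.ndarray | PopulationState,
    x_target: float,
    drive_cfg: ConnectorConfig,
    max_steps: int = 5000,
    epsilon_cap: float = 1.0,
) -> tuple[Trajectory, RewiringSchedule]:
    """Drive x towards ``x_target`` and then freeze it there.

    Evolves under ``drive_cfg`` until x crosses the target, then rewires to
    a configuration whose *exact* equilibrium sits at the target, stopping
    the flux.
    """
    from .diagram import realize_equilibrium

    hold_cfg = realize_equilibrium(netA, netB, x_target, eps_cap=epsilon_cap)
    if hold_cfg is None:
        raise ValueError(f"cannot realize a holding config at x={x_target}")
    state = n0 if isinstance(n0, PopulationState) else PopulationState(np.asarray(n0, float))
    sys_drive = build_coupled_matrix(netA, netB, drive_cfg)
    uA, uB = sys_drive.embedded_eigenvectors()
    from .dynamics import distribution_x

    x_now = distribution_x(state.n, uA, uB)
    rising = x_now < x_target
    parts = []
    cross_t = None
    for t in range(max_steps):
        part = evolve(sys_drive, state, steps=1, config_id=drive_cfg.label or "drive")
        state = part.final_state
        parts.append(part)
        x_now = part.x[1]
        if (rising and x_now >= x_target) or (not rising and x_now <= x_target):
            cross_t = t + 1
            break
    if cross_t is None:
        raise RuntimeError(f"x never reached {x_target} within {max_steps} steps")
    sys_hold = sys_drive.with_config(hold_cfg)
    tail = evolve(sys_hold, state, steps=max_steps - cross_t, config_id="hold")
    parts.append(tail)
    traj = Trajectory.concatenate(parts)
    traj.metadata["strategy"] = f"reach-and-hold x={x_target}"
    return traj, RewiringSchedule([(0, drive_cfg), (cross_t, hold_cfg)])
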