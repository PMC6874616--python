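"""File formats: edge lists, trajectories, flux grids, flow tables, run configs.

All formats are plain CSV (comma, UTF-8, LF) with exact headers; floats are
written with 17 significant digits so every round trip is lossless.  Node
ids are 0-based integers.  Run configurations are YAML trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import TRAJECTORY_COLUMNS, Trajectory
from .flows import FlowTable
from .networks import NodeNetwork

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "write_trajectory",
    "read_trajectory",
    "write_flux_grid",
    "write_path",
    "read_flow_table",
    "write_flow_table",
    "read_group_map",
    "write_points",
    "RunConfig",
]

FLOAT_FMT = "%.17g"


def read_edge_list(path, directed: bool = False, label: str = "") -> NodeNetwork:
    """Read a CSV/TSV edge list with header ``source,target[,weight]``.

    Node ids are 0-based integers and the network size is ``max id + 1``.
    Undirected input may list each edge once and is symmetrized; duplicate
    edges are summed with a warning.  Negative weights and malformed rows
    are errors.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = list(df.columns)
    if cols[:2] != ["source", "target"] or cols not in (
        ["source", "target"],
        ["source", "target", "weight"],
    ):
        raise ValueError(
            f"{path}: header must be 'source,target[,weight]', got {cols}"
        )
    if "weight" not in df.columns:
        df["weight"] = 1.0
    for col in ("source", "target"):
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = df.index[vals != vals.astype(int, errors="ignore")]
            try:
                df[col] = vals.astype(int)
            except (ValueError, TypeError) as exc:
                row = int(bad[0]) + 2 if len(bad) else "?"
                raise ValueError(f"{path}: malformed node id near line {row}") from exc
    if (df[["source", "target"]] < 0).any().any():
        raise ValueError(f"{path}: node ids must be nonnegative")
    if (df["weight"] < 0).any():
        line = int(df.index[df["weight"] < 0][0]) + 2
        raise ValueError(f"{path}: negative weight at line {line}")
    n = int(df[["source", "target"]].to_numpy().max()) + 1
    W = np.zeros((n, n))
    dup = df.duplicated(subset=["source", "target"]).any()
    if dup:
        warnings.warn(f"{path}: duplicate edges summed", stacklevel=2)
    for s, t, w in df.itertuples(index=False):
        W[int(s), int(t)] += float(w)
    if not directed:
        off = ~np.eye(n, dtype=bool)
        if np.any((W > 0) & (W.T > 0) & off):
            warnings.warn(f"{path}: edges listed in both orientations summed", stacklevel=2)
        W = W + W.T
        np.fill_diagonal(W, np.diag(W) / 2)
    return NodeNetwork(weights=W, directed=directed, label=label or path.stem)


def write_edge_list(net: NodeNetwork, path) -> None:
    """Write a network as a ``source,target,weight`` CSV (one row per edge)."""
    W = net.weights
    if net.directed:
        src, tgt = np.nonzero(W)
    else:
        src, tgt = np.nonzero(np.triu(W))
    df = pd.DataFrame({"source": src, "target": tgt, "weight": W[src, tgt]})
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the exact trajectory CSV: ``t,x,P_A,flux,config_id``."""
    traj.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(f"{path}: header must be {','.join(TRAJECTORY_COLUMNS)}")
    return Trajectory(
        t=df["t"].to_numpy(),
        x=df["x"].to_numpy(dtype=float),
        p_a=df["P_A"].to_numpy(dtype=float),
        flux=df["flux"].to_numpy(dtype=float),
        config_id=[str(c) for c in df["config_id"]],
    )


def write_flux_grid(grid, path) -> None:
    """Write a flux grid as ``a,x0,flux_abs,t,method`` rows."""
    grid.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_path(dpath, path) -> None:
    """Write a diagram path as ``type,start_a,start_x,end_a,end_x`` rows."""
    dpath.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_flow_table(path, group_map: dict[str, str] | None = None) -> FlowTable:
    """Read a square flow matrix CSV with node labels as header row/column."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels must match")
    return FlowTable(
        entries=df.to_numpy(dtype=float),
        node_labels=[str(c) for c in df.columns],
        group_map=group_map or {},
    )


def write_flow_table(table: FlowTable, path) -> None:
    pd.DataFrame(
        table.entries, index=table.node_labels, columns=table.node_labels
    ).to_csv(path, float_format=FLOAT_FMT, lineterminator="\n")


def read_group_map(path) -> dict[str, str]:
    """Read a two-column ``node,group`` CSV into a dict."""
    df = pd.read_csv(path)
    if list(df.columns) != ["node", "group"]:
        raise ValueError(f"{path}: header must be 'node,group'")
    return {str(r.node): str(r.group) for r in df.itertuples(index=False)}


def write_points(points: list[tuple], path, columns=("period", "strength", "x")) -> None:
    pd.DataFrame(points, columns=list(columns)).to_csv(
        path, index=False, float_format=FLOAT_FMT, lineterminator="\n"
    )


@dataclass
class RunConfig:
    """Declarative run configuration (YAML).

    Schema (all keys optional unless noted)::

        networks:              # required: either fixture or files
          fixture: {kind: scale_free_pair, N: 250, m: 3, seedA: 0, seedB: 1}
          # or: edges_a: a.csv, edges_b: b.csv, directed: false
        connector: {mode: CC, k_links: 1, epsilon: 1.0}
        # or connector: {pairs: [[0, 0]], epsilon: 0.1}
        strategy:  {kind: static, params: {}}
        initial:   {x0: 2.5}          # exactly one of x0 | all_on_b | vector_file
        steps: 500
        seed: 0
        outputs: {trajectory: traj.csv, schedule: sched.csv}
        log_level: INFO
    """

    networks: dict
    connector: dict = field(default_factory=dict)
    strategy: dict = field(default_factory=dict)
    initial: dict = field(default_factory=lambda: {"x0": 1.0})
    steps: int = 100
    seed: int = 0
    outputs: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sources = [k for k in ("x0", "all_on_b", "vector_file") if k in self.initial]
        if len(sources) != 1:
            raise ValueError(
                f"exactly one initial-condition source required, got {sources}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "networks": self.networks,
            "connector": self.connector,
            "strategy": self.strategy,
            "initial": self.initial,
            "steps": self.steps,
            "seed": self.seed,
            "outputs": self.outputs,
            "log_level": self.log_level,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
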