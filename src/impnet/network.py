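"""Weighted structural connectome construction from tractography summaries.

A subject's connectome is a symmetric nonnegative n x n matrix over atlas
regions (the 90 AAL cerebrum regions by default).  The weight of the edge
between regions i and j combines the streamline count FN and the mean
fractional anisotropy FA of the connecting fibers, normalized by the average
volume of the two regions so that large regions do not accumulate spuriously
strong connections:

    W_ij = FN * FA / ((vol_i + vol_j) / 2)

The module reads tractography summary edge lists (TSV) and node tables (TSV),
and reads/writes dense matrix CSVs with a sidecar label file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NodeTable",
    "WeightedNetwork",
    "edge_weight",
    "build_network",
    "load_node_table",
    "aal90_nodes",
    "read_edge_list",
    "write_matrix",
    "read_matrix",
]

_EDGE_COLUMNS = ["node_i", "node_j", "fiber_count", "mean_fa"]


@dataclass
class NodeTable:
    """Atlas regions serving as network nodes: id, label, volume (mm^3)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for c in ("node_id", "label", "volume_mm3"):
            if c not in t.columns:
                raise ValueError(f"node table missing column {c!r}")
        if list(t["node_id"]) != list(range(len(t))):
            raise ValueError("node_id must be 0..n-1 in order")
        if t["label"].duplicated().any():
            raise ValueError("node labels must be unique")
        if (t["volume_mm3"] <= 0).any():
            raise ValueError("region volumes must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    @property
    def volumes(self) -> np.ndarray:
        return self.table["volume_mm3"].to_numpy(dtype=float)


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative edge-weight matrix with node metadata."""

    weights: np.ndarray
    node_table: NodeTable

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if W.shape[0] != self.node_table.n_nodes:
            raise ValueError("weight matrix size does not match node table")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def edge_weight(fn: float, fa: float, vol_i: float, vol_j: float) -> float:
    """Edge weight ``FN * FA / mean(vol_i, vol_j)``.

    Zero iff there are no streamlines or the mean FA is zero.
    """
    if vol_i <= 0 or vol_j <= 0:
        raise ValueError("region volumes must be positive")
    if fn < 0:
        raise ValueError("fiber count must be nonnegative")
    if not 0 <= fa <= 1:
        raise ValueError("mean FA must lie in [0, 1]")
    return (fn * fa) / ((vol_i + vol_j) / 2.0)


def build_network(edges: pd.DataFrame, nodes: NodeTable) -> WeightedNetwork:
    """Assemble a WeightedNetwork from an edge-record table.

    ``edges`` has columns node_i, node_j, fiber_count, mean_fa (0-based node
    indices, undirected records).  Absent pairs get weight 0; duplicate pairs
    and self-loops are rejected.
    """
    missing = [c for c in _EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    n = nodes.n_nodes
    W = np.zeros((n, n), dtype=float)
    vols = nodes.volumes
    seen: set[tuple[int, int]] = set()
    for row in edges.itertuples(index=False):
        i, j = int(row.node_i), int(row.node_j)
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i},{j}) references node outside 0..{n - 1}")
        if i == j:
            raise ValueError(f"self-loop on node {i} is not allowed")
        pair = (min(i, j), max(i, j))
        if pair in seen:
            raise ValueError(f"duplicate edge record for pair {pair}")
        seen.add(pair)
        w = edge_weight(float(row.fiber_count), float(row.mean_fa), vols[i], vols[j])
        W[i, j] = W[j, i] = w
    return WeightedNetwork(W, nodes)


def load_node_table(path: str | Path) -> NodeTable:
    """Read a node table TSV (node_id, label, volume_mm3)."""
    return NodeTable(pd.read_csv(path, sep="\t", comment="#"))


def aal90_nodes() -> NodeTable:
    """The packaged 90-region AAL cerebrum node table.

    Labels follow the standard AAL order (left/right interleaved, cerebellum
    and vermis excluded); region volumes are synthetic nominal values, since
    native-space volumes are subject-specific.
    """
    ref = importlib.resources.files("impnet.data").joinpath("aal90_nodes_synthetic.tsv")
    with importlib.resources.as_file(ref) as p:
        return load_node_table(p)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a tractography summary edge list TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: edge list missing columns {missing}")
    return df


def write_matrix(net: WeightedNetwork, path: str | Path) -> None:
    """Write a dense headerless matrix CSV plus a ``.labels.txt`` sidecar."""
    path = Path(path)
    np.savetxt(path, net.weights, delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".labels.txt")
    sidecar.write_text("\n".join(net.node_table.labels) + "\n")


def read_matrix(path: str | Path, nodes: NodeTable | None = None) -> WeightedNetwork:
    """Read a dense matrix CSV back into a WeightedNetwork.

    If ``nodes`` is omitted, labels come from the sidecar written by
    :func:`write_matrix` (unit volumes), or fall back to generic names.
    """
    path = Path(path)
    W = np.loadtxt(path, delimiter=",")
    W = np.atleast_2d(W)
    if nodes is None:
        sidecar = path.with_suffix(path.suffix + ".labels.txt")
        if sidecar.exists():
            labels = sidecar.read_text().splitlines()
        else:
            labels = [f"node{i:03d}" for i in range(W.shape[0])]
        nodes = NodeTable(
            pd.DataFrame(
                {"node_id": range(len(labels)), "label": labels, "volume_mm3": 1.0}
            )
        )
    return WeightedNetwork(W, nodes)
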