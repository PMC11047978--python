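"""Topological metrics of the perineuronal-net mesh.

A PNN imaged at super-resolution appears as a mesh whose locally bright
junction points ("nodes") can be reduced to a 3D point cloud.  The mesh is
summarised by five statistics computed on a proximity graph: two node
coordinates are joined by an edge whenever their Euclidean distance is at
most a threshold (default 0.7 µm, the sweep floor of the R95 statistic).

The five metrics per PNN are

* ``n_nodes`` — number of detected mesh nodes;
* ``pct_connected`` — percentage of nodes with at least one neighbour
  within the base threshold;
* ``mean_internode_dist`` — mean edge length (µm) of the proximity graph;
* ``mean_degree`` — mean number of connections per node, ``2|E|/N``;
* ``r95`` — the smallest threshold, swept upward from 0.7 µm, at which at
  least 95 % of nodes are connected.  Compact meshes have a small R95;
  fragmented meshes need a large threshold, and meshes with more than 5 %
  of permanently isolated nodes never reach 95 % (flagged unreached).

"Connected node" means degree >= 1 in the proximity graph, not membership
in a giant component; this makes the 95 % criterion well defined node by
node.  All distances are physical (µm), computed from calibrated
coordinates; there is no periodic boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import ParameterError
from .nodes import NodeSet

__all__ = [
    "MeshGraph",
    "TopologyMetrics",
    "build_graph",
    "connected_fraction",
    "mean_internode_distance",
    "mean_degree",
    "r95",
    "summarize_topology",
    "summarize_many",
    "group_means",
    "BASE_THRESHOLD_UM",
    "R95_START_UM",
    "R95_STEP_UM",
    "R95_MAX_UM",
]

BASE_THRESHOLD_UM = 0.7
R95_START_UM = 0.7
R95_STEP_UM = 0.05
R95_MAX_UM = 3.0


def _coords(nodes) -> np.ndarray:
    if isinstance(nodes, NodeSet):
        return nodes.coords
    arr = np.asarray(nodes, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ParameterError("node coordinates must be an (N, 3) array of µm positions")
    return arr


@dataclass
class MeshGraph:
    """Proximity graph of a node cloud at a fixed distance threshold.

    ``edges`` holds unordered index pairs ``(i, j)`` with ``i < j`` and
    ``d(i, j) <= threshold``; ``edge_lengths`` the matching distances (µm).
    """

    coords: np.ndarray
    threshold: float
    edges: np.ndarray
    edge_lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.n_edges:
            np.add.at(deg, self.edges.ravel(), 1)
        return deg


def build_graph(nodes, threshold: float) -> MeshGraph:
    """Build the exact proximity graph at ``threshold`` µm.

    The edge set is exactly ``{(i, j) : d(i, j) <= threshold, i < j}``;
    neighbour search uses a k-d tree, so construction is deterministic and
    near-linear for the sparse clouds produced by a single PNN.
    """
    if threshold <= 0:
        raise ParameterError("graph threshold must be positive")
    coords = _coords(nodes)
    if len(coords) < 2:
        return MeshGraph(coords, threshold, np.empty((0, 2), dtype=int), np.empty(0))
    pairs = cKDTree(coords).query_pairs(r=threshold, output_type="ndarray")
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        lengths = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    else:
        lengths = np.empty(0)
    return MeshGraph(coords, threshold, pairs, lengths)


def connected_fraction(graph: MeshGraph) -> float:
    """Percentage of nodes with degree >= 1; an empty graph counts as 0 %."""
    if graph.n_nodes == 0:
        warnings.warn("connected_fraction of an empty node set is defined as 0",
                      stacklevel=2)
        return 0.0
    return 100.0 * float(np.count_nonzero(graph.degrees())) / graph.n_nodes


def mean_internode_distance(graph: MeshGraph) -> float:
    """Mean Euclidean edge length in µm; NaN when the graph has no edges."""
    if graph.n_edges == 0:
        return math.nan
    return float(graph.edge_lengths.mean())


def mean_degree(graph: MeshGraph) -> float:
    """Average connections per node, ``2|E| / N``; 0 for an empty cloud."""
    if graph.n_nodes == 0:
        warnings.warn("mean_degree of an empty node set is defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * graph.n_edges / graph.n_nodes


def _threshold_grid(start: float, step: float, max_threshold: float) -> np.ndarray:
    # inclusive grid start, start+step, ..., max_threshold; rounded to 9
    # decimals so accumulated float error cannot shift a threshold off the
    # decimal grid (0.7 + 6*0.05 must be exactly 1.0)
    n = int(math.floor((max_threshold - start) / step + 1e-9)) + 1
    return np.round(start + step * np.arange(n), 9)


def r95(
    nodes,
    start: float = R95_START_UM,
    step: float = R95_STEP_UM,
    max_threshold: float = R95_MAX_UM,
) -> float:
    """Connectivity-sweep statistic R95.

    Sweeps the proximity threshold over ``start, start+step, ...,
    max_threshold`` and returns the smallest threshold at which at least
    95 % of nodes have a neighbour within that distance.  Returns NaN
    (unreached) when even ``max_threshold`` leaves more than 5 % of nodes
    isolated, or when fewer than two nodes exist.

    A node is connected at threshold ``t`` iff its nearest-neighbour
    distance is <= ``t``, so the sweep is evaluated exactly from the
    nearest-neighbour distances; connectivity is non-decreasing in ``t``.
    """
    if start <= 0 or step <= 0:
        raise ParameterError("r95 start and step must be positive")
    if max_threshold < start:
        raise ParameterError("r95 max_threshold must be >= start")
    coords = _coords(nodes)
    if len(coords) < 2:
        warnings.warn("r95 undefined for fewer than 2 nodes; returning unreached",
                      stacklevel=2)
        return math.nan
    nn_dist = cKDTree(coords).query(coords, k=2)[0][:, 1]
    for t in _threshold_grid(start, step, max_threshold):
        if np.count_nonzero(nn_dist <= t) >= 0.95 * len(coords):
            return float(t)
    return math.nan


@dataclass
class TopologyMetrics:
    """The five per-PNN mesh statistics plus the parameters they used."""

    pnn_id: str
    n_nodes: int
    pct_connected: float
    mean_internode_dist: float
    mean_degree: float
    r95: float
    base_threshold: float = BASE_THRESHOLD_UM
    r95_params: tuple[float, float, float] = (R95_START_UM, R95_STEP_UM, R95_MAX_UM)
    labels: dict = field(default_factory=dict)

    @property
    def r95_reached(self) -> bool:
        return not math.isnan(self.r95)

    METRIC_COLUMNS = (
        "n_nodes", "pct_connected", "mean_internode_dist", "mean_degree", "r95",
    )

    def to_dict(self) -> dict:
        out = {"pnn_id": self.pnn_id, **self.labels}
        out.update({k: getattr(self, k) for k in self.METRIC_COLUMNS})
        out["r95_reached"] = self.r95_reached
        return out


def summarize_topology(
    nodes,
    base_threshold: float = BASE_THRESHOLD_UM,
    r95_start: float = R95_START_UM,
    r95_step: float = R95_STEP_UM,
    r95_max: float = R95_MAX_UM,
    labels: dict | None = None,
) -> TopologyMetrics:
    """Compute all five mesh metrics for one PNN node cloud."""
    coords = _coords(nodes)
    pnn_id = nodes.pnn_id if isinstance(nodes, NodeSet) else ""
    if len(coords) == 0:
        warnings.warn(f"empty node set for PNN {pnn_id!r}: metrics flagged",
                      stacklevel=2)
        return TopologyMetrics(pnn_id, 0, 0.0, math.nan, 0.0, math.nan,
                               base_threshold, (r95_start, r95_step, r95_max),
                               labels or {})
    g = build_graph(coords, base_threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = r95(coords, r95_start, r95_step, r95_max)
    return TopologyMetrics(
        pnn_id=pnn_id,
        n_nodes=len(coords),
        pct_connected=connected_fraction(g),
        mean_internode_dist=mean_internode_distance(g),
        mean_degree=mean_degree(g),
        r95=r,
        base_threshold=base_threshold,
        r95_params=(r95_start, r95_step, r95_max),
        labels=labels or {},
    )


def summarize_many(node_sets, **kwargs) -> pd.DataFrame:
    """Per-PNN metrics table for a batch of node sets (one row per PNN)."""
    rows = [summarize_topology(ns, **kwargs).to_dict() for ns in node_sets]
    return pd.DataFrame(rows)


def group_means(metrics: pd.DataFrame, group_keys) -> pd.DataFrame:
    """Average each metric across PNNs within experimental groups.

    R95 values flagged unreached (NaN) are excluded from the R95 mean,
    mirroring how per-PNN values were pooled per group in practice.
    """
    cols = [c for c in TopologyMetrics.METRIC_COLUMNS if c in metrics.columns]
    return metrics.groupby(list(group_keys), observed=True)[cols].mean().reset_index()
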