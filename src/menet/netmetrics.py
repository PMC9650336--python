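"""Binary network construction and efficiency metrics.

A PLV matrix becomes a binary graph by keeping edges with PLV strictly above
a threshold T.  Distances are unweighted hop counts (breadth-first search via
``scipy.sparse.csgraph``), with d = infinity for disconnected pairs and
1/infinity treated as exact 0.  Efficiencies:

    E_global(G) = 1/(N(N-1)) * sum_{j != k} 1/d_jk        (macro scale)
    E_nodal(j)  = 1/(N-1)    * sum_{k != j} 1/d_jk        (micro scale)

Both lie in [0, 1]; E_global equals the mean of all nodal efficiencies.
Regional efficiency is the arithmetic mean of the nodal efficiencies of the
channels assigned to a scalp region.  Isolated nodes stay in the node set
(they contribute zeros), so all averages are over the full N nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .errors import ConfigurationError, ParameterError
from .connectivity import ConnectivityMatrix
from .preprocess import BandSpec

__all__ = [
    "DEFAULT_THRESHOLDS",
    "BinaryNetwork",
    "EfficiencyResult",
    "binarize",
    "shortest_paths",
    "global_efficiency",
    "nodal_efficiency",
    "nodal_efficiencies",
    "regional_efficiency",
    "efficiency_sweep",
]

#: The threshold grid reported in the emulated analysis.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.64, 0.67, 0.70, 0.73, 0.76)


@dataclass
class BinaryNetwork:
    """Thresholded adjacency (0/1, symmetric, zero diagonal) over named nodes."""

    adjacency: np.ndarray
    node_ids: tuple[str, ...]
    threshold: float
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.node_ids):
            raise ParameterError("adjacency shape does not match node ids")
        self.adjacency = a.astype(np.int8)
        self.node_ids = tuple(self.node_ids)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class EfficiencyResult:
    """Global, per-node and per-region efficiency of one network."""

    e_global: float
    e_nodal: np.ndarray
    e_regional: dict[str, float]
    threshold: float
    band: BandSpec | None = None
    node_ids: tuple[str, ...] = ()


def binarize(conn: ConnectivityMatrix, threshold: float) -> BinaryNetwork:
    """Edge (i, j) present iff PLV_ij > T (strict) and i != j."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    adj = (conn.values > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)  # symmetry guard; PLV is already symmetric
    return BinaryNetwork(adjacency=adj, node_ids=conn.node_ids,
                         threshold=threshold, band=conn.band)


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """Hop-count distance matrix; np.inf for disconnected pairs."""
    d = _csgraph_shortest_path(csr_matrix(net.adjacency), method="D",
                               unweighted=True, directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def _inverse_distances(net: BinaryNetwork) -> np.ndarray:
    d = shortest_paths(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0  # 1/inf -> 0 and the 1/0 diagonal -> 0
    return inv


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse hop distance over ordered node pairs."""
    n = net.n_nodes
    if n < 2:
        raise ParameterError("global efficiency requires at least 2 nodes")
    inv = _inverse_distances(net)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiencies(net: BinaryNetwork) -> np.ndarray:
    """E_nodal(j) for every node j, in node order."""
    n = net.n_nodes
    if n < 2:
        raise ParameterError("nodal efficiency requires at least 2 nodes")
    inv = _inverse_distances(net)
    return inv.sum(axis=1) / (n - 1)


def nodal_efficiency(net: BinaryNetwork, node: str) -> float:
    if node not in net.node_ids:
        raise ParameterError(f"unknown node {node!r}")
    return float(nodal_efficiencies(net)[net.node_ids.index(node)])


def regional_efficiency(e_nodal: np.ndarray, node_ids: tuple[str, ...],
                        region_map: dict[str, str]) -> dict[str, float]:
    """Mean nodal efficiency per scalp region."""
    unmapped = [c for c in node_ids if c not in region_map]
    if unmapped:
        raise ConfigurationError(f"nodes missing from region map: {unmapped[:5]}")
    regions = sorted(set(region_map[c] for c in node_ids))
    e_nodal = np.asarray(e_nodal, dtype=np.float64)
    out = {}
    for region in regions:
        mask = np.array([region_map[c] == region for c in node_ids])
        out[region] = float(e_nodal[mask].mean())
    return out


def efficiency_sweep(conn: ConnectivityMatrix, thresholds=DEFAULT_THRESHOLDS,
                     region_map: dict[str, str] | None = None) -> list[EfficiencyResult]:
    """Efficiencies of one PLV matrix across a threshold grid.

    E_global is non-increasing in T for a fixed matrix because raising the
    threshold can only remove edges.
    """
    out = []
    for t in thresholds:
        net = binarize(conn, t)
        e_nodal = nodal_efficiencies(net)
        e_reg = (regional_efficiency(e_nodal, net.node_ids, region_map)
                 if region_map is not None else {})
        out.append(EfficiencyResult(
            e_global=float(e_nodal.mean()),
            e_nodal=e_nodal,
            e_regional=e_reg,
            threshold=t,
            band=conn.band,
            node_ids=net.node_ids,
        ))
    return out
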