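"""Graph construction and metrics on functional connectivity matrices.

A weighted connectivity matrix is reduced to a binary network by
proportional thresholding: the strongest PT% of all possible undirected
connections are kept and set to 1, the rest to 0, which equalises network
density across subjects before comparing topology.  On the binary network
two canonical metrics are computed: the clustering coefficient (mean
fraction of closed triangles around each node, a segregation measure) and
global efficiency (mean inverse shortest-path length over node pairs, an
integration measure; unreachable pairs contribute 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix


@dataclass
class BinaryNetwork:
    """Proportionally thresholded 0/1 adjacency with provenance."""

    adjacency: np.ndarray  # (n, n) symmetric 0/1, zero diagonal
    pt: float  # proportional threshold (%) that produced it
    labels: list[str]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if not (0 < self.pt <= 100):
            raise ValueError("pt must be in (0, 100]")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def overall_fc(C: ConnectivityMatrix) -> float:
    """Mean of the n(n-1)/2 off-diagonal connectivity values."""
    n = C.n_channels
    if n < 2:
        raise ValueError("overall FC needs at least 2 channels")
    iu = np.triu_indices(n, k=1)
    return float(C.values[iu].mean())


def weighted_degree(C: ConnectivityMatrix) -> np.ndarray:
    """Node strength: sum of incident edge weights per channel."""
    return C.values.sum(axis=1)


def edge_count(n_channels: int, pt: float) -> int:
    """Number of links retained at proportional threshold ``pt`` (%)."""
    n_pairs = n_channels * (n_channels - 1) // 2
    return int(np.floor(pt / 100.0 * n_pairs + 0.5))  # round half away from zero


def proportional_threshold(C: ConnectivityMatrix, pt: float) -> BinaryNetwork:
    """Keep the strongest ``pt`` % of possible connections, binarised.

    Ties at the cutoff are broken deterministically by (row, column)
    lexicographic order of the upper-triangle entries.
    """
    if not (0 < pt <= 100):
        raise ValueError("pt must be in (0, 100]")
    n = C.n_channels
    rows, cols = np.triu_indices(n, k=1)
    w = C.values[rows, cols]
    if not np.all(np.isfinite(w)):
        raise ValueError("connection weights must be finite")
    k = edge_count(n, pt)
    if k == 0:
        raise ValueError(f"pt = {pt}% keeps no links on {n} channels (empty network)")
    order = np.lexsort((cols, rows, -w))  # strongest first, then lexicographic
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[rows[keep], cols[keep]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, pt=pt, labels=list(C.labels))


def clustering_coefficient(B: BinaryNetwork) -> float:
    """Mean over nodes of 2*t_i / (k_i (k_i - 1)); degree-<2 nodes score 0."""
    a = B.adjacency.astype(float)
    deg = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1)
    cc = np.divide(2.0 * triangles, denom, out=np.zeros_like(denom), where=denom > 0)
    return float(cc.mean())


def global_efficiency(B: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Paths are unweighted (hop counts); unreachable pairs contribute 0.
    """
    n = B.n_nodes
    if n < 2:
        return 0.0
    d = shortest_path(csr_matrix(B.adjacency), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))
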