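"""ISOMAP (geodesic classical MDS) and its multi-view variants.

A K-nearest-neighbour graph carries Euclidean edge lengths; geodesic
distances are all-pairs shortest paths through that graph; classical MDS of
the double-centred squared geodesic matrix tau(D) = -HSH/2 yields the
embedding. Multi-ISOMAP combines the per-view graphs into one (edge present
if present in any view, length the weighted average of the finite per-view
lengths) before steps 2-3; m-ISOMAP averages per-view ISOMAP embeddings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist

from .data import Embedding, MultiViewDataset
from .lle import _fix_signs, _knn_indices
from .multisne import ViewWeights

logger = logging.getLogger(__name__)


class DisconnectedGraphError(ValueError):
    """The neighbourhood graph splits into several components."""


@dataclass
class NeighborGraph:
    """Symmetric K-NN graph with Euclidean edge lengths; non-edges are inf."""

    edge_lengths: np.ndarray
    K: int

    @property
    def n_vertices(self) -> int:
        return self.edge_lengths.shape[0]


@dataclass
class GeodesicMatrix:
    """All-pairs shortest-path distances; inf only across components."""

    D_G: np.ndarray
    component_count: int

    @property
    def N(self) -> int:
        return self.D_G.shape[0]


def build_knn_graph(X: np.ndarray, K: int) -> NeighborGraph:
    """Step 1: symmetrised K-NN graph (edge if either endpoint lists the other)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n - 1:
        logger.info("K=%d exceeds N-1=%d; capping", K, n - 1)
        K = n - 1
    D = cdist(X, X)
    nbrs = _knn_indices(X, K)
    mask = np.zeros((n, n), dtype=bool)
    mask[np.repeat(np.arange(n), K), nbrs.ravel()] = True
    mask |= mask.T
    lengths = np.where(mask, D, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return NeighborGraph(edge_lengths=lengths, K=K)


def _masked_csr(lengths: np.ndarray) -> sparse.csr_matrix:
    mask = np.isfinite(lengths) & ~np.eye(lengths.shape[0], dtype=bool)
    rows, cols = np.nonzero(mask)
    return sparse.csr_matrix(
        (lengths[rows, cols], (rows, cols)), shape=lengths.shape
    )


def geodesic_distances(g: NeighborGraph) -> GeodesicMatrix:
    """Step 2: exact all-pairs shortest paths (Dijkstra from every source)."""
    adj = _masked_csr(g.edge_lengths)
    D_G = shortest_path(adj, method="D", directed=False)
    ncomp, _ = connected_components(adj, directed=False)
    return GeodesicMatrix(D_G=D_G, component_count=ncomp)


def classical_mds_embed(D: GeodesicMatrix | np.ndarray, d: int = 2) -> Embedding:
    """Step 3: classical MDS of a distance matrix via the tau operator.

    Eigen-decomposes tau(D) = -HSH/2 (S the squared distances, H the
    centring matrix) and maps the top-``d`` positive eigenpairs to
    coordinates sqrt(lambda_p) u_p. Columns are mean-centred by the double
    centring; signs fixed deterministically.
    """
    Dm = D.D_G if isinstance(D, GeodesicMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if not np.all(np.isfinite(Dm)):
        raise DisconnectedGraphError(
            "distance matrix contains infinities (disconnected graph); "
            "increase K or embed the largest component only"
        )
    if d > n - 1:
        raise ValueError("d must be at most N-1")
    S = Dm**2
    H = np.eye(n) - 1.0 / n
    B = -H @ S @ H / 2.0
    evals, evecs = linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = np.max(np.abs(evals)) if evals.size else 0.0
    pos = evals > scale * 1e-12
    n_pos = int(np.sum(pos[:d]))
    if n_pos < d:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding with zero columns",
            RuntimeWarning,
        )
    coords = np.zeros((n, d))
    coords[:, :n_pos] = evecs[:, :n_pos] * np.sqrt(evals[:n_pos])
    coords[:, :n_pos] = _fix_signs(coords[:, :n_pos])
    return Embedding(coords=coords, method_tag="classical-mds")


def single_view_isomap(
    X: np.ndarray, K: int, d: int = 2, largest_component: bool = False
) -> Embedding:
    """ISOMAP of one view (steps 1-3)."""
    geo = geodesic_distances(build_knn_graph(X, K))
    return _embed_geodesics(geo, d, largest_component, "isomap")


def _embed_geodesics(
    geo: GeodesicMatrix, d: int, largest_component: bool, tag: str
) -> Embedding:
    if geo.component_count > 1:
        if not largest_component:
            raise DisconnectedGraphError(
                f"graph has {geo.component_count} components; increase K or "
                "pass largest_component=True to embed the largest one"
            )
        finite_counts = np.isfinite(geo.D_G).sum(axis=1)
        keep = np.flatnonzero(finite_counts == finite_counts.max())
        e = classical_mds_embed(geo.D_G[np.ix_(keep, keep)], d)
        e.method_tag = tag
        e.sample_index = keep
        return e
    e = classical_mds_embed(geo, d)
    e.method_tag = tag
    return e


def multi_isomap_embed(
    data: MultiViewDataset,
    K: int,
    w: ViewWeights | None = None,
    d: int = 2,
    largest_component: bool = False,
) -> Embedding:
    """Multi-ISOMAP: ISOMAP steps 2-3 on the combined neighbourhood graph.

    The combined graph has an edge wherever at least one view has one, with
    length the w-weighted average of the per-view lengths over the views in
    which the edge exists.
    """
    w = w or ViewWeights.uniform(data.M)
    if len(w.values) != data.M:
        raise ValueError("weight vector length must equal the number of views")
    graphs = [build_knn_graph(v, K) for v in data.views]
    n = data.N
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for wm, g in zip(w.values, graphs):
        finite = np.isfinite(g.edge_lengths)
        num += wm * np.where(finite, g.edge_lengths, 0.0)
        den += wm * finite
    lengths = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    combined = NeighborGraph(edge_lengths=lengths, K=min(K, n - 1))
    geo = geodesic_distances(combined)
    return _embed_geodesics(geo, d, largest_component, "multi-ISOMAP")


def m_isomap_embed(
    data: MultiViewDataset,
    K: int,
    beta: ViewWeights | None = None,
    d: int = 2,
    largest_component: bool = False,
) -> Embedding:
    """m-ISOMAP baseline: weighted average of sign-fixed per-view embeddings."""
    beta = beta or ViewWeights.uniform(data.M)
    if len(beta.values) != data.M:
        raise ValueError("weight vector length must equal the number of views")
    Y = sum(
        b * single_view_isomap(v, K, d, largest_component).coords
        for b, v in zip(beta.values, data.views)
    )
    return Embedding(coords=Y, method_tag="m-ISOMAP")
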