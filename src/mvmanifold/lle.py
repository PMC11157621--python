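"""Locally linear embedding and its multi-view variants.

LLE reconstructs each point from its K Euclidean nearest neighbours with
weights that sum to one, then finds low-dimensional coordinates preserving
those reconstruction weights via the bottom non-constant eigenvectors of
(I - W)^T (I - W). Multi-LLE forms a consensus weight matrix as a convex
combination of the per-view weight matrices before the eigen-embedding;
m-LLE instead averages the per-view LLE embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse
from scipy.spatial.distance import cdist

from .data import Embedding, MultiViewDataset
from .multisne import ViewWeights


@dataclass
class ReconstructionWeights:
    """Row-stochastic sparse reconstruction-weight matrix with its K-NN sets."""

    W: sparse.csr_matrix
    neighbour_sets: np.ndarray  # (N, K) neighbour indices, ties broken by index
    K: int

    @property
    def N(self) -> int:
        return self.W.shape[0]


def _knn_indices(X: np.ndarray, K: int) -> np.ndarray:
    """K nearest neighbours per row, self excluded, ties broken by index."""
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    idx = np.argsort(D, axis=1, kind="stable")[:, :K]
    return idx


#: relative Gram-matrix ridge; the conventional LLE conditioning constant
_REG = 1e-3


def reconstruction_weights(X: np.ndarray, K: int, reg: float = _REG) -> ReconstructionWeights:
    """Solve the constrained local least-squares problem of LLE step 2.

    Per point, the weights over its K nearest neighbours minimise the
    reconstruction error subject to summing to one, via the local Gram
    system. A ridge ``reg * trace(G)`` conditions every solve, the
    convention of the reference LLE implementations: besides handling
    singular Gram matrices (K above the feature count), it suppresses the
    near-exact local reconstructions whose localised null modes would
    otherwise dominate the bottom of the embedding spectrum as spikes.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must lie in [1, N-1={n - 1}], got {K}")
    nbrs = _knn_indices(X, K)
    rows = np.repeat(np.arange(n), K)
    vals = np.empty(n * K)
    ones = np.ones(K)
    for i in range(n):
        Z = X[nbrs[i]] - X[i]
        G = Z @ Z.T
        tr = np.trace(G)
        G = G + reg * (tr if tr > 0 else 1.0) * np.eye(K)
        w = linalg.solve(G, ones, assume_a="sym")
        vals[i * K:(i + 1) * K] = w / w.sum()
    W = sparse.csr_matrix((vals, (rows, nbrs.ravel())), shape=(n, n))
    return ReconstructionWeights(W=W, neighbour_sets=nbrs, K=K)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Resolve eigenvector sign ambiguity: largest-|entry| component positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def lle_embed(W: ReconstructionWeights | sparse.spmatrix, d: int = 2) -> Embedding:
    """Eigen-embedding of LLE step 3.

    Takes the ``d`` bottom eigenvectors of M = (I - W)^T (I - W) after
    discarding the constant eigenvector (eigenvalue ~ 0); columns are
    mean-centred by construction and signs fixed deterministically.
    """
    Wm = W.W if isinstance(W, ReconstructionWeights) else W
    n = Wm.shape[0]
    if d > n - 1:
        raise ValueError("d must be at most N-1")
    IW = np.eye(n) - Wm.toarray()
    Mmat = IW.T @ IW
    evals, evecs = linalg.eigh(Mmat)
    coords = _fix_signs(evecs[:, 1:d + 1])
    return Embedding(coords=coords, method_tag="lle")


def single_view_lle(X: np.ndarray, K: int, d: int = 2) -> Embedding:
    """LLE of one view: reconstruction weights then eigen-embedding."""
    return lle_embed(reconstruction_weights(X, K), d)


def multi_lle_embed(
    data: MultiViewDataset,
    K: int,
    alpha: ViewWeights | None = None,
    d: int = 2,
) -> Embedding:
    """Multi-LLE: eigen-embedding of the consensus weight matrix.

    Per-view weight matrices (each with its own neighbour sets) are combined
    as a convex combination, which keeps the rows stochastic.
    """
    alpha = alpha or ViewWeights.uniform(data.M)
    if len(alpha.values) != data.M:
        raise ValueError("weight vector length must equal the number of views")
    Wc = sum(
        a * reconstruction_weights(v, K).W
        for a, v in zip(alpha.values, data.views)
    )
    e = lle_embed(Wc, d)
    e.method_tag = "multi-LLE"
    return e


def m_lle_embed(
    data: MultiViewDataset,
    K: int,
    beta: ViewWeights | None = None,
    d: int = 2,
) -> Embedding:
    """m-LLE baseline: weighted average of sign-fixed per-view LLE embeddings."""
    beta = beta or ViewWeights.uniform(data.M)
    if len(beta.values) != data.M:
        raise ValueError("weight vector length must equal the number of views")
    Y = sum(
        b * single_view_lle(v, K, d).coords
        for b, v in zip(beta.values, data.views)
    )
    return Embedding(coords=Y, method_tag="m-LLE")
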