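"""Dimensionality pre-reduction applied before SNE-family optimisation.

PCA keeps the smallest number of principal components whose cumulative
explained-variance ratio reaches a threshold (default 80%). Multi-CCA
replaces the per-view PCA with a joint linear reduction: per-view projection
directions chosen to maximise the sum of pairwise correlations between the
projected views (the SUMCOR-style multiset CCA), which for two views reduces
to classical CCA. Views are centred but not scaled in either mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data import MultiViewDataset

_RIDGE = 1e-6  # relative ridge on within-view covariances before whitening


@dataclass
class PretrainResult:
    """Reduced views plus diagnostics of the reduction applied."""

    reduced_views: list[np.ndarray]
    components_kept: list[int]
    # per-view cumulative explained-variance fraction (PCA) or per-component
    # normalised sum-correlation scores shared by all views (multi-CCA)
    variance_explained: list[float] | np.ndarray
    mode: str


def pca_reduce(X: np.ndarray, var_threshold: float = 0.80) -> tuple[np.ndarray, dict]:
    """Project onto the fewest principal components explaining ``var_threshold``.

    Exact SVD of the centred data; returns the scores and a diagnostics dict
    with keys ``n_components``, ``variance_explained`` (fraction actually
    retained) and ``explained_variance_ratio`` (per component).
    """
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total == 0:
        raise ValueError("matrix has no variance; PCA is undefined")
    ratio = ev / total
    nonzero = int(np.sum(ev > ev[0] * 1e-12))
    cum = np.cumsum(ratio)
    q = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    q = min(q, nonzero)
    scores = U[:, :q] * s[:q]
    return scores, {
        "n_components": q,
        "variance_explained": float(cum[q - 1]),
        "explained_variance_ratio": ratio[:q],
    }


def _whitener(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of a ridge-regularised covariance."""
    C = C + _RIDGE * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
    evals, evecs = linalg.eigh(C)
    evals = np.maximum(evals, np.max(evals) * 1e-12)
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def multi_cca_reduce(
    data: MultiViewDataset, n_components: int | None = None
) -> PretrainResult:
    """Joint reduction maximising the summed pairwise view correlations.

    Each view is centred and whitened; the top eigenvectors of the whitened
    cross-correlation block matrix give per-view canonical directions whose
    scores are maximally correlated across views. The reported score per
    component is the Rayleigh objective rescaled to [0, 1] (for two views it
    equals the classical canonical correlation).
    """
    if data.M < 2:
        raise ValueError("multi-CCA needs at least two views; use pca_reduce")
    cap = min(min(data.N - 1, p) for p in data.p)
    if n_components is None:
        n_components = cap
    if not 1 <= n_components <= cap:
        raise ValueError(f"n_components must lie in [1, {cap}]")
    Xc = [v - v.mean(axis=0) for v in data.views]
    n = data.N
    Ws = [_whitener(x.T @ x / (n - 1)) for x in Xc]
    Z = [x @ w for x, w in zip(Xc, Ws)]  # whitened views
    p = [z.shape[1] for z in Z]
    offsets = np.concatenate([[0], np.cumsum(p)])
    total = offsets[-1]
    R = np.eye(total)
    for a in range(data.M):
        for b in range(a + 1, data.M):
            C = Z[a].T @ Z[b] / (n - 1)
            R[offsets[a]:offsets[a + 1], offsets[b]:offsets[b + 1]] = C
            R[offsets[b]:offsets[b + 1], offsets[a]:offsets[a + 1]] = C.T
    evals, evecs = linalg.eigh(R)
    order = np.argsort(evals)[::-1][:n_components]
    # Rayleigh value = 1 + (summed pairwise correlation term); rescale so a
    # perfectly correlated component scores 1 regardless of M
    scores = np.clip((evals[order] - 1.0) / (data.M - 1), -1.0, 1.0)
    reduced = []
    for m in range(data.M):
        block = evecs[offsets[m]:offsets[m + 1], order]
        norms = np.linalg.norm(block, axis=0)
        norms[norms == 0] = 1.0
        reduced.append(Z[m] @ (block / norms))
    return PretrainResult(
        reduced_views=reduced,
        components_kept=[n_components] * data.M,
        variance_explained=scores,
        mode="multi_cca",
    )


def pretrain_views(
    data: MultiViewDataset, mode: str = "pca", var_threshold: float = 0.80
) -> PretrainResult:
    """Apply the requested pre-reduction to every view of a dataset."""
    if mode == "none":
        return PretrainResult(
            reduced_views=list(data.views),
            components_kept=list(data.p),
            variance_explained=[1.0] * data.M,
            mode="none",
        )
    if mode == "pca":
        reduced, kept, var = [], [], []
        for v in data.views:
            scores, info = pca_reduce(v, var_threshold)
            reduced.append(scores)
            kept.append(info["n_components"])
            var.append(info["variance_explained"])
        return PretrainResult(reduced, kept, var, "pca")
    if mode == "multi_cca":
        if data.M == 1:
            raise ValueError("multi-CCA pre-training needs at least two views")
        return multi_cca_reduce(data)
    raise ValueError(f"unknown pre-training mode {mode!r}")
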