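"""Multi-SNE: joint t-SNE embedding of several data-views.

One shared low-dimensional Student-t distribution Q is optimised against the
per-view high-dimensional affinities by minimising the weighted sum of KL
divergences sum_m w^m KL(P^(m) || Q); the gradient is the w^m-weighted sum of
the per-view t-SNE gradients. The weight vector lives on the simplex and can
optionally be adapted during the run from the per-view KL values (views that
the embedding fits poorly are down-weighted, so pure-noise views are
effectively discarded without hard selection).

The m-SNE baseline instead combines the per-view affinities into one joint
matrix p_ij = sum_m beta^m p^m_ij and runs standard t-SNE on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Embedding, MultiViewDataset
from .pretrain import pretrain_views
from .tsne import (
    AffinityMatrix,
    OptimiserConfig,
    _descend,
    high_dim_affinities,
)


@dataclass
class ViewWeights:
    """Simplex-constrained per-view weights, optionally KL-adaptive."""

    values: np.ndarray
    kl_per_view: np.ndarray | None = None
    adaptive: bool = False
    freeze_iterations: int = 100

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("weights must be non-negative")
        total = self.values.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        if not np.isclose(total, 1.0, atol=1e-8):
            warnings.warn("weights did not sum to 1; renormalising", RuntimeWarning)
            self.values = self.values / total
        if self.kl_per_view is not None:
            self.kl_per_view = np.asarray(self.kl_per_view, dtype=float)
            if np.any(self.kl_per_view < 0):
                raise ValueError("KL values must be non-negative")

    @classmethod
    def uniform(cls, M: int, **kwargs) -> "ViewWeights":
        return cls(values=np.full(M, 1.0 / M), **kwargs)


def update_view_weights(k: np.ndarray) -> ViewWeights:
    """KL-driven weight update: the best-fitting view gets the largest weight.

    Step 1 normalises the per-view KL vector to sum 1; step 2 sets each weight
    to one minus its normalised KL; step 3 renormalises back to the simplex
    (a no-op for two views, where 1 - k already sums to 1).
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("KL values must be non-negative")
    M = len(k)
    total = k.sum()
    if total == 0 or M == 1:
        return ViewWeights(values=np.full(M, 1.0 / M), kl_per_view=k)
    k_norm = k / total
    raw = 1.0 - k_norm
    return ViewWeights(values=raw / raw.sum(), kl_per_view=k)


def _view_affinities(
    data: MultiViewDataset,
    perplexity: float,
    pretrain: str,
    var_threshold: float = 0.80,
) -> np.ndarray:
    views = pretrain_views(data, mode=pretrain, var_threshold=var_threshold).reduced_views
    return np.stack([high_dim_affinities(v, perplexity).probs for v in views])


def multi_sne_embed(
    data: MultiViewDataset,
    perplexity: float,
    weights: ViewWeights | None = None,
    cfg: OptimiserConfig | None = None,
    pretrain: str = "pca",
    d: int = 2,
) -> tuple[Embedding, ViewWeights, np.ndarray]:
    """Embed a multi-view dataset with multi-SNE.

    Returns the embedding, the final view weights (with the final per-view KL
    vector attached) and the per-iteration per-view KL trace, an array of
    shape ``(iterations, M)``.
    """
    cfg = cfg or OptimiserConfig()
    weights = weights or ViewWeights.uniform(data.M)
    if len(weights.values) != data.M:
        raise ValueError("weight vector length must equal the number of views")
    Ps = _view_affinities(data, perplexity, pretrain)
    Y, w, kl_trace, _, its = _descend(
        Ps,
        weights.values,
        d,
        cfg,
        adaptive=weights.adaptive,
        freeze_iterations=weights.freeze_iterations,
    )
    final = ViewWeights(
        values=w,
        kl_per_view=kl_trace[-1],
        adaptive=weights.adaptive,
        freeze_iterations=weights.freeze_iterations,
    )
    tag = "multi-SNE (adaptive weights)" if weights.adaptive else "multi-SNE"
    return Embedding(coords=Y, method_tag=tag, iterations_run=its), final, kl_trace


def msne_embed(
    data: MultiViewDataset,
    perplexity: float,
    beta: ViewWeights | None = None,
    cfg: OptimiserConfig | None = None,
    pretrain: str = "pca",
    d: int = 2,
) -> Embedding:
    """m-SNE baseline: t-SNE on the beta-combined joint affinity matrix."""
    cfg = cfg or OptimiserConfig()
    beta = beta or ViewWeights.uniform(data.M)
    if len(beta.values) != data.M:
        raise ValueError("weight vector length must equal the number of views")
    Ps = _view_affinities(data, perplexity, pretrain)
    combined = np.tensordot(beta.values, Ps, axes=1)
    # a convex combination of affinity matrices is itself a valid one
    AffinityMatrix(probs=combined, kind="high_dim")
    Y, _, _, _, its = _descend(combined[None, :, :], np.array([1.0]), d, cfg)
    return Embedding(coords=Y, method_tag="m-SNE", iterations_run=its)


def perplexity_criterion(kl_per_view: np.ndarray, n: int, perp: float) -> float:
    """Perplexity-selection score 2 sum_m KL(P^(m)||Q) + log(n) Perp / n.

    Natural logarithm; lower is better. With one view this is the single-view
    criterion S(Perp) = 2 KL + log(n) Perp / n.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if perp <= 0:
        raise ValueError("perplexity must be positive")
    kl = np.asarray(kl_per_view, dtype=float)
    return float(2.0 * kl.sum() + np.log(n) * perp / n)


def select_perplexity(
    data: MultiViewDataset,
    grid: tuple[float, ...] = (2, 10, 20, 50, 80, 100, 200),
    weights: ViewWeights | None = None,
    cfg: OptimiserConfig | None = None,
    pretrain: str = "pca",
) -> tuple[float, dict[float, float]]:
    """Evaluate the perplexity criterion over a grid; return its arg-min."""
    admissible = [p for p in grid if 1 < p < data.N]
    if not admissible:
        raise ValueError("no admissible perplexity values in the grid")
    scores: dict[float, float] = {}
    for perp in admissible:
        _, final_w, _ = multi_sne_embed(data, perp, weights=weights, cfg=cfg, pretrain=pretrain)
        scores[perp] = perplexity_criterion(final_w.kl_per_view, data.N, perp)
    best = min(scores, key=scores.get)
    return best, scores
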