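"""Single-view t-SNE machinery shared by all SNE-based methods.

High-dimensional affinities use per-point Gaussian kernels whose bandwidths
sigma_i are calibrated by binary search so that the smooth effective neighbour
count 2^H(P_i) matches a user-chosen perplexity; the conditional distributions
are then symmetrised to a joint matrix p_ij = (p_{j|i} + p_{i|j}) / (2N).
Low-dimensional affinities use the Student-t kernel (1 + ||y_i - y_j||^2)^-1
normalised over all ordered pairs. The embedding minimises KL(P || Q) by
gradient descent with momentum, optionally with early exaggeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import Embedding

_LOG2 = np.log(2.0)
_QFLOOR = 1e-12  # floor on q_ij inside logs only; gradients use exact Q


@dataclass
class AffinityMatrix:
    """Joint probability matrix over ordered sample pairs.

    ``probs`` sums to 1 over all ordered pairs (i, j), i != j, with a zero
    diagonal. ``sigmas`` holds the per-point Gaussian bandwidths for
    high-dimensional matrices.
    """

    probs: np.ndarray
    sigmas: np.ndarray | None = None
    perplexity: float | None = None
    kind: str = "high_dim"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n = self.probs.shape[0]
        if self.probs.shape != (n, n):
            raise ValueError("probs must be square")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if np.any(np.diag(self.probs) != 0):
            raise ValueError("diagonal must be zero")
        if self.sigmas is not None and np.any(np.asarray(self.sigmas) <= 0):
            raise ValueError("bandwidths must be positive")

    @property
    def N(self) -> int:
        return self.probs.shape[0]


@dataclass
class OptimiserConfig:
    """Gradient-descent settings for SNE-family optimisation.

    Defaults follow the standard t-SNE recipe: momentum 0.5 switching to 0.8
    at iteration 250, early exaggeration x4 for the first 100 iterations,
    learning rate 100 with per-parameter adaptive gains, 1000 iterations,
    Gaussian initialisation at scale 1e-4. ``stop_tol``, when set, stops
    early once the relative change of the cost falls below it (checked
    outside the exaggeration window).
    """

    iterations: int = 1000
    learning_rate: float = 100.0
    momentum_schedule: tuple[float, float, int] = (0.5, 0.8, 250)
    early_exaggeration: tuple[float, int] = (4.0, 100)
    seed: int = 0
    init_scale: float = 1e-4
    use_gains: bool = True
    stop_tol: float | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.early_exaggeration[0] < 1:
            raise ValueError("exaggeration factor must be >= 1")
        if self.momentum_schedule[2] > self.iterations:
            # clamp rather than fail: schedules are expressed for the default
            # 1000-iteration budget
            self.momentum_schedule = (
                self.momentum_schedule[0],
                self.momentum_schedule[1],
                self.iterations,
            )


def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    D = squareform(pdist(X, "sqeuclidean"))
    return D


def high_dim_affinities(
    X: np.ndarray, perplexity: float, tol: float = 1e-5
) -> AffinityMatrix:
    """Perplexity-calibrated, symmetrised joint affinities of one view.

    For each row a precision beta_i = 1/(2 sigma_i^2) is found by binary
    search (at most 50 bisections) so that the Shannon entropy of the
    conditional distribution matches log2(perplexity) within ``tol``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if not 1.0 < perplexity < n:
        raise ValueError(f"perplexity must lie in (1, N={n}), got {perplexity}")
    D = _pairwise_sq_dists(X)
    np.fill_diagonal(D, np.inf)  # excludes self from every conditional
    Dfin = D.copy()
    np.fill_diagonal(Dfin, 0.0)

    target = np.log2(perplexity)
    beta = np.ones(n)
    beta_lo = np.full(n, np.nan)
    beta_hi = np.full(n, np.nan)
    H = np.zeros(n)
    for _ in range(50):
        P = np.exp(-D * beta[:, None])
        sumP = np.maximum(P.sum(axis=1), 1e-300)
        # entropy in bits of the normalised conditional distribution
        H = (np.log(sumP) + beta * np.einsum("ij,ij->i", Dfin, P) / sumP) / _LOG2
        diff = H - target
        if np.all(np.abs(diff) < tol):
            break
        too_flat = diff > tol  # entropy too high -> raise beta
        too_sharp = diff < -tol
        beta_lo[too_flat] = beta[too_flat]
        beta_hi[too_sharp] = beta[too_sharp]
        up = too_flat & np.isnan(beta_hi)
        down = too_sharp & np.isnan(beta_lo)
        mid = too_flat | too_sharp
        beta[up] *= 2.0
        beta[down] /= 2.0
        both = mid & ~up & ~down
        beta[both] = (beta_lo[both] + beta_hi[both]) / 2.0
    else:
        worst = float(np.max(np.abs(H - target)))
        warnings.warn(
            f"perplexity calibration did not converge for every point "
            f"(worst |H - target| = {worst:.2e} bits); keeping best bandwidths",
            RuntimeWarning,
        )
    P = np.exp(-D * beta[:, None])
    P /= np.maximum(P.sum(axis=1, keepdims=True), 1e-300)
    joint = (P + P.T) / (2.0 * n)
    np.fill_diagonal(joint, 0.0)
    return AffinityMatrix(
        probs=joint,
        sigmas=np.sqrt(1.0 / (2.0 * beta)),
        perplexity=perplexity,
        kind="high_dim",
    )


def low_dim_affinities(Y: Embedding | np.ndarray) -> AffinityMatrix:
    """Student-t joint affinities of an embedding."""
    coords = Y.coords if isinstance(Y, Embedding) else np.asarray(Y, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least two samples")
    num = 1.0 / (1.0 + _pairwise_sq_dists(coords))
    np.fill_diagonal(num, 0.0)
    return AffinityMatrix(probs=num / num.sum(), kind="low_dim")


def kl_divergence(P: AffinityMatrix | np.ndarray, Q: AffinityMatrix | np.ndarray) -> float:
    """KL(P || Q) in nats over ordered pairs, with 0 log 0 := 0."""
    p = P.probs if isinstance(P, AffinityMatrix) else np.asarray(P, dtype=float)
    q = Q.probs if isinstance(Q, AffinityMatrix) else np.asarray(Q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("shape mismatch between P and Q")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], _QFLOOR))))


def _plogp(p: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask])))


def _descend(
    Ps: np.ndarray,
    weights: np.ndarray,
    d: int,
    cfg: OptimiserConfig,
    adaptive: bool = False,
    freeze_iterations: int = 100,
):
    """Shared KL gradient-descent loop over one or more affinity matrices.

    Minimises sum_m w_m KL(P^(m) || Q) for one shared Student-t Q. Returns
    the final coordinates, final weights, per-iteration per-view KL trace,
    per-iteration weight trace and the number of iterations run.
    """
    from .multisne import update_view_weights  # local import avoids a cycle

    M, n, _ = Ps.shape
    w = np.asarray(weights, dtype=float).copy()
    rng = np.random.default_rng(cfg.seed)
    Y = rng.normal(0.0, cfg.init_scale, size=(n, d))
    V = np.zeros_like(Y)
    plogp = np.array([_plogp(Ps[m]) for m in range(M)])
    exag, exag_iters = cfg.early_exaggeration
    mom0, mom1, switch = cfg.momentum_schedule

    Pbar = np.tensordot(w, Ps, axes=1)
    gains = np.ones_like(Y)
    kl_trace: list[np.ndarray] = []
    w_trace: list[np.ndarray] = []
    prev_cost = None
    it = 0
    for it in range(cfg.iterations):
        D2 = _pairwise_sq_dists(Y)
        num = 1.0 / (1.0 + D2)
        np.fill_diagonal(num, 0.0)
        Z = num.sum()
        Q = num / Z
        Peff = Pbar * exag if it < exag_iters else Pbar
        PQ = (Peff - Q) * num
        grad = 4.0 * (np.diag(PQ.sum(axis=1)) @ Y - PQ @ Y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                "non-finite gradient encountered; the learning rate is "
                "probably too high for this data"
            )
        mom = mom0 if it < switch else mom1
        if cfg.use_gains:
            # per-parameter adaptive gains of the original recipe
            same_sign = np.sign(grad) == np.sign(V)
            gains = np.where(same_sign, gains * 0.8, gains + 0.2)
            np.clip(gains, 0.01, None, out=gains)
            step = gains * grad
        else:
            step = grad
        V = mom * V - cfg.learning_rate * step
        Y = Y + V

        # un-exaggerated per-view costs, also drive the adaptive weights
        logQ = np.log(np.maximum(Q, _QFLOOR))
        kls = plogp - np.einsum("mij,ij->m", Ps, logQ)
        kl_trace.append(kls)
        w_trace.append(w.copy())
        if adaptive and it + 1 >= freeze_iterations:
            w = update_view_weights(kls).values
            Pbar = np.tensordot(w, Ps, axes=1)
        cost = float(w @ kls)
        if (
            cfg.stop_tol is not None
            and it >= exag_iters
            and prev_cost is not None
            and abs(prev_cost - cost) <= cfg.stop_tol * max(abs(prev_cost), 1e-30)
        ):
            break
        prev_cost = cost
    return Y, w, np.asarray(kl_trace), np.asarray(w_trace), it + 1


def tsne_embed(
    X: np.ndarray, perplexity: float, cfg: OptimiserConfig | None = None
) -> Embedding:
    """Standard t-SNE of a single view to ``d = 2`` dimensions.

    Deterministic given ``cfg.seed``; runs exactly ``cfg.iterations`` steps
    unless ``cfg.stop_tol`` is set.
    """
    cfg = cfg or OptimiserConfig()
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("t-SNE needs at least four samples")
    P = high_dim_affinities(X, perplexity)
    Y, _, _, _, its = _descend(P.probs[None, :, :], np.array([1.0]), 2, cfg)
    return Embedding(coords=Y, method_tag="tsne", iterations_run=its)
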