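"""Clustering-based quantification of embeddings.

An embedding is scored by running K-means (with the known cluster count) on
its coordinates and comparing the resulting partition with the ground truth
through four extrinsic measures - clustering accuracy (optimal one-to-one
matching), NMI (geometric-mean normalisation), Rand index and adjusted Rand
index - plus the misclustering error 1 - ACC and the silhouette score, which
needs no ground truth. A grid-based tuning protocol runs a method over a
set of candidate parameter values and picks the best-scoring one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skm
from sklearn.cluster import KMeans

from .data import ClusterLabels, Embedding, MultiViewDataset


@dataclass
class EvalReport:
    """Mean (sd) of each measure over replicate runs at one parameter value."""

    parameter_value: float | int | None = None
    replicates: int = 0
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "parameter_value": self.parameter_value,
            "replicates": self.replicates,
            "mean": self.mean,
            "sd": self.sd,
        }


def _as_int_labels(labels) -> np.ndarray:
    arr = np.asarray(labels.assignments if isinstance(labels, ClusterLabels) else labels)
    _, enc = np.unique(arr, return_inverse=True)
    return enc


def kmeans_labels(
    e: Embedding | np.ndarray, k: int, restarts: int = 10, seed: int = 0
) -> ClusterLabels:
    """Best-of-restarts K-means on embedding coordinates."""
    coords = e.coords if isinstance(e, Embedding) else np.asarray(e, dtype=float)
    if k > coords.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return ClusterLabels(assignments=km.fit_predict(coords), k=k)


def cluster_accuracy(truth, pred) -> float:
    """Agreement fraction under the optimal one-to-one cluster matching."""
    t = _as_int_labels(truth)
    p = _as_int_labels(pred)
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    cont = np.zeros((t.max() + 1, p.max() + 1))
    np.add.at(cont, (t, p), 1)
    rows, cols = linear_sum_assignment(cont, maximize=True)
    return float(cont[rows, cols].sum() / len(t))


def misclustering_error(truth, pred) -> float:
    return 1.0 - cluster_accuracy(truth, pred)


def nmi(truth, pred) -> float:
    """Normalised mutual information, I(U;V)/sqrt(H(U) H(V)); 0 if degenerate."""
    t, p = _as_int_labels(truth), _as_int_labels(pred)
    if len(np.unique(t)) < 2 or len(np.unique(p)) < 2:
        return 0.0
    return float(skm.normalized_mutual_info_score(t, p, average_method="geometric"))


def rand_index(truth, pred) -> float:
    """Fraction of sample pairs on which the two partitions agree."""
    return float(skm.rand_score(_as_int_labels(truth), _as_int_labels(pred)))


def adjusted_rand_index(truth, pred) -> float:
    """Chance-corrected Rand index via the contingency-table closed form."""
    return float(skm.adjusted_rand_score(_as_int_labels(truth), _as_int_labels(pred)))


def silhouette(e: Embedding | np.ndarray, labels) -> float:
    """Mean silhouette (b - a)/max(a, b) with Euclidean distances."""
    coords = e.coords if isinstance(e, Embedding) else np.asarray(e, dtype=float)
    lab = _as_int_labels(labels)
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette needs at least two non-empty clusters")
    return float(skm.silhouette_score(coords, lab))


_MEASURES = ("acc", "nmi", "ri", "ari", "misclustering_error", "silhouette")


def evaluate_embedding(
    e: Embedding, truth, k: int, restarts: int = 10, seed: int = 0
) -> dict[str, float]:
    """K-means on the embedding, then every measure against the truth."""
    pred = kmeans_labels(e, k, restarts=restarts, seed=seed)
    acc = cluster_accuracy(truth, pred)
    return {
        "acc": acc,
        "nmi": nmi(truth, pred),
        "ri": rand_index(truth, pred),
        "ari": adjusted_rand_index(truth, pred),
        "misclustering_error": 1.0 - acc,
        "silhouette": silhouette(e, pred.assignments),
    }


DEFAULT_GRID = (2, 10, 20, 50, 80, 100, 200)


def tune_parameter(
    method: Callable[[MultiViewDataset, float, int], Embedding],
    data: MultiViewDataset,
    grid: Sequence[float] = DEFAULT_GRID,
    k: int | None = None,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[float, dict[float, EvalReport]]:
    """Grid-based tuning: embed at each admissible value, cluster, score.

    ``method(data, value, seed)`` must return an :class:`Embedding`. Values
    at or above the sample count are dropped (the parameter cannot exceed
    N). Stochastic methods are repeated ``replicates`` times and the mean
    (sd) of each measure reported, as in benchmark tables; the optimum is
    the value with the highest mean accuracy, ties broken by mean NMI.
    """
    if data.labels is None:
        raise ValueError("tuning requires ground-truth labels")
    if k is None:
        k = len(np.unique(data.labels))
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    admissible = [v for v in grid if v < data.N]
    if not admissible:
        raise ValueError("no admissible grid values below N")
    rng = np.random.default_rng(seed)
    reports: dict[float, EvalReport] = {}
    for value in admissible:
        per_rep = {m: [] for m in _MEASURES}
        for _ in range(replicates):
            rep_seed = int(rng.integers(2**31))
            e = method(data, value, rep_seed)
            # K-means is seeded identically across replicates so that the
            # reported spread reflects the method's own stochasticity
            scores = evaluate_embedding(e, data.labels, k, seed=seed)
            for m in _MEASURES:
                per_rep[m].append(scores[m])
        reports[value] = EvalReport(
            parameter_value=value,
            replicates=replicates,
            mean={m: float(np.mean(v)) for m, v in per_rep.items()},
            sd={m: float(np.std(v)) for m, v in per_rep.items()},
        )
    best = max(
        reports, key=lambda v: (reports[v].mean["acc"], reports[v].mean["nmi"])
    )
    return best, reports
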