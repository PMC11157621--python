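"""Shared containers and I/O for multi-view data, embeddings and reports.

A *data-view* is one of several feature matrices measured on the same ordered
set of samples (e.g. expression and methylation on the same patients). All
methods in this package consume a :class:`MultiViewDataset` holding M aligned
views and, optionally, ground-truth cluster labels used for evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread


class AlignmentError(ValueError):
    """Views do not share the same ordered sample set."""


class ParseError(ValueError):
    """A cell in an input file could not be interpreted as a number."""


@dataclass
class MultiViewDataset:
    """M feature matrices over one ordered sample set, plus optional labels.

    Parameters
    ----------
    views
        List of ``N x p_m`` real matrices, one per data-view, with identical
        row (sample) order.
    sample_ids
        N opaque identifiers, taken from the first file's id column on load
        or defaulting to 0-based indices.
    labels
        Optional length-N vector of ground-truth cluster identities.
    """

    views: list[np.ndarray]
    sample_ids: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.views) < 1:
            raise ValueError("a dataset needs at least one data-view")
        self.views = [np.asarray(v, dtype=float) for v in self.views]
        n = self.views[0].shape[0]
        for i, v in enumerate(self.views):
            if v.ndim != 2 or v.shape[1] < 1:
                raise ValueError(f"view {i} is not a 2-D matrix with >=1 feature")
            if v.shape[0] != n:
                raise AlignmentError(
                    f"view {i} has {v.shape[0]} rows, expected {n} (views must "
                    "share the same ordered sample set)"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"view {i} contains non-finite entries")
        if self.sample_ids is None:
            self.sample_ids = np.arange(n).astype(str)
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(self.sample_ids) != n:
                raise AlignmentError("sample_ids length does not match view rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise AlignmentError(
                    f"labels have {len(self.labels)} entries, expected {n}"
                )

    @property
    def M(self) -> int:
        return len(self.views)

    @property
    def N(self) -> int:
        return self.views[0].shape[0]

    @property
    def p(self) -> tuple[int, ...]:
        return tuple(v.shape[1] for v in self.views)


@dataclass
class Embedding:
    """N x d low-dimensional coordinates with provenance."""

    coords: np.ndarray
    method_tag: str = ""
    iterations_run: int = 0
    sample_ids: np.ndarray | None = None
    # set only when an embedding covers a subset of samples (largest
    # connected component of a neighbourhood graph)
    sample_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be an N x d matrix with d >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")

    @property
    def N(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class ClusterLabels:
    """Integer cluster assignments in ``[0, k)`` for N samples."""

    assignments: np.ndarray
    k: int = 0

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.k == 0:
            self.k = int(self.assignments.max()) + 1 if self.assignments.size else 0
        if self.assignments.size and (
            self.assignments.min() < 0 or self.assignments.max() >= self.k
        ):
            raise ValueError("cluster ids must lie in [0, k)")

    def __len__(self) -> int:
        return len(self.assignments)


def _read_dense(path: Path, sep: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a samples x features delimited file, sniffing header/id column."""
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)

    def _numeric(x) -> bool:
        try:
            float(x)
            return True
        except (TypeError, ValueError):
            return False

    has_header = not all(_numeric(x) for x in first.iloc[0])
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    ids = None
    first_col = df.iloc[:, 0]
    if first_col.dtype == object and not all(_numeric(x) for x in first_col):
        ids = first_col.to_numpy()
        df = df.iloc[:, 1:]
    values = df.to_numpy()
    if values.dtype == object:
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                if not _numeric(values[i, j]):
                    raise ParseError(
                        f"{path}: non-numeric value {values[i, j]!r} at row {i}, "
                        f"column {j}"
                    )
        values = values.astype(float)
    return np.asarray(values, dtype=float), ids


def load_views(
    paths: Sequence[str | Path],
    format: str = "csv",
    labels_path: str | Path | None = None,
) -> MultiViewDataset:
    """Load M aligned views from delimited text or matrix-market files.

    ``csv``/``tsv`` files are samples x features with an optional header row
    and id column; ``mtx`` files are 1-based sparse triplets, densified on
    load. Row order is taken from the first file.
    """
    if format not in ("csv", "tsv", "mtx"):
        raise ValueError(f"unknown format {format!r}")
    views: list[np.ndarray] = []
    sample_ids: np.ndarray | None = None
    n = None
    for path in paths:
        path = Path(path)
        if format == "mtx":
            if path.stat().st_size == 0:
                raise ValueError(f"{path}: empty file")
            m = mmread(path)
            mat = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
            ids = None
        else:
            mat, ids = _read_dense(path, "," if format == "csv" else "\t")
        if n is None:
            n = mat.shape[0]
            sample_ids = ids
        elif mat.shape[0] != n:
            raise AlignmentError(
                f"{path}: has {mat.shape[0]} rows but previous views have {n}"
            )
        views.append(mat)
    labels = None
    if labels_path is not None:
        labels = np.loadtxt(labels_path, dtype=str, ndmin=1)
        if len(labels) != n:
            raise AlignmentError(
                f"{labels_path}: {len(labels)} labels for {n} samples"
            )
    return MultiViewDataset(views=views, sample_ids=sample_ids, labels=labels)


def concatenate_views(data: MultiViewDataset, normalise: bool = False) -> np.ndarray:
    """Concatenate views column-wise; optionally z-score each feature.

    Normalisation removes the mean and divides by the population (divide-by-N)
    standard deviation of each feature; zero-variance columns map to zeros.
    """
    X = np.hstack(data.views)
    if normalise:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)  # population convention
        sd_safe = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd_safe
        X[:, sd == 0] = 0.0
    return X


def save_embedding(e: Embedding, path: str | Path) -> None:
    """Write an embedding as TSV with columns sample_id, dim1..dimd."""
    ids = e.sample_ids if e.sample_ids is not None else np.arange(e.N).astype(str)
    df = pd.DataFrame(e.coords, columns=[f"dim{i + 1}" for i in range(e.d)])
    df.insert(0, "sample_id", ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_embedding(path: str | Path) -> Embedding:
    df = pd.read_csv(path, sep="\t")
    return Embedding(
        coords=df.iloc[:, 1:].to_numpy(dtype=float),
        sample_ids=df.iloc[:, 0].to_numpy(),
    )


def save_report(report: dict, path: str | Path) -> None:
    """Serialise a metrics/config report as JSON. NaN values are rejected."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=False, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
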