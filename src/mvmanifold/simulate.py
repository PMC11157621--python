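"""Synthetic multi-view cluster scenarios.

Each data-view draws every sample from a multivariate normal with identity
covariance; the mean depends only on the *group* the sample's cluster falls
into under that view's partition, so a view distinguishes exactly the groups
of its partition and nothing finer. Designated views receive an additive
noise term eps ~ MVN(mu_eps 1, I) that raises their variability, and a
random polynomial (one per view and group, shared by all samples whose
clusters the view merges) is applied elementwise to inject non-linearity
that defeats linear reductions such as PCA.

Three ready-made scenarios mirror a common benchmark design:

* MMDS - 3 views, 3 clusters (A, B, C), n=300, p_m=100; view 1 separates
  only C, view 2 only B, view 3 only A, and view 3 carries the extra noise.
* NDS - MMDS plus a fourth, pure-noise view (single group, no structure).
* MCS - 3 views, 5 clusters, n=500; the partitions jointly identify all
  five clusters while no single view does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MultiViewDataset

#: variance of a transformed block is kept within this factor of its input
_VAR_CAP = 10.0


@dataclass
class ScenarioSpec:
    """Generative grammar of one synthetic multi-view scenario."""

    n: int
    k: int
    p: list[int]
    # per view: partition of the k clusters into separable groups
    view_partitions: list[list[tuple[int, ...]]]
    mu_scale: float = 3.0  # per-coordinate group-mean offset, in sd units
    noisy_views: frozenset[int] = field(default_factory=frozenset)
    pure_noise_views: frozenset[int] = field(default_factory=frozenset)
    noise_mean: float = 0.5
    poly_degree_range: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n % self.k != 0:
            raise ValueError("n must be divisible by k (equal cluster sizes)")
        if len(self.p) != len(self.view_partitions):
            raise ValueError("one partition needed per view")
        if self.poly_degree_range[0] < 1:
            raise ValueError("polynomial degrees must be >= 1")
        # a pure-noise view is a single group holding every cluster
        parts = []
        for m, part in enumerate(self.view_partitions):
            if m in self.pure_noise_views:
                part = [tuple(range(self.k))]
            covered = sorted(c for grp in part for c in grp)
            if covered != list(range(self.k)):
                raise ValueError(
                    f"view {m}: partition must cover each of the {self.k} "
                    f"clusters exactly once, got {part}"
                )
            parts.append([tuple(g) for g in part])
        self.view_partitions = parts

    @property
    def M(self) -> int:
        return len(self.p)


def _apply_polynomial(block: np.ndarray, rng: np.random.Generator,
                      degree_range: tuple[int, int]) -> np.ndarray:
    """Elementwise random polynomial, rescaled to bound variance growth.

    The polynomial acts on the standardised block so that the strength of
    the non-linear distortion does not grow with the cluster-separation
    scale (a degree-4 term on raw values would otherwise be dominated by
    its extreme tails and erase the local neighbourhood structure the
    transform is meant to bend, not destroy). Output variance is capped at
    ``_VAR_CAP`` times the input variance.
    """
    degree = int(rng.integers(degree_range[0], degree_range[1] + 1))
    coeffs = rng.uniform(-1.0, 1.0, size=degree + 1)
    s_in = block.std()
    out = np.polynomial.polynomial.polyval(block / s_in, coeffs)
    s_out = out.std()
    cap = np.sqrt(_VAR_CAP) * s_in
    if s_out > cap and s_out > 0:
        out = out * (cap / s_out)
    return out


def generate_scenario(spec: ScenarioSpec) -> MultiViewDataset:
    """Draw a dataset from a scenario spec; fully reproducible from its seed.

    Views are generated from independent per-view random streams spawned
    from the seed, so adding a view leaves the earlier views unchanged.
    """
    size = spec.n // spec.k
    labels = np.repeat(np.arange(spec.k), size)
    children = np.random.SeedSequence(spec.seed).spawn(spec.M)
    views = []
    for m in range(spec.M):
        rng = np.random.default_rng(children[m])
        p_m = spec.p[m]
        X = rng.standard_normal((spec.n, p_m))
        for group in spec.view_partitions[m]:
            mu = spec.mu_scale * rng.choice([-1.0, 1.0], size=p_m)
            rows = np.isin(labels, group)
            X[rows] += mu
        if m in spec.noisy_views:
            X += spec.noise_mean + rng.standard_normal((spec.n, p_m))
        for group in spec.view_partitions[m]:
            rows = np.isin(labels, group)
            X[rows] = _apply_polynomial(X[rows], rng, spec.poly_degree_range)
        views.append(X)
    ids = np.array([f"s{i:04d}" for i in range(spec.n)])
    return MultiViewDataset(views=views, sample_ids=ids, labels=labels)


def _mmds_spec(seed: int, extra_noise_view: bool = False) -> ScenarioSpec:
    partitions = [
        [(2,), (0, 1)],  # view 1 separates only cluster C
        [(1,), (0, 2)],  # view 2 separates only cluster B
        [(0,), (1, 2)],  # view 3 separates only cluster A
    ]
    p = [100, 100, 100]
    pure = frozenset()
    if extra_noise_view:
        partitions = partitions + [[(0, 1, 2)]]
        p = p + [100]
        pure = frozenset({3})
    return ScenarioSpec(
        n=300,
        k=3,
        p=p,
        view_partitions=partitions,
        mu_scale=3.75,
        noisy_views=frozenset({2}),  # the third view carries the extra noise
        pure_noise_views=pure,
        seed=seed,
    )


def make_mmds(seed: int = 0) -> MultiViewDataset:
    """Motivational multi-view data scenario: 3 views, 3 clusters, n=300."""
    return generate_scenario(_mmds_spec(seed))


def make_nds(seed: int = 0) -> MultiViewDataset:
    """Noisy data-view scenario: MMDS plus a pure-noise fourth view."""
    return generate_scenario(_mmds_spec(seed, extra_noise_view=True))


def make_mcs(seed: int = 0) -> MultiViewDataset:
    """More-clusters-than-views scenario: 3 views, 5 clusters, n=500.

    The partitions jointly identify all five clusters while no single view
    does: view 1 {A | B | CDE}, view 2 {C | DE | AB}, view 3 {E | AC | BD}.
    Most cluster pairs are separated by at least two views; D and E are told
    apart only by the third view, which also carries the extra noise, so the
    joint embedding is hard but solvable there.
    """
    spec = ScenarioSpec(
        n=500,
        k=5,
        p=[100, 100, 100],
        view_partitions=[
            [(0,), (1,), (2, 3, 4)],
            [(2,), (3, 4), (0, 1)],
            [(4,), (0, 2), (1, 3)],
        ],
        mu_scale=1.25,
        noisy_views=frozenset({2}),
        seed=seed,
    )
    return generate_scenario(spec)
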