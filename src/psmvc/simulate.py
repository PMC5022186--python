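"""Synthetic paired-view networks with planted shared and specific complexes.

The generator mirrors the model's own generative reading: a clean
affinity matrix per view, ``W_clean^(m) = H_c H_c' + H_s^(m) H_s^(m)'``,
built from planted membership factors whose column supports are the true
complexes.  Shared complexes contribute to both views through H_c;
view-specific complexes to exactly one view — the structure a partially
shared factorization is designed to separate.  Symmetric Gaussian noise
is added, negative entries clipped to zero, the diagonal zeroed, and an
optional per-view coverage mask removes rows/columns of unobserved
proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ComplexSet, ProteinUniverse, WeightedNetworkView

__all__ = ["PlantedTruth", "generate"]


@dataclass
class PlantedTruth:
    """Ground truth behind a simulated view pair."""

    H_c_true: np.ndarray
    H_s_true: tuple[np.ndarray, np.ndarray]
    complexes_true: ComplexSet
    shared_complexes: ComplexSet
    specific_complexes: tuple[ComplexSet, ComplexSet]
    theta_true: tuple[np.ndarray, np.ndarray]


def _sample_supports(
    rng: np.random.Generator, n: int, n_complexes: int, size_range: tuple[int, int]
) -> list[np.ndarray]:
    """Sample complex supports that jointly cover all n proteins.

    Sizes are drawn uniformly from ``size_range`` conditioned on summing
    to at least n (the fitted assignment places every covered protein in
    some complex, so the benchmark plants membership for everyone).
    Supports are consecutive arcs on a random permutation of the
    proteins, spaced proportionally to the cumulative sizes: arcs
    overlap exactly where the total size exceeds n, so distinct
    complexes share proteins but never coincide.
    """
    lo, hi = size_range
    if n_complexes * hi < n:
        raise ValueError(
            f"{n_complexes} complexes of size <= {hi} cannot cover {n} proteins"
        )
    for _ in range(1000):
        sizes = rng.integers(lo, hi + 1, size=n_complexes)
        if sizes.sum() >= n:
            break
    else:  # pragma: no cover - essentially unreachable for feasible ranges
        raise ValueError("could not sample sizes covering all proteins")
    total = int(sizes.sum())
    perm = rng.permutation(n)
    starts = np.floor(n * np.concatenate([[0], np.cumsum(sizes)[:-1]]) / total).astype(int)
    return [perm[(s + np.arange(sz)) % n] for s, sz in zip(starts, sizes)]


def generate(
    n_proteins: int = 60,
    n_shared: int = 4,
    n_specific_per_view: int = 2,
    complex_size_range: tuple[int, int] = (6, 10),
    membership_strength: float = 1.0,
    noise_sd: float = 0.0,
    coverage_fraction: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
) -> tuple[tuple[WeightedNetworkView, WeightedNetworkView], PlantedTruth]:
    """Generate two aligned weighted network views with planted complexes.

    Complex supports are sampled uniformly without replacement (distinct
    complexes may overlap); planted factor entries equal
    ``membership_strength`` on the support and 0 elsewhere.  Noise is
    additive symmetric N(0, noise_sd) clipped at 0.  Coverage masks keep
    a ``coverage_fraction[m]`` share of proteins per view (rounded to
    the nearest count), zeroing the rest's rows and columns.
    Deterministic for a fixed seed.
    """
    lo, hi = complex_size_range
    if not (3 <= lo <= hi <= n_proteins):
        raise ValueError("complex sizes must satisfy 3 <= lo <= hi <= n_proteins")
    if membership_strength <= 0:
        raise ValueError("membership_strength must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if any(not 0 < c <= 1 for c in coverage_fraction):
        raise ValueError("coverage fractions must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    n = n_proteins
    universe = ProteinUniverse([f"P{i:04d}" for i in range(n)])

    n_total = n_shared + 2 * n_specific_per_view
    supports = _sample_supports(rng, n, n_total, complex_size_range)

    H_c = np.zeros((n, n_shared))
    shared_sets = []
    for k in range(n_shared):
        sup = supports[k]
        H_c[sup, k] = membership_strength
        shared_sets.append(frozenset(universe.ids[i] for i in sup))

    H_s: list[np.ndarray] = []
    specific_sets: list[list[frozenset[str]]] = []
    for m in range(2):
        Hm = np.zeros((n, n_specific_per_view))
        sets_m = []
        for k in range(n_specific_per_view):
            sup = supports[n_shared + m * n_specific_per_view + k]
            Hm[sup, k] = membership_strength
            sets_m.append(frozenset(universe.ids[i] for i in sup))
        H_s.append(Hm)
        specific_sets.append(sets_m)

    thetas = []
    for m in range(2):
        n_cov = int(round(coverage_fraction[m] * n))
        covered = rng.choice(n, size=n_cov, replace=False)
        theta = np.zeros(n)
        theta[covered] = 1.0
        thetas.append(theta)

    views = []
    for m in range(2):
        W = H_c @ H_c.T + H_s[m] @ H_s[m].T
        if noise_sd > 0:
            noise = rng.normal(scale=noise_sd, size=(n, n))
            W = W + np.triu(noise, 1) + np.triu(noise, 1).T
            W = np.clip(W, 0.0, None)
        np.fill_diagonal(W, 0.0)
        mask = np.outer(thetas[m], thetas[m])
        views.append(WeightedNetworkView(universe, W * mask, thetas[m]))

    shared_cs = ComplexSet([(f"shared{k}", s) for k, s in enumerate(shared_sets)])
    spec_cs = tuple(
        ComplexSet([(f"view{m + 1}_spec{k}", s) for k, s in enumerate(specific_sets[m])])
        for m in range(2)
    )
    all_cs = ComplexSet(
        [(f"shared{k}", s) for k, s in enumerate(shared_sets)]
        + [
            (f"view{m + 1}_spec{k}", s)
            for m in range(2)
            for k, s in enumerate(specific_sets[m])
        ]
    )
    truth = PlantedTruth(
        H_c_true=H_c,
        H_s_true=(H_s[0], H_s[1]),
        complexes_true=all_cs,
        shared_complexes=shared_cs,
        specific_complexes=spec_cs,
        theta_true=(thetas[0], thetas[1]),
    )
    return (views[0], views[1]), truth
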