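"""Partially shared multi-view NMF for overlapping complex detection.

Two score matrices ``W^(1)``, ``W^(2)`` over the same N proteins are
jointly factorized as ``A^(m) = H_c H_c' + H_s^(m) H_s^(m)'`` where the
shared block ``H_c`` (N x K_c) captures complexes supported by both data
sources and the view-specific blocks ``H_s^(m)`` (N x K_s) capture
structure visible in only one of them.  The loss is a coverage-masked
generalized KL divergence between each observed ``W^(m)`` and its
reconstruction, plus a Frobenius penalty

    J = -sum_m sum_{ij} theta_i theta_j [ W_ij log A_ij - A_ij ]
        + lambda ( ||H_c||_F^2 + sum_m ||H_s^(m)||_F^2 )

which acts as a trace-norm surrogate (for A = HH' with H >= 0 the sum of
singular values of A equals ||H||_F^2), suppressing irrelevant latent
dimensions so K can be set generously.  Optimization is by damped
multiplicative updates under alternating minimization with multiple
random restarts; the continuous solution is discretized row-wise by a
largest-gap rule into a binary assignment matrix from which overlapping
complexes are read off column by column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ComplexSet, ProteinUniverse, WeightedNetworkView

__all__ = [
    "ModelConfig",
    "LatentFactors",
    "FitResult",
    "split_latent_dims",
    "masked_kl",
    "objective",
    "update_shared",
    "update_specific",
    "fit",
    "discretize",
    "extract_complexes",
]

logger = logging.getLogger("psmvc")

# Relative slack allowed before an objective increase is reported.
MONOTONE_RTOL = 1e-9


def split_latent_dims(K: int, eta: float) -> tuple[int, int]:
    """Split a total latent dimension K into (K_c, K_s).

    K_c = round(eta*K), nudged by +/-1 when needed so that K - K_c is
    even (K = K_c + 2*K_s must hold exactly), preferring the larger K_c
    and keeping 0 <= K_c <= K.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    K_c = int(np.floor(eta * K + 0.5))
    if (K - K_c) % 2 == 1:
        K_c = K_c + 1 if K_c + 1 <= K else K_c - 1
    return K_c, (K - K_c) // 2


@dataclass
class ModelConfig:
    """Hyperparameters of the factorization.

    K: total latent dimension (upper bound on number of complexes).
    eta: shared-factor ratio K_c/K in [0, 1].
    lam: weight of the Frobenius (trace-norm surrogate) penalty.
    tol: relative objective-change stopping threshold.
    max_iter: iteration cap per restart.
    n_restarts: random restarts; the lowest final objective wins.
    seed: master RNG seed; per-restart streams are spawned from it.
    eps: numerical floor inside logs and denominators.
    min_size: smallest complex reported.
    """

    K: int
    eta: float = 0.5
    lam: float = 4.0
    tol: float = 1e-6
    max_iter: int = 200
    n_restarts: int = 20
    seed: int = 0
    eps: float = 1e-12
    min_size: int = 3
    dedupe: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("tol > 0, max_iter >= 1, n_restarts >= 1 required")
        if self.eps <= 0 or self.lam < 0:
            raise ValueError("eps > 0 and lam >= 0 required")
        self.K_c, self.K_s = split_latent_dims(self.K, self.eta)


@dataclass
class LatentFactors:
    """Shared block H_c (N x K_c) and per-view blocks H_s[m] (N x K_s)."""

    H_c: np.ndarray
    H_s: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if np.any(self.H_c < 0) or any(np.any(h < 0) for h in self.H_s):
            raise ValueError("factors must be nonnegative")
        if self.H_s[0].shape != self.H_s[1].shape:
            raise ValueError("view-specific blocks must share a shape")
        if self.H_s[0].shape[0] != self.H_c.shape[0]:
            raise ValueError("blocks must agree on N")

    @property
    def n(self) -> int:
        return self.H_c.shape[0]

    @property
    def K_c(self) -> int:
        return self.H_c.shape[1]

    @property
    def K_s(self) -> int:
        return self.H_s[0].shape[1]

    def view_concat(self, m: int) -> np.ndarray:
        """H^(m) = [H_c, H_s^(m)]."""
        return np.hstack([self.H_c, self.H_s[m]])

    def full_concat(self) -> np.ndarray:
        """H = [H_c, H_s^(1), H_s^(2)]."""
        return np.hstack([self.H_c, self.H_s[0], self.H_s[1]])

    def column_blocks(self) -> list[str]:
        """Block provenance of each column of the full concatenation."""
        return ["c"] * self.K_c + ["s1"] * self.K_s + ["s2"] * self.K_s

    def reconstruction(self, m: int) -> np.ndarray:
        """A^(m) = H_c H_c' + H_s^(m) H_s^(m)'."""
        return self.H_c @ self.H_c.T + self.H_s[m] @ self.H_s[m].T


@dataclass
class FitResult:
    factors: LatentFactors
    objective_trace: np.ndarray
    restart_objectives: np.ndarray
    best_restart: int
    assignment: np.ndarray
    complexes: ComplexSet
    config: ModelConfig
    unclustered: list[str] = field(default_factory=list)

    def column_blocks(self) -> list[str]:
        return self.factors.column_blocks()


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def masked_kl(W: np.ndarray, theta: np.ndarray, A: np.ndarray, eps: float = 1e-12) -> float:
    """Coverage-masked generalized KL divergence D(W || A).

    sum_{ij} theta_i theta_j [ W_ij log(W_ij/A_ij) - W_ij + A_ij ],
    with 0*log(0/x) = 0 and A floored at ``eps`` inside the ratio.
    """
    W = np.asarray(W, dtype=float)
    A = np.asarray(A, dtype=float)
    if W.shape != A.shape:
        raise ValueError(f"shape mismatch: W {W.shape} vs A {A.shape}")
    mask = np.outer(theta, theta)
    Af = np.maximum(A, eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        wlog = np.where(W > 0, W * np.log(np.where(W > 0, W, 1.0) / Af), 0.0)
    return float(np.sum(mask * (wlog - W + A)))


def objective(
    views: tuple[WeightedNetworkView, WeightedNetworkView],
    f: LatentFactors,
    lam: float,
    eps: float = 1e-12,
) -> float:
    """Model objective J (masked KL without the constant W log W - W term,
    plus the Frobenius penalty)."""
    J = 0.0
    for m, v in enumerate(views):
        mask = np.outer(v.theta, v.theta)
        WM = mask * v.W
        A = f.reconstruction(m)
        J -= float(np.sum(WM * np.log(np.maximum(A, eps)) - mask * A))
    J += lam * (
        float(np.sum(f.H_c**2))
        + float(np.sum(f.H_s[0] ** 2))
        + float(np.sum(f.H_s[1] ** 2))
    )
    if not np.isfinite(J):
        raise FloatingPointError("objective is not finite")
    return J


# ---------------------------------------------------------------------------
# Multiplicative updates (damped: new = old/2 + old/2 * ratio)
# ---------------------------------------------------------------------------

def update_shared(
    views: tuple[WeightedNetworkView, WeightedNetworkView],
    f: LatentFactors,
    lam: float,
    eps: float = 1e-12,
) -> np.ndarray:
    """One damped multiplicative update of the shared block H_c."""
    H_c = f.H_c
    num = np.zeros_like(H_c)
    den = lam * H_c
    for m, v in enumerate(views):
        mask = np.outer(v.theta, v.theta)
        A = np.maximum(f.reconstruction(m), eps)
        num += ((mask * v.W) / A) @ H_c
        den += mask @ H_c
    return H_c / 2.0 + 0.5 * H_c * num / np.maximum(den, eps)


def update_specific(
    view: WeightedNetworkView,
    f: LatentFactors,
    m: int,
    lam: float,
    eps: float = 1e-12,
) -> np.ndarray:
    """One damped multiplicative update of the view-specific block H_s^(m)."""
    H_s = f.H_s[m]
    mask = np.outer(view.theta, view.theta)
    A = np.maximum(f.reconstruction(m), eps)
    num = ((mask * view.W) / A) @ H_s
    den = mask @ H_s + lam * H_s
    return H_s / 2.0 + 0.5 * H_s * num / np.maximum(den, eps)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _run_restart(
    views: tuple[WeightedNetworkView, WeightedNetworkView],
    cfg: ModelConfig,
    rng: np.random.Generator,
) -> tuple[LatentFactors, list[float]]:
    n = views[0].n
    f = LatentFactors(
        rng.uniform(size=(n, cfg.K_c)),
        (rng.uniform(size=(n, cfg.K_s)), rng.uniform(size=(n, cfg.K_s))),
    )
    trace = [objective(views, f, cfg.lam, cfg.eps)]
    for it in range(1, cfg.max_iter + 1):
        H_c = update_shared(views, f, cfg.lam, cfg.eps)
        f = LatentFactors(H_c, f.H_s)
        H_s1 = update_specific(views[0], f, 0, cfg.lam, cfg.eps)
        f = LatentFactors(f.H_c, (H_s1, f.H_s[1]))
        H_s2 = update_specific(views[1], f, 1, cfg.lam, cfg.eps)
        f = LatentFactors(f.H_c, (f.H_s[0], H_s2))
        J = objective(views, f, cfg.lam, cfg.eps)
        prev = trace[-1]
        if J > prev + MONOTONE_RTOL * abs(prev):
            logger.warning(
                "objective increased at iteration %d: %.12g -> %.12g", it, prev, J
            )
        trace.append(J)
        if abs(J - prev) / max(abs(prev), cfg.eps) < cfg.tol:
            break
    return f, trace


def fit(
    views: tuple[WeightedNetworkView, WeightedNetworkView]
    | list[WeightedNetworkView],
    config: ModelConfig,
) -> FitResult:
    """Fit the model with multi-restart alternating optimization.

    Each restart draws i.i.d. uniform(0,1) initial factors from a stream
    spawned off the master seed, alternates the shared and per-view
    updates until the relative objective change falls below ``tol`` or
    ``max_iter`` is reached, and the restart with the smallest final
    objective is discretized into complexes.
    """
    views = tuple(views)
    if len(views) != 2:
        raise ValueError("exactly two views are required")
    if views[0].universe.ids != views[1].universe.ids:
        raise ValueError("views must be aligned onto one universe (align_views)")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    best: tuple[LatentFactors, list[float]] | None = None
    finals = np.full(config.n_restarts, np.nan)
    for r, ss in enumerate(streams):
        try:
            f, trace = _run_restart(views, config, np.random.default_rng(ss))
        except FloatingPointError:
            logger.warning("restart %d aborted: nonfinite objective", r)
            continue
        finals[r] = trace[-1]
        if best is None or trace[-1] < best[1][-1]:
            best = (f, trace)
    if best is None:
        raise FloatingPointError("all restarts failed with nonfinite objectives")
    factors, trace = best
    best_restart = int(np.nanargmin(finals))

    H_hat = factors.full_concat()
    H_star = discretize(H_hat)
    covered = (views[0].theta + views[1].theta) > 0
    unclustered = [
        views[0].universe.ids[i]
        for i in np.flatnonzero(covered & (H_star.sum(axis=1) == 0))
    ]
    if unclustered:
        logger.info("%d covered proteins received no assignment", len(unclustered))
    complexes = extract_complexes(
        H_star,
        views[0].universe,
        min_size=config.min_size,
        dedupe=config.dedupe,
        column_blocks=factors.column_blocks(),
    )
    return FitResult(
        factors=factors,
        objective_trace=np.asarray(trace),
        restart_objectives=finals,
        best_restart=best_restart,
        assignment=H_star,
        complexes=complexes,
        config=config,
        unclustered=unclustered,
    )


# ---------------------------------------------------------------------------
# Discretization and complex extraction
# ---------------------------------------------------------------------------

def discretize(H_hat: np.ndarray) -> np.ndarray:
    """Row-wise largest-gap thresholding of a nonnegative matrix.

    For each row, sort the values in descending order and pick the cut
    position K_i in {1, ..., K-1} with the largest drop between
    consecutive sorted values (ties broken toward the smallest K_i, i.e.
    the fewest assignments); entries >= the K_i-th sorted value get 1.
    The gap to an implicit zero after the last entry is not a candidate,
    so no row is assigned to all K columns.  All-zero rows get no
    assignment.
    """
    H_hat = np.asarray(H_hat, dtype=float)
    if H_hat.ndim != 2 or H_hat.shape[1] < 2:
        raise ValueError("H_hat must be 2-D with K >= 2 columns")
    s = np.sort(H_hat, axis=1)[:, ::-1]
    gaps = s[:, :-1] - s[:, 1:]
    cut = np.argmax(gaps, axis=1)  # first max = smallest K_i
    thresh = s[np.arange(H_hat.shape[0]), cut]
    H_star = (H_hat >= thresh[:, None]).astype(np.int8)
    H_star[s[:, 0] == 0] = 0  # all-zero rows stay unassigned
    return H_star


def extract_complexes(
    H_star: np.ndarray,
    universe: ProteinUniverse,
    min_size: int = 3,
    dedupe: bool = True,
    column_blocks: list[str] | None = None,
) -> ComplexSet:
    """Read complexes off the columns of a binary assignment matrix.

    Complex k is the member set of column k.  Columns with fewer than
    ``min_size`` members are dropped; identical member sets are
    deduplicated keeping the first column (labels record the column
    index, and its block when ``column_blocks`` is given).
    """
    H_star = np.asarray(H_star)
    out: list[tuple[str, frozenset[str]]] = []
    seen: set[frozenset[str]] = set()
    for k in range(H_star.shape[1]):
        members = frozenset(universe.ids[i] for i in np.flatnonzero(H_star[:, k]))
        if len(members) < min_size:
            continue
        if dedupe:
            if members in seen:
                continue
            seen.add(members)
        label = f"k{k}" if column_blocks is None else f"k{k}.{column_blocks[k]}"
        out.append((label, members))
    return ComplexSet(out)
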