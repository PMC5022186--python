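"""Reading, writing and aligning weighted network views and complex sets.

A *view* is one source of pairwise co-complex evidence over a shared
protein universe: an ``N x N`` symmetric nonnegative score matrix ``W``
together with a binary coverage vector ``theta`` marking which proteins
the source actually observed.  Complex sets (predicted or reference) use
the MCL convention: one complex per line, tab-separated member IDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProteinUniverse",
    "WeightedNetworkView",
    "ComplexSet",
    "EdgeListError",
    "read_edge_list",
    "read_coverage",
    "align_views",
    "read_complexes",
    "write_complexes",
]


class EdgeListError(ValueError):
    """Raised for malformed or invalid edge-list input."""


@dataclass
class ProteinUniverse:
    """Ordered set of protein identifiers with 0-based positions."""

    ids: list[str]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if any(not isinstance(i, str) or not i for i in self.ids):
            raise ValueError("protein identifiers must be non-empty strings")
        self.index = {p: i for i, p in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise ValueError("protein identifiers must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, pid: str) -> bool:
        return pid in self.index

    def extended(self, new_ids: Iterable[str]) -> "ProteinUniverse":
        """Universe with ``new_ids`` appended (existing order preserved)."""
        ids = list(self.ids)
        seen = set(self.index)
        for pid in new_ids:
            if pid not in seen:
                ids.append(pid)
                seen.add(pid)
        return ProteinUniverse(ids)


@dataclass
class WeightedNetworkView:
    """One view's score matrix W (symmetric, nonnegative, zero diagonal)
    and coverage vector theta over a shared universe."""

    universe: ProteinUniverse
    W: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.universe)
        self.W = np.asarray(self.W, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {self.W.shape}")
        if self.theta.shape != (n,):
            raise ValueError(f"theta must have length {n}")
        if np.any(self.W < 0):
            raise ValueError("W must be nonnegative")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")
        covered = self.theta > 0
        if np.any(self.W[~covered, :] > 0) or np.any(self.W[:, ~covered] > 0):
            raise ValueError("W has positive scores touching uncovered proteins")

    @property
    def n(self) -> int:
        return len(self.universe)


@dataclass
class ComplexSet:
    """Labelled collection of protein-member sets."""

    complexes: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.complexes]
        if len(set(labels)) != len(labels):
            raise ValueError("complex labels must be unique")
        if any(not members for _, members in self.complexes):
            raise ValueError("complexes must be non-empty")
        self.complexes = [(lab, frozenset(m)) for lab, m in self.complexes]

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    @property
    def member_sets(self) -> list[frozenset[str]]:
        return [m for _, m in self.complexes]

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]], prefix: str = "C") -> "ComplexSet":
        return cls([(f"{prefix}{i}", frozenset(s)) for i, s in enumerate(sets)])


def _merge(old: float, new: float, rule: str) -> float:
    if rule == "max":
        return max(old, new)
    if rule == "mean":
        # running mean is not well-defined pairwise; handled by caller
        raise AssertionError("mean merging handled in read_edge_list")
    raise ValueError(f"unknown merge rule: {rule!r}")


def read_edge_list(
    path: str | Path,
    universe: ProteinUniverse | None = None,
    merge: str = "max",
) -> WeightedNetworkView:
    """Read a TSV edge list (id_a, id_b, weight) into a network view.

    Duplicate undirected pairs (including asymmetric ``A B`` / ``B A``
    records) are merged by ``merge`` ("max", the default, or "mean").
    Self-edges are dropped from W but still mark the protein as covered.
    Lines starting with ``#`` are skipped.  ``theta[i] = 1`` iff protein
    *i* appears in any row of the file.
    """
    if merge not in ("max", "mean"):
        raise ValueError(f"unknown merge rule: {merge!r}")
    path = Path(path)
    pair_weights: dict[tuple[str, str], list[float]] = {}
    seen: list[str] = []
    seen_set: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise EdgeListError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            a, b, wtxt = fields[0], fields[1], fields[2]
            try:
                w = float(wtxt)
            except ValueError as exc:
                raise EdgeListError(
                    f"{path}:{lineno}: weight {wtxt!r} is not a number"
                ) from exc
            if not np.isfinite(w) or w < 0:
                raise EdgeListError(
                    f"{path}:{lineno}: weight must be finite and nonnegative, got {w}"
                )
            for pid in (a, b):
                if pid not in seen_set:
                    seen.append(pid)
                    seen_set.add(pid)
            if a == b:
                continue  # self-score dropped, coverage kept
            key = (a, b) if a <= b else (b, a)
            pair_weights.setdefault(key, []).append(w)

    if universe is None:
        uni = ProteinUniverse(list(seen))
    else:
        uni = universe.extended(seen)
    n = len(uni)
    W = np.zeros((n, n))
    for (a, b), ws in pair_weights.items():
        w = max(ws) if merge == "max" else float(np.mean(ws))
        i, j = uni.index[a], uni.index[b]
        W[i, j] = W[j, i] = w
    theta = np.zeros(n)
    for pid in seen:
        theta[uni.index[pid]] = 1.0
    return WeightedNetworkView(uni, W, theta)


def read_coverage(path: str | Path, universe: ProteinUniverse) -> np.ndarray:
    """Read a one-identifier-per-line coverage file into a theta vector."""
    theta = np.zeros(len(universe))
    with open(path) as fh:
        for raw in fh:
            pid = raw.strip()
            if not pid or pid.startswith("#"):
                continue
            if pid in universe:
                theta[universe.index[pid]] = 1.0
    return theta


def align_views(
    views: Sequence[WeightedNetworkView],
) -> tuple[ProteinUniverse, list[WeightedNetworkView]]:
    """Re-index all views onto the union universe.

    Proteins absent from a view get zero rows/columns in its W and
    ``theta = 0`` there; existing scores are preserved under re-indexing.
    """
    if not views:
        raise ValueError("need at least one view")
    union = views[0].universe
    for v in views[1:]:
        union = union.extended(v.universe.ids)
    n = len(union)
    out = []
    for v in views:
        perm = np.array([union.index[p] for p in v.universe.ids])
        W = np.zeros((n, n))
        W[np.ix_(perm, perm)] = v.W
        theta = np.zeros(n)
        theta[perm] = v.theta
        out.append(WeightedNetworkView(union, W, theta))
    return union, out


def read_complexes(path: str | Path) -> ComplexSet:
    """Read an MCL-style complex file (one tab-separated complex per line).

    Blank lines are skipped; duplicate members within a line are
    deduplicated with a warning.
    """
    complexes: list[tuple[str, frozenset[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if line:
                    warnings.warn(f"{path}:{lineno}: whitespace-only line skipped")
                continue
            members = [m for m in line.split("\t") if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members deduplicated")
            complexes.append((f"C{len(complexes)}", frozenset(uniq)))
    return ComplexSet(complexes)


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write a complex set in MCL style (members sorted for determinism)."""
    with open(path, "w") as fh:
        for _, members in cs:
            fh.write("\t".join(sorted(members)) + "\n")
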