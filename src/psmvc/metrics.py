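"""Evaluation metrics for predicted versus reference complex sets.

Implements the standard complex-detection metric suite: clustering-wise
sensitivity (Sn), positive predictive value (PPV) and their geometric
mean Acc; overlap-score matching at threshold omega with the derived
Precision / Recall / F-measure; the fraction of matched reference
complexes (FRAC); hypergeometric enrichment P-values; and the
reference-set preparation protocol (restrict to the input universe,
drop small complexes, exclude a tuning catalog).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io import ComplexSet, ProteinUniverse

__all__ = [
    "MetricReport",
    "overlap_table",
    "accuracy",
    "overlap_match",
    "precision_recall_f",
    "frac",
    "evaluate",
    "hypergeom_enrichment",
    "bonferroni",
    "prepare_reference",
]


@dataclass
class MetricReport:
    Sn: float
    PPV: float
    Acc: float
    Precision: float
    Recall: float
    Fmeasure: float
    FRAC: float
    TP: int
    FP: int
    FN: int

    def as_dict(self) -> dict:
        return {
            "Sn": self.Sn,
            "PPV": self.PPV,
            "Acc": self.Acc,
            "Precision": self.Precision,
            "Recall": self.Recall,
            "Fmeasure": self.Fmeasure,
            "FRAC": self.FRAC,
            "TP": self.TP,
            "FP": self.FP,
            "FN": self.FN,
        }


def overlap_table(reference: ComplexSet, predicted: ComplexSet) -> tuple[np.ndarray, np.ndarray]:
    """T[i, j] = |b_i ∩ q_j| and the vector of reference sizes n_i."""
    refs = reference.member_sets
    preds = predicted.member_sets
    T = np.array([[len(b & q) for q in preds] for b in refs], dtype=float)
    n = np.array([len(b) for b in refs], dtype=float)
    return T, n


def accuracy(reference: ComplexSet, predicted: ComplexSet) -> tuple[float, float, float]:
    """Clustering-wise (Sn, PPV, Acc).

    Sn = sum_i max_j T_ij / sum_i n_i weights each reference complex by
    how well its best-matching prediction covers it.  PPV
    = sum_j max_i T_ij / sum_j |union_i (b_i ∩ q_j)| measures how
    concentrated each prediction is in a single reference complex.
    Acc = sqrt(Sn * PPV).
    """
    if len(reference) == 0 or len(predicted) == 0:
        raise ValueError("both complex sets must be non-empty")
    T, n = overlap_table(reference, predicted)
    Sn = float(T.max(axis=1).sum() / n.sum())
    ref_union = frozenset().union(*reference.member_sets)
    ppv_den = sum(len(q & ref_union) for q in predicted.member_sets)
    if ppv_den == 0:
        warnings.warn("no predicted protein appears in any reference complex; PPV := 0")
        PPV = 0.0
    else:
        PPV = float(T.max(axis=0).sum() / ppv_den)
    return Sn, PPV, float(np.sqrt(Sn * PPV))


def overlap_match(b: frozenset | set, q: frozenset | set, omega: float = 0.25) -> bool:
    """Overlap-score match: |b ∩ q|^2 / (|b| |q|) >= omega (boundary inclusive)."""
    if not b or not q:
        raise ValueError("member sets must be non-empty")
    inter = len(set(b) & set(q))
    return inter * inter / (len(b) * len(q)) >= omega


def precision_recall_f(
    reference: ComplexSet, predicted: ComplexSet, omega: float = 0.25
) -> tuple[float, float, float, int, int, int]:
    """(Precision, Recall, F, TP, FP, FN) under omega-overlap matching.

    TP counts *predicted* complexes matched by at least one reference
    complex; FN counts *reference* complexes matched by no prediction —
    the two sides are deliberately asymmetric.
    """
    refs = reference.member_sets
    preds = predicted.member_sets
    TP = sum(1 for q in preds if any(overlap_match(b, q, omega) for b in refs))
    FP = len(preds) - TP
    FN = sum(1 for b in refs if not any(overlap_match(b, q, omega) for q in preds))
    recall = TP / (TP + FN) if TP + FN > 0 else 0.0
    precision = TP / (TP + FP) if TP + FP > 0 else 0.0
    if precision + recall == 0:
        warnings.warn("Precision + Recall = 0; F-measure := 0")
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return precision, recall, f, TP, FP, FN


def frac(reference: ComplexSet, predicted: ComplexSet, omega: float = 0.25) -> float:
    """Fraction of reference complexes matched by >= 1 predicted complex."""
    if len(reference) == 0:
        raise ValueError("reference set must be non-empty")
    matched = sum(
        1
        for b in reference.member_sets
        if any(overlap_match(b, q, omega) for q in predicted.member_sets)
    )
    return matched / len(reference)


def evaluate(reference: ComplexSet, predicted: ComplexSet, omega: float = 0.25) -> MetricReport:
    """Full metric report for a predicted set against a reference set."""
    Sn, PPV, Acc = accuracy(reference, predicted)
    precision, recall, f, TP, FP, FN = precision_recall_f(reference, predicted, omega)
    return MetricReport(
        Sn=Sn,
        PPV=PPV,
        Acc=Acc,
        Precision=precision,
        Recall=recall,
        Fmeasure=f,
        FRAC=frac(reference, predicted, omega),
        TP=TP,
        FP=FP,
        FN=FN,
    )


def hypergeom_enrichment(
    universe_size: int,
    group_size: int,
    complex_size: int,
    overlap: int,
    as_printed: bool = False,
) -> float:
    """P-value that a complex of size |q| contains >= x of a functional
    group F drawn from |V| proteins.

    Default: the standard hypergeometric upper tail P(X >= x).  With
    ``as_printed=True`` the cumulative sum starts at y = 1 rather than
    y = 0, i.e. P = 1 - sum_{y=1}^{x-1} C(|F|,y) C(|V|-|F|,|q|-y) / C(|V|,|q|),
    a commonly printed variant that omits the zero-overlap term.
    """
    V, F, q, x = universe_size, group_size, complex_size, overlap
    if not (0 <= x <= min(F, q) <= V and q <= V and F <= V):
        raise ValueError("require 0 <= x <= min(|F|, |q|) <= |V|")
    rv = hypergeom(V, F, q)
    if as_printed:
        y = np.arange(1, x)
        return float(1.0 - rv.pmf(y).sum())
    return float(rv.sf(x - 1))


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected P-value, capped at 1."""
    return min(1.0, p * n_tests)


def prepare_reference(
    raw: ComplexSet,
    input_universe: ProteinUniverse,
    min_size: int = 3,
    exclude: ComplexSet | None = None,
    exclude_omega: float | None = None,
) -> ComplexSet:
    """Reference-set preparation protocol.

    Each complex is restricted to proteins present in the input data;
    complexes falling below ``min_size`` after restriction are dropped;
    when ``exclude`` is given, complexes whose restricted member set
    exactly equals a member set in ``exclude`` are removed (or, with
    ``exclude_omega``, complexes overlap-matching any excluded set).
    """
    excl_sets = set(exclude.member_sets) if exclude is not None else set()
    out: list[tuple[str, frozenset[str]]] = []
    for label, members in raw:
        restricted = frozenset(m for m in members if m in input_universe)
        if len(restricted) < min_size:
            continue
        if exclude is not None:
            if exclude_omega is not None:
                if any(
                    overlap_match(restricted, e, exclude_omega)
                    for e in exclude.member_sets
                ):
                    continue
            elif restricted in excl_sets:
                continue
        out.append((label, restricted))
    return ComplexSet(out)
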