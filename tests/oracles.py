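"""Naive reference implementations used as independent oracles in tests.

Everything here is written index-by-index or set-by-set, with no shared
code paths with the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def masked_kl_loop(W, theta, A, eps=1e-12):
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if theta[i] == 0 or theta[j] == 0:
                continue
            a = max(A[i, j], eps)
            term = -W[i, j] + A[i, j]
            if W[i, j] > 0:
                term += W[i, j] * math.log(W[i, j] / a)
            total += term
    return total


def objective_loop(views, H_c, H_s, lam, eps=1e-12):
    n = H_c.shape[0]
    J = 0.0
    for m, v in enumerate(views):
        for i in range(n):
            for j in range(n):
                if v.theta[i] == 0 or v.theta[j] == 0:
                    continue
                a = sum(H_c[i, l] * H_c[j, l] for l in range(H_c.shape[1]))
                a += sum(
                    H_s[m][i, z] * H_s[m][j, z] for z in range(H_s[m].shape[1])
                )
                J -= v.W[i, j] * math.log(max(a, eps)) - a
    frob = sum(x * x for x in H_c.flat)
    frob += sum(x * x for x in H_s[0].flat) + sum(x * x for x in H_s[1].flat)
    return J + lam * frob


def _recon_entry(H_c, H_sm, i, j):
    a = sum(H_c[i, l] * H_c[j, l] for l in range(H_c.shape[1]))
    a += sum(H_sm[i, z] * H_sm[j, z] for z in range(H_sm.shape[1]))
    return a


def update_shared_loop(views, H_c, H_s, lam, eps=1e-12):
    n, kc = H_c.shape
    out = np.empty_like(H_c)
    for i in range(n):
        for l in range(kc):
            num = 0.0
            den = lam * H_c[i, l]
            for m, v in enumerate(views):
                for j in range(n):
                    t = v.theta[i] * v.theta[j]
                    if t == 0:
                        continue
                    a = max(_recon_entry(H_c, H_s[m], i, j), eps)
                    num += t * v.W[i, j] / a * H_c[j, l]
                    den += t * H_c[j, l]
            out[i, l] = H_c[i, l] / 2 + 0.5 * H_c[i, l] * num / max(den, eps)
    return out


def update_specific_loop(view, H_c, H_s, m, lam, eps=1e-12):
    Hm = H_s[m]
    n, ks = Hm.shape
    out = np.empty_like(Hm)
    for i in range(n):
        for z in range(ks):
            num = 0.0
            den = lam * Hm[i, z]
            for j in range(n):
                t = view.theta[i] * view.theta[j]
                if t == 0:
                    continue
                a = max(_recon_entry(H_c, Hm, i, j), eps)
                num += t * view.W[i, j] / a * Hm[j, z]
                den += t * Hm[j, z]
            out[i, z] = Hm[i, z] / 2 + 0.5 * Hm[i, z] * num / max(den, eps)
    return out


def discretize_row_brute(row):
    """Brute-force largest-gap cut for a single row."""
    row = np.asarray(row, dtype=float)
    K = row.size
    if row.max() == 0:
        return np.zeros(K, dtype=int)
    s = np.sort(row)[::-1]
    best_ki, best_gap = 1, -1.0
    for ki in range(1, K):
        gap = s[ki - 1] - s[ki]
        if gap > best_gap:
            best_gap, best_ki = gap, ki
    return (row >= s[best_ki - 1]).astype(int)


def sn_ppv_acc_sets(refs, preds):
    """Sn/PPV/Acc from first-principles set arithmetic."""
    sn_num = sum(max(len(b & q) for q in preds) for b in refs)
    sn_den = sum(len(b) for b in refs)
    ppv_num = sum(max(len(b & q) for b in refs) for q in preds)
    ppv_den = 0
    for q in preds:
        union = set()
        for b in refs:
            union |= b & q
        ppv_den += len(union)
    sn = sn_num / sn_den
    ppv = ppv_num / ppv_den if ppv_den else 0.0
    return sn, ppv, math.sqrt(sn * ppv)


def match_sets(b, q, omega=0.25):
    return len(b & q) ** 2 / (len(b) * len(q)) >= omega


def prf_sets(refs, preds, omega=0.25):
    tp = sum(1 for q in preds if any(match_sets(b, q, omega) for b in refs))
    fp = len(preds) - tp
    fn = sum(1 for b in refs if not any(match_sets(b, q, omega) for q in preds))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f, tp, fp, fn


def frac_sets(refs, preds, omega=0.25):
    return sum(
        1 for b in refs if any(match_sets(b, q, omega) for q in preds)
    ) / len(refs)


def hypergeom_tail_exact(V, F, q, x):
    """Exact upper tail P(X >= x) via integer combinatorics."""
    num = sum(math.comb(F, y) * math.comb(V - F, q - y) for y in range(x, min(F, q) + 1))
    return num / math.comb(V, q)
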