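"""Naive loop re-implementations of every encoder and statistic.

These are deliberately slow, index-by-index translations of the defining
formulas, independent of the library's vectorized code paths, used as
oracles in unit and acceptance tests.
"""

import math

import numpy as np

from acrstack.encoders import RPSSM_GROUPS, standardized_property_tables
from acrstack.records import AMINO_ACIDS, PSSM_COLUMNS


def naive_aac(seq: str) -> np.ndarray:
    out = np.zeros(20)
    for i, a in enumerate(AMINO_ACIDS):
        out[i] = sum(1 for c in seq if c == a) / len(seq)
    return out


def naive_paac(seq: str, lam: int, omega: float) -> np.ndarray:
    tables = standardized_property_tables()
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    L = len(seq)

    def theta_fn(a: str, b: str) -> float:
        return sum(
            (tables[q][aa_index[b]] - tables[q][aa_index[a]]) ** 2 for q in range(3)
        ) / 3.0

    f = naive_aac(seq)
    thetas = []
    for j in range(1, lam + 1):
        total = sum(theta_fn(seq[i], seq[i + j]) for i in range(L - j))
        thetas.append(total / (L - j))
    denom = f.sum() + omega * sum(thetas)
    return np.array(list(f / denom) + [omega * t / denom for t in thetas])


def naive_pssm_ac(matrix: np.ndarray, G: int) -> np.ndarray:
    L = matrix.shape[0]
    out = []
    for j in range(20):
        mean_j = sum(matrix[i, j] for i in range(L)) / L
        for g in range(1, G + 1):
            s = sum(
                (matrix[i, j] - mean_j) * (matrix[i + g, j] - mean_j)
                for i in range(L - g)
            )
            out.append(s / (L - g))
    return np.array(out)


def naive_reduce_pssm(matrix: np.ndarray) -> np.ndarray:
    L = matrix.shape[0]
    out = np.zeros((L, 10))
    for gi, group in enumerate(RPSSM_GROUPS):
        cols = [PSSM_COLUMNS.index(a) for a in group]
        for i in range(L):
            out[i, gi] = sum(matrix[i, c] for c in cols) / len(cols)
    return out


def naive_rpssm(matrix: np.ndarray) -> np.ndarray:
    r = naive_reduce_pssm(matrix)
    L = r.shape[0]
    pair = []
    for j in range(10):
        for t in range(10):
            s = sum((r[i, j] - r[i + 1, t]) ** 2 / 2.0 for i in range(L - 1))
            pair.append(s / (L - 1))
    cols = []
    for j in range(10):
        mean_j = sum(r[i, j] for i in range(L)) / L
        cols.append(sum((r[i, j] - mean_j) ** 2 for i in range(L)) / L)
    return np.array(pair + cols)


def naive_ssa_score(m1: np.ndarray, m2: np.ndarray) -> float:
    L1, L2 = m1.shape[0], m2.shape[0]
    d = np.zeros((L1, L2))
    for i in range(L1):
        for j in range(L2):
            d[i, j] = sum(abs(m1[i, q] - m2[j, q]) for q in range(m1.shape[1]))
    delta = np.zeros((L1, L2))
    eps = np.zeros((L1, L2))
    for i in range(L1):
        row_z = sum(math.exp(-d[i, k]) for k in range(L2))
        for j in range(L2):
            delta[i, j] = math.exp(-d[i, j]) / row_z
    for j in range(L2):
        col_z = sum(math.exp(-d[k, j]) for k in range(L1))
        for i in range(L1):
            eps[i, j] = math.exp(-d[i, j]) / col_z
    alpha = delta + eps - delta * eps
    A = alpha.sum()
    return float(-(alpha * d).sum() / A)


def naive_confusion(y_true, y_pred):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def naive_auc(y_true, scores) -> float:
    """Mann-Whitney pair statistic with half-credit for ties."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_mrmr(X: np.ndarray, y: np.ndarray, k: int, bins: int = 10) -> list[int]:
    """Exhaustive greedy MID selection using the same discretization rule."""
    from sklearn.metrics import mutual_info_score

    n, p = X.shape
    Xd = np.zeros((n, p), dtype=int)
    for j in range(p):
        lo, hi = X[:, j].min(), X[:, j].max()
        if hi > lo:
            edges = np.linspace(lo, hi, bins + 1)
            Xd[:, j] = np.clip(np.digitize(X[:, j], edges[1:-1]), 0, bins - 1)
    selected: list[int] = []
    while len(selected) < k:
        best, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            rel = mutual_info_score(Xd[:, j], y)
            if selected:
                red = np.mean([mutual_info_score(Xd[:, j], Xd[:, s]) for s in selected])
            else:
                red = 0.0
            score = rel - red
            if score > best_score:  # strict: ties keep the lower index
                best, best_score = j, score
        selected.append(best)
    return selected
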