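"""Independent brute-force oracles used by the test suite.

Everything here is written from the defining formulas, in plain
Python/numpy loops, with no reuse of the package's vectorised
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# graph metric oracles (dense symmetric weight matrix, zero diagonal)


def bf_scale(w: np.ndarray) -> np.ndarray:
    vals = [w[i, j] for i in range(len(w)) for j in range(i + 1, len(w)) if w[i, j] > 0]
    return w / (sum(vals) / len(vals))


def bf_clustering(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Onnela clustering by explicit triple enumeration."""
    n = len(w)
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j, l in itertools.combinations(nbrs, 2):
            if w[j, l] > 0:
                total += (w[i, j] * w[j, l] * w[l, i]) ** (1.0 / 3.0)
        c[i] = 2.0 * total / (k * (k - 1))
    return float(np.mean(c)), c


def bf_shortest_paths(w: np.ndarray, reciprocal: bool = True) -> np.ndarray:
    """Floyd-Warshall with explicit Python loops."""
    n = len(w)
    d = [[0.0 if i == j else math.inf for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i][j] = 1.0 / w[i, j] if reciprocal else w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = d[i][k] + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return np.array(d)


def bf_char_path(d: np.ndarray) -> tuple[float, bool]:
    vals = [d[i][j] for i in range(len(d)) for j in range(len(d)) if i != j]
    finite = [v for v in vals if math.isfinite(v)]
    return sum(finite) / len(finite), len(finite) < len(vals)


def bf_global_eff(d: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(d)
    nodal = np.zeros(n)
    for i in range(n):
        total = 0.0
        for j in range(n):
            if i != j and math.isfinite(d[i][j]) and d[i][j] > 0:
                total += 1.0 / d[i][j]
        nodal[i] = total / (n - 1)
    return float(np.mean(nodal)), nodal


def bf_local_eff(w: np.ndarray, reciprocal: bool = True) -> tuple[float, np.ndarray]:
    n = len(w)
    nodal = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = bf_shortest_paths(sub, reciprocal)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and math.isfinite(d[a][b]) and d[a][b] > 0:
                    total += 1.0 / d[a][b]
        nodal[i] = total / (k * (k - 1))
    return float(np.mean(nodal)), nodal


def random_weighted_matrix(
    rng: np.random.Generator, n: int, p_edge: float = 0.5
) -> np.ndarray:
    """Random symmetric positive-weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.1, 3.0)
    return w


# ---------------------------------------------------------------------------
# statistical oracles (from the defining formulas)


def bf_welch_anova(groups: dict[str, np.ndarray]) -> tuple[float, float, float]:
    """Welch's F*, df1, df2 from the textbook formula."""
    ns = {g: len(v) for g, v in groups.items()}
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    vars_ = {g: float(np.var(v, ddof=1)) for g, v in groups.items()}
    w = {g: ns[g] / vars_[g] for g in groups}
    bigw = sum(w.values())
    k = len(groups)
    mw = sum(w[g] * means[g] for g in groups) / bigw
    num = sum(w[g] * (means[g] - mw) ** 2 for g in groups) / (k - 1)
    a = sum((1 - w[g] / bigw) ** 2 / (ns[g] - 1) for g in groups)
    den = 1 + 2 * (k - 2) / (k**2 - 1) * a
    df2 = (k**2 - 1) / (3 * a)
    return num / den, float(k - 1), df2


def bf_games_howell(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float, float]:
    """(t, df, q) for one Games-Howell pair; p needs the studentized range."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1) / na, np.var(b, ddof=1) / nb
    t = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return float(t), float(df), abs(t) * math.sqrt(2.0)


def bf_levene(groups: dict[str, np.ndarray]) -> float:
    """Levene W (mean-centered) from the defining sums of squares."""
    k = len(groups)
    z = {g: np.abs(v - np.mean(v)) for g, v in groups.items()}
    n = sum(len(v) for v in z.values())
    zbar = sum(float(np.sum(v)) for v in z.values()) / n
    num = sum(len(v) * (float(np.mean(v)) - zbar) ** 2 for v in z.values()) / (k - 1)
    den = sum(float(np.sum((v - np.mean(v)) ** 2)) for v in z.values()) / (n - k)
    return num / den


def bf_bh(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def bf_chisq(table: np.ndarray) -> tuple[float, int]:
    table = np.asarray(table, dtype=float)
    total = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2, (table.shape[0] - 1) * (table.shape[1] - 1)


def bf_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average ranks."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def bf_anova_f(groups: list[np.ndarray]) -> float:
    """Classical one-way ANOVA F from sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    k = len(groups)
    n = len(allv)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def bf_pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(np.sum(x * y) / np.sqrt(np.sum(x**2) * np.sum(y**2)))
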