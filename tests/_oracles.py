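"""Independent brute-force / closed-form oracles used by the test suite.

Each oracle is a deliberately naive reimplementation (full DP tables,
exhaustive enumeration, direct formulas) kept independent of the package
code paths it checks.
"""

from __future__ import annotations

import itertools
from math import ceil

import numpy as np


def lcs_dp_oracle(a, b) -> int:
    """Full-table LCS dynamic program (pure Python)."""
    n, m = len(a), len(b)
    T = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                T[i][j] = T[i - 1][j - 1] + 1
            else:
                T[i][j] = max(T[i - 1][j], T[i][j - 1])
    return T[n][m]


def contains_oracle(elements, seq) -> bool:
    """Pattern containment by exhaustive search over event index choices."""

    def rec(ei, pos):
        if ei == len(elements):
            return True
        need = set(elements[ei])
        for i in range(pos, len(seq)):
            if need <= seq[i][1] and rec(ei + 1, i + 1):
                return True
        return False

    return rec(0, 0)


def brute_force_spade(db, minsup: float, max_len: int, use_istep: bool = True) -> dict:
    """Exhaustive sequential-pattern enumeration with direct containment
    counting: gather every subpattern occurring in any patient, then count
    each pattern's distinct-patient support by scanning all patients."""
    n = len(db)
    msc = ceil(minsup * n)

    def subpatterns(seq, max_items):
        out = set()

        def rec(pos, cur, items):
            if cur:
                out.add(tuple(cur))
            if items >= max_items or pos >= len(seq):
                return
            for i in range(pos, len(seq)):
                itemset = sorted(seq[i][1])
                for r in range(1, len(itemset) + 1):
                    if not use_istep and r > 1:
                        break
                    for c in itertools.combinations(itemset, r):
                        if items + len(c) <= max_items:
                            rec(i + 1, cur + [c], items + len(c))

        rec(0, [], 0)
        return out

    cands = set()
    for seq in db.values():
        cands |= subpatterns(seq, max_len)
    out = {}
    for p in cands:
        sup = sum(1 for seq in db.values() if contains_oracle(p, seq))
        if sup >= msc:
            out[p] = sup
    return out


def random_db(rng: np.random.Generator, n_max=20, vocab_max=5, len_max=6, itemset_max=2):
    """Random itemset-sequence database for miner cross-checks."""
    n = int(rng.integers(2, n_max + 1))
    vocab = [chr(65 + i) for i in range(int(rng.integers(2, vocab_max + 1)))]
    db = {}
    for s in range(n):
        L = int(rng.integers(1, len_max + 1))
        times = sorted(rng.choice(4 * len_max, size=L, replace=False))
        db[f"s{s}"] = [
            (
                int(t),
                frozenset(rng.choice(vocab, size=int(rng.integers(1, min(itemset_max, len(vocab)) + 1)), replace=False)),
            )
            for t in times
        ]
    return db


def naive_average_linkage(D: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) average-linkage agglomeration; returns the merge sequence as
    (cluster A members, cluster B members, merge height)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def silhouette_direct(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette s(i) = (b - a)/max(a, b) by direct evaluation;
    singleton clusters score 0."""
    labels = np.asarray(labels)
    out = np.zeros(len(labels))
    for i in range(len(labels)):
        own = np.flatnonzero((labels == labels[i]))
        if len(own) == 1:
            out[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in own if j != i])
        b = min(
            np.mean([D[i, j] for j in np.flatnonzero(labels == lab)])
            for lab in set(labels)
            if lab != labels[i]
        )
        out[i] = (b - a) / max(a, b)
    return out


def trimester_oracle(t: float, gw: float) -> str:
    start = -7.0 * gw
    if t > 0:
        return "postpartum"
    if t < start:
        return "pre-pregnancy"
    week = int((t - start) // 7) + 1
    if week <= 13:
        return "T1"
    if week <= 27:
        return "T2"
    return "T3"


def chi2_direct(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square Σ(O−E)²/E and its df, straight from the formula."""
    O = np.asarray(table, dtype=float)
    rowsum = O.sum(axis=1, keepdims=True)
    colsum = O.sum(axis=0, keepdims=True)
    E = rowsum @ colsum / O.sum()
    stat = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return stat, df
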