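"""Longest-common-subsequence similarity between clinical event sequences.

The LCS of two token sequences is the longest ordered (not necessarily
contiguous) sequence of tokens they share; a longer LCS means a more
similar course of clinical events.  The normalized distance used for
clustering is d = 1 - LCS(a, b) / norm(|a|, |b|) with the max length as the
default normalizer, keeping d in [0, 1] and penalizing length mismatch.

The pairwise matrix is the O(n^2 * L^2) hot spot of the pipeline; the DP
runs under numba over integer-encoded, padded sequences.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lcs_length", "lcs_distance", "pairwise_distance_matrix", "encode_sequences"]


@njit(cache=True)
def _lcs_len(a: np.ndarray, b: np.ndarray) -> int:
    n, m = len(a), len(b)
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            elif prev[j] >= cur[j - 1]:
                cur[j] = prev[j]
            else:
                cur[j] = cur[j - 1]
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _pairwise(codes: np.ndarray, lengths: np.ndarray, norm_mode: int) -> np.ndarray:
    # norm_mode: 0 = max, 1 = mean, 2 = sum
    n = codes.shape[0]
    maxlen = codes.shape[1]
    D = np.zeros((n, n), dtype=np.float64)
    prev = np.zeros(maxlen + 1, dtype=np.int64)
    cur = np.zeros(maxlen + 1, dtype=np.int64)
    for i in range(n):
        la = lengths[i]
        for j in range(i + 1, n):
            lb = lengths[j]
            for t in range(lb + 1):
                prev[t] = 0
            for ii in range(1, la + 1):
                ai = codes[i, ii - 1]
                cur[0] = 0
                for jj in range(1, lb + 1):
                    if ai == codes[j, jj - 1]:
                        cur[jj] = prev[jj - 1] + 1
                    elif prev[jj] >= cur[jj - 1]:
                        cur[jj] = prev[jj]
                    else:
                        cur[jj] = cur[jj - 1]
                for t in range(lb + 1):
                    prev[t] = cur[t]
            lcs = prev[lb]
            if norm_mode == 0:
                denom = la if la > lb else lb
            elif norm_mode == 1:
                denom = 0.5 * (la + lb)
            else:
                denom = la + lb
            d = 1.0 - lcs / denom
            D[i, j] = d
            D[j, i] = d
    return D


def lcs_length(a, b) -> int:
    """Length of the longest common subsequence of two token sequences."""
    if len(a) == 0 or len(b) == 0:
        return 0
    alphabet = {t: i for i, t in enumerate(dict.fromkeys(list(a) + list(b)))}
    av = np.array([alphabet[t] for t in a], dtype=np.int64)
    bv = np.array([alphabet[t] for t in b], dtype=np.int64)
    return int(_lcs_len(av, bv))


_NORMS = {"max": 0, "mean": 1, "sum": 2}


def lcs_distance(a, b, norm: str = "max") -> float:
    """Normalized LCS distance in [0, 1]; 0 for identical sequences, 1 when
    no token is shared.  Undefined (raises) when both sequences are empty."""
    if len(a) == 0 and len(b) == 0:
        raise ValueError("LCS distance is undefined for two empty sequences")
    if norm not in _NORMS:
        raise ValueError(f"unknown norm {norm!r}; choose from {sorted(_NORMS)}")
    lcs = lcs_length(a, b)
    la, lb = len(a), len(b)
    denom = {"max": max(la, lb), "mean": 0.5 * (la + lb), "sum": la + lb}[norm]
    return 1.0 - lcs / denom


def encode_sequences(sequences: list[list[str]]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode sequences into a padded (n, max_len) array plus lengths."""
    alphabet: dict[str, int] = {}
    for s in sequences:
        for t in s:
            if t not in alphabet:
                alphabet[t] = len(alphabet)
    lengths = np.array([len(s) for s in sequences], dtype=np.int64)
    codes = np.full((len(sequences), max(int(lengths.max()), 1)), -1, dtype=np.int64)
    for i, s in enumerate(sequences):
        for j, t in enumerate(s):
            codes[i, j] = alphabet[t]
    return codes, lengths


def pairwise_distance_matrix(sequences, ids=None, norm: str = "max"):
    """All-pairs LCS distance matrix.

    ``sequences`` is a list of token lists (or a dict id -> PatientSequence /
    token list).  Returns ``(ids, D)`` with D symmetric, zero-diagonal and
    entries in [0, 1].  Every sequence must be non-empty.
    """
    if isinstance(sequences, dict):
        ids = list(sequences.keys())
        seqs = [getattr(v, "tokens", v) for v in sequences.values()]
    else:
        seqs = [getattr(v, "tokens", v) for v in sequences]
        ids = list(ids) if ids is not None else list(range(len(seqs)))
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if any(len(s) == 0 for s in seqs):
        raise ValueError("empty sequences must be filtered out upstream")
    if norm not in _NORMS:
        raise ValueError(f"unknown norm {norm!r}")
    codes, lengths = encode_sequences(seqs)
    D = _pairwise(codes, lengths, _NORMS[norm])
    return ids, D
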