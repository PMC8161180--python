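"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: alignment is a
hand-written Needleman-Wunsch dynamic program (antidiagonal numpy), and
MUM enumeration works from the full pairwise match matrix plus literal
occurrence counting.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def nw_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Global alignment score, linear gap penalty, row-wise DP.

    With a linear gap cost the within-row dependency collapses to a
    running maximum: M[i][j] = max_k (T[k] + gap*(j-k)) where T holds the
    diagonal/vertical candidates, so each row is a cumulative-max pass.
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    j_idx = np.arange(m + 1)
    prev = gap * j_idx.astype(float)  # row 0
    for i in range(1, n + 1):
        T = np.empty(m + 1)
        T[0] = gap * i
        sub = np.where(av[i - 1] == bv, match, mismatch)
        T[1:] = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        cur = np.maximum.accumulate(T - gap * j_idx) + gap * j_idx
        prev = cur
    return float(prev[m])


def best_cyclic_oracle(u: str, v: str) -> float:
    """Exhaustive best normalized score over rotations of either argument
    and both strands; clipped to [0, 1]."""
    denom = min(len(u), len(v))
    best = -np.inf
    for w in (v, rc(v)):
        ww = w + w
        for r in range(len(w)):
            best = max(best, nw_score(u, ww[r : r + len(w)]) / denom)
        uu = u + u
        for r in range(len(u)):
            best = max(best, nw_score(uu[r : r + len(u)], w) / denom)
    return min(1.0, max(0.0, best))


def _count_occurrences(needle: str, hay: str) -> int:
    """Overlapping occurrence count."""
    count = start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _diag_runs(a: str, b: str, min_len: int) -> List[Tuple[int, int, int]]:
    """Maximal exact-match diagonal runs (i, j, length) with length >= min_len."""
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    eq = av[:, None] == bv[None, :]
    runs = []
    n, m = len(a), len(b)
    for d in range(-(n - 1), m):
        diag = np.diagonal(eq, offset=d)
        if diag.size < min_len:
            continue
        padded = np.concatenate(([False], diag, [False])).astype(np.int8)
        delta = np.diff(padded)
        starts = np.nonzero(delta == 1)[0]
        ends = np.nonzero(delta == -1)[0]
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                i = s if d >= 0 else s - d
                j = s + d if d >= 0 else s
                runs.append((int(i), int(j), int(e - s)))
    return runs


def find_mums_oracle(a: str, b: str, min_len: int) -> List[Tuple[int, int, int, str]]:
    """All MUMs between two sequences by brute force.

    Returns (start_a, start_b_forward, length, strand) with 1-based
    positions, strand of the second genome relative to the first, sorted.
    A MUM's substring occurs exactly once in each genome counting both
    strands, and its occurrence pair is a maximal diagonal run.
    """
    results = set()
    for strand, btext in (("+", b), ("-", rc(b))):
        for i, j, L in _diag_runs(a, btext, min_len):
            s = a[i : i + L]
            occ_a = _count_occurrences(s, a) + _count_occurrences(s, rc(a))
            occ_b = _count_occurrences(s, b) + _count_occurrences(s, rc(b))
            if occ_a == 1 and occ_b == 1:
                if strand == "+":
                    jb = j
                else:
                    jb = len(b) - (j + L)
                results.add((i + 1, jb + 1, L, strand))
    return sorted(results)
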