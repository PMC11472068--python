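"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the library's own code paths: the alignment oracle
enumerates every monotone matching explicitly, and the nearest-neighbour
oracle checks all pairs by exhaustive scan.
"""

from __future__ import annotations

import numpy as np


def best_monotone_matching_score(S: np.ndarray) -> float:
    """Maximum total score over all sets of cells strictly increasing in both
    indices, by explicit recursive enumeration (no dynamic programming)."""
    n, m = S.shape
    best = 0.0

    def rec(i0: int, j0: int, acc: float) -> None:
        nonlocal best
        if acc > best:
            best = acc
        for i in range(i0, n):
            for j in range(j0, m):
                rec(i + 1, j + 1, acc + S[i, j])

    rec(0, 0, 0.0)
    return best


def mutual_closest_by_enumeration(
    ref: np.ndarray, qry: np.ndarray, cutoff: float
) -> set[tuple[int, int]]:
    """Exhaustive-scan mutual-nearest-neighbour pairs below the cutoff,
    ties broken to the lower index."""
    out = set()
    for i in range(len(ref)):
        d_i = [float(np.linalg.norm(ref[i] - qry[j])) for j in range(len(qry))]
        j = int(np.argmin(d_i))
        d_j = [float(np.linalg.norm(ref[k] - qry[j])) for k in range(len(ref))]
        if int(np.argmin(d_j)) == i and d_i[j] < cutoff:
            out.add((i, j))
    return out
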