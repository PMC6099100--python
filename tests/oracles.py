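"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: a plain Gotoh
dynamic-programming global aligner (BLOSUM62, affine gaps: the first
residue of a gap costs 11, each further residue 1) with traceback, and
a union-find single-linkage clusterer built from the full identity
matrix.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11.0  # cost of a gap's first residue
GAP_EXTEND = 1.0  # cost of each further residue

NEG = -1e9


def nw_affine_identity(a: str, b: str) -> tuple[float, float]:
    """Optimal global alignment score and identity by explicit DP.

    Identity = identical aligned positions / alignment columns
    (including gaps), from a traceback of one optimal alignment.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - GAP_OPEN, Ix[i - 1, j] - GAP_EXTEND)
            Iy[i, j] = max(M[i, j - 1] - GAP_OPEN, Iy[i, j - 1] - GAP_EXTEND)
    score = max(M[n, m], Ix[n, m], Iy[n, m])

    # traceback one optimal path
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    i, j = n, m
    ident = 0
    cols = 0
    while i > 0 or j > 0:
        if state == 0:
            s = _B62[a[i - 1], b[j - 1]]
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            state_next = int(np.argmax(prev))
            if a[i - 1] == b[j - 1]:
                ident += 1
            i, j = i - 1, j - 1
        elif state == 1:
            if i == 0:
                raise AssertionError("bad traceback")
            if np.isclose(Ix[i, j], M[i - 1, j] - GAP_OPEN):
                state_next = 0
            else:
                state_next = 1
            i -= 1
        else:
            if np.isclose(Iy[i, j], M[i, j - 1] - GAP_OPEN):
                state_next = 0
            else:
                state_next = 2
            j -= 1
        cols += 1
        state = state_next
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return float(score), ident / cols


def single_linkage_clusters(
    records: list[tuple[str, str, str]], cutoff: float
) -> list[frozenset]:
    """Transitive single-linkage partition from the full DP identity matrix."""
    n = len(records)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            _s, ident = nw_affine_identity(records[i][2], records[j][2])
            if ident >= cutoff:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add((records[i][0], records[i][1]))
    return [frozenset(g) for g in groups.values()]
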