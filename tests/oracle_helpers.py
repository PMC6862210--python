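"""Independent brute-force oracles used to cross-check the implementation.

Everything here follows the *textual* definitions directly and slowly:
an O(L^2) double loop for recurrence edges and explicit closed-walk
enumeration for matrix traces.  These functions must stay independent of
the code paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_edges(residues: str, include_dummy: bool = True) -> set[tuple[int, int]]:
    """Edge set of the SRN by direct application of the construction rule.

    Chain edges between consecutive positions; for every position j, an edge
    to the nearest earlier position holding the same residue type; plus the
    dummy pendant (0, 1) when requested.  1-based positions.
    """
    L = len(residues)
    edges: set[tuple[int, int]] = set()
    if include_dummy:
        edges.add((0, 1))
    for i in range(1, L):
        edges.add((i, i + 1))
    for j in range(1, L + 1):  # O(L^2): scan backwards for the nearest match
        for i in range(j - 1, 0, -1):
            if residues[i - 1] == residues[j - 1]:
                edges.add((min(i, j), max(i, j)))
                break
    return edges


def closed_walk_trace(matrix: np.ndarray, k: int) -> float:
    """trace(M^k) as an explicit sum over closed walks of length k.

    Enumerates walks recursively, following only non-zero entries, and sums
    the product of entries along each walk that returns to its start.
    """
    n = matrix.shape[0]
    neighbours = [np.nonzero(matrix[i])[0] for i in range(n)]

    def walk(start: int, current: int, steps_left: int, product: float) -> float:
        if steps_left == 0:
            return product if current == start else 0.0
        total = 0.0
        for nxt in neighbours[current]:
            total += walk(start, int(nxt), steps_left - 1, product * matrix[current, nxt])
        return total

    return sum(walk(a, a, k, 1.0) for a in range(n))


def random_sequences(alphabet: str, max_length: int, count: int, seed: int) -> list[str]:
    """Deterministic random residue strings, lengths 1..max_length."""
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    out = []
    for _ in range(count):
        L = int(rng.integers(1, max_length + 1))
        out.append("".join(rng.choice(letters, size=L)))
    return out
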