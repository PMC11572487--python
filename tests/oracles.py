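"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results through a different route than the
package: an exhaustive Gotoh dynamic program for alignment, a literal
greedy replay for clustering, all-pairs loops for distances.  They are
slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def gotoh_align(a: str, b: str, open_gap: float = 10.0, extend_gap: float = 0.5):
    """Exhaustive affine-gap global alignment with free end gaps.

    Returns (optimal score, column pairs of one optimal alignment).
    A gap of length k costs open + (k-1)*extend; leading and trailing
    gaps are free.  Traceback prefers match > gap-in-b > gap-in-a, so
    the reported pairing is deterministic.
    """
    m, n = len(a), len(b)
    go, ge = -open_gap, -extend_gap

    M = np.full((m + 1, n + 1), NEG)
    Ix = np.full((m + 1, n + 1), NEG)  # gap in b (consume a)
    Iy = np.full((m + 1, n + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = 0.0  # free leading gap in b
    for j in range(1, n + 1):
        Iy[0, j] = 0.0  # free leading gap in a

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] + go, Ix[i - 1, j] + ge)
            Iy[i, j] = max(M[i, j - 1] + go, Iy[i, j - 1] + ge)

    # trailing end gaps are free: best over the last row and column
    best, where = NEG, None
    for i in range(m + 1):
        for mat, name in ((M, "M"), (Ix, "Ix"), (Iy, "Iy")):
            if mat[i, n] > best:
                best, where = mat[i, n], (i, n, name)
    for j in range(n + 1):
        for mat, name in ((M, "M"), (Ix, "Ix"), (Iy, "Iy")):
            if mat[m, j] > best:
                best, where = mat[m, j], (m, j, name)

    # traceback from `where` to (0, 0)
    pairs: list[tuple[int, int]] = []
    i, j, state = where
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            pairs.append((i - 1, j - 1))
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            prev = M[i, j] - s
            for cand_state, cand in (
                ("M", M[i - 1, j - 1]),
                ("Ix", Ix[i - 1, j - 1]),
                ("Iy", Iy[i - 1, j - 1]),
            ):
                if np.isclose(prev, cand):
                    state = cand_state
                    break
            i, j = i - 1, j - 1
        elif state == "Ix":
            if j == 0:
                i = 0  # leading free gap
                break
            if np.isclose(Ix[i, j], M[i - 1, j] + go):
                state = "M"
            i -= 1
        else:  # Iy
            if i == 0:
                j = 0
                break
            if np.isclose(Iy[i, j], M[i, j - 1] + go):
                state = "M"
            j -= 1
    pairs.reverse()
    return float(best), pairs


def gotoh_identity(a: str, b: str) -> float:
    """Identity of one optimal Gotoh alignment, shorter-length denominator."""
    _, pairs = gotoh_align(a, b)
    matches = sum(1 for i, j in pairs if a[i] == b[j] and a[i] != "X")
    return matches / min(len(a), len(b))


def greedy_cluster_replay(records, cutoff: float, identity_fn=gotoh_identity):
    """Literal greedy incremental clustering using an explicit identity table."""
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list = []
    members: list[list[str]] = []
    for rec in order:
        for k, rep in enumerate(reps):
            if identity_fn(rep.sequence, rec.sequence) >= cutoff:
                members[k].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return [(rep.id, tuple(mem)) for rep, mem in zip(reps, members)]


def brute_force_min_distance(atoms_i: np.ndarray, atoms_j: np.ndarray) -> float:
    """Minimum distance by explicit all-pairs loops."""
    best = float("inf")
    for p in atoms_i:
        for q in atoms_j:
            d = float(np.sqrt(((p - q) ** 2).sum()))
            best = min(best, d)
    return best
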