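"""Shared fixtures and independent oracles.

The oracles here (plain-DP edit distance, Needleman-Wunsch and Gotoh
Smith-Waterman implementations) are deliberately written from scratch so
they stay independent of the package's alignment path.
"""

from __future__ import annotations

import numpy as np
import pytest

from igconvert import NamedSequence, Params, ReferenceSet


@pytest.fixture
def params() -> Params:
    return Params()


@pytest.fixture
def tiny_refset() -> ReferenceSet:
    functional = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 nt
    return ReferenceSet(
        functional=NamedSequence("FUNC", functional),
        pseudogenes=(
            NamedSequence("P1", "ACGTACGTTTTTACGTACGTACGTACGTACGTACGTACGT"),
            NamedSequence("P2", "ACGTACGTACGTACGTCCCCACGTACGTACGTACGTACGT"),
        ),
    )


# ---------------------------------------------------------------------------
# oracles


def levenshtein_oracle(a: str, b: str) -> int:
    """Textbook full-matrix edit distance."""
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[n][m]


def smith_waterman_oracle(
    query: str,
    target: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -7.0,
    gap_extend: float = -2.0,
) -> tuple[float, int, int]:
    """Gotoh local alignment: (best score, matches, columns) of one optimal
    traceback with diagonal preference.  gap_open is the score of the first
    gapped position; gap_extend of each additional one."""
    n, m = len(query), len(target)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in target (consume query)
    F = np.full((n + 1, m + 1), NEG)  # gap in query (consume target)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if query[i - 1] == target[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
    best = float(H.max())
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    matches = columns = 0
    state = "H"
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            s = match if query[i - 1] == target[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                matches += query[i - 1] == target[j - 1]
                columns += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == E[i - 1][j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:
            columns += 1
            if F[i][j] == F[i][j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
    return best, matches, columns


def needleman_wunsch_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -7.0,
    gap_extend: float = -2.0,
) -> float:
    """Affine-gap global alignment score (Gotoh), for checking align_global."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0][0] = 0.0
    for i in range(1, n + 1):
        E[i][0] = gap_open + (i - 1) * gap_extend
        H[i][0] = E[i][0]
    for j in range(1, m + 1):
        F[0][j] = gap_open + (j - 1) * gap_extend
        H[0][j] = F[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return float(H[n][m])


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
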