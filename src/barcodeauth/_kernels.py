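"""Numba-jitted dynamic-programming fill for pairwise and profile alignment.

The fill works on a precomputed column-score matrix, so the same kernel serves
sequence-sequence and profile-profile alignment. Tie-breaking is fixed:
diagonal beats a gap in the second sequence ("up"), which beats a gap in the
first ("left") — strict ``>`` comparisons below encode exactly that priority.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DIAG, UP, LEFT = 0, 1, 2


@njit(cache=True)
def nw_fill(scores: np.ndarray, gap: float, free_ends: bool):
    """Fill the Needleman-Wunsch table over a (n, m) column-score matrix.

    ``free_ends`` makes terminal gaps free in both sequences (semiglobal /
    overlap alignment). Returns the score table S (n+1, m+1) and traceback
    table T with codes DIAG/UP/LEFT.
    """
    n, m = scores.shape
    S = np.empty((n + 1, m + 1), np.float64)
    T = np.zeros((n + 1, m + 1), np.uint8)
    S[0, 0] = 0.0
    for i in range(1, n + 1):
        S[i, 0] = 0.0 if free_ends else gap * i
        T[i, 0] = UP
    for j in range(1, m + 1):
        S[0, j] = 0.0 if free_ends else gap * j
        T[0, j] = LEFT
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = S[i - 1, j - 1] + scores[i - 1, j - 1]
            tb = DIAG
            up = S[i - 1, j] + gap
            if up > best:
                best = up
                tb = UP
            left = S[i, j - 1] + gap
            if left > best:
                best = left
                tb = LEFT
            S[i, j] = best
            T[i, j] = tb
    return S, T
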