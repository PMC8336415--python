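"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the aligner oracle is a
plain three-matrix affine-gap DP (checked against exhaustive enumeration at
tiny lengths), and the window oracle is a direct per-rank loop.
"""

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(a, b, gap_open=12.0, gap_extend=2.0):
    """Optimal global affine-gap score; a gap of length L costs
    gap_open + (L - 1) * gap_extend, end gaps penalized."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def enumerate_score(a, b, gap_open=12.0, gap_extend=2.0):
    """Exhaustive enumeration over every global alignment (tiny inputs)."""
    best = [-1e18]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _B62[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if last == "X" else gap_open), "X")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if last == "Y" else gap_open), "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


def loop_window_means(values, half_width, boundaries=None):
    """Direct-loop sliding-window means, missing-aware.

    ``boundaries``: optional list of (start, stop) intervals to truncate
    windows at (per-chromosome mode); default one interval over everything.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if boundaries is None:
        boundaries = [(0, n)]
    out = np.full(n, np.nan)
    for start, stop in boundaries:
        for k in range(start, stop):
            lo = max(k - half_width, start)
            hi = min(k + half_width + 1, stop)
            window = values[lo:hi]
            window = window[np.isfinite(window)]
            if len(window):
                out[k] = window.mean()
    return out
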