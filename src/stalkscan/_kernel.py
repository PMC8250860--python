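"""Numba-compiled affine-gap global alignment with free terminal gaps.

Three-state Gotoh dynamic program. State 0 aligns a residue pair, state 1
consumes a query residue against a gap, state 2 consumes a subject residue
against a gap. Terminal gaps cost nothing: leading gaps via zero-cost
initialisation of the gap states, trailing gaps by taking the best cell on
the last row/column and padding the traceback. When every overlap scores
negative, the optimum is the empty (all-terminal-gap) alignment at 0.

Tie-breaking is pinned everywhere (diagonal > up > left; earlier state
index wins) so that results are bit-reproducible across runs.

The DP rows roll (only the previous row is kept); per-cell traceback
pointers for the three states are packed into one byte (2 bits each).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


@njit(cache=True)
def _fill(a, b, sub, gap_open, gap_ext, free_ends):
    """Roll-row Gotoh fill; returns packed pointers and last row/col scores."""
    n = a.shape[0]
    m = b.shape[0]
    open_cost = gap_open + gap_ext

    prev_m = np.full(m + 1, NEG_INF)
    prev_x = np.full(m + 1, NEG_INF)
    prev_y = np.full(m + 1, NEG_INF)
    cur_m = np.empty(m + 1)
    cur_x = np.empty(m + 1)
    cur_y = np.empty(m + 1)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    # scores of the terminal candidates (last column per row, and last row)
    lastcol_m = np.full(n + 1, NEG_INF)
    lastcol_x = np.full(n + 1, NEG_INF)
    lastcol_y = np.full(n + 1, NEG_INF)

    prev_m[0] = 0.0
    for j in range(1, m + 1):
        # leading gap in a: free, or charged as one affine run
        prev_y[j] = 0.0 if free_ends else -(gap_open + j * gap_ext)

    for i in range(1, n + 1):
        ai = a[i - 1]
        row = sub[ai]
        cur_m[0] = NEG_INF
        cur_x[0] = 0.0 if free_ends else -(gap_open + i * gap_ext)
        cur_y[0] = NEG_INF
        for j in range(1, m + 1):
            # state 0: diagonal; predecessor preference M > X > Y
            dm = prev_m[j - 1]
            dx = prev_x[j - 1]
            dy = prev_y[j - 1]
            p0 = 0
            best0 = dm
            if dx > best0:
                best0 = dx
                p0 = 1
            if dy > best0:
                best0 = dy
                p0 = 2
            best0 += row[b[j - 1]]
            # state 1: gap in b (consume a, move down)
            v0 = prev_m[j] - open_cost
            v1 = prev_x[j] - gap_ext
            v2 = prev_y[j] - open_cost
            p1 = 0
            best1 = v0
            if v1 > best1:
                best1 = v1
                p1 = 1
            if v2 > best1:
                best1 = v2
                p1 = 2
            # state 2: gap in a (consume b, move right)
            w0 = cur_m[j - 1] - open_cost
            w1 = cur_x[j - 1] - open_cost
            w2 = cur_y[j - 1] - gap_ext
            p2 = 0
            best2 = w0
            if w1 > best2:
                best2 = w1
                p2 = 1
            if w2 > best2:
                best2 = w2
                p2 = 2
            cur_m[j] = best0
            cur_x[j] = best1
            cur_y[j] = best2
            ptr[i, j] = p0 | (p1 << 2) | (p2 << 4)
        lastcol_m[i] = cur_m[m]
        lastcol_x[i] = cur_x[m]
        lastcol_y[i] = cur_y[m]
        prev_m, cur_m = cur_m, prev_m
        prev_x, cur_x = cur_x, prev_x
        prev_y, cur_y = cur_y, prev_y
    # prev_* now hold row n
    return ptr, lastcol_m, lastcol_x, lastcol_y, prev_m, prev_x, prev_y


@njit(cache=True)
def align_codes(a, b, sub, gap_open, gap_ext, free_ends=True):
    """Optimal global alignment, free or charged terminal gaps.

    Returns (score, cols_a, cols_b): cols_* hold 0-based residue indices or
    -1 for a gap over the full padded alignment. With free ends the
    terminal cell is the best over the last row/column ((n, m) first, then
    the last column top-down, then the last row left-to-right; state order
    M > X > Y, first strict maximum wins); charged-end alignments always
    terminate at (n, m).
    """
    n = a.shape[0]
    m = b.shape[0]
    ptr, lc_m, lc_x, lc_y, row_m, row_x, row_y = _fill(
        a, b, sub, gap_open, gap_ext, free_ends)

    best = NEG_INF
    bi = n
    bj = m
    bs = 0
    for s in range(3):
        v = (row_m[m], row_x[m], row_y[m])[s]
        if v > best:
            best, bi, bj, bs = v, n, m, s
    if free_ends:
        for i in range(1, n):
            for s in range(3):
                v = (lc_m[i], lc_x[i], lc_y[i])[s]
                if v > best:
                    best, bi, bj, bs = v, i, m, s
        for j in range(1, m):
            for s in range(3):
                v = (row_m[j], row_x[j], row_y[j])[s]
                if v > best:
                    best, bi, bj, bs = v, n, j, s

    cols_a = np.empty(n + m, dtype=np.int32)
    cols_b = np.empty(n + m, dtype=np.int32)
    k = n + m
    if free_ends and best < 0.0:
        # every overlap scores negative: the all-terminal-gap (empty)
        # alignment at score 0 is optimal
        best = 0.0
        bi, bj = 0, 0
    # trailing padding
    ti, tj = n, m
    while ti > bi:
        k -= 1
        cols_a[k] = ti - 1
        cols_b[k] = -1
        ti -= 1
    while tj > bj:
        k -= 1
        cols_a[k] = -1
        cols_b[k] = tj - 1
        tj -= 1
    i, j, s = bi, bj, bs
    while i > 0 and j > 0:
        p = (ptr[i, j] >> (2 * s)) & 3
        k -= 1
        if s == 0:
            cols_a[k] = i - 1
            cols_b[k] = j - 1
            i -= 1
            j -= 1
        elif s == 1:
            cols_a[k] = i - 1
            cols_b[k] = -1
            i -= 1
        else:
            cols_a[k] = -1
            cols_b[k] = j - 1
            j -= 1
        s = p
    while i > 0:
        k -= 1
        cols_a[k] = i - 1
        cols_b[k] = -1
        i -= 1
    while j > 0:
        k -= 1
        cols_a[k] = -1
        cols_b[k] = j - 1
        j -= 1
    return best, cols_a[k:], cols_b[k:]
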