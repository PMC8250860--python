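"""Independent reference implementations used as test oracles.

Everything here is deliberately written with a different algorithmic
strategy from the package (exhaustive enumeration, pure-python matrix
iteration, O(n^3) agglomeration, hypergeometric enumeration) so that
agreement is meaningful.
"""

from __future__ import annotations

import math
from functools import lru_cache


# ---------------------------------------------------------------------------
# exhaustive pairwise alignment (free terminal gaps, affine internal gaps)
# ---------------------------------------------------------------------------

def enumerate_alignments(n: int, m: int):
    """Yield all op strings over D (pair), A (a vs gap), B (gap vs b)."""
    stack = [("", 0, 0)]
    while stack:
        ops, i, j = stack.pop()
        if i == n and j == m:
            yield ops
            continue
        if i < n and j < m:
            stack.append((ops + "D", i + 1, j + 1))
        if i < n:
            stack.append((ops + "A", i + 1, j))
        if j < m:
            stack.append((ops + "B", i, j + 1))


def score_alignment(ops: str, a: str, b: str, sub, gap_open: float,
                    gap_extend: float) -> tuple[float, float]:
    """(score, pid) of one op string under overlap (semiglobal) scoring.

    Exactly one *uniform* gap run is free at each end (a leading run of
    A's xor B's, and likewise trailing): the alignment path enters and
    leaves the DP grid on an edge. Every other gap run costs
    gap_open + len * gap_extend; adjacent A-run and B-run are separate
    runs. pid counts identical D columns over the first..last D span,
    which is also the denominator.
    """
    first = ops.find("D")
    if first == -1:
        return 0.0, 0.0
    # free leading run: maximal uniform prefix of one gap op
    lead = 0
    while lead < len(ops) and ops[lead] == ops[0] and ops[0] != "D":
        lead += 1
    trail = 0
    while trail < len(ops) - lead and ops[-1 - trail] == ops[-1] and ops[-1] != "D":
        trail += 1
    charged = ops[lead:len(ops) - trail]

    last = ops.rfind("D")
    i = ops[:first].count("D") + ops[:first].count("A")
    j = ops[:first].count("D") + ops[:first].count("B")
    ident = 0
    ncols = last - first + 1
    ii, jj = i, j
    for op in ops[first:last + 1]:
        if op == "D":
            if a[ii] == b[jj]:
                ident += 1
            ii += 1
            jj += 1
        elif op == "A":
            ii += 1
        else:
            jj += 1

    score = 0.0
    ci = ops[:lead].count("A")
    cj = ops[:lead].count("B")
    run_char = ""
    run_len = 0
    for op in charged:
        if op == "D":
            if run_len:
                score -= gap_open + run_len * gap_extend
                run_len = 0
                run_char = ""
            score += sub[a[ci]][b[cj]]
            ci += 1
            cj += 1
        else:
            if op != run_char and run_len:
                score -= gap_open + run_len * gap_extend
                run_len = 0
            run_char = op
            run_len += 1
            if op == "A":
                ci += 1
            else:
                cj += 1
    if run_len:
        score -= gap_open + run_len * gap_extend
    return score, 100.0 * ident / ncols


def brute_force_align(a: str, b: str, sub, gap_open: float = 11.0,
                      gap_extend: float = 1.0) -> tuple[float, set[float]]:
    """(optimal score, set of pids among optimal alignments)."""
    best = 0.0       # the empty (all-terminal-gap) alignment
    pids = {0.0}
    for ops in enumerate_alignments(len(a), len(b)):
        s, pid = score_alignment(ops, a, b, sub, gap_open, gap_extend)
        if s > best + 1e-9:
            best = s
            pids = {round(pid, 9)}
        elif abs(s - best) <= 1e-9:
            pids.add(round(pid, 9))
    return best, pids


# ---------------------------------------------------------------------------
# reference MCL (pure python, same pinned rules as the package)
# ---------------------------------------------------------------------------

def reference_mcl(nodes, edges, inflation=1.5, tol=1e-6, prune=1e-5,
                  max_iter=100):
    """Step-by-step matrix-iteration MCL on one graph (list arithmetic).

    ``edges`` is {(u, v): weight}. Returns a sorted list of sorted node
    lists forming a partition.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = [[0.0] * n for _ in range(n)]
    for (u, v), w in edges.items():
        A[idx[u]][idx[v]] = w
        A[idx[v]][idx[u]] = w
    for i in range(n):
        mx = max(A[i])
        A[i][i] = mx if mx > 0 else 1.0
    # column-normalize
    M = [[0.0] * n for _ in range(n)]
    for j in range(n):
        s = sum(A[i][j] for i in range(n))
        for i in range(n):
            M[i][j] = A[i][j] / s
    for _ in range(max_iter):
        prev = [row[:] for row in M]
        # expansion
        E = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
             for i in range(n)]
        # inflation + prune + renormalize
        for i in range(n):
            for j in range(n):
                E[i][j] = E[i][j] ** inflation
                if E[i][j] < prune:
                    E[i][j] = 0.0
        for j in range(n):
            s = sum(E[i][j] for i in range(n)) or 1.0
            for i in range(n):
                E[i][j] /= s
        M = E
        delta = max(abs(M[i][j] - prev[i][j]) for i in range(n) for j in range(n))
        if delta < tol:
            break
    attractors = [i for i in range(n) if M[i][i] > tol] or list(range(n))
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for x in attractors:
        for y in attractors:
            if x < y and (M[x][y] > 0 or M[y][x] > 0):
                rx, ry = find(x), find(y)
                if rx != ry:
                    parent[ry] = rx
    clusters = {}
    for a in attractors:
        clusters.setdefault(find(a), set()).add(nodes[a])
    for j in range(n):
        if j in parent:
            continue
        flows = [(M[a][j], a) for a in attractors]
        best = max(f for f, _ in flows)
        if best <= 0:
            clusters[n + j] = {nodes[j]}
            continue
        cand = [a for f, a in flows if f == best]
        a = min(cand, key=lambda x: nodes[x])
        clusters[find(a)].add(nodes[j])
    return sorted(sorted(c) for c in clusters.values())


# ---------------------------------------------------------------------------
# O(n^3) UPGMA
# ---------------------------------------------------------------------------

def brute_upgma(labels, dist):
    """Average-linkage agglomeration; returns {frozenset(leaves): height}.

    ``dist`` is a {(a, b): d} map with a < b. Heights are half the merge
    distance. Ties: smallest (key_i, key_j) pair, keys being each
    cluster's smallest leaf.
    """
    clusters = {lab: frozenset([lab]) for lab in labels}
    heights = {}
    d = dict(dist)
    while len(clusters) > 1:
        pair = min(d, key=lambda p: (d[p], p))
        a, b = pair
        merged = clusters[a] | clusters[b]
        heights[merged] = d[pair] / 2.0
        na, nb = len(clusters[a]), len(clusters[b])
        del clusters[b]
        others = [k for k in clusters if k not in (a, b)]
        clusters[a] = merged
        for c in others:
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            d[ka] = (na * d[ka] + nb * d[kb]) / (na + nb)
            del d[kb]
        del d[pair]
    return heights


# ---------------------------------------------------------------------------
# Fisher exact via hypergeometric enumeration
# ---------------------------------------------------------------------------

def hypergeom_fisher(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric point masses <= observed."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c

    @lru_cache(maxsize=None)
    def pmf(x: int) -> float:
        return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                / math.comb(n, c1))

    p_obs = pmf(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# naive sliding-window motif matcher
# ---------------------------------------------------------------------------

_STD = set("ACDEFGHIKLMNPQRSTVWY")


def naive_motif_scan(seq: str, pattern: str):
    """All (start, end) 1-based hits of a fixed/x pattern, brute force."""
    hits = []
    for start in range(len(seq)):
        window = seq[start:start + len(pattern)]
        if len(window) < len(pattern):
            break
        ok = True
        for pc, sc in zip(pattern, window):
            if pc == "x":
                if sc not in _STD:
                    ok = False
                    break
            elif sc != pc:
                ok = False
                break
        if ok:
            hits.append((start + 1, start + len(pattern)))
    return hits


# ---------------------------------------------------------------------------
# exhaustive 3-way alignment (unit costs) for the center-star bound
# ---------------------------------------------------------------------------

def optimal_sp_cost3(s1: str, s2: str, s3: str) -> float:
    """Minimal sum-of-pairs cost of a 3-way alignment, by 3D DP.

    Column cost between two symbols: 0 for an identical residue pair or a
    gap-gap pair, 1 otherwise (mismatch or residue-gap).
    """

    def pc(x, y):
        if x is None and y is None:
            return 0
        if x is None or y is None:
            return 1
        return 0 if x == y else 1

    n1, n2, n3 = len(s1), len(s2), len(s3)
    INF = float("inf")
    dp = [[[INF] * (n3 + 1) for _ in range(n2 + 1)] for _ in range(n1 + 1)]
    dp[0][0][0] = 0.0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                cur = dp[i][j][k]
                if cur == INF:
                    continue
                for di in (0, 1):
                    for dj in (0, 1):
                        for dk in (0, 1):
                            if di + dj + dk == 0:
                                continue
                            ni, nj, nk = i + di, j + dj, k + dk
                            if ni > n1 or nj > n2 or nk > n3:
                                continue
                            x = s1[i] if di else None
                            y = s2[j] if dj else None
                            z = s3[k] if dk else None
                            cost = pc(x, y) + pc(x, z) + pc(y, z)
                            if cur + cost < dp[ni][nj][nk]:
                                dp[ni][nj][nk] = cur + cost
    return dp[n1][n2][n3]
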