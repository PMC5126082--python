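"""Independent brute-force oracles used to cross-check the implementations.

Everything here is deliberately naive — exhaustive enumeration, textbook
recurrences written from scratch, dense grids — and never calls the code
path it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_local_score(query: str, subject: str, score, gap_open: int,
                          gap_extend: int) -> float:
    """Optimal local-alignment score by exhaustive recursive enumeration.

    Explores every alignment path from every start cell; a gap of length k
    costs gap_open + k*gap_extend. Exponential — only for tiny strings.
    """
    best = 0.0
    m, n = len(query), len(subject)

    def walk(i: int, j: int, acc: float, state: str) -> None:
        nonlocal best
        if acc > best:
            best = acc
        if i < m and j < n:
            walk(i + 1, j + 1, acc + score(query[i], subject[j]), "m")
        if i < m:
            cost = gap_extend if state == "gq" else gap_open + gap_extend
            walk(i + 1, j, acc - cost, "gq")
        if j < n:
            cost = gap_extend if state == "gs" else gap_open + gap_extend
            walk(i, j + 1, acc - cost, "gs")

    for i in range(m):
        for j in range(n):
            walk(i, j, 0.0, "start")
    return best


def gotoh_local_score(query: str, subject: str, score, gap_open: int,
                      gap_extend: int) -> float:
    """Textbook affine-gap local DP (Gotoh), written independently."""
    m, n = len(query), len(subject)
    neg = float("-inf")
    h = np.zeros((m + 1, n + 1))
    e = np.full((m + 1, n + 1), neg)
    f = np.full((m + 1, n + 1), neg)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e[i][j] = max(h[i][j - 1] - gap_open - gap_extend,
                          e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - gap_open - gap_extend,
                          f[i - 1][j] - gap_extend)
            h[i][j] = max(0.0, h[i - 1][j - 1] + score(query[i - 1], subject[j - 1]),
                          e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def enumerate_global_score(a: str, b: str, score, gap_open: int,
                           gap_extend: int) -> float:
    """Optimal global-alignment score by exhaustive enumeration (tiny inputs)."""
    best = float("-inf")
    m, n = len(a), len(b)

    def walk(i: int, j: int, acc: float, state: str) -> None:
        nonlocal best
        if i == m and j == n:
            best = max(best, acc)
            return
        if i < m and j < n:
            walk(i + 1, j + 1, acc + score(a[i], b[j]), "m")
        if i < m:
            cost = gap_extend if state == "gq" else gap_open + gap_extend
            walk(i + 1, j, acc - cost, "gq")
        if j < n:
            cost = gap_extend if state == "gs" else gap_open + gap_extend
            walk(i, j + 1, acc - cost, "gs")

    walk(0, 0, 0.0, "start")
    return best


def quartet_least_squares(ids, dmat):
    """Best of the 3 unrooted 4-taxon topologies by least-squares branch fit.

    Returns (split_pair, branch_lengths dict) for the winning topology,
    where split_pair is the frozenset of the two ids forming one cherry.
    """
    a, b, c, d = range(4)
    topologies = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    best = None
    for (p, q), (r, s) in topologies:
        # branches: ep, eq, er, es, internal ei
        # design matrix rows = 6 pairwise distances
        pairs = list(itertools.combinations(range(4), 2))
        design = []
        target = []
        for x, y in pairs:
            row = [0.0] * 5
            row[x] += 1
            row[y] += 1
            same_cherry = {x, y} in ({p, q}, {r, s})
            if not same_cherry:
                row[4] = 1
            design.append(row)
            target.append(dmat[x, y])
        sol, residual, *_ = np.linalg.lstsq(np.array(design), np.array(target),
                                            rcond=None)
        fit = np.array(design) @ sol
        rss = float(((fit - np.array(target)) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, frozenset({ids[p], ids[q]}), sol)
    return best[1], best[2]


def brute_force_average_linkage(ids, dmat):
    """Naive agglomeration: repeatedly merge the pair of clusters with the
    smallest unweighted mean pairwise distance. Returns a list of
    (frozenset(members), height) merge steps."""
    clusters = [frozenset([i]) for i in range(len(ids))]
    steps = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                dists = [dmat[i, j] for i in clusters[x] for j in clusters[y]]
                d = sum(dists) / len(dists)
                if best is None or d < best[0] - 1e-12:
                    best = (d, x, y)
        d, x, y = best
        merged = clusters[x] | clusters[y]
        steps.append((frozenset(ids[i] for i in merged), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return steps


def iupac_match_positions(seq: str, consensus: str, code_map) -> list[int]:
    """Position-by-position consensus matching on one strand (1-based)."""
    out = []
    for start in range(len(seq) - len(consensus) + 1):
        if all(seq[start + k] in code_map[c] for k, c in enumerate(consensus)):
            out.append(start + 1)
    return out


def pi_grid_scan(sequence: str, table, step: float = 0.0001) -> float:
    """Dense pH-grid pI: the grid point where net charge changes sign."""
    grid = np.arange(0.0, 14.0 + step, step)
    charge = 1.0 / (1.0 + 10.0 ** (grid - table.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (table.c_terminus - grid))
    for aa in sequence.upper():
        if aa in table.positive:
            charge += 1.0 / (1.0 + 10.0 ** (grid - table.positive[aa]))
        elif aa in table.negative:
            charge -= 1.0 / (1.0 + 10.0 ** (table.negative[aa] - grid))
    idx = int(np.argmax(charge <= 0))
    return float(grid[idx])
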