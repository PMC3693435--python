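"""Independent brute-force reference implementations used only by tests.

These deliberately avoid numpy vectorization and shared code paths with the
package: plain-Python loops over the defining formulas, so they can serve
as oracles for the library's implementations.
"""

import math


def ccc_brute_force(x, y):
    """Lin's CCC from the defining moment formula, by explicit loops."""
    n = len(x)
    xm = sum(x) / n
    ym = sum(y) / n
    sx2 = sum((v - xm) ** 2 for v in x) / n
    sy2 = sum((v - ym) ** 2 for v in y) / n
    sxy = sum((a - xm) * (b - ym) for a, b in zip(x, y)) / n
    return 2.0 * sxy / (sx2 + sy2 + (xm - ym) ** 2)


def kappa_brute_force(a, b, k):
    """Quadratic-weighted kappa from the contingency table, by loops."""
    n = len(a)
    table = [[0] * k for _ in range(k)]
    for i, j in zip(a, b):
        table[i][j] += 1
    p = [[table[i][j] / n for j in range(k)] for i in range(k)]
    pi = [sum(p[i][j] for j in range(k)) for i in range(k)]
    pj = [sum(p[i][j] for i in range(k)) for j in range(k)]
    p_o = 0.0
    p_e = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 - (i - j) ** 2 / (k - 1) ** 2
            p_o += w * p[i][j]
            p_e += w * pi[i] * pj[j]
    if p_e >= 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_table(table):
    """Quadratic-weighted kappa directly from a k x k count table."""
    k = len(table)
    n = sum(sum(row) for row in table)
    a = []
    b = []
    for i in range(k):
        for j in range(k):
            a.extend([i] * table[i][j])
            b.extend([j] * table[i][j])
    assert len(a) == n
    return kappa_brute_force(a, b, k)


def largest_component_brute_force(fg):
    """Largest 8-connected foreground component via explicit flood fill.

    Ties broken toward the component containing the smallest (row, col) in
    lexicographic order. Returns a set of (row, col) pixels.
    """
    rows = len(fg)
    cols = len(fg[0])
    seen = [[False] * cols for _ in range(rows)]
    best = set()
    for i in range(rows):
        for j in range(cols):
            if not fg[i][j] or seen[i][j]:
                continue
            comp = set()
            stack = [(i, j)]
            seen[i][j] = True
            while stack:
                ci, cj = stack.pop()
                comp.add((ci, cj))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = ci + di, cj + dj
                        if (
                            0 <= ni < rows
                            and 0 <= nj < cols
                            and fg[ni][nj]
                            and not seen[ni][nj]
                        ):
                            seen[ni][nj] = True
                            stack.append((ni, nj))
            # Raster-order scan means the first component of any size is the
            # lexicographically smallest; strict > keeps it on ties.
            if len(comp) > len(best):
                best = comp
    return best
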