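"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity along a route disjoint from the
package's implementation: exhaustive search for local alignment, dense
unpruned Markov clustering, sort-and-interpolate percentiles, an ECDF
sweep for the KS statistic, and full hypergeometric enumeration for
Fisher's one-sided p.
"""

from __future__ import annotations

import functools
import math
from math import comb

import numpy as np


def best_local_score(a: str, b: str, matrix, gap_open: int,
                     gap_extend: int) -> float:
    """Exhaustive search over all local alignments (any start, any op path).

    A gap of length k costs gap_open + k*gap_extend; alignments start
    with a match column (an optimal local alignment never gains from
    leading/trailing gaps). Memoised on (i, j, last_op) - the search
    space is unchanged, only repeated subtrees are shared.
    """
    def s(x, y):
        if x == "X" or y == "X":
            return 0.0
        return float(matrix[x, y])

    @functools.lru_cache(maxsize=None)
    def extend(i: int, j: int, last: str) -> float:
        best = 0.0  # stop the alignment here
        if i < len(a) and j < len(b):
            best = max(best, s(a[i], b[j]) + extend(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend + (gap_open if last != "I" else 0)
            best = max(best, -cost + extend(i + 1, j, "I"))
        if j < len(b):
            cost = gap_extend + (gap_open if last != "D" else 0)
            best = max(best, -cost + extend(i, j + 1, "D"))
        return best

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, s(a[i], b[j]) + extend(i + 1, j + 1, "M"))
    extend.cache_clear()
    return best


def mcl_dense(graph, inflation: float, max_iter: int = 200,
              tol: float = 1.0e-8, support_eps: float = 1.0e-4):
    """Whole-matrix dense Markov clustering with no pruning.

    Same self-loop convention as the implementation (loop weight = node's
    max incident edge weight, 1 for isolated nodes); clusters are the
    connected components of the converged support structure.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    loops = m.max(axis=0)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(m, loops)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(m, 2) ** inflation
        new = new / new.sum(axis=0, keepdims=True)
        if np.abs(new - m).max() < tol:
            m = new
            break
        m = new
    support = (m > support_eps) | (m > support_eps).T
    seen = [False] * n
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(nodes[u])
            for v in np.nonzero(support[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        clusters.append(frozenset(comp))
    return clusters


def percentile_linear(values, p: float) -> float:
    """Sort-and-interpolate percentile (linear between order statistics)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    pos = (n - 1) * p / 100.0
    lo = math.floor(pos)
    frac = pos - lo
    if lo + 1 >= n:
        return v[-1]
    return v[lo] * (1.0 - frac) + v[lo + 1] * frac


def ks_statistic_sweep(x, y) -> float:
    """sup |ECDF1 - ECDF2| by sweeping every sample point."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    d = 0.0
    for t in sorted(set(x) | set(y)):
        f1 = sum(1 for v in x if v <= t) / len(x)
        f2 = sum(1 for v in y if v <= t) / len(y)
        d = max(d, abs(f1 - f2))
    return d


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher p by full hypergeometric
    enumeration of the 2x2 tables with the observed margins."""
    row1, col1 = a + b, a + c
    n = a + b + c + d
    denom = comb(n, row1)
    p = 0
    for k in range(a, min(row1, col1) + 1):
        if row1 - k > n - col1:
            continue
        p += comb(col1, k) * comb(n - col1, row1 - k)
    return p / denom


def translate_regex_orf_count(genome: str, min_aa: int,
                              codon_to_aa: dict[str, str]) -> int:
    """Count six-frame stop-free segments >= min_aa via regex on
    independently translated frame strings."""
    import re

    comp = str.maketrans("ACGTN", "TGCAN")
    pattern = re.compile(r"[^*]{%d,}" % min_aa)
    count = 0
    for seq in (genome, genome.translate(comp)[::-1]):
        for f in range(3):
            aas = []
            for i in range(f, len(seq) - 2, 3):
                codon = seq[i:i + 3]
                aas.append(codon_to_aa.get(codon, "X"))
            count += len(pattern.findall("".join(aas)))
    return count
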