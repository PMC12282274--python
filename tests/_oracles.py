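"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
exhaustive enumeration for alignment scores, depth-first search for graph
components, set-partition search for subgroups, per-base boolean arrays for
coverage, and the textbook Welch formula for strain comparisons.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def enumerate_alignment_score(a: str, b: str, scheme) -> float:
    """Optimum over ALL gapped global alignments by exhaustive recursion.

    A maximal gap run of length L costs gap_open + (L-1)*gap_extend; end
    gaps are penalised.  Exponential — only for sequences of length <= ~8.
    """

    def rec(i: int, j: int, prev: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, scheme.score(a[i], b[j]) + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = scheme.gap_extend if prev == 1 else scheme.gap_open
            best = max(best, cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = scheme.gap_extend if prev == 2 else scheme.gap_open
            best = max(best, cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


def recount_identity_coverage(aligned_a: str, aligned_b: str) -> tuple[float, float]:
    """Column-by-column recount of identity and pair coverage."""
    matches = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x != "-" and y != "-" and x == y and x != "X"
    )
    cols = sum(1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-")
    la = len(aligned_a.replace("-", ""))
    lb = len(aligned_b.replace("-", ""))
    identity = 100.0 * matches / cols if cols else 0.0
    return identity, min(100.0 * cols / la, 100.0 * cols / lb)


def dfs_components(
    identity: np.ndarray, coverage: np.ndarray, min_identity: float, min_coverage: float
) -> list[int]:
    """Connected components of the thresholded graph by explicit DFS."""
    n = identity.shape[0]
    adj = [
        [
            j
            for j in range(n)
            if j != i and identity[i, j] >= min_identity and coverage[i, j] >= min_coverage
        ]
        for i in range(n)
    ]
    labels = [-1] * n
    comp = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        while stack:
            v = stack.pop()
            if labels[v] != -1:
                continue
            labels[v] = comp
            stack.extend(adj[v])
        comp += 1
    return labels


def _set_partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def minimal_clique_partition(identity: np.ndarray, threshold: float) -> int:
    """Fewest blocks such that every within-block pair has identity >= threshold.

    Exhaustive search over set partitions; only for n <= ~8.
    """
    n = identity.shape[0]
    best = n
    for part in _set_partitions(list(range(n))):
        ok = all(
            identity[i, j] >= threshold
            for block in part
            for i, j in combinations(block, 2)
        )
        if ok:
            best = min(best, len(part))
    return best


def per_base_covered_pct(intervals: list[tuple[int, int]], length: int) -> float:
    """Coverage by filling a boolean array, one cell per reference base."""
    covered = np.zeros(length, dtype=bool)
    for start, end in intervals:  # 1-based inclusive
        covered[start - 1 : min(end, length)] = True
    return 100.0 * covered.sum() / length


def welch_p_value(xa: np.ndarray, xb: np.ndarray) -> float:
    """Two-sided Welch t-test from the textbook formulas."""
    na, nb = len(xa), len(xb)
    va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
    se2 = va / na + vb / nb
    t = (np.mean(xa) - np.mean(xb)) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def random_additive_tree(rng: np.random.Generator, leaves: list[str]):
    """A random unrooted binary tree with branch lengths in [1, 10].

    Returns (pairwise distance dict keyed by sorted leaf pairs).
    Built by random sequential joins, entirely independent of the NJ code.
    """
    # each active node: dict leaf -> distance to this node
    active = [{leaf: 0.0} for leaf in leaves]
    dists: dict[tuple[str, str], float] = {}

    def join(a: dict, b: dict, la: float, lb: float) -> dict:
        for x, dx in a.items():
            for y, dy in b.items():
                key = (x, y) if x < y else (y, x)
                dists[key] = dx + la + dy + lb
        merged = {x: d + la for x, d in a.items()}
        merged.update({y: d + lb for y, d in b.items()})
        return merged

    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(int(j))
        a = active.pop(int(i))
        active.append(join(a, b, rng.uniform(1, 10), rng.uniform(1, 10)))
    if len(active) == 3:
        c = active.pop()
        b = active.pop()
        a = active.pop()
        la, lb, lc = rng.uniform(1, 10, size=3)
        ab = join(a, b, la, lb)
        join(ab, c, 0.0, lc)
    elif len(active) == 2:
        join(active[0], active[1], rng.uniform(1, 10), rng.uniform(1, 10))
    return dists
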