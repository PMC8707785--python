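"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal method available —
full enumeration for rank-test null distributions, all-subsets search for
covers, textbook Lance–Williams agglomeration for clustering — so they share
no code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import chain, combinations, product

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata


def ranksum_p_enumeration(x, y) -> tuple[float, float]:
    """(two-sided, greater) p by enumerating all rank splits of the pool."""
    x, y = list(x), list(y)
    pooled = np.asarray(x + y, dtype=float)
    n, n_x = len(pooled), len(x)
    ranks = rankdata(pooled)
    obs = ranks[:n_x].sum()
    sums = [ranks[list(c)].sum() for c in combinations(range(n), n_x)]
    total = len(sums)
    ge = sum(s >= obs for s in sums)
    le = sum(s <= obs for s in sums)
    return min(1.0, 2.0 * min(ge / total, le / total)), ge / total


def signedrank_p_enumeration(x, y) -> tuple[float, float]:
    """(two-sided, greater) p by enumerating all 2^n sign patterns."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0, 1.0
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    sums = [sum(r for r, keep in zip(ranks, signs) if keep)
            for signs in product((False, True), repeat=d.size)]
    total = len(sums)
    ge = sum(s >= obs for s in sums)
    le = sum(s <= obs for s in sums)
    return min(1.0, 2.0 * min(ge / total, le / total)), ge / total


def min_cover_all_subsets(values: np.ndarray) -> tuple[int, set[frozenset]]:
    """Minimum covering column subsets of a boolean matrix, by trying every
    subset in ascending size."""
    n_stim, n_cyt = values.shape
    best_size = None
    best: set[frozenset] = set()
    for subset in chain.from_iterable(
            combinations(range(n_cyt), k) for k in range(1, n_cyt + 1)):
        if best_size is not None and len(subset) > best_size:
            break
        if values[:, list(subset)].any(axis=1).all():
            best_size = len(subset)
            best.add(frozenset(subset))
    if best_size is None:
        raise ValueError("no cover exists")
    return best_size, best


def naive_linkage(data: np.ndarray, method: str) -> list[tuple[frozenset, frozenset, float]]:
    """Textbook O(n^3) agglomeration on Euclidean distances.

    Returns the merge sequence as (members_a, members_b, height) with leaf
    indices as members.  At each step the globally closest active pair is
    merged (ties: smallest id pair); distances to the new cluster follow the
    Lance–Williams update for complete or Ward linkage.
    """
    n = len(data)
    dist = {}
    full = squareform(pdist(data, metric="euclidean"))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = full[i, j]
    members = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dist[(min(i, j), max(i, j))]
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((members[i], members[j], d))
        for k in active:
            if k in (i, j):
                continue
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            if method == "complete":
                d_new = max(d_ik, d_jk)
            elif method == "ward":
                ni, nj, nk = sizes[i], sizes[j], sizes[k]
                d_new = np.sqrt(
                    ((ni + nk) * d_ik ** 2 + (nj + nk) * d_jk ** 2
                     - nk * d ** 2) / (ni + nj + nk))
            else:
                raise ValueError(method)
            dist[(min(next_id, k), max(next_id, k))] = d_new
        members[next_id] = members[i] | members[j]
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return merges
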