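"""Independent brute-force oracles used by the test suite only."""

from itertools import combinations

import numpy as np


def midranks(values):
    """Midranks computed from scratch (stable sort + tie averaging)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sv = values[order]
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # ranks are 1-based
        i = j
    return ranks


def kw_h_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from first principles."""
    allv = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = allv.size
    ranks = midranks(allv)
    _, counts = np.unique(allv, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction <= 0:
        return 0.0
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        h += ranks[start : start + k].sum() ** 2 / k
        start += k
    return (12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)) / correction


def kw_permutation_pvalue(groups):
    """Exact permutation p-value: enumerate all group assignments."""
    sizes = [len(g) for g in groups]
    allv = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    h_obs = kw_h_oracle(groups)
    idx = list(range(allv.size))
    count = total = 0
    for first in combinations(idx, sizes[0]):
        rest1 = [i for i in idx if i not in first]
        for second in combinations(rest1, sizes[1]):
            third = [i for i in rest1 if i not in second]
            perm = [allv[list(first)], allv[list(second)], allv[third]]
            total += 1
            if kw_h_oracle(perm) >= h_obs - 1e-12:
                count += 1
    return count / total, total
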