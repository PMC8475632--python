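"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration or direct formula,
sharing no code path with the package implementations they check.
"""

import numpy as np

from strainps.genotype_io import MISSING


def distinct_strings(calls, s, e):
    """Distinct complete allele strings over columns [s, e]."""
    window = calls[:, s : e + 1]
    assigned = ~(window == MISSING).any(axis=1)
    rows = {tuple(r) for r in window[assigned]}
    return len(rows)


def partition_of(calls, s, e):
    """Canonical strain partition over [s, e]; -1 marks unassigned."""
    window = calls[:, s : e + 1]
    labels, mapping = [], {}
    for row in window:
        t = tuple(row)
        if MISSING in t:
            labels.append(-1)
            continue
        if t not in mapping:
            mapping[t] = len(mapping) + 1
        labels.append(mapping[t])
    return tuple(labels)


def enumerate_blocks(calls, min_snps=4, max_h=5):
    """All maximal blocks by exhaustive enumeration of intervals and
    haplotype budgets, with nesting removal.  Returns sorted (s, e) pairs.

    An interval [s, e] is emitted when, for some budget H in {d..max_h}
    (d = its distinct-string count, required in [2, max_h]), extending one
    site right or left would exceed H or the chromosome.
    """
    m = calls.shape[1]
    cand = {}
    for s in range(m):
        for e in range(s + min_snps - 1, m):
            d = distinct_strings(calls, s, e)
            if not 2 <= d <= max_h:
                continue
            d_next = distinct_strings(calls, s, e + 1) if e + 1 < m else None
            d_left = distinct_strings(calls, s - 1, e) if s > 0 else None
            emitted = any(
                (d_next is None or d_next > h)
                and (d_left is None or d_left > h)
                for h in range(d, max_h + 1)
            )
            if emitted:
                cand[(s, e)] = partition_of(calls, s, e)
    keep = []
    for (s, e), part in cand.items():
        nested = any(
            a <= s and b >= e and (a, b) != (s, e) and cand[(a, b)] == part
            for (a, b) in cand
        )
        if not nested:
            keep.append((s, e))
    return sorted(keep)


def anova_by_hand(values, labels):
    """One-way ANOVA sums of squares from first principles."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    ssb = 0.0
    for g in set(labels):
        v = values[labels == g]
        ssb += len(v) * (v.mean() - grand) ** 2
    return ssb, sst - ssb, sst


def bh_by_hand(p):
    """Direct evaluation of the sorted cumulative-minimum step-up formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj_sorted[i] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
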