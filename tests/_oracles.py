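"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the exact-test oracle
enumerates every table with the observed margins using exact integer
binomial coefficients, and the sharing oracle recomputes uniqueness by
explicit set union.
"""
from __future__ import annotations

from bisect import bisect_right
from math import comb

import numpy as np

_REL_TOL = 1e-7


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by exhaustive enumeration with integer arithmetic."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    lo, hi = max(0, k - r2), min(k, r1)
    weights = [comb(r1, x) * comb(r2, k - x) for x in range(lo, hi + 1)]
    denom = comb(n, k)
    obs = weights[a - lo]
    total = sum(w for w in weights if w <= obs + obs * _REL_TOL)
    return min(1.0, total / denom)


def fisher_oracle_margin_sweep(max_margin: int):
    """Yield (a, b, c, d, p_oracle) for every table with row margins <= max_margin.

    Grouped by shared margins so each hypergeometric family is enumerated once;
    per-table p-values come from sorted prefix sums over the family's exact
    integer weights.
    """
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            n = r1 + r2
            for k in range(n + 1):
                lo, hi = max(0, k - r2), min(k, r1)
                if lo > hi:
                    continue
                weights = np.array(
                    [float(comb(r1, x) * comb(r2, k - x)) for x in range(lo, hi + 1)]
                )
                denom = float(comb(n, k))
                order = np.argsort(weights, kind="stable")
                sorted_w = weights[order]
                prefix = np.cumsum(sorted_w)
                degenerate = r1 == 0 or r2 == 0 or k == 0 or k == n
                for a in range(lo, hi + 1):
                    if degenerate:
                        p = 1.0
                    else:
                        obs = weights[a - lo]
                        idx = bisect_right(sorted_w.tolist(), obs + obs * _REL_TOL)
                        p = min(1.0, prefix[idx - 1] / denom)
                    c = k - a
                    yield a, r1 - a, c, r2 - c, p


def sharing_union_oracle(variant_set, panels, source) -> int:
    """Cohort-unique count recomputed as |set| minus the union of per-panel hits."""
    keys = set(variant_set)
    union = set()
    for p in panels:
        if p.source == source and p.af > 0 and p.key in keys:
            union.add(p.key)
    return len(keys) - len(union)
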