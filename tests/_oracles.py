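"""Independent reference implementations used as test oracles.

Everything here is deliberately simple, position-by-position Python:
these functions re-derive expected results by brute force and must stay
independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math


def brute_force_regions(neglog10p, cutoff, max_gap):
    """O(n) per-position scan: maximal above-cutoff runs, gap-merged.

    Returns a list of (start, end) half-open intervals. NaN (masked)
    positions count as sub-threshold.
    """
    regions = []
    cur_start = None
    last_pass = None
    for i, v in enumerate(neglog10p):
        ok = (v is not None) and not math.isnan(v) and v > cutoff
        if ok:
            if cur_start is None:
                cur_start = i
            elif i - last_pass - 1 > max_gap:
                regions.append((cur_start, last_pass + 1))
                cur_start = i
            last_pass = i
    if cur_start is not None:
        regions.append((cur_start, last_pass + 1))
    return regions


def brute_force_auc(neglog10p, start, end, cutoff, mode):
    total = 0.0
    for i in range(start, end):
        v = neglog10p[i]
        if v is None or math.isnan(v):
            continue
        if mode == "above_cutoff":
            total += max(0.0, v - cutoff)
        else:
            total += v
    return total


def welch_test_by_hand(xs, ys):
    """Closed-form Welch t statistic, Satterthwaite df and two-sided p."""
    from scipy import stats

    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2.0 * stats.t.sf(abs(t), df)
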