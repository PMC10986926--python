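"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized/incremental code paths:
plain Python loops, recomputation from scratch at every step.
"""

from __future__ import annotations

import numpy as np


def brute_turning_points(phi) -> list[int]:
    """Alternating extrema via a plain sign-change scan of first differences.

    Plateaus collapse to their first sample; both endpoints included.
    """
    phi = list(map(float, phi))
    n = len(phi)
    if n == 0:
        return []
    if n == 1:
        return [0]
    # keep first index of each run of equal values
    run_starts = [0]
    for i in range(1, n):
        if phi[i] != phi[run_starts[-1]]:
            run_starts.append(i)
    if len(run_starts) == 1:
        return [0]
    out = [run_starts[0]]
    prev_sign = None
    for a, b in zip(run_starts, run_starts[1:]):
        s = 1 if phi[b] > phi[a] else -1
        if prev_sign is not None and s != prev_sign:
            out.append(a)
        prev_sign = s
    out.append(run_starts[-1])
    return out


def brute_prune(values, indices, threshold):
    """Naive smallest-range-first pruning, recomputing everything each pass."""
    vals = list(map(float, values))
    idxs = list(map(int, indices))
    while True:
        if len(vals) < 2:
            break
        ranges = [abs(b - a) for a, b in zip(vals, vals[1:])]
        best = min(range(len(ranges)), key=lambda i: (ranges[i], i))
        if ranges[best] >= threshold:
            break
        if best == 0:
            vals.pop(0)
            idxs.pop(0)
        elif best == len(ranges) - 1:
            vals.pop()
            idxs.pop()
        else:
            vals.pop(best + 1)
            idxs.pop(best + 1)
            vals.pop(best)
            idxs.pop(best)
    return vals, idxs


def brute_detect_cycles(t, phi, threshold, band):
    """Full independent cycle detection; returns (start, peak, end) index triples."""
    tp = brute_turning_points(phi)
    vals, idxs = brute_prune([phi[i] for i in tp], tp, threshold)
    cycles = []
    for k in range(1, len(vals) - 1):
        if not (vals[k] > vals[k - 1] and vals[k] > vals[k + 1]):
            continue
        v_prev, v_next = vals[k - 1], vals[k + 1]
        lo, hi = idxs[k - 1], idxs[k + 1]
        i_start = None
        for i in range(lo, idxs[k] + 1):
            if phi[i] <= v_prev + band:
                i_start = i
        i_end = None
        for i in range(idxs[k], hi + 1):
            if phi[i] <= v_next + band:
                i_end = i
                break
        best_peak, best_val = None, -np.inf
        for i in range(i_start, i_end + 1):
            if phi[i] > best_val:
                best_peak, best_val = i, phi[i]
        cycles.append((i_start, best_peak, i_end))
    return cycles


def brute_classify(bouts, t) -> list[bool]:
    """Per-sample interval-membership test against the active bouts."""
    out = []
    for ti in t:
        out.append(
            any(
                b.kind == "active" and b.start_s <= ti <= b.end_s
                for b in bouts.bouts
            )
        )
    return out


def enumerate_wilcoxon_p(diffs) -> float:
    """Exact two-sided p by enumerating all 2^n sign vectors (n <= ~16).

    Zero differences dropped, |differences| mid-ranked by a naive rank loop.
    """
    d = [float(x) for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = [abs(x) for x in d]
    ranks = []
    for x in absd:
        less = sum(1 for y in absd if y < x)
        equal = sum(1 for y in absd if y == x)
        ranks.append(less + (equal + 1) / 2.0)
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    count_le = count_ge = 0
    for mask in range(1 << n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if w <= w_obs + 1e-12:
            count_le += 1
        if w >= w_obs - 1e-12:
            count_ge += 1
    total = 1 << n
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def random_walk_trace(rng, n=None, step_sd=6.0):
    """A random elevation-like trace on [0, 180] with plateaus and reversals."""
    if n is None:
        n = int(rng.integers(10, 301))
    steps = rng.normal(0.0, step_sd, n)
    # inject occasional plateaus so run-collapse paths are exercised
    plateau = rng.random(n) < 0.15
    steps[plateau] = 0.0
    phi = 60.0 + np.cumsum(steps)
    phi = np.clip(phi, 0.0, 180.0)
    t = np.arange(n) / 20.0
    return t, phi
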