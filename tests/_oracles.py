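"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literal, step-by-step pure-Python loops with
no shortcuts, so that agreement with the package is a meaningful check of
the algorithmic logic rather than of shared code.
"""

from __future__ import annotations

import math
from fractions import Fraction


def oracle_mean_sd(xs):
    n = len(xs)
    m = math.fsum(xs) / n
    if n < 2:
        return m, 0.0
    sd = math.sqrt(math.fsum((v - m) ** 2 for v in xs) / (n - 1))
    return m, sd


def oracle_median(xs):
    s = sorted(xs)
    n = len(s)
    mid = n // 2
    if n % 2:
        return s[mid]
    return (s[mid - 1] + s[mid]) / 2.0


def oracle_median_mad(xs, b=1.4826):
    med = oracle_median(xs)
    mad = oracle_median([abs(v - med) for v in xs])
    return med, b * mad


def oracle_excise(below_flags, k):
    """Trim k samples from each end of every True-run of below_flags."""
    flags = list(below_flags)
    n = len(flags)
    out = list(flags)
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j < n and flags[j]:
            j += 1
        if j - i <= 2 * k:
            for q in range(i, j):
                out[q] = False
        else:
            for q in range(i, i + k):
                out[q] = False
            for q in range(j - k, j):
                out[q] = False
        i = j
    return out


def oracle_iterate(speed, theta_init, lam, tol, max_iter, robust,
                   excise=False, k_excise=0, onset_multiplier=3.0,
                   b=1.4826, spread_floor=1e-9):
    """Literal re-implementation of the adaptive threshold iteration."""
    speed = list(speed)
    theta = float(theta_init)
    history = [theta]
    center = spread = float("nan")
    converged = False
    degenerate = False
    for _ in range(max_iter):
        below = [v < theta for v in speed]
        if excise:
            below = oracle_excise(below, k_excise)
        sel = [v for v, flag in zip(speed, below) if flag]
        if not sel:
            degenerate = True
            break
        if robust:
            c_, s_ = oracle_median_mad(sel, b)
            if s_ < spread_floor:
                c_cl, s_cl = oracle_mean_sd(sel)
                if s_cl > s_:
                    c_, s_ = c_cl, s_cl
        else:
            c_, s_ = oracle_mean_sd(sel)
        new_theta = c_ + lam * s_
        history.append(new_theta)
        center, spread = c_, s_
        if abs(new_theta - theta) < tol:
            theta = new_theta
            converged = True
            break
        theta = new_theta
    theta_onset = (
        center + onset_multiplier * spread if not math.isnan(center) else float("nan")
    )
    return {
        "theta_pt": theta,
        "theta_onset": theta_onset,
        "iterations": len(history) - 1,
        "history": history,
        "converged": converged,
        "degenerate": degenerate,
    }


def oracle_blocks(speed, theta, min_samples):
    """Exhaustive run-length scan for above-threshold blocks."""
    blocks = []
    n = len(speed)
    i = 0
    while i < n:
        if speed[i] > theta:
            j = i
            while j < n and speed[j] > theta:
                j += 1
            if j - i >= min_samples:
                blocks.append((i, j))
            i = j
        else:
            i += 1
    return blocks


def _local_min(speed, j):
    left = speed[j - 1] if j > 0 else float("inf")
    right = speed[j + 1] if j + 1 < len(speed) else float("inf")
    return speed[j] <= left and speed[j] <= right


def oracle_onset(speed, block_start, theta_onset):
    """Exhaustive backward scan: first sub-threshold sample, then the
    nearest local minimum."""
    i = block_start - 1
    while i >= 0 and speed[i] >= theta_onset:
        i -= 1
    if i < 0:
        return 0, True
    for j in range(i, -1, -1):
        if _local_min(speed, j):
            return j, False
    return 0, True


def oracle_offset(speed, block_end, theta_offset):
    """Exhaustive forward scan: first sub-threshold sample, then the
    nearest local minimum."""
    n = len(speed)
    i = block_end
    while i < n and speed[i] >= theta_offset:
        i += 1
    if i >= n:
        return n - 1, True
    for j in range(i, n):
        if _local_min(speed, j):
            return j, False
    return n - 1, True


def oracle_match(true_iv, det_iv, min_overlap=Fraction(1, 5)):
    """Greedy one-to-one interval matching with exact Fraction overlaps.

    ``true_iv`` / ``det_iv`` are lists of half-open (start, end) tuples.
    Returns (tp, fp, fn, pairs) with pairs as (true_index, det_index).
    """
    cands = []
    for i, (ts, te) in enumerate(true_iv):
        for j, (ds, de) in enumerate(det_iv):
            inter = min(te, de) - max(ts, ds)
            if inter <= 0:
                continue
            union = max(te, de) - min(ts, ds)
            iou = Fraction(inter, union)
            if iou > min_overlap:
                cands.append((-iou, ts, ds, i, j))
    cands.sort()
    used_t, used_d, pairs = set(), set(), []
    for _, _, _, i, j in cands:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    return tp, len(det_iv) - tp, len(true_iv) - tp, sorted(pairs)


def oracle_t_one_sample(diffs):
    """Textbook one-sample t statistic against zero."""
    n = len(diffs)
    m = math.fsum(diffs) / n
    s = math.sqrt(math.fsum((d - m) ** 2 for d in diffs) / (n - 1))
    return m / (s / math.sqrt(n))


def oracle_spearman(x, y):
    """Rank (average ranks for ties), then Pearson correlation."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for q in range(i, j + 1):
                r[order[q]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx = math.fsum(rx) / len(rx)
    my = math.fsum(ry) / len(ry)
    num = math.fsum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        math.fsum((a - mx) ** 2 for a in rx) * math.fsum((b - my) ** 2 for b in ry)
    )
    return num / den
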