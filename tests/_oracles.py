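"""Brute-force reference implementations used to cross-check the
preprocessing pipeline.  Deliberately naive (pure loops, explicit linear
algebra) and independent of the package's code paths."""

from __future__ import annotations

import math

import numpy as np


def brute_mask(x, k=3.0, floor=0.01):
    """Flag missing samples and raw-MAD outliers, one comparison at a time."""
    valid = [v for v in x if not math.isnan(v)]
    sv = sorted(valid)
    m = len(sv)
    med = (sv[m // 2] if m % 2 else 0.5 * (sv[m // 2 - 1] + sv[m // 2]))
    dev = sorted(abs(v - med) for v in valid)
    mad = (dev[m // 2] if m % 2 else 0.5 * (dev[m // 2 - 1] + dev[m // 2]))
    thr = max(k * mad, floor)
    return [math.isnan(v) or abs(v - med) > thr for v in x]


def brute_expand(mask, fs, pre_s=0.035, post_s=0.100):
    """Expand every flagged sample by the blink margins (sample-by-sample;
    equivalent to run-based expansion)."""
    back = math.ceil(pre_s * fs)
    fwd = math.ceil(post_s * fs)
    n = len(mask)
    out = [False] * n
    for i, f in enumerate(mask):
        if f:
            for j in range(max(0, i - back), min(n, i + fwd + 1)):
                out[j] = True
    return out


def natural_cubic_interp(xs, ys, xq):
    """Natural cubic spline through (xs, ys) evaluated at xq, via an explicit
    dense linear solve for the second-derivative coefficients."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    n = xs.size
    h = np.diff(xs)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    A[0, 0] = 1.0
    A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 3.0 * ((ys[i + 1] - ys[i]) / h[i] - (ys[i] - ys[i - 1]) / h[i - 1])
    c = np.linalg.solve(A, rhs)
    out = np.empty(len(xq))
    for j, xv in enumerate(np.asarray(xq, float)):
        i = int(np.clip(np.searchsorted(xs, xv, side="right") - 1, 0, n - 2))
        dx = xv - xs[i]
        b = (ys[i + 1] - ys[i]) / h[i] - h[i] * (2.0 * c[i] + c[i + 1]) / 3.0
        d = (c[i + 1] - c[i]) / (3.0 * h[i])
        out[j] = ys[i] + b * dx + c[i] * dx * dx + d * dx ** 3
    return out


def brute_interpolate(t, x, mask):
    """Spec interpolation rule: natural cubic through preserved samples for
    interior gaps, nearest-valid extension at the edges."""
    t = np.asarray(t, float)
    x = np.asarray(x, float).copy()
    mask = np.asarray(mask, bool)
    tv, xv = t[~mask], x[~mask]
    interior = [i for i in np.flatnonzero(mask) if tv[0] <= t[i] <= tv[-1]]
    if interior:
        vals = natural_cubic_interp(tv, xv, t[interior])
        for i, v in zip(interior, vals):
            x[i] = v
    for i in np.flatnonzero(mask):
        if t[i] < tv[0]:
            x[i] = xv[0]
        elif t[i] > tv[-1]:
            x[i] = xv[-1]
    return x


def windowed_max(times, values, lo, hi):
    """Max of values over the half-open window [lo, hi), by scan."""
    best = None
    for tt, vv in zip(times, values):
        if lo <= tt < hi and (best is None or vv > best):
            best = vv
    return best
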