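"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain scalar loops, directly from the
geometric/analytic definitions, and deliberately shares no code with
``koehler`` beyond numpy.  The mask oracle was written against the
stepwise construction on paper before the vectorized implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.special import gammaln


def brute_line_rect(p, q, h, w):
    """Intersections of the line through p=(x,y), q=(x,y) with the border
    rectangle x in [0, w-1], y in [0, h-1]; same-border pairs map to
    themselves."""
    (px, py), (qx, qy) = p, q
    tol = 1e-9
    for pv, qv, val in (
        (px, qx, 0.0), (px, qx, w - 1.0), (py, qy, 0.0), (py, qy, h - 1.0)
    ):
        if abs(pv - val) < tol and abs(qv - val) < tol:
            return [p, q]
    dx, dy = qx - px, qy - py
    cands = []
    if abs(dx) > tol:
        for xb in (0.0, w - 1.0):
            t = (xb - px) / dx
            y = py + t * dy
            if -1e-7 <= y <= h - 1 + 1e-7:
                cands.append((t, xb, min(max(y, 0.0), h - 1.0)))
    if abs(dy) > tol:
        for yb in (0.0, h - 1.0):
            t = (yb - py) / dy
            x = px + t * dx
            if -1e-7 <= x <= w - 1 + 1e-7:
                cands.append((t, min(max(x, 0.0), w - 1.0), yb))
    uniq = []
    for c in sorted(cands):
        if not any(abs(c[1] - u[1]) < 1e-7 and abs(c[2] - u[2]) < 1e-7 for u in uniq):
            uniq.append(c)
    return [(uniq[0][1], uniq[0][2]), (uniq[-1][1], uniq[-1][2])]


def brute_force_mask(points, h, w, reference=100.0):
    """Stepwise four-point deficit mask, computed pixel by pixel.

    ``points``: iterable of (x, y, lstar).  Returns an (h, w) array.
    """
    borders = {"top": [], "bottom": [], "left": [], "right": []}
    for (x1, y1, l1), (x2, y2, l2) in itertools.combinations(points, 2):
        m1, m2 = reference - l1, reference - l2
        norm2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
        for bx, by in brute_line_rect((x1, y1), (x2, y2), h, w):
            t = ((bx - x1) * (x2 - x1) + (by - y1) * (y2 - y1)) / norm2
            mv = m1 + t * (m2 - m1)
            if abs(by) < 1e-7:
                borders["top"].append((bx, mv))
            if abs(by - (h - 1.0)) < 1e-7:
                borders["bottom"].append((bx, mv))
            if abs(bx) < 1e-7:
                borders["left"].append((by, mv))
            if abs(bx - (w - 1.0)) < 1e-7:
                borders["right"].append((by, mv))

    A = [[1.0, x, y] for x, y, _ in points]
    d = [reference - l for _, _, l in points]
    coef, *_ = np.linalg.lstsq(np.array(A), np.array(d), rcond=None)

    def profile(entries, n, fixed, horizontal):
        pairs = [
            (p1, m1, p2, m2)
            for (p1, m1), (p2, m2) in itertools.combinations(entries, 2)
            if abs(p2 - p1) > 1e-7
        ]
        vals = []
        for pos in range(n):
            if pairs:
                acc = [m1 + (pos - p1) * (m2 - m1) / (p2 - p1) for p1, m1, p2, m2 in pairs]
                vals.append(sum(acc) / len(acc))
            elif horizontal:
                vals.append(coef[0] + coef[1] * pos + coef[2] * fixed)
            else:
                vals.append(coef[0] + coef[1] * fixed + coef[2] * pos)
        return vals

    top = profile(borders["top"], w, 0.0, True)
    bottom = profile(borders["bottom"], w, h - 1.0, True)
    left = profile(borders["left"], h, 0.0, False)
    right = profile(borders["right"], h, w - 1.0, False)

    mask = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            v1 = top[x] + (bottom[x] - top[x]) * (y / (h - 1))
            v2 = left[y] + (right[y] - left[y]) * (x / (w - 1))
            mask[y, x] = (v1 + v2) / 2.0
    return mask


def random_point_set(rng, h, w, lo=85.0, hi=100.0):
    """Four distinct, no-three-colinear integer points with random L*."""
    while True:
        pts = rng.integers(0, min(h, w), size=(4, 2))
        if len({tuple(p) for p in pts}) < 4:
            continue
        ok = all(
            abs((q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1])) > 1e-6
            for p, q, r in itertools.combinations(pts, 3)
        )
        if ok:
            L = rng.uniform(lo, hi, 4)
            return [(float(x), float(y), float(l)) for (x, y), l in zip(pts, L)]


def brute_convolve(plane, kernel):
    """Nested-loop 2-D correlation with replicate-edge padding."""
    h, w = plane.shape
    k = kernel.shape[0]
    r = k // 2
    out = np.zeros_like(plane, dtype=float)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    acc += plane[yy, xx] * kernel[dy + r, dx + r]
            out[y, x] = acc
    return out


def f_cdf_quadrature(x, df1, df2):
    """P(F_{df1,df2} <= x) by numerical integration of the density."""
    if x <= 0:
        return 0.0
    logc = (
        gammaln((df1 + df2) / 2.0)
        - gammaln(df1 / 2.0)
        - gammaln(df2 / 2.0)
        + (df1 / 2.0) * math.log(df1 / df2)
    )

    def pdf(t):
        return math.exp(
            logc + (df1 / 2.0 - 1.0) * math.log(t)
            - ((df1 + df2) / 2.0) * math.log1p(df1 * t / df2)
        )

    val, _ = integrate.quad(pdf, 0.0, x, limit=200)
    return min(val, 1.0)
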