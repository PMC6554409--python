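"""Hartigan's dip statistic for unimodality.

The dip of an empirical CDF F_n is the smallest sup-norm distance between
F_n and any unimodal CDF (nondecreasing, convex up to the mode, concave
after it, with at most one atom, at the mode).  It is computed from that
definition directly: for a candidate mode between order statistics, the
left part must admit a convex nondecreasing function and the right part a
concave nondecreasing function inside the band ``[F_n(x)-d, F_n(x^-)+d]``,
and the dip is the smallest feasible ``d``; modes carrying an atom at an
observed value are handled by splitting that point's constraints between
the two pieces.  For tie-free samples the one-sided feasibility radius has
a closed form (half the maximal deviation of the ECDF midpoints from their
convex/concave hull, plus 1/2n), and the optimal split is found by binary
search on the crossing of the two monotone one-sided radii.

Significance is assessed against the uniform null (the asymptotically
least-favourable unimodal distribution for the dip), with sqrt(n) scaling
between the reference bootstrap size and the observed sample size.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit

__all__ = ["dip_statistic", "dip_pvalue"]

_NEG_INF = -1e30


@njit(cache=False)
def _max_dev_convex(u, y, K):
    """max_{j<K} (y_j - lower_hull(y)(u_j)) over points 0..K-1 (tie-free)."""
    if K <= 2:
        return 0.0
    hull = np.empty(K, dtype=np.int64)
    h = 0
    for j in range(K):
        while h >= 2:
            i1, i2 = hull[h - 2], hull[h - 1]
            cross = (u[i2] - u[i1]) * (y[j] - y[i1]) - (u[j] - u[i1]) * (y[i2] - y[i1])
            if cross < 0.0:
                h -= 1
            else:
                break
        hull[h] = j
        h += 1
    best = 0.0
    seg = 0
    for j in range(K):
        while seg < h - 2 and u[hull[seg + 1]] <= u[j]:
            seg += 1
        i1, i2 = hull[seg], hull[seg + 1]
        if u[i2] > u[i1]:
            hy = y[i1] + (y[i2] - y[i1]) * (u[j] - u[i1]) / (u[i2] - u[i1])
        else:
            hy = y[i1]
        d = y[j] - hy
        if d > best:
            best = d
    return best


@njit(cache=False)
def _feas_convex(u, lo, hi):
    """Exists convex nondecreasing phi with lo <= phi(u) <= hi pointwise?

    Lower bounds of -1e30 mean 'unconstrained below'.
    """
    m = len(u)
    if m == 0:
        return True
    # monotone reachability: phi(u_j) <= min_{k>=j} hi_k
    ub = np.empty(m)
    acc = hi[m - 1]
    for j in range(m - 1, -1, -1):
        if hi[j] < acc:
            acc = hi[j]
        ub[j] = acc
    for j in range(m):
        if ub[j] < lo[j]:
            return False
    if m <= 2:
        return True
    # maximal convex minorant of ub = lower convex hull; must clear lo
    hx = np.empty(m)
    hy = np.empty(m)
    h = 0
    for j in range(m):
        while h >= 2:
            cross = (hx[h - 1] - hx[h - 2]) * (ub[j] - hy[h - 2]) \
                - (u[j] - hx[h - 2]) * (hy[h - 1] - hy[h - 2])
            if cross < 0.0:
                h -= 1
            else:
                break
        hx[h] = u[j]
        hy[h] = ub[j]
        h += 1
    seg = 0
    for j in range(m):
        while seg < h - 2 and hx[seg + 1] <= u[j]:
            seg += 1
        if hx[seg + 1] > hx[seg]:
            val = hy[seg] + (hy[seg + 1] - hy[seg]) * (u[j] - hx[seg]) / (hx[seg + 1] - hx[seg])
        else:
            val = hy[seg]
        if val < lo[j] - 1e-12:
            return False
    return True


@njit(cache=False)
def _feas_concave(u, lo, hi):
    """Concave mirror of :func:`_feas_convex` (upper bounds 1e30 = free)."""
    m = len(u)
    u2 = np.empty(m)
    lo2 = np.empty(m)
    hi2 = np.empty(m)
    for j in range(m):
        u2[j] = -u[m - 1 - j]
        lo2[j] = -hi[m - 1 - j]
        hi2[j] = -lo[m - 1 - j]
    return _feas_convex(u2, lo2, hi2)


@njit(cache=False)
def _radius(u, lo, hi, convex, tol=1e-9):
    """Smallest d >= 0 making one side feasible within bands [lo-d, hi+d]."""
    m = len(u)
    if m == 0:
        return 0.0
    a, b = 0.0, 0.6
    ld = np.empty(m)
    hd = np.empty(m)
    for j in range(m):
        ld[j] = lo[j] if lo[j] < -1e29 else lo[j] - a
        hd[j] = hi[j] + a
    ok = _feas_convex(u, ld, hd) if convex else _feas_concave(u, ld, hd)
    if ok:
        return 0.0
    while b - a > tol:
        mid = 0.5 * (a + b)
        for j in range(m):
            ld[j] = lo[j] if lo[j] < -1e29 else lo[j] - mid
            hd[j] = hi[j] + mid
        ok = _feas_convex(u, ld, hd) if convex else _feas_concave(u, ld, hd)
        if ok:
            b = mid
        else:
            a = mid
    return b


@njit(cache=False)
def _atom_value(u, lo, hi, j, m):
    """Dip contribution of a mode with an atom at point j.

    Left piece: convex through points [0, j) plus an upper-only constraint
    at u_j (the pre-jump limit must stay below F_n(u_j^-) + d); right
    piece: concave through points [j, m) with point j's upper band
    tightened to F_n(u_j) + d (the post-jump value tracks F_n at u_j).
    """
    ul = u[: j + 1].copy()
    lol = np.empty(j + 1)
    hil = np.empty(j + 1)
    for k in range(j):
        lol[k] = lo[k]
        hil[k] = hi[k]
    lol[j] = _NEG_INF
    hil[j] = hi[j]
    dl = _radius(ul, lol, hil, True)

    ur = u[j:].copy()
    lor = lo[j:].copy()
    hir = hi[j:].copy()
    hir[0] = lor[0]          # band [lo_j - d, lo_j + d]
    dr = _radius(ur, lor, hir, False)
    return max(dl, dr)


@njit(cache=False)
def _dl(u, lo, hi, y, n_half, K, fast):
    if K <= 0:
        return 0.0
    if fast:
        return n_half + 0.5 * _max_dev_convex(u, y, K)
    return _radius(u[:K], lo[:K], hi[:K], True)


@njit(cache=False)
def _dr(u, lo, hi, y, n_half, K, fast):
    m = len(u)
    if K >= m:
        return 0.0
    if fast:
        u2 = np.empty(m - K)
        y2 = np.empty(m - K)
        for j in range(m - K):
            u2[j] = -u[m - 1 - j]
            y2[j] = -y[m - 1 - j]
        return n_half + 0.5 * _max_dev_convex(u2, y2, m - K)
    return _radius(u[K:], lo[K:], hi[K:], False)


@njit(cache=False)
def _dip_from_bands(u, lo, hi, fast_between):
    """min over mode splits of the one-sided feasibility radii.

    ``fast_between`` enables the closed-form between-split radii valid for
    tie-free samples (unique points, unit counts).
    """
    m = len(u)
    if m <= 1:
        return 0.0
    n_half = 0.5 * (lo[0] - hi[0])     # = 1/(2n) for unit counts
    y = 0.5 * (lo + hi)

    klo, khi = 0, m
    while klo < khi:
        mid = (klo + khi) // 2
        if _dl(u, lo, hi, y, n_half, mid, fast_between) >= \
                _dr(u, lo, hi, y, n_half, mid, fast_between):
            khi = mid
        else:
            klo = mid + 1
    best = 1.0
    k0 = klo - 3 if klo - 3 > 0 else 0
    k1 = klo + 3 if klo + 3 < m else m
    for K in range(k0, k1 + 1):
        v = max(_dl(u, lo, hi, y, n_half, K, fast_between),
                _dr(u, lo, hi, y, n_half, K, fast_between))
        if v < best:
            best = v
    for j in range(k0, k1 + 1):
        if j >= m:
            break
        v = _atom_value(u, lo, hi, j, m)
        if v < best:
            best = v
    return best


def dip_statistic(x) -> float:
    """Hartigan's dip of a 1D sample (0 for degenerate samples)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        return 0.0
    xs = np.sort(x)
    n = xs.size
    if xs[0] == xs[-1]:
        return 0.0
    u, counts = np.unique(xs, return_counts=True)
    cum = np.cumsum(counts)
    lo = cum / n
    hi = (cum - counts) / n
    tie_free = len(u) == n
    return float(_dip_from_bands(u, lo, hi, tie_free))


@njit(cache=False)
def _null_dip_tiefree(u, n):
    lo = (np.arange(n) + 1.0) / n
    hi = np.arange(n) / n
    return _dip_from_bands(u, lo, hi, True)


@lru_cache(maxsize=8)
def _null_dips(n_ref: int, n_boot: int, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    dips = np.empty(n_boot)
    for i in range(n_boot):
        u = np.sort(rng.random(n_ref))
        dips[i] = _null_dip_tiefree(u, n_ref)
    return tuple(np.sort(dips))


def dip_pvalue(dip: float, n: int, n_boot: int = 500, n_ref: int = 10_000,
               seed: int = 12345) -> float:
    """Bootstrap p-value of a dip against the uniform null.

    Null dips are simulated once at a reference sample size and rescaled by
    sqrt(n_ref / n) (the dip decays as 1/sqrt(n) under any fixed unimodal
    null), so arbitrarily long traces can be gated without resampling them.
    """
    n_ref = min(n_ref, max(n, 10))
    null = np.asarray(_null_dips(n_ref, n_boot, seed))
    scaled = dip * np.sqrt(n / n_ref)
    return float((np.sum(null >= scaled) + 1) / (len(null) + 1))
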