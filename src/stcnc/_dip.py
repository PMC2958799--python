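"""Hartigan & Hartigan's dip statistic of unimodality.

The dip of an empirical CDF F_n is the smallest sup-norm distance between
F_n and any distribution function that is unimodal (convex up to some mode,
concave after it).  It is computed with the classical iterative scheme:
fit the greatest convex minorant (GCM) and least concave majorant (LCM) of
F_n over a candidate modal interval, measure their maximal separation,
shrink the modal interval to where that separation occurs, and accumulate
the deviations committed in the trimmed tails, until no improvement is
possible.  All distances are handled in spike-count units and divided by
2n at the end, so the dip of any n-sample is at least 1/(2n).

The core is a tight loop; when numba is importable it is JIT-compiled,
otherwise the identical pure-Python code runs (slower but exact).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic_sorted", "dip_statistic"]


def _dip_core(x: np.ndarray) -> float:
    n = x.shape[0]
    if n < 1:
        return 0.0
    if n <= 3 or x[n - 1] == x[0]:
        return 1.0 / (2.0 * n)
    low = 0
    high = n - 1
    dip = 1.0  # count units; /(2n) on return
    mn = np.empty(n, np.int64)
    mjj = np.empty(n, np.int64)
    gcm = np.empty(n + 1, np.int64)
    lcm = np.empty(n + 1, np.int64)
    while True:
        # support points of the greatest convex minorant on [low, high]
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                if mnj == low:
                    break
                mnmnj = mn[mnj]
                if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                    break
                mn[j] = mnmnj
        # support points of the least concave majorant on [low, high]
        mjj[high] = high
        for j in range(high - 1, low - 1, -1):
            mjj[j] = j + 1
            while True:
                mjk = mjj[j]
                if mjk == high:
                    break
                mjmjk = mjj[mjk]
                if (x[j] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (j - mjk):
                    break
                mjj[j] = mjmjk
        # gcm change points, high -> low
        i = 0
        gcm[0] = high
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i  # gcm[l_gcm] == low
        ig = l_gcm
        ix = l_gcm - 1
        # lcm change points, low -> high
        i = 0
        lcm[0] = low
        while lcm[i] < high:
            lcm[i + 1] = mjj[lcm[i]]
            i += 1
        l_lcm = i  # lcm[l_lcm] == high
        ih = l_lcm
        iv = 1

        # largest separation d between the two fitted curves, walking both
        # sequences of change points upward from the low end
        d = 0.0
        if l_gcm != 1 or l_lcm != 1:
            while True:
                gcm_ix = gcm[ix]
                lcm_iv = lcm[iv]
                if gcm_ix > lcm_iv:
                    # the next point upward comes from the LCM: distance of
                    # that LCM corner to the current GCM segment
                    gcm_i1 = gcm[ix + 1]
                    dx = (lcm_iv - gcm_i1 + 1) - (x[lcm_iv] - x[gcm_i1]) * (
                        gcm_ix - gcm_i1
                    ) / (x[gcm_ix] - x[gcm_i1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # the next point upward comes from the GCM
                    lcm_i1 = lcm[iv - 1]
                    dx = (x[gcm_ix] - x[lcm_i1]) * (lcm_iv - lcm_i1) / (
                        x[lcm_iv] - x[lcm_i1]
                    ) - (gcm_ix - lcm_i1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # deviations of the ECDF committed in the trimmed-off tails
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip_new = dip_u if dip_u > dip_l else dip_l
        if dip < dip_new:
            dip = dip_new
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]
    return dip / (2.0 * n)


try:  # optional JIT; the pure-Python fallback is identical
    from numba import njit as _njit

    _dip_core_jit = _njit(cache=False)(_dip_core)
except Exception:  # pragma: no cover - numba present in the supported env
    _dip_core_jit = _dip_core


def dip_statistic_sorted(x: np.ndarray) -> float:
    """Dip of an already-sorted 1-D sample."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    return float(_dip_core_jit(x))


def dip_statistic(samples: np.ndarray) -> float:
    """Dip statistic of a 1-D sample (sorts a copy).

    Invariant under affine maps of the data and bounded below by 1/(2n).
    """
    x = np.sort(np.asarray(samples, dtype=np.float64).ravel())
    if x.size < 4:
        raise ValueError("dip needs at least 4 observations")
    return dip_statistic_sorted(x)
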