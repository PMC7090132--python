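"""Hartigan's dip statistic and a seeded bootstrap p-value.

The dip of an empirical CDF is the minimal sup-norm distance to the set of
unimodal CDFs (convex below the mode, concave above it, atom allowed only at
the mode).  It is computed with the classic modal-interval iteration: on the
current candidate modal interval form the greatest convex minorant (GCM) of
the lower ECDF corners and the least concave majorant (LCM) of the upper
corners, take the largest gap between the two envelopes, shrink the modal
interval to the envelope touch-points bracketing that gap, and account the
one-sided fitting errors of the ECDF against the envelopes on the two parts
that were cut off.  The dip is half of the largest deviation encountered.

p-values follow Hartigan's original recipe: the null distribution of the dip
is bootstrapped from the uniform distribution (the asymptotically least
favourable unimodal law) at the observed sample size.  Null tables are cached
per sample size because the region-growing loop evaluates thousands of crops
of identical size.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue", "null_dip_table"]

_EPS = 1e-12


def _lower_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Indices of the greatest convex minorant of (xs, ys); xs strictly increasing.

    Jump-to-extreme-slope construction: from the current vertex the next hull
    vertex is the point of minimal chord slope (the farthest one among ties,
    so collinear interior points are skipped).  Vectorised per vertex, which
    is far faster than a monotone chain for the ~log(n)-vertex hulls of
    empirical CDFs.
    """
    idx = [0]
    i, last = 0, xs.size - 1
    while i < last:
        slopes = (ys[i + 1:] - ys[i]) / (xs[i + 1:] - xs[i])
        rev = slopes[::-1]
        j = slopes.size - 1 - int(np.argmin(rev))
        i = i + 1 + j
        idx.append(i)
    return idx


def _upper_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    idx = [0]
    i, last = 0, xs.size - 1
    while i < last:
        slopes = (ys[i + 1:] - ys[i]) / (xs[i + 1:] - xs[i])
        rev = slopes[::-1]
        j = slopes.size - 1 - int(np.argmax(rev))
        i = i + 1 + j
        idx.append(i)
    return idx


def dip_statistic(sample) -> float:
    """Dip statistic of a 1-D sample (ties allowed)."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("dip statistic of an empty sample")
    u, counts = np.unique(x, return_counts=True)
    m = u.size
    if m == 1:
        return 0.0
    n = x.size
    cum = np.cumsum(counts)
    upper = cum / n            # F(u_i)
    lower = (cum - counts) / n  # F(u_i^-)

    lo, hi = 0, m - 1
    best = 0.0
    while True:
        uu = u[lo:hi + 1]
        ll = lower[lo:hi + 1]
        hh = upper[lo:hi + 1]
        g_idx = _lower_hull(uu, ll)
        c_idx = _upper_hull(uu, hh)
        gcm = np.interp(uu, uu[g_idx], ll[g_idx])
        lcm = np.interp(uu, uu[c_idx], hh[c_idx])
        gap = lcm - gcm
        d = float(np.max(gap))
        # first near-maximal index: exact ties arise from interp round-off
        # and must resolve to a hull touch point so the interval shrinks
        i_star = int(np.argmax(gap >= d - 1e-12))
        if d <= best + _EPS:
            break
        new_lo = max(t for t in g_idx if t <= i_star)
        new_hi = min(t for t in c_idx if t >= i_star)
        # One-sided fit errors on the parts cut off the modal interval.  The
        # modal-interval endpoints themselves are excluded: a jump there can
        # be absorbed by an atom at the mode (it re-enters the accounting in
        # later iterations if the interval shrinks past it).
        dl = float(np.max((hh - gcm)[:new_lo])) if new_lo > 0 else 0.0
        du = float(np.max((lcm - ll)[new_hi + 1:])) if new_hi < hi - lo else 0.0
        best = max(best, dl, du)
        if new_lo == 0 and new_hi == hi - lo:
            break
        lo, hi = lo + new_lo, lo + new_hi
    return best / 2.0


_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def null_dip_table(n: int, n_boot: int = 2000, seed: int = 20200317) -> np.ndarray:
    """Sorted bootstrap null distribution of the dip for uniform samples of size n."""
    key = (n, n_boot)
    tab = _NULL_CACHE.get(key)
    if tab is None:
        rng = np.random.default_rng(seed + n)
        dips = np.empty(n_boot)
        for b in range(n_boot):
            dips[b] = dip_statistic(rng.random(n))
        tab = np.sort(dips)
        _NULL_CACHE[key] = tab
    return tab


def dip_pvalue(dip: float, n: int, n_boot: int = 2000) -> float:
    """Bootstrap p-value of an observed dip against the uniform null."""
    tab = null_dip_table(n, n_boot)
    # add-one rule keeps the p-value away from exactly 0
    return (1.0 + np.count_nonzero(tab >= dip)) / (tab.size + 1.0)
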