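"""Independent brute-force oracles used by the test-suite only.

These deliberately re-derive quantities from first principles (exhaustive
search, LP formulations, double loops) so that the package implementations
are checked against code that shares nothing with them.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# Dip statistic oracle: minimal sup-distance from the ECDF to a unimodal CDF.
#
# A unimodal CDF G is convex left of its mode m and concave right of it; an
# atom (jump) is allowed only at m.  For an ECDF with distinct values u_i and
# F(u_i) = c_i, F(u_i^-) = c_lo_i, the optimal G can be taken piecewise
# linear with knots at the u_i, so each mode hypothesis yields a small LP in
# the knot values g_i = G(u_i) minimising the sup deviation d:
#
#   |c_i - g_i| <= d, |c_lo_i - G(u_i^-)| <= d, g monotone in [0, 1],
#   chord slopes nondecreasing on the convex side, nonincreasing after.
#
# Mode hypotheses: mode at/before u_0 (all concave), at/after u_{m-1} (all
# convex), an atom exactly at a knot u_k (G(u_k^-) becomes a free variable),
# or an atom strictly inside a gap (u_k, u_{k+1}) - handled on a fine grid of
# positions, which only ever over-estimates the dip slightly.

def dip_lp_oracle(sample: np.ndarray, n_grid: int = 16) -> tuple[float, float]:
    """Return (lower, upper) bracketing values for the dip of `sample`.

    `upper` is the exact minimum over all mode hypotheses except
    interior-gap atoms, which are explored on a grid; `lower` subtracts
    nothing (the LP values are exact for their hypothesis classes), so the
    true dip lies in [min over grid-refined classes, upper].  In practice the
    interior-atom optimum coincides with a knot-atom optimum and
    upper == dip; the pair lets tests assert a rigorous band.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    u, counts = np.unique(x, return_counts=True)
    m = u.size
    if m == 1:
        return 0.0, 0.0
    c = np.cumsum(counts) / n
    c_lo = c - counts / n

    vals = [
        _mode_lp(u, c, c_lo, convex_upto=-1),          # all concave
        _mode_lp(u, c, c_lo, convex_upto=m - 2),       # all convex
    ]
    for k in range(m):
        vals.append(_atom_lp(u, c, c_lo, k))
    exact = min(vals)
    grid_vals = [exact]
    for k in range(m - 1):
        for t in np.linspace(0.0, 1.0, n_grid + 2)[1:-1]:
            mpos = u[k] + t * (u[k + 1] - u[k])
            grid_vals.append(_interior_lp(u, c, c_lo, k, mpos))
    return min(grid_vals), exact


class _LP:
    def __init__(self, n_extra=0):
        self.m = None
        self.rows, self.rhs = [], []
        self.n_extra = n_extra

    def setup(self, m):
        self.m = m

    def row(self, d_coef, pairs, rhs):
        r = np.zeros(1 + self.m + self.n_extra)
        r[0] = d_coef
        for j, v in pairs:
            r[1 + j] += v
        self.rows.append(r)
        self.rhs.append(rhs)

    def solve(self):
        nv = 1 + self.m + self.n_extra
        cvec = np.zeros(nv)
        cvec[0] = 1.0
        bounds = [(0, None)] + [(0, 1)] * (self.m + self.n_extra)
        res = linprog(cvec, A_ub=np.array(self.rows), b_ub=np.array(self.rhs),
                      bounds=bounds, method="highs")
        return res.fun if res.success else np.inf


def _base_constraints(lp: _LP, c, c_lo, skip_left_limit=()):
    m = c.size
    for i in range(m):
        lp.row(-1.0, [(i, -1.0)], -c[i])        # g_i >= c_i - d
        lp.row(-1.0, [(i, 1.0)], c[i])          # g_i <= c_i + d
        if i not in skip_left_limit:
            lp.row(-1.0, [(i, 1.0)], c_lo[i])   # G(u_i^-) = g_i <= c_lo_i + d
        if i + 1 < m:
            lp.row(0.0, [(i, 1.0), (i + 1, -1.0)], 0.0)     # monotone


def _chord(lp: _LP, du, i, j, convex, end_i=None, end_j=None):
    """slope(chord i) <= slope(chord j) if convex else >=.

    chord t goes u_t -> u_{t+1} with endpoint variables (t, t+1) unless
    overridden by end_i / end_j (variable index of the *upper* endpoint).
    """
    di, dj = du[i], du[j]
    ei = end_i if end_i is not None else i + 1
    ej = end_j if end_j is not None else j + 1
    sgn = 1.0 if convex else -1.0
    # convex: dj*(g_ei - g_i) - di*(g_ej - g_j) <= 0
    lp.row(0.0, [(i, -sgn * dj), (ei, sgn * dj), (j, sgn * di), (ej, -sgn * di)], 0.0)


def _mode_lp(u, c, c_lo, convex_upto):
    """Chords 0..convex_upto form the convex chain, the rest the concave one."""
    m = u.size
    du = np.diff(u)
    lp = _LP()
    lp.setup(m)
    _base_constraints(lp, c, c_lo)
    for i in range(1, convex_upto + 1):
        _chord(lp, du, i - 1, i, convex=True)
    for i in range(convex_upto + 1, m - 2):
        _chord(lp, du, i, i + 1, convex=False)
    return lp.solve()


def _atom_lp(u, c, c_lo, k):
    """Atom exactly at u_k; a = G(u_k^-) is an extra variable."""
    m = u.size
    du = np.diff(u)
    lp = _LP(n_extra=1)
    lp.setup(m)
    ai = m
    _base_constraints(lp, c, c_lo, skip_left_limit={k})
    lp.row(-1.0, [(ai, 1.0)], c_lo[k])           # |c_lo_k - a| <= d
    lp.row(-1.0, [(ai, -1.0)], -c_lo[k])
    if k > 0:
        lp.row(0.0, [(k - 1, 1.0), (ai, -1.0)], 0.0)    # g_{k-1} <= a
    lp.row(0.0, [(ai, 1.0), (k, -1.0)], 0.0)            # a <= g_k
    # convex chords end at (u_k, a)
    for i in range(1, k):
        _chord(lp, du, i - 1, i, convex=True,
               end_i=(ai if i - 1 == k - 1 else None),
               end_j=(ai if i == k - 1 else None))
    # concave chords start at (u_k, g_k)
    for i in range(k, m - 2):
        _chord(lp, du, i, i + 1, convex=False)
    return lp.solve()


def _interior_lp(u, c, c_lo, k, mpos):
    """Atom at mpos inside (u_k, u_{k+1}); j_lo/j_hi are G(mpos^-)/G(mpos)."""
    m = u.size
    du = np.diff(u)
    lp = _LP(n_extra=2)
    lp.setup(m)
    jlo, jhi = m, m + 1
    _base_constraints(lp, c, c_lo)
    lp.row(0.0, [(k, 1.0), (jlo, -1.0)], 0.0)          # g_k <= j_lo
    lp.row(0.0, [(jlo, 1.0), (jhi, -1.0)], 0.0)        # j_lo <= j_hi
    lp.row(0.0, [(jhi, 1.0), (k + 1, -1.0)], 0.0)      # j_hi <= g_{k+1}
    for i in range(1, k):
        _chord(lp, du, i - 1, i, convex=True)
    if k > 0:
        # slope(chord k-1) <= slope(u_k -> mpos)
        dl = mpos - u[k]
        lp.row(0.0, [(k - 1, -dl), (k, dl + du[k - 1]), (jlo, -du[k - 1])], 0.0)
    if k + 1 < m - 1:
        # slope(mpos -> u_{k+1}) >= slope(chord k+1)
        dr = u[k + 1] - mpos
        lp.row(0.0, [(jhi, du[k + 1]), (k + 1, -du[k + 1] - dr), (k + 2, dr)], 0.0)
    for i in range(k + 1, m - 2):
        _chord(lp, du, i, i + 1, convex=False)
    return lp.solve()


# ---------------------------------------------------------------------------
# other oracles


def otsu_bruteforce(values: np.ndarray) -> int:
    """Exhaustive search of the integer cut maximising between-class variance."""
    values = np.asarray(values)
    levels = np.arange(values.min(), values.max() + 1)
    hist = np.bincount(values - values.min(),
                       minlength=levels.size).astype(float)
    p = hist / hist.sum()
    best_t, best_v = levels[0], -np.inf
    for ti in range(levels.size - 1):
        w0 = p[: ti + 1].sum()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (p[: ti + 1] * levels[: ti + 1]).sum() / w0
        m1 = (p[ti + 1:] * levels[ti + 1:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, levels[ti]
    return int(best_t)


def sd_ssd_bruteforce(a: np.ndarray, b: np.ndarray, s: float):
    """Exhaustive double-loop spatial / substantial spatial distance."""
    dab = np.array([np.sqrt(((b - p) ** 2).sum(axis=1)).min() for p in a])
    dba = np.array([np.sqrt(((a - q) ** 2).sum(axis=1)).min() for q in b])
    sd = dab.sum() / (2 * len(a)) + dba.sum() / (2 * len(b))
    Dab = dab[dab > s]
    Dba = dba[dba > s]
    mab = Dab.mean() if Dab.size else 0.0
    mba = Dba.mean() if Dba.size else 0.0
    ssd = mab / 2 + mba / 2
    ssd_pct = 100.0 * (Dab.size + Dba.size) / (len(a) + len(b))
    return sd, ssd, ssd_pct


def prf_bruteforce(a: np.ndarray, b: np.ndarray, s: float,
                   matching: str = "nearest"):
    """Double-loop precision/recall/F under either matching rule."""
    if matching == "nearest":
        prec = np.mean([np.sqrt(((b - p) ** 2).sum(axis=1)).min() <= s for p in a])
        rec = np.mean([np.sqrt(((a - q) ** 2).sum(axis=1)).min() <= s for q in b])
    else:
        pairs = sorted(
            (np.linalg.norm(p - q), i, j)
            for i, p in enumerate(a)
            for j, q in enumerate(b)
        )
        used_a, used_b, tp = set(), set(), 0
        for d, i, j in pairs:
            if d > s:
                break
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            tp += 1
        prec = tp / len(a)
        rec = tp / len(b)
    f = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return float(prec), float(rec), float(f)
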