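"""Background/signal mixture model of confocal pixel statistics.

Photon-counting detectors produce integer intensities y that are well
described, at least locally, by a two-component mixture sharing an integer
system offset K0 (the detector baseline):

* background: a *discrete normal* centred on K0 with variance vB — the sharp
  symmetric peak of empty voxels;
* signal: a *negative binomial* on the excess counts k = y - K0 with size r
  and success probability p — the long overdispersed tail of fluorescent
  voxels.

The mixture pmf is

    psi(y) = alpha * exp(-(y-K0)^2 / (2 vB)) / Z(vB)
           + (1-alpha) * Gamma(k+r) / (k! Gamma(r)) * p^r (1-p)^k,   k = y-K0,

with the signal term zero for y < K0.  The negative binomial is
parameterised through its moments: p = muS/vS and r = muS^2/(vS - muS), so
muS = r(1-p)/p and vS = muS/p.  Fitting is by expectation-maximisation on a
local crop of voxels; the per-voxel posterior probability of *signal*
membership (1 - background responsibility) is the homogeneity predicate used
by the region-growing loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import nbinom

__all__ = [
    "MixtureParams",
    "FitReport",
    "mixture_pdf",
    "moments_to_nb",
    "fit_em",
    "signal_posterior",
]


class UnderdispersionError(ValueError):
    """Signal variance does not exceed the mean; no negative binomial exists."""


@dataclass(frozen=True)
class MixtureParams:
    """The five parameters (K0, vB, alpha, r, p) of the local mixture.

    K0 : int
        Integer system offset (detector baseline), in intensity counts.
    vB : float
        Background variance, counts^2.  Must be positive.
    alpha : float
        Background mixing weight in [0, 1].
    r : float
        Negative-binomial size parameter (> 0).
    p : float
        Negative-binomial success probability in (0, 1].
    """

    K0: int
    vB: float
    alpha: float
    r: float
    p: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not self.vB > 0:
            raise ValueError(f"vB must be > 0, got {self.vB}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.K0 < 0 or self.K0 != int(self.K0):
            raise ValueError(f"K0 must be a non-negative integer, got {self.K0}")

    @property
    def signal_mean(self) -> float:
        """Mean of the signal excess counts, muS = r(1-p)/p."""
        return self.r * (1.0 - self.p) / self.p

    @property
    def signal_var(self) -> float:
        """Variance of the signal excess counts, vS = muS/p."""
        return self.r * (1.0 - self.p) / self.p ** 2


@dataclass
class FitReport:
    """Outcome of an EM fit."""

    params: MixtureParams
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    n_pixels: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)


def moments_to_nb(muS: float, vS: float) -> tuple[float, float]:
    """Invert the signal moments to negative-binomial parameters (p, r)."""
    if not (vS > muS > 0):
        raise UnderdispersionError(
            f"need vS > muS > 0 for a negative binomial, got muS={muS}, vS={vS}"
        )
    p = muS / vS
    r = muS ** 2 / (vS - muS)
    return p, r


def _background_logpmf(y: np.ndarray, K0: int, vB: float) -> np.ndarray:
    """Discrete normal log-pmf on the integer window K0 +/- 6*sqrt(vB)."""
    half = max(1, int(math.ceil(6.0 * math.sqrt(vB))))
    support = np.arange(K0 - half, K0 + half + 1)
    logZ = _logsumexp(-((support - K0) ** 2) / (2.0 * vB))
    out = np.full(np.shape(y), -np.inf, dtype=float)
    y = np.asarray(y)
    inside = (y >= K0 - half) & (y <= K0 + half)
    out[inside] = -((y[inside] - K0) ** 2) / (2.0 * vB) - logZ
    return out


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    return float(m + np.log(np.sum(np.exp(a - m))))


def _signal_logpmf(y: np.ndarray, K0: int, r: float, p: float) -> np.ndarray:
    """Negative-binomial log-pmf on the excess counts; -inf below the offset."""
    y = np.asarray(y)
    out = np.full(y.shape, -np.inf, dtype=float)
    k = y - K0
    ok = k >= 0
    out[ok] = nbinom.logpmf(k[ok], r, p)
    return out


def mixture_pdf(y, params: MixtureParams) -> np.ndarray | float:
    """Probability mass of intensity y under the mixture."""
    scalar = np.isscalar(y)
    y = np.atleast_1d(np.asarray(y))
    lb = _background_logpmf(y, params.K0, params.vB)
    ls = _signal_logpmf(y, params.K0, params.r, params.p)
    with np.errstate(over="ignore"):
        out = params.alpha * np.exp(lb) + (1.0 - params.alpha) * np.exp(ls)
    return float(out[0]) if scalar else out


def _responsibilities(levels, params):
    """Background responsibility alpha_y per intensity level (log-space)."""
    lb = _background_logpmf(levels, params.K0, params.vB) + _safe_log(params.alpha)
    ls = _signal_logpmf(levels, params.K0, params.r, params.p) + _safe_log(1.0 - params.alpha)
    tot = np.logaddexp(lb, ls)
    # a level outside both supports is numerically impossible; call it background
    bad = ~np.isfinite(tot)
    a = np.exp(lb - np.where(bad, 0.0, tot))
    a[bad] = 1.0
    return a, tot


def _safe_log(v: float) -> float:
    return math.log(v) if v > 0 else -np.inf


def signal_posterior(pixels, params: MixtureParams) -> np.ndarray:
    """Per-pixel posterior probability of signal membership, 1 - alpha_y."""
    shape = np.shape(pixels)
    y = np.asarray(pixels).ravel()
    a, _ = _responsibilities(y, params)
    return (1.0 - a).reshape(shape)


def _loglik(levels, weights, params) -> float:
    _, tot = _responsibilities(levels, params)
    # impossible levels get a large finite penalty instead of -inf so the
    # trace stays comparable across K0 candidates
    tot = np.where(np.isfinite(tot), tot, -745.0)
    return float(np.sum(weights * tot))


def _initial_params(levels, weights) -> MixtureParams:
    """Deterministic data-driven start (histogram mode heuristics)."""
    mode = int(levels[np.argmax(weights)])
    below = levels <= mode
    wb = weights[below]
    if wb.sum() > 0:
        vB = float(np.sum(wb * (levels[below] - mode) ** 2) / wb.sum())
    else:
        vB = 1.0
    vB = max(vB, 0.25)
    cut = mode + 2.0 * math.sqrt(vB)
    alpha = float(weights[levels <= cut].sum() / weights.sum())
    alpha = min(max(alpha, 1e-3), 1.0 - 1e-3)
    rest = levels > cut
    wr = weights[rest]
    if wr.sum() > 0:
        k = levels[rest] - mode
        muS = float(np.sum(wr * k) / wr.sum())
        vS = float(np.sum(wr * (k - muS) ** 2) / wr.sum())
    else:
        muS, vS = 1.0, 2.0
    p, r = _clamped_nb(muS, vS)
    return MixtureParams(K0=mode, vB=vB, alpha=alpha, r=r, p=p)


def _clamped_nb(muS: float, vS: float) -> tuple[float, float]:
    muS = max(muS, 1e-6)
    if vS <= muS:
        p = 0.99
        r = muS * p / (1.0 - p)
    else:
        p, r = moments_to_nb(muS, vS)
    return p, r


def fit_em(
    pixels,
    init: MixtureParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FitReport:
    """Fit the mixture to a crop of integer intensities by EM.

    E-step: per-level background responsibilities alpha_y.  M-step: alpha is
    the responsibility mean; (K0, vB) maximise the responsibility-weighted
    background log-likelihood with K0 searched on an integer grid around the
    histogram mode; (p, r) come from responsibility-weighted moments of the
    excess counts.  Because the moment update is not an ascent step, every
    iteration is gated on the observed log-likelihood (generalized EM): a
    candidate that lowers it is reverted, which makes the trace monotone by
    construction.
    """
    y = np.asarray(pixels).ravel()
    if y.size == 0:
        raise ValueError("empty pixel collection")
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
        yi = np.asarray(np.round(y), dtype=np.int64)
        if np.any(yi < 0):
            raise ValueError("intensities must be non-negative integers")
        y = yi
    levels, weights = np.unique(y, return_counts=True)
    weights = weights.astype(float)
    n = y.size

    if levels.size == 1:
        params = MixtureParams(K0=int(levels[0]), vB=0.25, alpha=1.0, r=1.0, p=0.5)
        return FitReport(params=params, loglik_trace=[], n_iter=0,
                         converged=False, n_pixels=n)

    params = init if init is not None else _initial_params(levels, weights)
    mode = int(levels[np.argmax(weights)])
    k0_grid = np.arange(max(0, mode - 10), mode + 11)

    ll = _loglik(levels, weights, params)
    trace = [ll]
    converged = False
    for it in range(max_iter):
        a, _ = _responsibilities(levels, params)
        wa = weights * a
        ws = weights * (1.0 - a)
        sum_wa, sum_ws = wa.sum(), ws.sum()

        alpha_new = min(max(sum_wa / n, 1e-6), 1.0 - 1e-6)

        # (K0, vB): integer grid search maximising the background-restricted
        # log-likelihood under the current responsibilities
        best_k0, best_vb, best_obj = params.K0, params.vB, -np.inf
        for k0 in k0_grid:
            if sum_wa <= 0:
                break
            vb = float(np.sum(wa * (levels - k0) ** 2) / sum_wa)
            vb = max(vb, 0.25)
            lbp = _background_logpmf(levels, int(k0), vb)
            lbp = np.where(np.isfinite(lbp), lbp, -745.0)
            obj = float(np.sum(wa * lbp))
            if obj > best_obj:
                best_k0, best_vb, best_obj = int(k0), vb, obj

        # (p, r): responsibility-weighted method of moments on excess counts
        if sum_ws > 1e-12:
            kk = levels - best_k0
            pos = kk >= 0
            wsp = ws[pos]
            if wsp.sum() > 1e-12:
                muS = float(np.sum(wsp * kk[pos]) / wsp.sum())
                vS = float(np.sum(wsp * (kk[pos] - muS) ** 2) / wsp.sum())
                p_new, r_new = _clamped_nb(muS, vS)
            else:
                p_new, r_new = params.p, params.r
        else:
            p_new, r_new = params.p, params.r

        candidates = [
            MixtureParams(best_k0, best_vb, alpha_new, r_new, p_new),
            # fallbacks preserve monotonicity when a block update overshoots
            MixtureParams(params.K0, params.vB, alpha_new, r_new, p_new),
            MixtureParams(best_k0, best_vb, alpha_new, params.r, params.p),
            MixtureParams(params.K0, params.vB, alpha_new, params.r, params.p),
        ]
        new_params, new_ll = params, ll
        for cand in candidates:
            cll = _loglik(levels, weights, cand)
            if cll >= new_ll:
                new_params, new_ll = cand, cll
                break

        trace.append(new_ll)
        delta = new_ll - ll
        params, ll = new_params, new_ll
        if abs(delta) < tol * max(1.0, abs(ll)):
            converged = True
            break

    params = _prune_spurious_signal(levels, weights, params, ll, n, k0_grid)
    return FitReport(params=params, loglik_trace=trace, n_iter=len(trace) - 1,
                     converged=converged, n_pixels=n)


def _prune_spurious_signal(levels, weights, params, ll, n, k0_grid):
    """Collapse to the background-only model when BIC prefers it.

    On crops of pure background the unconstrained mixture happily spends its
    signal component on the upper half of the normal peak (mixtures are not
    identifiable within one component).  The two extra effective parameters
    (r, p; alpha pinned) must pay for themselves: if the likelihood gain over
    the best single discrete normal is below the BIC penalty, report the
    background-only fit (alpha = 1).
    """
    best_k0, best_vb, best_ll = params.K0, params.vB, -np.inf
    for k0 in k0_grid:
        vb = max(float(np.sum(weights * (levels - k0) ** 2) / n), 0.25)
        lbp = _background_logpmf(levels, int(k0), vb)
        lbp = np.where(np.isfinite(lbp), lbp, -745.0)
        obj = float(np.sum(weights * lbp))
        if obj > best_ll:
            best_k0, best_vb, best_ll = int(k0), vb, obj
    if ll - best_ll < 1.5 * math.log(n):
        return MixtureParams(K0=best_k0, vB=best_vb, alpha=1.0,
                             r=params.r, p=params.p)
    return params
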