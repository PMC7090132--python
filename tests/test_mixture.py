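"""Mixture model: pmf, moment inversion, EM fitting, posteriors."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from smrg.mixture import (MixtureParams, UnderdispersionError, fit_em,
                          mixture_pdf, moments_to_nb, signal_posterior)
from tests_util_simulate import simulate_mixture


def _discrete_normal_pmf(y, K0, vB):
    """Independent re-implementation: normalised Gaussian kernel on integers."""
    half = max(1, math.ceil(6 * math.sqrt(vB)))
    support = np.arange(K0 - half, K0 + half + 1)
    w = np.exp(-((support - K0) ** 2) / (2 * vB))
    z = w.sum()
    out = np.zeros(np.shape(y))
    for i, yi in enumerate(np.atleast_1d(y)):
        if K0 - half <= yi <= K0 + half:
            out[i] = math.exp(-((yi - K0) ** 2) / (2 * vB)) / z
    return out


def _nb_pmf(k, r, p):
    """Independent negative-binomial pmf via log-gamma."""
    k = np.atleast_1d(k).astype(float)
    out = np.zeros(k.shape)
    ok = k >= 0
    out[ok] = np.exp(gammaln(k[ok] + r) - gammaln(k[ok] + 1) - gammaln(r)
                     + r * math.log(p) + k[ok] * math.log1p(-p))
    return out


class TestMixturePdf:
    def test_pure_background_peaks_at_offset_and_normalises(self):
        pars = MixtureParams(K0=100, vB=25.0, alpha=1.0, r=1.0, p=0.5)
        ys = np.arange(0, 250)
        pmf = mixture_pdf(ys, pars)
        assert ys[np.argmax(pmf)] == 100
        assert pmf.sum() == pytest.approx(1.0, abs=1e-6)
        assert mixture_pdf(100, pars) == pytest.approx(
            _discrete_normal_pmf([100], 100, 25.0)[0], rel=1e-9)

    def test_pure_signal_is_negative_binomial_with_mean_r1pp(self):
        pars = MixtureParams(K0=0, vB=1.0, alpha=0.0, r=10.0, p=0.5)
        ys = np.arange(0, 400)
        pmf = mixture_pdf(ys, pars)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-6)
        assert (pmf * ys).sum() == pytest.approx(10.0, abs=1e-6)  # r(1-p)/p

    @pytest.mark.parametrize("y", [50, 60, 110])
    def test_matches_independent_component_sum(self, y):
        pars = MixtureParams(K0=50, vB=16.0, alpha=0.6, r=20.0, p=1 / 3)
        expected = (0.6 * _discrete_normal_pmf([y], 50, 16.0)[0]
                    + 0.4 * _nb_pmf([y - 50], 20.0, 1 / 3)[0])
        assert mixture_pdf(y, pars) == pytest.approx(expected, rel=1e-9)

    def test_no_signal_mass_below_offset(self):
        pars = MixtureParams(K0=50, vB=4.0, alpha=0.0, r=5.0, p=0.5)
        assert mixture_pdf(49, pars) == 0.0

    @pytest.mark.parametrize("pars", [
        MixtureParams(30, 9.0, 0.2, 4.0, 0.7),
        MixtureParams(0, 2.0, 0.9, 30.0, 0.25),
        MixtureParams(120, 50.0, 0.5, 2.5, 0.05),
    ])
    def test_pmf_sums_to_one(self, pars):
        # full integer support: the background component extends below K0
        lo = pars.K0 - int(10 * math.sqrt(pars.vB)) - 2
        hi = pars.K0 + int(pars.signal_mean + 40 * math.sqrt(pars.signal_var + pars.vB))
        total = mixture_pdf(np.arange(lo, hi), pars).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            MixtureParams(K0=10, vB=0.0, alpha=0.5, r=1.0, p=0.5)
        with pytest.raises(ValueError):
            MixtureParams(K0=10, vB=1.0, alpha=1.5, r=1.0, p=0.5)
        with pytest.raises(ValueError):
            MixtureParams(K0=10, vB=1.0, alpha=0.5, r=-1.0, p=0.5)
        with pytest.raises(ValueError):
            MixtureParams(K0=10, vB=1.0, alpha=0.5, r=1.0, p=0.0)
        with pytest.raises(ValueError):
            MixtureParams(K0=-3, vB=1.0, alpha=0.5, r=1.0, p=0.5)


class TestMomentsToNb:
    @pytest.mark.parametrize("muS,vS,p,r", [
        (10.0, 20.0, 0.5, 10.0),
        (40.0, 120.0, 1 / 3, 20.0),
    ])
    def test_known_inversions(self, muS, vS, p, r):
        got_p, got_r = moments_to_nb(muS, vS)
        assert got_p == pytest.approx(p, rel=1e-12)
        assert got_r == pytest.approx(r, rel=1e-12)

    def test_roundtrip_is_algebraic_inverse(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            muS = rng.uniform(1, 80)
            vS = muS * rng.uniform(1.01, 5)
            p, r = moments_to_nb(muS, vS)
            assert r * (1 - p) / p == pytest.approx(muS, rel=1e-12)
            assert r * (1 - p) / p ** 2 == pytest.approx(vS, rel=1e-12)

    def test_underdispersion_rejected(self):
        with pytest.raises(UnderdispersionError):
            moments_to_nb(10.0, 10.0)
        with pytest.raises(UnderdispersionError):
            moments_to_nb(0.0, 5.0)


class TestFitEm:
    def test_pure_background_yields_alpha_near_one(self):
        rng = np.random.default_rng(123)
        y = np.clip(100 + np.round(rng.normal(0, 5, 3072)).astype(int), 0, None)
        report = fit_em(y)
        assert report.params.alpha >= 0.95

    def test_parameter_recovery_from_generative_model(self):
        true = MixtureParams(K0=100, vB=25.0, alpha=0.7, r=20.0, p=1 / 3)
        hits = 0
        for s in range(12):
            y = simulate_mixture(true, 3072, np.random.default_rng(s))
            est = fit_em(y).params
            if (abs(est.alpha - 0.7) <= 0.05 and abs(est.K0 - 100) <= 2
                    and abs(est.signal_mean - 40) <= 4):
                hits += 1
        assert hits >= 11

    def test_loglik_trace_monotone(self):
        rng = np.random.default_rng(9)
        for s in range(5):
            pars = MixtureParams(K0=int(rng.integers(20, 150)),
                                 vB=rng.uniform(4, 40),
                                 alpha=rng.uniform(0.3, 0.95),
                                 r=rng.uniform(3, 60), p=rng.uniform(0.2, 0.8))
            y = simulate_mixture(pars, 2048, rng)
            tr = np.asarray(fit_em(y).loglik_trace)
            assert np.all(np.diff(tr) >= -1e-8)

    def test_degenerate_constant_crop_flagged(self):
        report = fit_em(np.full(4096, 7))
        assert not report.converged
        assert report.params.alpha == 1.0

    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError):
            fit_em(np.array([-1, 4, 5]))


class TestSignalPosterior:
    pars = MixtureParams(K0=100, vB=25.0, alpha=0.95, r=40.0, p=0.5)

    def test_background_peak_has_low_posterior(self):
        assert signal_posterior([100], self.pars)[0] < 0.05

    def test_far_tail_has_posterior_one(self):
        assert signal_posterior([250], self.pars)[0] == pytest.approx(1.0, abs=1e-9)

    def test_complements_background_responsibility(self):
        ys = np.arange(60, 260)
        post = signal_posterior(ys, self.pars)
        assert np.all((post >= 0) & (post <= 1))
        # posterior + background responsibility = 1 by construction
        from smrg.mixture import _responsibilities
        a, _ = _responsibilities(ys, self.pars)
        assert np.allclose(post + a, 1.0)

    def test_monotone_in_intensity_above_offset(self):
        ys = np.arange(100, 220)
        post = signal_posterior(ys, self.pars)
        assert np.all(np.diff(post) >= -1e-12)
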