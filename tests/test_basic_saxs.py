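"""Guinier analysis, Kratky transform, D_max estimation and MEM P(r)."""

import numpy as np
import pytest

from saxsemble import (BeadModel, GuinierResult, SaxsProfile, debye_profile,
                       estimate_dmax, guinier_fit, invert_pr_mem,
                       kratky_dimensionless)
from saxsemble.basic import GuinierError
from saxsemble.mem import maxent_fit

from conftest import gaussian_intensity, sphere_intensity


def ball_distance_distribution(r: np.ndarray, radius: float,
                               n_pairs: int = 1_000_000,
                               seed: int = 0) -> np.ndarray:
    """Monte-Carlo pair-distance histogram for a uniform ball (independent
    oracle for the sphere P(r))."""
    rng = np.random.default_rng(seed)

    def sample(n):
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        return pts * radius * rng.random(n)[:, None] ** (1.0 / 3.0)

    d = np.linalg.norm(sample(n_pairs) - sample(n_pairs), axis=1)
    edges = np.concatenate([[0.0], r + 0.5])
    hist, _ = np.histogram(d, bins=edges)
    return hist / hist.sum()


class TestGuinier:
    def test_gaussian_profile_exact(self, qgrid):
        prof = SaxsProfile(qgrid, gaussian_intensity(qgrid, 50.0, i0=7.0))
        g = guinier_fit(prof)
        assert g.rg == pytest.approx(50.0, rel=1e-9)
        assert g.i0 == pytest.approx(7.0, rel=1e-9)
        assert g.q_rg_max <= 1.3 + 1e-9

    def test_sphere_rg_within_2_percent(self, sphere_profile):
        g = guinier_fit(sphere_profile)
        assert g.rg == pytest.approx(np.sqrt(3.0 / 5.0) * 30.0, rel=0.02)

    def test_intensity_scaling_equivariance(self, qgrid):
        prof = SaxsProfile(qgrid, gaussian_intensity(qgrid, 40.0, i0=2.0))
        g1 = guinier_fit(prof)
        g2 = guinier_fit(prof.scaled(10.0))
        assert g2.rg == pytest.approx(g1.rg, rel=1e-12)
        assert g2.i0 == pytest.approx(10.0 * g1.i0, rel=1e-12)

    def test_rising_profile_rejected(self, qgrid):
        with pytest.raises(GuinierError):
            guinier_fit(SaxsProfile(qgrid, np.exp((qgrid * 30) ** 2)))

    def test_too_few_points_rejected(self):
        q = np.array([0.01, 0.02, 0.03, 0.04])
        with pytest.raises(GuinierError):
            guinier_fit(SaxsProfile(q, gaussian_intensity(q, 30.0)))


class TestKratky:
    def test_guinier_curve_peaks_at_sqrt3(self, qgrid):
        # (qRg)^2 exp(-(qRg)^2/3) is maximal at qRg = sqrt(3), value 3/e
        q = np.linspace(0.001, 0.2, 4000)
        prof = SaxsProfile(q, gaussian_intensity(q, 30.0, i0=4.0))
        g = guinier_fit(prof)
        x, y = kratky_dimensionless(prof, g)
        imax = np.argmax(y)
        assert x[imax] == pytest.approx(np.sqrt(3.0), abs=0.01)
        assert y[imax] == pytest.approx(3.0 / np.e, rel=1e-3)

    def test_low_q_limit_is_zero(self):
        q = np.linspace(0.001, 0.2, 1000)
        prof = SaxsProfile(q, gaussian_intensity(q, 30.0))
        x, y = kratky_dimensionless(prof, guinier_fit(prof))
        assert 0 < y[0] < 0.01

    def test_scale_invariance(self, qgrid):
        prof = SaxsProfile(qgrid, gaussian_intensity(qgrid, 30.0, i0=2.0))
        g = guinier_fit(prof)
        _, y1 = kratky_dimensionless(prof, g)
        _, y2 = kratky_dimensionless(prof.scaled(7.0), guinier_fit(prof.scaled(7.0)))
        np.testing.assert_allclose(y1, y2, rtol=1e-10)

    def test_nonpositive_i0_rejected(self, sphere_profile):
        bad = GuinierResult(rg=20.0, i0=0.0, q_first=0.01, q_last=0.05,
                            srg_limit=1.3, residual_rms=0.0, n_points=10)
        with pytest.raises(ValueError):
            kratky_dimensionless(sphere_profile, bad)


class TestPofRInversion:
    def test_sphere_distance_distribution(self, qgrid):
        I = sphere_intensity(qgrid, 30.0, i0=7.0)
        prof = SaxsProfile(qgrid, I, sigma=np.full_like(I, 1e-4 * I[0]))
        pofr = invert_pr_mem(prof, 66.0)
        oracle = ball_distance_distribution(pofr.r, 30.0)
        p = pofr.normalized()
        nrmsd = np.sqrt(np.mean((p - oracle) ** 2)) / oracle.max()
        assert nrmsd < 0.05

    def test_two_bead_peak_location(self, qgrid):
        sep = 80.0
        I = debye_profile(BeadModel(np.array([[0, 0, 0], [0, 0, sep]])), qgrid)
        prof = SaxsProfile(qgrid, I, sigma=np.full_like(I, 1e-3 * I[0]))
        pofr = invert_pr_mem(prof, 100.0)
        # the inter-bead peak (the self term lives near the origin)
        tail = pofr.r > 10.0
        mode = pofr.r[tail][np.argmax(pofr.p[tail])]
        assert abs(mode - sep) <= 2.0

    def test_rg_consistent_with_guinier(self, sphere_profile):
        pofr = invert_pr_mem(sphere_profile, 66.0)
        g = guinier_fit(sphere_profile)
        assert pofr.rg == pytest.approx(g.rg, rel=0.03)

    def test_nonnegative_with_decaying_ends(self, sphere_profile):
        pofr = invert_pr_mem(sphere_profile, 66.0)
        assert np.all(pofr.p >= 0)
        assert pofr.p[0] < 0.05 * pofr.p.max()
        assert pofr.p[-1] < 0.05 * pofr.p.max()

    def test_entropy_monotone_in_chi2_target(self, qgrid):
        rng = np.random.default_rng(2)
        I = sphere_intensity(qgrid, 30.0, i0=7.0)
        s = 0.01 * I[0]
        noisy = I + rng.normal(scale=s, size=I.shape)
        prof = SaxsProfile(qgrid, noisy, sigma=np.full_like(I, s))
        from saxsemble.basic import _pr_design

        r, A = _pr_design(prof.q, 66.0)
        prior = np.sin(np.pi * r / 66.0)
        prior = np.maximum(prior, 1e-6)
        yhat = A @ prior
        prior *= float(prof.intensity @ yhat / (yhat @ yhat))
        entropies = [
            maxent_fit(A, prof.intensity, prof.sigma, prior,
                       chi2_target=t).entropy
            for t in (1.0, 2.0, 8.0)
        ]
        assert entropies[0] <= entropies[1] <= entropies[2] <= 1e-9

    def test_invalid_dmax_rejected(self, sphere_profile):
        with pytest.raises(ValueError):
            invert_pr_mem(sphere_profile, -5.0)


class TestEstimateDmax:
    def test_sphere_diameter_recovered(self, qgrid):
        I = sphere_intensity(qgrid, 30.0, i0=7.0)
        dmax = estimate_dmax(SaxsProfile(qgrid, I), (40.0, 85.0, 3.0))
        assert 57.0 <= dmax <= 66.0

    def test_two_bead_separation_recovered(self, qgrid):
        I = debye_profile(BeadModel(np.array([[0, 0, 0], [0, 0, 100.0]])), qgrid)
        dmax = estimate_dmax(SaxsProfile(qgrid, I), (80.0, 130.0, 5.0))
        assert 95.0 <= dmax <= 110.0
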