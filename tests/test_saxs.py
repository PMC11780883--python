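"""Equilibrium SAXS transforms: file round trips, rebin error propagation,
Guinier recovery, Kratky analytics and the indirect Fourier transform
against the analytic sphere distance distribution."""

import numpy as np
import pytest

from g4fold import saxs, synth
from g4fold.datatypes import ScatteringCurve

SQRT35 = np.sqrt(3.0 / 5.0)


class TestDatIO:
    def test_round_trip(self, tmp_path, q_grid):
        c = synth.add_noise(synth.guinier_curve(12.0, 3.0, q_grid), 0.01, seed=0)
        p = tmp_path / "c.dat"
        saxs.write_dat(c, p, header="synthetic globule")
        back = saxs.read_dat(p)
        assert back.q == pytest.approx(c.q, rel=1e-6)
        assert back.I == pytest.approx(c.I, rel=1e-5)
        assert back.sigma == pytest.approx(c.sigma, rel=1e-5)

    def test_comment_and_header_lines_skipped(self, tmp_path):
        p = tmp_path / "h.dat"
        p.write_text(
            "# one\n# two\nsample header text\n# three\n# four\n"
            "0.01 10.0 0.1\n0.02 9.0 0.1\n0.03 8.5 0.1\n"
        )
        c = saxs.read_dat(p)
        assert len(c) == 3 and c.sigma is not None

    def test_two_column_file_gets_synthetic_sigma(self, tmp_path):
        p = tmp_path / "two.dat"
        p.write_text("0.01 10.0\n0.02 9.0\n")
        with pytest.warns(UserWarning, match="1%"):
            c = saxs.read_dat(p)
        assert c.sigma == pytest.approx(0.01 * c.I)

    def test_decreasing_q_names_offending_row(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("0.01 10 0.1\n0.03 9 0.1\n0.02 8 0.1\n")
        with pytest.raises(saxs.FormatError, match="line 3"):
            saxs.read_dat(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.dat"
        p.write_text("# nothing here\n")
        with pytest.raises(saxs.FormatError):
            saxs.read_dat(p)


class TestLogRebin:
    def test_identity_factor(self, q_grid):
        c = synth.add_noise(synth.guinier_curve(12, 1, q_grid), 0.01, seed=1)
        out = saxs.log_rebin(c, 1)
        assert np.array_equal(out.I, c.I)

    def test_constant_curve_preserved(self, q_grid):
        c = ScatteringCurve(q_grid, np.full_like(q_grid, 3.3), np.full_like(q_grid, 0.1))
        out = saxs.log_rebin(c, 4)
        assert out.I == pytest.approx(np.full_like(out.q, 3.3))
        # linear grid on log bins leaves some low-q bins empty
        assert 0.6 * len(c) // 4 <= len(out) <= len(c) // 4

    def test_error_propagation_equal_sigmas(self):
        """m equal-sigma points per bin give binned sigma = sigma/sqrt(m),
        matching the replicate-variance of resampled noisy bins."""
        q = np.geomspace(0.01, 0.3, 64)
        sigma0 = 0.2
        c = ScatteringCurve(q, np.full(64, 5.0), np.full(64, sigma0))
        out = saxs.log_rebin(c, 4)
        # log-spaced input on log bins: every bin holds exactly 4 points
        assert out.sigma == pytest.approx(np.full(len(out), sigma0 / 2.0), rel=1e-9)
        rng = np.random.default_rng(0)
        reps = []
        for _ in range(2000):
            nc = ScatteringCurve(q, 5.0 + rng.normal(0, sigma0, 64), np.full(64, sigma0))
            reps.append(saxs.log_rebin(nc, 4).I)
        emp = np.vstack(reps).std(axis=0, ddof=1)
        assert emp == pytest.approx(out.sigma, rel=0.15)

    def test_oversized_factor_rejected(self, q_grid):
        c = ScatteringCurve(q_grid, np.ones_like(q_grid))
        with pytest.raises(ValueError):
            saxs.log_rebin(c, len(c) + 1)


class TestGuinier:
    def test_noiseless_recovery_exact(self, q_grid):
        c = synth.guinier_curve(12.27, 1.0, q_grid)
        c.sigma = 0.01 * c.I
        g = saxs.guinier_fit(c)
        assert g.Rg == pytest.approx(12.27, abs=1e-4)
        assert g.I0 == pytest.approx(1.0, abs=1e-4)
        assert g.qmaxRg <= 1.3

    def test_sphere_rg_ratio(self, q_grid):
        """Guinier Rg of a sphere is sqrt(3/5) R; a narrow window keeps the
        shape-dependent truncation bias within 1%."""
        c = synth.sphere_curve(19.0, 1.0, q_grid)
        c.sigma = 0.005 * c.I
        g = saxs.guinier_fit(c, qmaxRg_limit=0.9)
        assert g.Rg / 19.0 == pytest.approx(SQRT35, rel=0.01)

    def test_noisy_replicates_calibration(self, q_grid):
        """200 replicates at 1% noise: mean recovered Rg within 1% of the
        24.26 A truth and the reported error within a factor 2 of the
        replicate scatter."""
        truth = 24.26
        clean = synth.guinier_curve(truth, 1.0, q_grid)
        rgs, errs = [], []
        for s in range(200):
            g = saxs.guinier_fit(synth.add_noise(clean, 0.01, seed=s))
            rgs.append(g.Rg)
            errs.append(g.Rg_err)
        rgs = np.array(rgs)
        assert rgs.mean() == pytest.approx(truth, rel=0.01)
        scatter = rgs.std(ddof=1)
        assert 0.5 < np.mean(errs) / scatter < 2.0

    def test_no_guinier_regime_raises(self, q_grid):
        c = ScatteringCurve(q_grid, 1.0 + q_grid**2, 0.01 * (1.0 + q_grid**2))
        with pytest.raises(saxs.GuinierError):
            saxs.guinier_fit(c)


class TestKratky:
    def test_ideal_globule_peak(self):
        """x^2 e^(-x^2/3) peaks at x = sqrt(3) with height 3/e."""
        q = np.linspace(1e-4, 0.35, 500)
        c = synth.guinier_curve(12.0, 1.0, q)
        c.sigma = 0.01 * c.I
        g = saxs.guinier_fit(c)
        k = saxs.dimensionless_kratky(c, g)
        assert k.peak_x == pytest.approx(np.sqrt(3.0), abs=0.01)
        assert k.peak_y == pytest.approx(3.0 / np.e, abs=0.01)

    def test_zero_at_origin(self):
        q = np.linspace(0.0, 0.3, 100)
        c = synth.guinier_curve(12.0, 1.0, q)
        k = saxs.dimensionless_kratky(
            c, saxs.GuinierResult(12.0, 0, 1.0, 0, (0, 0.1), 0, 1.2, 1.0, 10)
        )
        assert k.y[0] == 0.0

    def test_flexible_chain_plateau(self):
        """The ideal-chain (Debye function) Kratky transform rises to a
        plateau of 2 at high qRg instead of falling off."""
        rg = 24.0
        q = np.linspace(1e-3, 0.35, 400)
        c = synth.gaussian_chain_curve(rg, 1.0, q)
        g = saxs.GuinierResult(rg, 0, 1.0, 0, (0, 0.05), 0, 1.2, 1.0, 10)
        k = saxs.dimensionless_kratky(c, g)
        y_at = np.interp([4.0, 8.0], k.x, k.y)
        assert y_at[0] == pytest.approx(2 * (16 - 1 + np.exp(-16)) / 16, rel=1e-3)
        assert 1.8 < y_at[1] <= 2.0

    def test_nonpositive_i0_rejected(self, q_grid):
        c = synth.guinier_curve(12.0, 1.0, q_grid)
        bad = saxs.GuinierResult(12.0, 0, -1.0, 0, (0, 0.1), 0, 1.2, 1.0, 10)
        with pytest.raises(ValueError):
            saxs.dimensionless_kratky(c, bad)


class TestIFT:
    def test_sphere_pr_recovery(self, q_grid):
        """P(r) of a 0.5%-noise sphere curve matches the analytic distance
        distribution r^2(1 - 3r/4R + r^3/16R^3) with normalized RMS < 5%."""
        R = 19.0
        noisy = synth.add_noise(synth.sphere_curve(R, 1.0, q_grid), 0.005, seed=0)
        fit = saxs.ift_pr(noisy, 2 * R)
        ana = saxs.sphere_pr(fit.r, R)
        ana *= np.trapezoid(fit.p, fit.r) / np.trapezoid(ana, fit.r)
        nrms = np.sqrt(np.mean((fit.p - ana) ** 2)) / ana.max()
        assert nrms < 0.05

    def test_chi2_vanishes_without_regularization(self, q_grid):
        clean = synth.sphere_curve(19.0, 1.0, q_grid)
        clean.sigma = 0.01 * np.abs(clean.I) + 1e-9
        # weak regularization: misfit at the discretization floor;
        # oversmoothing drives it back up
        assert saxs.ift_pr(clean, 38.0, alpha=1e-14).chi2 < 1e-3
        chis = [saxs.ift_pr(clean, 38.0, alpha=a).chi2 for a in (1e10, 1e13, 1e16)]
        assert chis[0] < chis[1] < chis[2]
        assert chis[2] > 1.0

    def test_real_space_rg_matches_guinier(self, q_grid):
        """The two Rg estimators agree within 2% on an ideal globule."""
        c = synth.add_noise(synth.guinier_curve(12.27, 1.0, q_grid), 0.005, seed=3)
        g = saxs.guinier_fit(c)
        fit = saxs.ift_pr(c, 40.0)
        assert fit.Rg == pytest.approx(g.Rg, rel=0.02)

    def test_residuals_are_white(self, q_grid):
        """Lag-1 autocorrelation of the IFT residuals stays below 0.2 on
        correctly specified noisy data."""
        noisy = synth.add_noise(synth.sphere_curve(19.0, 1.0, q_grid), 0.01, seed=7)
        fit = saxs.ift_pr(noisy, 38.0)
        r_, A_int, _ = saxs._ift_design(noisy.q, 38.0, 101)
        resid = (A_int @ fit.p[1:-1] - noisy.I) / noisy.sigma
        resid = resid - resid.mean()
        rho = resid[:-1] @ resid[1:] / (resid @ resid)
        assert abs(rho) < 0.2

    def test_nonneg_option(self, q_grid):
        noisy = synth.add_noise(synth.sphere_curve(19.0, 1.0, q_grid), 0.01, seed=2)
        fit = saxs.ift_pr(noisy, 38.0, nonneg=True)
        assert np.all(fit.p >= 0)

    def test_resolution_warning(self, q_grid):
        noisy = synth.add_noise(synth.sphere_curve(4.0, 1.0, q_grid), 0.01, seed=2)
        with pytest.warns(UserWarning, match="resolution"):
            saxs.ift_pr(noisy, 8.0)

    def test_endpoints_pinned(self, q_grid):
        noisy = synth.add_noise(synth.sphere_curve(19.0, 1.0, q_grid), 0.01, seed=4)
        fit = saxs.ift_pr(noisy, 38.0)
        assert fit.p[0] == 0.0 and fit.p[-1] == 0.0


class TestPrMoments:
    def test_analytic_sphere_moments(self):
        R = 10.0
        r = np.linspace(0, 2 * R, 501)
        pd_ = saxs.PairDistribution(r, saxs.sphere_pr(r, R), 2 * R, 0, 0, 0, 0)
        m = saxs.pr_moments(pd_)
        assert m["Rg"] == pytest.approx(SQRT35 * R, rel=1e-3)

    def test_triangle_against_dense_quadrature(self):
        """Symmetric triangular P(r): moments against a 1e6-point
        quadrature oracle."""
        D = 40.0
        r = np.linspace(0, D, 201)
        p = np.minimum(r, D - r)
        pd_ = saxs.PairDistribution(r, p, D, 0, 0, 0, 0)
        m = saxs.pr_moments(pd_)
        rd = np.linspace(0, D, 1_000_001)
        pdense = np.minimum(rd, D - rd)
        rg_oracle = np.sqrt(np.trapezoid(rd**2 * pdense, rd) / (2 * np.trapezoid(pdense, rd)))
        i0_oracle = 4 * np.pi * np.trapezoid(pdense, rd)
        assert m["Rg"] == pytest.approx(rg_oracle, rel=1e-4)
        assert m["I0"] == pytest.approx(i0_oracle, rel=1e-4)

    def test_scaling_homogeneity(self):
        r = np.linspace(0, 38, 101)
        p = saxs.sphere_pr(r, 19.0)
        a = saxs.pr_moments(saxs.PairDistribution(r, p, 38, 0, 0, 0, 0))
        b = saxs.pr_moments(saxs.PairDistribution(r, 2 * p, 38, 0, 0, 0, 0))
        assert b["I0"] == pytest.approx(2 * a["I0"])
        assert b["Rg"] == pytest.approx(a["Rg"])

    def test_all_zero_rejected(self):
        r = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            saxs.pr_moments(saxs.PairDistribution(r, np.zeros(11), 10, 0, 0, 0, 0))


class TestEstimateDmax:
    def test_sphere_support_recovered(self, q_grid):
        noisy = synth.add_noise(synth.sphere_curve(19.0, 1.0, q_grid), 0.005, seed=0)
        scan = saxs.estimate_dmax(noisy, (26.0, 56.0), n_candidates=16)
        step = 30.0 / 15
        assert abs(scan.Dmax - 38.0) <= step + 1e-9

    def test_guinier_only_curve_flagged_low_confidence(self):
        """A pure Gaussian profile carries no support information beyond
        Rg; the scan must say so instead of inventing a Dmax."""
        q = synth.default_q_grid(120, 0.005, 0.12)
        noisy = synth.add_noise(synth.guinier_curve(15.0, 1.0, q), 0.01, seed=1)
        scan = saxs.estimate_dmax(noisy, (30.0, 90.0), n_candidates=13)
        assert scan.low_confidence

    def test_underestimated_dmax_increases_chi2(self, q_grid):
        noisy = synth.add_noise(synth.sphere_curve(19.0, 1.0, q_grid), 0.005, seed=0)
        alpha = saxs.ift_pr(noisy, 38.0, alpha="auto").alpha
        chi_true = saxs.ift_pr(noisy, 38.0, alpha=alpha).chi2
        chi_under = saxs.ift_pr(noisy, 30.0, alpha=alpha).chi2
        assert chi_under > chi_true
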