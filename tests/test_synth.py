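"""Generator correctness: chain geometry, Debye scattering, noise model,
kinetic series and SASA, each against an independent oracle where the
result is not a closed form."""

import numpy as np
import pytest

from g4fold import synth
from g4fold.datatypes import BeadModel


# --- independent self-avoiding-walk oracle (same step rules, separate code) ---


def _oracle_saw(rng, n, b):
    """Reference SAW: fixed bond b, non-bonded exclusion diameter b."""
    pts = [np.zeros(3)]
    while len(pts) < n:
        for _ in range(500):
            v = rng.normal(size=3)
            cand = pts[-1] + b * v / np.linalg.norm(v)
            if all(np.linalg.norm(cand - p) >= b for p in pts[:-1]):
                pts.append(cand)
                break
        else:
            pts = [np.zeros(3)]  # restart
    return np.array(pts)


def _rg(coords):
    c = coords - coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum(c**2, axis=1)))


class TestBeadChain:
    def test_single_bead_degenerate(self):
        m = synth.make_bead_chain(1, seed=0)
        s = synth.coord_stats(m)
        assert s == {"Rg": 0.0, "Dmax": 0.0, "end_to_end": 0.0}

    def test_two_bead_geometry(self):
        m = synth.make_bead_chain(2, bond_length=5.9, seed=3)
        s = synth.coord_stats(m)
        assert s["end_to_end"] == pytest.approx(5.9)
        assert s["Rg"] == pytest.approx(2.95)

    @pytest.mark.parametrize("mode", ["random_coil", "hairpin", "compact_globule"])
    def test_bond_lengths_exact(self, mode):
        m = synth.make_bead_chain(24, bond_length=5.9, mode=mode, seed=7)
        d = np.linalg.norm(np.diff(m.coords, axis=0), axis=1)
        assert d == pytest.approx(np.full(23, 5.9), rel=1e-9)

    def test_random_coil_matches_saw_oracle(self):
        """Mean coordinate Rg agrees with an independent SAW sampler
        implementing the same step rules, within 10%."""
        n_rep = 500
        mine = np.mean(
            [_rg(synth.make_bead_chain(24, 5.9, seed=s).coords) for s in range(n_rep)]
        )
        rng = np.random.default_rng(12345)
        ref = np.mean([_rg(_oracle_saw(rng, 24, 5.9)) for _ in range(n_rep)])
        assert mine == pytest.approx(ref, rel=0.10)

    def test_compact_globule_is_half_coil_size(self):
        coil = np.mean(
            [_rg(synth.make_bead_chain(24, seed=s).coords) for s in range(60)]
        )
        glob = np.mean(
            [
                _rg(synth.make_bead_chain(24, mode="compact_globule", seed=s).coords)
                for s in range(60)
            ]
        )
        assert glob == pytest.approx(0.5 * coil, rel=0.25)

    def test_determinism(self):
        a = synth.make_bead_chain(24, seed=11)
        b = synth.make_bead_chain(24, seed=11)
        assert np.array_equal(a.coords, b.coords)

    @pytest.mark.parametrize("n,b", [(0, 5.9), (5, 0.0), (5, -1.0)])
    def test_invalid_arguments(self, n, b):
        with pytest.raises(ValueError):
            synth.make_bead_chain(n, bond_length=b)


class TestCoordStats:
    def test_unit_square(self):
        m = BeadModel(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float), 1.0
        )
        s = synth.coord_stats(m)
        assert s["Rg"] == pytest.approx(np.sqrt(0.5))
        assert s["Dmax"] == pytest.approx(np.sqrt(2.0))

    def test_dmax_equals_exhaustive_pair_scan(self):
        m = synth.make_bead_chain(24, seed=5)
        c = m.coords
        brute = max(
            np.linalg.norm(c[i] - c[j]) for i in range(24) for j in range(i + 1, 24)
        )
        assert synth.coord_stats(m)["Dmax"] == pytest.approx(brute)


class TestDebyeCurve:
    def test_single_bead_flat(self, q_grid):
        m = BeadModel(np.zeros((1, 3)), 4.0)
        c = synth.debye_curve(m, q_grid)
        assert c.I == pytest.approx(np.ones_like(q_grid), abs=1e-12)

    def test_two_bead_closed_form(self, q_grid):
        d = 7.3
        m = BeadModel(np.array([[0, 0, 0], [0, 0, d]], float), 4.0)
        c = synth.debye_curve(m, q_grid)
        expected = (1.0 + np.sin(q_grid * d) / (q_grid * d)) / 2.0
        assert c.I / 4.0 == pytest.approx(expected, rel=1e-9)  # I(0) = N^2 = 4

    def test_forward_intensity_is_n_squared(self):
        q = np.linspace(1e-6, 0.3, 50)
        for n in (2, 7, 24):
            m = synth.make_bead_chain(n, seed=n)
            assert synth.debye_curve(m, q).I[0] == pytest.approx(n**2, rel=1e-6)

    def test_guinier_limit_matches_coordinate_rg(self):
        """-3 x (slope of ln I vs q^2 at low q) must equal the coordinate
        Rg^2 within 0.5%."""
        m = synth.make_bead_chain(24, seed=9)
        rg = _rg(m.coords)
        q = np.linspace(1e-4, 0.2 / rg, 50)
        c = synth.debye_curve(m, q)
        slope = np.polyfit(q**2, np.log(c.I), 1)[0]
        assert np.sqrt(-3 * slope) == pytest.approx(rg, rel=0.005)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            synth.debye_curve(synth.make_bead_chain(3, seed=0), np.array([]))


class TestAnalyticCurves:
    def test_sphere_forward_limit(self):
        c = synth.sphere_curve(19.0, 2.5, np.array([1e-8, 0.01, 0.1]))
        assert c.I[0] == pytest.approx(2.5, rel=1e-9)

    def test_sphere_first_zero_at_root_of_tan(self):
        """First zero of the sphere form factor sits at the first positive
        root of tan(x) = x, found independently by bisection."""
        lo, hi = np.pi / 2 + 1e-9, 3 * np.pi / 2 - 1e-9
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if np.tan(mid) - mid < 0:
                lo = mid
            else:
                hi = mid
        x_root = 0.5 * (lo + hi)  # ~4.4934
        R = 19.0
        q = np.linspace(3.5 / R, 5.5 / R, 20001)
        c = synth.sphere_curve(R, 1.0, q)
        q_zero = q[np.argmin(c.I)]
        assert q_zero * R == pytest.approx(x_root, abs=2e-3)
        assert x_root == pytest.approx(4.4934, abs=1e-3)

    def test_guinier_curve_values(self):
        q = np.array([1e-12, 1.0 / 12.0])
        c = synth.guinier_curve(12.0, 1.0, q)
        assert c.I[0] == pytest.approx(1.0)
        assert c.I[1] == pytest.approx(np.exp(-1.0 / 3.0))

    @pytest.mark.parametrize("fn", [synth.sphere_curve, synth.guinier_curve])
    def test_nonpositive_size_rejected(self, fn, q_grid):
        with pytest.raises(ValueError):
            fn(-1.0, 1.0, q_grid)


class TestNoise:
    def test_zero_noise_identity(self, q_grid):
        c = synth.guinier_curve(12.0, 1.0, q_grid)
        out = synth.add_noise(c, 0.0, seed=3)
        assert np.array_equal(out.I, c.I)

    def test_seed_determinism(self, q_grid):
        c = synth.guinier_curve(12.0, 1.0, q_grid)
        a = synth.add_noise(c, 0.02, seed=5)
        b = synth.add_noise(c, 0.02, seed=5)
        assert np.array_equal(a.I, b.I) and np.array_equal(a.sigma, b.sigma)

    def test_unbiased_over_replicates(self, q_grid):
        """Monte-Carlo: per-point mean of 1000 noisy replicates stays
        within 3 standard errors of the clean intensity."""
        c = synth.guinier_curve(12.0, 1.0, q_grid)
        reps = np.vstack([synth.add_noise(c, 0.02, seed=s).I for s in range(1000)])
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        z = np.abs(reps.mean(axis=0) - c.I) / se
        # 200 simultaneous z-scores: allow the expected few >3, none extreme
        assert np.mean(z > 3.0) < 0.02
        assert z.max() < 5.0

    def test_negative_noise_rejected(self, q_grid):
        with pytest.raises(ValueError):
            synth.add_noise(synth.guinier_curve(12, 1, q_grid), -0.1)


class TestCollapseSeries:
    def test_initial_frame_is_unfolded_curve(self, flexible_fixture, globule_fixture):
        cU, cF = flexible_fixture[0], globule_fixture[0]
        ser = synth.simulate_collapse_series(
            cU, cF, tau=0.28, time_grid=np.array([1e-9, 1.0])
        )
        assert ser.curves[0].I == pytest.approx(cU.I, rel=1e-6)

    def test_unfolded_fraction_at_tau(self, flexible_fixture, globule_fixture):
        cU, cF = flexible_fixture[0], globule_fixture[0]
        tau = 0.2
        ser = synth.simulate_collapse_series(
            cU, cF, tau=tau, time_grid=np.array([1e-6, tau])
        )
        expected = np.exp(-1.0) * cU.I + (1 - np.exp(-1.0)) * cF.I
        assert ser.curves[1].I == pytest.approx(expected, rel=1e-9)

    def test_default_grid_shape(self, flexible_fixture, globule_fixture):
        ser = synth.simulate_collapse_series(
            flexible_fixture[0], globule_fixture[0], tau=0.28
        )
        assert len(ser) == 118
        assert ser.times[0] == pytest.approx(1e-3)
        assert ser.times[-1] == pytest.approx(1.2)

    def test_mismatched_grids_rejected(self, flexible_fixture):
        cU = flexible_fixture[0]
        cF = synth.globule_curve(12.27, synth.default_q_grid(50))[0]
        with pytest.raises(ValueError):
            synth.simulate_collapse_series(cU, cF, tau=0.1)


class TestCDSeries:
    def test_initial_fractions(self, cd_basis):
        wl, basis = cd_basis
        ser = synth.simulate_cd_series(
            basis, wl, (875.0, 5254.0), np.array([1e-12, 100.0])
        )
        assert ser.values[:, 0] == pytest.approx(basis[0], rel=1e-9)

    def test_conservation_everywhere(self):
        from g4fold.kinetics import sequential_fractions

        t = np.geomspace(1, 2e4, 300)
        F = sequential_fractions(t, (875.0, 5254.0))
        assert F.sum(axis=0) == pytest.approx(np.ones_like(t), abs=1e-12)

    def test_intermediate_peak_position(self):
        """The intermediate's maximum matches the closed-form
        t* = ln(tau2/tau1) tau1 tau2/(tau2-tau1), cross-checked on a
        dense numerical evaluation."""
        from g4fold.kinetics import intermediate_peak_time, sequential_fractions

        tau1, tau2 = 875.0, 5254.0
        t_star = intermediate_peak_time(tau1, tau2)
        t = np.linspace(1.0, 2e4, 400001)
        f_b = sequential_fractions(t, (tau1, tau2))[1]
        assert t[np.argmax(f_b)] == pytest.approx(t_star, rel=1e-4)

    def test_nonincreasing_taus_rejected(self, cd_basis):
        wl, basis = cd_basis
        with pytest.raises(ValueError):
            synth.simulate_cd_series(basis, wl, (5254.0, 875.0), np.array([1.0, 2.0]))


class TestSASA:
    def test_isolated_sphere_exact(self):
        m = BeadModel(np.zeros((1, 3)), 4.0)
        assert synth.shrake_rupley_sasa(m) == pytest.approx(
            4 * np.pi * 5.4**2, rel=1e-12
        )

    def test_two_distant_beads_no_occlusion(self):
        m = BeadModel(np.array([[0, 0, 0], [0, 0, 30.0]]), np.array([4.0, 3.0]))
        expected = 4 * np.pi * (5.4**2 + 4.4**2)
        assert synth.shrake_rupley_sasa(m) == pytest.approx(expected, rel=1e-12)

    def test_overlapping_beads_vs_monte_carlo(self):
        """Two fused beads against a 1e5-point Monte-Carlo surface
        integration, within 2%."""
        centers = np.array([[0, 0, 0], [0, 0, 5.0]])
        m = BeadModel(centers, 4.0)
        got = synth.shrake_rupley_sasa(m)
        rng = np.random.default_rng(1)
        R = 5.4
        total = 0.0
        for i in (0, 1):
            v = rng.normal(size=(100_000, 3))
            pts = centers[i] + R * v / np.linalg.norm(v, axis=1, keepdims=True)
            other = centers[1 - i]
            frac = (np.linalg.norm(pts - other, axis=1) > R).mean()
            total += frac * 4 * np.pi * R**2
        assert got == pytest.approx(total, rel=0.02)


class TestFlexibleEnsembleFixture:
    def test_mixture_rg_is_exact(self, flexible_fixture):
        """Every conformer is rescaled to the target Rg, so the Guinier Rg
        of the intensity mixture equals the target exactly."""
        curve, models, _ = flexible_fixture
        for m in models[:10]:
            assert _rg(m.coords) == pytest.approx(24.26, rel=1e-9)
        # low-q expansion of the mean curve
        q = curve.q[:20]
        slope = np.polyfit(q**2, np.log(curve.I[:20]), 1)[0]
        assert np.sqrt(-3 * slope) == pytest.approx(24.26, rel=0.01)
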