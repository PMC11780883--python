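import numpy as np
import pytest

from g4fold import synth


@pytest.fixture(scope="session")
def q_grid():
    return synth.default_q_grid()


@pytest.fixture(scope="session")
def flexible_fixture(q_grid):
    """Unfolded-state stand-in: ensemble-averaged flexible chain, Rg 24.26 A.

    Returns (curve, models, ensemble_dmax)."""
    return synth.flexible_ensemble_curve(24.26, q_grid, n_conformers=50, seed=1)


@pytest.fixture(scope="session")
def globule_fixture(q_grid):
    """Folded-state stand-in: sphere with Rg 12.27 A.  Returns (curve, dmax)."""
    return synth.globule_curve(12.27, q_grid)


@pytest.fixture(scope="session")
def collapse_series(flexible_fixture, globule_fixture):
    """Standard two-state pH-jump series: tau = 0.28 s, 1% noise,
    118 log-spaced frames over 1 ms - 1.2 s."""
    cU = flexible_fixture[0]
    cF = globule_fixture[0]
    return synth.simulate_collapse_series(cU, cF, tau=0.28, noise_frac=0.01, seed=42)


@pytest.fixture(scope="session")
def cd_basis():
    """Three synthetic CD basis spectra (denatured A, intermediate B,
    folded C) on a 220-320 nm grid."""
    wl = np.arange(220.0, 321.0, 2.0)
    bA = 0.5 * np.exp(-(((wl - 255) / 18) ** 2)) - 1.0 * np.exp(-(((wl - 275) / 12) ** 2))
    bB = 2.0 * np.exp(-(((wl - 290) / 12) ** 2)) - 1.0 * np.exp(-(((wl - 260) / 10) ** 2))
    bC = 3.5 * np.exp(-(((wl - 290) / 11) ** 2)) + 1.5 * np.exp(-(((wl - 268) / 15) ** 2))
    return wl, np.vstack([bA, bB, bC])
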