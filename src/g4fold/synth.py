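"""Synthetic-data generators emulating a pH-jump G-quadruplex folding study.

The real experiment watches a 24-nucleotide telomeric sequence collapse
from an extended, flexible chain (Rg ~ 24 A, Dmax ~ 83 A) to a compact
globule (Rg ~ 12 A, Dmax ~ 38 A) after a pH jump, with scattering frames
collected over ~1 ms - 1.2 s and CD spectra over hours.  This module
builds coordinate-level and analytic stand-ins with the same statistical
structure: coarse-grained bead chains (one bead per nucleotide, bond
5.9 A ~ backbone P-P distance), Debye scattering curves, analytic sphere
and Guinier profiles, heteroscedastic SAXS-like noise, two-state
time-resolved series and three-component sequential CD series.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .datatypes import BeadModel, ScatteringCurve, ScatteringSeries, SpectraSeries
from .kinetics import sequential_fractions

# defaults matching the experimental setup being emulated
DEFAULT_BOND_LENGTH = 5.9  # A, approx. backbone P-P distance
DEFAULT_BEAD_RADIUS = 4.0  # A, one bead per nucleotide
Q_MIN, Q_MAX, N_Q = 0.005, 0.35, 200  # instrument q-range 0.0044-0.35 1/A
TR_T_MIN, TR_T_MAX, TR_N_TIMES = 1.0e-3, 1.2, 118  # s; 118 frames, 1 ms-1.2 s


def default_q_grid(n: int = N_Q, qmin: float = Q_MIN, qmax: float = Q_MAX) -> np.ndarray:
    """Uniform q-grid covering the emulated instrument range."""
    return np.linspace(qmin, qmax, n)


def default_time_grid(
    n: int = TR_N_TIMES, tmin: float = TR_T_MIN, tmax: float = TR_T_MAX
) -> np.ndarray:
    """Log-spaced acquisition times for the time-resolved series (seconds)."""
    return np.geomspace(tmin, tmax, n)


# ---------------------------------------------------------------------------
# bead-chain conformers
# ---------------------------------------------------------------------------


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _saw_walk(
    rng: np.random.Generator,
    n: int,
    bond_length: float,
    confine_radius: float | None = None,
    max_step_tries: int = 80,
    max_backtracks: int = 400,
) -> np.ndarray | None:
    """One self-avoiding walk attempt; None if it dead-ends.

    Step rules: fixed bond length; a new bead must stay at least one bond
    length away from every bead except its immediate predecessor; with
    confinement, every bead must lie inside a sphere of the given radius
    centred at the origin.
    """
    min_sep2 = bond_length**2
    coords = np.zeros((n, 3))
    i = 1
    backtracks = 0
    while i < n:
        placed = False
        for _ in range(max_step_tries):
            step = bond_length * _random_unit_vectors(rng, 1)[0]
            cand = coords[i - 1] + step
            if confine_radius is not None and cand @ cand > confine_radius**2:
                continue
            if i >= 2:
                d2 = np.einsum(
                    "ij,ij->i", coords[: i - 1] - cand, coords[: i - 1] - cand
                )
                if np.any(d2 < min_sep2):
                    continue
            coords[i] = cand
            placed = True
            break
        if placed:
            i += 1
        else:
            backtracks += 1
            if backtracks > max_backtracks or i <= 1:
                return None
            i -= 1  # retry the previous bead
    return coords


def _saw_coords(
    rng: np.random.Generator,
    n: int,
    bond_length: float,
    confine_radius: float | None = None,
) -> np.ndarray:
    for _ in range(200):
        coords = _saw_walk(rng, n, bond_length, confine_radius)
        if coords is not None:
            return coords
    raise RuntimeError("self-avoiding walk generation failed repeatedly")


@lru_cache(maxsize=32)
def _mean_coil_rg(n: int, bond_length: float, n_samples: int = 64) -> float:
    """Mean coordinate Rg of the random coil, cached; internal fixed stream."""
    rng = np.random.default_rng(20240517)
    vals = [
        _coord_rg(_saw_coords(rng, n, bond_length)) for _ in range(n_samples)
    ]
    return float(np.mean(vals))


def _coord_rg(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", c, c))))


def _arc_points(p1: np.ndarray, p2: np.ndarray, n_interior: int, bond_length: float) -> np.ndarray:
    """Interior points of a planar circular arc from p1 to p2 (bulging +z)
    whose n_interior+1 chords all have length bond_length."""
    k = n_interior + 1
    d = float(np.linalg.norm(p2 - p1))
    if k == 1:
        return np.empty((0, 3))
    # total turn angle phi solves  b*sin(phi/2)/sin(phi/(2k)) = d
    lo, hi = 1e-9, 2.0 * np.pi - 1e-9

    def chord(phi: float) -> float:
        return bond_length * np.sin(phi / 2.0) / np.sin(phi / (2.0 * k))

    if chord(lo) < d:
        raise ValueError("loop too short to span the stem separation")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if chord(mid) > d:
            lo = mid
        else:
            hi = mid
    phi = 0.5 * (lo + hi)
    rho = bond_length / (2.0 * np.sin(phi / (2.0 * k)))
    # circle centre in the plane y = p1.y, below the endpoints for the
    # minor arc, above for the major arc, so the arc always bulges up
    mid_xz = 0.5 * (p1 + p2)
    off = np.sqrt(max(rho**2 - (d / 2.0) ** 2, 0.0))
    up = np.array([0.0, 0.0, 1.0])
    centre = mid_xz - off * up if phi <= np.pi else mid_xz + off * up
    a1 = np.arctan2(p1[2] - centre[2], p1[0] - centre[0])
    a2 = np.arctan2(p2[2] - centre[2], p2[0] - centre[0])
    # sweep from a1 to a2 through the top of the circle
    sweep = (a2 - a1) % (2.0 * np.pi)
    if not np.isclose(sweep, phi, atol=1e-6):
        sweep = sweep - 2.0 * np.pi  # go the other way round
    ang = a1 + sweep * np.arange(1, k) / k
    pts = np.column_stack(
        [
            centre[0] + rho * np.cos(ang),
            np.full(k - 1, p1[1]),
            centre[2] + rho * np.sin(ang),
        ]
    )
    return pts


def _hairpin_coords(n: int, bond_length: float, stem_sep: float = 18.0) -> np.ndarray:
    """Antiparallel hairpin: two paired stems of ceil(n/3) beads plus a loop."""
    m = int(np.ceil(n / 3))
    n_loop = n - 2 * m
    k = n_loop + 1
    d = min(stem_sep, 0.9 * k * bond_length) if k > 1 else bond_length
    z = np.arange(m) * bond_length
    stem1 = np.column_stack([np.zeros(m), np.zeros(m), z])
    stem2 = np.column_stack([np.full(m, d), np.zeros(m), z[::-1]])
    top1 = stem1[-1]
    top2 = stem2[0]
    loop = _arc_points(top1, top2, n_loop, bond_length)
    return np.vstack([stem1, loop, stem2])


def make_bead_chain(
    n: int,
    bond_length: float = DEFAULT_BOND_LENGTH,
    mode: str = "random_coil",
    seed: int = 0,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
) -> BeadModel:
    """Build an n-bead chain conformer.

    Modes
    -----
    random_coil
        Self-avoiding walk with fixed bond length (excluded-volume
        diameter = one bond length for non-bonded beads).
    hairpin
        Antiparallel stem of ceil(n/3) paired beads plus a connecting
        loop; randomly oriented per seed (rigid rotation, so distances
        are deterministic given n and bond_length).
    compact_globule
        Self-avoiding walk confined to a sphere sized so the coordinate
        Rg is about half the random-coil mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    rng = np.random.default_rng(seed)
    if n == 1:
        coords = np.zeros((1, 3))
    elif n == 2:
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, bond_length]])
    elif mode == "random_coil":
        coords = _saw_coords(rng, n, bond_length)
    elif mode == "hairpin":
        coords = _hairpin_coords(n, bond_length)
    elif mode == "compact_globule":
        target_rg = 0.5 * _mean_coil_rg(n, bond_length)
        confine = target_rg * np.sqrt(5.0 / 3.0)
        coords = _saw_coords(rng, n, bond_length, confine_radius=confine)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # random rigid rotation (distance-preserving) for orientational variety
    if n > 1:
        a = _random_unit_vectors(rng, 1)[0]
        theta = rng.uniform(0, 2 * np.pi)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        coords = (coords - coords.mean(axis=0)) @ R.T
    return BeadModel(coords=coords, radii=np.full(n, bead_radius))


def coord_stats(model: BeadModel) -> dict[str, float]:
    """Coordinate Rg, maximum pairwise distance and end-to-end distance."""
    c = model.coords
    rg = _coord_rg(c)
    diff = c[:, None, :] - c[None, :, :]
    dmax = float(np.sqrt(np.max(np.einsum("ijk,ijk->ij", diff, diff))))
    e2e = float(np.linalg.norm(c[-1] - c[0]))
    return {"Rg": rg, "Dmax": dmax, "end_to_end": e2e}


# ---------------------------------------------------------------------------
# analytic and coordinate scattering curves
# ---------------------------------------------------------------------------


def debye_curve(model: BeadModel, q_grid: np.ndarray, label: str = "") -> ScatteringCurve:
    """Debye sum I(q) = sum_ij sinc(q r_ij) with unit form factors; I(0)=N^2."""
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("empty q grid")
    c = model.coords
    n = c.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(c[iu] - c[ju], axis=1)
    # np.sinc(x) = sin(pi x)/(pi x), so sinc(q d) = np.sinc(q d / pi)
    I = n + 2.0 * np.sinc(np.outer(q, d) / np.pi).sum(axis=1)
    return ScatteringCurve(q=q, I=I, sigma=None, label=label)


def sphere_curve(R: float, I0: float, q_grid: np.ndarray, label: str = "sphere") -> ScatteringCurve:
    """Homogeneous-sphere form factor, I(q) = I0 [3(sin qR - qR cos qR)/(qR)^3]^2."""
    if R <= 0:
        raise ValueError("R must be positive")
    q = np.asarray(q_grid, dtype=float)
    x = q * R
    amp = np.where(
        x < 1e-6, 1.0 - x**2 / 10.0, 3.0 * (np.sin(x) - x * np.cos(x)) / np.where(x == 0, 1, x) ** 3
    )
    return ScatteringCurve(q=q, I=I0 * amp**2, sigma=None, label=label)


def guinier_curve(Rg: float, I0: float, q_grid: np.ndarray, label: str = "guinier") -> ScatteringCurve:
    """Ideal globule: I(q) = I0 exp(-q^2 Rg^2 / 3) on the full grid."""
    if Rg <= 0:
        raise ValueError("Rg must be positive")
    q = np.asarray(q_grid, dtype=float)
    return ScatteringCurve(q=q, I=I0 * np.exp(-(q**2) * Rg**2 / 3.0), sigma=None, label=label)


def gaussian_chain_curve(
    Rg: float, I0: float, q_grid: np.ndarray, label: str = "gaussian_chain"
) -> ScatteringCurve:
    """Debye function for an ideal flexible chain, I/I0 = 2(e^-x + x - 1)/x^2
    with x = (q Rg)^2; its dimensionless Kratky plot plateaus at 2."""
    if Rg <= 0:
        raise ValueError("Rg must be positive")
    q = np.asarray(q_grid, dtype=float)
    x = (q * Rg) ** 2
    I = np.where(x < 1e-8, 1.0 - x / 3.0, 2.0 * (np.expm1(-x) + x) / np.where(x == 0, 1, x) ** 2)
    return ScatteringCurve(q=q, I=I0 * I, sigma=None, label=label)


def add_noise(curve: ScatteringCurve, noise_frac: float, seed: int = 0) -> ScatteringCurve:
    """Heteroscedastic Gaussian noise, sigma(q) = frac * I(q) * (1 + q/qmax).

    The (1 + q/qmax) factor mimics the relative-error growth toward high q
    seen in real buffer-subtracted SAXS.  noise_frac = 0 returns the input
    unchanged (with sigma attached when absent is NOT done; sigma is set
    only when noise is added).
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    if noise_frac == 0:
        return curve.copy()
    rng = np.random.default_rng(seed)
    qmax = curve.q[-1]
    sigma = noise_frac * np.abs(curve.I) * (1.0 + curve.q / qmax)
    sigma = np.maximum(sigma, 1e-12 * np.max(np.abs(curve.I)))
    I = curve.I + rng.normal(0.0, sigma)
    return ScatteringCurve(q=curve.q.copy(), I=I, sigma=sigma, label=curve.label)


def _attach_sigma(curve: ScatteringCurve, noise_frac: float) -> ScatteringCurve:
    """Noiseless copy carrying the sigma(q) the noise model would assign."""
    qmax = curve.q[-1]
    frac = max(noise_frac, 1e-4)
    sigma = frac * np.abs(curve.I) * (1.0 + curve.q / qmax)
    sigma = np.maximum(sigma, 1e-12 * np.max(np.abs(curve.I)))
    return ScatteringCurve(curve.q.copy(), curve.I.copy(), sigma, curve.label)


# ---------------------------------------------------------------------------
# kinetic series
# ---------------------------------------------------------------------------


def simulate_collapse_series(
    curve_U: ScatteringCurve,
    curve_F: ScatteringCurve,
    tau: float,
    time_grid: np.ndarray | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> ScatteringSeries:
    """Two-state collapse: I(q,t) = f_U(t) I_U(q) + (1-f_U(t)) I_F(q) + noise,
    with f_U(t) = exp(-t/tau).  Default grid: 118 log-spaced points, 1 ms-1.2 s."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if curve_U.q.shape != curve_F.q.shape or not np.allclose(curve_U.q, curve_F.q):
        raise ValueError("curve_U and curve_F must share one q-grid")
    times = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
    f_U = np.exp(-times / tau)
    curves = []
    for k, t in enumerate(times):
        I = f_U[k] * curve_U.I + (1.0 - f_U[k]) * curve_F.I
        c = ScatteringCurve(curve_U.q.copy(), I, None, label=f"t={t:.4g}s")
        if noise_frac > 0:
            c = add_noise(c, noise_frac, seed=seed + k)
        else:
            c = _attach_sigma(c, noise_frac)
        curves.append(c)
    return ScatteringSeries(times=times, curves=curves)


def simulate_cd_series(
    basis_spectra: np.ndarray,
    wavelengths: np.ndarray,
    taus: tuple[float, float],
    time_grid: np.ndarray,
    noise: float = 0.0,
    seed: int = 0,
) -> SpectraSeries:
    """Three-component sequential CD kinetics A -> B -> C.

    basis_spectra is (3, n_wavelength); fractions follow irreversible
    first-order kinetics with rate constants 1/tau1, 1/tau2 and sum to one
    at every time.  noise is the Gaussian sigma in the spectrum's units.
    """
    basis = np.asarray(basis_spectra, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    times = np.asarray(time_grid, dtype=float)
    if basis.shape != (3, wavelengths.size):
        raise ValueError("need exactly 3 basis spectra on the wavelength grid")
    tau1, tau2 = taus
    if not (0 < tau1 < tau2):
        raise ValueError("taus must be positive and increasing")
    F = sequential_fractions(times, (tau1, tau2))  # (3, n_t)
    values = basis.T @ F  # (n_w, n_t)
    if noise > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise, size=values.shape)
    return SpectraSeries(wavelengths=wavelengths, times=times, values=values)


# ---------------------------------------------------------------------------
# equilibrium-state fixtures used across the pipeline
# ---------------------------------------------------------------------------


def flexible_ensemble_curve(
    rg: float,
    q_grid: np.ndarray,
    n_beads: int = 24,
    n_conformers: int = 100,
    bond_length: float = DEFAULT_BOND_LENGTH,
    seed: int = 0,
) -> tuple[ScatteringCurve, list[BeadModel], float]:
    """Ensemble-averaged Debye curve of a flexible chain of known size.

    Each self-avoiding-walk conformer is rescaled isotropically to the
    target coordinate Rg, so the mixture's Guinier Rg equals `rg` exactly
    while shape dispersion (the Kratky plateau of a disordered chain) is
    retained.  Returns (mean curve normalised to I(0)=1, conformers,
    ensemble Dmax).  The ensemble Dmax is the 99.5% mass quantile of the
    exact pooled pair-distance distribution: the effective support of the
    ensemble P(r).  (The absolute longest pair across conformers is an
    extreme-value statistic carrying vanishing P(r) mass.)
    """
    q = np.asarray(q_grid, dtype=float)
    models: list[BeadModel] = []
    I_sum = np.zeros_like(q)
    dists = []
    for k in range(n_conformers):
        m = make_bead_chain(n_beads, bond_length, "random_coil", seed=seed * 100003 + k)
        scale = rg / _coord_rg(m.coords)
        m = BeadModel(coords=m.coords * scale, radii=m.radii, labels=m.labels)
        models.append(m)
        I_sum += debye_curve(m, q).I
        iu, ju = np.triu_indices(n_beads, k=1)
        dists.append(np.linalg.norm(m.coords[iu] - m.coords[ju], axis=1))
    I = I_sum / (n_conformers * n_beads**2)  # normalise I(0) to 1
    dmax = float(np.quantile(np.concatenate(dists), 0.995))
    return ScatteringCurve(q, I, None, label=f"flexible Rg={rg:g}"), models, dmax


def globule_curve(rg: float, q_grid: np.ndarray) -> tuple[ScatteringCurve, float]:
    """Compact-globule fixture: homogeneous sphere with the requested Rg
    (R = rg/sqrt(3/5)); returns (curve with I(0)=1, Dmax = 2R)."""
    R = rg / np.sqrt(3.0 / 5.0)
    return sphere_curve(R, 1.0, q_grid, label=f"globule Rg={rg:g}"), 2.0 * R


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform deterministic point set on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    model: BeadModel, probe: float = 1.4, n_sphere_points: int = 960
) -> float:
    """Total solvent-accessible surface area (A^2) by the rolling-probe
    point-counting method on a deterministic Fibonacci sphere lattice."""
    if probe < 0:
        raise ValueError("probe must be non-negative")
    if n_sphere_points < 32:
        raise ValueError("need at least 32 sphere points")
    pts = _fibonacci_sphere(n_sphere_points)
    coords = model.coords
    rads = model.radii + probe
    total = 0.0
    for i in range(model.n_beads):
        surf = coords[i] + rads[i] * pts
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in range(model.n_beads):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", surf - coords[j], surf - coords[j])
            exposed &= d2 > rads[j] ** 2
        total += exposed.mean() * 4.0 * np.pi * rads[i] ** 2
    return float(total)
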