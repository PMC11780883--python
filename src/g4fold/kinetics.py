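"""Relaxation kinetics: exponential fitting and SVD-based sequential-model
analysis of time-resolved CD spectra.

The slow phase of G-quadruplex folding is followed by circular dichroism
after a pH jump: the wavelength x time matrix is reduced by singular value
decomposition and the significant right singular vectors are fit globally
to an irreversible sequential first-order scheme A -> B -> C (variable
projection: the nonlinear search runs over the relaxation times only,
amplitudes are solved linearly at each step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datatypes import SpectraSeries

#: CD molar-normalization constant: delta-epsilon = theta / (32982 c l)
CD_NORMALIZATION = 32982.0


@dataclass
class ExpFit:
    """Single-exponential fit y = offset + amplitude * exp(-t/tau)."""

    tau: float
    tau_err: float
    amplitude: float
    amplitude_err: float
    offset: float
    residual_rms: float
    converged: bool
    decay_detected: bool


@dataclass
class SVDKineticFit:
    """Global sequential-model fit of an SVD-reduced spectral series."""

    n_components: int
    relaxation_times: np.ndarray  # s, increasing
    relaxation_time_errs: np.ndarray
    component_spectra: np.ndarray  # (n_components, n_wavelength)
    fractions: np.ndarray  # (n_components, n_time), rows of sequential model
    residual_matrix: np.ndarray  # data - reconstruction
    residual_rms: float
    identifiability_warning: bool = False
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))


def cd_normalize(theta, c: float, length: float):
    """Convert ellipticity (millidegrees) to molar delta-epsilon.

    delta_eps = theta / (32982 * c * l)  with c in mol/L and l in cm.
    Applies elementwise over a spectrum or matrix.
    """
    if c <= 0 or length <= 0:
        raise ValueError("concentration and path length must be positive")
    return np.asarray(theta, dtype=float) / (CD_NORMALIZATION * c * length)


def sequential_fractions(times: np.ndarray, taus) -> np.ndarray:
    """Closed-form fractions of the irreversible sequential scheme.

    One relaxation time -> two species (A -> B); two -> three (A -> B -> C)
    with rate constants 1/tau1, 1/tau2.  Returns (n_species, n_time);
    columns sum to one exactly.
    """
    t = np.asarray(times, dtype=float)
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if np.any(taus <= 0):
        raise ValueError("relaxation times must be positive")
    if taus.size == 1:
        fA = np.exp(-t / taus[0])
        return np.vstack([fA, 1.0 - fA])
    if taus.size != 2:
        raise ValueError("sequential model supports one or two relaxation times")
    k1, k2 = 1.0 / taus[0], 1.0 / taus[1]
    fA = np.exp(-k1 * t)
    if np.isclose(k1, k2, rtol=1e-9):
        fB = k1 * t * np.exp(-k1 * t)
    else:
        fB = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    fC = 1.0 - fA - fB
    return np.vstack([fA, fB, fC])


def intermediate_peak_time(tau1: float, tau2: float) -> float:
    """Time at which the sequential intermediate B is most populated:
    t* = ln(tau2/tau1) * tau1 tau2 / (tau2 - tau1)."""
    if np.isclose(tau1, tau2):
        return tau1
    return float(np.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1))


# ---------------------------------------------------------------------------
# single-exponential fitting
# ---------------------------------------------------------------------------


def _exp_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    offset, amp, log_tau = params
    expo = np.clip(-t / np.exp(np.clip(log_tau, -700, 700)), -700, 700)
    return offset + amp * np.exp(expo)


def fit_single_exponential(t, y, sigma=None, n_starts: int = 5) -> ExpFit:
    """Weighted least-squares fit of y = offset + amplitude exp(-t/tau).

    Initialization combines a log-linear fit of the detrended data with a
    log-spaced multi-start over tau; the best-chi^2 solution wins.  The
    result is flagged (decay_detected=False) when the amplitude's 95%
    confidence interval spans zero.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points")
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    w = np.ones_like(y) if sigma is None else 1.0 / np.asarray(sigma, dtype=float)

    offset0 = float(np.mean(y[t >= t[-1] / 3.0])) if t[-1] > 0 else float(y[-1])
    amp0 = float(y[0] - offset0)

    # log-linear initialization of tau from the detrended early decay
    tau_inits = list(np.geomspace(max(t[t > 0].min(), 1e-12), t[-1], n_starts))
    z = y - offset0
    usable = np.abs(z) > 0.1 * max(abs(amp0), 1e-300)
    if usable.sum() >= 3 and abs(amp0) > 0:
        slope = np.polyfit(t[usable], np.log(np.abs(z[usable])), 1)[0]
        if slope < 0:
            tau_inits.append(-1.0 / slope)

    best = None
    for tau0 in tau_inits:
        x0 = np.array([offset0, amp0 if amp0 != 0 else 1.0, np.log(tau0)])
        try:
            sol = least_squares(
                lambda p: w * (_exp_model(p, t) - y), x0, method="lm", max_nfev=2000
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("exponential fit failed for every initialization")

    offset, amp, log_tau = best.x
    tau = float(np.exp(log_tau))
    resid = _exp_model(best.x, t) - y
    dof = max(t.size - 3, 1)
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J)
        if sigma is None:
            cov = cov * (2.0 * best.cost / dof)
        diag = np.diag(cov)
        if np.any(~np.isfinite(diag)) or np.any(diag < 0):
            amp_err = log_tau_err = np.inf  # degenerate fit geometry
        else:
            errs = np.sqrt(diag)
            amp_err, log_tau_err = float(errs[1]), float(errs[2])
    except np.linalg.LinAlgError:
        amp_err = log_tau_err = np.inf
    tau_err = tau * log_tau_err
    # a decay is credible only if the amplitude CI excludes zero AND the
    # fitted time constant is resolvable within the observation window
    decay = bool(abs(amp) > 1.96 * amp_err) and tau < 10.0 * (t[-1] - t[0])
    return ExpFit(
        tau=tau,
        tau_err=float(tau_err),
        amplitude=float(amp),
        amplitude_err=amp_err,
        offset=float(offset),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=bool(best.success) and decay,
        decay_detected=bool(decay),
    )


# ---------------------------------------------------------------------------
# SVD + sequential-model global fit
# ---------------------------------------------------------------------------


def _lag1_autocorr(v: np.ndarray) -> float:
    v = v - v.mean()
    denom = float(v @ v)
    if denom == 0:
        return 0.0
    return float(v[:-1] @ v[1:] / denom)


def significant_svd_rank(values: np.ndarray, autocorr_min: float = 0.6) -> int:
    """Number of leading SVD components that look like signal: singular
    value above the trailing-noise floor and smooth (lag-1 autocorrelated)
    left and right singular vectors."""
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    tail = s[len(s) // 2 :]
    floor = 3.0 * np.median(tail) if np.median(tail) > 0 else s[0] * 1e-10
    rank = 0
    for k in range(len(s)):
        sig = s[k] > floor
        smooth = (
            abs(_lag1_autocorr(U[:, k])) > autocorr_min
            and abs(_lag1_autocorr(Vt[k])) > autocorr_min
        )
        if sig and smooth:
            rank = k + 1
        else:
            break
    return max(rank, 1)


def sequential_svd_fit(
    series: SpectraSeries,
    n_components: int = 3,
    n_starts: int = 9,
    fixed_initial_spectrum: np.ndarray | None = None,
) -> SVDKineticFit:
    """SVD reduction plus global sequential-model fit of a spectral series.

    The wavelength x time matrix is decomposed; the significant right
    singular vectors (weighted by their singular values) are modeled as
    linear combinations of the closed-form sequential fractions
    f_k(t; tau_1..tau_{n-1}).  Only the relaxation times are searched
    nonlinearly (multi-start over log-spaced seedings); mixing amplitudes
    are projected out linearly at every step, and the component spectra
    are recovered by back-rotation.

    fixed_initial_spectrum, when given, pins component A's spectrum to the
    pre-jump measurement instead of the freely rotated SVD estimate.
    """
    D = series.values
    t = series.times
    n_tau = n_components - 1
    if n_tau < 1:
        raise ValueError("need at least 2 components")
    rank = significant_svd_rank(D)
    if rank < n_components:
        raise ValueError(
            f"only {rank} significant SVD components found, "
            f"{n_components} requested"
        )
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    Ur, sr, Vr = U[:, :n_components], s[:n_components], Vt[:n_components]
    W = sr[:, None] * Vr  # data-space-weighted right vectors (ncomp, nt)

    def projected_residual(log_taus: np.ndarray) -> np.ndarray:
        taus = np.sort(np.exp(log_taus))
        F = sequential_fractions(t, taus)
        B, *_ = np.linalg.lstsq(F.T, W.T, rcond=None)  # W ~ B.T F
        return (B.T @ F - W).ravel()

    span = (max(t[t > 0].min(), 1e-12), t[-1])
    starts = np.geomspace(span[0] * 3, span[1] / 3, n_starts)
    best = None
    for i in range(n_starts):
        if n_tau == 1:
            x0 = np.log([starts[i]])
        else:
            x0 = np.log([starts[i], min(starts[i] * 6.0, span[1] * 3)])
        sol = least_squares(projected_residual, x0, method="lm", max_nfev=4000)
        if best is None or sol.cost < best.cost:
            best = sol

    taus = np.sort(np.exp(best.x))
    F = sequential_fractions(t, taus)
    B, *_ = np.linalg.lstsq(F.T, W.T, rcond=None)
    spectra = (Ur @ B.T).T  # (ncomp, n_wavelength)
    if fixed_initial_spectrum is not None:
        spectra[0] = np.asarray(fixed_initial_spectrum, dtype=float)
    recon = spectra.T @ F
    resid = D - recon

    # tau uncertainties from the variable-projection Jacobian
    J = best.jac
    dof = max(W.size - J.shape[1] - B.size, 1)
    try:
        cov = np.linalg.inv(J.T @ J) * (2.0 * best.cost / dof)
        tau_errs = taus * np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        tau_errs = np.full_like(taus, np.inf)

    ident_warn = bool(n_tau >= 2 and taus[1] / taus[0] < 2.0)
    if ident_warn:
        warnings.warn(
            "relaxation times are within a factor 2; the sequential model "
            "is weakly identifiable",
            stacklevel=2,
        )
    return SVDKineticFit(
        n_components=n_components,
        relaxation_times=taus,
        relaxation_time_errs=np.asarray(tau_errs),
        component_spectra=spectra,
        fractions=F,
        residual_matrix=resid,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        identifiability_warning=ident_warn,
        singular_values=s,
    )
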