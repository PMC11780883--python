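"""Deconvolution of time-resolved scattering series.

A pH-jump TR-SAXS dataset is a q x time matrix that mixes the scattering
of the evolving species.  The analysis here follows the standard
regularized alternating-least-squares recipe: (1) error-normalized SVD
counts the independent components (singular value above the pure-noise
floor AND smooth singular vectors); (2) the data matrix is factored into
non-negative, smooth concentration time-courses and component profiles,
with the equilibrium endpoint curves optionally anchored as fixed
component profiles; (3) per-frame Guinier fits track Rg(t) directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import lsq_linear

from .datatypes import ScatteringCurve, ScatteringSeries
from .saxs import GuinierError, guinier_fit


@dataclass
class RankDiagnostics:
    singular_values: np.ndarray
    autocorr_left: np.ndarray
    autocorr_right: np.ndarray
    rank: int
    noise_floor: float


@dataclass
class Decomposition:
    profiles: np.ndarray  # (n_components, n_q)
    concentrations: np.ndarray  # (n_components, n_t), >= 0
    lambdas: dict
    chi2: float  # reduced global misfit
    anchors: list[bool]  # which components carry a fixed equilibrium profile
    converged: bool
    n_iter: int
    objective_history: np.ndarray = field(default_factory=lambda: np.array([]))


def _lag1(v: np.ndarray) -> float:
    v = v - v.mean()
    d = float(v @ v)
    return float(v[:-1] @ v[1:] / d) if d > 0 else 0.0


def svd_rank(
    series: ScatteringSeries,
    sv_margin: float = 1.1,
    autocorr_min: float = 0.6,
) -> RankDiagnostics:
    """Component count from error-normalized SVD.

    The data matrix D/sigma has unit-variance noise, whose largest noise
    singular value sits near sqrt(n_q) + sqrt(n_t); a component is
    significant when its singular value exceeds that floor (times a small
    margin) and both its singular vectors are smooth (lag-1
    autocorrelation above `autocorr_min`).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 time points")
    # normalize by a per-q error scale (median over frames): dividing by the
    # full sigma(q,t) would cancel intensity evolution when errors track I
    sig_q = np.median(series.sigma_matrix(), axis=1)
    D = series.intensity_matrix() / sig_q[:, None]
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    floor = sv_margin * (np.sqrt(D.shape[0]) + np.sqrt(D.shape[1]))
    ac_l = np.array([_lag1(U[:, k]) for k in range(len(s))])
    ac_r = np.array([_lag1(Vt[k]) for k in range(len(s))])
    rank = 0
    for k in range(len(s)):
        if s[k] > floor and abs(ac_l[k]) > autocorr_min and abs(ac_r[k]) > autocorr_min:
            rank = k + 1
        else:
            break
    if rank <= 1:
        rank = 1
        warnings.warn("series shows a single significant component", stacklevel=2)
    return RankDiagnostics(
        singular_values=s,
        autocorr_left=ac_l,
        autocorr_right=ac_r,
        rank=rank,
        noise_floor=float(floor),
    )


# ---------------------------------------------------------------------------
# regularized alternating least squares
# ---------------------------------------------------------------------------


def _objective(P, C, D, W, lam_c):
    misfit = float(np.sum(W * (P.T @ C - D) ** 2))
    smooth = float(np.sum(np.diff(C, n=2, axis=1) ** 2))
    return misfit + lam_c * smooth


def _solve_concentrations(P, D, W, lam_c, nonneg):
    """Exact minimizer over C of sum W (P^T C - D)^2 + lam_c ||D2 C||^2,
    optionally with C >= 0.  The per-time data blocks are reduced by
    Cholesky before stacking with the smoothness rows."""
    ncomp, nq = P.shape
    nt = D.shape[1]
    blocks = []
    zs = []
    for t in range(nt):
        w = W[:, t]
        G = (P * w) @ P.T
        b = (P * w) @ D[:, t]
        G += 1e-12 * np.trace(G) / ncomp * np.eye(ncomp)
        R = np.linalg.cholesky(G).T  # R^T R = G
        z = np.linalg.solve(R.T, b)
        blocks.append(R)
        zs.append(z)
    A_data = sp.block_diag(blocks, format="csr")
    b_data = np.concatenate(zs)
    rows = [A_data]
    rhs = [b_data]
    if lam_c > 0 and nt >= 3:
        data, ri, ci = [], [], []
        row = 0
        for k in range(ncomp):
            for t in range(1, nt - 1):
                for dt, val in ((-1, 1.0), (0, -2.0), (1, 1.0)):
                    ri.append(row)
                    ci.append((t + dt) * ncomp + k)
                    data.append(np.sqrt(lam_c) * val)
                row += 1
        S = sp.csr_matrix((data, (ri, ci)), shape=(row, ncomp * nt))
        rows.append(S)
        rhs.append(np.zeros(row))
    A = sp.vstack(rows, format="csr")
    b = np.concatenate(rhs)
    if nonneg:
        sol = lsq_linear(A, b, bounds=(0, np.inf), tol=1e-12, max_iter=300)
        x = sol.x
    else:
        x = sp.linalg.spsolve((A.T @ A).tocsc(), A.T @ b)
    return x.reshape(nt, ncomp).T


def _solve_free_profiles(C, D_res, W, free):
    """Exact per-q weighted least squares for the unanchored profiles."""
    Cf = C[free]  # (nf, nt)
    G = np.einsum("kt,lt,qt->qkl", Cf, Cf, W)
    G += 1e-12 * np.eye(Cf.shape[0])[None, :, :] * np.trace(G, axis1=1, axis2=2)[
        :, None, None
    ] / Cf.shape[0]
    b = np.einsum("kt,qt->qk", Cf, W * D_res)
    return np.linalg.solve(G, b[:, :, None])[:, :, 0].T  # (nf, nq)


def _ift_basis(q: np.ndarray, Dmax: float, n_r: int = 51):
    r = np.linspace(0.0, Dmax, n_r)
    dr = r[1] - r[0]
    A = 4.0 * np.pi * dr * np.sinc(np.outer(q, r) / np.pi)
    return A[:, 1:-1]  # endpoint-zero basis


def _solve_free_profiles_realspace(C, D_res, W, free, bases, lam_p):
    """Free profiles parameterized as P_k = A_k pr_k (band-limited,
    endpoint-zero real-space distributions) with curvature penalty lam_p."""
    nf = int(np.sum(free))
    nq, nt = D_res.shape
    sizes = [bases[i].shape[1] for i in range(nf)]
    ntot = sum(sizes)
    G = np.zeros((ntot, ntot))
    b = np.zeros(ntot)
    Cf = C[free]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    for t in range(nt):
        w = W[:, t]
        for a in range(nf):
            Aa = bases[a] * np.sqrt(w)[:, None]
            da = np.sqrt(w) * D_res[:, t]
            for bnd in range(nf):
                Ab = bases[bnd] * np.sqrt(w)[:, None]
                G[offs[a] : offs[a + 1], offs[bnd] : offs[bnd + 1]] += (
                    Cf[a, t] * Cf[bnd, t] * (Aa.T @ Ab)
                )
            b[offs[a] : offs[a + 1]] += Cf[a, t] * (Aa.T @ da)
    for a in range(nf):
        n = sizes[a]
        D2 = np.diff(np.eye(n + 2), n=2, axis=0)[:, 1:-1]
        G[offs[a] : offs[a + 1], offs[a] : offs[a + 1]] += lam_p * (D2.T @ D2)
    x = np.linalg.solve(G + 1e-12 * np.trace(G) / ntot * np.eye(ntot), b)
    return [bases[a] @ x[offs[a] : offs[a + 1]] for a in range(nf)]


def regals_decompose(
    series: ScatteringSeries,
    n_components: int = 2,
    conc_smoothness: float | str = "auto",
    profile_mode: str = "direct",
    profile_dmax: list[float] | None = None,
    profile_smoothness: float = 10.0,
    nonneg_conc: bool = True,
    anchor_first: ScatteringCurve | None = None,
    anchor_last: ScatteringCurve | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> Decomposition:
    """Regularized ALS factorization of a scattering series.

    The first component is the species present at t=0 (decaying), the last
    the species formed at late times; supplying the equilibrium endpoint
    curves as anchors fixes those components' profiles (concentrations
    absorb the scale).  Concentrations are non-negative with a
    second-difference smoothness penalty; unanchored profiles are solved
    per-q ('direct') or as band-limited real-space distributions
    ('realspace', needs profile_dmax).  Alternating exact block solves
    make the penalized objective monotonically non-increasing.
    """
    D = series.intensity_matrix()
    sigma = series.sigma_matrix()
    W = 1.0 / sigma**2
    nq, nt = D.shape
    q = series.q

    anchors = [False] * n_components
    P = np.zeros((n_components, nq))
    if anchor_first is not None:
        if not np.allclose(anchor_first.q, q):
            raise ValueError("anchor_first is not on the series q-grid")
        P[0] = anchor_first.I
        anchors[0] = True
    if anchor_last is not None:
        if not np.allclose(anchor_last.q, q):
            raise ValueError("anchor_last is not on the series q-grid")
        P[-1] = anchor_last.I
        anchors[-1] = True
    free = ~np.array(anchors)
    # initialize unanchored profiles from the sign-fixed SVD components
    if free.any():
        U, s, _ = np.linalg.svd(D / sigma, full_matrices=False)
        kfree = np.nonzero(free)[0]
        for i, k in enumerate(kfree):
            u = U[:, i] * np.sign(np.sum(U[:, i]))
            P[k] = np.abs(u) * np.median(np.abs(D)) / max(np.median(np.abs(u)), 1e-300)
    if profile_mode not in ("direct", "realspace"):
        raise ValueError("profile_mode must be 'direct' or 'realspace'")
    bases = None
    if profile_mode == "realspace" and free.any():
        if profile_dmax is None:
            raise ValueError("realspace mode needs profile_dmax")
        bases = [_ift_basis(q, profile_dmax[i]) for i in range(int(free.sum()))]

    if conc_smoothness == "auto":
        lam_c = select_conc_smoothness(
            series, n_components, anchor_first=anchor_first, anchor_last=anchor_last,
            nonneg_conc=nonneg_conc,
        )
    else:
        lam_c = float(conc_smoothness)

    C = np.zeros((n_components, nt))
    obj_hist = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = _solve_concentrations(P, D, W, lam_c, nonneg_conc)
        if free.any():
            anchored = ~free
            D_res = D - P[anchored].T @ C[anchored] if anchored.any() else D
            if bases is not None:
                profs = _solve_free_profiles_realspace(C, D_res, W, free, bases, profile_smoothness)
                P[free] = np.vstack(profs)
            else:
                P[free] = _solve_free_profiles(C, D_res, W, free)
        obj = _objective(P, C, D, W, lam_c)
        obj_hist.append(obj)
        if len(obj_hist) >= 2:
            prev = obj_hist[-2]
            if prev - obj < tol * max(prev, 1e-300):
                converged = True
                break
        if not free.any() and it >= 2:
            converged = True  # fully anchored: C-solve is convex and exact
            break
    chi2 = float(np.sum(W * (P.T @ C - D) ** 2) / (nq * nt))
    return Decomposition(
        profiles=P,
        concentrations=C,
        lambdas={"conc_smoothness": lam_c, "profile_smoothness": profile_smoothness},
        chi2=chi2,
        anchors=anchors,
        converged=converged,
        n_iter=it,
        objective_history=np.asarray(obj_hist),
    )


def select_conc_smoothness(
    series: ScatteringSeries,
    n_components: int = 2,
    grid: np.ndarray | None = None,
    chi2_tol: float = 0.05,
    **kwargs,
) -> float:
    """Pick the largest concentration-smoothness weight whose reduced chi^2
    stays within `chi2_tol` of the scan minimum (log-grid scan)."""
    lams = np.logspace(-4, 8, 13) if grid is None else np.asarray(grid, float)
    chis = []
    for lam in lams:
        d = regals_decompose(
            series, n_components, conc_smoothness=lam, max_iter=30, **kwargs
        )
        chis.append(d.chi2)
    chis = np.asarray(chis)
    ok = np.nonzero(chis <= chis.min() * (1 + chi2_tol))[0]
    return float(lams[ok[-1]])


# ---------------------------------------------------------------------------
# per-frame Guinier tracking
# ---------------------------------------------------------------------------


def series_guinier_track(series: ScatteringSeries, qmaxRg_limit: float = 1.3) -> pd.DataFrame:
    """Guinier fit of every frame; failing frames are flagged, not dropped.

    Returns a DataFrame with columns t, Rg, Rg_err, I0, I0_err, qmaxRg, ok.
    Raises when more than half the frames fail.
    """
    rows = []
    for t, c in zip(series.times, series.curves):
        try:
            g = guinier_fit(c, qmaxRg_limit=qmaxRg_limit)
            rows.append(
                {"t": t, "Rg": g.Rg, "Rg_err": g.Rg_err, "I0": g.I0,
                 "I0_err": g.I0_err, "qmaxRg": g.qmaxRg, "ok": True}
            )
        except (GuinierError, ValueError) as err:
            rows.append(
                {"t": t, "Rg": np.nan, "Rg_err": np.nan, "I0": np.nan,
                 "I0_err": np.nan, "qmaxRg": np.nan, "ok": False, "error": str(err)}
            )
    out = pd.DataFrame(rows)
    n_fail = int((~out["ok"]).sum())
    if n_fail > 0.5 * len(out):
        raise RuntimeError(
            f"{n_fail}/{len(out)} frames failed the Guinier fit:\n"
            + out.loc[~out["ok"]].to_string()
        )
    return out
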