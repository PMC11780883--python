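"""Ensemble optimization against a scattering curve.

A flexible molecule in solution is a mixture: its scattering is the
average over an ensemble of conformations.  Given a large pool of
candidate conformers with theoretical curves, a genetic algorithm picks a
small sub-ensemble (with repetition, i.e. implicit weights) whose average
curve minimizes the reduced discrepancy

    chi^2 = 1/(K-1) sum_j [(mu I_calc(q_j) - I_exp(q_j)) / sigma_j]^2

where mu is a fitted scale factor (optionally together with a fitted
constant background).  The breadth of the selected ensemble's Rg
distribution relative to the pool's (entropy ratio Rflex, standard
deviation ratio Rsigma) diagnoses whether the target is flexible or
rigid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import BeadModel, ScatteringCurve
from .synth import coord_stats, debye_curve


@dataclass
class ConformerPool:
    """Candidate conformers with theoretical curves on one q-grid."""

    models: list[BeadModel]
    curves: np.ndarray  # (n_models, K) intensities on the shared q-grid
    q: np.ndarray
    Rg: np.ndarray  # per-model coordinate Rg (A)
    Dmax: np.ndarray  # per-model max pairwise distance (A)

    @classmethod
    def from_models(cls, models: list[BeadModel], q_grid: np.ndarray) -> "ConformerPool":
        q = np.asarray(q_grid, dtype=float)
        curves = np.vstack([debye_curve(m, q).I for m in models])
        stats = [coord_stats(m) for m in models]
        return cls(
            models=list(models),
            curves=curves,
            q=q,
            Rg=np.array([s["Rg"] for s in stats]),
            Dmax=np.array([s["Dmax"] for s in stats]),
        )

    @classmethod
    def from_curves(cls, curves: list[ScatteringCurve], Rg, Dmax) -> "ConformerPool":
        q = curves[0].q
        for c in curves[1:]:
            if not np.allclose(c.q, q):
                raise ValueError("pool curves must share one q-grid")
        return cls(
            models=[],
            curves=np.vstack([c.I for c in curves]),
            q=q,
            Rg=np.asarray(Rg, dtype=float),
            Dmax=np.asarray(Dmax, dtype=float),
        )

    @property
    def size(self) -> int:
        return self.curves.shape[0]


@dataclass
class GAConfig:
    ens_min: int = 5
    ens_max: int = 20
    population: int = 50
    generations: int = 600
    mutation_rate: float | None = None  # default 1/ensemble-size
    elitism: float = 0.1
    n_repeats: int = 100
    allow_repetition: bool = True
    allow_constant: bool = True
    tournament: int = 3
    stagnation: int = 100


@dataclass
class EnsembleSelection:
    member_indices: np.ndarray  # with repetition
    unique_indices: np.ndarray
    weights: np.ndarray  # per unique member, > 0, sum to 1
    chi2: float
    mu: float
    constant: float
    curve: ScatteringCurve  # fitted (scaled, offset) ensemble curve
    rg_values: np.ndarray  # Rg of the selected members (with repetition)
    dmax_values: np.ndarray
    rflex_pool: float
    rflex_ens: float
    rsigma: float
    chi2_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def ensemble_rg_mean(self) -> float:
        return float(np.mean(self.rg_values))


# ---------------------------------------------------------------------------
# chi^2 with fitted scale (and optional constant)
# ---------------------------------------------------------------------------


def chi2_scaled(I_calc: ScatteringCurve, I_exp: ScatteringCurve) -> dict[str, float]:
    """Reduced chi^2 between a calculated and an experimental curve with the
    closed-form optimal scale mu = (sum Ic Ie / s^2)/(sum Ic^2 / s^2)."""
    if I_calc.q.shape != I_exp.q.shape or not np.allclose(I_calc.q, I_exp.q):
        raise ValueError("curves must share one q-grid")
    sigma = I_exp.require_sigma()
    if np.all(I_calc.I == 0):
        raise ValueError("calculated intensity is identically zero")
    w = 1.0 / sigma**2
    mu = float(np.sum(w * I_calc.I * I_exp.I) / np.sum(w * I_calc.I**2))
    K = len(I_exp)
    chi2 = float(np.sum(w * (mu * I_calc.I - I_exp.I) ** 2) / (K - 1))
    return {"chi2": chi2, "mu": mu}


def _chi2_batch(Icalc: np.ndarray, Ie: np.ndarray, w: np.ndarray, constant: bool):
    """Vectorized chi^2/(K-1) over a batch of calculated curves with fitted
    scale mu (and optional constant offset c).  Icalc: (B, K)."""
    K = Ie.size
    if not constant:
        mu = (Icalc * (w * Ie)).sum(1) / np.maximum((Icalc**2 * w).sum(1), 1e-300)
        resid = mu[:, None] * Icalc - Ie
        c = np.zeros_like(mu)
    else:
        a11 = (Icalc**2 * w).sum(1)
        a12 = (Icalc * w).sum(1)
        a22 = np.full(Icalc.shape[0], w.sum())
        b1 = (Icalc * (w * Ie)).sum(1)
        b2 = np.full(Icalc.shape[0], (w * Ie).sum())
        det = np.maximum(a11 * a22 - a12**2, 1e-300)
        mu = (b1 * a22 - b2 * a12) / det
        c = (a11 * b2 - a12 * b1) / det
        resid = mu[:, None] * Icalc + c[:, None] - Ie
    chi2 = (w * resid**2).sum(1) / (K - 1)
    return chi2, mu, c


def ensemble_curve(pool: ConformerPool, member_indices) -> ScatteringCurve:
    """Unweighted mean of the member curves; repetition carries the weight."""
    idx = np.asarray(member_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return ScatteringCurve(pool.q.copy(), pool.curves[idx].mean(axis=0), None, "ensemble")


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


def _evaluate(pool_curves, idx, sizes, Ie, w, constant):
    mask = np.arange(idx.shape[1])[None, :] < sizes[:, None]
    sums = np.einsum("bek,be->bk", pool_curves[idx], mask.astype(float))
    means = sums / sizes[:, None]
    return _chi2_batch(means, Ie, w, constant)


def gajoe_select(
    pool: ConformerPool,
    I_exp: ScatteringCurve,
    ga: GAConfig | None = None,
    seed: int = 0,
) -> EnsembleSelection:
    """Genetic-algorithm selection of a weighted sub-ensemble.

    Chromosomes are index multisets of size ens_min..ens_max; fitness is
    the scaled chi^2 of the unweighted ensemble average (constant
    subtraction optional).  Tournament selection, single-point crossover,
    per-gene mutation and elitism; the whole GA is repeated n_repeats
    times and the best run returned.  Deterministic per seed.
    """
    cfg = ga or GAConfig()
    if not np.allclose(pool.q, I_exp.q):
        raise ValueError("pool curves must be on the experimental q-grid")
    if pool.size < cfg.ens_max and not cfg.allow_repetition:
        raise ValueError("pool smaller than ens_max with repetition disallowed")
    sigma = I_exp.require_sigma()
    Ie = I_exp.I
    w = 1.0 / sigma**2
    rng = np.random.default_rng(seed)
    n_pool = pool.size
    emin, emax = cfg.ens_min, cfg.ens_max
    pop_n = cfg.population
    n_elite = max(1, int(round(cfg.elitism * pop_n)))

    # best single member, used to seed every repeat (guarantees the final
    # ensemble is never worse than the best singleton)
    chi_single, _, _ = _chi2_batch(pool.curves, Ie, w, cfg.allow_constant)
    best_single = int(np.argmin(chi_single))

    global_best = None
    for _ in range(cfg.n_repeats):
        idx = rng.integers(0, n_pool, size=(pop_n, emax))
        sizes = rng.integers(emin, emax + 1, size=pop_n)
        idx[0, :] = best_single
        sizes[0] = emin
        best_chi = np.inf
        best_chrom = None
        history = []
        stagnant = 0
        for _gen in range(cfg.generations):
            chi2, _, _ = _evaluate(pool.curves, idx, sizes, Ie, w, cfg.allow_constant)
            order = np.argsort(chi2)
            if chi2[order[0]] < best_chi - 1e-15:
                best_chi = float(chi2[order[0]])
                best_chrom = (idx[order[0]].copy(), int(sizes[order[0]]))
                stagnant = 0
            else:
                stagnant += 1
            history.append(best_chi)
            if stagnant >= cfg.stagnation:
                break
            # elitism
            new_idx = np.empty_like(idx)
            new_sizes = np.empty_like(sizes)
            new_idx[:n_elite] = idx[order[:n_elite]]
            new_sizes[:n_elite] = sizes[order[:n_elite]]
            # tournament selection of parents
            n_child = pop_n - n_elite
            tmt = rng.integers(0, pop_n, size=(2 * n_child, cfg.tournament))
            winners = tmt[np.arange(2 * n_child), np.argmin(chi2[tmt], axis=1)]
            p1, p2 = winners[:n_child], winners[n_child:]
            # single-point crossover on the slot arrays
            cut = rng.integers(1, emax, size=n_child)
            child = idx[p1].copy()
            cols = np.arange(emax)[None, :] >= cut[:, None]
            child[cols] = idx[p2][cols]
            child_sizes = np.where(rng.random(n_child) < 0.5, sizes[p1], sizes[p2])
            # per-gene mutation at rate 1/ensemble-size (or configured)
            rate = cfg.mutation_rate
            mrate = (1.0 / child_sizes)[:, None] if rate is None else rate
            mut = rng.random((n_child, emax)) < mrate
            child[mut] = rng.integers(0, n_pool, size=int(mut.sum()))
            # occasional size mutation
            smut = rng.random(n_child) < 0.1
            child_sizes = np.clip(
                child_sizes + smut * rng.choice([-1, 1], size=n_child), emin, emax
            )
            if not cfg.allow_repetition:
                for b in range(n_child):  # repair duplicates
                    s = child_sizes[b]
                    seen = set()
                    for e in range(s):
                        while child[b, e] in seen:
                            child[b, e] = rng.integers(0, n_pool)
                        seen.add(int(child[b, e]))
            new_idx[n_elite:] = child
            new_sizes[n_elite:] = child_sizes
            idx, sizes = new_idx, new_sizes
        if global_best is None or best_chi < global_best[0]:
            global_best = (best_chi, best_chrom, np.array(history))

    chi_best, (slots, size), history = global_best
    members = np.sort(slots[:size])
    mean_curve = pool.curves[members].mean(axis=0)
    chi2v, mu, c = _chi2_batch(mean_curve[None, :], Ie, w, cfg.allow_constant)
    uniq, counts = np.unique(members, return_counts=True)
    weights = counts / counts.sum()
    fitted = ScatteringCurve(
        pool.q.copy(), mu[0] * mean_curve + c[0], None, "ensemble fit"
    )
    flex = flexibility_metrics_arrays(pool.Rg, pool.Rg[members])
    return EnsembleSelection(
        member_indices=members,
        unique_indices=uniq,
        weights=weights,
        chi2=float(chi2v[0]),
        mu=float(mu[0]),
        constant=float(c[0]),
        curve=fitted,
        rg_values=pool.Rg[members],
        dmax_values=pool.Dmax[members],
        rflex_pool=flex["rflex_pool"],
        rflex_ens=flex["rflex_ens"],
        rsigma=flex["rsigma"],
        chi2_history=history,
    )


# ---------------------------------------------------------------------------
# flexibility metrics
# ---------------------------------------------------------------------------


def _hist_entropy(values: np.ndarray, edges: np.ndarray, weights=None) -> float:
    h, _ = np.histogram(values, bins=edges, weights=weights)
    p = h / h.sum() if h.sum() > 0 else h
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def flexibility_metrics_arrays(
    pool_rg: np.ndarray, ens_rg: np.ndarray, n_bins: int = 10
) -> dict[str, float]:
    """Rflex (Shannon entropy of the Rg histogram as % of the uniform
    maximum, for pool and ensemble) and Rsigma (ratio of Rg standard
    deviations, ensemble over pool)."""
    if n_bins < 2:
        warnings.warn("degenerate single-bin histogram; Rflex set to 0", stacklevel=2)
        return {"rflex_pool": 0.0, "rflex_ens": 0.0, "rsigma": 0.0}
    edges = np.histogram_bin_edges(pool_rg, bins=n_bins)
    h_max = np.log(n_bins)
    rflex_pool = 100.0 * _hist_entropy(pool_rg, edges) / h_max
    rflex_ens = 100.0 * _hist_entropy(ens_rg, edges) / h_max
    sd_pool = float(np.std(pool_rg))
    rsigma = float(np.std(ens_rg)) / sd_pool if sd_pool > 0 else 0.0
    return {"rflex_pool": rflex_pool, "rflex_ens": rflex_ens, "rsigma": rsigma}


def flexibility_metrics(
    pool: ConformerPool, selection: EnsembleSelection, n_bins: int = 10
) -> dict[str, float]:
    return flexibility_metrics_arrays(pool.Rg, selection.rg_values, n_bins)
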