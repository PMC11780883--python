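#!/usr/bin/env python
"""Ensemble optimization of the unfolded-state scattering.

Builds a mixed conformer pool (random coils, hairpins, compact
globules), targets the unfolded-state ensemble curve at 1% noise, and
runs the genetic-algorithm selection.  Reports the chi^2 of the fit,
the selected ensemble's Rg statistics against the pool's (Rflex/Rsigma
flexibility diagnostics) and writes the Rg/Dmax histograms.

Writes results/eom_selection.json, results/eom_histograms.csv,
results/eom_fit.dat, and the selected bead models as PDB.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from g4fold import ensemble, io, synth

OUT = Path(__file__).resolve().parents[1] / "results"


def build_pool(q, n_models: int, seed: int):
    """Pool mixing the three conformer classes 2:1:1 (coil:hairpin:globule)."""
    models = []
    for i in range(n_models):
        mode = ("random_coil", "random_coil", "hairpin", "compact_globule")[i % 4]
        models.append(synth.make_bead_chain(24, mode=mode, seed=seed * 7919 + i))
    return ensemble.ConformerPool.from_models(models, q)


def main(seed: int, n_pool: int = 400) -> None:
    OUT.mkdir(exist_ok=True)
    q = synth.default_q_grid(100)
    pool = build_pool(q, n_pool, seed)

    # flexible target: average of a random half of the pool's coil curves
    rng = np.random.default_rng(seed)
    coil_idx = np.array([i for i in range(n_pool) if i % 4 in (0, 1)])
    chosen = rng.choice(coil_idx, size=len(coil_idx) // 2, replace=False)
    target_clean = ensemble.ensemble_curve(pool, chosen)
    target = synth.add_noise(target_clean, 0.01, seed=seed + 1)

    cfg = ensemble.GAConfig(n_repeats=10)
    sel = ensemble.gajoe_select(pool, target, cfg, seed=seed)

    truth_rg = float(np.sqrt(np.mean(pool.Rg[chosen] ** 2)))
    ens_rg = float(np.sqrt(np.mean(sel.rg_values**2)))
    report = {
        "chi2": sel.chi2,
        "mu": sel.mu,
        "constant": sel.constant,
        "n_members": int(len(sel.member_indices)),
        "ensemble_rg_A": ens_rg,
        "generator_rg_A": truth_rg,
        "rg_agreement_pct": 100.0 * abs(ens_rg / truth_rg - 1.0),
        "rflex_pool_pct": sel.rflex_pool,
        "rflex_ensemble_pct": sel.rflex_ens,
        "rsigma": sel.rsigma,
    }
    (OUT / "eom_selection.json").write_text(json.dumps(report, indent=2))

    edges = np.histogram_bin_edges(pool.Rg, bins=15)
    hist_pool, _ = np.histogram(pool.Rg, bins=edges, density=True)
    hist_ens, _ = np.histogram(sel.rg_values, bins=edges, density=True)
    pd.DataFrame(
        {"rg_bin_left": edges[:-1], "pool": hist_pool, "ensemble": hist_ens}
    ).to_csv(OUT / "eom_histograms.csv", index=False)

    from g4fold import saxs

    saxs.write_dat(sel.curve, OUT / "eom_fit.dat", header="GA ensemble fit")
    for rank, i in enumerate(sel.unique_indices[:5]):
        io.write_pdb_beads(pool.models[i], OUT / f"eom_member_{rank}.pdb")

    print(json.dumps(report, indent=2))
    print(
        "\nA flexible target selects a broad ensemble (Rflex close to the "
        "pool's, Rsigma near 1); the ensemble Rg matches the generating "
        "mixture's intensity-weighted Rg."
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
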