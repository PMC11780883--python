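#!/usr/bin/env python
"""Deconvolution of the time-resolved pH-jump scattering series.

Simulates the two-state collapse (24.26 A flexible chain -> 12.27 A
globule, tau = 0.28 s, 118 log-spaced frames over 1 ms - 1.2 s, 1%
noise), then: (1) SVD rank analysis finds exactly two components;
(2) anchored regularized ALS recovers the component profiles and
concentration time-courses; (3) exponential fits of the concentrations
and of the per-frame Guinier Rg(t) recover the relaxation time.

Writes results/tr_rank.json, tr_concentrations.csv, tr_profiles.dat,
tr_rg_track.csv and tr_kinetics.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from g4fold import decompose, io, kinetics, saxs, synth

OUT = Path(__file__).resolve().parents[1] / "results"
TAU_TRUE = 0.28  # s


def main(seed: int) -> None:
    OUT.mkdir(exist_ok=True)
    q = synth.default_q_grid()
    cU, _, dmaxU = synth.flexible_ensemble_curve(24.26, q, n_conformers=100, seed=seed)
    cF, dmaxF = synth.globule_curve(12.27, q)
    ser = synth.simulate_collapse_series(cU, cF, tau=TAU_TRUE, noise_frac=0.01, seed=seed)
    io.series_to_csv(ser, OUT / "tr_series.csv")

    rank = decompose.svd_rank(ser)
    (OUT / "tr_rank.json").write_text(
        json.dumps(
            {
                "rank": rank.rank,
                "singular_values": rank.singular_values[:6].tolist(),
                "noise_floor": rank.noise_floor,
            },
            indent=2,
        )
    )

    dec = decompose.regals_decompose(ser, 2, anchor_first=cU, anchor_last=cF)
    pd.DataFrame(
        {
            "t": ser.times,
            "extended": dec.concentrations[0],
            "collapsed": dec.concentrations[1],
        }
    ).to_csv(OUT / "tr_concentrations.csv", index=False)
    for k, name in ((0, "extended"), (1, "collapsed")):
        saxs.write_dat(
            synth.ScatteringCurve(q, dec.profiles[k], None, name),
            OUT / f"tr_profile_{name}.dat",
        )

    c0 = dec.concentrations[0]
    tau_conc = kinetics.fit_single_exponential(ser.times, c0 / c0.max())
    track = decompose.series_guinier_track(ser, qmaxRg_limit=1.0)
    track.to_csv(OUT / "tr_rg_track.csv", index=False)
    tau_rg = kinetics.fit_single_exponential(track.t, track.Rg)

    report = {
        "svd_rank": rank.rank,
        "tau_true_ms": 1e3 * TAU_TRUE,
        "tau_concentration_ms": 1e3 * tau_conc.tau,
        "tau_rg_track_ms": 1e3 * tau_rg.tau,
        "rg_initial_A": float(track.Rg.iloc[0]),
        "rg_final_A": float(track.Rg.iloc[-1]),
        "regals_chi2": dec.chi2,
        "regals_converged": dec.converged,
        "closure_deviation_pct": 100.0
        * float(
            (dec.concentrations.sum(0).max() - dec.concentrations.sum(0).min())
            / dec.concentrations.sum(0).mean()
        ),
    }
    (OUT / "tr_kinetics.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    print(
        "\nSVD finds two components; the deconvolved concentrations decay/"
        "rise with the generator relaxation time, and Rg(t) collapses "
        "monotonically between the equilibrium endpoints."
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
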