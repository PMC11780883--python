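#!/usr/bin/env python
"""SVD + sequential-model analysis of the slow CD folding kinetics.

Simulates the hand-mixing pH-jump experiment: three CD basis spectra
(denatured chain, early antiparallel-like intermediate, folded hybrid
form) evolving by irreversible sequential kinetics A -> B -> C with
relaxation times 875 s and 5254 s, sampled over 30 - 11000 s in
millidegrees and normalized to molar delta-epsilon (7.1 uM strand,
1 cm path).  The SVD global fit recovers both relaxation times and the
component spectra.

Writes results/cd_series.csv, cd_fit.json, cd_component_spectra.csv,
cd_fractions.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from g4fold import io, kinetics, synth

OUT = Path(__file__).resolve().parents[1] / "results"
TAUS_TRUE = (875.0, 5254.0)  # s
STRAND_CONC = 7.1e-6  # mol/L
PATH_CM = 1.0


def basis_spectra(wl: np.ndarray) -> np.ndarray:
    """Millidegree-scale basis spectra for the three kinetic species."""
    bA = 3.0 * np.exp(-(((wl - 255) / 18) ** 2)) - 6.0 * np.exp(-(((wl - 275) / 12) ** 2))
    bB = 12.0 * np.exp(-(((wl - 290) / 12) ** 2)) - 6.0 * np.exp(-(((wl - 260) / 10) ** 2))
    bC = 21.0 * np.exp(-(((wl - 290) / 11) ** 2)) + 9.0 * np.exp(-(((wl - 268) / 15) ** 2))
    return np.vstack([bA, bB, bC])


def main(seed: int) -> None:
    OUT.mkdir(exist_ok=True)
    wl = np.arange(220.0, 321.0, 1.0)
    basis_mdeg = basis_spectra(wl)
    tg = np.linspace(30.0, 11000.0, 220)
    clean = synth.simulate_cd_series(basis_mdeg, wl, TAUS_TRUE, tg)
    noise = 0.02 * np.sqrt(np.mean(clean.values**2))
    ser_mdeg = synth.simulate_cd_series(basis_mdeg, wl, TAUS_TRUE, tg, noise=noise, seed=seed)

    # normalize ellipticity (mdeg) to molar delta-epsilon before fitting
    ser = synth.SpectraSeries(
        wl, tg, kinetics.cd_normalize(ser_mdeg.values, STRAND_CONC, PATH_CM)
    )
    io.spectra_to_csv(ser, OUT / "cd_series.csv")

    fit = kinetics.sequential_svd_fit(ser, 3)
    pd.DataFrame(
        fit.component_spectra.T, index=pd.Index(wl, name="wavelength_nm"),
        columns=["denatured_A", "intermediate_B", "folded_C"],
    ).to_csv(OUT / "cd_component_spectra.csv")
    pd.DataFrame(
        fit.fractions.T, index=pd.Index(tg, name="t_s"),
        columns=["f_A", "f_B", "f_C"],
    ).to_csv(OUT / "cd_fractions.csv")

    report = {
        "tau1_s": float(fit.relaxation_times[0]),
        "tau2_s": float(fit.relaxation_times[1]),
        "tau1_true_s": TAUS_TRUE[0],
        "tau2_true_s": TAUS_TRUE[1],
        "tau1_err_s": float(fit.relaxation_time_errs[0]),
        "tau2_err_s": float(fit.relaxation_time_errs[1]),
        "intermediate_peak_time_s": kinetics.intermediate_peak_time(
            *fit.relaxation_times
        ),
        "residual_rms": fit.residual_rms,
        "singular_values": fit.singular_values[:5].tolist(),
    }
    (OUT / "cd_fit.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    print(
        "\nThree significant SVD components; the sequential global fit "
        "recovers both relaxation times, with the intermediate peaking "
        "near 1900 s."
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
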