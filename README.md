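# g4fold

Analysis pipeline for the biophysics of G-quadruplex (G4) folding as seen
by small-angle X-ray scattering (SAXS) and circular dichroism (CD): a
human-telomeric oligonucleotide, denatured at alkaline pH as an extended
flexible chain, collapses within a second of a pH jump into a compact
molten-globule-like particle, then matures over hours into the folded
hybrid topology. The package implements every computational stage of that
analysis and exercises it end-to-end on synthetic data with the same
statistical structure as the experiment.

## What it computes

**Equilibrium SAXS** (`g4fold.saxs`)
- Guinier analysis: weighted fit of ln I on q² over a self-consistent
  window with q·Rg ≤ 1.3 (1.0 recommended for flexible chains);
  Rg = √(−3·slope), I(0) = e^intercept.
- Dimensionless Kratky transform (qRg)²·I(q)/I(0) vs qRg — bell-shaped
  with a peak at √3 ≈ 1.73, height 3/e ≈ 1.10 for a globule; an elevated
  plateau → 2 for a flexible chain.
- Regularized indirect Fourier transform to the pair-distance
  distribution P(r) on [0, Dmax] with hard endpoint zeros, plus a Dmax
  scan and P(r)-moment estimators of Rg and I(0).

**Ensemble optimization** (`g4fold.ensemble`)
- Genetic-algorithm selection (5–20 curves per ensemble, repetition and
  constant subtraction allowed, many independent repeats) of a conformer
  sub-ensemble minimizing χ² = (1/(K−1)) Σ[(μ·I_calc − I_exp)/σ]² with the
  closed-form optimal scale μ; flexibility diagnostics Rflex (Rg-histogram
  entropy ratio) and Rsigma (Rg standard-deviation ratio).

**Time-resolved deconvolution** (`g4fold.decompose`)
- SVD rank analysis of the q×time matrix (singular value above the noise
  floor and smooth singular vectors).
- Regularized alternating least squares: non-negative, smooth
  concentration time-courses and component profiles, with the equilibrium
  endpoint curves anchored as fixed profiles.
- Per-frame Guinier tracking Rg(t).

**Kinetics** (`g4fold.kinetics`)
- Multi-start single-exponential fitting (y = offset + A·e^(−t/τ)).
- CD normalization Δε = θ/(32982·c·l) and an SVD + variable-projection
  global fit of spectral series to sequential A→B→C kinetics.

**Collapse thermodynamics** (`g4fold.thermo`)
- Conformational entropy S = R·(n−1)·ln 7 of an n-mer chain, entropic
  barrier ΔG_conf = TΔS, Spolar–Record hydrophobic free energy
  ΔG_hyd = 80·ΔCp, the heat-capacity/surface-area correlation
  ΔCp = 0.134·ΔSASA, and the ensemble-weighted ΔSASA from Shrake–Rupley
  bead-model surface areas.

**Synthetic data** (`g4fold.synth`) — first-class, tested code: coarse
one-bead-per-nucleotide conformers (self-avoiding coils, antiparallel
hairpins, confined globules; bond 5.9 Å ≈ backbone P–P distance), Debye
scattering curves, analytic sphere/Guinier/ideal-chain profiles,
heteroscedastic SAXS noise, two-state collapse series (118 log-spaced
frames, 1 ms–1.2 s) and three-component sequential CD series.

## Worked example

```python
import numpy as np
from g4fold import synth, saxs, decompose, kinetics

q = synth.default_q_grid()                       # 0.005-0.35 1/A
unfolded, models, dmax_u = synth.flexible_ensemble_curve(24.26, q, seed=1)
folded, dmax_f = synth.globule_curve(12.27, q)
series = synth.simulate_collapse_series(unfolded, folded,
                                        tau=0.28, noise_frac=0.01, seed=42)

print(decompose.svd_rank(series).rank)          # 2
track = decompose.series_guinier_track(series, qmaxRg_limit=1.0)
print(round(track.Rg.iloc[0], 2), round(track.Rg.iloc[-1], 2))
                                                # 24.23 12.34
dec = decompose.regals_decompose(series, 2,
                                 anchor_first=unfolded, anchor_last=folded)
c0 = dec.concentrations[0]
fit = kinetics.fit_single_exponential(series.times, c0 / c0.max())
print(round(1e3 * fit.tau))                     # 281
```

The series built from a 24.26 Å flexible chain and a 12.27 Å globule with
a 0.28 s relaxation time shows exactly two SVD components; the Guinier
track runs from 24.2 Å down to 12.3 Å, and the deconvolved extended
component decays with τ ≈ 281 ms — the generator truth back within noise.

The `analysis/` directory holds numbered drivers for each stage
(equilibrium characterization, ensemble fit, time-resolved deconvolution,
CD kinetics, collapse energetics); each prints a short report and writes
its tables under `results/`:

```bash
python analysis/01_equilibrium_saxs.py --seed 1
...
python analysis/05_collapse_thermo.py --seed 1
```

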