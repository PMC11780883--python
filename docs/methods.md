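# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know.

## The system being emulated

A 24-nucleotide telomeric G-quadruplex-forming sequence, alkaline
denatured (extended flexible chain, Guinier Rg ≈ 24.3 Å, effective
Dmax ≈ 70–85 Å) and refolded by a pH jump into a compact particle
(Rg ≈ 12.3 Å, Dmax ≈ 32–38 Å) on a sub-second timescale, followed by
slow (10²–10⁴ s) CD-visible maturation. Scattering frames span
~1 ms–1.2 s with 118 log-spaced time points on a q-grid of
0.005–0.35 Å⁻¹ (200 points) — the instrument range of the emulated
beamline experiment. Log spacing reflects continuous-flow
position-to-time mapping.

## Synthetic conformers and curves (`synth`)

- **Bead chains.** One bead per nucleotide, bond length 5.9 Å
  (≈ backbone P–P distance), bead radius 4.0 Å. `random_coil` is a
  self-avoiding walk (non-bonded exclusion diameter = one bond length,
  which also enforces bond angles ≥ 60° — mild, realistic stiffness).
  `hairpin` builds two antiparallel stems of ⌈n/3⌉ beads 18 Å apart
  (cross-strand P–P scale) joined by an exact-bond-length circular arc;
  orientation is randomized per seed by a rigid rotation so distances
  are deterministic. `compact_globule` confines the walk to a sphere
  sized so the coordinate Rg is ≈ half the random-coil mean (the mean is
  estimated once from an internal fixed-seed sample and cached).
- **Scattering.** The Debye sum with unit form factors, I(0) = N². The
  analytic sphere, Gaussian (Guinier) and ideal-chain (Debye function)
  profiles serve as fixtures with exact known transforms.
- **Unfolded-state fixture.** The mean Debye curve over self-avoiding
  conformers, each rescaled isotropically to the target Rg. Because a
  mixture's Guinier Rg is the intensity-weighted root-mean-square Rg,
  the fixture's Rg is exact by construction while shape dispersion (the
  flexible-chain Kratky plateau) is retained. Its reference Dmax is the
  99.5% mass quantile of the exact pooled pair-distance distribution:
  the effective support of the ensemble P(r). The absolute longest pair
  is an extreme-value statistic whose P(r) mass vanishes; no
  scattering-based estimator can recover it and it would grow without
  bound with the conformer count.
- **Folded-state fixture.** A homogeneous sphere with the target Rg
  (R = Rg·√(5/3)), so Dmax = 2R is sharp and known.
- **Noise.** σ(q) = f·I(q)·(1 + q/qmax), Gaussian, seed-deterministic.
  The (1 + q/qmax) factor mimics the relative-error growth toward high
  q of buffer-subtracted SAXS. Real counting statistics, beam-stream
  misalignment (I(0) discontinuities) and low-q aggregation upturns are
  not emulated.
- **CD series.** Irreversible sequential A→B→C kinetics in closed form;
  fractions sum to one exactly. "x% noise" in the analyses means
  homoscedastic Gaussian noise with σ = x% of the root-mean-square of
  the noiseless matrix — CD photometric noise is additive and
  wavelength-independent, so a homoscedastic floor is the realistic
  choice.
- **SASA.** Shrake–Rupley point counting on a deterministic Fibonacci
  lattice (default 960 points, probe 1.4 Å); deterministic tests need a
  fixed point set. Bead-level SASA is a coarse model: it reproduces the
  *sign and scale* of surface burial on collapse, not atomic values
  (the analysis driver reports it alongside the calorimetric route).

## Equilibrium transforms (`saxs`)

- **Guinier window.** qmax·Rg ≤ 1.3 by community convention, iterated
  to self-consistency (≤ 20 rounds, ties toward the larger window),
  qmin = first point. The Guinier law is exact only for the Gaussian
  profile; on spheres the 1.3 window carries ≈ +2% truncation bias and
  on flexible chains ≈ −2%. Analyses of flexible species therefore use
  qmax·Rg ≤ 1.0 (the usual convention for disordered scatterers); the
  tests document the residual bias rather than hiding it.
- **IFT.** P(r) on a uniform grid (default 101 points) with hard
  endpoint zeros via basis restriction — this makes P(0) = P(Dmax) = 0
  exactly testable. Objective: ‖(A·P − I)/σ‖² + α‖D₂P‖² with
  A_ij = 4πΔr·sinc(q_i r_j). Non-negativity is optional and off by
  default: slightly negative ripples are diagnostic of a misspecified
  Dmax.
- **Automatic α.** The largest α whose reduced misfit stays within a
  margin (5–10% relative, plus 0.05–0.1 absolute) of the attainable
  minimum. An L-curve corner was tried first and abandoned: on
  near-noiseless synthetic curves the corner curvature is numerically
  ill-defined and occasionally selects ~zero regularization. The
  misfit-margin rule is monotone in α and well-defined at every noise
  level. The absolute component of the margin matters only when the
  attainable misfit is ≈ 0 (noiseless data), where a purely relative
  band would collapse.
- **Dmax scan.** Candidates on a linear grid; α calibrated once at the
  scan midpoint and held fixed so χ² values are comparable; the
  smallest candidate within the χ² band whose P(r) tail (last 10% of r,
  ignoring ripples under 1% of the peak) does not change sign. A nearly
  flat χ² profile is returned flagged `low_confidence` — a pure Guinier
  curve carries no support information and the scan must say so.

## Ensemble optimization (`ensemble`)

- χ² uses K−1 degrees of freedom with the closed-form optimal scale μ;
  optional constant subtraction is a second closed-form parameter
  (joint 2×2 linear solve).
- GA internals (unconstrained by the emulated protocol): population 50,
  ≤ 600 generations with early stop after 100 stagnant generations,
  tournament size 3, single-point crossover, per-gene mutation rate
  1/ensemble-size, 10% elitism. Every repeat's initial population is
  seeded with the best single pool member, which (with elitism)
  guarantees the returned ensemble is never worse than the best
  singleton. Defaults: ensembles of 5–20 with repetition, 100 repeats
  (analyses use 3–10 repeats; convergence is typically reached in
  well under 100 generations on these pool sizes).
- Rflex is the Shannon entropy of the Rg histogram (10 bins spanning
  the pool) as a percentage of the uniform maximum ln(nbins), computed
  for pool and ensemble; Rsigma is the ratio of Rg standard deviations.
  The entropy-ratio definition follows the established ensemble-
  optimization convention; it is a convention, not a derived quantity.
- Pool curves come from the Debye sum over bead models, consistent with
  the coarse-grained generator — not all-atom amplitudes with a
  hydration shell.

## Time-resolved deconvolution (`decompose`)

- **Rank.** The intensity matrix is normalized by the per-q *median* σ
  over frames, not by the full σ(q,t): with multiplicative noise
  (σ tracking I) full error normalization cancels the intensity
  evolution and makes any series look rank-1. After per-q scaling the
  noise is ~unit variance and the largest pure-noise singular value
  sits near √n_q + √n_t; a component is significant when its singular
  value exceeds that floor (×1.1) and both singular vectors have lag-1
  autocorrelation > 0.6.
- **ALS.** Objective: Σ w_qt(PᵀC − D)² + λ_c‖D₂C‖², concentrations
  non-negative. Each half-step solves its block exactly (per-time
  Cholesky reduction + bounded least squares for C; per-q weighted
  normal equations, or a band-limited real-space P(r) parameterization,
  for unanchored profiles), so the objective is monotonically
  non-increasing — asserted per iteration in the tests. Anchored
  components have their profile fixed to the supplied equilibrium curve
  exactly; the concentration amplitude absorbs the scale. λ_c "auto"
  scans a log grid and keeps the largest value within 5% of the minimum
  reduced χ². Closure (Σ_k c_k(t) constant) is *not* imposed, so its
  emergence on two-state data is a genuine check (observed deviation
  ≈ 1% at 1% noise). Per-frame scale normalization for concentration
  jumps is available but off by default.
- Component count is fixed at the SVD-selected rank (2 for the
  two-state series); both direct and real-space profile modes are
  provided since either is defensible.

## Kinetics (`kinetics`)

- Exponential fits run from five log-spaced τ seeds plus a log-linear
  estimate of the detrended decay; best χ² wins. τ is parameterized as
  log τ (positivity, unit-scale invariance); uncertainties come from the
  Jacobian, scaled by residual variance when no σ is supplied. A decay
  is only "detected" when the amplitude's 95% CI excludes zero *and*
  the fitted τ is within 10× the observation window — otherwise the
  result is flagged, never silently returned as a success.
- The sequential model is irreversible first-order (closed-form
  fractions; fast, identifiable, and exactly closed). The SVD global
  fit weights right singular vectors by their singular values
  (equivalent to the data-space misfit restricted to the signal
  subspace) and searches only the relaxation times (variable
  projection, 9 log-spaced starts); mixing amplitudes and spectra are
  linear solves. τ estimates within a factor 2 of each other trigger an
  identifiability warning. An optional flag pins the first component's
  spectrum to a measured pre-jump spectrum.

## Thermodynamics (`thermo`)

Seven rotameric states per backbone unit give S = R(n−1)ln 7 with
R = 1.987 cal/(K·mol) — 88.9 cal/(K·mol) for n = 24 (printed literature
arithmetic rounds to 88.6; the ≈0.4% difference is rounding in R).
T defaults to 298.15 K, which reproduces both ends of the 18–26
kcal/mol barrier range from the measured (60.4) and chain-estimate
(88.9) entropies; the experimental temperature is exposed as a
parameter. Sign convention is the folding direction: ΔSASA < 0 ⇒
ΔCp < 0 ⇒ ΔG_hyd < 0. All cal↔kcal conversion goes through one
constant.

## Problem sizes

Defaults used by the tests and the acceptance script: 200-point q-grid,
118-frame series, conformer ensembles of 50–100 chains, pools of 2–400
models, 10-seed Monte-Carlo recovery loops, 150–220 CD time points.
These sizes keep every estimator in its asymptotic regime for this
system while the full pipeline runs in minutes on one CPU.

## Known limitations

- Bead-level conformers reproduce global size/flexibility statistics
  (Rg, Dmax, Kratky class), not atomic detail, hydration-shell
  scattering, hydrogen bonding or base stacking; SASA values are
  model-level.
- Passing recovery tests on this generator shows the estimators are
  correct and calibrated *for data matching the stated noise model*;
  real data add systematic effects (buffer mismatch, aggregation,
  inter-particle interference) that the generator deliberately omits.
- The Guinier window bias is shape-dependent (documented above); for
  unknown shapes the window limit is a user decision.
- The sequential CD model assumes irreversible steps; reversible
  schemes with comparable forward/back rates would need a different
  fraction model.
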