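# Methods

## Model

A balanced repeatability design — P patients, J = 2 observers, K = 2
replicate readings — is analysed metric-by-metric with the mixed-effects
model

    Y_ijk = μ + a_i + ab_ij + ε_ijk,
    a_i ~ N(0, σ_a²),   ab_ij ~ N(0, σ_ab²),   ε_ijk ~ N(0, σ_εj²),

under the constraint `ab_i1 + ab_i2 = 0`: with only two observers the
observer population is not identifiable, so the per-patient biases of the two
readers are forced to cancel and only `b_i ≡ ab_i1` is stored (2P + 5 free
parameters: μ, a_1..P, b_1..P, σ_a, σ_ab, σ_ε1, σ_ε2).  The model assumes
Gaussian, homoscedastic errors within each reader and exchangeable patients;
the absence of trend in the Bland–Altman diagnostics is the practical check
of the Gaussian error assumption.

Derived quantities, all formed per posterior draw: CoV = σ/μ (reported as
|CoV|; the CoV divides each σ draw by the *concurrent* μ draw, so the
reported CoV interval is a genuine joint-posterior summary rather than a
plug-in ratio), percentage repeatability 100·1.96·√2·CoV, and the intraclass
correlations ICC_inter = σ_a²/(σ_a²+σ_ab²), ICC_intra,j = σ_a²/(σ_a²+σ_εj²).

## Sampler

All full conditionals are conjugate (normal for μ, {a_i}, {b_i};
inverse-gamma for the four variances), so the posterior is explored by a
systematic-scan Gibbs sampler with fixed update order
μ → {a_i} → {b_i} → σ_a² → σ_ab² → σ_ε1² → σ_ε2².  One seeded generator
drives each chain and the draw order is part of the public contract: chains
are bit-reproducible.  Defaults: 60,000 sweeps, 10,000 burn-in, thinning 5 —
10,000 retained draws.  The tests and the acceptance script use 12,000
sweeps / 2,000 burn-in / no thinning, which retains the same 10,000 draws
with less wall time; at these problem sizes (P ≤ 200) the two schedules give
indistinguishable summaries.

Priors: μ ~ N(0, (10⁶ × sd(Y))²), variances ~ InverseGamma(10⁻³, 10⁻³ × Var(Y))
by default.  Both hyperparameters scale with the data deliberately: a fixed
inverse-gamma scale is only "vague" for variance components near unit
magnitude — for a component like σ_ε = 0.02 (variance 4 × 10⁻⁴) a fixed scale
of 10⁻³ would contribute ~25 % of the posterior scale, bias σ_ε upward by
~13 % and push frequentist coverage of the 95 % intervals below nominal.
Data-scaling keeps the prior contribution at O(10⁻³) of the residual sum at
every measurement scale and makes the whole posterior exactly equivariant
under unit rescaling (verified bitwise in the tests).  Explicit `Priors`
objects are honoured verbatim and recorded in every chain sidecar and report.

Numerical choices: drawn variances are floored at 10⁻¹² × Var(Y) (a relative
floor, preserving scale equivariance) so degenerate zero-noise data cannot
underflow the conditional precisions; non-finite conditional parameters raise
a `NumericalError` naming the offending block.  Starting values are
method-of-moments estimates (grand mean; centred patient means; half the
observer contrast; replicate-difference and excess-variance σ estimates
floored at 10⁻⁶ of the data scale).

Mixing: the σ components decorrelate within a few sweeps.  μ mixes slowest —
under the centred parameterisation μ and the {a_i} are strongly coupled and
the systematic scan moves their sum only slowly (split-R̂ for μ ≈ 1.07 at
10,000 retained draws vs < 1.01 for every σ).  This is inherent to the
blocking, harmless for the reported quantities (which depend on μ only
through the weakly-varying CoV denominator), and visible through the advisory
split-R̂ diagnostic computed whenever ≥ 2 chains are run.

## Posterior summaries

Each reported quantity is the kernel-density mode of its transformed chain
(mode of the ICC chain, never ICC of the σ modes) with the empirical
2.5–97.5 % percentile range (linear interpolation between order statistics —
the numpy default, fixed as part of the contract).  The mode estimator:
uniform seeded downsampling to at most 10,000 draws, Gaussian kernel with
Silverman bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on a
1000-point uniform grid over the sample range; ties break toward the lower
grid point; a constant sample is returned as-is.  Note the argmax of a KDE
has sampling scatter ≈ 0.134·sd·(n/10⁵)^(−1/4), i.e. mode estimates of broad
posteriors are intrinsically noisier than means — the tests therefore check
the operator against an independent KDE implementation exactly, and its
statistical calibration on sharp densities.

## Classical cross-checks

* σ_εj from replicate differences: a difference of two readings has variance
  2σ_εj² under the model, so σ̂_εj = √(Σᵢ dᵢ² / 2P) assuming zero-mean
  differences.  (The √(Σd²/P) variant — the SD of the differences
  themselves — is available behind `normalization="plain"`.)
* Bland–Altman: per-patient (replicate mean, replicate difference) pairs,
  with zero-centred 95 % repeatability limits ±1.96·√2·σ̂_εj, which equal
  ±1.96 × SD(difference) under the zero-bias model.
* Method-of-moments ANOVA components for the 2 × 2 layout: within-cell
  scatter gives σ_εj²; the patient-wise observer contrasts
  cᵢ = (Ȳ_i1 − Ȳ_i2)/2 have second moment σ_ab² + (σ_ε1²+σ_ε2²)/8; patient
  means carry no bias contribution (the constraint cancels it) and have
  excess variance (σ_ε1²+σ_ε2²)/8.  Negative moment estimates are clamped at
  zero with a warning.  These plug-in ICCs serve as fast point-estimate
  oracles for the Bayesian modes (agreement within 0.05 at P = 200 is part of
  the test suite), and an affine-invariant ensemble sampler (emcee) run on
  the joint posterior provides a fully independent MCMC cross-check.

## Synthetic data

No measurement tables or images from two-radiologist WB-DWI repeatability
studies are publicly deposited, so the generator provides every input:

* **Measurement tables** drawn exactly from the model above.  Default
  per-metric population values mirror a real nine-patient study's magnitudes,
  back-calculated from published mode/CoV ratios (μ = σ_ab/CoV) and ICCs —
  e.g. median gADC: μ = 0.914, σ_a = 0.180, σ_ab = 0.0181,
  σ_ε = (0.0179, 0.0190), in units of 10⁻³ mm²/s.  They are plausible
  fixtures, not measured data.
* **Voxel ADC sets**: a Gaussian base component (default
  N(0.8 × 10⁻³, (0.1 × 10⁻³)²) mm²/s, 0.045 ml voxels ≈ 3×3×5 mm) with a
  deterministic count round(n × fraction) of high-ADC outliers at seeded
  positions; the base sample is drawn before any outlier randomness so
  contamination comparisons share identical base draws.  Values are truncated
  at zero (a < 10⁻¹⁴ perturbation of normality at the defaults).
* **End-to-end reader study**: per patient a base lesion voxel set (patient
  mean ADC and lesion size vary across patients) plus a fixed higher-ADC
  "equivocal lesion" cluster (default 2 % of voxels at 1.9 × 10⁻³ mm²/s);
  each of the four readings includes the cluster with probability 0.25
  (observers disagreeing whether an equivocal site is active disease), adds
  small per-voxel reading noise (0.005 × 10⁻³ mm²/s), and re-traces the
  boundary (random subsampling, 2 % SD).  The standard ADC > 2.0 × 10⁻³
  exclusion is applied before the gADC statistics.  This reproduces the
  studied instability mechanism: the cluster barely moves median/mean gADC
  and log-tDV but destabilises variance, skewness and kurtosis, so their
  percentage repeatability is an order of magnitude worse.

What the generator does *not* emulate: image geometry (no voxel grids or
spatial correlation), scanner/protocol variability, repositioning or
biological change between sessions, non-Gaussian ADC distributions within
lesions, or correlated observer behaviour beyond the single
cluster-inclusion mechanism.  Passing tests therefore demonstrate that the
estimation machinery is correct and calibrated under the stated model, not
that real observer errors follow it.

## Problem sizes and calibration evidence

The test suite establishes, at sizes chosen to be decisive yet quick:
conditional-distribution correctness against grid-integrated densities
(P = 2, 10⁵ draws, 3-SE tolerance); parameter recovery at P = 100 (modes
within 25 % of truth, truth inside all 95 % intervals, ICC mode within 0.05
of closed form); frequentist coverage at study scale (100 seeded P = 9
replicates; ≥ 90 must cover — measured 95–98 per component); classical vs
Bayesian agreement at P = 200; exact scale/location equivariance; and the
outlier-sensitivity ordering end-to-end.

## Known limitations

* Specific to the 2-observer, 2-replicate design; the constraint and the
  (2P + 5)-parameter count do not generalise to J > 2 or K > 2.
* KDE modes of broad, skewed posteriors (small P) carry both sampling and
  bandwidth sensitivity; the credible range is the more stable summary.
* CoV and percentage repeatability assume μ > 0 on the metric's scale;
  metrics with near-zero population mean (possible for gADC skewness) make
  CoV unstable, and draws with μ = 0 are excluded with a warning.
* The ANOVA components can go negative at small P (clamped, flagged); the
  Bayesian machinery is the primary inference path there.
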