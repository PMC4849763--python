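# dwirepeat

Observer repeatability of quantitative whole-body diffusion-weighted MRI
(WB-DWI) biomarkers.

## The problem

Whole-body DWI with semi-automatic tumour segmentation yields quantitative
biomarkers of metastatic bone disease: the **total diffusion volume** (tDV,
ml; reported as its natural log, log-tDV) and the **global apparent diffusion
coefficient** (gADC) — the pooled distribution of ADC values (mm²/s) over all
segmented disease voxels, summarised by its median, mean, variance, skewness
and (non-excess) kurtosis.  Before such metrics can be used to call treatment
response in an individual patient, one must know how much of their variation
is observer-induced: two radiologists will not segment identical volumes, and
the same radiologist will not segment identically twice.

`dwirepeat` implements the statistical machinery for a balanced repeatability
study — P patients, each read twice by each of two observers — and a
synthetic-data generator standing in for the (undeposited) patient images of
such studies.

## The model

Each metric is modelled with the constrained two-observer mixed-effects model

    Y_ijk = μ + a_i + ab_ij + ε_ijk,          i = 1..P,  j, k ∈ {1, 2}

with patient effects `a_i ~ N(0, σ_a²)`, observer biases `ab_ij ~ N(0, σ_ab²)`
constrained by `ab_i1 + ab_i2 = 0` (two observers admit no observer-population
statistics), and within-observer errors `ε_ijk ~ N(0, σ_εj²)` — 2P + 5 free
parameters.  The posterior under vague conjugate priors is sampled by a
systematic-scan Gibbs sampler, giving full posterior distributions for

* **inter-observer repeatability** σ_ab, and **intra-observer repeatability**
  σ_εj per reader;
* the coefficients of variation CoV = σ/μ and the **percentage
  repeatability** 100 × 1.96 × √2 × CoV — the smallest relative change in a
  single patient declarable significant at p < 0.05;
* the intraclass correlation coefficients
  ICC_inter = σ_a²/(σ_a² + σ_ab²) and ICC_intra,j = σ_a²/(σ_a² + σ_εj²).

Every quantity is reported as the kernel-density mode of its (per-draw
transformed) posterior chain with a 2.5–97.5 % credible range.  Classical
cross-checks — Bland–Altman replicate analysis, the replicate-difference
estimate of σ_εj, and method-of-moments ANOVA ICCs — are provided alongside.

## Worked example

```python
import dwirepeat as dr

# a nine-patient study at published magnitudes (synthetic; ADC statistics in
# units of 1e-3 mm^2/s)
table = dr.simulate_table(dr.metric_spec("median_gadc", P=9, seed=1))

model = dr.GibbsRepeatability(random_state=1).fit(table)
rep = model.report_

def fmt(s, scale=1.0):
    return f"{scale*s.mode:.2f} ({scale*s.ci_low:.2f}-{scale*s.ci_high:.2f})"

print("sigma_ab (x100):      ", fmt(rep.sigma_ab, 100))
print("CoV_inter (x100):     ", fmt(rep.cov_inter, 100))
print("% repeatability inter:", fmt(rep.pct_rep_inter))
print("ICC_inter:            ", fmt(rep.icc_inter))
```

prints

```
sigma_ab (x100):       1.06 (0.40-2.31)
CoV_inter (x100):      1.12 (0.42-2.44)
% repeatability inter: 3.11 (1.16-6.77)
ICC_inter:             1.00 (0.96-1.00)
```

i.e. for this simulated cohort the two observers' median-gADC readings differ
by a bias SD of ~0.011 × 10⁻³ mm²/s (CoV ≈ 1.1 %), a single-patient change
of more than ~3 % would be declarable significant, and essentially all
between-reading variance is genuine patient variance (ICC ≈ 1.0).  The
classical estimators agree:

```python
ba = dr.BlandAltman(observer=1).fit(table)
an = dr.AnovaICC().fit(table)
print(f"Bland-Altman R1: bias {ba.bias_:.5f}, sigma {ba.sigma_:.5f}, "
      f"limits ({ba.loa_low_:.5f}, {ba.loa_high_:.5f})")
print(f"ANOVA ICC_inter {an.icc_inter_:.3f}, ICC_intra {an.icc_intra_.round(3)}")
```

```
Bland-Altman R1: bias -0.01161, sigma 0.01533, limits (-0.04250, 0.04250)
ANOVA ICC_inter 0.991, ICC_intra [0.984 0.987]
```

The same pipeline is scriptable from the shell (`dwirepeat simulate`,
`dwirepeat metrics`, `dwirepeat fit`, `dwirepeat bland-altman`,
`dwirepeat report`); all tabular I/O is CSV, reports are JSON, and every
artifact embeds the seed and a config hash for bit-exact reproduction.

## Voxel-level metrics

`dwirepeat.metrics` computes the biomarkers themselves from voxel ADC sets:
the two-point mono-exponential ADC fit, computed-DWI extrapolation to
synthetic high b-values, the ADC > 2.0 × 10⁻³ mm²/s necrosis exclusion, and
the gADC/tDV summary.  `dwirepeat.simulate` generates contaminated voxel sets
reproducing the key fragility of histogram metrics: replacing as little as
0.5 % of voxels with high-ADC values leaves the gADC median essentially
unchanged (< 0.1 %) while variance, skewness and kurtosis shift by tens to
hundreds of percent — which is why higher-order gADC statistics repeat so
much worse than median/mean gADC and log-tDV.

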