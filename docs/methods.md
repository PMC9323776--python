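# Methods

## The problem

Windmill palm fiber (WPF) is a lignocellulosic fiber whose Young's modulus
governs its usefulness for spinning. Measuring the modulus mechanically is
slow (45 single-fiber tensile tests per sample); measuring composition by wet
chemistry is slower still. The package implements the fast chain: NIR
spectroscopy → PLS → composition → grey model → modulus, together with the
reference methods both calibrations rest on.

## System-compliance tensile analysis

A single-fiber tensile test measures total crosshead displacement ΔL, which
includes the compliance of the machine and grips. Testing at several gauge
lengths L₀ identifies the fiber: with F the breaking force and A the fiber
cross-section,

    ΔL/F = (L₀/A)/E + C_S.

`ComplianceModel` fits this line by ordinary least squares (scipy's
`linregress`); E = 1/slope is in MPa because the slope carries mm²/N, and the
intercept C_S (mm/N) is the system compliance. Negative intercepts are
accepted — three of the study's fifteen fits print negative C_S and a small
negative intercept is within noise of a stiff load train — but a non-positive
*slope* is a hard error, since it implies a non-positive modulus. Raw records
(L₀, A, ΔL, F) are reduced to points by exact division with no replicate
averaging, which is the smallest-assumption reading of the protocol.

## GM(1,N) grey model

The grey model treats a short reference series (the modulus of samples
k = 1..n) as driven by comparative series (the three component contents).
Processing:

1. initialization X(0)(k) = X(k)/X(1), making every series dimensionless
   with first element exactly 1;
2. AGO, the running cumulative sum X(1)(k), which damps sample-to-sample
   fluctuation;
3. the mean-generating sequence Z₁(k) = ½(X₀(1)(k−1) + X₀(1)(k)) for k ≥ 2.
   (An alternative convention indexes the pair at (k, k+1); the
   consecutive-pair form implemented here is the one the study's own
   intermediate table follows.)
4. least squares on X₀(0)(k) = Σᵢ bᵢ Xᵢ(1)(k) − a Z₁(k) over k = 2..n. The
   design's mean-term column carries the minus sign, so the solved vector is
   (a, b₁..bₘ) with the conventional signs: a is the development coefficient,
   bᵢ the grey action quantities, and sign(bᵢ) classifies driver i as
   promoter or inhibitor of the reference.

Estimation uses `numpy.linalg.lstsq` (SVD) rather than the normal-equations
inverse; equivalence to (BᵀB)⁻¹BᵀY is asserted in the tests on
well-conditioned designs, not relied on numerically. Rank deficiency and
under-determined systems raise `RankError` with condition diagnostics.

### Reproduction modes

The study's printed tables are mutually inconsistent (see below), so
`palmfiber.reproduce` exposes two input modes. `"printed"` feeds the
published cumulative/mean table and coefficients verbatim — this reproduces
the published error analysis (per-sample relative errors, average 0.29).
`"recomputed"` rebuilds every sequence from the component table and the
printed moduli; the differences between the two are reported, never hidden.
Re-estimating (a, b) by least squares is reported as a *diagnostic* next to
the published coefficients in both modes: exact agreement is not expected,
because the design the study solved is only available rounded to 2 dp and
the identity of one regressor column is ambiguous (below).

### Rounding policy

Comparisons against printed values round half away from zero to 2 dp (the
tables' apparent convention) and allow ±0.01 where the inputs are themselves
2-dp-rounded, since a cumulative sum of rounded values legitimately drifts by
a unit in the last place.

## Errata in the packaged tables

`datasets.consistency_report()` flags, deterministically:

* five compliance-line rows (4, 7, 9, 13, 14) whose printed modulus differs
  from 1/slope by a leading digit (>1% relative); which of slope or E carries
  the typo is undecidable, and the grey-model reproduction follows the
  printed E column, which is what the cumulative table tracks;
* the cumulative-modulus entry at k = 12 (printed 20.61, implied 21.61);
* the regressor-column identities: no printed cumulative column matches any
  component's AGO over all 15 rows (±0.015). The closest matches are
  x3 ↔ cellulose and x2 ↔ hemicellulose (agreeing through k = 7) and
  x1 ↔ lignin (through k = 4), which contradicts the stated ordering
  (1 = cellulose, 2 = hemicellulose, 3 = lignin). Both labellings are
  carried; recomputed mode uses the stated ordering.
* the final error-analysis row duplicating the first;
* the stated calibration-set ranges for cellulose and lignin, which are
  swapped relative to the component table;
* one external-validation absolute error (0.73 printed vs 0.09 implied).

Fixtures always hold the printed values verbatim; corrections appear only in
reports.

## NIR / PLS calibration

Preprocessing steps operate per spectrum and are freely composable; the
default chain is unit-vector normalization → Savitzky–Golay first derivative
(window 15 points, polynomial order 2 — common NIR practice; the window is a
config parameter) → SNV. PLS is single-response NIPALS with mean centering
and no predictor scaling (`sklearn.cross_decomposition.PLSRegression,
scale=False`). RMSEC/Rc² come from the full-data fit; RMSEP/Rcv² from
leave-one-out cross-validation with the entire pipeline refit per fold.
Cross-validated R² is reported as computed, negative values included. Factor
selection minimizes LOO RMSEP with ties (at 1e-6 relative) resolved toward
fewer factors.

External validation computes per-sample absolute errors and the paired
two-tailed t statistic |mean(d)/(sd(d)/√n)| with d = predicted − measured and
the n−1-denominator standard deviation; with three validation samples the
critical value is t₀.₀₅(2) = 4.303. A zero-spread nonzero-mean difference is
reported as t = ∞ (significant).

The spectral grid is wavenumber in cm⁻¹ over 4,000–12,000; the synthetic
default step is 4 cm⁻¹ (2,001 points). The acquisition interval of the
original instrument is stated in mixed units in the source and is not
recoverable; the step is therefore a simulation parameter, not a claim about
the instrument.

## Synthetic data: what it emulates, and what it does not

No raw spectra or tensile curves were deposited, so generators stand in:

* **Component profiles** — uniform draws within the observed per-component
  ranges (cellulose 7.93–80.58%, hemicellulose 10.33–20.96%, lignin
  3.94–76.97%), rejection-resampled into a closure window: the three
  structural polymers must total 85–100% of dry mass. The closure bound
  reflects real lignocellulose (the packaged component table's totals run
  75–99% with 23 of 26 samples ≥ 85%) and is what makes shape-based
  quantification after SNV identifiable — scale-removing preprocessing can
  only work when composition, not total absorbance, carries the information.
* **Spectra** — Beer–Lambert mixtures: absorbance = (1 + s)·Σᵢ cᵢ·pureᵢ(ν) +
  baseline + noise, with each pure-component spectrum a sum of 5–6 Gaussian
  bands placed in the 4,000–9,000 cm⁻¹ overtone/combination region with
  deliberate overlap between components. Band positions/intensities are
  synthetic, not spectroscopic assignments. Per-sample multiplicative scatter
  s is uniform ±15% (powder diffuse reflectance is scatter-dominated — the
  regime SNV exists to correct), the linear baseline offset is 0–0.1 AU, and
  additive noise is 0.002 AU.
* **Tensile points** — the 3 gauge lengths × 15 replicates design, areas
  ~N(0.1, 0.02²) mm² (redrawn if ≤ 1e-4), Gaussian noise of 0.01 mm/N on
  ΔL/F.
* **Grey systems** — reference series forward-generated to satisfy the grey
  difference equation exactly for known (a, b): X₀(0)(k) =
  [Σ bᵢXᵢ(1)(k) − a X₀(1)(k−1)] / (1 + a/2), requiring 1 + a/2 ≠ 0.

All generators are pure functions of (config, seed); one global seed expands
into fixed per-generator substreams.

What passing tests on these data do **not** show: that real WPF spectra obey
a 3-component bilinear model (real fibers contain water, extractives and
pectin, and scatter is wavelength-dependent), that the true band structure is
separable at these overlaps, or that the published calibration statistics are
reproducible — they are not, since the spectra were never deposited. The
synthetic results demonstrate correctness of the *procedure*, not the
instrument-level performance.

## Problem sizes and accuracy expectations

Default simulations mirror the study scale: 26 spectra × 2,001 grid points,
45 tensile points, grey systems of length 15. At that scale the full suite
and the acceptance computation each run in seconds. Cross-validated R² at the
defaults is ≈ 0.97–0.99 for cellulose and lignin; hemicellulose saturates
near 0.92 under any preprocessing because its range is narrow (10.6
percentage points) relative to the residual noise at n = 26 — consistent
with the source calibration's own hemicellulose Rcv² of 0.93. Stochastic
comparisons between preprocessing chains use a 0.01 margin on mean R²cv over
three seeded replicates, the replicate-noise scale of that statistic.

## Known limitations

* The GM(1,N) implementation covers the algebraic fit used here; it does not
  solve the whitenization differential equation, so no out-of-sample
  time-extrapolation (GM(1,1)-style forecasting) is provided.
* The compliance fit assumes a shared E across gauge lengths and homoscedastic
  noise in ΔL/F; no Weibull strength analysis is attempted.
* The published grey coefficients cannot be verified to be the exact LS
  solution of the unrounded design (the unrounded design was never
  published); the package reports deviations instead of asserting equality.
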