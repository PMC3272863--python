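# Methods

## Model

For a group of K neighboring voxel time courses, stacked as the columns of
an n x K matrix **Y**, and an n x p temporal design **X** (both column
centered, no constant column), the multivariate multiple regression model
**Y** = **X** **B** + **E** is collapsed to a single equation by a spatial
weight vector **α**:

    Yα = Xβ + ε,     β = B α.

Minimizing ‖Yα − Xβ‖² over both vectors (up to scale) is equivalent to
canonical correlation analysis: the optimal α is the leading eigenvector of
S_yy⁻¹ S_yx S_xx⁻¹ S_xy with eigenvalue λ_m = r², r the maximal canonical
correlation, and β follows by ordinary least squares on Yα.  The weight
vector acts as a data-adaptive local smoothing kernel.

Two spatial constraints make the kernel behave like a smoothing filter and
protect specificity: all components of α must share one sign, and the
center voxel's weight must be at least 20 % of the maximum weight
(`center_min_fraction`, configurable).  Constraints are enforced by
filtering: the unconstrained CCA solution of every candidate voxel
configuration inside the 3 x 3 neighborhood is computed and infeasible
solutions discarded; among feasible ones the largest r wins.  The
single-voxel configuration is always feasible and is the fallback.  The
exhaustive search enumerates all 2⁸ = 256 center-containing subsets; the
region-growing search starts from the center and greedily adds the neighbor
with the largest feasible r until the improvement falls below 1e-6 (ties
broken by smallest lexicographic offset, for determinism).  Greedy growth
can only reach, never exceed, the exhaustive optimum; on random synthetic
patches it attains ≥ 99 % of the exhaustive correlation in well over 95 %
of neighborhoods (verified in the test suite).

## Directional contrast statistic

For a contrast vector c over the regressors, the null hypothesis
c′**B**α = c′β = 0 is tested through the scalarized Wilks' Λ

    Λ = E / (E + H),   E = (Yα − Xβ)′(Yα − Xβ),
                       H = (c′β)² / (c′(X′X)⁻¹c),

signed by sign(c′β).  The equivalent t-like form

    t_c = c′β √DF / √(c′(X′X)⁻¹c · E),   DF = n − p − K,

is used for mapping; Λ± = sign(t_c)/(1 + t_c²/DF) links the two forms
exactly, and t_c is invariant to the overall scale of α.  The degrees of
freedom charge the kernel size K, so the same effect estimated from fewer
voxels is more significant.  For K = 1, t_c is the classical GLM contrast
t with DF = n − p − 1.  Because of the adaptive kernel (and the temporal
and spatial correlation of fMRI noise) t_c is *not* t-distributed under the
null — its null spread on correlated data visibly exceeds the t(DF)
reference — so no parametric p-values are ever attached to it; the t CDF
appears nowhere in inference.  An unsigned F-type companion,
F = ((1 − Λ)/Λ)(ν_E/ν_H), covers multi-regressor effects without a
direction.

## Nonparametric family-wise-error control

Significance comes from the null distribution of the maximum statistic over
the map, estimated from phase-randomized surrogates of resting-state data:

1. Statistic maps are computed on surrogates and pooled; a Gaussian kernel
   density estimate of the pooled null (Silverman bandwidth, tail
   integrated analytically) converts any value to an upper-tail p, and
   −log p is approximately unit exponential under the null.
2. From each surrogate's k largest transformed order statistics
   Y¹ ≥ … ≥ Yᵏ and the anchor Y^{k+1}, the normalized spacings
   dᵢ = i(Yⁱ − Yⁱ⁺¹) are formed; for exponential samples they are i.i.d.
   exponential and the order statistics reconstruct exactly as
   Yʲ = Y^{k+1} + Σ_{i=j..k} dᵢ/i.
3. Resampling the spacings with replacement and rebuilding Y*¹ yields
   bootstrap draws of the per-map maximum; the (1 − α) quantile estimates
   the corrected threshold.

Defaults: k = 100, α = 0.05, 10 000 bootstrap draws.  When several
surrogates are available, each one contributes its own quantile estimate
and the estimates are averaged.  Pooling the bootstrap max *samples*
instead was measured (in an exact-exponential control experiment) to
inflate the threshold noticeably: the mixture convolves the
between-surrogate sampling variation of the order statistics into the null
of the maximum.  Averaging per-surrogate quantiles removes that bias.
Directional statistics are calibrated on the positive tail; the negative
tail mirrors the procedure on the negated statistic.  Thresholds are mapped
back to the raw statistic scale by monotone inversion of the transform.

## Synthetic data

All validation inputs are generated programmatically.

**Fourier surrogates.** One conjugate-symmetric random phase vector is
added to the rFFT phases of *every* voxel series (DC kept at zero shift to
preserve means; Nyquist kept real).  Per-voxel amplitude spectra are
preserved exactly, and because all voxels receive the same rotation,
inter-voxel phase differences — hence spatial correlations — are preserved
too.

**Resting-noise stand-in.** Per-voxel stationary AR(1) noise, smoothed
in-plane with a Gaussian kernel, then re-standardized to unit variance per
voxel.  Defaults: AR coefficient 0.5 (lag-1 autocorrelation typical of
unwhitened gray-matter BOLD at TR = 2 s) and spatial FWHM 1.2 voxels.  The
FWHM is calibrated to the *unsmoothed* EPI noise the method consumes:
under this construction it yields adjacent-voxel correlation ≈ 0.28 and
diagonal ≈ 0.09, matching the ~0.3 reported for raw EPI noise.  (FWHM 2
would give adjacent correlations near 0.7 — the signature of data already
passed through an analysis smoothing kernel.)  What the stand-in does
*not* reproduce: 1/f low-frequency drifts, physiological cardiac and
respiratory bands, motion residuals, and anatomical heterogeneity of the
noise; conclusions from passing tests therefore concern the statistical
machinery, not preprocessing robustness on real scans.

**Activation and mixture.** An activation time course is a linear
combination of the design regressors with amplitudes β₁..β₄ drawn uniform
on [0, 1], variance-normalized to 1.  Active voxels receive
(1 − f)·x_act + f·x_null with noise fraction f; other voxels keep their
noise.  f = 0.55 and 0.65 give peak SNR ((1 − f)/f)² of 67 % and 29 % (the
low- and high-noise regimes).  Activation shapes are random
center-containing subsets of the 3 x 3 grid with size uniform on
{2, …, 9}.  Truth labels are exact by construction, enabling ROC analysis.

**Recovery target.** Because x_act is variance-normalized and mixed with
weight (1 − f), the coefficients actually present in an active voxel are
(1 − f)·β/σ with σ = sd(Σβᵢ·regressorᵢ).  Amplitude-recovery error is
measured against this injected vector: measuring against the raw draws
would be dominated by the common normalization scale, which no estimator
can recover and which affects every method identically.

## Detectors and evaluation

* GLM-NS — per-voxel GLM contrast t, no smoothing.
* GLM-GS — the same after fixed isotropic Gaussian smoothing of every time
  point, FWHM 2.24 voxels: the square root of the mean size (5) of the 256
  center-containing 3 x 3 configurations, so the fixed kernel matches the
  adaptive one in average extent.
* cCCA-RG — constrained CCA by region growing, scored with t_c and
  per-voxel DF = n − p − K.

Metrics: per-regressor MSE of recovered amplitudes; ROC curves with the
area restricted to false-positive fraction ≤ 0.1 ("AUR", trapezoidal with
linear interpolation at the 0.1 endpoint — perfect separation attains 0.1,
chance ≈ 0.005); total false fraction (FP + FN)/total; and the gray-matter
confinement ratio count(detected ∧ GM)/count(detected ∧ ¬GM), reported as
infinity when nothing is detected outside gray matter.

## Problem sizes

Simulation studies run at desk scale, chosen to keep the full suite and the
acceptance script in the minutes range while leaving Monte-Carlo error well
below the effects being measured: 2 000 amplitude-recovery replicates
(3 x 3 patches, memory design, n = 283), 500 patches for the
region-growing/exhaustive equivalence study, 20 x 20 slices for detection
experiments, and 200 null replicates of 16 x 16 slices (40 calibration
surrogates) for the realized-FWE study.  All replicate counts are
overridable.

## Numerical choices and degenerate inputs

* The CCA eigenproblem is solved as an SVD of the whitened cross-covariance
  S_yy^{-1/2} S_yx S_xx^{-1/2} rather than the nonsymmetric product — the
  singular values are bounded by 1 and the computation is stable for
  ill-conditioned voxel covariances.
* Near-singular S_yy (condition number > 1e12, e.g. duplicated series) gets
  a ridge of 1e-10·trace/K and a warning instead of an exception.
* Eigenvector sign is fixed by sum(α) ≥ 0, so the same-sign constraint
  means α ≥ 0; α is scaled to unit sum of magnitudes (the statistic is
  scale invariant, but this keeps error terms comparable to the GLM's).
* A canonical eigenvalue exceeding 1 by more than 1e-6 raises a numerical
  failure; within tolerance it is clipped.
* Zero residuals (noise-free fits) raise a perfect-fit error rather than
  returning infinite statistics; c′β exactly 0 maps to statistic 0.
* Tail p-values are clipped at 1e-300 with a warning before the log.
* Region growing stops on improvement ≤ 1e-6 in r; candidate ties break by
  smallest lexicographic offset.
* Rank-deficient designs raise an error naming the offending columns
  (pivoted QR); constant regressors are rejected at construction.

## Known limitations

* Neighborhoods are 2D (per slice); the 3D 3 x 3 x 3 window appears only in
  configuration counting (2²⁶ subsets make per-voxel enumeration
  impractical without a heuristic).
* Temporal prewhitening is not implemented; the nonparametric calibration
  absorbs temporal autocorrelation of the null instead.
* Only the maximal canonical pair is used, and only vector contrasts (the
  multi-row contrast matrix case would need the full matrix Wilks
  machinery).
* The greedy search is validated against the exhaustive oracle
  empirically, not guaranteed optimal.
* Realized FWE is calibrated conditional on the resting dataset the
  surrogates are drawn from; across base datasets the realized rate
  fluctuates around nominal.
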