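# Methods

## The measures

For n z-scored regional signals X_1(t), …, X_n(t), the multivariate moment
m_{i,j,…} is the temporal average of the product of the listed signals.
Moments of order > 2 are not by themselves evidence of higher-order
dependence: with positive pairwise covariances, a fourth moment is positive
even when the four signals are jointly Gaussian.  The non-redundant part of
a moment — the part not expressible through lower-order moments — is the
corresponding multivariate **cumulant**, which vanishes for Gaussian
signals at orders > 2.  With zero means, cumulants up to order three equal
the moments, and the fourth-order cumulant is

    c_ijkl = m_ijkl − m_ij m_kl − m_ik m_jl − m_il m_jk.

Normalizing by the signals' standard deviations gives the dimensionless
measures implemented here:

* **correlation** r_ij (Pearson),
* **coskewness** r^c_ijk = c_ijk / (σ_i σ_j σ_k) — multivariate skewness,
* **cokurtosis** r^c_ijkl = c_ijkl / (σ_i σ_j σ_k σ_l) — multivariate
  excess kurtosis,
* **edge connectivity** ε_{ij,kl} = m_ijkl / √(m_iijj m_kkll), the cosine
  similarity of the two edge product signals X_i X_j and X_k X_l; its
  **redundant part** replaces all fourth moments by their Wick pairings of
  second moments, and the **corrected** edge connectivity is raw minus
  redundant, which is zero for Gaussian data.

Orders above four are out of scope (the number of tuples and the estimator
variance both explode), as is time-resolved edge-time-series analysis.

### Estimation conventions

Estimators are plug-in: population moments are replaced by 1/T temporal
averages of the z-scored signals.  Signals are z-scored with the standard
conventions — mean with 1/T, variance with 1/(T−1).  A deliberate
consequence is that the second self-moment of a standardized row is
(T−1)/T, so the "self-correlation" r̂_ii is (T−1)/T rather than 1; the
estimators do not correct for this, they document it (a warning is raised
for self-pair correlation queries).  After standardization every σ_i = 1,
so the normalizing divisions are omitted.  Public measures require
distinct regions; repeated-index moments (m_iijj etc.) are available
internally because the edge formulas need them.  Inputs not flagged as
standardized are z-scored automatically (logged at debug level).
Standardization is per subject; group maps average per-subject estimates.

## The generative model

Synthetic signals come from a first-order vector-autoregressive process
driven by the sum of a Gaussian and a shared non-Gaussian innovation:

    X_i(t+1) = φ X_i(t) + Z_i(t) + ψ U(t),

with Z(t) an equicorrelated Gaussian vector (unit variances, pairwise
correlation ρ, generated through the symmetric square root of the
equicorrelation matrix) and the same scalar U(t) added to every region.
Parameters, with defaults used throughout the studies:

| parameter | meaning | default |
|---|---|---|
| τ | autocorrelation time-scale in samples; φ = exp(−1/τ), so the lag-k autocorrelation is exp(−k/τ) | 2 |
| r | target pairwise signal correlation; ρ = r + (r−1)ψ² | 0.4 |
| ψ | strength of the shared non-Gaussian innovation, restricted to [0, 1] | — |
| innovation | skew-normal (shape α) for third-order structure, unit-variance Student-t (ν ≥ 5) for fourth-order structure | — |
| T | scan length in samples | 1200 |

τ = 2 and T = 1200 correspond to a typical resting-state fMRI session:
a time-scale of about two samples matches group-level autocorrelation of
band-pass-filtered parcel signals, and with a repetition time of 0.72 s,
1200 samples is a 14.4-minute scan.  r = 0.4 is slightly high but within the experimental
range, and must exceed 1/4 (n = 3) or 1/3 (n = 4) for the innovation
covariance to be positive definite at every ψ ∈ [0, 1]; `validate`
enforces the exact condition ρ > −1/(n−1) and reports the conservative
bound r > 1/2 − 1/(2(n−1)).

Because cumulants are additive over the independent innovations of the
stationary solution, every ground truth is closed-form: pairwise
correlation (ρ+ψ²)/(1+ψ²); coskewness
(1−φ²)^{3/2} ψ³ c3U / ((1−φ³)(1+ψ²)^{3/2}); cokurtosis
(1−φ²)² ψ⁴ c4U / ((1−φ⁴)(1+ψ²)²); raw edge connectivity
(K + 3r²)/(K + 1 + 2r²) with K the cokurtosis, redundant part
3r²/(1+2r²) (set c4U = 0), corrected part their difference.  c3U is the
closed-form third cumulant of the standardized skew-normal
(δ = α/√(1+α²)); c4U = 6/(ν−4).  Coskewness and cokurtosis are
independent of ρ; the edge connectivity is not.  At (τ=2, ψ=1, α=6) the
coskewness reaches its ceiling of ≈ 0.2.

Numerical choices: the recursion starts at X(0) = 0 and discards a burn-in
of ceil(20 τ) samples (configurable) to reach stationarity; the AR
recursion runs through a linear filter along the time axis; skew-normal
draws use the half-normal stochastic representation
U ∝ δ|Z₁| + √(1−δ²) Z₂ (exactly mean-0/variance-1 for every δ); one
seeded generator drives each simulation and the seed is recorded in the
output metadata.  Negative α (left skew) is permitted — it mirrors the
positive case by the sign symmetry of the coskewness.

### What the generator does and does not emulate

It reproduces the amplitude-free, dimensionless character of regional
signals, realistic autocorrelation (exponential, τ ≈ 2 samples), uniform
pairwise correlation, and tunable genuine third-/fourth-order structure
with known truth.  It does not emulate heterogeneous correlations,
region-specific time-scales or ψ, non-stationarity, measurement noise, or
the spatial structure of real parcellations.  Tests passing on this model
therefore validate the estimators and the inference machinery under
controlled dependence, not the neuroscientific claims one might make on
real data.

## Inference

The estimators are asymptotically normal but their i.i.d.-theory standard
errors are invalid under autocorrelation, so inference is resampling-based:

* **Block bootstrap** (default): T columns are cut into B = ⌊T/L⌋
  non-overlapping blocks of L = 10 consecutive samples (a trailing
  remainder is dropped — wrap-around was rejected for simplicity), B
  blocks are drawn with replacement and concatenated; all regions are
  resampled jointly so cross-region alignment is never broken.  L = 10
  follows from τ ≈ 2: the autocorrelation decays to ≈ zero within about
  10 samples, and performance is insensitive to L beyond that.  The
  statistic applied to each resample is the full plug-in pipeline
  including re-z-scoring.
* **Independent bootstrap**: single-column resampling (equivalently
  L = 1), kept for demonstrating its anti-conservativeness on
  autocorrelated data.
* From B_rep = 1000 replicates: SE = sample SD of the replicates; CI =
  θ̂ ± z_{β/2}·SE (normal approximation; a percentile CI is computed as a
  non-default alternative); two-sided z-test of θ = 0 (sidedness is a
  package choice; the size at the null is 0.05 either way).
* **Coherent phase randomization**: all rows' Fourier coefficients are
  rotated by the same uniform phases (DC and Nyquist untouched), an exact
  preservation of every auto- and cross-spectrum — hence of all
  second-order structure, including lag-0 cross-covariances — while
  higher-order structure is destroyed.  The empirical two-sided p-value
  uses the +1 correction, p = (1 + #{|T*| ≥ |T|})/(n_surr + 1).  The
  stationary bootstrap and autoregressive surrogates are deliberately
  omitted; circular-shift nulls are unsuitable because they test the
  wrong hypothesis (no cross-correlation rather than no higher-order
  dependence).

Known, reproduced limitations: the block bootstrap systematically
*underestimates* the true SE on this model, with the gap shrinking as T
grows; consequently the null rejection rate at nominal 5% is ≈ 9% at
T = 300 and settles near 6% for T ≥ 1200 (the practical reading: use
scans of at least ~10 minutes).  Independent resampling is worse, ≈ 12%
at T = 1200.

## Studies and mapping

The experiment harnesses tabulate ground-truth curves, Monte-Carlo
bias/SE/normality/detection summaries (detection = share of datasets with
|θ̂|/σ_MC above the two-sided 5% critical value, σ_MC the ensemble SD; a
per-dataset bootstrap SE is the exposed alternative), the 95% sampling
intervals of the fourth-order estimators, and the bootstrap calibration
versus scan length.  Default grids: ψ ∈ {0, 0.1, …, 1}, α ∈ {0, 0.5, …, 3}
(ground-truth curves extend to 6), ν ∈ {5, 8, 11, 14, 17, 20}.  Every
harness accepts reduced Monte-Carlo sizes; tests and the acceptance script
run between 400 and 10,000 datasets per point (error bars scale as 1/√n).
`fit_ar_timescale` recovers τ by least squares on exp(−k/τ) over lags
1..20 of an empirical autocorrelation function.

Seed-based maps fix two seed regions and vary one target (coskewness) or
one homologous target pair (cokurtosis / corrected edge connectivity, the
two edges being the seed pair and the target pair); correlation maps
average over the two seeds.  Group thresholding bootstraps subjects
(10,000 resamples), converts the bootstrap SE to a two-sided
normal-approximation p, and Bonferroni-corrects over the number of targets
in the map at hand.  Non-homologous target pairs are supported but emitted
as a matrix table.  Sign interpretation for significant triplets follows
the pairwise-correlation signs: all non-negative with negative coskewness
reads as coherent extreme deactivations, positive as coherent extreme
activations, mixed signs as a two-vs-one extreme pattern.  Median
re-thresholding of correlation maps is a display option, not inference.

## Design choices made where the design was open

* φ = exp(−1/τ): the only reading consistent with an exp(−k/τ)
  autocorrelation, the L = 10 block-length rationale, and the ≈ 0.2
  coskewness ceiling.
* Bootstrap and surrogate tests are two-sided throughout.
* Degenerate cases: constant rows raise a named error; zero bootstrap SE
  yields p = 1 for a zero estimate and p = 0 otherwise; a zero edge
  product norm raises a degenerate-edge error.
* Burn-in (20 τ) and the X(0) = 0 start are implementation choices; they
  are configurable and irrelevant after burn-in at these time-scales.
* Floating-point tolerance for exactness/invariance tests is 1e-10 to
  1e-12 absolute.

## Limitations

Fourth-order inference from a single realization is essentially infeasible
except under strong heavy tails (ν = 5, large ψ): the estimators are
negatively biased under connectivity and their 95% sampling intervals
exclude zero only there — both reproduced by the test suite.  At ν = 5 the
estimator's sampling variance involves the innovation's 8th moment, which
is infinite, so Monte-Carlo convergence is slow and long-right-tailed.
Real-data preprocessing (filtering, parcellation, artifact removal) and
clinical statistics are outside this package's scope.
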