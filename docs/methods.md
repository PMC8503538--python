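# Methods

## Colour spectra

Pixels are assumed to be colour-calibrated 8-bit RGB from a pre-segmented
dorsal region of interest (a binary mask or an explicit pixel table; the
package does no segmentation or colour-chart calibration). The RGB→HSV
transform is the standard hexcone mapping (hue in degrees on [0, 360),
saturation and value in [0, 1]); achromatic pixels (R = G = B) are assigned
hue 0 and saturation 0 — a convention is required because hue is undefined
there, and 0 keeps them in the first hue bin rather than spreading them.

Specular highlights are removed by a joint threshold: a pixel is dropped
when V ≥ `v_min` (default 0.95) **and** S ≤ `s_max` (default 0.10).
Reflected-light pixels are both bright and desaturated; either condition
alone would also delete legitimately pale or bright body colour. The filter
is idempotent and errors rather than silently returning an empty set.

Spectra use uniform bins over the full channel range with the right edge of
the last bin inclusive. Defaults: 360 one-degree bins for hue, 256 bins for
saturation and value (mirroring 8-bit quantization). The bin count is
configurable; analyses at lower per-individual pixel counts should coarsen
the bins so that spectra are not dominated by multinomial noise (the
acceptance script uses 72/64/64 for exactly this reason).

Group spectra are per-bin means across individuals with per-bin
highest-density bands over the individuals' frequencies. For strongly
skewed per-bin distributions the mean can in principle leave the band; the
band is a description of inter-individual spread, not a confidence interval
for the mean.

## PCA scores

One PCA per channel, pooled across sexes and populations, on the covariance
(not correlation) of the spectrum matrix: all bins share frequency units,
so per-bin rescaling would only amplify empty-bin noise. The decomposition
is a thin SVD of the centered matrix, which makes the zero-variance case
(identical rows) well defined — all explained fractions are reported as 0 —
and is deterministic up to component sign.

The PC1 sign is fixed by a biological orientation rule, making scores fully
reproducible: for hue, the summed PC1 loading over the green interval
(90–150°) is made positive, so positive scores mean greener animals (the
contrast of interest is green versus orange-yellow at roughly 30–60°); for
saturation and value, the covariance between raw scores and the
individuals' mean channel level is made positive, so higher scores mean
more saturated / brighter animals. If the orientation statistic is exactly
zero the sign is left as the SVD returned it.

Only PC1 feeds the downstream model; further components are retained in the
result object for audit but not modelled.

## Cosinor mixed model

The response y_i (a PC1 score) follows

y_i = M + ΔM·m_i + β·x_i + γ·z_i + δ·s_i + Δβ·m_i x_i + Δγ·m_i z_i
      + Δδ·m_i s_i + u_pop(i) + ε_i

with x = cos(2πt/τ), z = sin(2πt/τ), τ = 365 days (leap days are mapped to
day 60 of the 365-day basis on input), m a male indicator (female is the
reference level, so male quantities are reconstructed per draw as
female + offset), s the SVL standardized to mean 0 / sample sd 1 pooled
over all rows, u_p ~ N(0, σ_pop) and ε ~ N(0, σ_err). Amplitude and
acrophase derive from the coefficients via β = A·cos φ, γ = −A·sin φ, so
A = √(β²+γ²), φ = atan2(−γ, β), and the peak falls at t = −φτ/2π (mod τ).
When β = γ = 0 the phase is undefined and returned as 0 with a degeneracy
flag.

Priors: independent Normal(0, σ_c) on all coefficients and half-Cauchy
(scale 25) on both standard deviations. The coefficient spread is specified
either as a precision (default 0.001, i.e. σ_c ≈ 31.6 — effectively flat on
the score scale) or directly as an sd; the precision convention is the
default because a literal sd that small would be a point-mass prior, not a
flat one. The half-Cauchy is placed on the standard deviations (its
location/scale parameterisation only makes sense for a scale variable), a
standard weakly-informative choice for few groups.

Sampling is a seeded Gibbs scheme. The coefficients and the population
intercepts are drawn as one joint multivariate-normal block per iteration
(their full conditional given the two sigmas is conjugate); updating them
in separate blocks was observed to random-walk along the intercept ↔
mean-random-intercept ridge with split R-hat up to ~1.9, and the joint
block removes that pathology. The two standard deviations are updated by
slice sampling on the log scale (stepping-out and shrinkage, Jacobian
included). The sampler targets exactly the density exposed as
`log_posterior`, which is validated three independent ways in the tests:
a hand-computed density oracle, the analytic conjugate posterior with both
sigmas clamped, and an ensemble sampler (emcee) run on the same density.

Defaults are a desk-scale run — 3 chains × 6,000 iterations, 1,000 burn-in,
thinning 3 — chosen so a full fit takes seconds while leaving
Monte-Carlo error well below posterior spread at n ≈ 300–900;
`FULL_SCALE_MCMC` (3 × 34,000 / 4,000 / 3) reproduces a long-run
configuration. Convergence is monitored with split R-hat per parameter
(threshold 1.1); non-convergence warns and flags the output, never errors.

## Posterior summaries

Point estimates are the half-sample mode (HSM): recursively keep the
shortest contiguous window of ⌈n/2⌉ sorted draws (ties toward the smallest
start index) down to ≤ 3 points (n = 2 → mean; n = 3 → mean of the closest
pair, or of all three on an exact tie). Intervals are highest-density
intervals (HDI): the shortest window of ⌈mass·n⌉ sorted draws, ties toward
the smallest lower bound; the window is clamped to at least two points so
an interval always has two distinct endpoints. Note that exact gap ties in
the HSM recursion are a measure-zero event for continuous draws; they
matter only for gridded input, and binary floating point can break a tie
that is exact in decimal notation.

Peak-day uncertainty lives on a circle (annual peaks near 1 January have
posteriors spanning the year boundary). The peak-day HDI therefore rotates
the draws so their HSM maps to τ/2, applies the linear HDI, and rotates
back; the reported endpoints may satisfy lower > upper, which encodes an
interval wrapping 1 January. Calendar dates use a non-leap year with day 1
= 1 January; fractional days round to the nearest day, and day 0 (a peak
exactly at the origin) reports as 1 January.

Contrast probabilities P(a > b) are computed over paired draws with ties
counted one half (symmetry). Seasonality evidence is the fraction of
amplitude draws above a threshold; since A ≥ 0 by construction this is 1
at the default threshold 0 for any non-degenerate posterior, so meaningful
thresholds should be expressed on the response scale (e.g. a fraction of
the score sd). The variance partition is σ²_pop/(σ²_pop+σ²_err) per draw.
With only three populations this quantity is weakly identified: the
σ_pop posterior inherits a heavy right tail from the half-Cauchy prior,
so the ICC posterior can pile up near its boundaries and its HSM should be
read together with the (typically very wide) HDI.

## Synthetic data

The generator mimics the study design: three sites (CA, BG, PA) with equal
assignment probability, monthly sampling March–October (uniform day within
the month), sex assigned with male fraction 419/910, SVL from a normal
(mean 68 mm, sd 8 mm) truncated at the 50 mm adult threshold, and
per-individual pixel counts from a log-normal matched to mean 59,806 and
sd 44,296, clamped to [2,469, 452,305]. Default effect sizes are synthetic,
chosen to mimic the qualitative field pattern rather than any estimate:
female MESOR 0, male +0.3; amplitudes 0.75 (f) and 1.5 (m); peaks on day 52
(f) and 75 (m); male-only size slope 0.5; σ_err = 1 and σ_pop = 0.655
(ICC ≈ 0.30).

Pixel-level data draw each pixel's hue from a two-mode mixture — green
N(110°, 15°) versus orange-yellow N(45°, 12°) — whose green weight is
logistic in a sex intercept, a sex-specific seasonal cosine, a size term
and a population effect; saturation and value are Beta draws whose means
follow small cosinor curves. What this emulates is the bimodal hue spectrum
and its seasonal green shift; what it does **not** emulate includes camera
noise, illumination gradients, spatial pixel correlation within an animal,
and — importantly — individual heterogeneity beyond the covariates: the
green weight is a deterministic function of sex, day, size and site, so
pixel-level residual variance comes only from pixel sampling. Consequently
the pixel path yields near-deterministic scores at study-scale pixel
counts (PC1 ↔ latent green weight correlations near 1, ICC near its
boundary), and passing pixel-path tests demonstrates the plumbing and the
sign conventions, not realistic noise levels. Calibration statements about
the model come from the score-level path, which uses the model's own
generative process.

`recovery_experiment` runs simulate → fit → summarize over seeded
replicates and reports fixed-effect bias, 95% HDI coverage, amplitude
ordering and peak-day recovery. At the default truth with n = 300 and the
desk-scale sampler, coverage is at the nominal level and the male peak is
recovered within days; with a zero-effect truth the posterior probability
of the sex contrast is approximately uniform across replicates — the
expected behaviour of a calibrated Bayesian analysis under a flat prior,
meaning single-study "P(m>f) near 0.5" statements should not be expected
under the null, only the absence of systematic drift.

## Numerical and design choices

- All randomness flows through numpy Generators seeded from explicit
  integers; same seed, same output, at every level including the sampler.
- Sex labels are normalized on input (m/M/male → male); juveniles
  (SVL < 50 mm) are excluded at read time with a logged count; duplicate
  individual ids are an error.
- Population grouping uses sorted labels for a stable design regardless of
  row order; rows keep input order.
- `aggregate_spectra` with a single spectrum returns bands equal to it;
  zero-variance PCA input returns explained fractions of 0 rather than NaN.
- Degenerate inputs error loudly ("no pixels", "empty after highlight
  filter", "zero variance") rather than propagating empty arrays.

## Known limitations

- The highlight-removal thresholds are declared conventions, not estimates
  of any particular camera setup.
- Only PC1 is modelled; colour variation orthogonal to PC1 is ignored.
- One cosinor harmonic: asymmetric seasonal waveforms fold into the nearest
  sinusoid.
- Three populations identify the variance partition only weakly; its
  summaries are prior-sensitive.
- The acceptance script and default tests run at desk-scale MCMC settings;
  long-chain runs are available via `FULL_SCALE_MCMC` or configuration.
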