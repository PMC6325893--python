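# Methods

This note documents the statistical models behind `sizedist`, the
parameters that matter, the calibration and numerical choices, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Data model

The raw input is a binned size-frequency table as exported by
Coulter-type channelyzers: one strictly increasing column of channel
values in femtoliters plus one nonnegative frequency column per strain.
Channel values are interpreted as **bin centers**; bin edges are inferred
from consecutive midpoints, with the first and last edge extending the
nearest internal width outward. This matches how channelyzers report
channel centers and makes within-bin jitter well defined.

Frequencies are converted back to per-cell values by seeded
**multinomial resampling**: n cells (default 1000) are allocated to bins
with probability proportional to frequency, and each cell takes its bin's
center value. A deterministic alternative (largest-remainder rounding of
frequency × n) is available. Center resampling produces heavily tied
samples; the EDF statistics and the Shapiro-Wilk test tolerate ties but
are mildly distorted by them, so a `jitter` flag replaces each center
with a uniform draw inside its bin and is recorded in output metadata.
Spurious small-particle peaks ("debris") are *not* trimmed by default; an
optional minimum-size cutoff exists for sensitivity analyses.

Seeding: one master seed; each strain's seed derives deterministically
from (master seed, CRC32 of the strain id) through a `SeedSequence`, so
results are reproducible strain-by-strain and invariant to cohort order.

The weighted median of a histogram is the smallest bin value whose
cumulative frequency exceeds one half (a bin where the cumulative mass
equals 0.5 exactly leaves half the mass strictly below the next bin, so
the crossing bin carries the median).

## Distribution fits

All families are fitted by maximum likelihood on the positive half-line:

* **Gamma**(shape α, rate β): the profile score equation
  ln α − ψ(α) = ln x̄ − mean(ln x) is solved by Newton iteration from the
  Minka closed-form initializer α₀ = (3 − s + √((s−3)² + 24s))/(12s);
  β̂ = α̂/x̄, so the fitted mean equals the sample mean exactly.
  Convergence: |score| < 1e-10 or 100 iterations; non-convergence is an
  explicit flag on the result, not an exception, whenever a usable
  iterate exists. Samples with all values equal (s = 0) are rejected as
  degenerate.
* **Lognormal**: closed form on the logs, with the MLE convention
  σ̂² = mean((ln x − μ̂)²) (divisor n).
* **Weibull**(shape k, scale λ): Newton iteration on the shape profile
  score 1/k + mean(ln x) − Σxᵏ ln x / Σxᵏ, initialized from the moment of
  logs k₀ = π/(sd(ln x)·√6); λ̂ = (mean(xᵏ̂))^(1/k̂).
* **Generalized gamma**: density ∝ x^(αp−1) exp(−(βx)^p), chosen for the
  clean nesting — at p = 1 it is exactly the gamma above. For fixed p the
  transformed values x^p are gamma distributed, so the fit reduces to a
  1-D search over p (coarse geometric grid on [0.2, 6], then bounded
  refinement), with the inner gamma profile solved as above. p = 1 is
  always evaluated, which guarantees loglik(gengamma) ≥ loglik(gamma).
  A Wald interval for p comes from the finite-difference curvature of the
  profile log-likelihood.

Model comparison uses AIC/BIC (k = 2 free parameters, 3 for the
generalized gamma) and the EDF statistics below. On gamma data the BIC
penalty reliably prefers the two-parameter gamma over the generalized
gamma, which is the basis for using the simpler family throughout.

## Goodness of fit

With u₍ᵢ₎ = F(x₍ᵢ₎) the probability-integral transforms of the sorted
sample under the candidate cdf F:

* A² = −n − (1/n) Σ (2i−1)[ln u₍ᵢ₎ + ln(1 − u₍ₙ₊₁₋ᵢ₎)]
* D = maxᵢ max(i/n − u₍ᵢ₎, u₍ᵢ₎ − (i−1)/n)
* W² = Σ (u₍ᵢ₎ − (2i−1)/(2n))² + 1/(12n)

u values are clamped to [1e-12, 1−1e-12] before logs; clamping is
surfaced as a warning. The test suite checks the summation forms against
exact piecewise integration of the defining integrals.

Two null regimes require different calibrations:

* **Composite gamma null** (parameters estimated from the tested
  sample): A²'s null distribution depends on the estimation step, so the
  p-value is calibrated by **parametric bootstrap** — B resamples of size
  n from the fitted gamma, each refitted before its A² is computed;
  p = (1 + #{A²_b ≥ A²_obs})/(B + 1), hence in (0, 1] and bit-reproducible
  for fixed (B, seed). Default B = 999; B < 99 is refused as
  uncalibrated. The bootstrap p-value is exact in size at levels that are
  multiples of 1/(B+1): with B = 199, the rule p ≤ 0.01 has true size
  2/200 = 1%.
* **Fixed gamma null** (shape and rate given a priori): the classical
  asymptotic distribution of A² applies; it is evaluated with the
  Marsaglia & Marsaglia (2004) approximation plus its finite-n
  correction, verified against the published asymptotic percentage points
  (1.933 → 0.10, 2.492 → 0.05, 3.857 → 0.01). For n < 50 the test falls
  back to a (no-refit) bootstrap.

Normality is screened with the Shapiro-Wilk test (Royston's algorithm,
3 ≤ n ≤ 5000, via scipy); lognormality is screened by applying the same
test to the log-transformed values, since lognormal data have normal
logs.

## The cohort screen

For each strain: resample n = 1000 cells → Shapiro-Wilk on raw and log
values → fit gamma/lognormal/Weibull (generalized gamma optional) →
per-family EDF statistics → composite-gamma bootstrap p → fixed-null A²
and p → weighted median. Rows are returned in input order; per-strain
failures are recorded in a `status` field and rank last rather than
aborting the cohort.

The **reference null** is the arithmetic mean of the wild-type gamma
fits (for the haploid deletion-collection background: shape 3.8277, rate
0.078949, the average of the two BY4741 wild-type samples). **Deviant
ranking** sorts by descending fixed-null A² — the statistic, not the
p-value; under a fixed null both orderings coincide except far in the
tail, where the asymptotic p saturates at machine precision while the
statistic still discriminates. Ties break by strain id. Replicate
measurements (systematic name + suffix matching `[._-]\d+$`, a
configurable pattern) collapse to unique strains *after* top-k selection,
so k samples may map to fewer strains.

**Size classes**: exactly ⌈qN⌉ strains with the largest medians are
`lge` and ⌈qN⌉ with the smallest are `whi` (default q = 0.05), by ordinal
rank with ties broken by strain id; if the tails would overlap in a tiny
cohort, the large tail claims its strains first.

Screening is done at raw α = 0.01 per strain with no multiplicity
correction — the screen's operating characteristic is the ranking, not a
family-wise error guarantee.

`ScreenConfig` allows `bootstrap_B=None` (skip the composite bootstrap)
and `fit_gengamma=False`; deviant ranking needs only the fixed-null
statistic, so spike-in and calibration studies run the light
configuration.

## Group comparisons

All comparisons are rank-based and two-sided (the screen's effects are
large and side-insensitive). The Wilcoxon rank-sum test uses midranks;
p-values come from full enumeration of rank assignments when both groups
have ≤ 10 observations without ties (enumeration also handles tied
inputs when forced), otherwise from the normal approximation with
tie-corrected variance and a ±0.5 continuity correction. The normal
approximation is accurate to ~10% relative error outside the extreme
tail; below exact p ≈ 0.05 only absolute accuracy (~0.005) holds, the
known behaviour of the approximation. Kruskal-Wallis uses the
tie-corrected H with a χ²(k−1) reference; when every pooled value is
identical, H is defined as 0 with p = 1. The Nemenyi post-hoc test refers
tie-corrected mean-rank differences to the studentized-range distribution
with infinite degrees of freedom. p-values below 2.2e-16 are *printed* as
"< 2.2e-16" while raw values are retained in data output.

## Synthetic cohorts

The generator emulates what the screen consumes: per-strain histograms
built by binning simulated single-cell volumes onto 256 linear channels
over 5–250 fL (a channelyzer-like window for yeast), 20,000 cells per
histogram by default (instrument acquisitions typically count 10⁴–10⁵
particles). Wild-type strains draw from gamma(3.8277, 0.078949 /fL), the
averaged haploid reference. Mutant classes:

* **shifted_gamma** — rate divided by a shift factor (default 1.6):
  larger cells, unchanged shape. At shift = 1 the output is bit-identical
  to the wild-type generator for the same seed.
* **left_skew** — anchor − gamma(4, 0.05 /fL) with anchor 200 fL,
  truncated at the grid minimum: a large mode near 140 fL with a heavy
  left shoulder (sample skewness ≈ −1). A reflected gamma is used because
  order statistics of gamma draws (e.g. the maximum of two) remain
  positively skewed and cannot produce this class.
* **multimodal** — an equal-weight two-component gamma mixture with means
  ≈ 60 and ≈ 138 fL, well separated on the default grid.
* **debris** — a wild-type histogram with 3% of mass moved into the 3
  smallest bins, mimicking small-particle culture debris.

What the generator does *not* emulate: instrument noise and channel-width
nonlinearity, counting error, cell-cycle and budded/unbudded
substructure, debris that overlaps the true size range, and day-to-day
drift between replicate acquisitions. Passing spike-in tests therefore
demonstrate the pipeline's statistical behaviour under the stated
generative classes, not robustness to every artifact of real Coulter
data.

## Problem sizes and verification

The test suite and the acceptance script keep Monte-Carlo studies at
sizes chosen for tight-enough binomial error at interactive runtimes:
type-I calibration of the composite test uses 500–1000 simulations at
B = 199 (the band [0.003, 0.03] around the nominal 1% is ~±6 binomial
standard deviations at 1000 runs); spike-in recovery uses 50–100
synthetic cohorts of 100 strains; parameter recovery uses 200 simulations
per generating shape; the Kruskal-Wallis size check uses 2000
simulations. The refitted rich-medium shape is reported as the mean over
25 independent n = 1000 resamples because a single resample carries a
shape standard error of ≈ 0.34.

Independent oracles back the implementations: a zoomed dense grid search
for the gamma and Weibull MLEs (agreement within 1e-3), scipy's
constrained fits and R's `MASS::fitdistr` (agreement at R's optimizer
precision, ~0.3%), exact piecewise integration for A²/W², R's
`stats::shapiro.test` for the Shapiro-Wilk statistic, published
asymptotic percentage points for the fixed-null AD law, and full
enumeration for the rank tests.

## Known limitations

* The composite-null bootstrap reproduces the *calibration principle*,
  not the exact internals of any particular packaged test; third-decimal
  differences from historically reported p-values are expected. Rank
  orderings are the robust output.
* The asymptotic fixed-null p saturates near machine precision for
  extreme statistics; ranking by the statistic itself avoids this.
* Bin-center resampling without jitter slightly inflates EDF statistics
  through ties; jitter removes the effect and is flagged in metadata.
* The generalized-gamma power search is bounded to [0.2, 6]; samples
  preferring more extreme powers are reported at the boundary with the
  convergence flag cleared.
* Histograms whose mass concentrates in a single bin produce degenerate
  resamples; these strains are reported with a failure status and ranked
  last rather than dropped.
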