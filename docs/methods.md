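# Methods

`osmoshock` implements a single-cell analysis that connects the abundance of
the mechanosensitive channel MscL in *E. coli* to the probability of surviving
a hypo-osmotic shock. This note records the models, the numerical choices, and
the limits of what the synthetic-data tests demonstrate.

## The survival model

Each cell is treated as an independent Bernoulli trial whose success
probability depends on its effective channel copy number `N_c` through a
logistic law on the log scale:

    log[ p_s / (1 - p_s) ] = β₀ + β₁ ln N_c
    p_s = 1 / (1 + N_c^(-β₁) e^(-β₀))

β₀ is the log-odds of survival at `N_c = 1` (dimensionless) and β₁ the change
in log-odds per e-fold increase in channel count. Regression is performed on
`ln N_c` because observed copy numbers span roughly three decades; regressing
on `N_c` directly would let the sparse high-copy tail dominate the fit. The
natural logarithm is forced by the algebraic pairing of `e^(-β₀)` with
`N_c^(-β₁)` — the two forms above are identical only in base *e*, and the
package asserts that identity to 1e-12.

Fits are stratified by shock class — "slow" (< 1.0 Hz) and "fast" (≥ 1.0 Hz)
medium exchange — because survival also depends on how quickly tension is
applied. A pooled fit across classes is available behind a flag but is not the
default.

Coefficients get independent Normal(0, 5) priors: wide enough to be dominated
by the likelihood at the sample sizes involved (n ≈ 10³ cells), narrow enough
to keep the sampler away from regions of perfect separation. Both locations
and scales are config-overridable. Data containing a single outcome class are
rejected loudly (`SeparationError`) rather than silently regularised.

Sampling uses an affine-invariant ensemble sampler (emcee), 32 walkers ×
1,500 steps with a 500-step burn-in, initialised in a small ball around the
numerically-optimised posterior mode. Convergence is checked with a
split-chain R̂ over walkers (threshold 1.1, error on failure) and
autocorrelation-based effective sample sizes (typically > 1,000 for the
default settings). The posterior mean of the draws is reported as the point
estimate. Two independent oracles back the sampler in the test suite: a
maximum-likelihood logistic fit (statsmodels) that must match the flat-prior
MAP within 2%, and a brute-force 2-D quadrature of the same posterior on
small datasets that must match the MCMC posterior means within 2%.

Inverse queries ("how many channels for 80% survival?") invert the log-odds
line per posterior draw, `N_c = exp[(logit(p) − β₀)/β₁]`, reporting the median
and central 95% interval over draws with β₁ > 0. If more than half the draws
have non-positive slope the query is refused as ill-posed.

## Fluorescence calibration and effective copy number

Fluorescence is converted to molecule counts with a standard-candle strain
whose mean copy number ⟨N⟩ is known independently; the calibration factor is

    α = ⟨I_A⟩ ⟨A⟩ / ⟨N⟩   [a.u. per channel]

where ⟨I_A⟩ is the mean areal fluorescence density and ⟨A⟩ the mean cell area
of the candle population. The default ⟨N⟩ is 480 channels/cell (quantitative
Western-blot value for the candle strain); it is an input, never inferred.

The hierarchical error model treats each biological replicate's mean density
and mean area as draws around population means: `obs_r ~ Normal(μ, √(τ² +
se_r²))` with `se_r = sd_r/√n_r` the within-replicate standard error and τ the
inter-replicate spread. Priors: weakly-informative lognormal on μ (keeps the
mean positive; scale 2 in log units, centred on the observed mean) and
half-normal on τ (scale 3× the observed replicate spread). τ's support is
bounded within [1e-4 × mean, 10 × prior scale]: the lower bound prevents the
unbounded density spike at τ → 0 when replicates are (synthetically)
identical; that exactly-degenerate case is detected and returns the plug-in
point mass analytically. Density and area are fitted independently and their
posterior draws pushed through the formula above to α draws. A single
replicate degenerates to the plug-in estimate with sampling-error-only
uncertainty.

The effective copy number corrects for aberrant morphology by using
expression per unit area rather than per cell:

    N_c = density × ⟨A⟩ / α

evaluated per calibration draw, giving each cell a point estimate (mean of
draws) and a 95% credible interval. The estimate is exactly independent of
the individual cell's area — two cells with equal density and areas 2 µm² vs
8 µm² receive identical counts. Per-cell photon noise is *not* propagated
(only calibration uncertainty is); this is a documented limitation shared
with the convention of treating the density measurement as exact.

## Shock-rate estimation

The medium-exchange rate is measured from a dye-fluorescence trace: normalise
to the pre/post-shock plateaus (medians of the first/last 5% of samples when
not given explicitly), then fit a least-squares line to the points in the
"middle region", made precise here as the 10–90% normalised band
(config-overridable). The slope is the rate in Hz = fraction of full exchange
per second, so a complete exchange in T seconds gives 1/T Hz. Fewer than
three in-band points or a non-positive fitted slope raise errors. Shocks are
classified fast at ≥ 1.0 Hz, slow below.

## Binned survival statistics

For a bin with n survivors of N cells, a binomial likelihood with a uniform
prior gives the posterior `g(p|n,N) = (N+1)!/(n!(N−n)!) p^n (1−p)^(N−n)`,
i.e. Beta(n+1, N−n+1). The package reports the plug-in mode `p* = n/N` with
the Laplace sigma `σ = √(n(N−n)/N³)`, and exposes the exact density (via
log-gamma, since literal factorials overflow past N ≈ 170) plus exact central
Beta intervals as the boundary-safe alternative when n ∈ {0, N}, where σ
degenerates to zero. Binning is either by strain identifier or by pooling all
cells into half-open channel windows [k·w, (k+1)·w) anchored at zero
(default width 50). Bins with fewer than 25 cells are flagged, not dropped.

## The synthetic-data generator

The generator emulates the study conditions end to end, with ground truth
recorded in `truth__`-prefixed columns that downstream stages never read.
Defaults, chosen once as the standard conditions:

| parameter | default | rationale |
|---|---|---|
| β₀, β₁ (truth) | −11.57, 2.0 | survival crosses 80% near 650 channels, inside the experimentally relevant 500–700 band |
| α (truth) | 800 a.u./channel | arbitrary but realistic camera scale |
| channel range | 4–1,000, log-uniform | the ~3 decades spanned by the expression mutants; log-uniform exercises the regression evenly on the log axis |
| candle ⟨N⟩ | 480 channels/cell | Western-blot literature value for the candle strain |
| candle replicates | 6 × 100 cells | matches the imaging protocol's replicate structure |
| inter-replicate CV | 10% | replicate variation exists but is unquantified; 10% is a typical day-to-day microscopy drift |
| candle cell CV | 30% | wide single-cell expression distributions |
| mean area / CV | 4.0 µm² / 25% | projected area of a typical rod |
| density noise CV | 10% | multiplicative lognormal (keeps intensity positive), the scale of integrated-fluorescence measurement error |

Cells draw `N_c` log-uniformly and area lognormally, independently; the areal
density is `α N_c / ⟨A⟩` times mean-one lognormal noise and the total
intensity is density × area. Density is therefore independent of area by
construction (the morphology-independence the effective-count correction
assumes), a cell of typical area carries total fluorescence `α N_c`, and the
population mean obeys ⟨I_tot⟩ = α⟨N⟩. Survival is Bernoulli with the logistic
law at the true `N_c`.

Exchange traces are logistic in time — smooth, saturating, with a
well-defined central linear region. The steepness is `k = rate/c` where `c`
is the least-squares slope of a unit logistic over its 10–90% band (computed
numerically once), so the rate estimator's mid-band line fit returns the
requested rate up to discretisation; a full exchange spans ≈ 1/rate seconds.

Image pairs render cells as non-overlapping rotated ellipses (aspect 2.5)
whose pixel area matches the table's area and whose summed fluorescence
equals the table's total intensity, over a uniform background, under a linear
illumination field of configurable left-to-right ratio, with additive
Gaussian noise. Phase contrast is two-level (dark cells, light background).

What the generator does **not** emulate — and hence what passing tests do not
show about real data: photobleaching and fluorophore maturation kinetics,
aberrant branched/filamentous shapes as rendered geometry (only the
density–area decoupling they motivate), cell clusters and division during
outgrowth, detector-specific noise statistics, and focus drift. Recovery and
coverage results on synthetic data certify the inference machinery, not the
microscopy.

## Numerical and design choices

- All randomness flows from explicit integer seeds; a pipeline run derives
  stage seeds from one master seed via `SeedSequence`, and its manifest
  (inputs, seeds, SHA-256 checksums) reproduces a synthetic run
  bit-identically.
- Marker-to-cell linkage is greedy over ascending (distance, marker index):
  the globally closest remaining pair links first, ties resolve by marker
  order and are flagged as ambiguous, links beyond a 20 px cutoff are flagged
  for review, and excess markers are returned unmatched. On well-separated
  instances this equals the optimal (Hungarian) assignment, which the tests
  verify by brute force.
- Illumination correction divides by a provided flat-field directly, or by a
  60 px Gaussian blur of the image itself when none is given, preserving the
  global mean; denoising is a 3 px median filter (unbiased under symmetric
  noise; impulse outliers are deliberately discarded).
- Phase segmentation thresholds with Otsu's method and keeps connected
  components inside a 0.5–50 µm² area window; each component ("individual
  cells or small clusters") is one object — cluster splitting is out of
  scope.
- Background for intensity measurement is the median over unmasked pixels.
- Problem sizes used by the acceptance study: 100 seeded datasets of 2,000
  cells for logistic coverage, 100 seeded candles of 6 × 100 cells for
  calibration coverage, 50 noisy traces per rate for the shock sweep — sizes
  at which the binomial error of a coverage estimate (~±3%) is small against
  the 90% pass bound.

## Known limitations

- Per-cell intensity measurement error is not propagated into `N_c`
  intervals (calibration uncertainty only).
- The logistic model extrapolates outside the observed copy-number range by
  assumption of linear log-odds; nothing in the data constrains it there.
- The hierarchical calibration model assumes normal replicate-mean
  likelihoods; with only ~6 replicates the inter-replicate variance is weakly
  identified and the half-normal prior scale matters.
- Multi-predictor survival models (area, shock rate as covariates) are
  deliberately out of scope; the regression is one-dimensional in `ln N_c`.
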