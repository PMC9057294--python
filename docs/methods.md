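# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions at the edges.

## Fractional vegetation cover

NDVI is `(NIR − Red) / (NIR + Red)`; a zero denominator yields nodata.
FVC follows the dichotomous pixel model: a pixel is a linear mixture of
a bare-ground endmember `NDVI_n` and a full-vegetation endmember
`NDVI_v`, so the vegetation fraction is
`(NDVI − NDVI_n) / (NDVI_v − NDVI_n)`, set to 0 at or below `NDVI_n` and
1 at or above `NDVI_v`.  Endmembers are the 5th and 95th percentiles of
the cumulative frequency of valid NDVI (linear interpolation between
order statistics — the most common percentile convention, stated here
because the endmembers inherit its exact values).  Whether endmembers
should be taken per annual image or once for a whole multi-year stack is
genuinely open; per-image is the default (each annual composite has its
own radiometric context) and `global_endmembers=True` /
`--global-endmembers` switches to a single stack-wide pair.  Because
both endmembers are percentiles, FVC is invariant to positive affine
transforms of the NDVI histogram; this is tested.

## Per-pixel trend

The trend statistic is the OLS slope of FVC on the year index `i = 1..n`
written in normal-equation form; it is algebraically identical to a
generic least-squares fit (tested to machine precision against
`numpy.linalg.lstsq` and `scipy.stats.linregress`).  Significance is the
two-sided t-test of the slope with `n − 2` degrees of freedom, requiring
`n ≥ 4`.  Classes:

| class | rule |
| --- | --- |
| extremely significant increase | slope > 0, p ≤ 0.01 |
| significant increase | slope > 0, 0.01 < p ≤ 0.05 |
| insignificant | p > 0.05 (or slope = 0) |
| significant decrease | slope < 0, 0.01 < p ≤ 0.05 |
| extremely significant decrease | slope < 0, p ≤ 0.01 |

A p-value exactly at a class boundary goes to the *more* significant
bin (strict inequalities would leave a measure-zero gap; the choice is
documented rather than consequential).  Degenerate series: an exactly
flat series gets slope 0 and p = 1; a noiseless non-flat line gets
p = 0.  Flatness is detected by zero range, not by a tolerance on the
fitted slope, so round-off in the normal equations cannot produce
spurious significance.  Pixels must share the full year set; the stack
carries one nodata mask constant over time, matching the cloud-free
annual-composite assumption.  Per-pixel slopes are in FVC fraction per
year; zonal annual-mean series and their regressions are in percent,
against calendar year (the intercept is only meaningful there).

## Hurst exponent by rescaled range

For a window of length `w`: deviations from the window mean are
cumulated; `R` is the range of the cumulated series, `S` the population
standard deviation of the window; windows with `S = 0` are skipped.  `H`
is the OLS slope of `log(mean R/S)` on `log(w)` over at least three
window lengths.  The *cumulated* range is what produces the `w^H`
scaling law; a variant that ranges the raw deviations is available as
`literal_eq5=True` / `--literal-eq5` for comparison but is not used by
default (it does not yield the scaling law).

Window sets.  Short records (`n ≤ 64`, e.g. 21 annual composites) use
every length in `{4, …, ⌊n/2⌋} ∪ {n}` with non-overlapping windows,
discarding the remainder tail — a 21-point series has so few usable
scales that all of them are needed.  Long records use ~12 log-spaced
lengths in `[32, n/2]`: the R/S statistic is strongly biased at small
windows, and a minimum window of 32 keeps the mean estimate within
±0.08 of planted H across H ∈ {0.3, 0.5, 0.7, 0.9} at n = 4096 (the
well-known residual bias pulls estimates toward 0.5 — upward at low H,
downward at high H — and is documented rather than corrected; no
Anis–Lloyd-style adjustment is applied, keeping the estimator the plain
log–log regression).

Classification.  An estimated H exactly equal to 0.5 has probability
zero, so "random fluctuation" is a band: `|H − 0.5| ≤ 0.05` by default
(configurable).  `H < 0.45` is anti-persistent ("opposite"), `H > 0.55`
persistent ("continuous").  The combined future-trend classifier is a
total function of (H class, slope sign, significance at α = 0.05):

- random → random fluctuation;
- persistent → continuous increase/decrease, "significant" when
  p ≤ α;
- anti-persistent → improvement-to-degradation (slope > 0) or
  degradation-to-improvement (slope ≤ 0).

A slope of exactly 0 is placed on the decrease side of the
non-significant classes; exhaustiveness over all combinations is tested
by enumeration.  Estimating H from 21 points is intrinsically noisy:
per-pixel H values should be read as a classification aid, not as
precise exponents — which is exactly how the pipeline uses them.

## Geographical Detector

The factor detector measures spatial stratified heterogeneity:
`q = 1 − Σ_h N_h σ_h² / (N σ²) = 1 − SSW/SST` with population
variances, `q ∈ [0, 1]`, invariant to stratum relabeling and to
positive affine transforms of the response.  Each stratum needs ≥ 2
members; a single-stratum partition returns q = 0 (it explains
nothing).  Significance is by permutation of stratum labels by default
(999 permutations, seeded, `p = (1 + #{q* ≥ q}) / (perms + 1)`), which
is exact under exchangeability and makes no distributional assumption;
the noncentral-F test used by the original Geodetector software is
available with `method="ncf"`.

Interaction detector: q on the cross-classification of two factors.
Cross cells with fewer than two members are merged into the sibling
cell with the nearest mean response (count reported) so within-cell
variance stays defined.  Types, checked in order: *independent* if
`|q_ab − (q_a + q_b)| ≤ 1e−9` (exact equality is measure-zero; the
tolerance is the documented surrogate), *enhance nonlinear* if
`q_ab > q_a + q_b`, *enhance bivariate* if `q_ab > max(q_a, q_b)`,
*weaken nonlinear* if `q_ab < min(q_a, q_b)`, else *weaken univariate*.
When one factor refines the other, the cross-classification equals the
finer partition and `q_ab = q(finer)` exactly; refining a
stratification can never decrease q (both tested).

Risk detector: per-level means of the response with pairwise
two-sample t-tests.  The statistic is the standard Welch form — each
level's variance over its own sample size, Welch–Satterthwaite degrees
of freedom.  Singleton levels are excluded with a warning; the
maximum-mean level is flagged most favorable.  Risk tables report the
mean FVC slope ×10⁴, the conventional display scale for per-year FVC
slopes.

Screening and discretization.  Continuous drivers are screened by VIF
(`1/(1 − R²)` of each factor on the rest, intercept included, via
statsmodels OLS); factors with VIF strictly above 10 are removed
iteratively, worst first, with perfect collinearity reported as +inf
and removed before anything else.  Discretization schemes:
equal-interval, quantile, custom breaks, and circular aspect (eight
45° compass bins offset by 22.5°, so north spans 337.5°–22.5°).
Default class counts where a study does not fix them: aspect 8 circular
bins, distance-type drivers equal-interval bins, other continuous
drivers quantile k = 5 — all overridable.

## Synthetic generators and what passing tests show

`generate_trend_stack` plants `intercept + slope·i + N(0, σ)` per pixel
(σ default 0.05 FVC, a typical interannual variability for annual
composites of a recovering landscape), clipped to [0, 1]; a warning
fires if clipping moves more than 5% of values, preventing silent
truncation bias.  `generate_fgn_stack` synthesises exact fractional
Gaussian noise by Davies–Harte circulant embedding — exact rather than
approximate aggregation so the planted H is a true parameter, not an
asymptotic one — and maps it affinely to mean 0.5, sd 0.1 (affine maps
preserve the R/S slope).  `generate_stratified_field` assigns levels
uniformly at random and adds within-level Gaussian noise; the planted
`q = Vb/(Vb + Vw)` is known in closed form, and `means_for_q` inverts
it.

`build_basin` composes one study-shaped scene (default 200×200, 21
years from 2000, 2% nodata): a 13-type microtopography map (smoothed
random surface cut into quantile classes) sets zone intercepts from
0.55 down to 0.25 FVC; the northern half carries the driver experiment
— two categorical factors contribute additive slope effects sized so
their planted q is exactly 0.5 and 0.2 *on the estimated slope*,
i.e. the within-stratum variance term includes the OLS slope-estimation
noise `σ²/Σ(i−ī)²` in closed form — plus white noise; the southern half
carries zero-trend fGn bands at H = 0.25, 0.5, 0.85.  The trended north
half has no planted H (a deterministic trend is persistent by
construction, so an H "truth" there would be ill-defined); for the
21-year fGn bands the R/S estimator's bias and variance are far larger
than at long n, so the basin-level check is ordering (higher planted H
⇒ higher regional mean estimate), while the ±0.08 recovery tolerance is
enforced at n = 4096 where it is meaningful.

What the generators do *not* emulate: Landsat radiometry, cloud cover
and compositing artefacts, spatial autocorrelation of the noise field
(pixels are independent), mixed land-cover transitions, or per-pixel
gaps in the year set.  Passing tests therefore demonstrate that the
estimators recover what they claim from data matching their model
assumptions — not that those assumptions hold for any particular
satellite record.

## Numerical conventions and problem sizes

- Rasters are float32 on disk (nodata −9999, one TIFF per year plus a
  JSON sidecar), float64 in memory; pixel-space row/col addressing,
  origin top-left.  Area fractions are pixel-count fractions.
- Every CSV product carries the run seed in a leading comment line;
  identical config + seed reproduce identical bytes.
- Test problem sizes were chosen as the smallest at which the checked
  quantities are statistically stable: 10⁴ pixels for test-calibration
  rates, 100 series of n = 4096 for Hurst recovery, 10⁴ pixels for
  planted-q recovery, 1000 replicates × 999 permutations for null
  calibration, and the full 200×200 basin for the end-to-end run.
- Zone rasters coarser than the value raster are aligned by
  nearest-neighbour resampling of the categorical codes only.

## Known limitations

- No Theil–Sen or Mann–Kendall trend alternatives; the trend model is
  OLS + t-test by design, and p-values carry no spatial-autocorrelation
  correction.
- No DFA or wavelet Hurst estimators; R/S only, with its small-sample
  bias documented above.
- The q-statistic decomposes variance; it does not identify causal
  drivers, and the ecological detector of the wider Geodetector family
  is out of scope.
- TIFF files carry no geo-referencing tags; the pipeline operates on
  aligned pixel grids and leaves projection handling upstream.
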