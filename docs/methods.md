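# Methods

## The estimation problem

A dating chart predicts gestational age (GA, weeks) from crown-rump length
(CRL, mm). Cohorts recruited only between 9+0 and 13+6 weeks observe GA on
a doubly truncated window, and because truncation acts on the *outcome* of
the dating regression, a naive fit of GA on CRL is biased wherever the
conditional GA distribution is clipped — increasingly so toward both ends
of the CRL range. The size regression (CRL on GA) is not biased by the
window, since there GA is the covariate; every strategy in this package
leans on that asymmetry.

## Centile model

Both chart types use the classical mean-and-SD construction: an FP
(fractional polynomial) regression for the mean, a second FP regression for
the residual SD, and centiles mean(x) + K·SD(x) with K the standard-normal
quantile of the level. GA is modelled as ln GA (its conditional
distribution is right-skewed and roughly lognormal; CRL is modelled on its
natural scale). K uses exact quantiles (1.880794 for the 97th); clinical
tables often print 1.88, and all printed-precision comparisons in the test
suite hold under either convention.

FP terms are powers of the covariate from {−2, −1, −0.5, 0, 0.5, 1, 2, 3},
power 0 meaning ln x and a repeated power p meaning the pair
(x^p, x^p·ln x); degree ≤ 2 (8 degree-1 and 36 degree-2 candidates). Fits
are ordinary least squares on the transformed design. Degree selection uses
the closed function-selection procedure at α = 0.05: the best degree-2
model must beat the straight line (3 df), and then the best degree-1 model
(2 df), on chi-square tests of the Gaussian deviance difference
n·ln(RSS₀/RSS₁); otherwise the simpler shape wins. A
`selection="lowest_deviance"` override is available. Deviance ties within
1e-8 go to the lower degree, then the lexicographically earlier power
tuple, so refits are deterministic.

The SD curve is estimated by the half-normal absolute-residual method:
regress √(π/2)·|r| on the covariate (E|r| = σ√(2/π) for Gaussian
residuals). SD fits default to degree ≤ 1 and may select a constant. This
is the standard mean-and-SD chart construction; the source literature for
this problem does not spell out its SD estimator, and the absolute-residual
method is the default in the chart-making tradition it cites.

### Plausibility screening

Fitted curves here are routinely *extrapolated* — to 7 weeks for low-end
augmentation, to 17 weeks for high-end augmentation, and across 10–100 mm
for reporting. FP shapes that fit equally well inside a 5-week window can
behave very differently outside it; occasionally the lowest-deviance choice
turns over (CRL decreasing in GA below 9 weeks) or sends an SD negative.
Both are physically impossible, so the power search accepts only candidates
that are *plausible over the span they will be used on*: size-model means
must be strictly increasing and SD curves strictly positive over the
augmentation/evaluation span, and dating-model medians strictly increasing
over the observed CRL span. The screen removes candidates before the closed
test; if no candidate passes, fitting fails loudly. Fixed user-supplied
powers bypass the screen (a non-positive SD still raises).

## Simulation design

`simulate_from_dating` draws ln GA ~ N(mean(CRL), σ) at each grid CRL. The
defaults — integer CRL 5–110 mm, 100 draws per value, 10,600 rows total,
the built-in Verburg coefficients (b₀ = 1.4653, b₁ = 0.001737, b₂ = 0.2313,
σ = 0.04590, natural logs) — are the published validation design: 100 per
CRL value mirrors the average per-GA-day sample size of the motivating
cohort and is large enough to tame sampling noise. Truncation keeps
9 ≤ GA < 14 (half-open, encoding the clinical 9+0–13+6 range).

`simulate_from_size` draws CRL ~ N(mean(GA), SD(GA)) at each gestational
day, 100 per day by default. Low augmentation uses days 49–62 (7+0–8+6),
high augmentation days 98–119 (14+0–17+0); the source describes the spans
only as "between 7 and 9" and "between 14 and 17" weeks, so the endpoint
convention (stop one day short of a boundary that the observed window
already covers) is this package's choice, and the grids are configurable.
Gaussian tails can produce non-physical CRL ≤ 0 at early GA; such draws are
rejected and redrawn, with the count recorded in the metadata. All
randomness flows through `numpy.random.default_rng(seed)`; the default seed
is 20131207.

What the generator emulates: the joint (CRL, GA) distribution implied by a
published lognormal dating equation under a uniform-in-CRL sampling design.
What it does not: measurement error structure, digit preference, maternal
recall error, centre effects, or any real-cohort covariates. Passing tests
therefore demonstrate that the *truncation-handling machinery* recovers a
known truth, not that any particular clinical chart is correct.

## The three approaches

**Approach 1** fits the size chart on the truncated data, simulates CRL for
each day of 7+0–8+6 weeks, refits the dating chart on the augmented set
restricted to CRL 20–65 mm, and extrapolates. 65 mm is the largest CRL
whose conditional GA distribution is essentially untouched by the 14-week
cut; 20 mm (configurable; a sensitivity helper compares 10/15/20 mm) trims
the region where augmentation quality dominates. The model's `fit_range`
records the restriction and downstream tables flag every extrapolated cell.

**Approach 2** augments both ends and fits the dating chart to the full
augmented set, with no restriction or extrapolation beyond the data.

**Approach 3** needs no simulation: the size fit's 3rd/50th/97th CRL
centiles are evaluated one point per gestational day (9 to 17 weeks by
default — the size chart is extrapolated only toward larger GA, where its
centiles keep rising), the axes are interchanged, and ln GA is regressed on
each coordinate set. Note the relabelling: the *low* CRL centile becomes
the *high* GA centile after inversion, so the three fitted curves are
ordered by predicted GA rather than by their input labels. The SD curve is
recovered as the average of the two log half-spreads,
SD(CRL) = (ln c97 − ln c3)/(2K), regressed on CRL (degree ≤ 1); for an
exactly lognormal model the two half-spreads coincide, which the tests
exploit as an exactness oracle. Centile curves must increase strictly in GA
to be invertible; extrapolated curves that turn over at the far grid edges
are trimmed back to the largest increasing span covering the observed
window, while a violation inside the window raises an inversion error.

Approach 3 carries an intrinsic bias: inverting the median of CRL|GA is not
the median of GA|CRL when the size model's SD varies and the sampling
design is non-uniform, so its dating chart systematically underestimates GA
by a fraction of a day — visible in the mean signed difference its
comparison table reports.

## Evaluation

`compare_to_reference` tabulates 3rd/50th/97th centile GA from a fitted
chart and a reference equation on a CRL grid (default 10–100 mm by 5 mm)
with differences in days, sign convention diff = (reference − fit) × 7;
tables keep unrounded values, and a `rounded()` view formats weeks/days to
2 dp. `coverage_counts` counts observations below the 3rd and above the
97th fitted centile; calibration is assessed on the data set the chart was
*fitted to* (for Approach 1 that is the augmented, CRL-restricted set —
roughly 4,500 rows over 20–100 mm), because that is where the nominal 3%
tails are meaningful. `agreement_summary` reduces one difference column
over a CRL window to (max |diff|, mean diff).

## Monte-Carlo behaviour and limitations

The agreement statistics of the extrapolating pipelines are noisy.
Analytically, the SE of an extrapolated log-median at 100 mm for a
degree-2 FP fitted to CRL 20–65 mm at 100 rows/mm is ≈ 0.008 log-units
(≈ 0.8 days), before power-selection variability; the cross-seed spread of
Approach 1's max-|difference| statistic is therefore on the order of a day
or more, and single-run values should be read accordingly. Approaches 2
and 3, which never extrapolate the dating fit far beyond supported CRL,
are markedly more stable. The acceptance script reports single-seed values
of all of these.

Other known limitations: augmentation quality rests entirely on how well
the size fit extrapolates a few weeks beyond the window (the plausibility
screen removes impossible shapes but cannot make extrapolation accurate);
the discrete day grids approximate a continuous GA distribution; the SD
model is a degree-≤1 FP, which cannot capture non-monotone heteroscedasticity;
and no skewness modelling is attempted — centiles assume conditional
(log)normality.
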