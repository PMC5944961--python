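# Methods

## The problem

A community census yields, for each species, an abundance `r` (number of
individuals).  The species abundance distribution (SAD) — the number of
species per abundance class — is almost always a hollow curve: many rare
species, few common ones.  On a log2 abundance axis ("octaves", `R = log2 r`,
Preston's scale) the observed SAD typically becomes a left-truncated bell:
the left flank is hidden behind the *veil line*, because species rarer than
one individual in the sample cannot be observed.

`sadoctave` implements the standard comparative workflow on this scale:
bin the abundances into octaves, fit a set of seven candidate SAD models to
the binned counts `S_obs(R)` by least squares, judge each fit by a
chi-square test, the adjusted coefficient of determination and AIC/BIC,
extrapolate total richness `S*` from the area under the untruncated fitted
curve, and compare communities through left-truncated unit-area versions of
the best fitted curves.

## Octave binning

Two dialects are implemented (`binning.bin_octaves`):

* **halfopen** (default): octave `R >= 1` holds abundances in
  `(2^(R-1), 2^R]`, so octave 1 holds {1, 2}, octave 2 holds {3, 4}, octave
  3 holds {5..8}.  Counts are integers and nothing is discarded.  This
  dialect is the default because it conserves species exactly and puts the
  mode where singletons and doubletons dominate, which is the qualitative
  signature of the field histograms this pipeline targets.
* **preston_halving**: class boundaries at the powers of two; a species at
  a boundary `2^R` contributes half a species to each adjacent octave, and
  the half of the singletons below the lowest boundary is *discarded as
  below the veil* and reported (never redistributed).  Counts can be
  half-integers; they enter the regression and the chi-square statistic
  as-is.

Interior zero-count octaves are retained: an empty abundance class is an
observation, and the regression's sample size `n` counts all octaves from
`R_min` to `R_max` inclusive.

## The model set

All seven models are expressed as expected species count per octave,
`S(R)`; see `models.py` for the exact forms.  GS (geometric series) is
constant on this scale; BS (broken stick) is the octave transform of an
exponential abundance density; ON (overlapping niche) carries two frozen
data constants (`N_oct`, the octave-transformed total abundance, and
`R_max`) and only one free parameter; LSer (logseries) decays doubly
geometrically, `Sm * alpha^(2^R)`, and is defined for `R >= 0`; LN, LC and
LS (lognormal, logCauchy, log-sech) are symmetric unimodal curves with
height `Sm`, mode `Rm` and width `1/alpha`, differing in tail weight
(Cauchy heaviest, Gaussian lightest).

Two typographic ambiguities in the source forms were resolved as follows:

* The lognormal exponent is read as `exp[-alpha^2 (R - Rm)^2]` (Preston's
  canonical form), which makes its richness extrapolation
  `S* = sqrt(pi) * Sm / alpha`.
* The logseries octave form is read as `Sm * alpha^(2^R)` on `R >= 0`.

`S*` is the integral of the untruncated curve over the whole octave axis.
For BS, LN, LC and LS the closed forms equal that integral (verified
against quadrature to 0.1% in the test suite).  For ON the conventional
closed form `S* = Sm / (2 ln 2)` is reported as printed in the model-set
literature; it is **not** the integral of the octave curve given above
(that integral is `Sm * N_oct / (2 ln 2)`), and the package makes no
attempt to reconcile the two — the discrepancy is documented here and the
closed form is what `estimate_total_richness` returns.  GS and LSer have no
finite `S*`.

## Fitting and statistics

Models are fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`; the bounded equivalent of the classical
Levenberg–Marquardt procedure) with a deterministic multistart:
`Sm0 = max S_obs`, `Rm0 =` modal octave, `alpha0 in {0.3, 1.0, 3.0}`
(LSer: `{0.2, 0.5, 0.8}`, bounded inside (0, 1); BS additionally starts at
`1/mean(2^R)`).  Bounds: `Sm in (0, 10 max S_obs]`, `alpha > 1e-6`,
`Rm in [R_min - 2, R_max + 2]`.  Convergence: relative tolerance 1e-10,
at most 2000 function evaluations per start; the best start by residual sum
of squares wins.  GS is solved in closed form (`Sm =` mean count), which
makes its adjusted R² identically zero — the natural baseline row of every
comparison table.  Fitting is fully deterministic.

Statistics per fit:

* **Adjusted R²**: `1 - [SS_res/(n-k)] / [SS_tot/(n-1)]`; may be negative.
  The plain R² is selectable (`FitOptions(adjusted_r2=False)`).
* **Chi-square**: `sum (S_obs - S_fit)^2 / S_fit` after pooling octaves
  whose expected count falls below 1.0 with their inner neighbour (the
  classical expected-count floor; configurable off via `chi2_floor=0`).
  Degrees of freedom default to `n_pooled - k`; `n - k - 1` is selectable.
  The source analyses state the test but not their df or pooling
  convention, so both are explicit options and the defaults are the
  documented reproduction setting.  `P` is reported as NaN when `df < 1`.
* **AIC/BIC** in residual-sum-of-squares form,
  `AIC = n ln SS + 2k - n ln n`, `BIC = n ln SS + k ln n - n ln n`, so
  `AIC - BIC = k(2 - ln n)` identically; a zero-residual fit reports
  `-inf` for both.

Model selection: per criterion, argmin AIC/BIC or argmax R², ties broken by
fewer parameters then conventional model order.  The combined "best
overall" rule is lowest AIC among chi-square-adequate models, falling back
to lowest AIC outright; the source analyses use the criteria jointly but
never define a single formal rule, so this one is the package's own,
stated here rather than attributed.

## Truncated curves

`truncated_density` renormalises a fitted LN/LC/LS curve to unit area over
`[L, inf)`.  Default `L` is the left edge of the smallest observed octave
(octave 1 spans `(2^0, 2^1]` under the half-open dialect, so `L = 0`
there) — the veil line; the published figures state left truncation but
not its position, so the choice is configurable.  The LC normaliser is
closed form, `(Sm/alpha)(pi/2 - arctan(alpha(L - Rm)))`; LN uses the
Gaussian tail (erfc); LS is integrated by adaptive quadrature with an
overflow-safe `sech`.  Default grid: 512 points from `L` to `Rm +
12/alpha`.  Curve comparisons rank by peak height and split each curve's
mass into "rare" (left) and "common" (right) at a configurable octave,
default the grid midpoint.

## Synthetic communities

The generator (`simulate.generate_community`) draws from each model's
generative reading; the defaults emulate the surveyed communities (tens of
species, hundreds to thousands of individuals, left-truncated at one
individual):

* GS and BS: deterministic abundances `round(N p_j)` (round half up) from
  the niche-preemption and broken-stick rank proportions; a multinomial
  draw of `N` individuals over `p_j` is available behind a flag.
* ON: each species' relative abundance is an inverse-CDF draw from the
  linear density `f(r) = 2 - 2r` on [0, 1] (`r = 1 - sqrt(1 - u)`),
  normalised and scaled to `N`.
* LSer: abundance from the continuous logseries density
  `alpha^r / (r E1(-ln alpha))` on `[1, inf)` by a log-spaced inverse-CDF
  table on `[1, 1e6]`; draws beyond the table are resampled.
* LN/LC/LS: the species' octave is a normal / Cauchy / hyperbolic-secant
  draw centred at `Rm` (scales `1/(alpha sqrt 2)`, `1/alpha`, `1/alpha`);
  the sech quantile `Rm + ln tan(pi u/2) / alpha` was derived analytically
  and is unit-tested against scipy's hypsecant and rejection sampling.

**Quantisation of octave draws.**  A continuous octave draw `R` is
assigned to its *nearest integer class* `C = round(R)` and receives an
integer abundance `round(2^R)` clipped into that class's abundance range
`(2^(C-1), 2^C]` (class 1 also holds abundance 1).  Binning the community
therefore returns exactly the drawn classes, whose expected counts are the
model density integrated over `(C - 1/2, C + 1/2]` — the quantisation that
leaves the fitted curve's location and shape asymptotically unbiased, which
is what makes the recovery harness's bias and RMSE interpretable.  The
naive alternative (bin `round(2^R)` directly by the half-open rule) makes
integer class 1 span continuous octaves `[-1, 1.32)`; the first octave then
absorbs over twice its nominal width of probability mass, and the fitted
logCauchy degenerates (location driven below zero, width parameter roughly
tripled) even at infinite sample size.  Draws whose class falls below
class 1 are behind the veil: resampled when `truncate_at_one` is set,
otherwise dropped and counted.  Cauchy octave draws are clipped to
`[-200, 62]` so abundances stay inside 64-bit integers.

What the generator does **not** emulate: spatial aggregation, sampling
error of the quadrat design, inter-layer dependence, and species
identities.  Passing recovery tests therefore show that the estimator
chain is consistent for data that truly follow a model's octave density —
not that field data do.

## Problem sizes and reproducibility

Every stochastic stage takes an explicit integer seed
(`numpy.random.default_rng`); per-replicate seeds in the recovery harness
are spawned from the configured seed via `SeedSequence` and kept below
2^31.  The shipped validation uses communities of 80–10,000 species and
recovery trials of 100 replicates at S = 500 — sizes at which the
logCauchy recovery statistics (location bias well under 0.1 octaves,
relative width bias of a few percent, generating model selected by AIC in
essentially all replicates) are stable run-to-run.

## Known limitations

* The published per-species Dinghushan census (the deposited spreadsheet)
  is not redistributable with the package; the reproduction tests in
  `tests/test_acceptance.py::TestFieldReproduction` document the expected
  published values and run once `data/dinghushan.csv` is supplied.
* The ON richness formula is reported as conventionally printed although
  it is not the integral of the ON octave curve (see above).
* Least-squares fitting of binned counts is the method being mirrored, not
  the statistically optimal estimator for SADs; no likelihoods, bootstrap
  intervals or model averaging are provided.
* The LSer inverse-CDF table truncates at abundance 1e6; communities with
  a realistic `alpha` never reach it, but extremely flat logseries draws
  are resampled from within the table range.
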