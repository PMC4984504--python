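# Methods

This note records the models, conventions and numerical choices behind
`divetrace`, and what the synthetic-data tests do and do not demonstrate.

## Excursion detection

A tag series is a strictly time-ordered stream of (timestamp, depth,
temperature) records at a nominal interval (default 120 s, the archival
rate of the tags this analysis targets). Gaps larger than ±1% of the
nominal interval split the series into segments; every downstream scan
works within a segment, so a deep run abutting a gap is never credited
with a bounding record it does not have.

A mesopelagic excursion (ME) is a maximal run of at least `min_run = 5`
consecutive records with depth strictly greater than 200 m, bounded on
both sides by a record with depth strictly less than 200 m. The bounding
records are the ME's start and end, so each ME spans at least 7 records
(≥ 14 min at 2-min sampling). Ties at exactly 200.0 m are resolved
conservatively: such a record neither extends a run nor serves as a
bound, which can only reduce the number of detected MEs. Both the depth
threshold and the run length are parameters of `detect_excursions`.

Derived per-ME quantities: the apex is the *first* record attaining the
maximum depth; descent duration runs from the start record to the apex
and ascent duration from the apex to the end record, so the two always
partition the ME duration; minimum temperature is taken over the full
slice.

## Environmental annotation

**Diel period.** Sunrise and sunset are computed from the NOAA
solar-position closed forms (equation-of-time and declination Fourier
series), accurate to a couple of minutes — ample for hour-wide windows.
Dawn is [sunrise − 1 h, sunrise + 1 h), dusk the same around sunset; day
and night are the remainder, and the four durations partition 24 h (they
double as exposure offsets in the count models). The event is defined by
the solar zenith angle crossing `zenith_deg`, default 90.0° (geometric
horizon). The conventional refraction-corrected 90.833° is available via
the parameter; with the geometric default, equatorial equinox day and
night periods agree to a few minutes, which makes exposure bookkeeping
easiest to reason about. Latitudes beyond ±66° are rejected rather than
given a polar day/night convention.

**Lunar phase.** A mean synodic-month clock (29.530588853 d) anchored at
the new moon of 2000-01-06 18:14 UTC assigns each date an age; the month
is partitioned into four equal windows centred on the principal phases.
The mean clock drifts less than ±0.8 d from the true ephemeris, small
against the 7.38 d windows.

**Daily SST** is the per-date maximum recorded temperature — a standard
estimate for a tag that surfaces regularly, unaffected by deep cold
excursions.

**OMZ class.** Oxygen is resolved either from an analytic environment
model or a two-column (depth, oxygen) table interpolated linearly; a
table that does not cover the excursion's depth range is an error rather
than an extrapolation. A dive is `none` if no record sees O₂ ≤ 3.5 mL/L,
`apex_within` if the maximum-depth record does, and `passed_through` if
some record does but the apex has recovered above the threshold.

## Phase standardization and clustering

Each ME splits at the apex (shared by both phases). A phase profile is
standardized by mapping elapsed time and depth each affinely onto
[0, 1] and resampling by linear interpolation onto P = 20 uniform time
points. P = 20 resolves 2-min sampling for phases of ≥ 4 min while
keeping the Euclidean geometry insensitive to raw units (standardization
is affine-invariant by construction); it is a parameter, not a constant.
Zero depth range is a degenerate-profile error.

K-means (Euclidean, Lloyd's algorithm, best of `n_restarts = 25`
seeded restarts) clusters descents and ascents separately. Clusters are
canonically relabelled by descending membership, so "cluster 1" is
always the most common shape. R² = 1 − within-SS/total-SS is reported
for k = 2…10; each k is additionally warm-started from the previous k's
centroids plus the farthest point, which guarantees the R² sequence is
non-decreasing and makes the elbow interpretable. The default analysis
fixes k = 3 per phase (three descent and three ascent shape families);
choosing k from the R² table remains an operator judgement.

Mean vertical velocity of a phase is the endpoint definition,
|depth(last) − depth(first)| / duration, consistent in magnitude with
fitted segment slopes (e.g. ~450 m in ~6.6 min ≈ 1.1 m/s).

## Broken-stick ascent regression

Transition-point ascents are fit with the sharp-hinge two-segment model
`depth(t) = b₀ + b₁ t + b₂ (t − c)₊`, time origin at the apex record, on
non-standardized records. For fixed `c` the model is linear and solved
by least squares; `c` is profiled on a 200-point grid between the second
and second-to-last record (≥ 2 records on each side of the hinge), then
refined by bounded scalar minimization within the best bracket, so
noise-free two-segment profiles are recovered to numerical precision.
Five records is the identification minimum (4 parameters + 1 residual
df); shorter ascents raise an error and are omitted from the analysis.
A fit whose residual sum of squares does not improve on a single
straight line (relative tolerance 1e−10 on the data scale) is flagged
unidentifiable instead of raising. The 95% CI inverts the Gaussian
profile likelihood, {c : n·log(RSS(c)/RSS(ĉ)) ≤ χ²₁(0.95)}, evaluated on
the grid; with zero residual the interval collapses to the estimate.
The transition point is the first record strictly *after* the
real-valued change point (a change point landing exactly on a record
time points to the next record), and carries that record's depth and
temperature. The velocity change at the transition is reported as
|slope2| − |slope1| (negative = deceleration).

In the pipeline, the transition-point cluster is identified
automatically as the ascent cluster whose standardized centroid gains
most (relative RSS) from a broken-stick fit with a decelerating bend.

## Count models

ME frequency models are NB2 regressions with log link, a log exposure
offset, and a Gaussian random intercept per individual:

    y_ij ~ NB2(μ_ij, α),  log μ_ij = x_ij'β + log E_ij + b_i,  b_i ~ N(0, σ²)

The marginal likelihood integrates b_i by Gauss–Hermite quadrature
(20 nodes by default; 16 suffices for the calibration suites) and is
maximized by L-BFGS-B over (β, log α, log σ) with wide bounds guarding
the linear predictor against overflow. Standard errors come from the
numerical Hessian at the optimum. Factor significance is an
analysis-of-deviance likelihood-ratio χ² against the intercept-only
(plus random intercept) null. Because the offset enters the linear
predictor exactly, scaling all exposures by c shifts the intercept by
−log c and leaves rate ratios unchanged.

The likelihood-ratio test is asymptotic: with very few individuals or
mean counts near 1 it is anti-conservative (measured ~8–10% at 12–16
individuals with mean counts ~1–5). The null-calibration suite
therefore uses 24 individuals × 2 categories with mean counts ≈ 5,
where the measured type-I error is 4–8% over 200 replicates. The
rate-ratio recovery suite uses 16 individuals with season-long
exposures and mild dispersion (α = 0.05), putting the ML sampling error
of the log rate ratio (se ≈ 0.09) well inside a ±25% accuracy band; at
field-realistic dispersions the same estimator is unbiased but a single
dataset's estimate can vary far more.

Exposures: diel exposures sum the four daily period durations over
tracked dates; lunar and monthly exposures count 24 h per tracked date
in each phase/month; the monthly model carries the monthly mean of
daily SST as a continuous covariate (covariate-only, no month factor).

## Linear mixed models and post hoc contrasts

Dive-characteristic responses are Box–Cox transformed (λ chosen by
profile maximum likelihood on a grid over [−2, 2] in steps of 0.01;
λ = 0 is the log branch) and modelled with statsmodels `MixedLM`
(REML, random intercept by individual; optimizer falls back lbfgs →
powell → cg). Per-factor tests are approximate F statistics: Wald χ²
of the factor's coefficient block divided by its df, with residual
denominator df = n − rank(X); the method label is stored with every
test, since denominator-df conventions differ across software. A
singular random-effect variance is floored at zero with a warning.

Pairwise level contrasts use the single-step (Tukey-type)
multiplicity adjustment: the adjusted p for contrast k is
P(max_j |Z_j| ≥ |z_k|) under the joint normal law of all contrast
statistics, computed as multivariate-normal rectangle probabilities.
The compact letter display uses insert-and-absorb; the letter 'a'
labels the group with the largest estimated mean, and two levels share
no letter exactly when their adjusted p < 0.05.

## Temperature windows

Pre-ME windows cover the configured width (default 300 min; 30–300 min
are the analysis widths) ending at each ME's start record. Non-ME
windows are drawn uniformly without replacement from record-aligned
start times whose window overlaps neither any ME interval ± 1 h nor any
pre-ME window — the latter exclusion prevents label leakage between the
two samples. If fewer eligible windows exist than requested, all are
returned with a warning.

## Synthetic tracks

The simulator emulates the vertical regime the analysis targets:

- a mean-reverting reflected random walk in the mixed layer
  (mean ≈ 55 m, stationary sd ≈ 33 m, bounded by the 150 m mixing
  depth), giving ≈ 90% of records above 100 m;
- excursions at Poisson times (default 0.25/day) with apex depths
  uniform on 202–1190 m, descent durations ~N(6.61, 3.53²) min
  truncated to 2–18, ascent durations ~N(14.40, 7.16²) min truncated to
  4–36 — together ≈ 0.3–0.4% of records below 200 m;
- three descent shape classes (linear; slowing, a sine easing with
  strictly decreasing increments; delayed, a convex approach with a
  bounded wiggle) and three ascent classes (linear; transition-point,
  two linear segments with the corner at ≈ 1/3 of the time and ≈ 70% of
  the depth range, matching the observed segment structure; variable, a
  low-frequency high-amplitude meander that reverses vertical
  direction), mixed 0.58/0.33/0.09 and 0.47/0.37/0.16;
- an exponential thermocline T(d) = deep + (SST − deep)·e^(−d/scale)
  and a continuous piecewise-linear oxygen "bathtub" equal to the
  3.5 mL/L threshold exactly at the OMZ boundaries, dipping to the OMZ
  minimum at the band core and recovering to oxygen-rich deep water
  below — so all three OMZ dive classes occur;
- Gaussian depth noise (default 1 m) and temperature noise (0.1 °C),
  with optional pre-ME linear cooling and diel rate multipliers
  (thinning) for generative tests of the statistics.

Two construction choices matter. First, the below-200 m interior of
each excursion is parameterized directly on the sample grid between the
200 m crossing and the apex, with a small clearance
(min(2.5 m, 40% of the apex excess)) above the isobath, so every
simulated excursion satisfies the detection rule by construction — even
apexes barely beyond 200 m — and after noise the interior is clamped
above 200.6 m and the exterior below 199 m to keep that guarantee.
Second, the two bounding records extrapolate the phase trajectory one
sample beyond the crossing (clipped into the epipelagic layer) rather
than taking the ambient mixed-layer depth: this keeps the standardized
profile carrying the class shape rather than an apex-dependent initial
jump, at the cost of a small discontinuity between the track baseline
and the dive's first record.

Within-class shape parameters scatter tightly around each class
archetype. The classes emulate empirically *discovered clusters* —
which are compact shape families by construction — not a continuum of
dive geometries; with wide parameter ranges the transition class
degenerates toward linear and no clustering method could (or should)
separate them. Likewise the variable-ascent meander uses ≈ 1.8 cycles
per ascent: faster wiggles alias at 2-min sampling of the shortest
ascents and become indistinguishable from linear.

What passing tests therefore show: the detector is exactly equivalent
to its specification on arbitrary depth sequences; the clustering,
change-point and count-model machinery recover known structure at
realistic sampling rates, noise levels and effect sizes. What they do
not show: recovery when real dive shapes form a continuum rather than
distinct families, robustness to depth sensor drift or clock drift
(assumed absent), tag-specific quantization, or behaviour near the
poles. The mixed-layer random walk is a stand-in for baseline vertical
behaviour, not an inference target.

## Problem sizes and determinism

The validation suites use: 1000 random series for detector/oracle
equivalence; the default simulation (10 individuals × 30 days, 2-min
records) for recall/precision and occupancy; 500 noisy transition-point
ascents (slopes −1.2/−0.25 m/s, 2 m depth noise, 120 s sampling) for
change-point recovery; 300 simulated ascents (noise 0.05 standardized
units) for cluster recovery; 200 replicates for count-model null
calibration; and 1000 random layouts for the window-exclusion property.
Every stochastic component takes an explicit seed (numpy Generator);
the pipeline records all seeds and thresholds in its run manifest, and
reruns with the same config reproduce identical CSV artifacts.
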