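# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pmexposure`, and what the synthetic-data validation does and does
not demonstrate about real monitoring data.

## The measurement problem

A wearable monitor logs, once per minute: six particle-count channels
(> 0.3/0.5/1/2.5/5/10 µm), three mass channels (PM1/PM2.5/PM10, µg/m³),
temperature, relative humidity, and a GPS fix. Minute-level personal PM2.5
exposure is the quantity of interest; the raw optical mass estimate is
biased and must be calibrated in situ, and the GPS trace must be turned
into microenvironment context (which land use, indoors or outdoors,
stationary or travelling) before exposure can be apportioned.

## Pre-processing

Records missing a timestamp, participant id, or any of the nine pollution
channels are dropped (the any-channel rule is deliberately conservative; a
`missing_rule="all"` variant is available). GPS-less minutes are kept —
they still carry pollution data and feed the overall exposure assessment.
Participants whose count *and* mass channels are simultaneously zero for
strictly more than 99% of their records are removed as dead sensors; a
participant at exactly 99.0% is retained, reading the threshold as
exceedance. Duplicate (participant, timestamp) pairs keep the first record.
Every stage reports counts and percentages against the raw total, not the
prior stage, so the ledger lines add up.

## Context identification

All metric geometry runs in a local azimuthal equidistant projection about
the region centroid (spherical Earth, R = 6 371 008.8 m); degree-space
distances are anisotropic at mid-latitudes and are never used. The
projection is hand-implemented from the closed form and round-trip tested
to nanometre-scale error over the study region.

*Smoothing and imputation.* Coordinates are smoothed by a centred moving
median (default window 5 fixes, shrunk at the edges); the median is applied
over the sequence of present fixes, leaving gaps in place. Interior gaps of
at most 10 minutes are filled by linear interpolation in projected
coordinates; longer and edge gaps are excluded from context analysis but
remain in the overall-exposure stream.

*Stay/trip segmentation.* A stay is a maximal temporally contiguous window
whose fixes all lie within `eps` (default 30 m) of the window's centroid
and whose span is at least `min_stay` (default 5 min); the scan is greedy
from the left, and the contiguous remainder forms trips. Contiguity breaks
across time gaps over 10 minutes. The incremental implementation is tested
against a naive re-derivation (recomputing every window from scratch) on
random tracks up to 200 fixes.

*Labels.* Stays take the class of the nearest land-use polygon (distance 0
if inside; near-ties within 1 µm resolve to the smallest feature id, which
keeps labels stable under projection round-trip jitter on boundary points)
and are indoor iff the stay centroid lies within 10 m of a building
footprint. The centroid, not every fix, is tested, which damps GPS jitter.
Stays whose centroid falls outside the study region are excluded and
counted. Trips are vehicle-based when mean speed exceeds 2.5 m/s, or when
the path exceeds 500 m and mean+sd speed exceeds the threshold; vehicle
minutes are labelled `vehicle` and treated as indoor, walking minutes are
outdoor and take the nearest land-use class per minute (a walk may cross
parcels). Single-fix trips carry no speed information and are dropped with
a warning. The clustering and mode thresholds are conventional defaults,
declared in `ContextParams` and exposed in the run config rather than
hard-coded.

*Valid days.* Participant-days with fewer than 6 h of labelled minutes
(local calendar days in the configured IANA zone, DST-aware) are removed
before time budgets and dose apportionment; exactly 6 h is retained.

## In-situ calibration

For each (participant, UTC hour) with at least 30 outdoor-labelled minutes,
the hourly means of raw PM2.5, RH, temperature, and position are paired
with the nearest station when it lies within the active cut-off and reports
that hour. The calibration model is

    reference ~ raw + RH + temperature + (1 | participant),   REML.

RH and temperature are included because optical scattering sensors are
humidity-sensitive and the device logs both; the covariate set is
configurable. The cut-off grid {0.5, 0.6, 0.75, 1, 1.5, 2, 3, 4, 5} km is
scanned and the R²-maximising cut-off kept (ties → smallest); R² is the
squared Pearson correlation of fitted versus reference values. A singular
or non-convergent mixed fit falls back to OLS with a flag. Calibrated
minute values are fixed-effects predictions — random intercepts are not
identified away from collocation conditions — floored at zero with a
counter. With a positive slope the correction is rank-preserving before
flooring.

## Exposure metrics

Summaries report mean, sd, the 2.5/25/50/75/97.5 percentiles (linear
interpolation between order statistics — the rule is declared because
percentile conventions differ), min, and max. Dose per minute is
concentration × breathing rate × 1 min with a constant default breathing
rate of 0.012 m³/min; dose *proportions* are invariant to that constant, so
its exact value only scales the absolute µg totals. Home-address exposure
is IDW over in-radius stations (power 2, radius 50 km, weights summing to
one per hour; a station at the home coordinate returns its own series).
The personal-vs-home comparison reports Pearson r at both minute and hour
scale — aggregation smooths indoor spikes and raises r, so both are kept —
and the P/O ratio as the ratio of participant-period means (minute-wise
ratios explode when the home value approaches zero).

## Inference

Design rows are minute-level: calibrated exposure against the 8-level
microenvironment factor (reference `other`), an indoor indicator
(reference outdoor) interacting with the IDW home background, season
(meteorological, local time, reference spring), local hour (reference 0),
and six participant-level demographic factors, with a random intercept per
participant. Factors are treatment-coded against fixed reference levels;
rank deficiency is detected by pivoted QR and reported by aliased column
name.

The REML point fit uses statsmodels MixedLM. Profile-likelihood CIs are
computed with a dedicated ML engine: for the single-random-intercept
Gaussian model, the GLS solution at a fixed variance ratio
λ = σ²_between/σ²_resid is closed-form in group sufficient statistics, and
pinning a coefficient at `c` is equivalent to regressing `y − c·x_j` on the
reduced design, so the profile deviance can be inverted by exact root
finding (bracket expansion from the Wald step, then Brent). ML rather than
REML is used for profiling because the REML criterion is not comparable
across fixed-effect specifications; the engine's likelihood and estimates
are cross-checked against statsmodels in the tests. BH adjustment (via
statsmodels, verified in tests against a direct step-up implementation)
covers all non-intercept fixed effects of the final model — the family had
to be chosen, and this is the widest defensible one.

EMMs average predictions over the levels of every other factor with equal
weights, hold the continuous background at its observed mean, and set
random effects to zero; with the single indoor-by-background interaction
this reduces to closed-form coefficient sums, and EMM differences within a
factor equal coefficient differences. The indoor-stratum background slope
is the main effect plus the interaction. The ICC comes from an
intercept-only random-intercept model as σ²_between/(σ²_between+σ²_resid).
Land-use Shannon entropy is −Σ pᵢ ln pᵢ over time fractions, with vehicle
counted as a class (configurable). Subgroup comparisons use the Wilcoxon
rank-sum and Kruskal–Wallis tests with midranks and tie correction;
at pooled n ≤ 10 the p-value is exact by enumeration of group assignments,
otherwise asymptotic. Sensitivity analyses refit the model with
demographics removed (Model 1) or restricted to age and sex (Model 2), and
leave one of ten seeded participant groups out at a time, reporting
per-coefficient ranges; refits that lose a factor level are flagged
non-estimable.

A packaged CSV of published fully adjusted coefficients and EMMs from a
two-week, 163-adult monitoring cohort serves as a worked example for the
coefficient algebra (indoor-stratum slope 0.279 − 0.168 = 0.111; EMM
contrasts industrial−office 3.2 and residential−office 3.0 µg/m³); the
package recomputes these from the table rather than asserting them.

## The synthetic world

The generator's defaults are the emulated study conditions: 160
participants, 14 days each at 1-min resolution, staggered start dates
across the year, an indoor-time target of 0.78 and residential-time target
of 0.67. Desk-scale runs (tests, the analysis scripts, the acceptance
script) pass smaller explicit cohort sizes — 3–10 participants over 2–7
days — chosen so the full suite runs in minutes while every pathway is
still exercised at realistic rates.

*Landscape.* A regular parcel grid (250 m, with interstitial gaps) over a
~22 × 16 km region; classes drawn with residential-dominated weights;
every non-park parcel holds one 16-m building at its centre, so indoor
stays sit inside footprints and park stays are unambiguously outdoors.
Stations sit on a jittered grid (a quasi-uniform regulatory network),
optionally at explicit coordinates; stations marked decorrelated report an
independent series, which is how the cut-off-scan experiment constructs
far stations that share no airshed with the cohort.

*Behaviour.* Each participant has a home (residential building), workplace
(office; a commercial venue at weekends), and nearby park. The daily
skeleton — home overnight, a morning on-foot park excursion, a vehicle
commute to an indoor work block, home in the evening — solves its stay
durations from the indoor/residential targets, with seeded minute jitter;
trips run at constant speed (walk 1.4 m/s, vehicle 12 m/s) on straight
lines, with fixes strictly between the endpoints so segment boundaries are
sharp. An indoor target of 1 degenerates to a single home stay.

*Pollution.* Regional hourly ambient: 8 + 3·cos(2π·doy/365) +
2·cos(2π·(hour−19)/24) + AR(1) (φ = 0.8, σ = 1), floored at 0.3 µg/m³ —
winter and evening maxima with a closed deterministic form when the noise
is off. Amplitudes were chosen once to put cohort means and winter levels
in the single-digit-to-low-teens µg/m³ range typical of the US Pacific
Northwest. Indoors the truth is infiltration (0.6) × ambient plus a
dinnertime cooking peak (Gaussian in local time around 19:00, sd 45 min,
lognormal amplitude with median 20 µg/m³, on 80% of home-days) and a
constant 3 µg/m³ heating boost in December–February; the magnitudes of the
indoor sources are free configuration, not calibrated to any cohort, since
no distributional parameters are published for them. Vehicles behave like
other non-residential indoor spaces (infiltration only). Stations report
the ambient truth without error, so calibration error is attributable to
the sensor model alone.

*Sensor and GPS.* The raw sensor reports (truth − intercept)/slope times
mean-one multiplicative lognormal noise (σ = 0.05 — small enough that
errors-in-x attenuation of the recovery fit is below half a percent),
floored at zero; defaults slope 0.5, intercept 2 µg/m³. Count channels
derive from raw mass by fixed decreasing per-bin factors, so bins are
monotone by construction. GPS fixes add isotropic N(0, 10² m²) noise and
are dropped with probability 0.02 per minute; pollution channels are never
dropped by the generator, so emitted records always number
participants × days × 1440.

*Known-coefficient cohorts.* For estimator calibration the package also
draws design rows directly from the linear mixed model the fitter assumes
(`simulate_design`), with named true coefficients (defaults: indoor +0.5,
winter +0.45, evening hour bin +2.6, background slope 0.279, interaction
−0.168), a participant random intercept (sd 1) and residual sd 2 — the 1:4
variance ratio that makes the true ICC 0.20. Participant-level categories
are assigned by proportional composition (every level appears), which
avoids aliasing at small n without changing the marginal mix. The 20-seed
coverage study uses 40 participants × 3 days thinned to 5-min rows with the
hour factor collapsed to six 4-h bins — sizes chosen to keep the study
under a minute while leaving hundreds of residual degrees of freedom per
effect.

## What the synthetic validation does not show

The generator's world is deliberately simple: rectangular parcels, straight
constant-speed trips, a spatially flat regional ambient field, no
meteorology or wildfire episodes, no twin-pair behavioural correlation, and
station series without instrument error. Passing the recovery suites
therefore demonstrates that the algorithms are implemented correctly and
are well-calibrated under their stated assumptions — not that a real
cohort's context labels would be 99% accurate (urban canyons, indoor GPS
loss, and irregular buildings will do worse), nor that real in-situ
calibration achieves any particular R². Numbers like the indoor dose share
measured on synthetic runs reflect the configured behaviour targets, not an
empirical finding about any population.

## Numerical notes and limitations

- Near-tie nearest-polygon assignment uses a 1 µm tolerance with
  smallest-id tie-break in both the generator and the pipeline, so labels
  are reproducible across coordinate round trips.
- The profile-CI engine bounds log λ in [−16, 12] and checks the λ = 0
  boundary explicitly; a boundary optimum reports the OLS-equivalent fit.
- The λ optimisation and deviance inversion tolerances (1e-8 on log λ,
  1e-6·SE on the root) are far below the statistical noise floor of any
  quantity reported.
- `hour` accepts either 24 hourly levels or labelled bins ("16-19"); bins
  are ordered by starting hour.
- Exposure minutes whose hour lacks an IDW background value (no in-radius
  station) are excluded from the model rows and counted.
- The pipeline's inference stage refits without demographics when a small
  cohort leaves participant-level covariates aliased; `fit_model` itself
  raises with the aliased column names, as a library call should.
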