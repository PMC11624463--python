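# Methods

`gpsmobility` implements a GPS digital-phenotyping analysis for month-long
smartphone monitoring studies: raw location streams are segmented into
flights and pauses, missing stretches are imputed, thirteen interpretable
daily mobility features are extracted, collapsed into monthly means and
day-to-day intraindividual variability (iSD), and reduced to a single
relative mobility-pattern score (MDS1) via Gaussian-mixture density
distances and classical multidimensional scaling.  A synthetic-cohort
generator with known ground truth stands in for participant data, which
studies of this kind cannot share.

## Trajectory model and segmentation

A raw stream is a time-ordered sequence of fixes (timestamp, latitude,
longitude, altitude, accuracy).  Fixes with reported accuracy worse than
100 m are discarded (configurable).  Coordinates are projected to planar
meters with an equirectangular projection about a participant-level anchor;
at city scale (< 50 km) planar distances agree with the spherical
(haversine, R = 6,371,000 m) distance to well under 0.5%.

Segmentation assumes movement alternates between *pauses* (stationary
within a small radius) and *flights* (approximately linear movement);
curvature is represented by chains of flights.  The algorithm:

- **Pauses** — greedy scan: an interval grows while each next fix stays
  within `pause_radius` (default 10 m) of the running centroid; intervals
  lasting at least `min_pause_duration` (default 300 s) become pauses,
  positioned at their centroid.
- **Flights** — the fix path between consecutive pauses (endpoints snapped
  to the pause centroids), merged while intermediate fixes deviate less
  than `collinear_tol` (default 10 m) from the chord.
- **Gaps** — fixes more than `max_fix_gap` (default 300 s) apart never form
  a segment; the interval becomes missing data.

The defaults assume GPS jitter of a few meters; a pause radius of 10 m
tolerates noise up to roughly 3–4 m SD before long stationary periods begin
to fragment (fragmentation adds only small spurious flights).  Days are cut
at local midnight of a single configured study timezone.  The
implementation uses a fixed UTC offset for the whole study, so a
daylight-saving transition mid-study would shift subsequent day boundaries
by an hour — a known limitation.

**Missing minutes** are counted pre-imputation on a per-day minute grid: a
minute counts as observed when a fix falls in it or when it is bridged by
two fixes at most `max_fix_gap` apart.  Each edge of a missing interval can
therefore lose up to one minute to grid rounding; the tiling identity
(observed seconds + 60·missing minutes = 86,400) holds to that resolution.

## Gap imputation

Missing intervals are filled by hot-deck resampling of the participant's
own observed trajectory, a deliberately simple single-imputation stand-in
for full multiple-imputation approaches.  For each gap, candidate donor
windows are the same clock window on other days, allowed to shift by 0,
±30, ±60 or ±120 minutes and required to be fully observed; a donor is
sampled with Gaussian kernel weights on the clock shift (SD 2 h).  The
donor's minute-resolution path is translated to start at the last observed
position and linearly sheared to end at the next observed position, so
imputed trajectories are anchored to the surrounding evidence; the filled
path is then re-segmented into flights and pauses and flagged `imputed`.
When no donor window exists anywhere (e.g. a gap pattern shared by every
day), the gap is filled stationary at the last known location and a warning
is raised.  Observed segments and the pre-imputation missing-minute count
are never modified.  A repetitions option refits features over several
imputation draws and averages them.

The donor requirement is per-window rather than per-day on purpose: at the
~29% daily missingness typical of smartphone GPS, essentially no day is
ever *fully* observed, so a whole-day donor rule would never fire.

## Daily features

Thirteen features per participant-day, computed on post-imputation
segments:

| feature | definition |
|---|---|
| distance_traveled (m) | sum of flight lengths |
| radius_of_gyration (m) | duration-weighted mean distance of segment positions (pauses at centroid, flights at midpoint) from the day's duration-weighted centroid |
| max_diameter (m) | largest pairwise distance between the day's pause locations |
| max_distance_home (m) | farthest pause from home; 0 when every pause is within the 200 m home radius |
| avg_flight_length (m), avg_flight_duration (s) | means over the day's flights (0 when there are none) |
| home_time (min) | pause minutes within 200 m of home |
| probability_paused | pause seconds / (pause + flight seconds) |
| circadian_routine | fraction of 30-min clock bins in which the participant is within 200 m of their position at the same time on other days (mean over bins of the per-bin fraction of comparable days); 0 = never, 1 = identical days |
| weekend_circadian_routine | same, comparing weekends only with weekends and weekdays with weekdays |
| sig_location_entropy (nats) | −Σ pᵢ ln pᵢ over the day's pause-time shares at significant locations |
| sig_locations_visited | number of significant locations with nonzero share |
| minutes_missing (min) | pre-imputation missing minutes |

**Significant locations** are duration-weighted K-means clusters of all
pauses of ≥ 10 min across the study.  The cluster count is not fixed:
fitting starts from `k_max` (default 10, capped at the number of distinct
pause positions, seeded k-means++ with 25 restarts), and any two centers
closer than 400 m are merged duration-weighted and the solution
re-converged, keeping the maximal number of well-separated locations.
**Home** is the significant location accumulating the most pause time in
the nightly 21:00–06:00 windows (ties: larger total time, then lowest
label).

The circadian-routine bin width (30 min) and the natural-log entropy base
are package choices; both are configurable and recorded here because the
feature values depend on them.

## Monthly summaries and transforms

Per participant and feature, the monthly mean and the day-to-day iSD
(sample SD, n−1) are computed over non-excluded, non-missing days; iSD is
undefined below two usable days.  Days listed as travel or otherwise
excluded contribute to nothing downstream.  Across the cohort, any summary
column with |sample skewness| > 2 is log(x+c) transformed (c = 1 for
minute/meter counts), after the iSD computation, and the per-column
decision and constant are recorded in the output metadata.  The transform
is decided per variable across participants, not per participant.

## Mobility composite (MDS1)

Each participant's usable daily feature vectors (12 features by default —
all but `minutes_missing`, which reflects the sensor, not mobility; the
strict all-13 variant is available) are z-standardized with cohort-level
mean/SD and modeled as a k = 3 Gaussian mixture (full covariances, EM with
10 seeded restarts, tolerance 1e-8; k is reduced to ⌊days/3⌋ with a warning
for short records).  Pairwise dissimilarity is the L2 distance between
mixture densities, evaluated in closed form via the Gaussian product
integral

    D²(f,g) = ⟨f,f⟩ + ⟨g,g⟩ − 2⟨f,g⟩,
    ⟨f,g⟩ = Σₐ Σ_b wₐ v_b N(μₐ − ν_b; 0, Σₐ + Λ_b),

and classical (Torgerson) MDS of the squared-distance matrix yields the
one-dimensional score MDS1 (top eigenpair of the double-centered matrix;
negative eigenvalues, which a non-Euclidean configuration can produce, are
logged and ignored).  MDS1 is defined up to sign; the package fixes the
global sign by nonnegative correlation with mean daily distance traveled,
and downstream correlations should be read through |r|.

Numerical choice worth flagging: the per-fit covariance ridge default is
1e-6, but the cohort composite uses 1e-2 (a floor of 0.1 cohort-SD per
standardized feature dimension).  With a near-zero floor, a participant
whose value of even one feature never varies (common for count-valued
features such as locations visited) contributes a near-delta density whose
12-dimensional L2 norm is astronomically large, and the embedding degrades
into an indicator of degeneracy rather than of mobility-pattern
similarity.  The 0.1-SD floor represents the day-to-day measurement
granularity of the features.

## Validation statistics

Feature-validator associations are Pearson or Spearman correlations with
pairwise deletion and two-tailed p-values.  |r| > 0.3 is flagged
"meaningful" (a moderate effect under small-sample conventions,
irrespective of significance); a second flag marks p below the
Bonferroni-corrected threshold α/m for the 13-feature family
(.05/13 = .0038; a 17-test family gives .0029).  One-way ANOVA reports the
classical F unless a Levene pre-test (p < .05) indicates unequal variances,
in which case the Welch F with Satterthwaite degrees of freedom is used
(the trigger is recorded per result); η² always comes from the classical
SS_between/SS_total decomposition, and pairwise Welch t tests with
Bonferroni-adjusted p complete the result.  Contingency tables use the
Pearson chi-square without continuity correction.

## Missing-data monitoring

The alert detector replicates the collection-time rule: a participant-day
is "missing" when all 1440 minutes are missing (the per-day minute
threshold is configurable), and an alert fires for each maximal run of
consecutive missing days strictly longer than 3 days, triggered on the
first day the run exceeds the threshold.  Whether the original rule counted
consecutive or cumulative days is ambiguous; consecutive is the default and
a cumulative option is provided.

## Synthetic cohort generator

The generator emulates the data-generating process the analysis assumes,
with recoverable ground truth:

- **Places.** Each participant has a home (≈800 m SD scatter around the
  configured city anchor) and 3–6 significant locations 0.8–8 km away,
  pairwise ≥ 500 m apart, with Dirichlet visit weights.
- **Schedules.** Days run midnight-to-midnight in one timezone; the
  participant is home all of 21:00–06:00 every day.  Outings (travel to a
  location at 8 m/s — a walking/driving mix — a stay of 30–150 min, travel
  back) fall in an 08:00–20:30 window.  Outing counts are gamma-Poisson:
  participant-level rate = configured rate × mean-one lognormal (σ = 0.4)
  and day-level overdispersion from a participant-specific gamma mixing
  factor, giving separable mobility *level* and *day-to-day variability*.
  Outing blocks are placed in non-overlapping slots (Dirichlet spacings) so
  the realized outing count matches the configured rate.
- **Sensor model.** Fixes at a configurable period (default 60 s; the
  hardware ceiling of 1 Hz is not a realistic duty cycle) with isotropic
  Gaussian noise (default 3 m, within the 10 m pause radius of the
  segmentation defaults).  Missingness mixes one long "phone off" block
  (40–70% of the day's budget) and 6–15 min short dropouts per day,
  calibrated to a target fraction (default 0.29 of each day) with ±2
  percentage points of day-to-day variation.
- **Validators.** Baseline scores (cognitive, depression, function,
  life-space, community-participation, gait) are linear in the z-scores of
  each participant's planted mobility level (mean daily scheduled travel
  distance) and planted IIV (day-to-day SD of the same), plus Gaussian
  noise.  Default coefficients plant the hypothesized signs — more activity
  and diversity with better cognition/function/life space and less
  depression; `null_effects()` zeroes every slope for type-I-error studies.

What the generator does **not** emulate: indoor/urban-canyon noise
inflation, accuracy-correlated missingness, multi-day trips, shared
devices, accelerometer or app-use streams, or seasonal modulation beyond
what the outing process produces.  Passing recovery tests on this cohort
shows the pipeline recovers the structure this process plants — not that
real GPS data meet these assumptions.

## Problem sizes used by the test suite

Statistical recovery tests use 200-participant replicate cohorts at
reduced size — 14 study days and 120 s sampling — with all other
conditions at their defaults; ten replicates each for sign recovery
(every replicate must recover all four planted signs at p < .05) and for
the null family-wise error check (at most 8 of 70 validator families with
any rejection at the .0038 threshold, the upper 99% binomial envelope of a
5% family-wise rate).  The end-to-end check runs 50 participants × 28 days
at full defaults.  Oracle tests (feature brute-force, L2 quadrature, MDS
double-centering) run on hand-built traces and random low-dimensional
mixtures.

## Known limitations

- The imputation scheme is a simplified hot-deck, not the published
  multiple-imputation machinery it stands in for; distance-type features on
  heavily missing days inherit donor-day variability.
- Circadian routine is computed per day against all other (comparable)
  days, treating the feature as daily, and on post-imputation traces.
- minutes-missing accounting is minute-grid based (±1 min per gap edge).
- The composite's scale depends on the covariance floor; MDS1 values are
  comparable within a cohort run, not across runs.
- Welch ANOVA is triggered by a pre-test rather than applied
  unconditionally; both the trigger and the flag are recorded.
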