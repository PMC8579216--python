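# Methods

## Data model and time handling

Each participant contributes four raw event streams over a 14-day study
window: GPS fixes, call events, screen on/off events, and ambient-light
samples, all as comma-delimited text with ISO-8601 timestamps. Timestamps
are stored as UTC instants; every feature window is computed on the
participant's local wall clock, carried as a per-participant timezone (a
fixed UTC offset such as `-04:00`, or an IANA name). A "day" is the
half-open local interval [00:00, 24:00). The synthetic cohort uses fixed
offsets, which avoids daylight-saving ambiguity; for real IANA zones,
durations are measured in wall-clock time, so the two annual transition
nights are mis-measured by up to one hour — a deliberate simplification.

Retention follows the enrollment ledger: a participant is analyzed iff
enrolled, not withdrawn, with ≥14 days of data and the required sensors.
Exclusions are attributed to exactly one reason in the fixed order
withdrawal → insufficient days → missing sensors, so the flow always
reconciles (enrolled = retained + Σ exclusions).

## Mobility features

GPS sampling is displacement-triggered: the device emits a fix only when
it has moved more than 20 m (Haversine, spherical Earth of radius
6,371,000 m) from the previously emitted fix. Two consequences drive the
feature definitions:

- **Dwell attribution.** No new fix means no movement, so the interval
  between consecutive fixes belongs to the *earlier* fix's location, and
  the last fix of a day carries forward to local midnight. Hours with no
  fixes but a prior fix that day therefore inherit the carried-forward
  location and classify as stationary; hours before the first fix of a
  day are unobserved (`no_data`) and excluded from the day's denominator.
- **Location clusters.** Fixes are grouped by a greedy first-fit sweep in
  time order: a fix joins the first existing cluster (creation order)
  whose centroid lies within 150 m, else founds a new cluster. Centroids
  are running means, so they can drift along a travel path; tests assert
  membership within twice the radius. Ties break to the first qualifying
  cluster.

Per-day features: distance = Σ Haversine steps between retained
(post-filter) fixes, in km to match the study's reported magnitudes;
normalized entropy of the dwell-share vector with natural logs (the base
cancels in the ratio; asserted by test); and the hourly budget, counting
clusters with ≥2 min of within-hour dwell (intervals clipped at hour
boundaries): 1 → stationary, 2–9 → moving, ≥10 → transportation. A count
of exactly 10 goes to transportation so the partition is contiguous.
"Time moving" aggregates moving + transportation hours. Days with zero
fixes yield missing mobility cells and drop out of participant averages.

## Usage features

Screen on/off events are paired into sessions after deterministic
repairs, each counted and logged: consecutive same-state events keep the
first; an `off` with no open session is dropped; a trailing `on` closes at
the next local midnight. Sessions straddling midnight split at the
boundary; the minutes split across days while the unlock is credited to
the day the screen came on. Screen time is the summed session duration
(an event-count difference cannot yield minutes).

A call is *connected* when incoming or outgoing with positive duration;
incoming/outgoing counts include connected calls only, so
connected = incoming + outgoing by construction; missed calls are counted
separately and contribute no duration.

Ambient light logs changes, so samples hold their value until the next
sample (zero-order hold). Night features integrate the held value over
the local 11 PM–7 AM window (attributed to the date containing 11 PM):
time-weighted mean lux, plus minutes strictly below 10 lux (darkness) and
strictly above 1,000 lux (bright light); both thresholds are
configurable, since no standard ranges exist. Nights with no observable
value (no sample in or before the window) are missing.

## Instrument scoring

SCARED (33 items, 0–2) and ASRS (18 items, 0–4) are plain sums; CES-DC
(20 items, 0–3) reverse-scores the four positively worded items (4, 8,
12, 16; the key is overridable). Totals are missing unless ≥80% of items
are answered; missing items are imputed with the participant's mean over
answered items of that instrument. Which 8 of the original 41 SCARED
items were dropped to form the 33-item version is the caller's
responsibility; the scorer sums whatever 33-vector it is given.

## Statistical analysis

Participant-level predictors are unweighted means of each daily feature
over non-missing days. Extreme outliers are screened per sensor domain
(GPS features; call features) with Tukey far-out fences
[Q1 − 3·IQR, Q3 + 3·IQR]; a flagged participant is excluded from that
domain's analyses only.

The adjusted correlation is a partial Spearman in the standard
construction: ranks (average ranks for ties) of x, y and every numeric
covariate; categorical covariates dummy-coded (first level absorbed by
the intercept; constant columns dropped); both rank vectors residualized
on the covariate design by least squares; Pearson correlation of the
residuals tested against a t distribution on n − 2 − k degrees of
freedom (k = non-intercept columns). Covariates are age, sex, maternal
education (the "missing" category kept as its own level), operating
system, assessment month, and — operationalizing comorbidity adjustment —
the other two instruments' totals. Unadjusted Spearman coefficients are
reported alongside, and Benjamini–Hochberg q-values are emitted next to
raw p-values.

The nested model comparison fits OLS with covariates only versus
covariates plus sensor features on listwise-complete cases and reports
the RSS-reduction F statistic. The linear-model predictor set drops two
features that are exact linear combinations of the rest under the adopted
definitions (connected calls; moving hours under full coverage), leaving
nine; the correlation analyses keep all eleven. Discriminant validity
correlates the full model's fitted (predicted) scores for one instrument
with the observed totals of the others, Spearman, on the same cases.

## Synthetic cohort generator

The generator emulates the study conditions: ~161 enrolled youths; age
drawn from a normal with SD 2.76 clipped to the eligibility range [10, 21]
(the sampling mean is pre-shifted by +0.224 so the post-clipping mean is
18.0); sex, OS and maternal education at the published proportions;
assessment months spread over February–July 2020; retention categories
drawn once per participant at rates 11/161 (withdraw), 25/161 (<14 days),
3/161 (missing sensors).

Latent anxiety and depression are standard bivariate normal with
correlation 0.5; ADHD is independent. Planted couplings act log-linearly
on generating rates at a standardized magnitude of 0.3 (the scale of the
weak-to-moderate rank correlations such designs report): trip rate
increases with anxiety and decreases with depression (driving distance
up/down and sedentary hours down/up); outgoing-call rate decreases with
depression; screen-session duration increases with anxiety; nighttime
light-event rate increases with depression. Independent log-normal
frailties (SD 0.5) on every rate keep realized between-person
correlations in the r ≈ 0.2–0.4 band rather than near-deterministic.

Trajectories are anchor-based: a home anchor, 3 secondary anchors at
0.8–2.5 km, Poisson-many round trips per day with waypoints every ~150 m
at 8 m/s, log-normal destination dwells, and an optional evening visit to
a fixed social anchor whose per-participant propensity (Beta-distributed)
is independent of the latents. Raw traces pass through the 20 m
displacement filter, so the emitted streams look like the device's.
Surveys draw a continuous target total with loading 0.85 on the relevant
latent, calibrated to the published instrument means/SDs (SCARED
33.02/14.79, CES-DC 32.59/15.23), then decompose it into items by
binomial thinning, which preserves the target in expectation.

Everything is a pure function of (seed, config); RNG streams split per
participant and per day, so growing the cohort never perturbs existing
participants. A malformation switch (off by default) injects duplicate
and unpaired screen events to exercise the repair paths.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: street-network geometry, weekday/weekend
or school-term structure, seasonal and pandemic-era behavior shifts,
measurement gaps from phones powering off, OS-specific sampling quirks,
and any within-person (day-level) symptom dynamics — couplings are
between-person only. Two features acquire *emergent* correlations with
the latents despite zero planted coupling, because they are functions of
coupled quantities: location entropy (through trip rate, damped by
independent dwell-length and evening-visit heterogeneity) and total call
duration (through outgoing-call count). The structurally null features
used for null checks are incoming calls and unlock counts.

## Numerical choices and test scale

Entropy uses the 0·ln 0 = 0 convention, returns 0 for a single cluster,
and validates Σp = 1 to 1e−9. The displacement rule is strictly greater
than 20 m; the cluster-join rule is ≤150 m to the centroid. Hour windows
and the night window are half-open. Rank ties use average ranks. Design
matrices are checked for full column rank before fitting, and singular
designs raise errors naming the collinear columns.

Statistical suites run at sizes chosen to balance power against runtime
on a single CPU: null calibration uses 2,000 replicates (n = 80, 17 noise
predictors for the F test; n = 100 with two covariates for the adjusted
correlation), and end-to-end sign recovery uses 100 seeded cohorts of 300
enrolled participants, asserting each planted direction recovered in
≥90% of seeds and |mean r| < 0.1 for the structurally null features.

## Known limitations

- Greedy first-fit clustering is order-dependent and its running-mean
  centroids drift along travel corridors; entropy values therefore depend
  on fix density during movement, and many small travel clusters deflate
  normalized entropy relative to stay-point-style clustering.
- The adjusted-correlation p-values rely on the t approximation for
  partial rank correlations; exactness holds only asymptotically.
- Wall-clock windows mis-handle daylight-saving transition nights for
  IANA timezones.
- The pipeline models between-person differences only; it is not suited
  to within-person prediction, and no causal reading of the associations
  is licensed.
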