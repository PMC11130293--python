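# Methods

This note documents the models, conventions and numerical choices behind
`migflow`, and what the synthetic validation does and does not establish.

## Data model and conventions

All artifacts are UTF-8 CSV with a header row. Dates are ISO-8601; XDR
timestamps are ISO-8601 and interpreted in a single configured study
timezone (offset-aware inputs are converted on read, and all internal
arithmetic is naive study-local time). Quarantine intervals are half-open
`[start, end)` and are merged to a canonical non-overlapping form per
comuna, which avoids double counting at boundaries. Population density is
persons per km².

Weeks are Monday-start calendar weeks, indexed contiguously from the week
containing the study start. The pre-shock reference ("baseline") week is
the *second* Monday-start week fully inside March — the week before the
usual return to school, when devices are expected to be at their primary
residence — and is exposed as an override. The November comparison uses
the four Monday-start weeks fully contained in November.

## Home detection

The weekly home antenna is the modal antenna over night-time weekday
pings; the home comuna is that antenna's comuna. Conventions the night-
tower heuristic itself does not fix, chosen once and used everywhere:

* night window 22:00–06:00 local; a ping before 06:00 is attributed to the
  previous evening, so 01:00 Saturday counts as Friday night (standard CDR
  practice: a "night" belongs to the evening that started it);
* qualifying evenings are Monday–Friday;
* ties break toward the lexicographically smallest antenna id. Ties are
  essentially measure-zero on realistic streams but common on tiny
  fixtures, and a deterministic rule keeps every run reproducible;
* a week with no qualifying ping is absent, not imputed; absence at the
  baseline week excludes the device from everything downstream.

Known limitation: published home-detection algorithms sometimes merge
nearby towers before taking the mode; we implement the bare modal-tower
rule only.

## Migration inference

A device migrated when the mode of its weekly home over the four November
weeks (computed over non-absent weeks, ties to the smallest comuna id)
lies in a different *region* than its baseline home. The comuna-level
November home is retained for OD analytics. Devices absent in all four
November weeks are excluded from both the numerator and the denominator of
emigration percentages, so attrition does not masquerade as staying.

The net migration rate is `per · (inflow − outflow) / population`,
`per = 1000` by default. Because every migrant is one comuna's outflow and
another's inflow, the country-wide sum of (inflow − outflow) is identically
zero; the pipeline asserts this closed-system invariant rather than
assuming it.

`validate_against_reference` mirrors a census-validation workflow: Pearson
correlations between recovered and reference flows at four aggregation
levels (host regions ↔ focal region, outside comunas ↔ focal region as a
whole, focal comunas ↔ rest of country, comuna ↔ comuna), separately for
emigration and immigration, only counting movements that cross the focal
region's boundary. At the finest level, pairs with zero flow in both
sources are dropped so the correlation is not inflated by structural
zeros. In tests the reference is the generator's ground truth; on real
data it would be a census table.

Scaling device counts to persons is an optional multiplier on the OD
matrix, off by default: the device-to-population mapping of any real feed
is operator-specific and should be an explicit analyst choice.

## Destination analytics

Year-over-year comparisons align two OD matrices on the union of their
keys (missing cells are zero) and compare destination *shares* per origin,
in percentage points; an origin with no emigrants in a year has undefined
shares and is reported missing rather than zero.

**z-score filter.** The difference matrix is standardized over all finite
cells (grand mean, sample SD with ddof 1) and a destination is retained
when at least one of its cells exceeds z = 1.96. The reference
distribution for the standardization is genuinely open; per-origin
standardization is available via `mode="per_origin"`, and the global mode
is the default because the filter is meant to flag cells extreme relative
to the whole year-over-year change surface.

**1-Wasserstein divergence.** Destination distributions are compared by
the exact 1-D earth mover's distance (via
`scipy.stats.wasserstein_distance`) after embedding destinations on a
ground coordinate. The metric space for comparing destination mixes is
not canonical; the default coordinate is the destination's average income
decile, consistent with sorting destination axes by income elsewhere in
the analysis, and rurality, density or any numeric comuna attribute can be
selected instead. The test suite checks the implementation against an
explicit optimal-transport linear program and the metric axioms.

**Rurality and amenity trade-offs.** `R_x` for a year is the mean
destination rural-household fraction weighted by the share of x's
emigrants choosing each destination; ΔR_x differences it against a
baseline year, and is invariant to uniform scaling of a year's counts
(shares, not volumes, matter). Weighted density works the same way. ICVU
(urban quality-of-life index) differences are weighted means of
icvu(destination) − icvu(origin); destinations outside the index's
coverage are dropped, weights renormalized, and the retained weight
fraction reported, mirroring an index that only covers urban comunas.

**Gravity ordering.** Host regions are ranked by population divided by
distance to the focal centre; the focal region (distance 0) is excluded.
Host-region impact is arrivals from the focal region as a percentage of
host population, per year and differenced.

**Decile-binned OD.** Flows are aggregated by rounded origin and
destination decile into a 10×10 matrix and normalized per origin column;
empty columns stay zero with a warning rather than producing NaN surfaces.

## Daily mobility

A movement is a transition between two *different* antennas in a device's
time-ordered stream; repeated pings at one antenna emit nothing. Internal
means both antennas share a comuna. A transition spanning midnight belongs
to the day of the second event (fixed for determinism). The daily index
per comuna is the mean number of transitions per active homed device —
devices are attributed to their *baseline* home so long-term migrants do
not contaminate another comuna's stratum mid-study (weekly attribution is
a one-line change: pass a different homes table). Normalization per active
device makes years with different device counts comparable; raw totals are
available via `normalize=False`. Published mobility indices differ in
normalization; ours is documented, not asserted as identical to any.

Reductions are `100 · (baseline_mean − day) / baseline_mean` percentage
points, positive = less movement; by construction the reduction averaged
over the baseline week is zero. Comunas with a zero baseline mean get
missing reductions with a warning. Quarantine stratification is an exact
partition of study days per comuna from the (merged) calendar.

Estimating a per-comuna mean reduction involves a ratio of two noisy
means; with very few devices per comuna the reciprocal of the baseline
mean is biased upward (Jensen), so comuna-level reductions in thinly
observed comunas are noisy and slightly biased low. Decile-level checks
therefore pool comunas of a decile weighted by active devices before
forming the ratio.

## The synthetic generator

`migflow.synth` emulates, at desk scale, the structure the estimators rely
on. One RNG seeded from `rng_seed` drives geography, device placement,
relocations and events, so every fixture is exactly reproducible.

**Geography.** One dense focal metropolitan region plus sparser host
regions; comuna income deciles cover 1–10 by construction (cyclic
assignment plus jitter); log-density is drawn per region class and
rurality is a declining function of log-density plus noise, so rurality
and density are strongly anti-correlated as in real municipal data; the
quality-of-life score exists only for urban (low-rurality) comunas.

**Devices and relocations.** Devices sit in comunas proportionally to
population. A device's emigration probability is
`migration_fraction · exp(slope · (decile − 5.5) + u_c)` with a lognormal
comuna effect `u_c` — multiplicative, so a zero base fraction means
exactly zero migrants, and the planted income gradient is log-linear
(default slope 0.15 per decile, comuna effect SD 0.25; chosen to give
visible but noisy comuna-level gradients, like survey-derived decile
effects). Destination regions are drawn with gravity weights
(population / distance from the focal centre, floored at 50 km),
destination comunas by population. Relocation weeks are uniform between
the baseline week and the last week before November, so the November mode
unambiguously reflects the destination. Within-region home moves can be
planted as confounders (`within_region_move_fraction`, default off).

**Events.** Per device-day: Poisson(8 · night_ping_rate) night pings at
the current primary home antenna, each replaced by a uniformly random
antenna with probability `noise_fraction` (tower noise); Poisson(16 ·
day_ping_rate) daytime anchor pings at the primary antenna; and
excursions. Each of the N+1 gaps of the anchor sequence independently
hosts a single-ping excursion with probability `day_excursion_rate · s /
(N+1)`, where the scale `s` is 1 before the shock date and
`1 − reduction(decile)` after it. An excursion ping sits at a different
antenna (another comuna with probability `external_excursion_fraction`,
else another antenna of the home comuna), and because excursions occupy
distinct gaps they contribute exactly two transitions each (out and
back). Hence the expected daily transition count is exactly
`2 · day_excursion_rate · s` per device — up to a truncation correction
of order P(N+1 < day_excursion_rate), negligible at the default anchor
rate — internal/external split by the excursion kernel. This is what
makes the planted mobility reduction recoverable to within sampling error
from transition counts. Default rates (0.5 pings/hour night and day,
two excursions/day) give ≈13 events per device-day, a deliberately
thinned version of a real feed's ≈48, keeping desk-scale runs tractable
without changing any estimator's logic.

**Quarantine calendars** assign each comuna, with a configurable
probability, a random 2–13-week interval inside the post-shock period.
They exercise the stratification machinery; the generator does not plant
an additional quarantine-specific mobility effect.

**What the generator does not emulate** — and therefore what passing
tests do *not* establish about real data: device sharing and churn,
multi-residence households, tower load balancing and outages,
distance-dependent daytime dispersal kernels, seasonal or weekend
mobility structure, correlated (non-Poisson) ping bursts, and any
device-to-population selection bias. Recovery results here show the
estimators are correct under the stated model, not that a real feed
satisfies that model.

## Validation scenarios and problem sizes

The acceptance suite uses a full-window (March–November) scenario with
20,000 devices, 20% night-tower noise and 0.5 night pings/hour for home
and migration recovery (the day-side stream is thinned to 0.1 anchors/hour
since relocation inference reads only weekday nights), and two
spring-window (March–May) 20,000-device scenarios for daily mobility — one
with the income-graded reduction (10% to 55% across deciles 1–10), one
null. The mobility scenarios set tower noise and migration to zero: noise
pings add an antenna-transition floor that is deliberately *not* scaled by
the planted reduction (it is measurement noise, not behaviour), so a
noisy scenario recovers an attenuated reduction by design; the clean
scenarios test the estimator against the exact planted value. The
acceptance script runs the same designs at 10,000 devices. Statistical
calibration uses 40 synthetic comuna records per draw, 1000 null draws
for the t-test size and 200 draws for slope-CI coverage.

## Numerical choices and degenerate inputs

* All tie-breaks (modal antenna, November mode) are deterministic and
  lexicographic; all randomness flows from a single integer seed; pipeline
  outputs are byte-identical across runs with the same seed, verified by
  content hash.
* Zero denominators (no observed devices, no emigrants, zero baseline
  mobility, regions without quarantine records) yield missing values with
  warnings, never silent zeros; genuinely invalid inputs (non-positive
  population, malformed intervals, unknown antennas) raise typed errors
  naming the offending column, row or id.
* Welch's unequal-variance t-test is the default rich/poor comparison
  (robust to the heteroscedasticity that comuna-level aggregates usually
  have); the pooled-variance variant is a flag. The rich stratum is the
  top 20% of the decile covariate by quantile cut — deciles 9–10 on a full
  1–10 scale — with the fraction exposed as a parameter.
* R² is reported as the square of Pearson r, exact for the simple linear
  regression used.
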