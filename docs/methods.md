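# Methods

This note records the models, estimators, conventions and design
decisions behind `triage_eval`, and what the tests do and do not
establish.

## Profiles and aggregators

An AIS profile is the multiset of a patient's three highest AIS grades,
stored canonically as a descending triplet (A, B, C), each grade an
integer 0–5.  Aggregators are weighted power sums `wA·Aᵖ + wB·Bᵖ + wC·Cᵖ`
(`p ≥ 1` integer, weights ≥ 0); any callable from profiles to reals is
accepted wherever an `AggregationSpec` is.  All combinatorial layers use
exact integer arithmetic so pair counts are bit-exact.

Enumeration excludes the uninjured profile (0,0,0): there are 55 non-zero
profiles and 1485 unordered pairs.  The achievable score domains are
computed, not tabulated: 15 values for the sum (every integer 1–15 is
achievable — published prose mentions both 13 and 15; brute force settles
it at 15), 44 for the ISS (maximum 75), 55 for the cubes (maximum 375).
The cubic aggregator is injective on the 55 profiles, which is what later
makes its plug-in mutual information with any outcome saturate.

## Discordance counting

Two profiles are discordant under aggregators f and g when the strict
orders disagree: `(f(x)−f(y))·(g(x)−g(y)) < 0`.  Ties under either
function are classified separately (the predicate is strict on both
sides).  `DiscordanceReport` carries two counts: the unordered count
(each pair once — 42 / 60 / 110 for ISS–cubes / ISS–sum / cubes–sum) and
the both-orders count (84 / 120 / 220).  The published figures (84 pairs,
"5.6%", "8%", "14.81%") are exactly the both-orders counts divided by the
1485 *unordered* pairs; no other convention fits all three printed
percentages, so the headline `fraction` follows it.  The 14.81% figure
belongs to cubes-vs-sum (the in-text re-attribution of that number to
ISS-vs-cubes elsewhere is inconsistent with the exhaustive count).

## Association estimators

*Pearson correlation* is the ordinary (optionally weighted)
product-moment coefficient; zero variance raises rather than returning 0.

*Entropy, MI, NMI* use the plug-in (maximum-likelihood) estimator on the
exact observed values treated as categories, log base 2.  MI is computed
as `H(X) − H(X|Y)`; the identity against `H(X)+H(Y)−H(X,Y)` is verified
in tests as a second code path.  On the bundled 12-row mortality table
this yields NMI = 0.523 (sum), 0.767 (ISS), 0.801 (cubes).  The published
normalised values for the same data (0.46 / 0.55 / 0.71) evidently come
from an unstated discretisation or estimator and are **not reproducible
from the stated formulas**: under any plug-in scheme the cubic column,
taking 12 distinct values, forces `MI = H(mortality)` exactly.  The
contract here is the strict ordering cubes > ISS > sum, which holds.

*Permutation test*: one column is permuted with a seeded generator and
the add-one estimate `p = (1 + #{T* ≥ T}) / (1 + B)` is reported.  Note a
degeneracy worth knowing: when the score column is injective (as cubes is
on this table), plug-in MI/NMI are invariant under *any* permutation of
the outcome, so the test is uninformative there (p = 1) — tested as a
theorem.  Small p-values for this table are demonstrated with the Pearson
statistic instead.

*Variance demonstration*: sample variance uses the n−1 denominator, which
reproduces the published 0.5 / 4.5 / 0.5 for the three two-patient
samples at consecutive ISS ranks (the population convention would give
0.25 / 2.25 / 0.25).  One transcription quirk: the printed third sample
assigns 42 to (5,3,3) and 43 to (5,4,1); the arithmetic gives 43 and 42.
The scores are swapped within the pair, leaving ranks-consecutiveness and
the variance unchanged; fixtures store the profiles and recompute.

## Axiomatic scans

A change vector [dA,dB,dC] adds signed AIS points to the components of a
profile; the result is re-sorted to canonical order before scoring (the
aggregators are multiset functions — this matches the worked examples,
e.g. (4,4,0)+[−1,0,0] scoring as (4,3,0) = 25).  Applicability bounds are
0 ≤ grade+delta ≤ 5 per component (the printed bound "−A ≥ x_A ≥ 6−A" in
the source material is empty as written; this is the only reading
consistent with every worked example).

*Compensation*: for a fixed change, profiles are split by the sign of
their score delta; every (degraded, improved) pair is an anomaly.  Linear
aggregators have profile-independent deltas, hence none.  For the ISS the
change [0,+1,−2] yields 11 degraded × 5 improved = 55 anomalous pairs
(including the worked (5,4,3)/(4,4,4) pair).  For the cubes that same
change degrades *every* applicable profile — no anomaly; the scan finds
cubes anomalies under e.g. [−1,+2,0] (29 × 10 pairs).

*Rank reversals*: an identical change sequence is applied to both
patients; every step at which the strict score order flips is recorded.
The two worked two-step scenarios each flip twice (32/33 → 25/24 → 20/21
and 32/33 → 41/38 → 42/43).

*Independence*: the scan considers quadruples (x, y, x+δ·e_k, y+δ·e_k)
where one shared component is shifted (+1 on a single component; the
shifted profiles must stay descending as written so the criterion keeps
its identity), probed with the six single-component ±1 changes; all
comparisons strict.  A violation is a change that flips the order within
exactly one of the two pairs.  Counts: 0 for the sum (provably — additive
shifts preserve score differences; confirmed exhaustively), 147 for the
ISS (including the worked (3,2,0)/(4,0,0) vs (4,2,0)/(5,0,0) instance),
201 for the cubes.  The search space is a design choice; widening the
shift or change sets finds more quadruples but the existence results are
unaffected.

## Queue simulation

Single-server queue, Poisson arrivals (λ), exponential service (rate μ),
non-preemptive: at each service completion the waiting patient with the
highest aggregate score starts service, ties broken by earliest arrival.
Each arrival's profile is three independent grade draws from a
categorical distribution over grades 1–5, sorted descending — the minimal
assumption given that only marginal grade distributions are published.
Critical patients are those with highest grade 5.  Replications use
independent `SeedSequence`-spawned streams: results are bit-reproducible
and replication-order-insensitive.

The study regime is deliberately overloaded (λ = 10, μ = 1, horizon 1000
time-units, 100 replications; one time-unit = one mean service time), so
only ~10% of arrivals are ever served and the waiting-time census
matters.  Default (`censoring="served"`): only patients entering service
before the horizon contribute, wait = service start − arrival.  The
alternative (`censoring="all"`) adds `horizon − arrival` for the
still-waiting; under it the overall mean is essentially
discipline-invariant (work conservation with identical service
distributions), so every discipline comparison in this regime rests on
the served census.

Validation: with a constant priority the discipline is FIFO and the
simulated mean wait at ρ = 0.5 matches the analytic
`W_q = λ/(μ(μ−λ)) = 1.0` within Monte-Carlo error; tests run 20–50
replications at horizon 5000 (the analytic value is a steady-state limit,
and short horizons carry a small warm-up bias).

The grade-distribution fixtures deserve caution: the printed rows sum to
93.5%–122%, so they are renormalised on load, and a "corrected"
motor-vehicle variant (4.2/20.2/49.2/13.2/13.2%, consistent with the same
cohort's main-injury distribution and summing to exactly 100) is bundled
and used by default for waiting-time reproduction.  Under these
conditions the simulation reproduces the reference pattern only in part:
sum-priority waits clearly exceed ISS-priority waits
(+2.6 ± 0.3 time-units paired), and the ISS mean wait for served patients
(38.8 ± 1.5) matches the reference 39.1; but cubes-priority comes out
*slightly worse* than ISS for this distribution (+0.53 ± 0.13 paired),
whereas the reference table has it marginally better.  For the falls and
tornado distributions the cubes advantage is large and unambiguous
(≈ 5–11 time-units), in line with the published conclusion.  No single
sampling scheme, censoring rule or tie-break reproduces the full
published waiting-time grid — unsurprising given the inconsistencies in
its input distributions — and the corresponding acceptance check is left
failing rather than tuned.

## Reproduction pipeline

`repro_all(out_dir, seed, ...)` regenerates every surface as CSV plus a
JSON manifest, logging the switches in force (distribution variant,
census, estimator).  Output is byte-identical for a fixed seed and
settings; determinism tests run a scaled-down configuration (2
replications, horizon 60–100 time-units), which exercises the identical
code paths since determinism does not depend on problem size.

## Known limitations

* The synthetic queue emulates stationary Poisson arrivals, a single
  resource and iid profiles; real trauma arrivals are time-varying and
  profiles correlate with arrival mode, so passing tests validate the
  comparison machinery, not operational waiting-time forecasts.
* Mortality rates enter as published aggregates (12 profile groups), not
  patient-level outcomes; association metrics are therefore unweighted
  unless row weights are supplied.
* Weight estimation for weighted variants (e.g. a fitted wISS) is out of
  scope; the weighted family is provided, its calibration is not.
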