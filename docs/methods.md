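# Methods

## Scope and model

perilink links two registers of birth records — a cohort register (one row
per baby, near-complete fields) and a routine hospital-episode register
(large, incomplete, partly miscoded) — by scoring candidate record pairs
on per-field agreement.  Three scorers share one comparison
representation (per field: agree / disagree / missing):

* **Fellegi–Sunter**: per-field natural-log likelihood ratios
  w_m = ln(m/u) on agreement and w_nm = ln((1−m)/(1−u)) on disagreement,
  summed over observed fields.  m and u must lie strictly inside (0, 1);
  boundary values would give infinite weights and are rejected at table
  construction rather than clamped.
* **EM**: the same score with (m, u, p) estimated from the comparison
  vectors as a two-class mixture (conditional independence of fields given
  match status; missing outcomes skipped in the likelihood product).
  E-step: per-pair match responsibility in log space; M-step: m and u as
  responsibility-weighted agreement rates over pairs where the field is
  observed, p as mean responsibility.  Stops when the largest parameter
  change falls below `tol` (default 1e-6) or after `max_iter` (default
  100) iterations.  Default initialisation m = 0.9, u = 0.1, and
  p = expected matches / pairs when supplied (0.01 otherwise).  The
  log-likelihood is non-decreasing across iterations (tested).  Inputs
  with a single comparison pattern, or fits whose mixture collapses to
  p ∈ {0, 1}, return `converged=False` with a diagnostic, and both scorers
  refuse unconverged parameters — the run yields no matches instead of
  arbitrary ones.
* **EpiLink**: per-field weights log2((1−e)/f) from a-priori error rates
  e and average value frequencies f, score = Σ wγ / Σ w over observed
  fields.  The shipped identification from an m/u table is e = 1−m,
  f = u, making the field weight log2(m/u).  Fields whose weight is not
  positive (chance collision at least as likely as true agreement) carry
  no discriminating information and are excluded from both sums; this is
  the EpiLink analogue of an m = u field contributing zero to a
  Fellegi–Sunter sum and keeps the score inside [0, 1].

### Missing comparisons

A field missing on either side contributes nothing: zero weight in the
log-ratio scorers, dropped from both EpiLink sums.  An all-missing pair
therefore scores 0 (log scorers) or is undefined and skipped with a log
entry (EpiLink).  This choice avoids punishing incompleteness as if it
were disagreement; its cost is that heavily missing pairs concentrate near
zero weight, which is exactly the sensitivity-loss mechanism the
missingness experiment demonstrates.

## Candidate pairs

Blocking on date of birth (the default) pairs each day's episode records
against the cohort; records missing the key are crossed against the whole
opposite register (`compare_all`, default) so that missing-date records
remain reachable, or dropped on request.  A no-blocking mode enumerates
the full cross product and is the oracle in equivalence tests: a pair's
score is identical under either route.  Note the structural consequence,
visible in the worked example: with exact-equality comparison, blocking on
a field with agreement probability m makes ~(1−m) of true pairs
unreachable.  Comparators are exact equality only; no string-distance
comparison is provided because the registers carry no name-like fields.

## Thresholds, review, error cells

Threshold inclusion is strict (weight > cutoff) for determinism.
Candidate sets from several runs are merged by pair, keeping per-run
weights (and each run's best weight for a pair scored twice).  Clerical
review visits candidates in descending weight (ties by identifier pair),
alternating cohort-grouped and episode-grouped rounds; a confirmed pair
removes all candidates sharing either identifier; the loop ends when a
round confirms nothing, or at `max_rounds` (flagged incomplete).  The
oracle interface returns True / False / None per pair, so a complete truth
map, a partial reviewer, or a terminal prompt all fit; bookkeeping
conserves pairs exactly (confirmed + rejected + removed + unresolved =
candidates).

Error cells take the maximum potential matches M as the cohort size by
default (configurable), and N as the full cross-pair count even when
blocking was used.  Metrics are reported to 3 dp, percentages to 1–2 dp.

## The synthetic generator

The generator reproduces the statistics linkage assumes, not the clinical
joint distribution of a real population.  Each field is an integer code
drawn from a per-field categorical distribution with one common category
plus a uniform remainder, skewed so the collision probability equals the
requested u exactly whenever the field's realistic domain allows.  Two
domains are too small for their requested u and fall back to their
uniform floor: sex (floor 0.50 vs requested 0.49) and gestational age
(floor 1/26 ≈ 0.038 vs requested 0.02, with the rendered range held to
20–45 completed weeks); attained values are reported in the generation
log's `effective_u`.  True-match episode records copy the cohort value
per field with probability m and otherwise resample from the distribution
excluding the true value, so agreement among truth pairs is exactly m.
Birth order is folded into [1, n_babies] so every record satisfies the
plurality invariant.

Missingness is injected independently per field and register (the
available completeness figures are marginal only; correlated missingness
is a known limitation).  Discordance injection gives selected records a
birth weight under 500 g together with a gestational age ≥ 35 weeks —
marginally valid, jointly implausible, the signature transcription error
of routine birth data.  Duplicates are exact row copies with fresh
identifiers, recorded in the generation log.  Vital status
(live/still/unknown, default proportions 0.716/0.246/0.038) is shared
within a truth pair so birth-count accounting across epochs can be
exercised.  Identical config + seed reproduces byte-identical output.

Defaults encode the 1995-epoch study conditions: 668 cohort records
against 486,705 episodes with full cohort overlap, the `best_guess` m/u
table, epoch-1995 missingness available as a preset, discordance rate
0.004 (the approximate share of episode records in the implausible
under-500 g-at-term region), duplicate rate 0 (duplicates only appear in
the 2006-style preset era).  What passing synthetic tests show is that
the pipeline's statistical machinery is correct under its own
assumptions; they cannot show robustness to correlated errors,
register-coverage bias, or within-day heterogeneity that real routine
data exhibit.

## Problem sizes in tests and the acceptance script

Statistical tests run scaled register pairs chosen for tight Monte-Carlo
behaviour at interactive runtimes: 5,000×5,000 for agreement-rate checks,
150×2,000 (full cross product, no blocking, full overlap) for the
missingness experiment, 20,000 vectors × 8 fields for EM recovery, and
≤ 50×50 for blocked-vs-full equivalence.  The missingness experiment
asserts direction and bounds (sensitivity < 1 at 30% missingness,
returning ≥ 0.9 at 0%), not a point value, because the sensitivity level
depends on the cut-off and field set.

## Design choices where the design was open

* Natural log for Fellegi–Sunter weights — fixed by exact agreement with
  the published per-field weight tables (e.g. ln(0.90/0.00274) = 5.794).
* Duplicate = whole-row equality; period restriction inclusive of both
  endpoints; maternal age as completed years (floor); date of death
  derived from discharge date where the discharge method indicates death.
* Ethnicity recode maps and concordance plausibility maps are
  configuration, not code.
* EM can be run globally (recommended) or per block via the pipeline's
  blocked comparison; per-block runs inherit the failure mode that an
  uninformative day converges nowhere and contributes no scores.
* Review order and tie-breaks are fixed (descending weight, then
  identifier pair) purely for reproducibility; with a consistent oracle
  the confirmed set does not depend on order.

## Known limitations

No fuzzy comparators; no 1-to-many linkage model; no frequency-adaptive
u estimation; independence of fields assumed by all three scorers and by
the generator; no inference (confidence intervals) on population-change
percentages.  The interactive review path writes no audit trail beyond
the confirmed-pairs CSV.
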