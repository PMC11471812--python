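# Methods note

This note records the model, the numerical conventions, the synthetic-data
design, and the places where the design was genuinely open — in the order
the data flows through the package.

## Secret-sharing substrate (`fedstats.ring`)

**Ring and fixed point.** Values live in `Z_{2^64}` with `f = 16`
fractional bits. The choice is pragmatic: 64-bit words give native numpy
arithmetic (`uint64` wraps modulo 2⁶⁴ for free), and a 2⁻¹⁶ ≈ 1.5·10⁻⁵
grid covers ages, months, Gy and cm³ at well beyond clinical precision.
Encoding is round-half-even; scaling by a power of two is exact in binary
floating point, so every representable grid value round-trips exactly and
off-grid values land within 2⁻¹⁷. Reduced rings (e.g. `Z_256`) are
supported so the share-distribution privacy property can be tested
exhaustively with χ² statistics.

**Adversary model.** Semi-honest, honest majority: no two of the three
compute parties collude. Correlated randomness (Beaver triples, random
ring elements with bit shares) comes from a logical *dealer* that never
sees data but must not collude with any party either. This replaces the
internal resharing protocol of the commercial three-party backends, which
is not public; the privacy and correctness properties are enforced by
tests rather than inherited from a reference.

**Multiplication and truncation.** Beaver multiplication opens only
uniformly masked differences. Fixed-point × fixed-point products are
rescaled by *exact* dealer-assisted floor truncation: the value (offset by
2⁶² so its two's-complement sign cannot interfere) is opened masked by a
dealer value `r` whose bit shares are known, and the borrow chain of
`c − r` is evaluated with one Beaver AND per ring bit, yielding both the
wrap bit and the low-bits borrow needed for `⌊·/2¹⁶⌋`. Exact truncation
(rather than probabilistic) makes every statistic reproducible bit for bit
under a fixed seed; the cost, ~65 secure ANDs per truncation, is
irrelevant at cohort scale. The same borrow-chain primitive yields the
sign bit (comparisons: `a < b` is the MSB of `a − b`, sound while
`|a − b| < 2⁶³`) and bitwise-agreement products (equality against a
public constant).

## Private tables and masks (`fedstats.table`, `fedstats.dictionary`)

CSV ingestion (comma separator, `.` decimal, header required, dates
pre-resolved to numeric months client-side) is validated against a
versioned data dictionary; categorical cells are coded to dictionary
indices, metric cells fixed-point encoded, every cell shared, and the
plaintext buffers overwritten. Row count and schema are the only public
facts about a table: the study design itself publishes per-site n, so n is
deliberately unprotected.

The shipped 44-column dictionary (20 categorical, 24 metric) is a
*reconstruction*: the study's agreed spreadsheet format is not published
column by column, so the dictionary rebuilds it from the published
patient-characteristic, therapy and outcome tables and pads with generic
clinical covariates. It is versioned (`reconstruction-1`) and replaceable.

Selection predicates are conjunctions of `column <relation> constant`
clauses only — exactly the shapes a restricted evaluation session needs;
disjunctions are out of scope. Ordering relations on categoricals are
type errors.

## Aggregate statistics and disclosure control (`fedstats.stats`)

Only aggregates are ever opened: counts (as sums of oblivious indicator
bits), the mean's aggregate sum and count (division happens publicly on
two already-safe aggregates — oblivious division would add cost without
adding protection), five-number summaries, and per-month life tables.

**Quantile convention.** `h = (n−1)p + 1` with linear interpolation (the
common statistical default). The backend convention of the original
deployment is unpublished; the package pins its convention with a
24-element conformance vector whose five-number summary
`{38.0, 62.5, 66.0, 72.25, 91.0}` must reproduce exactly, interpolating
*on shares* with public weights so exactly five values are reconstructed.
Order statistics use a bitonic sorting network (pad to a power of two with
a public sentinel, compare-and-swap = one oblivious comparison + one
Beaver multiplication per pair).

**Survival tables.** Follow-up months are floor-binned on shares
(exact truncation), and for each month the event and censoring counts are
opened as aggregate sums; the at-risk series follows publicly from the
conservation invariant `n_{m+1} = n_m − d_m − c_m`. Whether the original
study's granularity was whole months at source or floored from days is
not stated; flooring is assumed.

**SDC.** `sdc_guard` refuses any statistic over a non-empty selection
smaller than the threshold `k`. The default is `k = 0` — the
session-reproduction mode, since the printed transcript releases cells of
size 1 — with `k = 5` the recommended production value. The guard applies
to selection size, not output cell size; empty selections yield refused
"undefined" results for mean/quantile/survival.

## Federation (`fedstats.federation`, `fedstats.expression`, `fedstats.httpd`)

The gateway implements the four-call contract with role separation and
stub credentials; envelope schemas are invented (the original middleware's
schema is unpublished) and byte counts are explicitly not contractual.
The default transport is in-process; a stdlib HTTP wrapper provides the
same four endpoints for shell use. Transport security is a deployment
concern and out of scope. Logs are JSON lines of request metadata only; a
test scans that no uploaded value ever appears in a log line, and another
inspects per-node state to confirm no single node can decode any cell.

The expression language is a deterministic recursive-descent parser over
exactly the session vocabulary. One deliberate contract decision: `freq`
on a *metric* column is a type error; the month-counting idiom a session
would express as `freq` over a follow-up column is provided by the
dedicated `survival_table` statistic instead, which also derives the
at-risk series.

## Clinical layer (`fedstats.clinical`)

* **BED₁₀** in exact rational arithmetic, `D(1 + (D/n)/(α/β))`, with a
  reporting helper rounding to integer Gy.
* **Kaplan–Meier** from the aggregate table: events within a month are
  simultaneous at the month boundary; same-month censorings are processed
  after events. The step median is the smallest month with S ≤ 0.5 and is
  undefined when never reached. The restricted mean up to the largest
  observed month is provided as the convention-dependent counterpart of a
  "mean overall survival".
* **Grouped-data median.** On month-grouped tables the step median is
  quantised to whole months and, with same-month censorings fully at
  risk, biased upward by roughly half a month. `life_table_median`
  therefore implements the classical actuarial (Cutler–Ederer) estimator
  — half-weight for same-month censorings, linear interpolation inside
  the crossing month — which is unbiased on grouped data and is the
  estimator used for parameter-recovery checks. Note that at n = 2000
  with uniform-accrual censoring the *sampling* standard deviation of any
  median estimator (row-level Kaplan–Meier included) is ~0.6–0.8 months;
  recovery bands should be read with that in mind.
* **Log-rank (Mantel–Cox)** with the tie-corrected hypergeometric
  variance; cross-checked against an independent row-level implementation
  (lifelines) on expanded tables, and calibrated under the null
  (rejection rate 0.05 ± 0.02 over 1000 simulations).
* **Fisher exact**, two-sided by the sum-of-small-probabilities
  convention (delegated to scipy, which implements exactly that); the
  doubling convention is selectable but non-default.
* **Summary-statistics z and power.** "±" in published group summaries is
  read as a standard error, consistent with the accompanying 95% CIs
  (half-width / 1.96). Power is the exact two-sided normal expression
  `Φ(z − z_c) + Φ(−z − z_c)`: at zero effect it equals the nominal α, and
  for any practically relevant effect the far-tail term vanishes,
  recovering the usual one-term approximation. Two of the originally
  reported power figures (0.89 and 0.10) are not reproducible under
  either the SE or SD reading of "±" with normal-approximation formulas;
  their computation method is unstated, so they are documented as
  non-verified and not asserted anywhere.

## Synthetic cohorts (`fedstats.cohort`)

The generator emulates the published *marginals*: per-site n = 24, 60%
male, ECOG 18/22/8 of 48, laterality 24/18/6, 3fx/5fx = 21%/79% with
doses uniform on the printed ranges snapped to a 0.5 Gy grid, motion
management 39/7/2, lognormal GTV with 21 cm³ median, exponential survival
and administrative censoring from uniform accrual over a 27-month window.
The BED₁₀ column is computed from the sampled scheme via the clinical
layer, so the arithmetic identities hold row by row.

Joint structure is invented — the study publishes no correlations — so
factors are independent except the ECOG→hazard link: ECOG-2 patients run
at a hazard multiplier of 2.2 (the ratio of the published group mean
survivals), and the baseline hazard is calibrated by root finding so the
*mixture* survival crosses one half exactly at the configured 19-month
median. Ground truth (hazards, marginals, median) is retrievable per
(config, seed) for recovery tests. Same seed, same bytes.

What passing tests on these cohorts show: the pipeline's statistics are
correct and the survival machinery recovers known generating parameters.
What they cannot show: anything about real inter-column dependencies
(dose–volume, toxicity–dose), calendar-time effects, or data-entry
artifacts of real registries — and the study's own headline numbers
(median OS 19.0 months, χ² = 1.8, toxicity proportions) are functions of
the protected row-level data and are not reproduced here.

## Problem sizes and numerical choices

Tests run the oracle-equivalence battery on 100 randomized tables of up
to ~16 rows, the privacy χ² at 10⁵ samples on `Z_256`, survival recovery
at n = 2000, and the log-rank calibration at 1000 simulations — sizes
chosen so the whole suite completes in about a minute on one core while
leaving every estimate's sampling error well inside its tolerance.
Fixed-point statistics are asserted within 2⁻¹⁰ (the accumulated floor-
truncation error is ≤ 2⁻¹⁶ per multiplication); counting statistics are
asserted exactly. Comparison soundness requires plaintext magnitudes
below 2⁴⁵; the sorting sentinel sits at 2⁶¹ ring units, far above any
clinical value. Ties in the sorting network are stable by construction
(`swap` only when strictly out of order).

## Known limitations

* The dealer is trusted for correlated randomness; dealer–party collusion
  is outside the threat model (a fully dealer-free three-party protocol
  would remove this assumption at the cost of a different multiplication
  subprotocol).
* Passive security only; a malicious node can corrupt results undetected.
* SDC thresholds guard selection sizes, not inference across multiple
  overlapping queries (no query auditing or differential privacy).
* Aggregation is monthly; day-level survival conventions of the original
  analysis are unknowable from aggregates.
* The default dictionary and all joint distributions of the generator are
  labeled reconstructions, not study data.
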