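# fedstats

Privacy-friendly federated evaluation of multi-site clinical cohorts by
secure multiparty computation, at desk scale.

Multicentric studies of rare conditions — here the motivating setting is
MR-guided stereotactic radiotherapy of adrenal gland metastases, with two
sites contributing 24 patients each — need pooled statistics, but strict
privacy law often forbids sharing row-level patient tables. `fedstats`
implements the alternative: each site's cohort CSV is converted into
**additive secret shares** distributed across three simulated compute
nodes, and the only computations available are a pre-agreed vocabulary of
**aggregate statistics** (frequency tables, means, five-number summaries,
filtered subsets, concatenations, per-month survival tables), each gated
by statistical disclosure control. A downstream plaintext layer turns
those aggregates into the clinical statistics of such a study: BED₁₀,
Kaplan–Meier curves, the log-rank test, the two-sided Fisher exact test,
and summary-statistics z tests with power.

## The model

**Secret sharing.** A value *x* is fixed-point encoded as
`round(x · 2¹⁶) mod 2⁶⁴` and split into three uniform ring elements with
`s₁ + s₂ + s₃ ≡ enc(x) (mod 2⁶⁴)`. Any single share — and any single
node's entire state — is marginally uniform; security holds against
semi-honest parties as long as no two of the three nodes collude.

**Computation.** Addition, subtraction, and public scaling are local.
Products use Beaver triples `(a, b, ab)` from a trusted dealer, opening
only uniformly masked differences. Comparisons and equality tests extract
the sign/zero bit of a difference through a masked opening against a
dealer-shared random value with known bit shares, evaluated as a borrow
chain of Beaver AND gates — no comparison outcome is ever revealed. Order
statistics run on a bitonic sorting network built from these oblivious
compare-and-swaps, so a median costs `O(n log² n)` secure gates and opens
exactly the requested aggregate values. (The dealer is a deviation from a
fully peer-to-peer three-party resharing protocol: it distributes
correlated randomness but never sees data, and must not collude with a
compute party.)

**Federation.** A middleware gateway exposes exactly four calls —
request a connection (POST), request the microservice descriptor (GET),
upload data (PATCH), request a result (GET) — with uploader and researcher
roles separated. Uploads are parsed against a versioned 44-column data
dictionary (20 categorical + 24 metric columns), shared, and the plaintext
wiped; results are evaluated from a restricted R-style expression language
(`load`, `$`, `c()`, `subset(t, a == v & b == w)`, `freq`, `mean`,
`median`, `quantile`, `length`, `survival_table`). Requesting a raw column
is a policy refusal: row-level access is impossible by design.

**Clinical layer.** `BED = D (1 + (D/n)/(α/β))` with α/β = 10 Gy;
Kaplan–Meier `S(t) = Π_{m≤t} (1 − d_m/n_m)` driven directly by the
per-month life table exported from the secure layer; Mantel–Cox log-rank;
Fisher exact (sum-of-small-probabilities two-sided convention); and
`z = |m₁ − m₂| / √(se₁² + se₂²)` with exact two-sided normal power.

Because real patient data cannot ship with the package, a deterministic
synthetic-cohort generator reproduces the published *marginal* structure
(60% male, ECOG 18/22/8, 3fx/5fx = 21%/79% with the printed dose ranges,
lognormal tumor volumes, exponential survival with a 19-month target
median and censoring by uniform accrual over 27 months) with retrievable
ground truth for parameter-recovery tests.

## Worked example

```python
from fedstats.federation import Cluster, ClusterConfig, Gateway
from fedstats.cohort import CohortConfig, generate_site

gw = Gateway(Cluster(ClusterConfig(seed=42)))
munich, _ = generate_site(CohortConfig(), 7, "munich")
rome,   _ = generate_site(CohortConfig(), 8, "rome")

up = gw.request_connection({"user": "munich", "secret": "demo"})
gw.upload_data(up, munich, "munich_production")
up = gw.request_connection({"user": "rome", "secret": "demo"})
gw.upload_data(up, rome, "rome_production")

rs = gw.request_connection({"user": "analyst", "secret": "demo"})
gw.request_result(rs, 'tm <- load("DS1", "munich_production")')
gw.request_result(rs, 'tr <- load("DS1", "rome_production")')
for expr in ("length(c(tm$age, tr$age))",
             "freq(c(tm$gender, tr$gender))",
             "quantile(c(tm$age, tr$age))"):
    print(expr, "->", gw.request_result(rs, expr)["result"]["payload"])
```

prints (values are properties of the seeded synthetic cohorts):

```
length(c(tm$age, tr$age)) -> 48
freq(c(tm$gender, tr$gender)) -> {'male': 30, 'female': 18}
quantile(c(tm$age, tr$age)) -> [44.337..., 56.931..., 63.772..., 71.683..., 91.0]
```

`length` confirms the two 24-patient sites pooled to 48 without either
site seeing the other's rows; the frequency table and five-number summary
are the only values that were ever reconstructed. Evaluating
`survival_table(c(tm$follow_up, tr$follow_up), c(tm$event_death,
tr$event_death))` on the same session exports a per-month life table
(here `n₀ = 48`, events `[2, 1, 3, 2, 2, 1, ...]`); feeding it to
`fedstats.clinical.km` gives a product-limit median of 18 months and an
actuarial life-table median of 18.0 — close to the generator's true
19-month median, as expected at n = 48.

A CLI covers the same flow from a shell: `fedstats synth`,
`fedstats cluster` (stdlib HTTP transport), `fedstats upload`,
`fedstats eval '<expression>'`, and `fedstats report`.

## What is deliberately out of scope

Deployment hardening (VPN, TLS, firewalls, key activation), malicious-
security protocols, more than three compute parties, FHIR sourcing, and
any clinical headline number that would require the protected row-level
study data — the latter are covered qualitatively by parameter-recovery
tests on synthetic cohorts instead. See `docs/methods.md` for the methods
note and known limitations.
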