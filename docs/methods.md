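# Methods

## The effort-risk model

The method is descriptive, not inferential. A *consumer* is a
household on one insurance plan; the observation window is one plan
year (12 months), the standard period over which plan benefits,
provider networks and therefore a consumer's navigation problem reset.
Six effort factors are counted per household over the window:

1. **household size** — distinct members appearing on the household's
   claims (people needing care multiply the caretaker's burden);
2. **out-of-network visits** — claim lines flagged out-of-network;
3. **adjustments** — claim lines that needed reprocessing;
4. **denials** — claim lines with payment denied;
5. **calls** — phone contacts to the payer's service center;
6. **web/mobile inquiries** — web-portal plus mobile-app contacts.

A claim flagged both denied and adjusted increments both counts: a
denial and the rework it triggers are distinct effort events. Denied,
adjusted and out-of-network counts are per claim *line*; whether the
source systems would count "visits" as lines or distinct service dates
is unknowable from an extract, and claim-line counting is the declared
convention.

**Attribution.** Contact events carry no diagnosis, so effort cannot
be apportioned across a household's diagnoses. The model therefore
attributes each household's whole-year counts *in full* to every
diagnosis code on any of its claims. Per-diagnosis factor averages are
means over the households carrying the code (medians are computed
alongside, midpoint convention for even samples, but nothing downstream
consumes them — they are emitted for inspection).

**Scoring.** Expert-elicited weights assign each factor a percentage
of total effort; the six must sum to 100 and are read from
configuration, never hard-coded. The score of diagnosis *d* is
`sum_f (w_f/100) * mean_f(d)`. The score is linear and monotone in
every factor mean; scaling all means by *c* scales the score by *c*.
Totals are computed from unrounded components. Rendering rounds
half-up to two decimals (`decimal`-based; a pre-round at 10 decimals
absorbs IEEE-754 noise on exact decimal sums). When recomputing the
published reference table from its printed two-decimal averages, 23 of
25 totals reproduce exactly and two differ by 0.01 — the source
computed totals from unrounded averages, so this is the expected
input-rounding artifact, and the package's regression tests assert
precisely that structure. One printed component cell (denials of the
worked example, 25% × 7.11 = 1.7775, printed 1.77) is inconsistent
with half-up rounding in its own source and is not reproducible; the
total is.

**Scoping.** Diagnosis occurrences are counted one per code per claim
line. The retained set is the shortest descending-frequency prefix
whose cumulative occurrence share reaches the threshold (default
0.80); ties in counts break lexicographically so selection is
deterministic. Achieved coverage is reported at full precision and
generally overshoots the threshold. Selections are provably minimal
and nested across thresholds (property-tested against a prefix-scan
oracle).

**Correlations.** Pairwise Pearson correlations (rank correlation
optional) of the six factor counts across households, requiring ≥ 3
households; zero-variance factors yield flagged undefined cells. The
observation unit is the household count vector — the only unit on
which all six factors co-exist.

## Synthetic-data generator

`effortrisk.simulate` emulates one plan-year extract at desk scale:

* **Households**: sizes are `1 + Poisson(household_size_mean − 1)`
  (default mean 2.5, a plausible covered-household size).
* **Diagnoses**: each household draws `1 + Poisson(lam − 1)` codes
  (default mean 2.0) i.i.d. from a Zipf-like prevalence over the
  vocabulary (rank-r probability ∝ r^−s, default s = 1, 150 codes),
  duplicates collapsed. This reproduces the structural fact that a
  modest head of the vocabulary covers 80% of occurrences.
* **Events**: per household-code pair, one clean "encounter" claim
  line always (a diagnosis exists in data only on a claim), plus
  independent Poisson counts of out-of-network, adjusted and denied
  lines and of phone and web/mobile contacts, at per-code yearly rates.
  The default rate table spans realistic magnitudes (denials largest,
  adjustments smallest) and is a deterministic part of the
  configuration. Encounter lines are cycled over members — topped up
  with wellness lines for large households — so every member has a
  claim and members-with-claims equals household size by construction.
* **Contacts** are recorded with household only, like real data.
* An optional lognormal household frailty multiplier (mean 1, default
  off) induces cross-factor correlation for exercising the correlation
  stage; by default factors are independent given the code set,
  matching the elicited view that effort on one factor does not imply
  effort on another.

Everything is driven by one `numpy` generator seeded from the config:
identical configs yield byte-identical tables.

**Exact ground truth.** Under whole-household attribution the true
per-code mean of an event factor is
`rate_f(c) + Σ_{c'≠c} P(c' ∈ S | c ∈ S) · rate_f(c')`, where S is the
household code set. The inclusion probabilities have closed form under
the (1+Poisson)-with-dedup draw:
`P(c ∉ S) = (1−p_c)·exp(−(λ−1)p_c)` and
`P(c,c' ∉ S) = (1−p_c−p_c')·exp(−(λ−1)(p_c+p_c'))`, with
inclusion-exclusion giving the conditional. The true household-size
factor is `household_size_mean` for every code (size is drawn
independently of codes). True scores apply the same weighted sum as
the scoring stage. Parameter-recovery tests at 50,000 households
verify ≥ 95% of (code, factor) cells within 3 standard errors and
Spearman ≥ 0.95 between recovered and true scores; both hold with
margin at the defaults (the observed rates are ≈ 99.9% and ρ ≈ 0.97).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real ICD ontologies and comorbidity
structure (codes are opaque labels with independent draws),
overdispersed or zero-inflated event counts, seasonality and
enrollment churn within the year, claim cost amounts, member-level
clinical trajectories, and any causal coupling between factors. Tests
demonstrate that the *pipeline arithmetic* is correct and unbiased
under the stated model, not that the model describes any particular
payer's population.

## Numerical and design choices

* Problem sizes: recovery tests simulate 50,000 households (~900k
  claim lines, seconds on one core); oracle-equivalence tests compare
  200 random toy extracts of ≤ 50 households against nested-loop
  rescans, exactly.
* Weight validation tolerance: sum within 1e-9 of 100; scores carry
  full float precision; the total-equals-component-sum identity is
  asserted at 1e-12.
* Degenerate inputs: empty claims tables are errors for counting and
  aggregation; a header-only file reads as a valid empty collection;
  contact-only households are retained with zero members-with-claims
  and a warning; scoped codes with no claims are excluded with a
  warning; an all-zero rate configuration is valid and warns that the
  extract will contain no effort events.
* Tie-breaks: equal occurrence counts order lexicographically; equal
  totals rank lexicographically by code.
* The pipeline stages communicate only via documented text formats
  (CSV/TSV/JSON/YAML), so each stage is independently runnable,
  inspectable and replaceable; the one-shot runner is byte-identical
  to the stagewise composition.

## Limitations

* Whole-household attribution deliberately over-credits every
  diagnosis a household carries; comorbid high-utilization households
  lift the averages of every code they touch. The published method
  shares this property; the ground-truth construction accounts for it
  exactly in simulation.
* Weights are expert priors, not estimates; the package treats them as
  given configuration and offers no elicitation or calibration.
* Correlations are descriptive; no causal reading is supported.
* The coverage rule drops consumers whose only diagnoses are rare
  codes; with skewed prevalence this is a small fraction, but the rule
  is applied, not justified, here.
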