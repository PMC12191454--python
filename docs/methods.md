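# Methods

This note documents the statistical procedures, the modelling assumptions
behind the synthetic-data generator, the numerical choices, and the known
limits of what the test suite demonstrates.

## Cohort construction

A cohort is the set of spontaneous reports naming the drug of interest in
either the *suspect product names* or *suspect active ingredients* column.
Term matching is exact after case-folding, whitespace collapsing, and an
explicit synonym map (default: the brand name "precedex" and the salt form
"dexmedetomidine hydrochloride" map to "dexmedetomidine").  Fuzzy matching
is deliberately excluded: every inclusion decision must be reproducible
from the synonym table alone.

Deduplication applies two rules, in order:

1. **Literature reports removed.**  Reports whose origin field matches a
   configurable pattern set (default: contains "literature") are dropped
   wholesale.  Publication-derived reports can duplicate the same
   patient-event pair many times under distinct case IDs, inflating joint
   counts and thus every downstream statistic.
2. **Duplicate case IDs collapsed.**  Among direct reports sharing a case
   ID, the latest received date wins; ties (including missing dates) keep
   the first in input order.  This is standard spontaneous-report hygiene;
   it is a no-op on exports that are already one-row-per-case.

Both rules are idempotent and commute with cohort filtering
(property-tested).  Demographics are parsed and carried but no analysis
stratifies on them.

## Rule mining

Each report becomes an itemset of its adverse-event terms and/or its
co-reported suspect drugs.  The cohort drug itself is excluded from
transactions: it is present in 100% of the cohort by construction, so as an
item it would enter every frequent itemset while carrying no information.

Rules are anchored on a fixed consequent (the index event).  Support,
confidence, coverage, and lift are exact rational counts evaluated in
floating point; full precision is kept on the rule objects and display
rounding (support/coverage 4 dp, confidence/lift 3 dp) happens only in
`summary()`.  Antecedents are enumerated level-wise; because the joint
count with the fixed consequent is anti-monotone in the antecedent, the
minimum-count threshold prunes exactly, and the output provably equals
exhaustive subset enumeration (oracle-equivalence test on small
vocabularies).  Antecedents default to single items — multi-item
antecedents are supported via `max_antecedent_size` but single-item rules
are what the 2×2 validation consumes.

Drug–drug interaction screening is the same machinery with drug-kind
antecedents inside the cohort: the third partner of every screened
"interaction" (the cohort drug) is implicit.

Ties in ranked output break deterministically: lift descending, then joint
count descending, then antecedent label; the top-event ranking breaks count
ties lexicographically.

## Exact 2×2 validation

A lift threshold is an arbitrary cutoff with no error control, so screened
rules are validated on their 2×2 contingency tables.  Conditioning on all
margins, n₁₁ follows Fisher's noncentral hypergeometric distribution with
parameter ψ (the odds ratio).  The point estimate is the conditional MLE,
found as the root of E_ψ[n₁₁] − n₁₁ on the log-ψ scale (the conditional
mean is strictly increasing in ψ, so the root is unique).  The exact
central CI solves P_ψ(X ≥ n₁₁) = α/2 (lower) and P_ψ(X ≤ n₁₁) = α/2
(upper).  Defaults: α = 0.05, two-sided.

Numerical choices: roots are bracketed on log ψ ∈ [−40, 40] and solved by
Brent's method at 1e−8 relative tolerance — far tighter than the 2-dp
reporting scale, pinned for cross-platform determinism.  Boundary tables
(n₁₁ at the edge of its conditional support) return 0 or +∞ estimates with
the appropriate one-sided interval; a degenerate margin returns NaN; no
continuity correction is used anywhere, as the exact framework needs none.
The sample (cross-product) odds ratio is always reported alongside the
conditional MLE for transparency; the two agree within 1% once all cells
reach ~20 (property-tested).

No multiplicity adjustment is applied to the validation by default — the
reported significance criterion is per-rule CI-excludes-1.  A BH adjustment
(`pvsignal.disproportionality.bh_adjust`) is available for users who want
family-wise FDR control over a screened rule set.

## Over-representation analysis

Fold enrichment FE = (k/n)/(K/N) with K counted after intersecting each
gene set with the background; p-values are upper hypergeometric tails
computed via `logsf` to avoid underflow at large N; the BH adjustment is
the step-up estimator with a running minimum, computed over exactly the
sets with non-zero overlap (sets the list cannot hit contribute no test).
The background defaults to the union of the collection's genes — a
conservative stand-in; supplying the assayed universe is always preferable
and changes both FE and the tails.  Upstream differential-expression
testing is out of scope: the module consumes a finished symbol list, and
symbols are plain case-insensitive strings with no ortholog mapping.

## Synthetic data: what it emulates and what it does not

The generator's role is to produce report databases whose *margins* are
known exactly, so every pipeline statistic has a hand-checkable value.

**Exact-marginal mode.**  The index event occupies a uniformly chosen set
of `consequent_count` report slots.  Each configured pair places its
`joint_count` among the index slots and its remaining antecedent count
among the others, so the realized 2×2 table against the index event is
exact by construction.  Pairs are packed independently — since each pair
involves a distinct item, their mutual overlaps cannot perturb any pair's
own table — which is what makes paper-scale specs satisfiable without
integer programming.  Feasibility (joint ≤ consequent marginal,
antecedent-only ≤ non-consequent slots) is checked up front and violations
name the offending pair.

**Stochastic mode.**  The index event is Bernoulli per report; each pair's
antecedent is drawn conditionally on the index event at the rates the
configured 2×2 implies, so mined lift converges to the configured target
(seeded regression at N = 500 and 5000; per-replicate sd of mined lift at
the N = 5000 condition is ≈ 0.28).

The bundled spec (`pvsignal/data/table4_table6.json`) encodes a
1611-report cohort with a 209-count index event, sixteen configured pairs
spanning realistic co-event and co-drug margins, four independent
background noise items, and 1050 literature-sourced duplicates for the
deduplication stage.  With the shipped seed one noise item happens to pass
the lift screen and is then flagged not-significant by the exact
validation — a faithful illustration of why the screen alone over-calls.
Reports lacking any adverse event receive a filler term so every report is
valid; the filler never co-occurs with the index event and cannot enter any
rule.

What the generator does **not** emulate: reporting biases, secular trends,
demographic structure, correlated multi-event syndromes beyond the
configured pairs, or free-text messiness in term fields.  Passing tests
therefore demonstrate the *arithmetic* of the pipeline on cohorts with
known margins, not robustness to real-world reporting artifacts.

## Scale choices

All worked examples run at the natural desk scale of the method
(N ≈ 1.6k reports, 13k-gene background), where the full pipeline completes
in seconds.  The CI-coverage simulation uses 200–250 tables at N ≈ 200–240
per table, putting the binomial sampling error of the empirical coverage
near 1.5 percentage points; the assertion allows three standard errors.

## Known limitations

- Exact CI inversion follows the textbook definition; tools that invert
  with loose root tolerances can differ in the third significant figure of
  interval endpoints (point estimates are unaffected).
- The conditional MLE is undefined (NaN) when a margin is degenerate; the
  caller must handle that case when feeding hand-built tables.
- Mining enumerates antecedents only; multi-item *consequents* are not
  supported.
- The exact-marginal generator guarantees pairwise tables against the
  consequent, not three-way joint distributions among antecedents.
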