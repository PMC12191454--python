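# pvsignal

Pharmacovigilance signal mining for spontaneous adverse-event report
cohorts, built around the drug-safety question: *within the reports naming a
given suspect drug, which other adverse events and which co-administered
drugs travel with an index adverse event more often than chance?*

The package was written for analyses of dashboard-style exports from
spontaneous reporting systems (one row per case: suspect products, suspect
active ingredients, reaction terms, report origin, demographics, dates,
outcomes, indications).  The worked examples use a sedative cohort
(dexmedetomidine) with bradycardia as the index event, but every term and
threshold is configurable.

## What it computes

**Association rules.** Each deduplicated report is an itemset; for a rule
{X} → {Y} over N reports,

    support    = n(X ∪ Y) / N
    coverage   = n(X) / N
    confidence = n(X ∪ Y) / n(X)
    lift       = support / (coverage · support(Y))

Lift is 1 under independence and symmetric in X and Y.  Mining is
consequent-anchored and Apriori-pruned on the joint count with the index
event; the default screen keeps rules with lift ≥ 1.5 and joint count ≥ 10.

**Exact disproportionality validation.** Lift has no sampling distribution,
so each screened rule is re-tested on its 2×2 table (with/without the index
event × with/without the candidate item).  The estimator is the conditional
maximum-likelihood odds ratio ψ̂ — with all margins fixed, n₁₁ follows
Fisher's noncentral hypergeometric law, and ψ̂ solves E_ψ[n₁₁] = n₁₁ — with
the exact central 95% CI obtained by inverting the conditional tail
probabilities (the estimator and interval of R's `fisher.test`).  A rule is
a signal when its CI excludes 1.

**Gene-set over-representation.** For a gene list of size n against a
background of N genes, a pathway of size K with k list genes scores fold
enrichment FE = (k/n)/(K/N), an upper hypergeometric tail p-value
P(X ≥ k), and a Benjamini–Hochberg FDR over all tested sets.

**Synthetic cohorts.** `pvsignal.simulate` generates report databases with
known structure, including an exact-marginal mode in which every configured
pair realizes its 2×2 table against the index event *exactly*, so every
statistic above has a deterministic desk-scale example.

## Worked example

```python
from pvsignal import CohortSignalModel, deduplicate, generate_exact, load_bundled_spec

spec = load_bundled_spec()            # 1611-report cohort, 209 index events,
cohort, removed = deduplicate(generate_exact(spec))   # + 1050 literature dupes
print(removed)                        # {'literature': 1050, 'duplicate_case_id': 0}

model = CohortSignalModel(cohort, cohort_drug="dexmedetomidine",
                          consequent_ade="bradycardia")
results = model.fit(min_lift=1.5, min_count=10, alpha=0.05)
print(results.ade_rules.summary().head(3).to_string(index=False))
```

```
           antecedent  consequent  support  confidence  coverage  lift  count
              syncope bradycardia   0.0068       0.611    0.0112 4.711     11
loss of consciousness bradycardia   0.0087       0.519    0.0168 3.997     14
       cardiac arrest bradycardia   0.0273       0.370    0.0739 2.850     44
```

Syncope is reported together with bradycardia 4.7 times more often than
independence predicts (11 joint reports, confidence 0.611: 61% of syncope
reports also report bradycardia).  The validation stage then confirms which
screened rules survive exact inference:

```python
from pvsignal.disproportionality import validation_summary
print(validation_summary(results.ade_validation).head(2).to_string(index=False))
```

```
                 item  odds_ratio  ci_lower  ci_upper  sample_or  significant
              syncope       11.04      3.86     34.01      11.07         True
loss of consciousness        7.65      3.28     17.98       7.67         True
```

In the bundled cohort six of nine screened co-events and four of the
screened co-drugs are significant; the rest (for example respiratory
arrest, OR 1.76, CI 0.91–3.22) illustrate why a lift screen alone
over-calls signals.

The same stages are available from a shell:

```
pvsignal simulate src/pvsignal/data/table4_table6.json --out cohort.csv
pvsignal run-all --spec src/pvsignal/data/table4_table6.json --out-dir out/
```

which writes the dedup audit, top-event ranking, both rule tables, both
validation tables, and a JSON manifest of row counts and thresholds.

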