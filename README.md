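# metaconcord

**Can the best single trial stand in for a full meta-analysis?**
`metaconcord` is a toolkit for answering that question quantitatively. It
implements inverse-variance meta-analysis (fixed-effect and
DerSimonian–Laird random-effects), recovers standard errors and uniform
z-test p-values from reported confidence intervals, and measures the
*concordance* between the most precise trial in each review — the trial
contributing the greatest statistical weight — and the pooled result of
the whole meta-analysis. A calibrated simulator of review corpora makes
every stage testable with known ground truth.

It is aimed at meta-epidemiologists and systematic reviewers: people who
want to know how often, and under what circumstances, a clinician relying
on the single "largest" trial would reach the same statistical conclusion
as an entire systematic review.

## The model

Each trial *i* reports an effect (risk ratio, odds ratio, hazard ratio,
or a mean difference) with a 95% confidence interval. Ratio measures are
analysed on the log scale; differences on the natural scale. The standard
error is recovered from the interval, assuming symmetry on the analysis
scale:

    se_i = (g(u_i) − g(l_i)) / (2 · z_{0.975}),   g = ln or identity

with the exact normal quantile z₀.₉₇₅ = 1.959964 (a compatibility flag
reproduces the rounded 1.96 used by some review software). The p-value of
any effect is a two-sided z-test, p = 2·(1 − Φ(|y|/se)).

Pooling is by inverse variance. Fixed effect: wᵢ = 1/seᵢ²,
ŷ = Σwᵢyᵢ/Σwᵢ, se(ŷ) = (Σwᵢ)^(−1/2). Heterogeneity:
Q = Σwᵢ(yᵢ − ŷ)², I² = max(0, (Q − df)/Q)·100. Random effects
(DerSimonian–Laird): τ² = max(0, (Q − df)/C) with C = Σw − Σw²/Σw, then
re-weight with wᵢ* = 1/(seᵢ² + τ²).

For each review the pipeline identifies the highest-weight trial (ties →
larger n, then input order), recomputes its p-value, pools all trials
under the model the review's authors declared, and classifies the pair as
significant/non-significant at α = 0.05 (strict inequality). Corpus-level
outputs: the 2×2 agreement table with single-trial sub-counts,
conditional rates such as P(meta significant | trial not significant),
Spearman rank correlation of paired estimates, a discrepancy report for
reviews where only the trial is significant, confidence-interval
containment/overlap checks, and stratification by the top trial's weight
share.

## Worked example

The package ships a fully synthetic reference corpus engineered so that
its agreement pattern matches the one observed in a published survey of
200 Cochrane reviews (whose hand-extracted data were never deposited):

```python
from metaconcord import (
    reference_agreement_corpus, build_corpus_records,
    agreement_table, conditional_rates, discrepancy_report,
)

corpus = reference_agreement_corpus()
records = build_corpus_records(corpus)
table = agreement_table(records)
rates = conditional_rates(table)

print(f"reviews classified: {table.total}")
print(f"both significant:        {table.n11} ({table.n11_single} single-trial)")
print(f"trial significant only:  {table.n10}")
print(f"meta significant only:   {table.n01}")
print(f"neither significant:     {table.n00} ({table.n00_single} single-trial)")
print(f"P(meta sig | trial sig)    = {rates.p_meta_sig_given_trial_sig:.1%}")
print(f"P(meta sig | trial nonsig) = {rates.p_meta_sig_given_trial_nonsig:.1%}")
print(discrepancy_report(records)[["review_id", "k", "meta_p", "trial_p", "i2"]].round(4))
```

which prints:

```
reviews classified: 161
both significant:        55 (14 single-trial)
trial significant only:  5
meta significant only:   31
neither significant:     70 (15 single-trial)
P(meta sig | trial sig)    = 91.7%
P(meta sig | trial nonsig) = 30.7%
  review_id  k  meta_p  trial_p       i2
0     S0056  2  0.7068   0.0124  90.6956
1     S0057  2  0.7001   0.0098  91.3056
2     S0058  2  0.6934   0.0077  91.8574
3     S0059  2  0.6867   0.0060  92.3584
4     S0060  2  0.6801   0.0046  92.8145
```

Read: when the most precise trial is significant, the meta-analysis
almost always agrees (92%); when it is not, the meta-analysis still finds
an effect in roughly a third of reviews — single trials are often
underpowered. The five discordant reviews all show substantial
heterogeneity (I² > 90% here), which is exactly the situation in which a
single trial can mislead.

## Command line

```bash
metaconcord simulate --seed 7 --n-reviews 500 --out-dir corpus/
metaconcord concord corpus/trials.csv --out-dir reports/
metaconcord pool corpus/trials.csv --out pooled.csv
metaconcord summary corpus/trials.csv --out summary.csv
```

`concord` writes the agreement table and conditional rates
(`agreement.json`), the discrepancy report (`discrepancies.csv`) and
scatter-ready CSVs of paired estimates and p-values. The trials CSV
schema is documented in `metaconcord.io`.

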