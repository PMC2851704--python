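# Methods

This note records the statistical model, the calibration of the synthetic
corpus generator, and the design decisions taken where more than one
defensible choice existed.

## Effect scales and standard-error recovery

All analysis happens on a scale where the sampling distribution of the
estimate is approximately normal: the natural log for ratio measures
(RR, OR, HR — all treated identically) and the raw scale for (weighted)
mean differences. The null is always 0 on the analysis scale.

Standard errors are recovered from reported confidence intervals under
the assumption that the interval is symmetric on the analysis scale,

    se = (g(upper) − g(lower)) / (2 z),

which is exact for intervals that were themselves constructed by
inverse-variance software. `z` is the exact standard-normal quantile for
the interval's level (1.959964… at 95%); `rounded_quantile=True`
substitutes 1.96 to match published intervals computed with the rounded
constant. A degenerate interval (upper = lower) yields se = 0, which is
accepted for a lone trial but rejected in multi-trial pooling, where it
would imply an infinite weight.

P-values are two-sided z-tests, p = 2(1 − Φ(|y − 0|/se)). The declared
direction of benefit is metadata used only to label effects as
favouring/neutral/against the treatment; it never enters a p-value.

## Pooling

Fixed-effect weights are wᵢ = 1/seᵢ². Heterogeneity uses the standard
Higgins convention: Q = Σwᵢ(yᵢ − ŷ_fixed)², df = k − 1,
I² = max(0, (Q − df)/Q)·100, defined as 0 when Q = 0 or k = 1.
DerSimonian–Laird τ² is the moment estimate max(0, (Q − df)/C) with
C = Σw − Σw²/Σw computed from fixed-effect weights; random-effects
results re-weight with wᵢ* = 1/(seᵢ² + τ²). The random-effects p-value
uses the plain normal approximation on the DL pooled SE — no
Knapp–Hartung adjustment — because that is what the review software
behind the corpora this package targets uses. When Q ≤ df the DL result
reduces exactly to the fixed-effect one. A single trial "pools" to
itself bit-for-bit under either model.

Out of scope by design: Peto and Mantel–Haenszel pooling, REML/profile
likelihood τ², meta-regression, and anything requiring 2×2 cell counts —
the pipeline works from estimate + CI alone.

## Concordance pipeline

The most precise trial is the one with the largest weight fraction under
the review's declared model; exact ties are broken by larger sample
size, then input order. Significance is dichotomised strictly
(significant iff p < α, so p = 0.05 is *not* significant; α defaults
to 0.05). Single-trial reviews sit on the agreement-table diagonal by
construction and are reported as sub-counts rather than being dropped.
Conditional rates return an explicit `None` for empty denominators.

"Rank correlation" is Spearman's rho (Pearson on mid-ranks — the two are
the same thing, and the test suite checks against a from-scratch
rank-and-correlate oracle). Because ratio and difference effects live on
incommensurable scales, correlations are reported per measure class, or
on a combined basis only after standardising each estimate by its
standard error; raw scales are never silently mixed.

## Synthetic corpus generator

The generator emulates the statistical shape of a large hand-extracted
sample of Cochrane-style reviews; no machine-readable version of such a
corpus exists, so it is the package's test bed.

* **Trial counts.** With probability 35/167 ≈ 0.21 a review contains a
  single trial; otherwise k = 2 + NegBin(r = 0.5, mean = 5.3). This
  yields a multi-trial mean of ≈ 7.3 trials, median 4, with the long
  tail (k approaching 100+) that real review collections show.
* **Trial sizes.** Marginally log-normal with median 183 and log-sd
  1.916 (fixed by the observed mean/median ratio 1148/183). The log-sd
  is decomposed into a between-review component (1.569) and a
  within-review component (1.1): trials inside one review are far more
  alike in size than trials across reviews. The within-review spread is
  the calibration knob for the largest-trial weight share; 1.1 puts the
  median share at ≈ 51%. Drawing sizes independently from the marginal
  would give ≈ 65%, visibly over-dominant top trials.
* **Within-trial error.** se = c/√n with c = 4.0 by default, roughly a
  log risk ratio for a dichotomous outcome with a 20% event rate
  (se ≈ 2√((1 − p)/(np))).
* **Effects.** True mean effect θ (default ln 0.8, a typical modest
  treatment benefit). Heterogeneity is spike-and-slab across reviews: a
  review is exactly homogeneous with probability 0.6, otherwise its
  trials' true effects are Normal(θ, τ²) with τ = 0.3. A single fixed τ
  cannot reproduce the empirical I² shape (median ≈ 1%, mean ≈ 27%,
  tail to 90%); the mixture does.
* **Model choice.** `always_fixed` by default; `by_Q` mimics review
  authors switching to random effects when Q is significant at 0.10.
* **Determinism.** One global seed; each review consumes a child stream
  spawned from a `numpy` `SeedSequence`, so corpora are byte-identical
  across runs and robust to parallel generation. Generated CIs are
  back-computed from (y, se) with the exact quantile, so reading the
  emitted CSV reproduces the generating standard errors to 1e-10.

What the generator does **not** emulate: publication bias and
small-study effects, outcome-reporting bias, correlated outcomes within
a review, non-normal within-trial sampling (counts near zero), and
rounding of published estimates. Passing calibration and recovery tests
therefore demonstrates internal correctness of the pipeline under its
assumed normal model, not robustness of real review corpora to those
artefacts.

## Reference agreement corpus

`reference_agreement_corpus()` is engineered, cell by cell, to land on a
prescribed 2×2 agreement pattern (defaults: 55/5/31/70 with 14 and 15
single-trial reviews on the diagonal, matching a published survey whose
underlying data were never deposited). Cells are populated by template
reviews — concordant well-powered pairs, strongly conflicting pairs
(high I², trial-significant-only), jointly-but-not-individually
significant triples, and near-null effects — with small deterministic
jitter so records are distinct. It is synthetic: nothing in it is
extracted from any publication, and the arithmetic on it (conditional
rates, discrepancy rows) is genuinely computed by the pipeline.

## Problem sizes and numerical choices

The validation experiments use 5000-review corpora for calibration,
stratified agreement, CI coverage and type-I error, and 2000 reviews for
bias — sizes at which binomial Monte-Carlo error is a few parts per
thousand, so the checks are sharp while the whole suite stays fast.
Weight fractions are normalised to sum to 1 within 1e-12; pooling agrees
with an independently coded brute-force oracle to 1e-10; τ² truncates at
0; the analysis-scale/natural-scale round trip is exact to 1e-10.
Reviews whose rows fail validation are excluded all-or-nothing with a
machine-readable reason code (`invalid_row`, `invalid_model`,
`no_trials`) and logged once, mirroring the evaluable-subset accounting
a review-of-reviews reports.

## Known limitations

* SE recovery assumes analysis-scale symmetry; intervals from exact or
  score methods will be slightly mis-recovered.
* The DL estimator's negative-moment truncation makes τ̂² = 0 the median
  outcome under homogeneity (a property, not a bug, and tested as such),
  but it under-covers when k is small and τ is large — inherited from
  the method itself.
* `pooled_override` replaces only the pooled side of a comparison;
  reviews with no trial rows at all cannot enter the concordance
  analysis and are excluded upstream.
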