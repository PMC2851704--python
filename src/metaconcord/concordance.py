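"""Agreement between the most precise trial and the full meta-analysis.

Given a review outcome (a set of trials plus the pooling model its authors
chose), this module identifies the trial carrying the greatest
inverse-variance weight, recomputes its p-value with a uniform z-test,
pools all trials, and classifies agreement in statistical significance at a
common alpha.  Corpus-level summaries follow: the 2x2 agreement table with
single-trial sub-counts, conditional significance rates, rank correlation
of paired effect estimates, confidence-interval relationship checks, a
discrepancy report for reviews where the top trial is significant but the
pooled result is not, and stratification by the top trial's weight share.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Direction,
    HeterogeneityStats,
    PooledResult,
    PoolingError,
    PoolingModel,
    Scale,
    TrialEffect,
    pool,
    to_analysis_scale,
    weight_fractions,
    z_pvalue,
)

__all__ = [
    "ReviewOutcome",
    "ConcordanceRecord",
    "AgreementTable",
    "AgreementClass",
    "EffectDirection",
    "MeasureClass",
    "ConditionalRates",
    "CiRelationship",
    "StratumSummary",
    "most_precise_trial",
    "classify_significance",
    "build_concordance",
    "build_corpus_records",
    "agreement_table",
    "conditional_rates",
    "estimate_rank_correlation",
    "ci_relationship",
    "discrepancy_report",
    "stratify_by_weight",
]


class AgreementClass(str, enum.Enum):
    BOTH_SIG = "both_sig"
    BOTH_NONSIG = "both_nonsig"
    TRIAL_SIG_ONLY = "trial_sig_only"
    META_SIG_ONLY = "meta_sig_only"
    SINGLE_TRIAL_SIG = "single_trial_sig"
    SINGLE_TRIAL_NONSIG = "single_trial_nonsig"


class EffectDirection(str, enum.Enum):
    FAVORS = "favors"
    NEUTRAL = "neutral"
    AGAINST = "against"


class MeasureClass(str, enum.Enum):
    """Grouping used when correlating paired estimates across reviews."""

    RATIO = "ratio"
    DIFFERENCE = "difference"
    POOLED_STANDARDIZED = "pooled_standardized"


@dataclass(frozen=True)
class ReviewOutcome:
    """One review outcome: its trials and the authors' pooling model.

    ``pooled_override`` carries an externally supplied pooled result for
    reviews where only summary rows are available; when present it replaces
    the recomputed pooled side of the comparison but trials are still
    needed to identify the most precise one.
    """

    review_id: str
    outcome_name: str
    trials: tuple[TrialEffect, ...]
    model: PoolingModel = PoolingModel.FIXED
    pooled_override: Optional[PooledResult] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "model", PoolingModel(self.model))
        if not self.trials and self.pooled_override is None:
            raise ValueError(
                f"review {self.review_id!r}: needs at least one trial or a "
                f"pooled override"
            )

    @property
    def k(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class ConcordanceRecord:
    """Paired most-precise-trial vs meta-analysis result for one review."""

    review_id: str
    outcome_name: str
    k: int
    scale: Scale
    trial_y: float
    trial_se: float
    trial_p: float
    trial_estimate: float
    trial_ci_lower: float
    trial_ci_upper: float
    meta_y: float
    meta_se: float
    meta_p: float
    meta_estimate: float
    meta_ci_lower: float
    meta_ci_upper: float
    weight_share: float
    i2: float
    trial_sig: bool
    meta_sig: bool
    agreement_class: AgreementClass
    trial_direction: EffectDirection
    meta_direction: EffectDirection
    alpha: float

    @property
    def agree(self) -> bool:
        return self.trial_sig == self.meta_sig

    @property
    def measure_class(self) -> MeasureClass:
        return (
            MeasureClass.RATIO
            if self.scale is Scale.LOG
            else MeasureClass.DIFFERENCE
        )


@dataclass(frozen=True)
class AgreementTable:
    """2x2 counts of significance agreement, with single-trial sub-counts.

    n11: both significant; n10: trial significant only; n01: meta
    significant only; n00: neither.  Single-trial reviews sit on the
    diagonal by construction and are additionally tracked in
    ``n11_single`` / ``n00_single``.
    """

    n11: int
    n10: int
    n01: int
    n00: int
    n11_single: int
    n00_single: int
    alpha: float

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class ConditionalRates:
    """Conditional significance rates; ``None`` marks an empty denominator."""

    p_meta_sig_given_trial_sig: Optional[float]
    p_meta_sig_given_trial_nonsig: Optional[float]
    overall_agreement: Optional[float]


@dataclass(frozen=True)
class CiRelationship:
    contains_pooled_estimate: bool
    intervals_overlap: bool


def classify_significance(p: float, alpha: float = 0.05) -> bool:
    """Strictly-less-than dichotomisation: significant iff p < alpha."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    return bool(p < alpha)


def most_precise_trial(
    review: ReviewOutcome, *, model: PoolingModel | str | None = None
) -> tuple[int, float]:
    """Index and weight share of the trial with the greatest weight.

    The weight fractions follow the review's declared pooling model unless
    overridden.  Exact weight ties are broken by larger sample size, then
    by input order.
    """
    if not review.trials:
        raise PoolingError(
            f"review {review.review_id!r}: no trials to weigh"
        )
    model = PoolingModel(model) if model is not None else review.model
    effects = [to_analysis_scale(t) for t in review.trials]
    fractions = weight_fractions(effects, model)
    best = int(np.argmax(fractions))
    top = fractions[best]
    tied = [i for i, f in enumerate(fractions) if f == top]
    if len(tied) > 1:
        sizes = [(review.trials[i].n or 0) for i in tied]
        best = tied[int(np.argmax(sizes))]
    return best, float(fractions[best])


def _direction(y: float, benefit: Direction) -> EffectDirection:
    if y == 0.0:
        return EffectDirection.NEUTRAL
    below = y < 0.0
    favors = below == (benefit is Direction.LESS_THAN_NULL)
    return EffectDirection.FAVORS if favors else EffectDirection.AGAINST


def build_concordance(
    review: ReviewOutcome,
    alpha: float = 0.05,
    *,
    model: PoolingModel | str | None = None,
) -> ConcordanceRecord:
    """Pool a review, recompute the top trial's z-test p, classify agreement.

    Pooling follows the review's declared model (or an explicit override);
    single-trial reviews yield ``single_trial_*`` classes with a weight
    share of 1.  Pooling errors are re-raised with the review id attached.
    """
    model = PoolingModel(model) if model is not None else review.model
    try:
        idx, share = most_precise_trial(review, model=model)
        trial = review.trials[idx]
        effect = to_analysis_scale(trial)
        if review.pooled_override is not None:
            pooled = review.pooled_override
            effects = [to_analysis_scale(t) for t in review.trials]
            from .core import _heterogeneity  # fixed-weight heterogeneity

            if len(effects) > 1:
                het = _heterogeneity(
                    np.array([e.y for e in effects]),
                    np.array([1.0 / e.se**2 for e in effects]),
                )
            else:
                het = HeterogeneityStats(Q=0.0, df=0, tau2=0.0, C=0.0, i2=0.0)
        else:
            effects = [to_analysis_scale(t) for t in review.trials]
            pooled, het = pool(effects, model)
        trial_p = (
            1.0 if effect.se == 0.0 and effect.y == 0.0 else z_pvalue(effect)
        )
    except (PoolingError, ValueError) as err:
        raise PoolingError(f"review {review.review_id!r}: {err}") from err

    trial_sig = classify_significance(trial_p, alpha)
    meta_sig = classify_significance(pooled.p, alpha)
    if review.k == 1:
        cls = (
            AgreementClass.SINGLE_TRIAL_SIG
            if trial_sig
            else AgreementClass.SINGLE_TRIAL_NONSIG
        )
    elif trial_sig and meta_sig:
        cls = AgreementClass.BOTH_SIG
    elif trial_sig:
        cls = AgreementClass.TRIAL_SIG_ONLY
    elif meta_sig:
        cls = AgreementClass.META_SIG_ONLY
    else:
        cls = AgreementClass.BOTH_NONSIG

    return ConcordanceRecord(
        review_id=review.review_id,
        outcome_name=review.outcome_name,
        k=review.k,
        scale=effect.scale,
        trial_y=effect.y,
        trial_se=effect.se,
        trial_p=trial_p,
        trial_estimate=trial.point,
        trial_ci_lower=trial.ci_lower,
        trial_ci_upper=trial.ci_upper,
        meta_y=pooled.y_pooled,
        meta_se=pooled.se_pooled,
        meta_p=pooled.p,
        meta_estimate=pooled.estimate,
        meta_ci_lower=pooled.ci_lower,
        meta_ci_upper=pooled.ci_upper,
        weight_share=share,
        i2=het.i2,
        trial_sig=trial_sig,
        meta_sig=meta_sig,
        agreement_class=cls,
        trial_direction=_direction(effect.y, trial.direction_of_benefit),
        meta_direction=_direction(pooled.y_pooled, trial.direction_of_benefit),
        alpha=alpha,
    )


def build_corpus_records(
    reviews: Sequence[ReviewOutcome],
    alpha: float = 0.05,
    *,
    model: PoolingModel | str | None = None,
    on_error: str = "raise",
) -> list[ConcordanceRecord]:
    """Classify every review; ``on_error='skip'`` drops failing reviews."""
    records = []
    for review in reviews:
        try:
            records.append(build_concordance(review, alpha, model=model))
        except PoolingError:
            if on_error != "skip":
                raise
    return records


def agreement_table(
    records: Sequence[ConcordanceRecord], alpha: float = 0.05
) -> AgreementTable:
    """Tabulate significance agreement; empty input gives a zero table."""
    n11 = n10 = n01 = n00 = n11s = n00s = 0
    for r in records:
        if r.trial_sig and r.meta_sig:
            n11 += 1
            n11s += r.k == 1
        elif r.trial_sig:
            n10 += 1
        elif r.meta_sig:
            n01 += 1
        else:
            n00 += 1
            n00s += r.k == 1
    return AgreementTable(
        n11=n11, n10=n10, n01=n01, n00=n00,
        n11_single=n11s, n00_single=n00s, alpha=alpha,
    )


def conditional_rates(table: AgreementTable) -> ConditionalRates:
    """P(meta sig | trial sig), P(meta sig | trial nonsig), overall agreement.

    Empty denominators yield ``None`` rather than raising.
    """
    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return ConditionalRates(
        p_meta_sig_given_trial_sig=ratio(table.n11, table.n11 + table.n10),
        p_meta_sig_given_trial_nonsig=ratio(table.n01, table.n01 + table.n00),
        overall_agreement=ratio(table.n11 + table.n00, table.total),
    )


def estimate_rank_correlation(
    records: Sequence[ConcordanceRecord],
    measure_class: MeasureClass | str = MeasureClass.POOLED_STANDARDIZED,
) -> float:
    """Spearman correlation of paired trial vs pooled estimates.

    'Pearson correlation on ranks' is Spearman's rho by definition; ties
    are mid-ranked.  Within the ratio or difference class the raw
    analysis-scale estimates are correlated; the pooled-standardized class
    combines both by standardising each estimate by its standard error
    (a unitless z-like quantity), never mixing raw scales.
    """
    measure_class = MeasureClass(measure_class)
    if measure_class is MeasureClass.POOLED_STANDARDIZED:
        sel = [r for r in records if r.trial_se > 0 and r.meta_se > 0]
        xs = [r.trial_y / r.trial_se for r in sel]
        ys = [r.meta_y / r.meta_se for r in sel]
    else:
        sel = [r for r in records if r.measure_class is measure_class]
        xs = [r.trial_y for r in sel]
        ys = [r.meta_y for r in sel]
    if len(xs) < 3:
        raise ValueError(
            f"need at least 3 records in class {measure_class.value!r}, "
            f"got {len(xs)}"
        )
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        raise ValueError(
            "rank correlation undefined: one side of the pairing is constant"
        )
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)


def ci_relationship(
    trial: TrialEffect, pooled: PooledResult
) -> CiRelationship:
    """Does the trial CI contain the pooled point, and do the CIs overlap?

    Both intervals are compared on the natural scale; the trial's measure
    class must match the pooled result's scale.
    """
    if trial.scale is not pooled.scale:
        raise ValueError(
            f"scale mismatch: trial on {trial.scale.value}, pooled on "
            f"{pooled.scale.value}"
        )
    contains = trial.ci_lower <= pooled.estimate <= trial.ci_upper
    overlap = max(trial.ci_lower, pooled.ci_lower) <= min(
        trial.ci_upper, pooled.ci_upper
    )
    return CiRelationship(
        contains_pooled_estimate=bool(contains),
        intervals_overlap=bool(overlap),
    )


DISCREPANCY_COLUMNS = [
    "review_id",
    "outcome_name",
    "k",
    "meta_p",
    "trial_p",
    "weight_share",
    "meta_estimate",
    "trial_estimate",
    "i2",
]


def discrepancy_report(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """Rows where the most precise trial is significant but the pooled
    result is not, sorted by review id — the classic discordance listing
    (number of trials, both p-values, trial weight, both effect estimates,
    and I-squared)."""
    rows = [
        {
            "review_id": r.review_id,
            "outcome_name": r.outcome_name,
            "k": r.k,
            "meta_p": r.meta_p,
            "trial_p": r.trial_p,
            "weight_share": r.weight_share,
            "meta_estimate": r.meta_estimate,
            "trial_estimate": r.trial_estimate,
            "i2": r.i2,
        }
        for r in records
        if r.agreement_class is AgreementClass.TRIAL_SIG_ONLY
    ]
    frame = pd.DataFrame(rows, columns=DISCREPANCY_COLUMNS)
    return frame.sort_values("review_id", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class StratumSummary:
    """Summary of one weight-share stratum, with scatter-ready point sets."""

    label: str
    count: int
    agreement_rate: Optional[float]
    rank_correlation: Optional[float]
    estimate_points: pd.DataFrame  # trial_y vs meta_y (+ scale, share)
    pvalue_points: pd.DataFrame  # trial_p vs meta_p


def _stratum(
    label: str, records: list[ConcordanceRecord]
) -> StratumSummary:
    agree = (
        sum(r.agree for r in records) / len(records) if records else None
    )
    try:
        rho = estimate_rank_correlation(
            records, MeasureClass.POOLED_STANDARDIZED
        )
    except ValueError:
        rho = None
    est = pd.DataFrame(
        {
            "review_id": [r.review_id for r in records],
            "scale": [r.scale.value for r in records],
            "trial_y": [r.trial_y for r in records],
            "meta_y": [r.meta_y for r in records],
            "weight_share": [r.weight_share for r in records],
        }
    )
    pvals = pd.DataFrame(
        {
            "review_id": [r.review_id for r in records],
            "trial_p": [r.trial_p for r in records],
            "meta_p": [r.meta_p for r in records],
            "weight_share": [r.weight_share for r in records],
        }
    )
    return StratumSummary(
        label=label,
        count=len(records),
        agreement_rate=agree,
        rank_correlation=rho,
        estimate_points=est,
        pvalue_points=pvals,
    )


def stratify_by_weight(
    records: Sequence[ConcordanceRecord], threshold: float = 0.5
) -> dict[str, StratumSummary]:
    """Partition records at a weight-share threshold (share > t vs <= t).

    Returns per-stratum counts, significance-agreement rates, rank
    correlations, and the paired point sets used for scatter exports of
    trial-vs-meta estimates and p-values.
    """
    high = [r for r in records if r.weight_share > threshold]
    low = [r for r in records if r.weight_share <= threshold]
    return {
        "high": _stratum(f"share>{threshold:g}", high),
        "low": _stratum(f"share<={threshold:g}", low),
    }
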