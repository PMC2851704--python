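"""Built-in synthetic example corpora.

The hand-extracted review data behind the published concordance survey
were never deposited, so this module constructs a fully synthetic stand-in:
a corpus of review outcomes engineered, cell by cell, to reproduce the
survey's significance-agreement pattern — 55 reviews significant on both
sides (14 of them single-trial), 5 where only the most precise trial is
significant, 31 where only the meta-analysis is, and 70 significant on
neither side (15 single-trial).  Every review is generated from explicit
analysis-scale effects and standard errors; nothing is extracted from any
publication.
"""

from __future__ import annotations

import itertools

from .concordance import ReviewOutcome
from .core import (
    Direction,
    Measure,
    PoolingModel,
    Scale,
    TrialEffect,
    from_analysis_scale,
    normal_quantile,
)

__all__ = ["reference_agreement_corpus"]


def _trial(
    trial_id: str,
    measure: Measure,
    y: float,
    se: float,
    n: int | None = None,
) -> TrialEffect:
    """Build a TrialEffect from an analysis-scale effect and SE."""
    scale = Scale.LOG if measure.is_ratio else Scale.IDENTITY
    z = normal_quantile(0.95)
    return TrialEffect(
        trial_id=trial_id,
        measure=measure,
        point=from_analysis_scale(y, scale),
        ci_lower=from_analysis_scale(y - z * se, scale),
        ci_upper=from_analysis_scale(y + z * se, scale),
        ci_level=0.95,
        n=n,
        direction_of_benefit=Direction.LESS_THAN_NULL,
    )


def _review(
    review_id: str,
    measure: Measure,
    effects: list[tuple[float, float]],
) -> ReviewOutcome:
    trials = tuple(
        _trial(f"{review_id}.t{j + 1}", measure, y, se)
        for j, (y, se) in enumerate(effects)
    )
    return ReviewOutcome(
        review_id=review_id,
        outcome_name="primary",
        trials=trials,
        model=PoolingModel.FIXED,
    )


def reference_agreement_corpus(
    n_both_sig_multi: int = 41,
    n_both_sig_single: int = 14,
    n_trial_sig_only: int = 5,
    n_meta_sig_only: int = 31,
    n_both_nonsig_multi: int = 55,
    n_both_nonsig_single: int = 15,
) -> list[ReviewOutcome]:
    """Construct a corpus with prescribed significance-agreement cells.

    Each cell is populated by a template review whose effects are chosen
    so that the most precise trial's z-test and the fixed-effect pooled
    result land in that cell at alpha = 0.05, with a small deterministic
    jitter so records are distinct:

    * both significant — two concordant, well-powered trials;
    * trial significant only — two strongly conflicting trials whose
      pooled effect cancels (these carry high I-squared by construction);
    * meta significant only — three modest same-direction trials, each
      underpowered alone but jointly significant;
    * neither significant — small near-null effects.

    Defaults reproduce the agreement pattern reported in a survey of the
    concordance between the most precise trial and its meta-analysis
    across a random sample of Cochrane reviews.
    """
    reviews: list[ReviewOutcome] = []
    counter = itertools.count(1)

    def rid() -> str:
        return f"S{next(counter):04d}"

    for i in range(n_both_sig_multi):
        measure = Measure.RR if i % 2 == 0 else Measure.OR
        eps = 0.002 * i
        reviews.append(
            _review(
                rid(), measure,
                [(-0.50 - eps, 0.10), (-0.45 - eps, 0.14)],
            )
        )
    for i in range(n_both_sig_single):
        reviews.append(
            _review(rid(), Measure.RR, [(-0.50 - 0.003 * i, 0.15)])
        )
    for i in range(n_trial_sig_only):
        eps = 0.01 * i
        reviews.append(
            _review(
                rid(), Measure.RR,
                [(0.30 + eps, 0.12), (-(0.28 + eps), 0.13)],
            )
        )
    for i in range(n_meta_sig_only):
        eps = 0.001 * i
        reviews.append(
            _review(
                rid(), Measure.RR,
                [
                    (-0.25 - eps, 0.16),
                    (-0.24 - eps, 0.17),
                    (-0.26 - eps, 0.18),
                ],
            )
        )
    for i in range(n_both_nonsig_multi):
        measure = Measure.RR if i % 2 == 0 else Measure.MD
        eps = 0.001 * i
        reviews.append(
            _review(
                rid(), measure,
                [(0.05 + eps, 0.20), (-0.04 - eps, 0.25)],
            )
        )
    for i in range(n_both_nonsig_single):
        reviews.append(
            _review(rid(), Measure.RR, [(0.05 + 0.002 * i, 0.30)])
        )
    return reviews
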