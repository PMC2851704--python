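"""CSV schemas and readers/writers for trial-level review data.

The exchange format is a flat trials CSV: one row per trial per review
outcome, UTF-8, '.' decimal point, with the exact ordered header

    review_id,outcome_name,trial_id,measure,point,ci_lower,ci_upper,
    ci_level,n,model,direction_of_benefit

``n`` may be empty.  Rows are grouped into review outcomes by
(review_id, outcome_name); a row that violates an invariant invalidates
its whole review (all-or-nothing), which is recorded as an exclusion with
a machine-readable reason code and the offending row numbers, never a
crash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .concordance import ReviewOutcome
from .core import Direction, EffectInputError, Measure, PoolingModel, TrialEffect

logger = logging.getLogger(__name__)

__all__ = [
    "TRIALS_COLUMNS",
    "Exclusion",
    "ReadResult",
    "read_trials_csv",
    "write_trials_csv",
    "reviews_to_frame",
]

TRIALS_COLUMNS = [
    "review_id",
    "outcome_name",
    "trial_id",
    "measure",
    "point",
    "ci_lower",
    "ci_upper",
    "ci_level",
    "n",
    "model",
    "direction_of_benefit",
]

# reason codes mirror the accounting a review-of-reviews reports:
# reviews dropped for having no trials, unparseable rows, or invalid effects
REASON_BAD_ROW = "invalid_row"
REASON_NO_TRIALS = "no_trials"
REASON_BAD_MODEL = "invalid_model"


@dataclass(frozen=True)
class Exclusion:
    """One excluded review: which, why, and the rows responsible."""

    review_id: str
    outcome_name: str
    reason: str
    detail: str
    rows: tuple[int, ...]  # 1-based data row numbers (header excluded)


@dataclass(frozen=True)
class ReadResult:
    reviews: list[ReviewOutcome]
    exclusions: list[Exclusion]


def _parse_trial(row: pd.Series) -> TrialEffect:
    n_raw = row["n"]
    n = None
    if n_raw is not None and str(n_raw).strip() != "" and not pd.isna(n_raw):
        n = int(float(n_raw))
    return TrialEffect(
        trial_id=str(row["trial_id"]),
        measure=Measure(str(row["measure"]).strip()),
        point=float(row["point"]),
        ci_lower=float(row["ci_lower"]),
        ci_upper=float(row["ci_upper"]),
        ci_level=float(row["ci_level"]),
        n=n,
        direction_of_benefit=Direction(str(row["direction_of_benefit"]).strip()),
    )


def read_trials_csv(path: str | Path) -> ReadResult:
    """Read and validate a trials CSV into review outcomes.

    Validation is all-or-nothing per review: every bad row is collected
    with its 1-based data row number, the affected review is excluded and
    logged, and all remaining reviews are returned.  A header mismatch or
    an unreadable file raises immediately.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != TRIALS_COLUMNS:
        raise ValueError(
            f"{path}: header mismatch; expected {TRIALS_COLUMNS}, "
            f"got {list(frame.columns)}"
        )
    reviews: list[ReviewOutcome] = []
    exclusions: list[Exclusion] = []
    if frame.empty:
        return ReadResult(reviews=reviews, exclusions=exclusions)

    frame = frame.assign(_row=frame.index + 1)
    for (review_id, outcome_name), group in frame.groupby(
        ["review_id", "outcome_name"], sort=False
    ):
        trials, bad_rows, messages = [], [], []
        for _, row in group.iterrows():
            try:
                trials.append(_parse_trial(row))
            except (EffectInputError, ValueError) as err:
                bad_rows.append(int(row["_row"]))
                messages.append(f"row {row['_row']}: {err}")
        if bad_rows:
            exc = Exclusion(
                review_id=str(review_id),
                outcome_name=str(outcome_name),
                reason=REASON_BAD_ROW,
                detail="; ".join(messages),
                rows=tuple(bad_rows),
            )
            exclusions.append(exc)
            logger.warning(
                "excluding review %s/%s (%s): %s",
                review_id, outcome_name, exc.reason, exc.detail,
            )
            continue
        models = {str(m).strip() for m in group["model"]}
        try:
            model = PoolingModel(models.pop()) if len(models) == 1 else None
            if model is None:
                raise ValueError(f"conflicting model declarations: {models}")
        except ValueError as err:
            exc = Exclusion(
                review_id=str(review_id),
                outcome_name=str(outcome_name),
                reason=REASON_BAD_MODEL,
                detail=str(err),
                rows=tuple(int(r) for r in group["_row"]),
            )
            exclusions.append(exc)
            logger.warning(
                "excluding review %s/%s (%s): %s",
                review_id, outcome_name, exc.reason, exc.detail,
            )
            continue
        reviews.append(
            ReviewOutcome(
                review_id=str(review_id),
                outcome_name=str(outcome_name),
                trials=tuple(trials),
                model=model,
            )
        )
    logger.info(
        "read %d reviews (%d excluded) from %s",
        len(reviews), len(exclusions), path,
    )
    return ReadResult(reviews=reviews, exclusions=exclusions)


def reviews_to_frame(reviews: Sequence[ReviewOutcome]) -> pd.DataFrame:
    """Flatten review outcomes into the trials CSV schema."""
    rows = [
        {
            "review_id": review.review_id,
            "outcome_name": review.outcome_name,
            "trial_id": trial.trial_id,
            "measure": trial.measure.value,
            "point": trial.point,
            "ci_lower": trial.ci_lower,
            "ci_upper": trial.ci_upper,
            "ci_level": trial.ci_level,
            "n": "" if trial.n is None else trial.n,
            "model": review.model.value,
            "direction_of_benefit": trial.direction_of_benefit.value,
        }
        for review in reviews
        for trial in review.trials
    ]
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def write_trials_csv(reviews: Sequence[ReviewOutcome], path: str | Path) -> None:
    """Write review outcomes as a trials CSV (full float precision)."""
    reviews_to_frame(reviews).to_csv(path, index=False)
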