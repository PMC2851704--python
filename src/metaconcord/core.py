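"""Effect-size arithmetic and inverse-variance pooling.

This module implements the numerical core of the package: recovery of
standard errors from reported confidence intervals, z-test p-values,
fixed-effect inverse-variance pooling, DerSimonian-Laird random-effects
pooling, and the usual heterogeneity statistics (Cochran's Q, tau-squared,
I-squared).

Conventions
-----------
Ratio measures (risk ratio, odds ratio, hazard ratio) are analysed on the
natural-log scale; mean differences on the identity scale.  The null value
on the analysis scale is always 0 (a ratio of 1 or a difference of 0).
Confidence intervals are assumed symmetric on the analysis scale, which is
how inverse-variance software constructs them in the first place.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Measure",
    "Scale",
    "Direction",
    "PoolingModel",
    "TrialEffect",
    "AnalysisEffect",
    "PooledResult",
    "HeterogeneityStats",
    "EffectInputError",
    "PoolingError",
    "UndefinedPValueError",
    "normal_quantile",
    "to_analysis_scale",
    "from_analysis_scale",
    "z_pvalue",
    "pool_fixed",
    "pool_random_dl",
    "pool",
    "weight_fractions",
]


class Measure(str, enum.Enum):
    """Effect measure as reported by a trial or review."""

    RR = "RR"
    OR = "OR"
    HR = "HR"
    MD = "MD"
    WMD = "WMD"

    @property
    def is_ratio(self) -> bool:
        return self in (Measure.RR, Measure.OR, Measure.HR)


class Scale(str, enum.Enum):
    """Analysis scale: log for ratio measures, identity for differences."""

    LOG = "log"
    IDENTITY = "identity"


class Direction(str, enum.Enum):
    """Which side of the null favours the experimental treatment."""

    LESS_THAN_NULL = "less_than_null"
    GREATER_THAN_NULL = "greater_than_null"


class PoolingModel(str, enum.Enum):
    FIXED = "fixed"
    RANDOM = "random"


class EffectInputError(ValueError):
    """A trial effect violates its invariants (bad CI, bad measure, ...)."""


class PoolingError(ValueError):
    """Pooling inputs are unusable (empty, mixed scales, zero SE, ...)."""


class UndefinedPValueError(ValueError):
    """z-test requested for a degenerate effect (se = 0, estimate off-null)."""


@dataclass(frozen=True)
class TrialEffect:
    """One trial's reported effect on its natural scale.

    Parameters
    ----------
    trial_id : str
        Opaque label.
    measure : Measure
        RR/OR/HR (analysed on the log scale) or MD/WMD (identity scale).
    point, ci_lower, ci_upper : float
        Point estimate and confidence bounds on the natural scale.
    ci_level : float
        Coverage of the reported interval as a fraction, default 0.95.
    n : int, optional
        Total randomised participants.
    direction_of_benefit : Direction
        Metadata declaring which side of the null favours treatment; it
        never enters a p-value.
    """

    trial_id: str
    measure: Measure
    point: float
    ci_lower: float
    ci_upper: float
    ci_level: float = 0.95
    n: Optional[int] = None
    direction_of_benefit: Direction = Direction.LESS_THAN_NULL

    def __post_init__(self) -> None:
        object.__setattr__(self, "measure", Measure(self.measure))
        object.__setattr__(
            self, "direction_of_benefit", Direction(self.direction_of_benefit)
        )
        if not (0.0 < self.ci_level < 1.0):
            raise EffectInputError(
                f"trial {self.trial_id!r}: ci_level must lie in (0, 1), "
                f"got {self.ci_level}"
            )
        if self.ci_upper < self.ci_lower:
            raise EffectInputError(
                f"trial {self.trial_id!r}: ci_upper < ci_lower "
                f"({self.ci_upper} < {self.ci_lower})"
            )
        if not (self.ci_lower <= self.point <= self.ci_upper):
            raise EffectInputError(
                f"trial {self.trial_id!r}: point {self.point} outside CI "
                f"[{self.ci_lower}, {self.ci_upper}]"
            )
        if self.measure.is_ratio and (self.point <= 0 or self.ci_lower <= 0):
            raise EffectInputError(
                f"trial {self.trial_id!r}: ratio measure requires strictly "
                f"positive estimate and bounds"
            )
        if self.n is not None and self.n <= 0:
            raise EffectInputError(
                f"trial {self.trial_id!r}: n must be a positive integer"
            )

    @property
    def scale(self) -> Scale:
        return Scale.LOG if self.measure.is_ratio else Scale.IDENTITY


@dataclass(frozen=True)
class AnalysisEffect:
    """An effect on the analysis scale: log-ratio or raw difference."""

    y: float
    se: float
    scale: Scale = Scale.LOG
    null_value: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale", Scale(self.scale))
        if self.se < 0 or not math.isfinite(self.se):
            raise EffectInputError(f"se must be finite and >= 0, got {self.se}")
        if not math.isfinite(self.y):
            raise EffectInputError(f"estimate must be finite, got {self.y}")


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q, its df, the DL scaling constant C, tau^2 and I^2 (%)."""

    Q: float
    df: int
    tau2: float
    C: float
    i2: float


@dataclass(frozen=True)
class PooledResult:
    """An inverse-variance pooled estimate with CI, p-value and weights."""

    estimate: float
    y_pooled: float
    se_pooled: float
    ci_lower: float
    ci_upper: float
    p: float
    model: PoolingModel
    weights: tuple[float, ...]
    k: int
    scale: Scale
    ci_level: float = 0.95


def normal_quantile(ci_level: float, *, rounded: bool = False) -> float:
    """Two-sided standard-normal quantile for a CI level.

    ``rounded=True`` returns the conventional 1.96 for a 95% interval,
    matching software that hard-codes the rounded constant; otherwise the
    exact quantile (1.959964...) is used.
    """
    if rounded and abs(ci_level - 0.95) < 1e-12:
        return 1.96
    return float(stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0))


def to_analysis_scale(
    trial: TrialEffect, *, rounded_quantile: bool = False
) -> AnalysisEffect:
    """Map a reported effect to the analysis scale and recover its SE.

    The standard error is back-calculated from the CI width assuming the
    interval is symmetric on the analysis scale:

        se = (g(upper) - g(lower)) / (2 * z)

    with g = ln for ratio measures and the identity otherwise, and z the
    standard-normal quantile for the interval's level.  A degenerate
    interval (upper == lower) yields se = 0.
    """
    g = math.log if trial.measure.is_ratio else float
    y = g(trial.point)
    z = normal_quantile(trial.ci_level, rounded=rounded_quantile)
    se = (g(trial.ci_upper) - g(trial.ci_lower)) / (2.0 * z)
    return AnalysisEffect(y=y, se=se, scale=trial.scale)


def from_analysis_scale(y: float, scale: Scale) -> float:
    """Inverse of the scale map: exp for log scale, identity otherwise."""
    return math.exp(y) if Scale(scale) is Scale.LOG else y


def z_pvalue(effect: AnalysisEffect) -> float:
    """Two-sided z-test p-value of an effect against its null.

    p = 2 * (1 - Phi(|y - null| / se)).  A zero SE is only admissible when
    the estimate sits exactly on the null (then p = 1); otherwise the
    p-value is undefined and an error is raised.
    """
    if effect.se == 0.0:
        if effect.y == effect.null_value:
            return 1.0
        raise UndefinedPValueError(
            f"z-test undefined: se = 0 with estimate {effect.y} != null "
            f"{effect.null_value}"
        )
    z = abs(effect.y - effect.null_value) / effect.se
    return float(2.0 * stats.norm.sf(z))


def _check_poolable(effects: Sequence[AnalysisEffect]) -> Scale:
    if len(effects) == 0:
        raise PoolingError("cannot pool an empty list of effects")
    scales = {e.scale for e in effects}
    if len(scales) > 1:
        raise PoolingError(f"cannot pool effects on mixed scales: {scales}")
    if len(effects) > 1 and any(e.se <= 0 for e in effects):
        raise PoolingError(
            "zero or negative SE gives an infinite inverse-variance weight; "
            "remove or repair the degenerate trial before pooling"
        )
    return next(iter(scales))


def _single_trial_result(
    effect: AnalysisEffect, model: PoolingModel, ci_level: float
) -> tuple[PooledResult, HeterogeneityStats]:
    """k = 1: the 'pooled' result is the trial itself, bit for bit."""
    z = normal_quantile(ci_level)
    if effect.se == 0.0:
        p = 1.0 if effect.y == effect.null_value else 0.0
    else:
        p = z_pvalue(effect)
    lo, hi = effect.y - z * effect.se, effect.y + z * effect.se
    pooled = PooledResult(
        estimate=from_analysis_scale(effect.y, effect.scale),
        y_pooled=effect.y,
        se_pooled=effect.se,
        ci_lower=from_analysis_scale(lo, effect.scale),
        ci_upper=from_analysis_scale(hi, effect.scale),
        p=p,
        model=model,
        weights=(1.0,),
        k=1,
        scale=effect.scale,
        ci_level=ci_level,
    )
    het = HeterogeneityStats(Q=0.0, df=0, tau2=0.0, C=0.0, i2=0.0)
    return pooled, het


def _assemble(
    y: np.ndarray,
    w: np.ndarray,
    model: PoolingModel,
    scale: Scale,
    het: HeterogeneityStats,
    ci_level: float,
) -> PooledResult:
    sw = float(w.sum())
    y_pooled = float((w * y).sum() / sw)
    se_pooled = sw ** -0.5
    z = normal_quantile(ci_level)
    lo, hi = y_pooled - z * se_pooled, y_pooled + z * se_pooled
    p = z_pvalue(AnalysisEffect(y=y_pooled, se=se_pooled, scale=scale))
    return PooledResult(
        estimate=from_analysis_scale(y_pooled, scale),
        y_pooled=y_pooled,
        se_pooled=se_pooled,
        ci_lower=from_analysis_scale(lo, scale),
        ci_upper=from_analysis_scale(hi, scale),
        p=p,
        model=model,
        weights=tuple(float(x) for x in (w / sw)),
        k=int(len(y)),
        scale=scale,
        ci_level=ci_level,
    )


def _heterogeneity(y: np.ndarray, w: np.ndarray) -> HeterogeneityStats:
    """Q, C, tau^2 and I^2 from fixed-effect weights (Higgins convention)."""
    k = len(y)
    sw = float(w.sum())
    y_fixed = float((w * y).sum() / sw)
    Q = float((w * (y - y_fixed) ** 2).sum())
    df = k - 1
    C = sw - float((w**2).sum()) / sw
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HeterogeneityStats(Q=Q, df=df, tau2=tau2, C=C, i2=i2)


def pool_fixed(
    effects: Sequence[AnalysisEffect], *, ci_level: float = 0.95
) -> tuple[PooledResult, HeterogeneityStats]:
    """Fixed-effect inverse-variance pooling.

    Weights are w_i = 1/se_i^2; the pooled estimate is the weighted mean
    and its SE is (sum w_i)^{-1/2}.  Heterogeneity statistics are computed
    from the same weights.  A single trial is returned unchanged.
    """
    scale = _check_poolable(effects)
    if len(effects) == 1:
        return _single_trial_result(effects[0], PoolingModel.FIXED, ci_level)
    y = np.array([e.y for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    w = 1.0 / se**2
    het = _heterogeneity(y, w)
    return _assemble(y, w, PoolingModel.FIXED, scale, het, ci_level), het


def pool_random_dl(
    effects: Sequence[AnalysisEffect], *, ci_level: float = 0.95
) -> tuple[PooledResult, HeterogeneityStats]:
    """DerSimonian-Laird random-effects pooling.

    tau^2 is the method-of-moments estimate max(0, (Q - df)/C) with
    C = sum(w) - sum(w^2)/sum(w) from the fixed-effect weights; trials are
    then re-weighted as w*_i = 1/(se_i^2 + tau^2).  The p-value uses the
    plain normal approximation on the re-weighted pooled SE, matching the
    behaviour of standard review software (no Knapp-Hartung adjustment).
    When Q <= df the estimate truncates to tau^2 = 0 and the result
    coincides with the fixed-effect one.
    """
    scale = _check_poolable(effects)
    if len(effects) == 1:
        return _single_trial_result(effects[0], PoolingModel.RANDOM, ci_level)
    y = np.array([e.y for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    het = _heterogeneity(y, 1.0 / se**2)
    w_star = 1.0 / (se**2 + het.tau2)
    return _assemble(y, w_star, PoolingModel.RANDOM, scale, het, ci_level), het


def pool(
    effects: Sequence[AnalysisEffect],
    model: PoolingModel | str,
    *,
    ci_level: float = 0.95,
) -> tuple[PooledResult, HeterogeneityStats]:
    """Dispatch to fixed-effect or DL random-effects pooling."""
    model = PoolingModel(model)
    if model is PoolingModel.FIXED:
        return pool_fixed(effects, ci_level=ci_level)
    return pool_random_dl(effects, ci_level=ci_level)


def weight_fractions(
    effects: Sequence[AnalysisEffect], model: PoolingModel | str
) -> np.ndarray:
    """Per-trial weight fractions (summing to 1) under the given model."""
    model = PoolingModel(model)
    _check_poolable(effects)
    if len(effects) == 1:
        return np.array([1.0])
    se = np.array([e.se for e in effects], dtype=float)
    y = np.array([e.y for e in effects], dtype=float)
    w = 1.0 / se**2
    if model is PoolingModel.RANDOM:
        het = _heterogeneity(y, w)
        w = 1.0 / (se**2 + het.tau2)
    return w / w.sum()
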