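"""Standardised mean differences and cross-study pooling.

Effect magnitude is expressed as Cohen's *d* — the between-arm mean
difference divided by the pooled standard deviation — oriented so that
benefit is positive regardless of whether the outcome is scored
lower-is-better (infarct volume) or higher-is-better (behavioural
performance).  Being unit-free, *d* harmonises studies that report absolute
and relative volume reductions.

Pooling across studies offers the meta-analytic routes (inverse-variance
fixed effect, DerSimonian–Laird random effects) and the simpler cross-study
median.  Pooled values are banded into the readiness categories
small [0.2, 0.4), medium [0.4, 0.7), large [0.7, ∞); anything below 0.2
(including harm) is "none".  The intervals are half-open so the partition is
exhaustive and gap-free.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evidence_model import Direction, OutcomeMeasure

__all__ = [
    "EffectEstimate",
    "PooledEffect",
    "PoolMethod",
    "EffectCategory",
    "DegenerateVarianceError",
    "DEFAULT_BOUNDARIES",
    "cohens_d",
    "hedges_correction",
    "pool_fixed",
    "pool_random_dl",
    "cross_study_median",
    "categorize_effect",
    "pool",
    "read_effects_csv",
]

#: Default category cutpoints (small / medium / large lower bounds).
DEFAULT_BOUNDARIES: tuple[float, float, float] = (0.2, 0.4, 0.7)


class DegenerateVarianceError(ValueError):
    """Pooled SD is zero while the arm means differ: d is undefined."""


class PoolMethod(str, enum.Enum):
    FIXED = "fixed"
    RANDOM_DL = "random_dl"
    MEDIAN = "median"


class EffectCategory(str, enum.Enum):
    NONE = "none"
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


@dataclass(frozen=True)
class EffectEstimate:
    """Cohen's d for one study outcome with its large-sample variance."""

    study_id: str
    d: float
    var_d: float
    n_t: int
    n_c: int


@dataclass(frozen=True)
class PooledEffect:
    """A pooled standardized mean difference with its readiness category."""

    method: PoolMethod
    d_pooled: float
    se: Optional[float]
    tau2: Optional[float]
    k: int
    category: EffectCategory


def cohens_d(outcome: OutcomeMeasure, study_id: str = "") -> EffectEstimate:
    """Two-sample Cohen's d from arm summary statistics.

    d = oriented mean difference / pooled SD, with the difference signed so
    that benefit is positive: (mean_c − mean_t) for lower-is-better
    outcomes, (mean_t − mean_c) for higher-is-better.  The sampling variance
    is the common large-sample approximation
    var(d) = (n_t + n_c)/(n_t·n_c) + d²/(2·(n_t + n_c)).

    Raises :class:`DegenerateVarianceError` when the pooled SD is zero but
    the means differ; equal means with zero pooled SD yield d = 0.
    """
    t, c = outcome.treated, outcome.control
    if t.n < 2 or c.n < 2:
        raise ValueError(f"each arm needs n ≥ 2 (got n_t={t.n}, n_c={c.n})")
    if outcome.direction is Direction.LOWER_IS_BETTER:
        diff = c.mean - t.mean
    else:
        diff = t.mean - c.mean
    pooled_var = ((t.n - 1) * t.sd**2 + (c.n - 1) * c.sd**2) / (t.n + c.n - 2)
    pooled_sd = math.sqrt(pooled_var)
    if pooled_sd == 0.0:
        if diff == 0.0:
            d = 0.0
        else:
            raise DegenerateVarianceError(
                "pooled SD is zero but arm means differ")
    else:
        d = diff / pooled_sd
    n_tot = t.n + c.n
    var_d = n_tot / (t.n * c.n) + d**2 / (2 * n_tot)
    return EffectEstimate(study_id=study_id, d=d, var_d=var_d, n_t=t.n, n_c=c.n)


def hedges_correction(est: EffectEstimate) -> EffectEstimate:
    """Small-sample bias correction J = 1 − 3/(4·(n_t+n_c−2) − 1).

    d is multiplied by J and var(d) by J².
    """
    n_tot = est.n_t + est.n_c
    if n_tot < 3:
        raise ValueError("Hedges correction requires n_t + n_c ≥ 3")
    j = 1.0 - 3.0 / (4.0 * (n_tot - 2) - 1.0)
    return EffectEstimate(
        study_id=est.study_id,
        d=est.d * j,
        var_d=est.var_d * j * j,
        n_t=est.n_t,
        n_c=est.n_c,
    )


def categorize_effect(
    d_pooled: float,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> EffectCategory:
    """Band a pooled d into none / small / medium / large.

    Half-open intervals [small, medium), [medium, large), [large, ∞);
    values below the small cutpoint — including negative (harmful) effects —
    map to "none".
    """
    if not math.isfinite(d_pooled):
        raise ValueError("d must be finite")
    small, medium, large = boundaries
    if d_pooled >= large:
        return EffectCategory.LARGE
    if d_pooled >= medium:
        return EffectCategory.MEDIUM
    if d_pooled >= small:
        return EffectCategory.SMALL
    return EffectCategory.NONE


def _check_estimates(estimates: Sequence[EffectEstimate], min_k: int) -> None:
    if len(estimates) < min_k:
        raise ValueError(f"need at least {min_k} estimate(s), got {len(estimates)}")
    for est in estimates:
        if not (est.var_d > 0):
            raise ValueError(f"var_d must be > 0 (study {est.study_id!r})")
        if not math.isfinite(est.d):
            raise ValueError(f"d must be finite (study {est.study_id!r})")


def pool_fixed(
    estimates: Sequence[EffectEstimate],
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> PooledEffect:
    """Inverse-variance fixed-effect pooling (weights 1/var_d)."""
    _check_estimates(estimates, 1)
    d = np.array([e.d for e in estimates])
    w = 1.0 / np.array([e.var_d for e in estimates])
    d_pooled = float(np.sum(w * d) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    return PooledEffect(
        method=PoolMethod.FIXED,
        d_pooled=d_pooled,
        se=se,
        tau2=None,
        k=len(estimates),
        category=categorize_effect(d_pooled, boundaries),
    )


def pool_random_dl(
    estimates: Sequence[EffectEstimate],
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> PooledEffect:
    """DerSimonian–Laird random-effects pooling.

    The between-study variance is the moment estimator
    tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with Q the fixed-effect
    heterogeneity statistic, followed by inverse-variance pooling with
    weights 1/(var_d + tau²).
    """
    if len(estimates) < 2:
        raise ValueError(
            "random-effects pooling needs k ≥ 2; use pool_fixed for k = 1")
    _check_estimates(estimates, 2)
    d = np.array([e.d for e in estimates])
    w = 1.0 / np.array([e.var_d for e in estimates])
    k = len(estimates)
    d_fixed = np.sum(w * d) / np.sum(w)
    q = float(np.sum(w * (d - d_fixed) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (np.array([e.var_d for e in estimates]) + tau2)
    d_pooled = float(np.sum(w_star * d) / np.sum(w_star))
    se = float(math.sqrt(1.0 / np.sum(w_star)))
    return PooledEffect(
        method=PoolMethod.RANDOM_DL,
        d_pooled=d_pooled,
        se=se,
        tau2=tau2,
        k=k,
        category=categorize_effect(d_pooled, boundaries),
    )


def cross_study_median(
    estimates: Sequence[EffectEstimate],
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> PooledEffect:
    """Cross-study median d (midpoint convention for even k); no SE."""
    _check_estimates(estimates, 1)
    d_pooled = float(np.median([e.d for e in estimates]))
    return PooledEffect(
        method=PoolMethod.MEDIAN,
        d_pooled=d_pooled,
        se=None,
        tau2=None,
        k=len(estimates),
        category=categorize_effect(d_pooled, boundaries),
    )


def pool(
    estimates: Sequence[EffectEstimate],
    method: PoolMethod = PoolMethod.RANDOM_DL,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    hedges: bool = False,
) -> PooledEffect:
    """Pool by the named method, applying the Hedges correction if asked.

    Random-effects pooling falls back to fixed-effect when only one
    estimate is available.
    """
    _check_estimates(estimates, 1)
    if hedges:
        estimates = [hedges_correction(e) for e in estimates]
    method = PoolMethod(method)
    if method is PoolMethod.MEDIAN:
        return cross_study_median(estimates, boundaries)
    if method is PoolMethod.RANDOM_DL and len(estimates) >= 2:
        return pool_random_dl(estimates, boundaries)
    return pool_fixed(estimates, boundaries)


def read_effects_csv(path) -> list[EffectEstimate]:
    """Read per-study effect summaries and compute Cohen's d for each row.

    Expected columns: study_id, n_t, mean_t, sd_t, n_c, mean_c, sd_c,
    direction (lower_is_better / higher_is_better).
    """
    from .evidence_model import OutcomeKind, SummaryStats

    frame = pd.read_csv(path)
    required = {"study_id", "n_t", "mean_t", "sd_t", "n_c", "mean_c", "sd_c",
                "direction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"effects CSV missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        outcome = OutcomeMeasure(
            kind=OutcomeKind.INFARCT_VOLUME,
            direction=Direction(row.direction),
            treated=SummaryStats(n=int(row.n_t), mean=float(row.mean_t),
                                 sd=float(row.sd_t)),
            control=SummaryStats(n=int(row.n_c), mean=float(row.mean_c),
                                 sd=float(row.sd_c)),
        )
        out.append(cohens_d(outcome, study_id=str(row.study_id)))
    return out
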