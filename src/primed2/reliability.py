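"""Inter-rater agreement for item-level 0/1/2 ratings.

Two independent raters apply the instrument; agreement is summarised by
Cohen's kappa over the pooled (agent, item) rating units, with optional
linear/quadratic weighting for the ordinal scale, and disagreements are
resolved into a consensus rating set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RatingSet",
    "KappaResult",
    "UndefinedKappaError",
    "cohen_kappa",
    "weighted_kappa",
    "kappa_report",
    "kappa_from_scores",
    "consensus",
    "read_ratings_csv",
    "write_ratings_csv",
]

N_CATEGORIES = 3  # the 0/1/2 scale

RatingKey = tuple[str, str]  # (agent_id, item_id)


class UndefinedKappaError(ValueError):
    """Expected agreement is 1 (both raters constant): kappa is undefined."""


@dataclass
class RatingSet:
    """One rater's (agent_id, item_id) → score map."""

    rater_id: str
    ratings: dict[RatingKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, score in self.ratings.items():
            if score not in (0, 1, 2):
                raise ValueError(f"rating at {key} must be 0, 1 or 2, got {score}")


@dataclass(frozen=True)
class KappaResult:
    """Kappa with its ingredients and the disagreeing units."""

    kappa: float
    p_o: float
    p_e: float
    n_units: int
    disagreements: tuple[RatingKey, ...]


def _disagreement_weights(scheme: Optional[str]) -> np.ndarray:
    idx = np.arange(N_CATEGORIES)
    diff = np.abs(idx[:, None] - idx[None, :]).astype(float)
    if scheme is None:
        return (diff > 0).astype(float)
    if scheme == "linear":
        return diff / (N_CATEGORIES - 1)
    if scheme == "quadratic":
        return (diff / (N_CATEGORIES - 1)) ** 2
    raise ValueError(f"weighting scheme must be 'linear' or 'quadratic', got {scheme!r}")


def kappa_from_scores(
    a: np.ndarray,
    b: np.ndarray,
    scheme: Optional[str] = None,
) -> float:
    """Kappa from two aligned score arrays (the array-level workhorse).

    Unweighted kappa is (p_o − p_e)/(1 − p_e) over the 3×3 confusion
    matrix; weighted variants use disagreement weights |i−j|/2 (linear) or
    ((i−j)/2)² (quadratic) via kappa_w = 1 − Σw·p_obs / Σw·p_exp.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score arrays must be 1-D and aligned")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 rating units")
    confusion = np.zeros((N_CATEGORIES, N_CATEGORIES))
    np.add.at(confusion, (a, b), 1.0)
    p_obs = confusion / n
    marg_a = p_obs.sum(axis=1)
    marg_b = p_obs.sum(axis=0)
    p_exp = np.outer(marg_a, marg_b)
    # the weights are symmetric, so symmetrising changes nothing
    # mathematically but makes kappa(a,b) == kappa(b,a) bit-for-bit
    p_obs = (p_obs + p_obs.T) / 2.0
    p_exp = (p_exp + p_exp.T) / 2.0
    w = _disagreement_weights(scheme)
    expected_disagreement = float((w * p_exp).sum())
    if expected_disagreement == 0.0:
        raise UndefinedKappaError(
            "both raters are constant in the same category; kappa undefined")
    observed_disagreement = float((w * p_obs).sum())
    return 1.0 - observed_disagreement / expected_disagreement


def _aligned(a: RatingSet, b: RatingSet) -> tuple[list[RatingKey], np.ndarray, np.ndarray]:
    keys_a, keys_b = set(a.ratings), set(b.ratings)
    if keys_a != keys_b:
        diff = sorted(keys_a ^ keys_b)
        raise ValueError(f"rating sets cover different units: {diff}")
    keys = sorted(keys_a)
    sa = np.array([a.ratings[k] for k in keys], dtype=int)
    sb = np.array([b.ratings[k] for k in keys], dtype=int)
    return keys, sa, sb


def cohen_kappa(a: RatingSet, b: RatingSet) -> float:
    """Unweighted Cohen's kappa over the shared rating units."""
    _, sa, sb = _aligned(a, b)
    return kappa_from_scores(sa, sb)


def weighted_kappa(
    a: RatingSet,
    b: RatingSet,
    scheme: Literal["linear", "quadratic"] = "linear",
) -> float:
    """Weighted kappa for the ordinal 0/1/2 scale.

    Adjacent-category disagreement costs half (linear) or a quarter
    (quadratic) of an extreme 0↔2 disagreement.
    """
    _, sa, sb = _aligned(a, b)
    return kappa_from_scores(sa, sb, scheme=scheme)


def kappa_report(
    a: RatingSet,
    b: RatingSet,
    scheme: Optional[str] = None,
) -> KappaResult:
    """Kappa together with p_o, p_e, unit count, and disagreeing keys."""
    keys, sa, sb = _aligned(a, b)
    kappa = kappa_from_scores(sa, sb, scheme=scheme)
    p_o = float(np.mean(sa == sb))
    confusion = np.zeros((N_CATEGORIES, N_CATEGORIES))
    np.add.at(confusion, (sa, sb), 1.0)
    p_obs = confusion / sa.size
    p_e = float(np.sum(p_obs.sum(axis=1) * p_obs.sum(axis=0)))
    disagreements = tuple(k for k, x, y in zip(keys, sa, sb) if x != y)
    return KappaResult(kappa=kappa, p_o=p_o, p_e=p_e, n_units=sa.size,
                       disagreements=disagreements)


def consensus(
    a: RatingSet,
    b: RatingSet,
    resolutions: Mapping[RatingKey, int],
) -> RatingSet:
    """Resolve rater disagreements into a consensus rating set.

    ``resolutions`` must cover exactly the keys on which the raters
    disagree; agreeing keys are copied through unchanged.
    """
    keys, sa, sb = _aligned(a, b)
    disagreeing = {k for k, x, y in zip(keys, sa, sb) if x != y}
    extra = sorted(set(resolutions) - disagreeing)
    missing = sorted(disagreeing - set(resolutions))
    if extra:
        raise ValueError(f"resolutions supplied for agreeing units: {extra}")
    if missing:
        raise ValueError(f"resolutions missing for disagreeing units: {missing}")
    merged = {}
    for key in keys:
        merged[key] = resolutions[key] if key in disagreeing else a.ratings[key]
    return RatingSet(rater_id="consensus", ratings=merged)


def read_ratings_csv(path, rater_id: Optional[str] = None) -> RatingSet:
    """Read one rater's item-level scores.

    Columns: rater_id, agent_id, item_id, score.  If the file contains
    several raters, ``rater_id`` selects one.
    """
    frame = pd.read_csv(path)
    required = {"rater_id", "agent_id", "item_id", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
    raters = frame["rater_id"].unique().tolist()
    if rater_id is None:
        if len(raters) != 1:
            raise ValueError(
                f"file contains raters {raters}; pass rater_id to choose one")
        rater_id = raters[0]
    sub = frame[frame["rater_id"] == rater_id]
    if sub.empty:
        raise ValueError(f"no rows for rater {rater_id!r} (found {raters})")
    ratings: dict[RatingKey, int] = {}
    for row in sub.itertuples(index=False):
        key = (str(row.agent_id), str(row.item_id))
        if key in ratings:
            raise ValueError(f"duplicate rating unit {key} for rater {rater_id!r}")
        ratings[key] = int(row.score)
    return RatingSet(rater_id=str(rater_id), ratings=ratings)


def write_ratings_csv(rating_set: RatingSet, path) -> None:
    """Write a rating set in the ratings CSV layout."""
    rows = [
        {"rater_id": rating_set.rater_id, "agent_id": agent, "item_id": item,
         "score": score}
        for (agent, item), score in sorted(rating_set.ratings.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
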