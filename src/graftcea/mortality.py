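"""Life-table handling and construction of year-indexed death probabilities.

Background mortality comes from a national life table (annual death
probability ``qx`` by single year of age).  The cohort enters at a mean
starting age and each model year looks up the ``qx`` at the integer age the
cohort has reached; above age 100 death is certain, which terminates the
cohort.

A year spent in a revision state (the initial revision or a re-revision)
carries extra surgical risk concentrated in the first 90 days after surgery.
The convention used here is that the perioperative window *replaces*
background mortality for its duration: the annual survival of a revision-state
year is the product of surviving the 90-day surgical window and surviving the
remaining 275 days of background hazard,

    1 - q_rev = (1 - p90) * (1 - q_bg)^(275/365)

This replacement convention is what allows revision-state mortality to drop
below background mortality at high ages, as observed in the published
schedules (0.306 vs 0.364 at the oldest model age).  The window length is
configurable.

The default 90-day surgical mortality is age-dependent: it is anchored by
inverting the published blended schedule endpoints (0.047 against background
0.0195 at age 71, and 0.306 against 0.364 at age 100) and linearly
interpolating between the two anchors.  A constant or user-supplied
age-indexed value can be used instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LifeTable",
    "MortalitySchedule",
    "CoverageError",
    "schedule_from_lifetable",
    "blend_perioperative",
    "invert_perioperative",
    "default_perioperative_90day",
    "build_mortality_schedule",
    "years_to_age_limit",
    "MAX_MODEL_AGE",
    "PERIOPERATIVE_WINDOW_DAYS",
]

#: Age above which the model forces the annual death probability to 1.
MAX_MODEL_AGE = 100

#: Default length of the elevated-risk surgical window, in days.
PERIOPERATIVE_WINDOW_DAYS = 90

_DAYS_PER_YEAR = 365


class CoverageError(ValueError):
    """The life table does not cover an age the model needs."""


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities (``qx``), single-year ages.

    Ages must be contiguous integers; probabilities must lie in [0, 1].
    Lookups above :data:`MAX_MODEL_AGE` return 1 regardless of table content.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("ages and qx must be equal-length 1-D sequences")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("life-table ages must be contiguous and unique")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life-table qx values must be in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age: float) -> float:
        """Annual death probability at integer age ``floor(age)``.

        Ages above :data:`MAX_MODEL_AGE` map to certain death.  Ages the
        table does not cover raise :class:`CoverageError`.
        """
        a = math.floor(age)
        if a > MAX_MODEL_AGE:
            return 1.0
        if a < self.age_min or a > self.age_max:
            raise CoverageError(
                f"life table covers ages {self.age_min}..{self.age_max}, needed {a}"
            )
        return float(self.qx[a - self.age_min])

    def q_interp(self, age: float) -> float:
        """Annual death probability linearly interpolated at fractional age."""
        if age > MAX_MODEL_AGE:
            return 1.0
        lo, hi = math.floor(age), math.ceil(age)
        if lo < self.age_min or hi > self.age_max:
            raise CoverageError(
                f"life table covers ages {self.age_min}..{self.age_max}, needed {age}"
            )
        if lo == hi:
            return float(self.qx[lo - self.age_min])
        w = age - lo
        return float((1 - w) * self.qx[lo - self.age_min] + w * self.qx[hi - self.age_min])

    # -- I/O --------------------------------------------------------------

    @classmethod
    def read_csv(cls, path: str | Path) -> "LifeTable":
        """Read an ``age,qx`` delimited file (national life-table style)."""
        import pandas as pd

        table = pd.read_csv(path)
        for column in ("age", "qx"):
            if column not in table.columns:
                raise ValueError(f"life-table file {path} must have columns 'age' and 'qx'")
        return cls(ages=table["age"].to_numpy(), qx=table["qx"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)


def years_to_age_limit(starting_age: float, limit: int = MAX_MODEL_AGE) -> int:
    """Number of one-year cycles until cohort age exceeds ``limit``.

    Cycle ``k`` (1-based) is lived at integer age ``floor(starting_age+k-1)``;
    the count returned is the number of cycles with that age still <= limit.
    """
    horizon = int(math.floor(limit + 1 - starting_age - 1e-9)) + 1
    return max(horizon, 1)


def schedule_from_lifetable(
    lifetable: LifeTable,
    starting_age: float,
    horizon: int,
    *,
    interpolate: bool = False,
) -> np.ndarray:
    """Background (post-revision) death probability for model years 1..horizon.

    Year ``k`` uses the life-table probability at age
    ``floor(starting_age + k - 1)`` (or the linearly interpolated value at the
    fractional age when ``interpolate=True``); ages above 100 map to 1.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    lookup = lifetable.q_interp if interpolate else lifetable.q_at
    return np.array([lookup(starting_age + k - 1) for k in range(1, horizon + 1)])


def blend_perioperative(
    p_background: float,
    p_surgical_90d: float,
    *,
    window_days: int = PERIOPERATIVE_WINDOW_DAYS,
) -> float:
    """Annual death probability of a revision-state year.

    The surgical window of ``window_days`` replaces background mortality; the
    rest of the year runs at the background hazard.
    """
    for name, p in (("p_background", p_background), ("p_surgical_90d", p_surgical_90d)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p!r}")
    rest = (_DAYS_PER_YEAR - window_days) / _DAYS_PER_YEAR
    return 1.0 - (1.0 - p_surgical_90d) * (1.0 - p_background) ** rest


def invert_perioperative(
    p_combined: float,
    p_background: float,
    *,
    window_days: int = PERIOPERATIVE_WINDOW_DAYS,
) -> float:
    """Surgical-window mortality that blends back to ``p_combined``.

    Inverse of :func:`blend_perioperative` in its first argument.  If the
    combined probability is below the surgery-free floor (background-only
    exposure over the non-window part of the year) the result would be
    negative; it is clamped to 0 with a warning.
    """
    for name, p in (("p_combined", p_combined), ("p_background", p_background)):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {p!r}")
    rest = (_DAYS_PER_YEAR - window_days) / _DAYS_PER_YEAR
    survival_rest = (1.0 - p_background) ** rest
    p90 = 1.0 - (1.0 - p_combined) / survival_rest
    if p90 < 0.0:
        warnings.warn(
            "combined mortality below the surgery-free floor; clamping 90-day "
            "surgical mortality to 0",
            stacklevel=2,
        )
        return 0.0
    return min(p90, 1.0)


# Published blended revision-state schedule endpoints and the background
# probabilities they pair with, used to anchor the default age profile of
# 90-day surgical mortality.
_ANCHOR_YOUNG_AGE, _ANCHOR_OLD_AGE = 71, 100
_P90_YOUNG = invert_perioperative(0.047, 0.0195)  # ~0.0327
_P90_OLD = invert_perioperative(0.306, 0.364)  # ~0.0239


def default_perioperative_90day(age: float) -> float:
    """Default 90-day surgical mortality at a given age.

    Linear interpolation between the two anchor ages (71 and 100), constant
    outside that range.  The anchors are derived by inverting the published
    blended revision-state schedule endpoints against background mortality.
    """
    return float(
        np.interp(age, [_ANCHOR_YOUNG_AGE, _ANCHOR_OLD_AGE], [_P90_YOUNG, _P90_OLD])
    )


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-model-year death probabilities for the two living states."""

    post_revision_death: np.ndarray
    revision_state_death: np.ndarray

    def __post_init__(self) -> None:
        post = np.asarray(self.post_revision_death, dtype=float)
        rev = np.asarray(self.revision_state_death, dtype=float)
        if post.shape != rev.shape or post.ndim != 1:
            raise ValueError("schedules must be equal-length 1-D arrays")
        for name, arr in (("post_revision_death", post), ("revision_state_death", rev)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} values must be in [0, 1]")
        object.__setattr__(self, "post_revision_death", post)
        object.__setattr__(self, "revision_state_death", rev)

    @property
    def horizon(self) -> int:
        return int(self.post_revision_death.size)


def build_mortality_schedule(
    lifetable: LifeTable,
    starting_age: float,
    horizon: int | None = None,
    *,
    p_surgical_90d: float | Callable[[float], float] | Sequence[float] | None = None,
    window_days: int = PERIOPERATIVE_WINDOW_DAYS,
    interpolate: bool = False,
) -> MortalitySchedule:
    """Build both death-probability schedules for a cohort.

    Parameters
    ----------
    lifetable : LifeTable
        Background mortality source.
    starting_age : float
        Cohort mean age at the initial revision.
    horizon : int, optional
        Number of model years; defaults to the number of years until cohort
        age exceeds 100.
    p_surgical_90d : float, callable or sequence, optional
        90-day surgical mortality — a constant, a function of age, or one
        value per model year.  Defaults to the age-interpolated profile of
        :func:`default_perioperative_90day`.
    """
    if horizon is None:
        horizon = years_to_age_limit(starting_age)
    post = schedule_from_lifetable(lifetable, starting_age, horizon, interpolate=interpolate)
    ages = np.floor(starting_age + np.arange(horizon))
    if p_surgical_90d is None:
        p90 = np.array([default_perioperative_90day(a) for a in ages])
    elif callable(p_surgical_90d):
        p90 = np.array([float(p_surgical_90d(a)) for a in ages])
    elif np.isscalar(p_surgical_90d):
        p90 = np.full(horizon, float(p_surgical_90d))
    else:
        p90 = np.asarray(p_surgical_90d, dtype=float)
        if p90.shape != (horizon,):
            raise ValueError("per-year p_surgical_90d must have one value per model year")
    revision = np.array(
        [
            1.0 if q >= 1.0 else blend_perioperative(q, s, window_days=window_days)
            for q, s in zip(post, p90)
        ]
    )
    return MortalitySchedule(post_revision_death=post, revision_state_death=revision)
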