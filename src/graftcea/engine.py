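"""Yearly-cycle Markov cohort evaluation of one graft strategy.

Three health states: ``post_revision`` (living with a functioning revision),
``re_revision`` (undergoing a further revision this year) and ``death``
(absorbing).  The cohort enters through a decision-tree root at year 0, where
everyone has their first revision surgery: the full cohort incurs the
per-surgery cost and accrues the revision-year utility.  Because a revision
year — first or repeat — carries the same perioperative mortality and
utility, year 0 is modelled as occupancy of the re-revision state, so the
transition out of year 0 uses the revision-state death probability (the
elevated perioperative value).  From year 1 onward occupancy propagates
through year-specific 3x3 transition matrices, and each living state accrues
its yearly cost and utility, discounted at a constant annual rate.

No half-cycle correction is applied by default: transitions happen at cycle
end and rewards attach to the state occupied during the cycle.  A standard
half-cycle correction (trapezoidal occupancy averaging) is available via a
flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mortality import MortalitySchedule
from .parameters import ModelSettings, StrategyParameters, total_revision_surgery_cost

__all__ = [
    "STATES",
    "TransitionMatrixSequence",
    "CohortTrace",
    "InfeasibleTransitionError",
    "build_matrices",
    "run_cohort",
    "discount_factor",
]

#: State order used throughout: columns/rows of every transition matrix.
STATES = ("post_revision", "re_revision", "death")
_POST, _REV, _DEATH = 0, 1, 2


class InfeasibleTransitionError(ValueError):
    """A transition row would go negative for the given parameters."""


@dataclass(frozen=True)
class TransitionMatrixSequence:
    """One 3x3 transition matrix per model year, rows indexed by STATES."""

    matrices: np.ndarray  # shape (horizon, 3, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (3, 3):
            raise ValueError("matrices must have shape (horizon, 3, 3)")
        if np.any((m < 0) | (m > 1)):
            raise ValueError("transition probabilities must be in [0, 1]")
        if not np.allclose(m.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("every transition row must sum to 1")
        if not (np.all(m[:, _DEATH, _DEATH] == 1.0) and np.all(m[:, _DEATH, :_DEATH] == 0.0)):
            raise ValueError("death must be absorbing")
        object.__setattr__(self, "matrices", m)

    @property
    def horizon(self) -> int:
        return int(self.matrices.shape[0])


def build_matrices(
    strategy: StrategyParameters, schedule: MortalitySchedule
) -> TransitionMatrixSequence:
    """Assemble the year-specific transition matrices for one strategy.

    From ``post_revision`` the yearly exits are re-revision (constant annual
    probability) and death at the background rate; remaining in place is the
    forced complement.  From ``re_revision`` the same re-revision probability
    applies but death uses the perioperative-blended rate.  A year whose death
    probability is 1 (cohort older than 100) is fully absorbing.  Any other
    combination that would drive the stay-probability negative raises
    :class:`InfeasibleTransitionError` naming the model year.
    """
    p_rev = strategy.annual_re_revision_probability
    horizon = schedule.horizon
    matrices = np.zeros((horizon, 3, 3))
    matrices[:, _DEATH, _DEATH] = 1.0
    for k in range(horizon):
        for state, p_death in (
            (_POST, schedule.post_revision_death[k]),
            (_REV, schedule.revision_state_death[k]),
        ):
            if p_death >= 1.0:
                matrices[k, state, _DEATH] = 1.0
                continue
            stay = 1.0 - p_rev - p_death
            if stay < -1e-12:
                raise InfeasibleTransitionError(
                    f"year {k + 1}, state {STATES[state]!r}: re-revision probability "
                    f"{p_rev:.4g} + death probability {p_death:.4g} exceeds 1"
                )
            matrices[k, state, _POST] = max(stay, 0.0)
            matrices[k, state, _REV] = p_rev
            matrices[k, state, _DEATH] = p_death
    return TransitionMatrixSequence(matrices)


def discount_factor(year: int, rate: float) -> float:
    """Present-value factor ``1 / (1 + rate)**year``; year 0 maps to 1."""
    if year < 0:
        raise ValueError("year must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return (1.0 + rate) ** -year


@dataclass(frozen=True)
class CohortTrace:
    """Per-year state occupancy and discounted accruals of one strategy arm.

    Row 0 is the surgery year (decision-tree entry); rows 1..horizon are the
    Markov cycles.  ``occupancy`` rows are proportions over STATES and sum
    to 1.
    """

    occupancy: np.ndarray  # (horizon + 1, 3)
    discounted_cost_per_year: np.ndarray
    discounted_qaly_per_year: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.discounted_cost_per_year.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.discounted_qaly_per_year.sum())

    def to_frame(self):
        """Trace as a DataFrame (year, occupancy x3, discounted accruals)."""
        import pandas as pd

        frame = pd.DataFrame(self.occupancy, columns=list(STATES))
        frame.insert(0, "year", np.arange(self.occupancy.shape[0]))
        frame["discounted_cost"] = self.discounted_cost_per_year
        frame["discounted_qaly"] = self.discounted_qaly_per_year
        return frame


def run_cohort(
    strategy: StrategyParameters,
    matrices: TransitionMatrixSequence,
    settings: ModelSettings,
    *,
    half_cycle: bool = False,
    year0_utility: bool = True,
) -> CohortTrace:
    """Propagate the cohort and accrue discounted costs and QALYs.

    Year 0: the whole cohort undergoes its first revision (full surgery cost,
    revision-year utility, no discounting).  Years 1..horizon: occupancy
    propagates through that year's matrix; post-revision occupancy accrues
    the annual care cost and post-revision utility, re-revision occupancy
    accrues the full surgery cost and revision-year utility, discounted at
    ``1/(1+r)^year``.

    ``year0_utility=False`` suppresses the year-0 utility accrual (the
    alternative decision-tree convention).  ``half_cycle=True`` averages
    adjacent-cycle occupancy when accruing rewards.
    """
    horizon = matrices.horizon
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    rate = settings.discount_rate
    surgery_cost = total_revision_surgery_cost(strategy)
    care_cost = strategy.annual_post_revision_care_cost
    u_post = strategy.utility_post_revision
    u_rev = strategy.utility_re_revision

    occupancy = np.zeros((horizon + 1, 3))
    occupancy[0, _REV] = 1.0  # surgery year occupies the revision state
    cost = np.zeros(horizon + 1)
    qaly = np.zeros(horizon + 1)
    cost[0] = surgery_cost
    qaly[0] = u_rev if year0_utility else 0.0

    for year in range(1, horizon + 1):
        occupancy[year] = occupancy[year - 1] @ matrices.matrices[year - 1]
        occ = occupancy[year]
        if half_cycle:
            occ = 0.5 * (occupancy[year - 1] + occupancy[year])
        factor = discount_factor(year, rate)
        cost[year] = factor * (occ[_POST] * care_cost + occ[_REV] * surgery_cost)
        qaly[year] = factor * (occ[_POST] * u_post + occ[_REV] * u_rev)

    return CohortTrace(
        occupancy=occupancy,
        discounted_cost_per_year=cost,
        discounted_qaly_per_year=qaly,
    )
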