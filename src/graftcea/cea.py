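"""Pairwise cost-effectiveness statistics and threshold searches.

The decision rule compared here is the incremental cost-effectiveness ratio

    ICER = (C1 - C0) / (E1 - E0)

between the intervention (decellularised allograft, subscript 1) and the
comparator (fresh-frozen allograft, subscript 0), judged against a
willingness-to-pay (WTP) threshold per QALY (UK guidance band 20,000-30,000
GBP/QALY).  Dominance short-circuits the ratio: an intervention that is
cheaper and more effective dominates; one that is dearer and less effective
is dominated.  Net monetary benefit (NMB = WTP x dE - dC) linearises the same
rule and underpins the acceptability curves in :mod:`graftcea.uncertainty`.

Break-even searches invert the full model numerically: the graft price (or
the re-revision probability) at which the ICER equals a given WTP, found by
bracketed root-finding on repeated whole-model evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .engine import CohortTrace, build_matrices, run_cohort
from .mortality import LifeTable, build_mortality_schedule
from .parameters import ModelSettings, ParameterBundle, StrategyParameters

__all__ = [
    "CEResult",
    "WTPThreshold",
    "PairEvaluation",
    "ThresholdError",
    "icer",
    "net_monetary_benefit",
    "run_strategy",
    "evaluate",
    "threshold_price",
    "threshold_revision_rate",
    "DEFAULT_WTP",
]

#: Upper end of the UK guidance willingness-to-pay band (GBP per QALY).
DEFAULT_WTP = 30_000.0


class ThresholdError(RuntimeError):
    """A break-even search found no crossing in its bracket."""


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness to pay per QALY, in GBP."""

    willingness_to_pay: float

    def __post_init__(self) -> None:
        if self.willingness_to_pay < 0:
            raise ValueError("willingness_to_pay must be >= 0")


@dataclass(frozen=True)
class CEResult:
    """Paired strategy outcomes with incremental statistics.

    ``icer`` is ``None`` when the strategies are equally effective (the
    ratio is undefined; reports print a dash).
    """

    cost_intervention: float
    effect_intervention: float
    cost_comparator: float
    effect_comparator: float

    @property
    def incremental_cost(self) -> float:
        return self.cost_intervention - self.cost_comparator

    @property
    def incremental_effect(self) -> float:
        return self.effect_intervention - self.effect_comparator

    @property
    def icer(self) -> float | None:
        if self.incremental_effect == 0.0:
            return None
        return self.incremental_cost / self.incremental_effect

    @property
    def dominance_label(self) -> str:
        d_cost, d_effect = self.incremental_cost, self.incremental_effect
        if d_effect == 0.0:
            return "equal_effect"
        if d_cost <= 0.0 and d_effect > 0.0:
            return "intervention_dominant"
        if d_cost >= 0.0 and d_effect < 0.0:
            return "comparator_dominant"
        return "trade_off"

    def favoured(self, wtp: float = DEFAULT_WTP) -> str:
        """Which strategy the NMB rule prefers at the given WTP (ties -> comparator)."""
        return "intervention" if net_monetary_benefit(self, wtp) > 0 else "comparator"


def icer(
    cost_intervention: float,
    effect_intervention: float,
    cost_comparator: float,
    effect_comparator: float,
) -> CEResult:
    """Incremental comparison of two strategies (intervention vs comparator)."""
    return CEResult(
        cost_intervention=float(cost_intervention),
        effect_intervention=float(effect_intervention),
        cost_comparator=float(cost_comparator),
        effect_comparator=float(effect_comparator),
    )


def net_monetary_benefit(result: CEResult, wtp: float | WTPThreshold) -> float:
    """NMB of the intervention: WTP x incremental effect - incremental cost."""
    if isinstance(wtp, WTPThreshold):
        wtp = wtp.willingness_to_pay
    return wtp * result.incremental_effect - result.incremental_cost


@dataclass(frozen=True)
class PairEvaluation:
    """Full two-arm model run: per-arm traces plus the incremental result."""

    intervention: CohortTrace
    comparator: CohortTrace
    result: CEResult


def run_strategy(
    strategy: StrategyParameters,
    settings: ModelSettings,
    lifetable: LifeTable,
    **conventions,
) -> CohortTrace:
    """Evaluate one arm: mortality schedule, matrices, cohort propagation."""
    schedule = build_mortality_schedule(
        lifetable, settings.starting_age, settings.horizon_years
    )
    matrices = build_matrices(strategy, schedule)
    return run_cohort(strategy, matrices, settings, **conventions)


def evaluate(
    bundle: ParameterBundle, lifetable: LifeTable, **conventions
) -> PairEvaluation:
    """Run both arms of a bundle and compare them incrementally."""
    intervention = run_strategy(bundle.decellularised, bundle.settings, lifetable, **conventions)
    comparator = run_strategy(bundle.fresh_frozen, bundle.settings, lifetable, **conventions)
    result = icer(
        intervention.total_cost,
        intervention.total_qaly,
        comparator.total_cost,
        comparator.total_qaly,
    )
    return PairEvaluation(intervention=intervention, comparator=comparator, result=result)


def _icer_gap(value_setter, bundle, lifetable, wtp):
    def gap(x: float) -> float:
        result = evaluate(value_setter(bundle, x), lifetable).result
        if result.icer is None:
            raise ThresholdError("ICER undefined inside the search bracket (equal effects)")
        return result.icer - wtp
    return gap


def _bisect(gap, lo: float, hi: float, what: str) -> float:
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ThresholdError(
            f"no break-even {what} in bracket [{lo:.6g}, {hi:.6g}]: "
            f"ICER - WTP is {g_lo:.6g} at the lower end and {g_hi:.6g} at the upper end"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10, rtol=1e-14))


def threshold_price(
    bundle: ParameterBundle,
    lifetable: LifeTable,
    wtp: float | WTPThreshold = DEFAULT_WTP,
    *,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Decellularised graft price per head at which the ICER equals the WTP.

    Bisection over the price (default bracket: 0 to the current price), over
    which the ICER is decreasing.  The returned price satisfies
    ``|ICER - WTP| < 1`` GBP/QALY on re-evaluation.
    """
    if isinstance(wtp, WTPThreshold):
        wtp = wtp.willingness_to_pay
    if bracket is None:
        bracket = (0.0, bundle.decellularised.graft_price_per_head)

    def set_price(b: ParameterBundle, price: float) -> ParameterBundle:
        return replace(b, decellularised=replace(b.decellularised, graft_price_per_head=price))

    gap = _icer_gap(set_price, bundle, lifetable, wtp)
    root = _bisect(gap, *bracket, what="price")
    if abs(gap(root)) >= 1.0:
        raise ThresholdError("price search did not converge to within 1 GBP/QALY")
    return root


def threshold_revision_rate(
    bundle: ParameterBundle,
    lifetable: LifeTable,
    wtp: float | WTPThreshold = DEFAULT_WTP,
    *,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Decellularised annual re-revision probability at which ICER equals WTP.

    The ICER increases with the intervention's re-revision probability (less
    health gain for the same cost premium).  Returned as an annual
    probability; multiply by 10,000 for a per-10,000-patients-per-year rate.
    Raises :class:`ThresholdError` with a diagnostic when no crossing exists
    in the bracket (e.g. the comparator probability as upper end makes the
    effects equal and the ICER undefined).
    """
    if isinstance(wtp, WTPThreshold):
        wtp = wtp.willingness_to_pay
    if bracket is None:
        upper = bundle.fresh_frozen.annual_re_revision_probability
        bracket = (0.0, max(upper - 1e-9, 1e-9))

    def set_rate(b: ParameterBundle, p: float) -> ParameterBundle:
        return replace(
            b, decellularised=replace(b.decellularised, annual_re_revision_probability=p)
        )

    gap = _icer_gap(set_rate, bundle, lifetable, wtp)
    root = _bisect(gap, *bracket, what="re-revision probability")
    if abs(gap(root)) >= 1.0:
        raise ThresholdError("rate search did not converge to within 1 GBP/QALY")
    return root
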