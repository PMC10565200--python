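"""Model inputs and cost arithmetic for the bone-graft comparison.

The package compares two acetabular impaction bone grafting (IBG) strategies
used during revision hip arthroplasty (RHA): a decellularised femoral-head
allograft (the intervention) and the standard fresh-frozen allograft (the
comparator).  This module holds the strongly-typed inputs of that comparison —
revision-rate evidence, the manufacturing cost build-up of a decellularised
graft, per-strategy cost/utility parameters and global model settings — plus
the small pieces of arithmetic that turn them into model-ready quantities:

* conversion of a cumulative revision fraction observed over a follow-up
  period into an annual transition probability via a constant-hazard
  (exponential) assumption,
* the selling price implied by a component cost breakdown under a fixed
  sales-and-distribution fraction and operating margin,
* per-surgery graft cost (price per femoral head x heads used per procedure)
  and the total cost of one revision surgery.

All monetary amounts are 2022 GBP and carried at full floating precision;
rounding to whole pounds happens only in report layers.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any, Mapping

__all__ = [
    "ConfigurationError",
    "RevisionEvidence",
    "GraftCostBreakdown",
    "StrategyParameters",
    "ModelSettings",
    "ParameterBundle",
    "annual_probability_from_cumulative",
    "selling_price",
    "per_surgery_graft_cost",
    "total_revision_surgery_cost",
    "DEFAULT_HEADS_PER_SURGERY",
    "DEFAULT_SURGERY_BASE_COST",
]

#: Mean number of femoral-head grafts consumed per revision surgery.
DEFAULT_HEADS_PER_SURGERY = 2.43

#: Cost of the revision procedure itself (theatre, inpatient stay, implants),
#: excluding the graft.  Back-computed from the published per-surgery totals
#: (overall decellularised-arm surgery cost minus 2.43 heads at the graft
#: selling price); documented as a derived default and overridable.
DEFAULT_SURGERY_BASE_COST = 14_618.05


class ConfigurationError(ValueError):
    """Raised when supplied parameters cannot form a coherent model."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigurationError(message)


@dataclass(frozen=True)
class RevisionEvidence:
    """Cumulative re-revision evidence from a clinical follow-up study.

    Parameters
    ----------
    cumulative_revision_fraction : float
        Proportion of implants revised by the end of follow-up, in ``[0, 1)``.
    followup_years : float
        Length of the follow-up period in years, strictly positive.
    """

    cumulative_revision_fraction: float
    followup_years: float

    def __post_init__(self) -> None:
        f = self.cumulative_revision_fraction
        _check(
            0.0 <= f < 1.0,
            f"cumulative_revision_fraction must be in [0, 1), got {f!r}",
        )
        _check(
            self.followup_years > 0,
            f"followup_years must be positive, got {self.followup_years!r}",
        )


def annual_probability_from_cumulative(
    evidence: RevisionEvidence,
) -> float:
    """Annual transition probability implied by cumulative follow-up evidence.

    Assumes a constant revision hazard: the cumulative fraction ``f`` over
    ``t`` years implies a rate ``r = -ln(1 - f) / t``, which converts to the
    one-year transition probability ``p = 1 - exp(-r)``.

    Returns a probability in ``[0, 1)``.  For a one-year follow-up the
    round-trip is exact: the cumulative fraction is returned unchanged.
    """
    if not isinstance(evidence, RevisionEvidence):
        evidence = RevisionEvidence(*evidence)
    rate = -math.log1p(-evidence.cumulative_revision_fraction) / evidence.followup_years
    return -math.expm1(-rate)


#: Field names of the seven production-cost components, in build-up order.
COST_COMPONENTS = (
    "tissue",
    "reagents",
    "labour",
    "lab_rent",
    "consumables_packaging",
    "amortised_investment",
    "indirect_overheads",
)


@dataclass(frozen=True)
class GraftCostBreakdown:
    """Per-graft manufacturing cost build-up for a decellularised allograft.

    The seven production components are absolute GBP amounts per femoral
    head.  Sales & distribution and the operating margin are modelled as
    fixed fractions of the final selling price, so the selling price solves

        S = production_cost / (1 - sales_distribution_fraction - operating_margin)
    """

    tissue: float = 0.0
    reagents: float = 0.0
    labour: float = 0.0
    lab_rent: float = 0.0
    consumables_packaging: float = 0.0
    amortised_investment: float = 0.0
    indirect_overheads: float = 0.0
    sales_distribution_fraction: float = 0.5
    operating_margin: float = 0.194

    def __post_init__(self) -> None:
        for name in COST_COMPONENTS:
            _check(getattr(self, name) >= 0, f"cost component {name!r} must be >= 0")
        _check(
            self.sales_distribution_fraction >= 0 and self.operating_margin >= 0,
            "price fractions must be >= 0",
        )
        _check(
            self.sales_distribution_fraction + self.operating_margin < 1.0,
            "sales_distribution_fraction + operating_margin must be < 1",
        )

    @property
    def production_cost(self) -> float:
        """Sum of the seven production components (GBP per head)."""
        return float(sum(getattr(self, name) for name in COST_COMPONENTS))

    @classmethod
    def read_csv(cls, path: str | Path, **fractions: float) -> "GraftCostBreakdown":
        """Load the component costs from a two-column ``component,gbp`` file."""
        import pandas as pd

        table = pd.read_csv(path, comment="#")
        _check(
            table.shape[1] >= 2,
            f"breakdown file {path} must have two columns (component, GBP)",
        )
        values: dict[str, float] = {}
        for component, amount in zip(table.iloc[:, 0], table.iloc[:, 1]):
            key = str(component).strip()
            _check(key in COST_COMPONENTS, f"unknown cost component {key!r} in {path}")
            values[key] = float(amount)
        return cls(**values, **fractions)


def selling_price(breakdown: GraftCostBreakdown) -> float:
    """Selling price implied by the cost build-up (GBP per femoral head)."""
    denominator = 1.0 - breakdown.sales_distribution_fraction - breakdown.operating_margin
    _check(denominator > 0, "price fractions leave no room for production cost")
    return breakdown.production_cost / denominator


def per_surgery_graft_cost(price_per_head: float, heads: float = DEFAULT_HEADS_PER_SURGERY) -> float:
    """Graft cost of one revision surgery: price per head x heads used."""
    _check(price_per_head >= 0, "price_per_head must be >= 0")
    _check(heads >= 0, "heads must be >= 0")
    return price_per_head * heads


@dataclass(frozen=True)
class StrategyParameters:
    """All per-strategy model inputs for one graft choice.

    ``annual_re_revision_probability`` is the yearly probability of moving
    from the post-revision state into a further revision; utilities are
    QALY weights for a year spent in each living state.
    """

    graft_price_per_head: float
    annual_re_revision_probability: float
    heads_per_surgery: float = DEFAULT_HEADS_PER_SURGERY
    surgery_base_cost: float = DEFAULT_SURGERY_BASE_COST
    annual_post_revision_care_cost: float = 54.19
    utility_post_revision: float = 0.685
    utility_re_revision: float = 0.397

    def __post_init__(self) -> None:
        for name in (
            "graft_price_per_head",
            "heads_per_surgery",
            "surgery_base_cost",
            "annual_post_revision_care_cost",
        ):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("utility_post_revision", "utility_re_revision"):
            u = getattr(self, name)
            _check(0.0 <= u <= 1.0, f"{name} must be in [0, 1], got {u!r}")
        p = self.annual_re_revision_probability
        _check(0.0 <= p <= 1.0, f"annual_re_revision_probability must be in [0, 1], got {p!r}")


def total_revision_surgery_cost(strategy: StrategyParameters) -> float:
    """Total cost of one revision surgery: base procedure cost plus grafts."""
    return strategy.surgery_base_cost + per_surgery_graft_cost(
        strategy.graft_price_per_head, strategy.heads_per_surgery
    )


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings shared by both strategies.

    ``horizon_years=None`` lets the engine run until the cohort ages past
    100, at which point background mortality becomes certain; an explicit
    horizon overrides that.  Only one-year cycles are supported.
    """

    starting_age: float = 71.7
    discount_rate: float = 0.035
    horizon_years: int | None = None
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        _check(self.starting_age > 0, "starting_age must be positive")
        _check(self.discount_rate >= 0, "discount_rate must be >= 0")
        if self.horizon_years is not None:
            _check(
                int(self.horizon_years) == self.horizon_years and self.horizon_years >= 1,
                "horizon_years must be a positive integer or None",
            )
        _check(self.cycle_length == 1.0, "only one-year cycles are supported")


@dataclass(frozen=True)
class ParameterBundle:
    """A fully resolved pair of strategies plus shared settings."""

    settings: ModelSettings
    decellularised: StrategyParameters
    fresh_frozen: StrategyParameters

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "settings": asdict(self.settings),
            "strategies": {
                "decellularised": asdict(self.decellularised),
                "fresh_frozen": asdict(self.fresh_frozen),
            },
        }

    @classmethod
    def from_config(cls, config: Mapping[str, Any]) -> "ParameterBundle":
        """Build a bundle from a hierarchical config mapping.

        Recognised sections::

            settings                 -> ModelSettings fields
            strategies.decellularised / strategies.fresh_frozen
                                     -> StrategyParameters fields (partial OK)
            costing                  -> GraftCostBreakdown fields; supplies the
                                        decellularised price (selling price) and
                                        the fresh-frozen price (tissue cost)
                                        when not given explicitly
            evidence.<strategy>      -> RevisionEvidence fields; supplies
                                        annual_re_revision_probability when not
                                        given explicitly

        Raises :class:`ConfigurationError` naming the offending dotted field.
        """
        unknown = set(config) - {"settings", "strategies", "costing", "evidence"}
        _check(not unknown, f"unknown config sections: {sorted(unknown)}")

        settings = _build("settings", ModelSettings, config.get("settings", {}))

        costing = config.get("costing")
        breakdown = None
        if costing is not None:
            breakdown = _build("costing", GraftCostBreakdown, costing)

        strategies_cfg = config.get("strategies", {})
        evidence_cfg = config.get("evidence", {})
        strategies: dict[str, StrategyParameters] = {}
        for name in ("decellularised", "fresh_frozen"):
            fields = dict(strategies_cfg.get(name, {}))
            if "graft_price_per_head" not in fields:
                _check(
                    breakdown is not None,
                    f"strategies.{name}.graft_price_per_head missing and no costing section given",
                )
                if name == "decellularised":
                    fields["graft_price_per_head"] = selling_price(breakdown)
                else:
                    # fresh-frozen grafts are bought at the tissue retrieval price
                    fields["graft_price_per_head"] = breakdown.tissue
            if "annual_re_revision_probability" not in fields:
                _check(
                    name in evidence_cfg,
                    f"strategies.{name}.annual_re_revision_probability missing "
                    f"and no evidence.{name} section given",
                )
                ev = _build(f"evidence.{name}", RevisionEvidence, evidence_cfg[name])
                fields["annual_re_revision_probability"] = annual_probability_from_cumulative(ev)
            strategies[name] = _build(f"strategies.{name}", StrategyParameters, fields)

        return cls(
            settings=settings,
            decellularised=strategies["decellularised"],
            fresh_frozen=strategies["fresh_frozen"],
        )

    @classmethod
    def read_json(cls, path: str | Path) -> "ParameterBundle":
        with open(path) as handle:
            try:
                config = json.load(handle)
            except json.JSONDecodeError as exc:
                raise ConfigurationError(f"config file {path} is not valid JSON: {exc}") from exc
        return cls.from_config(config)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def replace_settings(self, **changes: Any) -> "ParameterBundle":
        return replace(self, settings=replace(self.settings, **changes))


def _build(section: str, cls: type, fields: Mapping[str, Any]):
    """Instantiate a parameter dataclass, rewriting errors with dotted paths."""
    allowed = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
    unknown = set(fields) - allowed
    _check(not unknown, f"unknown field(s) in {section}: {sorted(unknown)}")
    try:
        return cls(**fields)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{section}: {exc}") from exc
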