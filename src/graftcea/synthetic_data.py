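"""Generators for every input the pipeline needs, with no downloads.

Three artefacts:

* a **synthetic national life table** — a Gompertz–Makeham hazard whose two
  Gompertz parameters are solved in closed form so the annual death
  probabilities hit the model's two anchor points exactly (q(71) = 0.0195 and
  q(100) = 0.364, the first- and last-year background mortality of a cohort
  starting at age 71.7).  The shape between and outside the anchors is
  synthetic: it is exponential-hazard growth plus a small age-independent
  Makeham term, not a reproduction of any published national table;

* a **reconstructed base-case parameter bundle** assembling the published
  point values: state utilities 0.397 (revision year) and 0.685
  (post-revision), decellularised graft selling price 10,040.72 GBP against
  the fresh-frozen tissue price 709.71 GBP, 2.43 heads per surgery, base
  surgical cost 14,618.05 GBP, 54.19 GBP/year post-revision care, 3.5%
  discounting, starting age 71.7.  The decellularised annual re-revision
  probability derives from 8% cumulative revisions over a 13-year follow-up
  (0.0064/year).  The fresh-frozen probability is not published as a point
  value; the packaged default is a calibrated cumulative-evidence pair chosen
  once so the deterministic model reproduces the published base-case
  incremental QALY gain (0.077) — it is a derived estimate, overridable like
  every other field;

* **PSA distribution specs** on the natural scale of each parameter (beta for
  utilities and probabilities, gamma for costs, truncated normal for age,
  71.7 +/- 11.16 years).

``write_fixtures`` materialises all of them as plain-text files that
round-trip through the package readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mortality import LifeTable
from .parameters import (
    DEFAULT_SURGERY_BASE_COST,
    GraftCostBreakdown,
    ModelSettings,
    ParameterBundle,
    RevisionEvidence,
    StrategyParameters,
    annual_probability_from_cumulative,
)
from .uncertainty import DistributionSpec, ScenarioSpec

__all__ = [
    "SyntheticLifeTableSpec",
    "make_lifetable",
    "lifetable_from_hazard",
    "make_base_case",
    "make_psa_specs",
    "make_scenarios",
    "write_fixtures",
    "TABLE_COST_BREAKDOWN",
    "DECELLULARISED_PRICE",
    "FRESH_FROZEN_PRICE",
    "DECELLULARISED_EVIDENCE",
    "FRESH_FROZEN_EVIDENCE",
]

#: Published per-head cost build-up of the decellularised graft.
TABLE_COST_BREAKDOWN = GraftCostBreakdown(
    tissue=709.71,
    reagents=557.56,
    labour=12.12,
    lab_rent=219.75,
    consumables_packaging=30.48,
    amortised_investment=7.18,
    indirect_overheads=1536.80,
    sales_distribution_fraction=0.5,
    operating_margin=0.194,
)

#: Published selling price per decellularised femoral head (GBP).
DECELLULARISED_PRICE = 10_040.72

#: Fresh-frozen graft price per head: the tissue retrieval price (GBP).
FRESH_FROZEN_PRICE = 709.71

#: 8% cumulative revisions over 13 years (demineralised-bone proxy study).
DECELLULARISED_EVIDENCE = RevisionEvidence(0.08, 13.0)

#: Calibrated stand-in for the unpublished fresh-frozen evidence: cumulative
#: fraction over a 10-year follow-up whose constant-hazard conversion makes
#: the deterministic model reproduce the published incremental QALY gain of
#: 0.077.  Derived, not published; override with real study data when
#: available.
FRESH_FROZEN_EVIDENCE = RevisionEvidence(0.2238, 10.0)


@dataclass(frozen=True)
class SyntheticLifeTableSpec:
    """Gompertz–Makeham specification with two calibration anchors.

    Hazard: ``mu(x) = makeham_constant + alpha * exp(beta * x)`` with
    ``alpha``/``beta`` solved so q at the two anchor ages matches exactly.
    """

    makeham_constant: float = 5e-4
    age_min: int = 0
    age_max: int = 105
    anchor_young: tuple[int, float] = (71, 0.0195)
    anchor_old: tuple[int, float] = (100, 0.364)


def _gompertz_calibrate(spec: SyntheticLifeTableSpec) -> tuple[float, float]:
    """Closed-form solve of (alpha, beta) from the two anchors.

    With G(x) = -ln(1 - q(x)) - makeham_constant = c * exp(beta * x), the two
    anchors give beta from the log-ratio and c (hence alpha) from either one.
    """
    (x1, q1), (x2, q2) = spec.anchor_young, spec.anchor_old
    if x1 == x2:
        raise ValueError("anchor ages must differ")
    g1 = -math.log1p(-q1) - spec.makeham_constant
    g2 = -math.log1p(-q2) - spec.makeham_constant
    if g1 <= 0 or g2 <= 0:
        raise ValueError(
            "calibration infeasible: anchor probabilities must exceed the "
            f"Makeham floor (residuals {g1:.3g}, {g2:.3g})"
        )
    beta = math.log(g2 / g1) / (x2 - x1)
    c = g1 / math.exp(beta * x1)
    alpha = c * beta / math.expm1(beta)
    return alpha, beta


def lifetable_from_hazard(
    makeham_constant: float,
    alpha: float,
    beta: float,
    age_min: int = 0,
    age_max: int = 105,
) -> LifeTable:
    """Life table from an explicit Gompertz–Makeham hazard (no calibration).

    ``q(x) = 1 - exp(-makeham - (alpha/beta)(e^beta - 1) e^(beta x))``; with
    all parameters zero the table is identically zero.
    """
    ages = np.arange(age_min, age_max + 1)
    if alpha == 0.0 or beta == 0.0:
        cumulative = np.full(ages.shape, alpha, dtype=float)  # beta -> 0 limit
    else:
        cumulative = (alpha / beta) * math.expm1(beta) * np.exp(beta * ages)
    qx = -np.expm1(-(makeham_constant + cumulative))
    return LifeTable(ages=ages, qx=np.clip(qx, 0.0, 1.0))


def make_lifetable(spec: SyntheticLifeTableSpec | None = None) -> LifeTable:
    """Synthetic national life table hitting both anchors exactly."""
    spec = spec or SyntheticLifeTableSpec()
    alpha, beta = _gompertz_calibrate(spec)
    table = lifetable_from_hazard(
        spec.makeham_constant, alpha, beta, spec.age_min, spec.age_max
    )
    for age, target in (spec.anchor_young, spec.anchor_old):
        got = table.qx[age - spec.age_min]
        if abs(got - target) > 5e-5:
            raise RuntimeError(
                f"life-table calibration failed at age {age}: {got:.6f} vs {target}"
            )
    return table


def make_base_case() -> ParameterBundle:
    """Reconstructed deterministic base case (no randomness)."""
    shared = dict(
        surgery_base_cost=DEFAULT_SURGERY_BASE_COST,
        annual_post_revision_care_cost=54.19,
        utility_post_revision=0.685,
        utility_re_revision=0.397,
    )
    return ParameterBundle(
        settings=ModelSettings(starting_age=71.7, discount_rate=0.035),
        decellularised=StrategyParameters(
            graft_price_per_head=DECELLULARISED_PRICE,
            annual_re_revision_probability=annual_probability_from_cumulative(
                DECELLULARISED_EVIDENCE
            ),
            **shared,
        ),
        fresh_frozen=StrategyParameters(
            graft_price_per_head=FRESH_FROZEN_PRICE,
            annual_re_revision_probability=annual_probability_from_cumulative(
                FRESH_FROZEN_EVIDENCE
            ),
            **shared,
        ),
    )


#: Starting-age distribution: mean 71.7, SD 11.16 (one-SD points 60.54/82.86).
AGE_MEAN, AGE_SD = 71.7, 11.16


def make_psa_specs(*, fixed: bool = False) -> list[DistributionSpec]:
    """Distribution specs for the PSA, or a degenerate all-fixed variant.

    SDs for parameters whose spread is not published are chosen once as
    conventional health-economic defaults (documented in the methods note):
    utilities 0.05 on the QALY-weight scale, cost SDs proportional to their
    means sized to the published extreme scenarios (the care-cost gamma puts
    essentially all its mass across the published 0–301 GBP range), and
    re-revision probabilities with SD equal to 75% of the mean.
    """
    base = make_base_case()
    p_decell = base.decellularised.annual_re_revision_probability
    p_fresh = base.fresh_frozen.annual_re_revision_probability
    entries = [
        ("strategies.*.utility_post_revision", "beta", 0.685, 0.05, None, None),
        ("strategies.*.utility_re_revision", "beta", 0.397, 0.05, None, None),
        ("strategies.*.annual_post_revision_care_cost", "gamma", 54.19, 61.5, None, None),
        ("strategies.*.surgery_base_cost", "gamma", DEFAULT_SURGERY_BASE_COST, 2923.6, None, None),
        ("strategies.decellularised.graft_price_per_head", "gamma", DECELLULARISED_PRICE, 5020.36, None, None),
        ("strategies.fresh_frozen.graft_price_per_head", "gamma", FRESH_FROZEN_PRICE, 354.86, None, None),
        ("strategies.decellularised.annual_re_revision_probability", "beta", p_decell, 0.75 * p_decell, None, None),
        ("strategies.fresh_frozen.annual_re_revision_probability", "beta", p_fresh, 0.75 * p_fresh, None, None),
        ("settings.starting_age", "normal", AGE_MEAN, AGE_SD, 40.0, 100.0),
    ]
    return [
        DistributionSpec(
            parameter_path=path,
            family="fixed" if fixed else family,
            mean=mean,
            sd=0.0 if fixed else sd,
            low=low,
            high=high,
        )
        for path, family, mean, sd, low, high in entries
    ]


def make_scenarios() -> list[ScenarioSpec]:
    """The six published one-way sensitivity scenarios."""
    base = make_base_case()
    return [
        ScenarioSpec("Discount rate 3.5% -> 1.5%", "settings.discount_rate", 0.015),
        ScenarioSpec("Low cohort age (mean - SD): 60.54", "settings.starting_age", AGE_MEAN - AGE_SD),
        ScenarioSpec("High cohort age (mean + SD): 82.86", "settings.starting_age", AGE_MEAN + AGE_SD),
        ScenarioSpec("Low post-revision care cost: 0/year", "strategies.*.annual_post_revision_care_cost", 0.0),
        ScenarioSpec("High post-revision care cost: 301/year", "strategies.*.annual_post_revision_care_cost", 301.0),
        ScenarioSpec(
            "Same re-revision rate",
            "strategies.decellularised.annual_re_revision_probability",
            base.fresh_frozen.annual_re_revision_probability,
        ),
    ]


def write_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write every generated artefact as plain text; returns the paths.

    Produces ``lifetable.csv`` (age,qx), ``config.json`` (hierarchical
    parameter bundle with costing and evidence sections so derived fields are
    derived on load), ``scenarios.json`` and ``psa_specs.json``.
    """
    import json
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = make_lifetable()
    paths["lifetable"] = outdir / "lifetable.csv"
    table.to_csv(paths["lifetable"])

    base = make_base_case()
    config = base.to_dict()
    # carry the derivable inputs too, dropping the fields they determine
    config["costing"] = asdict(TABLE_COST_BREAKDOWN)
    config["evidence"] = {
        "decellularised": asdict(DECELLULARISED_EVIDENCE),
        "fresh_frozen": asdict(FRESH_FROZEN_EVIDENCE),
    }
    for name in ("decellularised", "fresh_frozen"):
        del config["strategies"][name]["annual_re_revision_probability"]
    paths["config"] = outdir / "config.json"
    paths["config"].write_text(json.dumps(config, indent=2) + "\n")

    paths["scenarios"] = outdir / "scenarios.json"
    paths["scenarios"].write_text(
        json.dumps([asdict(s) for s in make_scenarios()], indent=2) + "\n"
    )
    paths["psa_specs"] = outdir / "psa_specs.json"
    paths["psa_specs"].write_text(
        json.dumps([asdict(s) for s in make_psa_specs()], indent=2) + "\n"
    )
    return paths
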