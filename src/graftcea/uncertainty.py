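"""One-way sensitivity scenarios and probabilistic sensitivity analysis.

Two complementary treatments of parameter uncertainty:

* **Scenario (one-way) analysis** — one parameter is pushed to an extreme
  value and the whole two-arm model re-evaluated, yielding a table of
  incremental cost, incremental QALYs, ICER and the favoured strategy.

* **Probabilistic sensitivity analysis (PSA)** — each uncertain parameter is
  given a distribution (beta for probabilities and utilities, gamma for
  costs, normal for age — the conventional assignments by support), the model
  is evaluated on thousands of independent joint draws, and the resulting
  cloud of incremental outcomes is summarised on the incremental plane and as
  cost-effectiveness acceptability curves (CEAC): at each willingness-to-pay,
  the fraction of draws in which each strategy has the higher net monetary
  benefit.

Parameters are addressed by dotted paths into the bundle
(``settings.starting_age``, ``strategies.decellularised.graft_price_per_head``);
the wildcard segment ``strategies.*`` applies one value — or one shared draw —
to both arms, which is how shared quantities (utilities, care cost, the base
surgery cost) stay common between strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .cea import DEFAULT_WTP, CEResult, evaluate, net_monetary_benefit
from .engine import InfeasibleTransitionError
from .mortality import CoverageError, LifeTable
from .parameters import ConfigurationError, ParameterBundle

__all__ = [
    "ScenarioSpec",
    "DistributionSpec",
    "PSAResult",
    "apply_override",
    "run_scenarios",
    "sample_parameters",
    "run_psa",
    "ceac_from_draws",
    "default_wtp_grid",
]


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid for CEACs: 0 to 50,000 GBP/QALY in 500 steps."""
    return np.arange(0.0, 50_000.0 + 1, 500.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One named parameter override for a one-way sensitivity run."""

    name: str
    parameter_path: str
    override_value: float


def apply_override(bundle: ParameterBundle, path: str, value: Any) -> ParameterBundle:
    """Return a new bundle with the parameter at ``path`` replaced.

    ``strategies.*.<field>`` fans the value out to both arms.  Unknown paths
    raise :class:`~graftcea.parameters.ConfigurationError`; the replacement is
    re-validated by the dataclass invariants, so out-of-range overrides fail
    loudly.
    """
    config = bundle.to_dict()
    parts = path.split(".")
    if parts[0] == "strategies" and len(parts) == 3 and parts[1] == "*":
        targets = [["strategies", name, parts[2]] for name in ("decellularised", "fresh_frozen")]
    else:
        targets = [parts]
    for target in targets:
        node = config
        for key in target[:-1]:
            if not isinstance(node, dict) or key not in node:
                raise ConfigurationError(f"unknown parameter path {path!r}")
            node = node[key]
        if not isinstance(node, dict) or target[-1] not in node:
            raise ConfigurationError(f"unknown parameter path {path!r}")
        node[target[-1]] = value
    return ParameterBundle.from_config(config)


def run_scenarios(
    bundle: ParameterBundle,
    lifetable: LifeTable,
    scenarios: Sequence[ScenarioSpec],
    *,
    wtp: float = DEFAULT_WTP,
) -> pd.DataFrame:
    """Evaluate the base case plus each one-way scenario.

    Returns a table with one row per evaluation and columns mirroring a
    published sensitivity table: scenario name, incremental cost, incremental
    QALYs, ICER (NaN when effects are equal) and the favoured strategy at the
    given willingness-to-pay.
    """
    rows = []
    evaluations = [("Base case", bundle)]
    for scenario in scenarios:
        evaluations.append(
            (scenario.name, apply_override(bundle, scenario.parameter_path, scenario.override_value))
        )
    for name, case in evaluations:
        result = evaluate(case, lifetable).result
        rows.append(
            {
                "scenario": name,
                "incremental_cost": result.incremental_cost,
                "incremental_qalys": result.incremental_effect,
                "icer": np.nan if result.icer is None else result.icer,
                "favoured": (
                    "decellularised" if result.favoured(wtp) == "intervention" else "fresh_frozen"
                ),
            }
        )
    return pd.DataFrame(rows)


_FAMILIES = ("beta", "gamma", "normal", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one parameter, given on the natural scale.

    Families by support: ``beta`` for probabilities and utilities (moment
    matched), ``gamma`` for non-negative costs, ``normal`` (optionally
    truncated to ``[low, high]`` by rejection) for age, ``fixed`` for
    degenerate parameters.
    """

    parameter_path: str
    family: str
    mean: float
    sd: float = 0.0
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"{self.parameter_path}: unknown family {self.family!r}; choose from {_FAMILIES}"
            )
        if self.sd < 0:
            raise ConfigurationError(f"{self.parameter_path}: sd must be >= 0")
        if self.family == "beta":
            if not 0.0 < self.mean < 1.0:
                raise ConfigurationError(
                    f"{self.parameter_path}: beta mean must be in (0, 1), got {self.mean!r}"
                )
            if self.sd > 0 and self.sd**2 >= self.mean * (1 - self.mean):
                raise ConfigurationError(
                    f"{self.parameter_path}: beta sd {self.sd!r} too large for mean {self.mean!r}"
                )
        if self.family == "gamma" and self.mean <= 0 and self.sd > 0:
            raise ConfigurationError(f"{self.parameter_path}: gamma mean must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value; always respects the family's support by construction."""
        if self.family == "fixed" or self.sd == 0.0:
            return self.mean
        if self.family == "beta":
            nu = self.mean * (1 - self.mean) / self.sd**2 - 1.0
            return float(rng.beta(self.mean * nu, (1 - self.mean) * nu))
        if self.family == "gamma":
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            return float(rng.gamma(shape, scale))
        # truncated normal by rejection; deterministic given the generator state
        low = -np.inf if self.low is None else self.low
        high = np.inf if self.high is None else self.high
        while True:
            value = float(rng.normal(self.mean, self.sd))
            if low <= value <= high:
                return value


def _draw_rng(seed: int, draw: int) -> np.random.Generator:
    # per-draw sub-stream: draw i is invariant to the total number of draws
    return np.random.default_rng([int(seed), int(draw)])


def sample_parameters(
    base: ParameterBundle,
    dists: Sequence[DistributionSpec],
    n: int,
    seed: int,
) -> list[ParameterBundle]:
    """Draw ``n`` parameter bundles, one independent joint draw each.

    Reproducible given ``seed``; each draw uses its own deterministic
    sub-stream, so draw ``i`` does not depend on ``n``.  A wildcard path
    receives a single draw applied to both strategies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bundles = []
    for i in range(n):
        rng = _draw_rng(seed, i)
        case = base
        for spec in dists:
            case = apply_override(case, spec.parameter_path, spec.sample(rng))
        bundles.append(case)
    return bundles


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental outcomes, summary statistics and CEAC curves."""

    draws: pd.DataFrame  # columns: draw, incremental_cost, incremental_effect
    seed: int
    n_rejected: int
    summary: dict[str, float]
    ceac: pd.DataFrame  # columns: wtp, p_decellularised, p_fresh_frozen


def ceac_from_draws(
    draws: pd.DataFrame, wtp_grid: Iterable[float] | None = None
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each willingness-to-pay the intervention's probability of being
    cost-effective is the fraction of draws with strictly positive net
    monetary benefit; ties (NMB exactly zero) go to the comparator.  The two
    strategies' probabilities sum to 1 at every threshold.
    """
    if len(draws) == 0:
        raise ValueError("at least one draw is required")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(list(wtp_grid), dtype=float)
    d_cost = draws["incremental_cost"].to_numpy()
    d_effect = draws["incremental_effect"].to_numpy()
    nmb = grid[:, None] * d_effect[None, :] - d_cost[None, :]
    p_intervention = (nmb > 0).mean(axis=1)
    return pd.DataFrame(
        {
            "wtp": grid,
            "p_decellularised": p_intervention,
            "p_fresh_frozen": 1.0 - p_intervention,
        }
    )


def run_psa(
    base: ParameterBundle,
    lifetable: LifeTable,
    dists: Sequence[DistributionSpec],
    n: int = 10_000,
    seed: int = 0,
    *,
    wtp_grid: Iterable[float] | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis: ``n`` joint draws through the model.

    Each draw re-evaluates the full two-arm lifetime model.  Draws whose
    sampled parameters make a transition row infeasible (or push the cohort
    outside the life table) are rejected and counted, not silently clipped.

    The summary reports the mean incremental cost and effect, the ICER of
    those means (ratio of means), and the fractions of draws in which the
    intervention is cheaper and in which it is more effective.
    """
    records = []
    n_rejected = 0
    for i in range(n):
        rng = _draw_rng(seed, i)
        case = base
        try:
            for spec in dists:
                case = apply_override(case, spec.parameter_path, spec.sample(rng))
            result = evaluate(case, lifetable).result
        except (InfeasibleTransitionError, CoverageError, ConfigurationError):
            n_rejected += 1
            continue
        records.append(
            {
                "draw": i,
                "incremental_cost": result.incremental_cost,
                "incremental_effect": result.incremental_effect,
            }
        )
    if not records:
        raise RuntimeError("every PSA draw was rejected; check the distribution specs")
    draws = pd.DataFrame(records)
    mean_cost = float(draws["incremental_cost"].mean())
    mean_effect = float(draws["incremental_effect"].mean())
    summary = {
        "mean_incremental_cost": mean_cost,
        "mean_incremental_effect": mean_effect,
        "icer_of_means": mean_cost / mean_effect if mean_effect != 0 else float("nan"),
        "fraction_cheaper": float((draws["incremental_cost"] < 0).mean()),
        "fraction_more_effective": float((draws["incremental_effect"] > 0).mean()),
    }
    ceac = ceac_from_draws(draws, wtp_grid)
    return PSAResult(draws=draws, seed=seed, n_rejected=n_rejected, summary=summary, ceac=ceac)
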