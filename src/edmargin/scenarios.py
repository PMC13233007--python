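"""Efficiency sensitivity sweeps and break-even tool cost.

An efficiency change ``e`` shortens median ED length of stay to
``L' = L * (1 - e)`` (so ``e = +0.05`` is a 5% throughput gain and
``e = -0.10`` a 10% loss).  Two operating scenarios translate that into
financials, both anchored to a pre-intervention baseline period:

* **Capacity-constrained** (demand exceeds supply): the freed capacity
  fills with new visits, ``V' = V * (1 + e)``, at constant revenue per
  visit, so ``R' = R * (1 + e)``.  The hospital-management care-hours
  driver becomes ``(1 + e)(1 - e) = 1 - e^2``.
* **Volume-stable** (demand is met): volume and revenue are unchanged;
  shorter stays reduce care hours, letting the hospital flex modifiable
  labour down by ``e * capture``, where ``capture`` in [0, 1] is the
  share of the care-hours reduction actually converted into savings
  (default 1, a fully commensurate reduction).  Public-policy cost, tied
  to revenue, does not move in this scenario.

The break-even tool cost per visit is the margin gain over baseline
divided by scenario visit volume — the highest per-visit price an
efficiency intervention can charge without eroding operating margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from pydantic import BaseModel, Field, field_validator

from .cohort import PeriodSummary
from .model import (
    CostStructure,
    FrameworkResult,
    ModelParams,
    baseline_cost,
    policy_cost,
)

ScenarioKind = Literal["capacity_constrained", "volume_stable"]

#: Default sweep grid: e from -10% to +10% in 1-point steps.
DEFAULT_E_GRID: tuple[float, ...] = tuple(i / 100.0 for i in range(-10, 11))

#: Sanity bound on |e|; the model is not meant for larger perturbations.
MAX_ABS_E = 0.5


class EfficiencyScenario(BaseModel):
    """One point of the sensitivity analysis: scenario kind, efficiency
    change ``e``, and the modifiable-cost capture fraction."""

    kind: ScenarioKind
    e: float
    modifiable_capture: float = Field(default=1.0, ge=0.0, le=1.0)

    model_config = {"frozen": True}

    @field_validator("e")
    @classmethod
    def _e_within_bounds(cls, v: float) -> float:
        if abs(v) > MAX_ABS_E:
            raise ValueError(f"|e| must be <= {MAX_ABS_E}, got {v}")
        return v


@dataclass(frozen=True)
class BreakEvenResult:
    """Per-visit tool cost at which margin gain is exactly offset.

    A negative ``per_visit`` (margin loss) means there is no sustainable
    tool cost; it is reported as-is, flagged by :attr:`sustainable`.
    """

    per_visit: float
    margin_delta: float
    post_visits: float

    @property
    def sustainable(self) -> bool:
        return self.per_visit >= 0


@dataclass(frozen=True)
class ScenarioPoint:
    """Projected financials at one efficiency change ``e``."""

    e: float
    kind: ScenarioKind
    volume: float
    ed_los: float
    hospital_management: FrameworkResult
    public_policy: FrameworkResult
    hm_margin_delta: float
    policy_margin_delta: float

    def break_even_hm(self) -> BreakEvenResult:
        return break_even_from_delta(self.hm_margin_delta, self.volume)

    def break_even_policy(self) -> BreakEvenResult:
        return break_even_from_delta(self.policy_margin_delta, self.volume)


def project_scenario(
    baseline: PeriodSummary,
    scenario: EfficiencyScenario,
    params: ModelParams | None = None,
) -> ScenarioPoint:
    """Project financials for an efficiency change ``e`` from a baseline.

    Baseline cost is derived from baseline revenue at the configured
    margin rate and partitioned 70/20/10; the scenario then moves the
    volume-variable and care-hours-modifiable components as described in
    the module docstring.
    """
    params = params or ModelParams()
    e = scenario.e
    base: CostStructure = baseline_cost(baseline.total_revenue, params)
    base_margin = baseline.total_revenue - base.total
    ed_los = baseline.median_ed_los * (1.0 - e)

    if scenario.kind == "capacity_constrained":
        volume = baseline.n_visits * (1.0 + e)
        revenue = baseline.total_revenue * (1.0 + e)
        hm = (
            base.fixed
            + base.variable * (1.0 + e)
            + base.modifiable * (1.0 + e) * (1.0 - e)
        )
        pp = policy_cost(revenue, params)
    else:  # volume_stable
        volume = float(baseline.n_visits)
        revenue = baseline.total_revenue
        hm = (
            base.fixed
            + base.variable
            + base.modifiable * (1.0 - e * scenario.modifiable_capture)
        )
        pp = base.total  # cost tied to revenue, which is unchanged

    hm_result = FrameworkResult("hospital_management", revenue, hm)
    pp_result = FrameworkResult("public_policy", revenue, pp)
    return ScenarioPoint(
        e=e,
        kind=scenario.kind,
        volume=volume,
        ed_los=ed_los,
        hospital_management=hm_result,
        public_policy=pp_result,
        hm_margin_delta=hm_result.margin - base_margin,
        policy_margin_delta=pp_result.margin - base_margin,
    )


def break_even(
    margin_baseline: float, margin_scenario: float, post_visits: float
) -> BreakEvenResult:
    """Break-even tool cost per visit: margin gain / scenario visits."""
    return break_even_from_delta(margin_scenario - margin_baseline, post_visits)


def break_even_from_delta(margin_delta: float, post_visits: float) -> BreakEvenResult:
    if post_visits <= 0:
        raise ValueError(f"post_visits must be > 0, got {post_visits}")
    return BreakEvenResult(
        per_visit=margin_delta / post_visits,
        margin_delta=margin_delta,
        post_visits=post_visits,
    )


def sweep(
    baseline: PeriodSummary,
    kind: ScenarioKind,
    params: ModelParams | None = None,
    e_grid: Sequence[float] = DEFAULT_E_GRID,
    modifiable_capture: float = 1.0,
) -> list[ScenarioPoint]:
    """Project a grid of efficiency changes (default -10% .. +10%).

    Returns one :class:`ScenarioPoint` per grid value, in grid order;
    break-evens for each framework are available from each point.
    """
    if len(e_grid) == 0:
        raise ValueError("e_grid must not be empty")
    return [
        project_scenario(
            baseline,
            EfficiencyScenario(kind=kind, e=e, modifiable_capture=modifiable_capture),
            params,
        )
        for e in e_grid
    ]
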