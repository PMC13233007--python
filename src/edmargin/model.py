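"""Dual-framework operating-margin model for ED efficiency interventions.

Baseline cost is anchored to pre-intervention revenue through an expected
operating-margin rate ``m`` (default 5.8%): ``C = R_pre * (1 - m)``.  Two
costing frameworks then project cost forward:

* **Hospital management (HM)** partitions baseline cost into fixed
  (70%), volume-variable (20%) and care-hours-modifiable (10%) shares.
  Post cost is ``fixed + variable * (V'/V) + modifiable * (V'L')/(VL)``
  where ``V`` is visit volume and ``L`` median ED length of stay — the
  product ``V * L`` being total care hours, the driver of flexible
  labour such as contract nursing and overtime.
* **Public policy** costs care through a constant cost-to-charge ratio,
  making cost proportional to revenue: ``cost = R' * (1 - m)``.  Its
  margin rate is therefore ``m`` whatever the revenue.  A constant
  cost-per-visit variant (cost = baseline cost/visit × ``V'``) is
  available as a named mode; it differs whenever revenue per visit
  changes.

Both frameworks coincide at the pre period by construction.  All
currency arithmetic is carried at full float precision; rounding belongs
to the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from pydantic import BaseModel, Field, model_validator

from .cohort import PeriodSummary

Framework = Literal["hospital_management", "public_policy"]
PolicyMode = Literal["proportional_to_revenue", "constant_cost_per_visit"]


class ModelParams(BaseModel):
    """Economic model inputs: margin rate and HM cost-share partition.

    Defaults are the study values: 5.8% expected operating-margin rate
    and a 70/20/10 fixed/variable/modifiable split.  All fields may be
    overridden to reflect local hospital characteristics.
    """

    margin_rate: float = Field(default=0.058, ge=0.0, lt=1.0)
    fixed_share: float = Field(default=0.70, ge=0.0, le=1.0)
    variable_share: float = Field(default=0.20, ge=0.0, le=1.0)
    modifiable_share: float = Field(default=0.10, ge=0.0, le=1.0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _shares_sum_to_one(self) -> "ModelParams":
        total = self.fixed_share + self.variable_share + self.modifiable_share
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"cost shares must sum to 1, got {total!r} "
                f"({self.fixed_share}/{self.variable_share}/{self.modifiable_share})"
            )
        return self


@dataclass(frozen=True)
class CostStructure:
    """Total cost partitioned into fixed/variable/modifiable components."""

    total: float
    fixed: float
    variable: float
    modifiable: float

    def __post_init__(self) -> None:
        if min(self.total, self.fixed, self.variable, self.modifiable) < 0:
            raise ValueError("cost components must be >= 0")
        if abs(self.fixed + self.variable + self.modifiable - self.total) > 0.01:
            raise ValueError("cost components must sum to total (cent tolerance)")


@dataclass(frozen=True)
class FrameworkResult:
    """Revenue, cost and operating margin under one costing framework."""

    framework: Framework
    revenue: float
    cost: float

    @property
    def margin(self) -> float:
        return self.revenue - self.cost

    @property
    def margin_rate(self) -> float | None:
        """Margin as a fraction of revenue; ``None`` when revenue is 0."""
        if self.revenue == 0:
            return None
        return self.margin / self.revenue

    def to_dict(self) -> dict:
        return {
            "framework": self.framework,
            "revenue": self.revenue,
            "cost": self.cost,
            "margin": self.margin,
            "margin_rate": self.margin_rate,
        }


def baseline_cost(revenue: float, params: ModelParams | None = None) -> CostStructure:
    """Derive the baseline cost structure from pre-intervention revenue.

    Total cost is ``revenue * (1 - m)``; the fixed/variable/modifiable
    components are the configured shares of that total.
    """
    params = params or ModelParams()
    if revenue < 0:
        raise ValueError(f"revenue must be >= 0, got {revenue}")
    total = revenue * (1.0 - params.margin_rate)
    return CostStructure(
        total=total,
        fixed=params.fixed_share * total,
        variable=params.variable_share * total,
        modifiable=params.modifiable_share * total,
    )


def hm_cost(
    baseline: CostStructure, volume_ratio: float, care_hours_ratio: float
) -> float:
    """Hospital-management cost at given volume and care-hours ratios.

    ``volume_ratio`` is ``V_post / V_pre``; ``care_hours_ratio`` is
    ``(V_post * L_post) / (V_pre * L_pre)`` with ``L`` the median ED LOS.
    Fixed cost is unchanged, variable cost scales with volume, and
    modifiable labour scales with care hours.
    """
    if volume_ratio <= 0 or care_hours_ratio <= 0:
        raise ValueError(
            f"ratios must be > 0, got volume_ratio={volume_ratio}, "
            f"care_hours_ratio={care_hours_ratio}"
        )
    return (
        baseline.fixed
        + baseline.variable * volume_ratio
        + baseline.modifiable * care_hours_ratio
    )


def policy_cost(revenue: float, params: ModelParams | None = None) -> float:
    """Public-policy cost: proportional to revenue at the baseline
    cost-to-revenue (cost-to-charge) ratio, ``revenue * (1 - m)``."""
    params = params or ModelParams()
    if revenue < 0:
        raise ValueError(f"revenue must be >= 0, got {revenue}")
    return revenue * (1.0 - params.margin_rate)


def policy_cost_per_visit(
    n_visits: float, baseline_cost_per_visit: float
) -> float:
    """Alternative public-policy mode: constant cost per visit.

    ``n_visits * baseline_cost_per_visit``.  Differs from the
    proportional-to-revenue mode whenever revenue per visit changes.
    """
    if n_visits <= 0:
        raise ValueError(f"n_visits must be > 0, got {n_visits}")
    if baseline_cost_per_visit < 0:
        raise ValueError("baseline_cost_per_visit must be >= 0")
    return n_visits * baseline_cost_per_visit


def margin(revenue: float, cost: float) -> tuple[float, float | None]:
    """Operating margin and margin rate.

    Returns ``(revenue - cost, (revenue - cost)/revenue)``; the rate is
    ``None`` (explicitly undefined) when revenue is 0.
    """
    m = revenue - cost
    rate = None if revenue == 0 else m / revenue
    return m, rate


@dataclass(frozen=True)
class FrameworkComparison:
    """Pre/post results and differences under one framework."""

    pre: FrameworkResult
    post: FrameworkResult

    @property
    def revenue_diff(self) -> float:
        return self.post.revenue - self.pre.revenue

    @property
    def cost_diff(self) -> float:
        return self.post.cost - self.pre.cost

    @property
    def margin_diff(self) -> float:
        return self.post.margin - self.pre.margin


@dataclass(frozen=True)
class PeriodComparison:
    """Table-1-style pre/post comparison: operations block plus one
    :class:`FrameworkComparison` per costing framework."""

    pre_summary: PeriodSummary
    post_summary: PeriodSummary
    params: ModelParams
    hospital_management: FrameworkComparison
    public_policy: FrameworkComparison

    @property
    def volume_ratio(self) -> float:
        return self.post_summary.n_visits / self.pre_summary.n_visits

    @property
    def care_hours_ratio(self) -> float:
        return (self.post_summary.n_visits * self.post_summary.median_ed_los) / (
            self.pre_summary.n_visits * self.pre_summary.median_ed_los
        )

    def to_dict(self) -> dict:
        return {
            "operations": {
                "pre": self.pre_summary.to_dict(),
                "post": self.post_summary.to_dict(),
                "volume_ratio": self.volume_ratio,
                "care_hours_ratio": self.care_hours_ratio,
            },
            "hospital_management": {
                "pre": self.hospital_management.pre.to_dict(),
                "post": self.hospital_management.post.to_dict(),
                "difference": {
                    "revenue": self.hospital_management.revenue_diff,
                    "cost": self.hospital_management.cost_diff,
                    "margin": self.hospital_management.margin_diff,
                },
            },
            "public_policy": {
                "pre": self.public_policy.pre.to_dict(),
                "post": self.public_policy.post.to_dict(),
                "difference": {
                    "revenue": self.public_policy.revenue_diff,
                    "cost": self.public_policy.cost_diff,
                    "margin": self.public_policy.margin_diff,
                },
            },
            "params": self.params.model_dump(),
        }


def compare_periods(
    pre: PeriodSummary,
    post: PeriodSummary,
    params: ModelParams | None = None,
    *,
    policy_mode: PolicyMode = "proportional_to_revenue",
) -> PeriodComparison:
    """Evaluate both costing frameworks on a pre/post period pair.

    Baseline cost is anchored to the *pre* period; HM ratios come from
    the two summaries.  At the pre period both frameworks give the same
    cost and margin by construction.
    """
    params = params or ModelParams()
    base = baseline_cost(pre.total_revenue, params)
    pre_result_hm = FrameworkResult("hospital_management", pre.total_revenue, base.total)
    pre_result_pp = FrameworkResult("public_policy", pre.total_revenue, base.total)

    volume_ratio = post.n_visits / pre.n_visits
    care_hours_ratio = (post.n_visits * post.median_ed_los) / (
        pre.n_visits * pre.median_ed_los
    )
    post_hm = FrameworkResult(
        "hospital_management",
        post.total_revenue,
        hm_cost(base, volume_ratio, care_hours_ratio),
    )
    if policy_mode == "proportional_to_revenue":
        pp_cost = policy_cost(post.total_revenue, params)
    elif policy_mode == "constant_cost_per_visit":
        pp_cost = policy_cost_per_visit(post.n_visits, base.total / pre.n_visits)
    else:
        raise ValueError(f"unknown policy mode {policy_mode!r}")
    post_pp = FrameworkResult("public_policy", post.total_revenue, pp_cost)

    return PeriodComparison(
        pre_summary=pre,
        post_summary=post,
        params=params,
        hospital_management=FrameworkComparison(pre_result_hm, post_hm),
        public_policy=FrameworkComparison(pre_result_pp, post_pp),
    )
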