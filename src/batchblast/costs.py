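"""Compute and storage cost arithmetic.

Cloud charges accrue per instance-hour (discounted capacity pays a
fraction of the on-demand rate — 20% for GCP preemptible instances) and
per GB-month of object storage.  Rounding convention: currency totals of
a cent or more round half-up to 2 decimals; sub-cent amounts (tiny
storage charges) are reported at full precision; per-unit figures (cost
per read) at 2 significant figures.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from pydantic import BaseModel, Field

from .planner import SearchPlan

DEFAULT_STORAGE_RATE = 0.023    # $/GB-month, current GCP/AWS standard storage
DEFAULT_SPOT_DISCOUNT = 0.2     # GCP preemptible: 20% of on-demand price


class PricingContext(BaseModel):
    hourly_price: float = Field(gt=0)
    spot_discount: float = Field(gt=0, le=1, default=DEFAULT_SPOT_DISCOUNT)
    storage_rate: float = Field(gt=0, default=DEFAULT_STORAGE_RATE)


class CostReport(BaseModel):
    instance_hours: float = Field(ge=0)
    compute_cost: float = Field(ge=0)
    storage_cost: float = Field(ge=0)
    preemptible: bool = False
    per_unit_cost: Optional[float] = None

    @property
    def total(self) -> float:
        return round_currency(self.compute_cost + self.storage_cost)


def round_currency(amount: float) -> float:
    """Half-up to 2 decimals for amounts >= $0.01; full precision below."""
    if amount >= 0.01:
        return float(Decimal(str(amount)).quantize(Decimal("0.01"),
                                                   rounding=ROUND_HALF_UP))
    return amount


def compute_cost(hours: float, n_instances: int, pricing: PricingContext,
                 preemptible: bool = False) -> float:
    """Instance-hours times the hourly rate, discounted if preemptible."""
    if hours < 0:
        raise ValueError("hours must be >= 0")
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    rate = pricing.hourly_price * (pricing.spot_discount if preemptible else 1.0)
    return round_currency(hours * n_instances * rate)


def compute_cost_from_vcpus(hours: float, total_vcpus: int,
                            vcpus_per_instance: int, hourly_price: float,
                            spot_discount: float = DEFAULT_SPOT_DISCOUNT,
                            preemptible: bool = False) -> float:
    """Cost when the workload is described by its total vCPU count.

    The instance count is ``ceil(total_vcpus / vcpus_per_instance)``;
    delegates to :func:`compute_cost`.
    """
    n_instances = math.ceil(total_vcpus / vcpus_per_instance)
    pricing = PricingContext(hourly_price=hourly_price,
                             spot_discount=spot_discount)
    return compute_cost(hours, n_instances, pricing, preemptible=preemptible)


def storage_cost(size_gb: float, months: float = 1.0,
                 rate: float = DEFAULT_STORAGE_RATE) -> float:
    """Object-storage cost: GB x months x rate (sub-cent kept exact)."""
    if size_gb < 0 or months < 0:
        raise ValueError("size and months must be >= 0")
    return round_currency(size_gb * months * rate)


def per_unit_cost(total: float, n_units: int,
                  significant_figures: int = 2) -> float:
    """Total cost divided over units (e.g. reads), to N significant figures."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    value = total / n_units
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + significant_figures - 1)


def estimate_run(plan: SearchPlan, predicted_hours: float,
                 pricing: PricingContext | None = None,
                 result_size_gb: float = 0.0, storage_months: float = 1.0,
                 n_units: int | None = None) -> CostReport:
    """Pre-submission what-if estimate for a planned run.

    Assumes the full node ceiling runs for ``predicted_hours`` (the
    autoscaled reality bills less; the simulator's billing meter is the
    supported path for that).  Useful for the small-test-run-first
    costing workflow.
    """
    if pricing is None:
        pricing = PricingContext(hourly_price=plan.instance.hourly_price,
                                 spot_discount=plan.instance.spot_discount)
    hours = predicted_hours * plan.max_nodes
    compute = compute_cost(predicted_hours, plan.max_nodes, pricing,
                           preemptible=plan.preemptible)
    storage = storage_cost(result_size_gb, storage_months, pricing.storage_rate)
    unit = (per_unit_cost(compute + storage, n_units)
            if n_units else None)
    return CostReport(instance_hours=hours, compute_cost=compute,
                      storage_cost=storage, preemptible=plan.preemptible,
                      per_unit_cost=unit)
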