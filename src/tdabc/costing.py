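"""Capacity costing: salary inputs to capacity cost rates, and point costs.

Time-driven activity-based costing attributes labour cost to an activity as
(minutes of staff time) x (capacity cost rate, CCR).  The CCR of a staff
resource is its full annual expense divided by its *practical* capacity --
the fraction of contracted minutes actually available for service delivery
after breaks, training and other non-service work.  The conventions used
here are a flat on-cost uplift on base salary (default 25%, covering leave
and superannuation) and a practical capacity of 80% of theoretical capacity.

All monetary quantities are A$ (costing year metadata is carried separately
by callers); durations are minutes.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

#: Currency / costing-year tag carried on reported outputs.
CURRENCY = "A$ 2023"

#: Default employer on-cost uplift on base salary (leave, superannuation).
DEFAULT_ON_COST_FRACTION = 0.25

#: Default practical capacity as a fraction of theoretical capacity.
DEFAULT_PRACTICAL_FRACTION = 0.80


class CapacityInputs(BaseModel):
    """Salary-side inputs from which a capacity cost rate can be derived."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    annual_base_salary: float = Field(gt=0, description="A$ per year")
    on_cost_fraction: float = Field(default=DEFAULT_ON_COST_FRACTION, ge=0)
    contracted_minutes_per_year: float = Field(gt=0)
    practical_fraction: float = Field(default=DEFAULT_PRACTICAL_FRACTION, gt=0, le=1)

    def derived_ccr(self) -> float:
        """Capacity cost rate (A$/minute) implied by these salary inputs."""
        return capacity_cost_rate(
            annual_labour_cost(self.annual_base_salary, self.on_cost_fraction),
            practical_capacity_minutes(
                self.contracted_minutes_per_year, self.practical_fraction
            ),
        )


def annual_labour_cost(salary: float, on_cost_fraction: float) -> float:
    """Full annual expense of a staff resource: salary plus on-costs.

    Parameters
    ----------
    salary : base salary, A$/year.
    on_cost_fraction : employer on-costs as a fraction of salary.
    """
    if salary < 0:
        raise ValueError(f"salary must be non-negative, got {salary}")
    if on_cost_fraction < 0:
        raise ValueError(f"on_cost_fraction must be non-negative, got {on_cost_fraction}")
    return salary * (1.0 + on_cost_fraction)


def practical_capacity_minutes(contracted_minutes: float, practical_fraction: float) -> float:
    """Practical capacity (minutes/year) from contracted minutes.

    ``practical_fraction`` must lie in (0, 1]; 1.0 means theoretical
    capacity is fully available for service delivery.
    """
    if contracted_minutes <= 0:
        raise ValueError(f"contracted_minutes must be positive, got {contracted_minutes}")
    if not 0 < practical_fraction <= 1:
        raise ValueError(
            f"practical_fraction must be in (0, 1], got {practical_fraction}"
        )
    return contracted_minutes * practical_fraction


def capacity_cost_rate(annual_cost: float, practical_minutes: float) -> float:
    """Capacity cost rate (A$/minute): annual expense over practical minutes."""
    if practical_minutes <= 0:
        raise ValueError(f"practical_minutes must be positive, got {practical_minutes}")
    return annual_cost / practical_minutes


def point_cost(activity, resource) -> float:
    """Deterministic point cost of one activity: mean duration x mean CCR.

    This is the pre-simulation cost of TDABC step 5; the Monte Carlo
    machinery in :mod:`tdabc.uncertainty` propagates the elicitation
    uncertainty around it.

    ``resource`` must be the activity's declared performer.
    """
    if activity.performer != resource.id:
        raise ValueError(
            f"activity {activity.id} is performed by {activity.performer!r}, "
            f"not {resource.id!r}"
        )
    return activity.duration.mean * resource.ccr.mean
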