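"""Referral/response scenario composition, costing, and annual projection.

A *scenario* is one complete path through the workflow: a referral route
(source and triage complexity), the booking step, a reminder timing, and an
attendance-outcome response (what staff do when the patient fails to attend
or cancels).  Its cost is the per-iteration sum of the Monte Carlo cost
draws of its component activities; its annual burden is projected linearly
from clinic volumes under the hypothetical assumption that 100% of the
relevant events resolve through that scenario.

Enumeration crosses every referral route with every failure-to-attend
response under each reminder timing, plus every cancellation response under
the first (within-one-week SMS) reminder timing.  On the bundled two-clinic
fixture this yields 3 x (4 x 2 + 2) = 30 scenarios.  The roster is a
reconstruction of the published scenario set from the workflow branch
structure; the published supplementary listing was not available, so the
composition is documented rather than copied.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .model import ClinicModel, ClinicProfile, ProcessMap
from .uncertainty import (
    DEFAULT_ITERATIONS,
    DEFAULT_SEED,
    CostEstimate,
    child_seed,
    draw_product,
    normal_from_interval,
    product_moment_oracle,
    summarize_samples,
)


class Scenario(BaseModel):
    """One referral-source x response path as an ordered activity bundle."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str
    referral_source: Literal["internal", "external"]
    complexity: Literal["simple", "complex", "n/a"]
    response: str
    response_kind: Literal["fta", "cancel", "attend"]
    activity_ids: list[int] = Field(min_length=1)


class ProjectionResult(BaseModel):
    """Annual cost of a scenario under a 100%-to-outcome assumption."""

    model_config = ConfigDict(frozen=True)

    clinic: str
    scenario_id: str
    rate: float
    annual_events: float
    annual_cost: float
    assumption: str


def _route_attrs(route_name: str) -> tuple[str, str]:
    """Parse (source, complexity) out of a referral route name."""
    source = "external" if route_name.startswith("external") else "internal"
    if route_name.endswith("simple"):
        complexity = "simple"
    elif route_name.endswith("complex"):
        complexity = "complex"
    else:
        complexity = "n/a"
    return source, complexity


def enumerate_scenarios(process_map: ProcessMap) -> list[Scenario]:
    """Build the full referral x response scenario roster from a process map.

    Failure-to-attend responses are crossed with every reminder timing;
    cancellation responses use the first declared reminder timing only
    (a cancellation bundle needs a reminder to have been issued, but the
    timing split is not informative for it).
    """
    pw = process_map.pathways
    if not pw.referral:
        raise ValueError("process map declares no referral routes")
    if not pw.booking:
        raise ValueError("process map declares no booking segment")
    if not pw.reminder:
        raise ValueError("process map declares no reminder segment")
    fta = {k: v for k, v in pw.response.items() if v.kind == "fta"}
    cancel = {k: v for k, v in pw.response.items() if v.kind == "cancel"}
    if not fta:
        raise ValueError("process map declares no failure-to-attend response")
    if not cancel:
        raise ValueError("process map declares no cancellation response")

    booking = next(iter(pw.booking.values()))
    first_reminder_key = next(iter(pw.reminder))

    scenarios: list[Scenario] = []
    for route_name, route in pw.referral.items():
        source, complexity = _route_attrs(route_name)
        for resp_name, resp in fta.items():
            for rem_name, reminder in pw.reminder.items():
                scenarios.append(
                    Scenario(
                        id=f"{route_name}:{rem_name}:{resp_name}",
                        referral_source=source,
                        complexity=complexity,
                        response=resp_name,
                        response_kind="fta",
                        activity_ids=route + booking + reminder + resp.activities,
                    )
                )
        for resp_name, resp in cancel.items():
            reminder = pw.reminder[first_reminder_key]
            scenarios.append(
                Scenario(
                    id=f"{route_name}:{first_reminder_key}:{resp_name}",
                    referral_source=source,
                    complexity=complexity,
                    response=resp_name,
                    response_kind="cancel",
                    activity_ids=route + booking + reminder + resp.activities,
                )
            )
    return scenarios


def scenario_cost(
    scenario: Scenario,
    model: ClinicModel,
    n: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_SEED,
    shared_rates: bool = False,
) -> CostEstimate:
    """Monte Carlo cost of a scenario: per-iteration sum over its activities.

    By default every activity gets its own independent time *and* rate draw
    each iteration, matching the per-activity uncertainty treatment.  With
    ``shared_rates=True`` each staff resource's rate is drawn once per
    iteration and reused across that resource's activities in the bundle,
    inducing positive correlation between same-performer activity costs.
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    rng = np.random.default_rng(seed)
    # draw in id order so the estimate is exactly invariant to the order in
    # which the bundle lists its activities (the sum itself is order-free)
    activities = [
        model.process_map.activity(i) for i in sorted(scenario.activity_ids)
    ]

    rate_draws: dict[str, np.ndarray] = {}
    if shared_rates:
        for res_id in sorted({a.performer for a in activities}):
            rate_draws[res_id] = rng.normal(
                *_rate_params(model, res_id), size=n
            )

    total = np.zeros(n)
    for a in activities:
        t = normal_from_interval(a.duration)
        if shared_rates:
            times = rng.normal(t.mu, t.sigma, size=n)
            total += times * rate_draws[a.performer]
        else:
            r = normal_from_interval(model.resource_for(a).ccr)
            total += draw_product(t, r, n, rng)
    return summarize_samples(total, seed)


def _rate_params(model: ClinicModel, resource_id: str) -> tuple[float, float]:
    p = normal_from_interval(model.resources[resource_id].ccr)
    return p.mu, p.sigma


def scenario_oracle(scenario: Scenario, model: ClinicModel) -> tuple[float, float]:
    """Closed-form mean and SD of a scenario cost under independent draws."""
    mean = 0.0
    var = 0.0
    for i in scenario.activity_ids:
        a = model.process_map.activity(i)
        m, s = product_moment_oracle(
            normal_from_interval(a.duration),
            normal_from_interval(model.resource_for(a).ccr),
        )
        mean += m
        var += s**2
    return mean, float(np.sqrt(var))


def project_annual_cost(
    clinic: ClinicProfile,
    scenario: Scenario,
    rate: float,
    cost: CostEstimate,
) -> ProjectionResult:
    """Project the annual cost of resolving all rate-events via one scenario.

    ``annual_events = annual_referrals * rate`` and
    ``annual_cost = annual_events * cost.mean``.  This is the generic
    linear projection; it deliberately assumes every event in the rate
    class follows this single scenario.
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    annual_events = clinic.annual_referrals * rate
    return ProjectionResult(
        clinic=clinic.name,
        scenario_id=scenario.id,
        rate=rate,
        annual_events=annual_events,
        annual_cost=annual_events * cost.mean,
        assumption=(
            f"assumes 100% of events at rate {rate:.0%} of "
            f"{clinic.annual_referrals} annual referrals resolve via "
            f"scenario {scenario.id}"
        ),
    )


def scenario_cost_table(
    model: ClinicModel,
    n: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_SEED,
    shared_rates: bool = False,
) -> pd.DataFrame:
    """Cost every enumerated scenario; one row per scenario.

    Each scenario uses its own seed sub-stream derived from ``seed`` and
    the scenario id, so adding or reordering scenarios does not perturb
    the others' estimates.
    """
    rows = []
    for s in enumerate_scenarios(model.process_map):
        est = scenario_cost(
            s, model, n=n, seed=child_seed(seed, "scenario", s.id), shared_rates=shared_rates
        )
        rows.append(
            {
                "scenario_id": s.id,
                "referral_source": s.referral_source,
                "complexity": s.complexity,
                "response": s.response,
                "response_kind": s.response_kind,
                "activity_ids": "+".join(map(str, s.activity_ids)),
                "mean": est.mean,
                "sd": est.sd,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_iterations": est.n_iterations,
            }
        )
    return pd.DataFrame(rows)


def projection_table(
    model: ClinicModel,
    scenario_costs: pd.DataFrame,
) -> pd.DataFrame:
    """Annual projections for every costed scenario of one clinic.

    Failure-to-attend scenarios are projected at the clinic's
    non-attendance rate, cancellation scenarios at its cancellation rate.
    """
    scenarios = {s.id: s for s in enumerate_scenarios(model.process_map)}
    rows = []
    for rec in scenario_costs.to_dict("records"):
        s = scenarios[rec["scenario_id"]]
        rate = (
            model.profile.non_attendance_rate
            if s.response_kind == "fta"
            else model.profile.cancellation_rate
        )
        est = CostEstimate(
            mean=rec["mean"],
            sd=rec["sd"],
            ci_low=rec["ci_low"],
            ci_high=rec["ci_high"],
            n_iterations=int(rec["n_iterations"]),
            seed=0,
        )
        proj = project_annual_cost(model.profile, s, rate, est)
        rows.append(
            {
                "clinic": proj.clinic,
                "scenario_id": proj.scenario_id,
                "response_kind": s.response_kind,
                "rate": proj.rate,
                "annual_events": proj.annual_events,
                "mean_cost_per_event": rec["mean"],
                "annual_cost": proj.annual_cost,
                "assumption": proj.assumption,
            }
        )
    return pd.DataFrame(rows)
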