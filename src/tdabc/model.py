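"""Data model for clinic workflows: resources, activities, pathways, clinics.

The unit of analysis is an *activity*: one numbered step of a clinic work
process (referral handling, booking, reminders, appointment attendance),
performed by one staff resource for an expert-elicited duration.  Durations
and capacity cost rates are elicited as (mean, low, high), with (low, high)
read as a symmetric 95% uncertainty interval around the mean.

A :class:`ProcessMap` holds the activities together with the branch
structure of the workflow, encoded as ordered activity-id lists per named
pathway segment (referral routes, booking, reminder timings, and
attendance-outcome responses).  The branch structure is small and fixed, so
explicit lists are used rather than a general graph language; acyclicity of
the implied activity graph is still checked during validation.
"""

from __future__ import annotations

from typing import Literal, Optional

import networkx as nx
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .costing import CapacityInputs

Process = Literal["referral", "booking", "reminder", "attendance"]
ResponseKind = Literal["fta", "cancel", "attend"]

#: Tolerance for agreement between a declared CCR and one derived from
#: salary inputs (A$/minute; half a cent covers 2-dp rounding).
CCR_ROUNDING_TOL = 0.005


class ElicitedQuantity(BaseModel):
    """An expert-elicited value: point estimate with a 95% interval.

    ``low`` and ``high`` are the elicited minimum/maximum, interpreted as
    the bounds of a symmetric 95% uncertainty interval (not hard bounds).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    mean: float = Field(gt=0)
    low: float = Field(ge=0)
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "ElicitedQuantity":
        if not self.low <= self.mean <= self.high:
            raise ValueError(
                f"interval must satisfy low <= mean <= high, got "
                f"({self.low}, {self.mean}, {self.high})"
            )
        return self

    @property
    def width(self) -> float:
        return self.high - self.low


class StaffResource(BaseModel):
    """A labour category with a capacity cost rate in A$/minute.

    The CCR may be given directly (as elicited, with its own interval) or
    derived from salary inputs; if both are present they must agree.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str
    label: str
    ccr: ElicitedQuantity
    salary_inputs: Optional[CapacityInputs] = None

    @model_validator(mode="after")
    def _salary_consistent(self) -> "StaffResource":
        if self.salary_inputs is not None:
            derived = self.salary_inputs.derived_ccr()
            if abs(derived - self.ccr.mean) > CCR_ROUNDING_TOL:
                raise ValueError(
                    f"resource {self.id!r}: CCR derived from salary inputs "
                    f"({derived:.4f}) disagrees with declared ccr.mean "
                    f"({self.ccr.mean:.4f}) beyond tolerance {CCR_ROUNDING_TOL}"
                )
        return self


class Activity(BaseModel):
    """One numbered workflow step binding a performer to an elicited duration."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    id: int
    label: str
    process: Process
    performer: str
    duration: ElicitedQuantity
    pathway_tags: frozenset[str] = frozenset()


class ResponseSegment(BaseModel):
    """An attendance-outcome branch: the activities a staff response triggers."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    kind: ResponseKind
    activities: list[int]


class Pathways(BaseModel):
    """Branch structure of the workflow as ordered activity lists per segment.

    ``referral`` maps route names (e.g. ``internal_simple``, ``external``)
    to the activity ids on that route; ``reminder`` maps reminder timings;
    ``response`` maps attendance outcomes (attend / fail-to-attend /
    cancel responses) to :class:`ResponseSegment`.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    referral: dict[str, list[int]]
    booking: dict[str, list[int]]
    reminder: dict[str, list[int]]
    response: dict[str, ResponseSegment]

    def all_activity_ids(self) -> set[int]:
        ids: set[int] = set()
        for seg in (self.referral, self.booking, self.reminder):
            for lst in seg.values():
                ids.update(lst)
        for resp in self.response.values():
            ids.update(resp.activities)
        return ids


class ProcessMap(BaseModel):
    """All activities of a clinic plus their pathway structure."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    activities: list[Activity]
    pathways: Pathways

    def activity(self, activity_id: int) -> Activity:
        for a in self.activities:
            if a.id == activity_id:
                return a
        raise KeyError(f"no activity with id {activity_id}")

    @property
    def activity_ids(self) -> list[int]:
        return [a.id for a in self.activities]


class ClinicProfile(BaseModel):
    """Volume and event-rate parameters of one clinic."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    specialty: str = ""
    annual_referrals: int = Field(gt=0)
    non_attendance_rate: float = Field(ge=0, le=1)
    cancellation_rate: float = Field(ge=0, le=1)
    n_physiotherapists: int = Field(gt=0)


class ClinicModel(BaseModel):
    """A complete clinic: process map, profile, and staff resources."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    process_map: ProcessMap
    profile: ClinicProfile
    resources: dict[str, StaffResource]

    def resource_for(self, activity: Activity) -> StaffResource:
        return self.resources[activity.performer]


class ValidationIssue(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: str
    message: str


class ValidationReport(BaseModel):
    """Outcome of structural validation; empty ``issues`` means valid."""

    issues: list[ValidationIssue] = []

    @property
    def ok(self) -> bool:
        return not self.issues

    def raise_if_invalid(self) -> None:
        if not self.ok:
            lines = "; ".join(f"[{i.code}] {i.message}" for i in self.issues)
            raise ValueError(f"invalid process map: {lines}")


def _pathway_graph(pathways: Pathways) -> nx.DiGraph:
    """Directed graph of activity precedence implied by the pathway lists.

    Edges join consecutive activities within each segment, and the last
    activity of each stage to the first of each following-stage segment,
    for every composable route.
    """
    g = nx.DiGraph()
    stage_lists: list[list[list[int]]] = [
        list(pathways.referral.values()),
        list(pathways.booking.values()),
        list(pathways.reminder.values()),
        [r.activities for r in pathways.response.values()],
    ]
    for stage in stage_lists:
        for seg in stage:
            g.add_nodes_from(seg)
            g.add_edges_from(zip(seg, seg[1:]))
    for prev_stage, next_stage in zip(stage_lists, stage_lists[1:]):
        for prev in prev_stage:
            for nxt in next_stage:
                if prev and nxt:
                    g.add_edge(prev[-1], nxt[0])
    return g


def validate_process_map(
    process_map: ProcessMap, resources: dict[str, StaffResource]
) -> ValidationReport:
    """Structural validation of a process map against declared resources.

    Checks: unique activity ids, performers resolve, elicited intervals are
    proper (low <= mean <= high with positive low for durations), every
    pathway reference resolves, every activity is reachable from a referral
    entry point, and the implied activity graph is acyclic.
    """
    issues: list[ValidationIssue] = []

    seen: set[int] = set()
    for a in process_map.activities:
        if a.id in seen:
            issues.append(
                ValidationIssue(code="duplicate-id", message=f"activity id {a.id} declared twice")
            )
        seen.add(a.id)
        if a.performer not in resources:
            issues.append(
                ValidationIssue(
                    code="unknown-resource",
                    message=f"activity {a.id} names undeclared performer {a.performer!r}",
                )
            )
        if not a.duration.low <= a.duration.mean <= a.duration.high:
            issues.append(
                ValidationIssue(
                    code="interval",
                    message=(
                        f"activity {a.id} interval violates low <= mean <= high: "
                        f"({a.duration.low}, {a.duration.mean}, {a.duration.high})"
                    ),
                )
            )
        if a.duration.low <= 0:
            issues.append(
                ValidationIssue(
                    code="interval",
                    message=f"activity {a.id} duration.low must be positive, got {a.duration.low}",
                )
            )

    referenced = process_map.pathways.all_activity_ids()
    for missing in sorted(referenced - seen):
        issues.append(
            ValidationIssue(
                code="unknown-activity",
                message=f"pathways reference undeclared activity id {missing}",
            )
        )
    for unreachable in sorted(seen - referenced):
        issues.append(
            ValidationIssue(
                code="unreachable",
                message=f"activity {unreachable} appears on no pathway segment",
            )
        )

    graph = _pathway_graph(process_map.pathways)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        issues.append(
            ValidationIssue(
                code="cycle",
                message=f"pathway graph contains a cycle: {cycle}",
            )
        )

    return ValidationReport(issues=issues)
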