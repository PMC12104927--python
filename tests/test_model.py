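"""Structural model: elicited intervals, fixture integrity, validation."""

import pytest
from pydantic import ValidationError

from tdabc import (
    Activity,
    CapacityInputs,
    ClinicModel,
    ElicitedQuantity,
    StaffResource,
    load_paper_fixture,
    read_clinic_config,
    validate_process_map,
    write_clinic_config,
)
from tdabc.model import Pathways, ProcessMap, ResponseSegment


def _resources():
    return {
        "admin": StaffResource(
            id="admin", label="admin", ccr=ElicitedQuantity(mean=1.0, low=0.8, high=1.2)
        )
    }


def _tiny_map(**overrides):
    activities = overrides.pop(
        "activities",
        [
            Activity(
                id=1,
                label="a",
                process="referral",
                performer="admin",
                duration=ElicitedQuantity(mean=5, low=4, high=6),
            ),
            Activity(
                id=2,
                label="b",
                process="booking",
                performer="admin",
                duration=ElicitedQuantity(mean=2, low=1, high=3),
            ),
        ],
    )
    pathways = overrides.pop(
        "pathways",
        Pathways(
            referral={"internal": [1]},
            booking={"standard": [2]},
            reminder={"sms": []},
            response={},
        ),
    )
    return ProcessMap(activities=activities, pathways=pathways)


class TestElicitedQuantity:
    def test_ordering_enforced(self):
        with pytest.raises(ValidationError, match="low <= mean <= high"):
            ElicitedQuantity(mean=5, low=6, high=7)

    def test_degenerate_interval_allowed(self):
        q = ElicitedQuantity(mean=3, low=3, high=3)
        assert q.width == 0


class TestValidation:
    def test_valid_map_has_no_issues(self):
        report = validate_process_map(_tiny_map(), _resources())
        assert report.ok and report.issues == []

    def test_unknown_performer_reported(self):
        bad = Activity(
            id=3,
            label="x",
            process="referral",
            performer="X",
            duration=ElicitedQuantity(mean=1, low=0.5, high=1.5),
        )
        pmap = _tiny_map(
            activities=[bad],
            pathways=Pathways(
                referral={"internal": [3]}, booking={"b": []}, reminder={"r": []}, response={}
            ),
        )
        report = validate_process_map(pmap, _resources())
        codes = [i.code for i in report.issues]
        assert codes == ["unknown-resource"]
        assert "'X'" in report.issues[0].message

    def test_interval_violation_reported(self):
        bad_duration = ElicitedQuantity.model_construct(mean=5.0, low=6.0, high=7.0)
        bad = Activity.model_construct(
            id=9,
            label="x",
            process="referral",
            performer="admin",
            duration=bad_duration,
            pathway_tags=frozenset(),
        )
        pmap = ProcessMap.model_construct(
            activities=[bad],
            pathways=Pathways(
                referral={"internal": [9]}, booking={"b": []}, reminder={"r": []}, response={}
            ),
        )
        report = validate_process_map(pmap, _resources())
        assert any(i.code == "interval" for i in report.issues)

    def test_duplicate_id_and_unreachable_reported(self):
        a = Activity(
            id=1,
            label="a",
            process="referral",
            performer="admin",
            duration=ElicitedQuantity(mean=5, low=4, high=6),
        )
        orphan = Activity(
            id=4,
            label="orphan",
            process="attendance",
            performer="admin",
            duration=ElicitedQuantity(mean=5, low=4, high=6),
        )
        pmap = _tiny_map(
            activities=[a, a, orphan],
            pathways=Pathways(
                referral={"internal": [1]}, booking={"b": []}, reminder={"r": []}, response={}
            ),
        )
        report = validate_process_map(pmap, _resources())
        codes = {i.code for i in report.issues}
        assert {"duplicate-id", "unreachable"} <= codes

    def test_conflicting_order_reported_as_cycle(self):
        acts = [
            Activity(
                id=i,
                label=str(i),
                process="referral",
                performer="admin",
                duration=ElicitedQuantity(mean=1, low=0.5, high=1.5),
            )
            for i in (1, 2)
        ]
        pmap = _tiny_map(
            activities=acts,
            pathways=Pathways(
                referral={"fwd": [1, 2], "rev": [2, 1]},
                booking={"b": []},
                reminder={"r": []},
                response={},
            ),
        )
        report = validate_process_map(pmap, _resources())
        assert any(i.code == "cycle" for i in report.issues)


class TestSalaryInputs:
    def test_derived_rate_consistent_with_declared(self):
        # 80 800 A$/yr over 80 000 practical minutes -> 1.01 A$/min
        res = StaffResource(
            id="admin",
            label="admin",
            ccr=ElicitedQuantity(mean=1.01, low=0.81, high=1.21),
            salary_inputs=CapacityInputs(
                annual_base_salary=64640,
                on_cost_fraction=0.25,
                contracted_minutes_per_year=100000,
                practical_fraction=0.80,
            ),
        )
        assert res.salary_inputs.derived_ccr() == pytest.approx(1.01)

    def test_inconsistent_declared_rate_rejected(self):
        with pytest.raises(ValidationError, match="disagrees"):
            StaffResource(
                id="admin",
                label="admin",
                ccr=ElicitedQuantity(mean=2.0, low=1.5, high=2.5),
                salary_inputs=CapacityInputs(
                    annual_base_salary=64640,
                    on_cost_fraction=0.25,
                    contracted_minutes_per_year=100000,
                ),
            )


class TestBundledFixture:
    def test_both_clinics_validate_cleanly(self, clinic1, clinic2):
        for m in (clinic1, clinic2):
            assert validate_process_map(m.process_map, m.resources).ok

    def test_activity_union_covers_all_numbered_steps(self, clinic1, clinic2):
        union = set(clinic1.process_map.activity_ids) | set(clinic2.process_map.activity_ids)
        assert union == set(range(1, 29))
        # consults are clinic-specific, everything else shared
        assert set(clinic1.process_map.activity_ids) & {17, 18, 19, 20, 21} == set()
        assert set(clinic2.process_map.activity_ids) & {14, 15, 16} == set()

    def test_clinic_profiles_match_published_volumes(self, clinic1, clinic2):
        assert clinic1.profile.annual_referrals == 2997
        assert clinic1.profile.non_attendance_rate == 0.08
        assert clinic1.profile.cancellation_rate == 0.04
        assert clinic2.profile.annual_referrals == 3347
        assert clinic2.profile.non_attendance_rate == 0.10
        assert clinic2.profile.cancellation_rate == 0.08

    def test_capacity_cost_rates_as_published(self, clinic1):
        assert clinic1.resources["admin"].ccr == ElicitedQuantity(
            mean=1.01, low=0.81, high=1.21
        )
        assert clinic1.resources["physio"].ccr == ElicitedQuantity(
            mean=1.48, low=1.18, high=1.77
        )
        assert clinic1.resources["referral_hub"].ccr == ElicitedQuantity(
            mean=1.01, low=0.81, high=1.21
        )

    def test_triage_activity_as_published(self, clinic1):
        a = clinic1.process_map.activity(2)
        assert a.performer == "physio"
        assert (a.duration.mean, a.duration.low, a.duration.high) == (2.0, 1.0, 3.0)

    def test_all_intervals_well_formed(self, clinic1, clinic2):
        for m in (clinic1, clinic2):
            for a in m.process_map.activities:
                assert 0 < a.duration.low <= a.duration.mean <= a.duration.high
            for r in m.resources.values():
                assert 0 < r.ccr.low <= r.ccr.mean <= r.ccr.high

    def test_unknown_clinic_rejected(self):
        with pytest.raises(Exception, match="clinic9"):
            load_paper_fixture("clinic9")

    def test_serialisation_round_trip(self, clinic1, tmp_path):
        path = tmp_path / "clinic1.yaml"
        write_clinic_config(clinic1, path)
        again = read_clinic_config(path)
        assert again == clinic1
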