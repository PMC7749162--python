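"""Era logic, required/conditional field audit, PI partition, contacts."""

import pytest

from trialaudit.completeness_audit import (
    audit_completeness,
    audit_contact_details,
    classify_era,
    classify_pi,
)
from trialaudit.record_io import read_record, write_record
from trialaudit.synthetic_corpus import GeneratorConfig, generate


def _record(start_date: str | None = None, **kw):
    from trialaudit.record_io import TrialRecord

    rec = TrialRecord(record_id="NCTX", study_type="Interventional")
    rec.start_date_raw = start_date
    for key, value in kw.items():
        setattr(rec, key, value)
    return rec


@pytest.mark.parametrize("raw, era", [
    ("January 17, 2017", "pre_final_rule"),
    ("January 18, 2017", "post_final_rule"),
    ("January 19, 2017", "post_final_rule"),
    ("January, 2017", "pre_final_rule"),     # day-absent -> day 1
    ("February, 2017", "post_final_rule"),
    ("December, 2016", "pre_final_rule"),
    ("Unknown", "unknown_start_date"),
    (None, "unknown_start_date"),
    ("garbled", "unknown_start_date"),
])
def test_final_rule_era_classification(raw, era):
    assert classify_era(_record(raw)) == era


def test_exclude_convention_marks_cutoff_month_ambiguous():
    rec = _record("January, 2017")
    assert classify_era(rec, convention="day1") == "pre_final_rule"
    assert classify_era(rec, convention="exclude") == "unknown_start_date"
    # only the cutoff month is affected
    assert classify_era(_record("February, 2017"),
                        convention="exclude") == "post_final_rule"


def _interventional(seed=31, n=12):
    records, _ = generate(GeneratorConfig(n_records=n, seed=seed))
    return [r for r in records if r.study_type == "Interventional"]


def _reread(rec):
    return read_record(write_record(rec))


def test_fully_populated_record_has_no_missing_fields(registry):
    for rec in _interventional():
        report = audit_completeness(rec, registry)
        assert report.missing_required == set()
        assert report.missing_conditional == set()
        assert report.contact_rule_satisfied


def test_non_interventional_records_are_rejected(registry):
    rec = _record(None)
    rec.study_type = "Observational"
    with pytest.raises(ValueError, match="interventional"):
        audit_completeness(rec, registry)


def test_terminated_without_reason_is_conditionally_missing(registry):
    rec = next(r for r in _interventional()
               if classify_era(r) == "post_final_rule")
    rec.overall_status_raw = "Terminated"
    rec.why_stopped = None
    report = audit_completeness(_reread(rec), registry)
    assert "why study stopped" in report.missing_conditional
    assert "why study stopped" not in report.missing_required
    rec.why_stopped = "Low enrollment."
    assert "why study stopped" not in audit_completeness(
        _reread(rec), registry).missing


def test_why_stopped_not_required_before_final_rule(registry):
    rec = next(r for r in _interventional()
               if classify_era(r) == "pre_final_rule")
    rec.overall_status_raw = "Terminated"
    rec.why_stopped = None
    assert "why study stopped" not in audit_completeness(
        _reread(rec), registry).missing


def test_pre_rule_recommended_fields_are_not_counted(registry):
    pre = next(r for r in _interventional()
               if classify_era(r) == "pre_final_rule")
    post = next(r for r in _interventional()
                if classify_era(r) == "post_final_rule")
    for rec in (pre, post):
        rec.official_title = None
        rec.completion_date_raw = None
    assert audit_completeness(_reread(pre), registry).missing == set()
    assert audit_completeness(_reread(post), registry).missing == {
        "official title", "study completion date"}


def test_missing_start_date_is_counted_in_the_unknown_era(registry):
    rec = _interventional()[0]
    rec.start_date_raw = None
    rec.start_date_attr = None
    report = audit_completeness(_reread(rec), registry)
    assert report.era == "unknown_start_date"
    assert "study start date" in report.missing_required


def test_zero_arms_makes_arm_information_and_count_missing(registry):
    rec = next(r for r in _interventional()
               if classify_era(r) == "post_final_rule")
    rec.design.arms = []
    rec.design.number_of_arms_raw = None
    report = audit_completeness(_reread(rec), registry)
    assert {"arm information", "number of arms"} <= report.missing_required


def test_outcome_subfields_audited_only_when_outcomes_exist(registry):
    rec = next(r for r in _interventional()
               if classify_era(r) == "post_final_rule")
    for o in rec.primary_outcomes:
        o.time_frame = None
    report = audit_completeness(_reread(rec), registry)
    assert "outcome time frame" in report.missing_required
    rec.outcomes = [o for o in rec.outcomes if o.rank != "primary"]
    report = audit_completeness(_reread(rec), registry)
    assert "primary outcome measure information" in report.missing_required
    assert "outcome time frame" not in report.missing_required


def test_contact_rule_overall_contact_covers_contactless_sites(registry):
    from trialaudit.record_io import Location

    rec = _interventional()[0]
    rec.contacts.locations = [
        Location(facility_name=f"Site {i}", city="Springfield",
                 country="United States", site_status_raw="Recruiting",
                 site_contact=None)
        for i in range(50)]
    report = audit_completeness(_reread(rec), registry)
    assert report.overall_contact_present
    assert not report.all_sites_have_contact
    assert report.contact_rule_satisfied


def test_contact_rule_fails_without_overall_or_full_site_coverage(registry):
    rec = _interventional()[0]
    rec.contacts.overall_contact = None
    rec.contacts.locations[0].site_contact = None
    report = audit_completeness(_reread(rec), registry)
    assert not report.contact_rule_satisfied


@pytest.mark.parametrize("rp_type, officials, expected", [
    ("Sponsor", 1, "official_with_nonscientific_rp"),
    ("Sponsor-Investigator", 0, "rp_investigator_only"),
    ("Principal Investigator", 0, "rp_investigator_only"),
    ("Sponsor", 0, "no_pi"),
    ("Sponsor-Investigator", 1, "both"),
    (None, 0, "no_pi"),
])
def test_pi_partition(rp_type, officials, expected):
    from trialaudit.record_io import Official

    rec = _record(None)
    rec.parties.responsible_party_type_raw = rp_type
    rec.parties.overall_officials = [
        Official(last_name_raw="Sarah Smith, M.D.")] * officials
    assert classify_pi(rec) == expected


def test_pi_categories_partition_the_corpus(registry):
    records, _ = generate(GeneratorConfig(n_records=60, seed=13))
    counts = {}
    for rec in records:
        counts[classify_pi(rec)] = counts.get(classify_pi(rec), 0) + 1
    assert sum(counts.values()) == 60


def test_contact_detail_counting():
    rec = _record(None)
    rec.contacts.overall_contact = None
    assert audit_contact_details([rec]) == (0, 0, 0)
    from trialaudit.record_io import ContactDetail

    rec.contacts.overall_contact = ContactDetail(
        last_name_raw="Sarah Smith, M.D.", phone="555-0100", email=None)
    assert audit_contact_details([rec]) == (1, 0, 1)


def test_filling_a_value_never_grows_the_missing_sets(registry):
    """Monotonicity: adding values only removes missingness."""
    config = GeneratorConfig(
        n_records=40, seed=17,
        missing_plan={"allocation": 8, "official title": 5, "enrollment": 6,
                      "masking": 4})
    records, _ = generate(config)
    for rec in records:
        if rec.study_type != "Interventional":
            continue
        before = audit_completeness(rec, registry).missing
        rec.design.allocation_raw = rec.design.allocation_raw or "Randomized"
        rec.official_title = rec.official_title or "Filled Title"
        rec.enrollment_raw = rec.enrollment_raw or "50"
        after = audit_completeness(_reread(rec), registry).missing
        assert after <= before
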