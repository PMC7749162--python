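"""Completeness audit of interventional records against FDAAA801.

The audit covers the 28 required fields that are checkable from public
records (composite groups such as study design and primary outcome
information are audited per sub-element). Era logic follows the Final Rule
cutoff (2017-01-18): four fields that were only recommended before the
cutoff are not counted missing for pre-rule records. Conditional fields
are missing only when their condition is active. Multiple-occurrence
fields are missing iff they have zero occurrences; sub-fields of a present
composite are missing iff no occurrence of the sub-element exists.

Two presence rules reported alongside the 28 fields:

* contact rule — an overall contact, or a contact for every listed site;
* principal-investigator partition — a PI may appear as an
  investigator-typed responsible party, as an overall official, as both,
  or not at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from .record_io import TrialRecord
from .schema_registry import FINAL_RULE_CUTOFF, Registry
from .type_validation import DATE_RE, MONTHS

__all__ = [
    "CompletenessReport", "classify_era", "parse_registry_date",
    "audit_completeness", "classify_pi", "audit_contact_details",
    "STOPPED_STATUSES", "PI_CATEGORIES", "ERAS",
]

ERAS = ("pre_final_rule", "post_final_rule", "unknown_start_date")
PI_CATEGORIES = ("no_pi", "rp_investigator_only",
                 "official_with_nonscientific_rp", "both")
STOPPED_STATUSES = frozenset({"Suspended", "Terminated", "Withdrawn"})
_INVESTIGATOR_RP_TYPES = frozenset({"Principal Investigator",
                                    "Sponsor-Investigator"})


@dataclass
class CompletenessReport:
    record_id: str
    era: str
    era_day_convention_applied: bool
    agency_class: str | None
    missing_required: set[str] = field(default_factory=set)
    missing_conditional: set[str] = field(default_factory=set)
    pi_category: str = "no_pi"
    overall_contact_present: bool = False
    all_sites_have_contact: bool = False
    n_locations: int = 0
    contact_rule_satisfied: bool = False

    @property
    def missing(self) -> set[str]:
        return self.missing_required | self.missing_conditional


def parse_registry_date(raw: str | None) -> tuple[object | None, bool]:
    """Interpret a registry-dialect date for comparisons.

    Returns ``(date, day_absent)`` where ``date`` is a ``datetime.date``
    with absent days mapped to day 1, or ``None`` for ``Unknown``,
    absent, or non-conformant text. Raw storage elsewhere is deliberate:
    general-purpose date parsers have undefined behavior on day-less input,
    so only this one convention is applied, and only here.
    """
    import datetime

    if raw is None:
        return None, False
    m = DATE_RE.match(raw.strip())
    if m is None or m.group("month") is None:
        return None, False
    day_absent = m.group("day") is None
    day = 1 if day_absent else int(m.group("day"))
    month = MONTHS.index(m.group("month")) + 1
    try:
        return datetime.date(int(m.group("year")), month, day), day_absent
    except ValueError:
        return None, day_absent


def classify_era(record: TrialRecord, convention: str = "day1") -> str:
    """Era of a record relative to the Final Rule cutoff (2017-01-18).

    Day-absent dates compare as day 1 under the default ``day1``
    convention; under ``exclude``, a day-absent date in the cutoff month
    (January 2017) is treated as era-ambiguous and classified
    ``unknown_start_date``.
    """
    date, day_absent = parse_registry_date(record.start_date_raw)
    if date is None:
        return "unknown_start_date"
    if (convention == "exclude" and day_absent
            and (date.year, date.month) == (FINAL_RULE_CUTOFF.year,
                                            FINAL_RULE_CUTOFF.month)):
        return "unknown_start_date"
    return "post_final_rule" if date >= FINAL_RULE_CUTOFF else "pre_final_rule"


# ---------------------------------------------------------------------------
# field presence evaluators
#
# Each audited field name maps to a predicate "is this field present?".
# Composite groups are expanded: the parent predicate checks the group has
# occurrences at all; sub-fields are checked only when the parent has
# occurrences (zero-occurrence semantics per sub-element).

def _has_primary_outcomes(r: TrialRecord) -> bool:
    return bool(r.primary_outcomes)


_PRESENCE: dict[str, Callable[[TrialRecord], bool]] = {
    "brief title": lambda r: r.brief_title is not None,
    "brief summary": lambda r: r.brief_summary is not None,
    "study phase": lambda r: r.phase is not None,
    "study type": lambda r: r.study_type is not None,
    "condition": lambda r: bool(r.conditions),
    "intervention name": lambda r: any(i.name for i in r.interventions),
    "intervention type": lambda r: any(i.intervention_type
                                       for i in r.interventions),
    "eligibility criteria": lambda r: r.eligibility_text is not None,
    "sex": lambda r: r.gender is not None,
    "minimum age": lambda r: r.minimum_age_raw is not None,
    "maximum age": lambda r: r.maximum_age_raw is not None,
    "overall recruitment status": lambda r: r.overall_status_raw is not None,
    "lead sponsor name": lambda r: r.sponsor_name is not None,
    "responsible party type":
        lambda r: r.parties.responsible_party_type_raw is not None,
    "secondary id": lambda r: bool(r.secondary_ids),
    "official title": lambda r: r.official_title is not None,
    "primary purpose": lambda r: r.design.primary_purpose_raw is not None,
    "interventional study model":
        lambda r: r.design.interventional_model_raw is not None,
    "number of arms": lambda r: r.design.number_of_arms_raw is not None,
    "allocation": lambda r: r.design.allocation_raw is not None,
    "masking": lambda r: r.design.masking_raw is not None,
    "arm information": lambda r: bool(r.design.arms),
    "intervention description": lambda r: any(i.description
                                              for i in r.interventions),
    "study start date": lambda r: r.start_date_raw is not None,
    "primary completion date":
        lambda r: r.primary_completion_date_raw is not None,
    "study completion date": lambda r: r.completion_date_raw is not None,
    "enrollment": lambda r: r.enrollment_raw is not None,
    "primary outcome measure information": _has_primary_outcomes,
    "outcome measure": lambda r: any(o.measure for o in r.primary_outcomes),
    "outcome time frame": lambda r: any(o.time_frame
                                        for o in r.primary_outcomes),
    "outcome description": lambda r: any(o.description
                                         for o in r.primary_outcomes),
    "accepts healthy volunteers":
        lambda r: r.healthy_volunteers_raw is not None,
    "why study stopped": lambda r: r.why_stopped is not None,
    "individual site status": lambda r: any(l.site_status_raw
                                            for l in r.contacts.locations),
    "availability of expanded access":
        lambda r: r.has_expanded_access_raw is not None,
    "facility information": lambda r: bool(r.contacts.locations),
    "facility name": lambda r: all(l.facility_name
                                   for l in r.contacts.locations),
    "facility city": lambda r: all(l.city for l in r.contacts.locations),
    "facility country": lambda r: all(l.country
                                      for l in r.contacts.locations),
}

#: Sub-fields audited only when their composite parent has occurrences.
_SUBFIELD_PARENT = {
    "outcome measure": "primary outcome measure information",
    "outcome time frame": "primary outcome measure information",
    "outcome description": "primary outcome measure information",
    "facility name": "facility information",
    "facility city": "facility information",
    "facility country": "facility information",
    "individual site status": "facility information",
}

#: Active-condition predicates for conditionally required fields.
_CONDITIONS: dict[str, Callable[[TrialRecord], bool]] = {
    "stopped_before_completion":
        lambda r: r.overall_status_raw in STOPPED_STATUSES,
    "has_listed_locations": lambda r: bool(r.contacts.locations),
}


def _audit_names(registry: Registry) -> list[tuple[str, str, bool, str | None]]:
    """Leaf-level audit entries: (name, requirement, post_only, cond_id).

    Composites expand into their sub-element rows; sub-elements inherit the
    parent's requirement status.
    """
    entries = []
    for spec in registry.audited():
        if spec.value_kind == "composite":
            if spec.dictionary_name in _PRESENCE:
                # multiple-occurrence group: the group itself must occur
                entries.append((spec.dictionary_name, spec.requirement,
                                spec.required_only_after_final_rule,
                                spec.requirement_condition_id))
            for child in registry.children_of(spec.dictionary_name):
                if child.dictionary_name in _PRESENCE:
                    entries.append((child.dictionary_name, spec.requirement,
                                    spec.required_only_after_final_rule,
                                    spec.requirement_condition_id))
        else:
            entries.append((spec.dictionary_name, spec.requirement,
                            spec.required_only_after_final_rule,
                            spec.requirement_condition_id))
    return entries


def audit_completeness(record: TrialRecord, registry: Registry,
                       era_convention: str = "day1") -> CompletenessReport:
    """Audit one interventional record for the 28 required fields.

    Raises ``ValueError`` for non-interventional records: FDAAA801 defines
    required fields for interventional trials only.
    """
    if record.study_type != "Interventional":
        raise ValueError(
            f"completeness is audited on interventional records only; "
            f"{record.record_id} has study_type {record.study_type!r}")

    era = classify_era(record, era_convention)
    _, day_absent = parse_registry_date(record.start_date_raw)
    report = CompletenessReport(
        record_id=record.record_id,
        era=era,
        era_day_convention_applied=day_absent,
        agency_class=record.agency_class,
    )

    for name, requirement, post_only, cond_id in _audit_names(registry):
        if post_only and era == "pre_final_rule":
            continue  # recommended, not required, before the Final Rule
        parent = _SUBFIELD_PARENT.get(name)
        if parent is not None and not _PRESENCE[parent](record):
            continue  # the group is absent; counted once at group level
        if requirement == "conditional":
            active = _CONDITIONS[cond_id](record) if cond_id else True
            if active and not _PRESENCE[name](record):
                report.missing_conditional.add(name)
        else:
            if not _PRESENCE[name](record):
                report.missing_required.add(name)

    report.pi_category = classify_pi(record)
    c = record.contacts
    report.n_locations = len(c.locations)
    report.overall_contact_present = (c.overall_contact is not None
                                      and c.overall_contact.provided)
    report.all_sites_have_contact = bool(c.locations) and all(
        l.site_contact is not None and l.site_contact.provided
        for l in c.locations)
    report.contact_rule_satisfied = (report.overall_contact_present
                                     or report.all_sites_have_contact)
    return report


def classify_pi(record: TrialRecord) -> str:
    """Four-way principal-investigator partition.

    A PI may be named through an investigator-typed responsible party
    ("Principal Investigator" or "Sponsor-Investigator"), through one or
    more overall officials, through both, or through neither.
    """
    rp_is_investigator = (record.parties.responsible_party_type_raw
                          in _INVESTIGATOR_RP_TYPES)
    official_present = bool(record.parties.overall_officials)
    if rp_is_investigator and official_present:
        return "both"
    if rp_is_investigator:
        return "rp_investigator_only"
    if official_present:
        return "official_with_nonscientific_rp"
    return "no_pi"


def audit_contact_details(
    corpus: Iterable[TrialRecord],
) -> tuple[int, int, int]:
    """Count provided contact details lacking a phone number or email.

    Every provided contact (the overall contact and each site contact;
    provided means at least one sub-field present) counts once. Returns
    ``(n_contacts, n_missing_phone, n_missing_email)``.
    """
    n = missing_phone = missing_email = 0
    for record in corpus:
        details = [record.contacts.overall_contact]
        details += [l.site_contact for l in record.contacts.locations]
        for d in details:
            if d is None or not d.provided:
                continue
            n += 1
            if d.phone is None:
                missing_phone += 1
            if d.email is None:
                missing_email += 1
    return n, missing_phone, missing_email
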