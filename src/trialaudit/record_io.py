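"""Reading and writing trial-registration records (public-XML dialect).

A :class:`TrialRecord` is a typed view over one registration. Only elements
the audit consumes are promoted to typed fields; every leaf element
occurrence is additionally preserved verbatim in ``raw_values`` (a mapping
from slash-delimited element path to the ordered list of text values), so
the typed fields are views that never disagree with the raw document. No
value coercion happens here: dates, ages, integers and Booleans are kept as
raw text and interpreted by the validation stage.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Iterable, Iterator

from lxml import etree

log = logging.getLogger(__name__)

__all__ = [
    "TrialRecord", "DesignInfo", "Arm", "PartyInfo", "Official",
    "ContactDetail", "Location", "ContactSet", "OutcomeMeasure",
    "Intervention", "ParseError", "StructuralError", "CorpusReader",
    "read_record", "write_record", "read_corpus", "record_to_json",
    "export_jsonl",
]


class ParseError(ValueError):
    """The source is not well-formed XML."""


class StructuralError(ValueError):
    """Well-formed XML missing structurally required content (the record id)."""


@dataclass
class ContactDetail:
    last_name_raw: str | None = None
    phone: str | None = None
    email: str | None = None

    @property
    def provided(self) -> bool:
        return any((self.last_name_raw, self.phone, self.email))


@dataclass
class Location:
    facility_name: str | None = None
    city: str | None = None
    country: str | None = None
    site_status_raw: str | None = None
    site_contact: ContactDetail | None = None


@dataclass
class ContactSet:
    overall_contact: ContactDetail | None = None
    locations: list[Location] = field(default_factory=list)


@dataclass
class Official:
    last_name_raw: str
    role_raw: str | None = None
    affiliation: str | None = None


@dataclass
class PartyInfo:
    responsible_party_type_raw: str | None = None
    rp_investigator_full_name: str | None = None
    rp_investigator_affiliation: str | None = None
    rp_investigator_title: str | None = None
    overall_officials: list[Official] = field(default_factory=list)


@dataclass
class Arm:
    label: str
    arm_type_raw: str
    description: str | None = None


@dataclass
class DesignInfo:
    interventional_model_raw: str | None = None
    allocation_raw: str | None = None
    masking_raw: str | None = None
    primary_purpose_raw: str | None = None
    observational_model_raw: str | None = None
    time_perspective_raw: str | None = None
    sampling_method_raw: str | None = None
    number_of_arms_raw: str | None = None
    arms: list[Arm] = field(default_factory=list)


@dataclass
class OutcomeMeasure:
    rank: str = "primary"  # primary | secondary
    measure: str | None = None
    time_frame: str | None = None
    description: str | None = None


@dataclass
class Intervention:
    intervention_type: str | None = None
    name: str | None = None
    description: str | None = None


@dataclass
class TrialRecord:
    record_id: str
    study_type: str | None = None
    org_study_id: str | None = None
    secondary_ids: list[str] = field(default_factory=list)
    brief_title: str | None = None
    official_title: str | None = None
    brief_summary: str | None = None
    sponsor_name: str | None = None
    agency_class: str | None = None
    overall_status_raw: str | None = None
    why_stopped: str | None = None
    start_date_raw: str | None = None
    start_date_attr: str | None = None
    completion_date_raw: str | None = None
    completion_date_attr: str | None = None
    primary_completion_date_raw: str | None = None
    primary_completion_date_attr: str | None = None
    verification_date_raw: str | None = None
    phase: str | None = None
    enrollment_raw: str | None = None
    enrollment_attr: str | None = None
    has_expanded_access_raw: str | None = None
    conditions: list[str] = field(default_factory=list)
    interventions: list[Intervention] = field(default_factory=list)
    design: DesignInfo = field(default_factory=DesignInfo)
    outcomes: list[OutcomeMeasure] = field(default_factory=list)
    eligibility_text: str | None = None
    gender: str | None = None
    minimum_age_raw: str | None = None
    maximum_age_raw: str | None = None
    healthy_volunteers_raw: str | None = None
    parties: PartyInfo = field(default_factory=PartyInfo)
    contacts: ContactSet = field(default_factory=ContactSet)
    raw_values: dict[str, list[str]] = field(default_factory=dict)

    @property
    def primary_outcomes(self) -> list[OutcomeMeasure]:
        return [o for o in self.outcomes if o.rank == "primary"]


# ---------------------------------------------------------------------------
# reading


def _text(el: etree._Element | None) -> str | None:
    if el is None or el.text is None:
        return None
    t = el.text.strip()
    return t or None


def _find_text(parent: etree._Element, path: str) -> str | None:
    return _text(parent.find(path))


def _collect_raw(root: etree._Element) -> dict[str, list[str]]:
    raw: dict[str, list[str]] = {}
    for el in root.iter():
        if el is root or not isinstance(el.tag, str):
            continue
        path = root.getroottree().getelementpath(el)
        # strip positional predicates lxml adds for repeated siblings
        path = "/".join(p.split("[")[0] for p in path.split("/"))
        if len(el) == 0:
            t = _text(el)
            if t is not None:
                raw.setdefault(path, []).append(t)
        for attr, value in sorted(el.attrib.items()):
            raw.setdefault(f"{path}@{attr}", []).append(value)
    return raw


def _parse_contact(el: etree._Element | None) -> ContactDetail | None:
    if el is None:
        return None
    return ContactDetail(
        last_name_raw=_find_text(el, "last_name"),
        phone=_find_text(el, "phone"),
        email=_find_text(el, "email"),
    )


def read_record(source: bytes | str | Path | IO[bytes] | etree._Element) -> TrialRecord:
    """Parse one registration document into a :class:`TrialRecord`.

    Unknown elements are preserved in ``raw_values``; nothing is coerced or
    validated beyond well-formedness and the presence of a record id.
    """
    if isinstance(source, etree._Element):
        root = source
    else:
        try:
            if isinstance(source, bytes):
                root = etree.fromstring(source)
            elif isinstance(source, str) and source.lstrip().startswith("<"):
                root = etree.fromstring(source.encode("utf-8"))
            else:
                root = etree.parse(str(source)).getroot()
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"not well-formed XML: {exc}") from exc

    nct = _find_text(root, "id_info/nct_id") or _find_text(root, "nct_id")
    if nct is None:
        raise StructuralError("record has no nct_id element")

    rec = TrialRecord(record_id=nct)
    rec.raw_values = _collect_raw(root)
    rec.study_type = _find_text(root, "study_type")
    rec.org_study_id = _find_text(root, "id_info/org_study_id")
    rec.secondary_ids = [t for el in root.findall("id_info/secondary_id")
                         if (t := _text(el))]
    rec.brief_title = _find_text(root, "brief_title")
    rec.official_title = _find_text(root, "official_title")
    rec.brief_summary = _find_text(root, "brief_summary/textblock")
    rec.sponsor_name = _find_text(root, "sponsors/lead_sponsor/agency")
    rec.agency_class = _find_text(root, "sponsors/lead_sponsor/agency_class")
    rec.overall_status_raw = _find_text(root, "overall_status")
    rec.why_stopped = _find_text(root, "why_stopped")
    for name in ("start_date", "completion_date", "primary_completion_date"):
        el = root.find(name)
        setattr(rec, f"{name}_raw", _text(el))
        setattr(rec, f"{name}_attr",
                el.get("type") if el is not None else None)
    rec.verification_date_raw = _find_text(root, "verification_date")
    rec.phase = _find_text(root, "phase")
    enr = root.find("enrollment")
    rec.enrollment_raw = _text(enr)
    rec.enrollment_attr = enr.get("type") if enr is not None else None
    rec.has_expanded_access_raw = _find_text(
        root, "oversight_info/has_expanded_access")
    rec.conditions = [t for el in root.findall("condition") if (t := _text(el))]
    rec.interventions = [
        Intervention(
            intervention_type=_find_text(el, "intervention_type"),
            name=_find_text(el, "intervention_name"),
            description=_find_text(el, "description"),
        )
        for el in root.findall("intervention")
    ]

    d = rec.design
    sdi = root.find("study_design_info")
    if sdi is not None:
        d.interventional_model_raw = _find_text(sdi, "intervention_model")
        d.allocation_raw = _find_text(sdi, "allocation")
        d.masking_raw = _find_text(sdi, "masking")
        d.primary_purpose_raw = _find_text(sdi, "primary_purpose")
        d.observational_model_raw = _find_text(sdi, "observational_model")
        d.time_perspective_raw = _find_text(sdi, "time_perspective")
    d.number_of_arms_raw = _find_text(root, "number_of_arms")
    d.arms = [
        Arm(label=_find_text(el, "arm_group_label") or "",
            arm_type_raw=_find_text(el, "arm_group_type") or "",
            description=_find_text(el, "description"))
        for el in root.findall("arm_group")
    ]

    for rank, tag in (("primary", "primary_outcome"),
                      ("secondary", "secondary_outcome")):
        for el in root.findall(tag):
            rec.outcomes.append(OutcomeMeasure(
                rank=rank,
                measure=_find_text(el, "measure"),
                time_frame=_find_text(el, "time_frame"),
                description=_find_text(el, "description"),
            ))

    elig = root.find("eligibility")
    if elig is not None:
        rec.eligibility_text = _find_text(elig, "criteria/textblock")
        rec.gender = _find_text(elig, "gender")
        rec.minimum_age_raw = _find_text(elig, "minimum_age")
        rec.maximum_age_raw = _find_text(elig, "maximum_age")
        rec.healthy_volunteers_raw = _find_text(elig, "healthy_volunteers")
        d.sampling_method_raw = _find_text(elig, "sampling_method")

    p = rec.parties
    rp = root.find("responsible_party")
    if rp is not None:
        p.responsible_party_type_raw = _find_text(rp, "responsible_party_type")
        p.rp_investigator_full_name = _find_text(rp, "investigator_full_name")
        p.rp_investigator_affiliation = _find_text(rp, "investigator_affiliation")
        p.rp_investigator_title = _find_text(rp, "investigator_title")
    p.overall_officials = [
        Official(last_name_raw=_find_text(el, "last_name") or "",
                 role_raw=_find_text(el, "role"),
                 affiliation=_find_text(el, "affiliation"))
        for el in root.findall("overall_official")
    ]

    c = rec.contacts
    c.overall_contact = _parse_contact(root.find("overall_contact"))
    for el in root.findall("location"):
        c.locations.append(Location(
            facility_name=_find_text(el, "facility/name"),
            city=_find_text(el, "facility/address/city"),
            country=_find_text(el, "facility/address/country"),
            site_status_raw=_find_text(el, "status"),
            site_contact=_parse_contact(el.find("contact")),
        ))
    return rec


# ---------------------------------------------------------------------------
# writing


def _sub(parent: etree._Element, tag: str, text: str | None,
         attr: str | None = None, attr_name: str = "type") -> None:
    if text is None and attr is None:
        return
    el = etree.SubElement(parent, tag)
    el.text = text
    if attr is not None:
        el.set(attr_name, attr)


def write_record(record: TrialRecord) -> bytes:
    """Serialize a :class:`TrialRecord` to the public-XML dialect.

    Element ordering is fixed, so serialization is deterministic and
    ``read_record(write_record(r))`` reproduces every retained field.
    """
    root = etree.Element("clinical_study")
    idinfo = etree.SubElement(root, "id_info")
    _sub(idinfo, "org_study_id", record.org_study_id)
    for sid in record.secondary_ids:
        _sub(idinfo, "secondary_id", sid)
    _sub(idinfo, "nct_id", record.record_id)
    _sub(root, "brief_title", record.brief_title)
    _sub(root, "official_title", record.official_title)
    sponsors = etree.SubElement(root, "sponsors")
    lead = etree.SubElement(sponsors, "lead_sponsor")
    _sub(lead, "agency", record.sponsor_name)
    _sub(lead, "agency_class", record.agency_class)
    if record.brief_summary is not None:
        bs = etree.SubElement(root, "brief_summary")
        _sub(bs, "textblock", record.brief_summary)
    _sub(root, "overall_status", record.overall_status_raw)
    _sub(root, "why_stopped", record.why_stopped)
    _sub(root, "start_date", record.start_date_raw, record.start_date_attr)
    _sub(root, "completion_date", record.completion_date_raw,
         record.completion_date_attr)
    _sub(root, "primary_completion_date", record.primary_completion_date_raw,
         record.primary_completion_date_attr)
    _sub(root, "phase", record.phase)
    _sub(root, "study_type", record.study_type)
    if record.has_expanded_access_raw is not None:
        ov = etree.SubElement(root, "oversight_info")
        _sub(ov, "has_expanded_access", record.has_expanded_access_raw)

    d = record.design
    if any((d.interventional_model_raw, d.allocation_raw, d.masking_raw,
            d.primary_purpose_raw, d.observational_model_raw,
            d.time_perspective_raw)):
        sdi = etree.SubElement(root, "study_design_info")
        _sub(sdi, "allocation", d.allocation_raw)
        _sub(sdi, "intervention_model", d.interventional_model_raw)
        _sub(sdi, "primary_purpose", d.primary_purpose_raw)
        _sub(sdi, "masking", d.masking_raw)
        _sub(sdi, "observational_model", d.observational_model_raw)
        _sub(sdi, "time_perspective", d.time_perspective_raw)

    for o in record.outcomes:
        tag = "primary_outcome" if o.rank == "primary" else "secondary_outcome"
        el = etree.SubElement(root, tag)
        _sub(el, "measure", o.measure)
        _sub(el, "time_frame", o.time_frame)
        _sub(el, "description", o.description)
    _sub(root, "number_of_arms", d.number_of_arms_raw)
    _sub(root, "enrollment", record.enrollment_raw, record.enrollment_attr)
    for cond in record.conditions:
        _sub(root, "condition", cond)
    for arm in d.arms:
        el = etree.SubElement(root, "arm_group")
        _sub(el, "arm_group_label", arm.label or None)
        _sub(el, "arm_group_type", arm.arm_type_raw or None)
        _sub(el, "description", arm.description)
    for iv in record.interventions:
        el = etree.SubElement(root, "intervention")
        _sub(el, "intervention_type", iv.intervention_type)
        _sub(el, "intervention_name", iv.name)
        _sub(el, "description", iv.description)

    elig_fields = (record.eligibility_text, record.gender,
                   record.minimum_age_raw, record.maximum_age_raw,
                   record.healthy_volunteers_raw, d.sampling_method_raw)
    if any(v is not None for v in elig_fields):
        elig = etree.SubElement(root, "eligibility")
        if record.eligibility_text is not None:
            crit = etree.SubElement(elig, "criteria")
            _sub(crit, "textblock", record.eligibility_text)
        _sub(elig, "gender", record.gender)
        _sub(elig, "minimum_age", record.minimum_age_raw)
        _sub(elig, "maximum_age", record.maximum_age_raw)
        _sub(elig, "healthy_volunteers", record.healthy_volunteers_raw)
        _sub(elig, "sampling_method", d.sampling_method_raw)

    for off in record.parties.overall_officials:
        el = etree.SubElement(root, "overall_official")
        _sub(el, "last_name", off.last_name_raw or None)
        _sub(el, "role", off.role_raw)
        _sub(el, "affiliation", off.affiliation)
    oc = record.contacts.overall_contact
    if oc is not None:
        el = etree.SubElement(root, "overall_contact")
        _sub(el, "last_name", oc.last_name_raw)
        _sub(el, "phone", oc.phone)
        _sub(el, "email", oc.email)
    for loc in record.contacts.locations:
        el = etree.SubElement(root, "location")
        fac = etree.SubElement(el, "facility")
        _sub(fac, "name", loc.facility_name)
        if loc.city is not None or loc.country is not None:
            addr = etree.SubElement(fac, "address")
            _sub(addr, "city", loc.city)
            _sub(addr, "country", loc.country)
        _sub(el, "status", loc.site_status_raw)
        sc = loc.site_contact
        if sc is not None:
            cel = etree.SubElement(el, "contact")
            _sub(cel, "last_name", sc.last_name_raw)
            _sub(cel, "phone", sc.phone)
            _sub(cel, "email", sc.email)
    rp = record.parties
    if any((rp.responsible_party_type_raw, rp.rp_investigator_full_name,
            rp.rp_investigator_affiliation, rp.rp_investigator_title)):
        el = etree.SubElement(root, "responsible_party")
        _sub(el, "responsible_party_type", rp.responsible_party_type_raw)
        _sub(el, "investigator_full_name", rp.rp_investigator_full_name)
        _sub(el, "investigator_affiliation", rp.rp_investigator_affiliation)
        _sub(el, "investigator_title", rp.rp_investigator_title)
    _sub(root, "verification_date", record.verification_date_raw)

    return etree.tostring(root, pretty_print=True, encoding="UTF-8",
                          xml_declaration=True)


# ---------------------------------------------------------------------------
# corpus streaming


class CorpusReader:
    """Streams records from a directory or zip of per-record XML files.

    Files are visited in lexicographic name order; per-file parse failures
    are collected in :attr:`errors` (as ``(name, message)`` pairs) without
    aborting the stream, and non-XML entries are skipped with a warning.
    """

    def __init__(self, source: str | Path):
        self.source = Path(source)
        self.errors: list[tuple[str, str]] = []
        if not self.source.exists():
            raise IOError(f"corpus container not found: {self.source}")

    def _entries(self) -> Iterator[tuple[str, bytes]]:
        if self.source.is_dir():
            for p in sorted(self.source.iterdir()):
                if p.suffix.lower() != ".xml":
                    if p.is_file():
                        log.warning("skipping non-XML entry %s", p.name)
                    continue
                yield p.name, p.read_bytes()
        elif zipfile.is_zipfile(self.source):
            with zipfile.ZipFile(self.source) as zf:
                for name in sorted(zf.namelist()):
                    if not name.lower().endswith(".xml"):
                        log.warning("skipping non-XML entry %s", name)
                        continue
                    yield name, zf.read(name)
        else:
            raise IOError(f"{self.source} is neither a directory nor a zip")

    def __iter__(self) -> Iterator[TrialRecord]:
        for name, data in self._entries():
            try:
                yield read_record(data)
            except (ParseError, StructuralError) as exc:
                self.errors.append((name, str(exc)))


def read_corpus(source: str | Path) -> CorpusReader:
    """Open a corpus container for streaming (constant memory in corpus size)."""
    return CorpusReader(source)


# ---------------------------------------------------------------------------
# debugging export


def record_to_json(record: TrialRecord) -> dict:
    return asdict(record)


def export_jsonl(records: Iterable[TrialRecord], path: str | Path) -> int:
    """Write records as JSON Lines; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_json(rec), sort_keys=True) + "\n")
            n += 1
    return n
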