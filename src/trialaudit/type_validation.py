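"""Simple-type and enumerated-value validation of trial records.

Boolean, integer, date and age fields are checked against the registry
dialect's grammars; enumerated fields are checked against the data
dictionary's permitted sets, with the two known record-syntax divergences
(interventional study model and masking) accepted and annotated rather than
flagged as rogue. All violations are emitted as :class:`Finding` values;
validation never raises on bad data.

Grammars (anchored, case-sensitive):

* Boolean: exactly ``Yes`` or ``No``.
* Integer: a sign-free decimal integer.
* Date: ``Unknown``, or a month name, an optional day 1-31 and a comma, and
  a four-digit year — ``January 3, 2004`` or ``March, 2005``. The optional
  XML attribute must be ``Actual``, ``Anticipated`` or ``Estimate``. Day
  plausibility (e.g. ``February 31, 2010``) is accepted by the grammar; an
  optional strict mode rejects impossible calendar dates.
* Age: ``N/A``, or a positive integer without leading zeros, one space, and
  a unit word (Year(s), Month(s), Week(s), Day(s), Hour(s), Minute(s)).
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass

from .record_io import TrialRecord
from .schema_registry import FieldSpec, Registry

__all__ = [
    "Finding", "NormalizedAge", "SEVERITY_BY_CODE", "MONTHS",
    "MINUTES_PER_UNIT", "DATE_RE", "AGE_RE", "INTEGER_RE", "BOOLEAN_VALUES",
    "DATE_ATTR_VALUES", "date_matches", "age_matches", "normalize_age",
    "validate_simple", "validate_enumerated", "canonicalize_enumerated",
    "CanonicalizationError",
]

#: PRS warning levels.
SEVERITIES = ("error", "warning", "alert", "note")

#: Severity attached to each finding code. The entry system documents four
#: warning levels but no per-rule mapping (its own level assignment is
#: visibly inconsistent), so this mapping is this package's convention.
SEVERITY_BY_CODE = {
    "TYPE_MISMATCH": "error",
    "ROGUE_VALUE": "warning",
    "MISSING_REQUIRED": "error",
    "MISSING_CONDITIONAL": "warning",
    "FORMAT_VARIANT": "note",
}


@dataclass(frozen=True)
class Finding:
    """One audit observation: the atom every report aggregates."""

    record_id: str
    dictionary_name: str
    severity: str
    code: str
    observed: str | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        assert self.severity in SEVERITIES
        assert self.code and self.dictionary_name

    def to_json(self) -> dict:
        return {
            "record_id": self.record_id,
            "dictionary_name": self.dictionary_name,
            "severity": self.severity,
            "code": self.code,
            "observed": self.observed,
            "detail": self.detail,
        }


def _finding(record: TrialRecord, spec: FieldSpec, code: str,
             observed: str | None, detail: str) -> Finding:
    return Finding(record_id=record.record_id,
                   dictionary_name=spec.dictionary_name,
                   severity=SEVERITY_BY_CODE[code], code=code,
                   observed=observed, detail=detail)


MONTHS = ("January", "February", "March", "April", "May", "June", "July",
          "August", "September", "October", "November", "December")

_DAY = r"([1-9]|[12][0-9]|3[01])"
DATE_RE = re.compile(
    r"^(Unknown|(?P<month>" + "|".join(MONTHS) + r")"
    r"( (?P<day>" + _DAY + r"))?, (?P<year>[12][0-9]{3}))$"
)
DATE_ATTR_VALUES = frozenset({"Actual", "Anticipated", "Estimate"})

AGE_UNITS = ("Year", "Years", "Month", "Months", "Week", "Weeks",
             "Day", "Days", "Hour", "Hours", "Minute", "Minutes")
AGE_RE = re.compile(
    r"^(N/A|(?P<mag>[1-9][0-9]*) (?P<unit>" + "|".join(AGE_UNITS) + r"))$"
)

INTEGER_RE = re.compile(r"^[0-9]+$")
BOOLEAN_VALUES = frozenset({"Yes", "No"})

#: Fixed minute-equivalents used to compare ages across units.
MINUTES_PER_UNIT = {
    "Year": 525_600,
    "Month": 43_800,
    "Week": 10_080,
    "Day": 1_440,
    "Hour": 60,
    "Minute": 1,
}


def date_matches(raw: str, strict: bool = False) -> bool:
    """Whether ``raw`` matches the date grammar.

    With ``strict=True``, additionally require the day (when present) to be
    a possible day of the named month and year.
    """
    m = DATE_RE.match(raw)
    if m is None:
        return False
    if strict and m.group("day"):
        month = MONTHS.index(m.group("month")) + 1
        _, last = calendar.monthrange(int(m.group("year")), month)
        return int(m.group("day")) <= last
    return True


def age_matches(raw: str) -> bool:
    return AGE_RE.match(raw) is not None


@dataclass(frozen=True)
class NormalizedAge:
    """An age value reduced to a magnitude, a singular unit and minutes."""

    raw: str
    magnitude: int
    unit: str  # Minute | Hour | Day | Week | Month | Year | not_applicable
    minutes_equivalent: int | None

    @property
    def not_applicable(self) -> bool:
        return self.unit == "not_applicable"


def normalize_age(raw: str) -> NormalizedAge:
    """Parse an age-grammar value into magnitude, unit and minute equivalent.

    ``"2 Years"`` and ``"24 Months"`` normalize to the same
    ``minutes_equivalent`` (1,051,200); ``"N/A"`` maps to the
    ``not_applicable`` sentinel with no minute equivalent.
    """
    m = AGE_RE.match(raw)
    if m is None:
        raise ValueError(f"not a valid age value: {raw!r}")
    if m.group("mag") is None:
        return NormalizedAge(raw=raw, magnitude=0, unit="not_applicable",
                             minutes_equivalent=None)
    magnitude = int(m.group("mag"))
    unit = m.group("unit")
    if unit.endswith("s"):
        unit = unit[:-1]
    return NormalizedAge(raw=raw, magnitude=magnitude, unit=unit,
                         minutes_equivalent=magnitude * MINUTES_PER_UNIT[unit])


# ---------------------------------------------------------------------------
# simple-type validation


def validate_simple(record: TrialRecord, registry: Registry,
                    strict_dates: bool = False) -> list[Finding]:
    """Check every occurrence of every Boolean/integer/date/age field.

    Returns one ``TYPE_MISMATCH`` finding per violating occurrence; a fully
    conformant record yields an empty list. Absent fields are the
    completeness audit's concern, not this stage's.
    """
    findings: list[Finding] = []
    for spec in registry.of_kind("boolean", "integer", "date", "age"):
        if not spec.xml_path:
            continue
        for raw in record.raw_values.get(spec.xml_path, []):
            value = raw.strip()
            if spec.value_kind == "boolean":
                ok = value in BOOLEAN_VALUES
                expected = "Yes or No"
            elif spec.value_kind == "integer":
                ok = INTEGER_RE.match(value) is not None
                expected = "a decimal integer"
            elif spec.value_kind == "date":
                ok = date_matches(value, strict=strict_dates)
                expected = "Unknown, or like 'January 3, 2004' / 'March, 2005'"
            else:  # age
                ok = age_matches(value)
                expected = "N/A, or like '18 Years'"
            if not ok:
                findings.append(_finding(
                    record, spec, "TYPE_MISMATCH", raw,
                    f"expected {expected}"))
        if spec.value_kind == "date":
            for attr in record.raw_values.get(spec.xml_path + "@type", []):
                if attr not in DATE_ATTR_VALUES:
                    findings.append(_finding(
                        record, spec, "TYPE_MISMATCH", attr,
                        "date attribute must be Actual, Anticipated or "
                        "Estimate"))
    return findings


# ---------------------------------------------------------------------------
# enumerated-value validation


_MASKING_COUNT_WORDS = {"Single": 1, "Double": 2, "Triple": 3, "Quadruple": 4}
_MASKING_RE = re.compile(
    r"^(?P<count>Single|Double|Triple|Quadruple)\((?P<roles>[^()]*)\)$")
_MASKING_ROLES = ("Participant", "Care Provider", "Investigator",
                  "Outcomes Assessor")


class CanonicalizationError(ValueError):
    """Record-form value cannot be mapped to dictionary form."""


def _parse_masking(value: str) -> tuple[str, ...] | None:
    """Roles named by a record-form masking value, or None if invalid."""
    if value == "No Masking":
        return ("No Masking",)
    m = _MASKING_RE.match(value)
    if m is None:
        return None
    roles = tuple(r.strip() for r in m.group("roles").split(","))
    if not all(r in _MASKING_ROLES for r in roles):
        return None
    if len(set(roles)) != len(roles):
        return None
    if _MASKING_COUNT_WORDS[m.group("count")] != len(roles):
        return None
    return roles


def validate_enumerated(record: TrialRecord, registry: Registry) -> list[Finding]:
    """Check every occurrence of every enumerated field against its set.

    Matching is exact and case-sensitive after trimming. Values valid only
    in record-form syntax (interventional study model's ``... Assignment``
    suffix; masking's ``Double(Participant, Care Provider)``) are accepted,
    with a ``FORMAT_VARIANT`` note recording the dictionary-form
    divergence; everything else outside the permitted set is a
    ``ROGUE_VALUE`` warning.
    """
    findings: list[Finding] = []
    for spec in registry.of_kind("enumerated"):
        record_form = spec.record_values()
        for raw in record.raw_values.get(spec.xml_path, []):
            value = raw.strip()
            if record_form == "@masking_pattern":
                if value in spec.allowed_values_dictionary:
                    continue
                roles = _parse_masking(value)
                if roles is not None:
                    findings.append(_finding(
                        record, spec, "FORMAT_VARIANT", raw,
                        "record syntax Count(role, ...) diverges from the "
                        "dictionary's role list"))
                else:
                    findings.append(_finding(
                        record, spec, "ROGUE_VALUE", raw,
                        "not a permitted masking value"))
            elif record_form is not spec.allowed_values_dictionary and record_form:
                # distinct record-form set (interventional study model)
                if value in spec.allowed_values_dictionary:
                    continue
                if value in record_form:
                    findings.append(_finding(
                        record, spec, "FORMAT_VARIANT", raw,
                        "record syntax diverges from the dictionary value "
                        f"{canonicalize_enumerated(spec, value)!r}"))
                else:
                    findings.append(_finding(
                        record, spec, "ROGUE_VALUE", raw,
                        "not in the permitted value set"))
            else:
                if value not in spec.allowed_values_dictionary:
                    findings.append(_finding(
                        record, spec, "ROGUE_VALUE", raw,
                        "not in the permitted value set"))
    return findings


#: Record-form -> dictionary-form for the interventional study model.
_MODEL_CANONICAL = {
    "Single Group Assignment": "Single Group",
    "Parallel Group Assignment": "Parallel",
    "Crossover Assignment": "Crossover",
    "Factorial Assignment": "Factorial",
    "Sequential Assignment": "Sequential",
}


def canonicalize_enumerated(field: FieldSpec, observed: str):
    """Map a valid record-form value to its dictionary form.

    For the interventional study model this strips the ``Assignment``
    suffix (``"Parallel Group Assignment"`` -> ``"Parallel"``); for masking
    it returns the set of masked roles, discarding the
    Single/Double/Triple/Quadruple count word after checking that the count
    word equals the number of roles. Other enumerated fields are identity.
    """
    observed = observed.strip()
    if field.record_values() == "@masking_pattern":
        if observed in field.allowed_values_dictionary:
            return frozenset({observed})
        m = _MASKING_RE.match(observed)
        if m is None:
            raise CanonicalizationError(
                f"not a record-form masking value: {observed!r}")
        roles = tuple(r.strip() for r in m.group("roles").split(","))
        bad = [r for r in roles if r not in _MASKING_ROLES]
        if bad:
            raise CanonicalizationError(f"unknown masking roles: {bad}")
        if _MASKING_COUNT_WORDS[m.group("count")] != len(set(roles)):
            raise CanonicalizationError(
                f"count word {m.group('count')!r} does not match "
                f"{len(set(roles))} role(s) in {observed!r}")
        return frozenset(roles)
    if field.dictionary_name == "interventional study model":
        if observed in field.allowed_values_dictionary:
            return observed
        try:
            return _MODEL_CANONICAL[observed]
        except KeyError:
            raise CanonicalizationError(
                f"not a record-form study model: {observed!r}") from None
    if observed in field.allowed_values_dictionary:
        return observed
    raise CanonicalizationError(
        f"{observed!r} is not a permitted value for {field.dictionary_name}")


# ---------------------------------------------------------------------------
# findings export


def findings_to_jsonl(findings, path) -> int:
    """Write findings as JSON Lines (one finding per line)."""
    import json

    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for f in findings:
            fh.write(json.dumps(f.to_json(), sort_keys=True) + "\n")
            n += 1
    return n
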