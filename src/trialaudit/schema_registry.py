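"""Machine-readable registry of the ClinicalTrials.gov data dictionary.

Each data-dictionary element is encoded as a :class:`FieldSpec` carrying its
type category, enumerated value sets (in dictionary form and, where the
record syntax differs, in record form), requirement status under FDAAA801
and its Final Rule, and the dictionary <-> XML <-> FDAAA801 <-> WHO name
mapping. The registry ships as a versioned TSV inside the package
(``data/registry.tsv``) and is the single source of truth for every other
audit stage.
"""

from __future__ import annotations

import datetime
import difflib
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping

__all__ = [
    "FieldSpec",
    "Registry",
    "RegistryError",
    "LookupError_",
    "FINAL_RULE_CUTOFF",
    "PRE_RULE_RECOMMENDED_FIELDS",
    "load_registry",
    "lookup",
]

#: Effective date of the FDAAA801 Final Rule: element definitions are
#: legally required for trials whose start date is on or after this day.
FINAL_RULE_CUTOFF = datetime.date(2017, 1, 18)

#: Fields that were recommended, but not required, for studies starting
#: before the Final Rule's effective date.
PRE_RULE_RECOMMENDED_FIELDS = frozenset(
    {"official title", "why study stopped", "study start date",
     "study completion date"}
)

VALUE_KINDS = frozenset(
    {"boolean", "integer", "date", "age", "enumerated",
     "ontology_recommended", "free_text", "composite"}
)
REQUIREMENTS = frozenset(
    {"always", "conditional", "optional", "excluded_from_audit"}
)
EXCLUSION_REASONS = frozenset(
    {"none", "conditional_unknowable", "internal_nonpublic",
     "post_2017_addition", "administrative_always_present"}
)
APPLICABILITIES = frozenset(
    {"interventional", "observational", "expanded_access"}
)
NAMESPACES = ("dictionary", "xml", "fdaaa", "who")


class RegistryError(ValueError):
    """Raised for malformed registry data or bad overrides."""


class LookupError_(KeyError):
    """Raised when a name cannot be resolved in the requested namespace."""


@dataclass(frozen=True)
class FieldSpec:
    """One registry entry for a data-dictionary element."""

    dictionary_name: str
    xml_path: str
    value_kind: str
    allowed_values_dictionary: tuple[str, ...] = ()
    allowed_values_record_form: tuple[str, ...] | str = ()
    multiplicity: str = "single"
    xsd_typed: bool = False
    fdaaa_field: str | None = None
    who_field: str | None = None
    requirement: str = "optional"
    requirement_condition_id: str | None = None
    required_only_after_final_rule: bool = False
    applicability: frozenset[str] = APPLICABILITIES
    exclusion_reason: str = "none"
    parent: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise RegistryError(
                f"{self.dictionary_name}: unknown value_kind {self.value_kind!r}")
        if self.requirement not in REQUIREMENTS:
            raise RegistryError(
                f"{self.dictionary_name}: unknown requirement {self.requirement!r}")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise RegistryError(
                f"{self.dictionary_name}: unknown exclusion_reason "
                f"{self.exclusion_reason!r}")
        if bool(self.allowed_values_dictionary) != (self.value_kind == "enumerated"):
            raise RegistryError(
                f"{self.dictionary_name}: allowed_values_dictionary must be "
                f"nonempty iff value_kind is 'enumerated'")
        if (self.requirement == "excluded_from_audit") != (
                self.exclusion_reason != "none"):
            raise RegistryError(
                f"{self.dictionary_name}: requirement 'excluded_from_audit' "
                f"iff exclusion_reason is set")
        if not self.applicability <= APPLICABILITIES:
            raise RegistryError(
                f"{self.dictionary_name}: bad applicability {self.applicability}")

    @property
    def xml_leaf(self) -> str:
        return self.xml_path.rsplit("/", 1)[-1] if self.xml_path else ""

    def record_values(self) -> tuple[str, ...] | str:
        """Allowed values as they appear in records.

        Returns the record-form set where the record syntax diverges from
        the dictionary (or the sentinel ``"@masking_pattern"``); otherwise
        the dictionary set itself.
        """
        return self.allowed_values_record_form or self.allowed_values_dictionary


class Registry:
    """An ordered, name-indexed collection of :class:`FieldSpec`."""

    def __init__(self, specs: Iterable[FieldSpec]):
        self._specs: list[FieldSpec] = list(specs)
        self._by_dictionary: dict[str, FieldSpec] = {}
        for spec in self._specs:
            if spec.dictionary_name in self._by_dictionary:
                raise RegistryError(
                    f"duplicate dictionary_name {spec.dictionary_name!r}")
            self._by_dictionary[spec.dictionary_name] = spec
        self._by_xml_path = {s.xml_path: s for s in self._specs if s.xml_path}
        leaves: dict[str, list[FieldSpec]] = {}
        for s in self._specs:
            if s.xml_path:
                leaves.setdefault(s.xml_leaf, []).append(s)
        self._by_xml_leaf = leaves
        self._by_fdaaa = {s.fdaaa_field: s for s in self._specs if s.fdaaa_field}
        self._by_who = {s.who_field: s for s in self._specs if s.who_field}

    def __iter__(self) -> Iterator[FieldSpec]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, dictionary_name: str) -> bool:
        return dictionary_name in self._by_dictionary

    def get(self, dictionary_name: str) -> FieldSpec:
        return self.lookup(dictionary_name, "dictionary")

    def lookup(self, name: str, namespace: str = "dictionary") -> FieldSpec:
        """Resolve ``name`` in one of the four naming namespaces.

        Matching is exact after trimming surrounding whitespace. In the
        ``xml`` namespace a full slash path is tried first, then an
        unambiguous leaf element name.
        """
        if namespace not in NAMESPACES:
            raise RegistryError(f"unknown namespace {namespace!r}")
        name = name.strip()
        if namespace == "dictionary":
            table: Mapping[str, FieldSpec] = self._by_dictionary
        elif namespace == "fdaaa":
            table = self._by_fdaaa
        elif namespace == "who":
            table = self._by_who
        else:  # xml
            if name in self._by_xml_path:
                return self._by_xml_path[name]
            hits = self._by_xml_leaf.get(name, [])
            if len(hits) == 1:
                return hits[0]
            if len(hits) > 1:
                raise LookupError_(
                    f"ambiguous XML leaf {name!r}; candidates: "
                    + ", ".join(sorted(h.xml_path for h in hits)))
            table = self._by_xml_path
        if name in table:
            return table[name]
        near = difflib.get_close_matches(name, table.keys(), n=3, cutoff=0.5)
        raise LookupError_(
            f"no {namespace} field named {name!r}"
            + (f"; did you mean: {', '.join(near)}?" if near else ""))

    # -- audit-facing selections --------------------------------------------

    def audited(self) -> list[FieldSpec]:
        """Top-level FDAAA801 fields subject to the completeness audit."""
        return [s for s in self._specs
                if s.fdaaa_field and s.requirement in ("always", "conditional")]

    def excluded(self, reason: str | None = None) -> list[FieldSpec]:
        specs = [s for s in self._specs
                 if s.requirement == "excluded_from_audit"]
        if reason is not None:
            specs = [s for s in specs if s.exclusion_reason == reason]
        return specs

    def of_kind(self, *kinds: str) -> list[FieldSpec]:
        return [s for s in self._specs if s.value_kind in kinds]

    def children_of(self, dictionary_name: str) -> list[FieldSpec]:
        return [s for s in self._specs if s.parent == dictionary_name]


def _parse_row(cells: list[str], lineno: int) -> FieldSpec:
    if len(cells) != 16:
        raise RegistryError(f"registry.tsv line {lineno}: expected 16 columns, "
                            f"got {len(cells)}")
    (name, path, kind, dv, rv, mult, typed, fdaaa, who, req, cond, post,
     appl, excl, parent, notes) = cells
    record_form: tuple[str, ...] | str
    if rv.startswith("@"):
        record_form = rv
    else:
        record_form = tuple(v for v in rv.split("|") if v)
    appl_set = (APPLICABILITIES if appl in ("all", "")
                else frozenset(appl.split("|")))
    return FieldSpec(
        dictionary_name=name,
        xml_path=path,
        value_kind=kind,
        allowed_values_dictionary=tuple(v for v in dv.split("|") if v),
        allowed_values_record_form=record_form,
        multiplicity=mult or "single",
        xsd_typed=typed == "1",
        fdaaa_field=fdaaa or None,
        who_field=who or None,
        requirement=req,
        requirement_condition_id=cond or None,
        required_only_after_final_rule=post == "1",
        applicability=appl_set,
        exclusion_reason=excl or "none",
        parent=parent or None,
        notes=notes,
    )


def _builtin_rows() -> list[FieldSpec]:
    text = (resources.files("trialaudit") / "data" / "registry.tsv").read_text(
        encoding="utf-8")
    specs = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        specs.append(_parse_row(line.split("\t"), lineno))
    return specs


def load_registry(
    overrides: Mapping[str, Mapping[str, object]] | None = None,
) -> Registry:
    """Load the built-in field registry, optionally overriding entries.

    Parameters
    ----------
    overrides
        Mapping from ``dictionary_name`` to a mapping of FieldSpec field
        names to replacement values, e.g. ``{"enrollment": {"requirement":
        "optional"}}``. Every key must name an existing registry element.
    """
    specs = _builtin_rows()
    if overrides:
        known = {s.dictionary_name for s in specs}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise RegistryError(
                "overrides reference unknown dictionary elements: "
                + ", ".join(unknown))
        specs = [
            replace(s, **dict(overrides[s.dictionary_name]))
            if s.dictionary_name in overrides else s
            for s in specs
        ]
    return Registry(specs)


def lookup(registry: Registry, name: str, namespace: str = "dictionary") -> FieldSpec:
    """Functional alias for :meth:`Registry.lookup`."""
    return registry.lookup(name, namespace)
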