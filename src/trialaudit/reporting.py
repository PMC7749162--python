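"""Corpus-level orchestration and paper-shaped summary tables.

``run_audit`` makes a single streaming pass over a corpus, applying
simple-type validation, enumerated-value validation, the completeness
audit (interventional records only), eligibility-criteria classification
and lexicon coverage, and accumulates one :class:`CorpusSummary`.
``render`` writes the summary as JSON or as a set of delimited tables
(per-field type violations; rogue counts with observed examples; missing
required fields split by era and by agency class; the PI partition;
contact accounting; criteria format classes with a multi-group
extrapolation; coverage per vocabulary and per intervention type).

Rendering precision is table-specific: criteria-class percentages carry
one decimal, other percentages are integers. An asterisk after a percent
flags an empty denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .completeness_audit import (
    PI_CATEGORIES,
    audit_completeness,
    audit_contact_details,
)
from .eligibility_criteria import (
    FORMAT_CLASSES,
    classify_criteria,
    extrapolate,
)
from .lexicon_coverage import Lexicon, match_terms
from .record_io import CorpusReader, TrialRecord, read_corpus
from .schema_registry import Registry
from .type_validation import (
    Finding,
    validate_enumerated,
    validate_simple,
)

__all__ = ["CorpusSummary", "run_audit", "render", "fmt_pct"]

ERA_COLUMNS = ("pre_final_rule", "post_final_rule", "unknown_start_date")


@dataclass
class CorpusSummary:
    n_records: int = 0
    n_interventional: int = 0
    n_findings: int = 0
    #: field -> code -> count (simple-type stage)
    simple_violations: dict = field(default_factory=dict)
    #: field -> {count, examples} (rogue values) and field -> count (variants)
    rogue_values: dict = field(default_factory=dict)
    format_variants: dict = field(default_factory=dict)
    #: field -> {era: count, "all": count, "by_agency": {class: count}}
    missing_fields: dict = field(default_factory=dict)
    #: interventional record count per era / per agency class
    era_denominators: dict = field(default_factory=dict)
    agency_denominators: dict = field(default_factory=dict)
    pi_partition: dict = field(default_factory=dict)
    contact_summary: dict = field(default_factory=dict)
    criteria_classes: dict = field(default_factory=dict)
    multi_group_suspected: int = 0
    multi_group_extrapolation: dict = field(default_factory=dict)
    coverage_tables: list = field(default_factory=list)
    parse_errors: list = field(default_factory=list)

    def to_json(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "n_records", "n_interventional", "n_findings",
            "simple_violations", "rogue_values", "format_variants",
            "missing_fields", "era_denominators", "agency_denominators",
            "pi_partition", "contact_summary", "criteria_classes",
            "multi_group_suspected", "multi_group_extrapolation",
            "parse_errors")}
        out["coverage_tables"] = [
            {"stratum": t.stratum, "total_values": t.total_values,
             "per_source_matched": dict(sorted(t.per_source_matched.items())),
             "union_matched": t.union_matched, "unmatched": t.unmatched,
             "field": f}
            for f, t in self.coverage_tables]
        return out


def run_audit(
    corpus: str | Path | Iterable[TrialRecord],
    registry: Registry,
    lexicons: Sequence[Lexicon] = (),
    *,
    strict_dates: bool = False,
    era_convention: str = "day1",
    restrict_to: Iterable[str] | None = None,
) -> tuple[CorpusSummary, list[Finding]]:
    """Audit a corpus (a path or an iterable of records) in one pass."""
    if isinstance(corpus, (str, Path)):
        corpus = read_corpus(corpus)

    summary = CorpusSummary()
    summary.pi_partition = {cat: 0 for cat in PI_CATEGORIES}
    summary.criteria_classes = {cls: 0 for cls in FORMAT_CLASSES}
    contact = {"n_contacts": 0, "missing_phone": 0, "missing_email": 0,
               "records_without_overall_contact": 0,
               "records_contact_rule_unsatisfied": 0}
    findings: list[Finding] = []
    condition_values: list[str] = []
    intervention_values: dict[str, list[str]] = {}
    incorrect_format = 0  # headers_only + malformed_headers
    multi_in_incorrect = 0

    for record in corpus:
        summary.n_records += 1

        findings.extend(validate_simple(record, registry,
                                        strict_dates=strict_dates))
        for f in validate_enumerated(record, registry):
            findings.append(f)
            if f.code == "ROGUE_VALUE":
                entry = summary.rogue_values.setdefault(
                    f.dictionary_name, {"count": 0, "examples": []})
                entry["count"] += 1
                if f.observed not in entry["examples"]:
                    entry["examples"] = sorted(
                        set(entry["examples"]) | {f.observed})[:5]
            elif f.code == "FORMAT_VARIANT":
                summary.format_variants[f.dictionary_name] = (
                    summary.format_variants.get(f.dictionary_name, 0) + 1)

        if record.study_type == "Interventional":
            summary.n_interventional += 1
            report = audit_completeness(record, registry,
                                        era_convention=era_convention)
            summary.era_denominators[report.era] = (
                summary.era_denominators.get(report.era, 0) + 1)
            agency = report.agency_class or "(absent)"
            summary.agency_denominators[agency] = (
                summary.agency_denominators.get(agency, 0) + 1)
            for name in report.missing:
                entry = summary.missing_fields.setdefault(
                    name, {"all": 0, "by_agency": {}})
                entry["all"] += 1
                entry[report.era] = entry.get(report.era, 0) + 1
                entry["by_agency"][agency] = (
                    entry["by_agency"].get(agency, 0) + 1)
            if not report.contact_rule_satisfied:
                contact["records_contact_rule_unsatisfied"] += 1

        summary.pi_partition[_pi_of(record)] += 1

        cls = classify_criteria(record.eligibility_text,
                                record_id=record.record_id)
        summary.criteria_classes[cls.format_class] += 1
        if cls.multi_group_suspected:
            summary.multi_group_suspected += 1
        if cls.format_class in ("headers_only", "malformed_headers"):
            incorrect_format += 1
            multi_in_incorrect += cls.multi_group_suspected

        n, no_phone, no_email = audit_contact_details([record])
        contact["n_contacts"] += n
        contact["missing_phone"] += no_phone
        contact["missing_email"] += no_email
        oc = record.contacts.overall_contact
        if oc is None or not oc.provided:
            contact["records_without_overall_contact"] += 1

        condition_values.extend(record.conditions)
        for iv in record.interventions:
            if iv.name:
                intervention_values.setdefault(
                    iv.intervention_type or "(untyped)", []).append(iv.name)

    summary.contact_summary = contact
    summary.n_findings = len(findings)
    if isinstance(corpus, CorpusReader):
        summary.parse_errors = list(corpus.errors)

    if incorrect_format:
        ext = extrapolate(multi_in_incorrect, incorrect_format,
                          max(summary.n_records, incorrect_format))
        summary.multi_group_extrapolation = {
            "sample_positive": ext.sample_positive,
            "sample_size": ext.sample_size,
            "population_size": summary.n_records,
            "proportion": ext.proportion,
            "point_estimate": round(ext.proportion * summary.n_records),
            "ci_low": ext.ci_low,
            "ci_high": ext.ci_high,
        }

    if lexicons:
        summary.coverage_tables.append(
            ("condition", match_terms(condition_values, lexicons,
                                      restrict_to, stratum="all")))
        all_interventions: list[str] = []
        for itype in sorted(intervention_values):
            values = intervention_values[itype]
            all_interventions.extend(values)
            summary.coverage_tables.append(
                ("intervention", match_terms(values, lexicons, restrict_to,
                                             stratum=itype)))
        summary.coverage_tables.append(
            ("intervention", match_terms(all_interventions, lexicons,
                                         restrict_to, stratum="all")))
    return summary, findings


def _pi_of(record: TrialRecord) -> str:
    rp = record.parties.responsible_party_type_raw in (
        "Principal Investigator", "Sponsor-Investigator")
    off = bool(record.parties.overall_officials)
    if rp and off:
        return "both"
    if rp:
        return "rp_investigator_only"
    if off:
        return "official_with_nonscientific_rp"
    return "no_pi"


# ---------------------------------------------------------------------------
# rendering


def fmt_pct(count: int, denominator: int, decimals: int = 0) -> str:
    """Percent as text; a trailing ``*`` flags an empty denominator."""
    if denominator == 0:
        return "0*" if decimals == 0 else f"{0:.{decimals}f}*"
    return f"{100.0 * count / denominator:.{decimals}f}"


def _write(path: Path, lines: list[str]) -> None:
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def render(summary: CorpusSummary, destination: str | Path,
           format: str = "delimited") -> list[Path]:
    """Write summary tables; returns the files written (deterministic bytes)."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if format == "json":
        path = dest / "summary.json"
        path.write_text(json.dumps(summary.to_json(), indent=1,
                                   sort_keys=True), encoding="utf-8")
        return [path]
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")

    n = summary.n_records
    ni = summary.n_interventional

    lines = ["field\tcode\tcount"]
    for fname in sorted(summary.simple_violations):
        for code, count in sorted(summary.simple_violations[fname].items()):
            lines.append(f"{fname}\t{code}\t{count}")
    path = dest / "simple_type_findings.tsv"
    _write(path, lines)
    written.append(path)

    lines = ["field\trogue_count\tpercent\texample_values"]
    for fname in sorted(summary.rogue_values):
        entry = summary.rogue_values[fname]
        lines.append(f"{fname}\t{entry['count']}\t"
                     f"{fmt_pct(entry['count'], n)}\t"
                     f"{'; '.join(entry['examples'])}")
    path = dest / "rogue_values.tsv"
    _write(path, lines)
    written.append(path)

    lines = ["field\t" + "\t".join(
        f"{era}_missing\t{era}_percent" for era in ERA_COLUMNS)
        + "\tall_missing\tall_percent"]
    for fname in sorted(summary.missing_fields):
        entry = summary.missing_fields[fname]
        cells = [fname]
        for era in ERA_COLUMNS:
            c = entry.get(era, 0)
            cells += [str(c), fmt_pct(c, summary.era_denominators.get(era, 0))]
        cells += [str(entry["all"]), fmt_pct(entry["all"], ni)]
        lines.append("\t".join(cells))
    path = dest / "missing_fields.tsv"
    _write(path, lines)
    written.append(path)

    agencies = sorted(summary.agency_denominators)
    lines = ["field\t" + "\t".join(
        f"{a}_missing\t{a}_percent" for a in agencies)]
    for fname in sorted(summary.missing_fields):
        entry = summary.missing_fields[fname]
        cells = [fname]
        for a in agencies:
            c = entry["by_agency"].get(a, 0)
            cells += [str(c),
                      fmt_pct(c, summary.agency_denominators.get(a, 0))]
        lines.append("\t".join(cells))
    path = dest / "missing_by_agency.tsv"
    _write(path, lines)
    written.append(path)

    lines = ["pi_category\tcount\tpercent"]
    for cat, count in summary.pi_partition.items():
        lines.append(f"{cat}\t{count}\t{fmt_pct(count, n)}")
    path = dest / "pi_partition.tsv"
    _write(path, lines)
    written.append(path)

    cs = summary.contact_summary
    lines = ["measure\tcount\tdenominator\tpercent"]
    nc = cs.get("n_contacts", 0)
    lines.append(f"contacts_provided\t{nc}\t{nc}\t{fmt_pct(nc, nc)}")
    lines.append(f"contacts_missing_phone\t{cs.get('missing_phone', 0)}\t{nc}"
                 f"\t{fmt_pct(cs.get('missing_phone', 0), nc)}")
    lines.append(f"contacts_missing_email\t{cs.get('missing_email', 0)}\t{nc}"
                 f"\t{fmt_pct(cs.get('missing_email', 0), nc)}")
    lines.append(
        f"records_without_overall_contact\t"
        f"{cs.get('records_without_overall_contact', 0)}\t{n}\t"
        f"{fmt_pct(cs.get('records_without_overall_contact', 0), n)}")
    lines.append(
        f"records_contact_rule_unsatisfied\t"
        f"{cs.get('records_contact_rule_unsatisfied', 0)}\t{ni}\t"
        f"{fmt_pct(cs.get('records_contact_rule_unsatisfied', 0), ni)}")
    path = dest / "contacts.tsv"
    _write(path, lines)
    written.append(path)

    lines = ["format_class\tcount\tpercent"]
    for cls in FORMAT_CLASSES:
        count = summary.criteria_classes.get(cls, 0)
        lines.append(f"{cls}\t{count}\t{fmt_pct(count, n, decimals=1)}")
    ext = summary.multi_group_extrapolation
    if ext:
        lines.append(
            f"multi_group_estimate\t{ext['point_estimate']}\t"
            f"{100 * ext['proportion']:.1f} "
            f"[{100 * ext['ci_low']:.1f}, {100 * ext['ci_high']:.1f}]")
    path = dest / "criteria_classes.tsv"
    _write(path, lines)
    written.append(path)

    lines = ["field\tstratum\tsource\tmatched\ttotal\tpercent"]
    for fname, table in summary.coverage_tables:
        for sid in sorted(table.per_source_matched):
            c = table.per_source_matched[sid]
            lines.append(f"{fname}\t{table.stratum}\t{sid}\t{c}\t"
                         f"{table.total_values}\t"
                         f"{fmt_pct(c, table.total_values)}")
        lines.append(f"{fname}\t{table.stratum}\tANY\t{table.union_matched}\t"
                     f"{table.total_values}\t"
                     f"{fmt_pct(table.union_matched, table.total_values)}")
    path = dest / "coverage.tsv"
    _write(path, lines)
    written.append(path)

    return written
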