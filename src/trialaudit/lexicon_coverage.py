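"""Exact-match terminology coverage of condition and intervention values.

A :class:`Lexicon` is a term -> identifier table standing in for one
vocabulary's preferred-name space (MeSH, MedDRA, SNOMED-CT, RxNorm, ...).
"Exact match" means membership of the normalized free-text value in the
lexicon's normalized preferred-name key set; normalization trims, collapses
internal whitespace and case-folds (registry values capitalize
inconsistently), with a strict-case mode available. Values are counted as
a bag — every listed occurrence counts once — matching how registry
condition/intervention listings are denominated.

The package bundles a small synthetic fixture lexicon
(``data/lexicon_synthetic.tsv``) so coverage analyses run without any
terminology license or network service; any exported three-column
(source_id, preferred_name, identifier) table plugs into the same
contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .record_io import TrialRecord

__all__ = [
    "Lexicon", "CoverageTable", "LexiconLoadError", "load_lexicon",
    "load_lexicons", "bundled_lexicon_path", "normalize_term",
    "match_terms", "coverage_by_stratum",
]


class LexiconLoadError(ValueError):
    pass


def normalize_term(term: str, strict_case: bool = False) -> str:
    """Trim, collapse internal whitespace, and (by default) case-fold."""
    t = " ".join(term.split())
    return t if strict_case else t.casefold()


@dataclass
class Lexicon:
    """One vocabulary's preferred-name -> identifier-set table."""

    source_id: str
    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, normalized_term: str) -> bool:
        return normalized_term in self.entries

    @classmethod
    def from_pairs(cls, source_id: str,
                   pairs: Iterable[tuple[str, str]],
                   strict_case: bool = False) -> "Lexicon":
        """Build from (preferred_name, identifier) pairs.

        Duplicate preferred names merge their identifier sets.
        """
        merged: dict[str, set[str]] = {}
        for name, identifier in pairs:
            merged.setdefault(normalize_term(name, strict_case),
                              set()).add(identifier)
        return cls(source_id=source_id,
                   entries={k: frozenset(v) for k, v in merged.items()})


def _parse_lexicon_rows(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3 or not all(c.strip() for c in cells):
                raise LexiconLoadError(
                    f"{path}: malformed row at line {lineno}: expected 3 "
                    f"non-empty tab-separated columns")
            yield cells[0].strip(), cells[1], cells[2].strip()


def load_lexicons(path: str | Path,
                  strict_case: bool = False) -> list[Lexicon]:
    """Load every vocabulary present in a delimited lexicon file.

    The file has columns (source_id, preferred_name, identifier); rows
    sharing a source_id form one lexicon, in first-appearance order.
    """
    by_source: dict[str, list[tuple[str, str]]] = {}
    for source_id, name, identifier in _parse_lexicon_rows(path):
        by_source.setdefault(source_id, []).append((name, identifier))
    return [Lexicon.from_pairs(sid, pairs, strict_case)
            for sid, pairs in by_source.items()]


def load_lexicon(path: str | Path, source_id: str | None = None,
                 strict_case: bool = False) -> Lexicon:
    """Load one vocabulary from a delimited lexicon file.

    If the file holds a single source_id that lexicon is returned;
    otherwise ``source_id`` selects which one.
    """
    lexicons = load_lexicons(path, strict_case)
    if not lexicons:
        return Lexicon(source_id=source_id or "(empty)", entries={})
    if source_id is not None:
        for lx in lexicons:
            if lx.source_id == source_id:
                return lx
        raise LexiconLoadError(
            f"{path} has no source {source_id!r}; found "
            + ", ".join(lx.source_id for lx in lexicons))
    if len(lexicons) != 1:
        raise LexiconLoadError(
            f"{path} holds {len(lexicons)} vocabularies; pass source_id "
            "or use load_lexicons()")
    return lexicons[0]


def bundled_lexicon_path() -> Path:
    """Path of the bundled synthetic fixture lexicon."""
    return Path(str(resources.files("trialaudit") / "data"
                    / "lexicon_synthetic.tsv"))


@dataclass
class CoverageTable:
    """Per-vocabulary exact-match accounting over a bag of values."""

    total_values: int
    per_source_matched: dict[str, int]
    union_matched: int
    unmatched: int
    stratum: str | None = None

    def percent(self, source_id: str | None = None) -> float:
        """Coverage percent for one source, or for the union when None."""
        if self.total_values == 0:
            return 0.0
        matched = (self.union_matched if source_id is None
                   else self.per_source_matched.get(source_id, 0))
        return 100.0 * matched / self.total_values


def match_terms(values: Iterable[str], lexicons: Sequence[Lexicon],
                restrict_to: Iterable[str] | None = None,
                strict_case: bool = False,
                stratum: str | None = None) -> CoverageTable:
    """Exact-match a bag of values against a set of lexicons.

    A value matches a source iff its normalized form is a key of that
    source's entry table; ``restrict_to`` limits the analysis to a subset
    of source ids (e.g. the vocabularies inside one metathesaurus).
    """
    if restrict_to is not None:
        keep = set(restrict_to)
        lexicons = [lx for lx in lexicons if lx.source_id in keep]
    bag = Counter(normalize_term(v, strict_case) for v in values)
    total = sum(bag.values())
    per_source: dict[str, int] = {}
    union = 0
    for term, count in bag.items():
        hits = [lx.source_id for lx in lexicons if term in lx.entries]
        for sid in hits:
            per_source[sid] = per_source.get(sid, 0) + count
        if hits:
            union += count
    for lx in lexicons:
        per_source.setdefault(lx.source_id, 0)
    return CoverageTable(total_values=total, per_source_matched=per_source,
                         union_matched=union, unmatched=total - union,
                         stratum=stratum)


def coverage_by_stratum(records: Iterable[TrialRecord], field_name: str,
                        lexicons: Sequence[Lexicon],
                        restrict_to: Iterable[str] | None = None,
                        stratifier: str | None = None,
                        strict_case: bool = False) -> list[CoverageTable]:
    """Coverage tables for condition or intervention values over a corpus.

    With ``stratifier="intervention_type"`` (valid only for
    ``field_name="intervention"``) one table per intervention type is
    produced, plus an all-strata table labeled ``"all"`` (always last).
    """
    if field_name not in ("condition", "intervention"):
        raise ValueError("field_name must be 'condition' or 'intervention'")
    if stratifier is not None:
        if stratifier != "intervention_type" or field_name != "intervention":
            raise ValueError("stratifier='intervention_type' is only valid "
                             "with field_name='intervention'")

    strata: dict[str, list[str]] = {}
    everything: list[str] = []
    for rec in records:
        if field_name == "condition":
            values = [(None, c) for c in rec.conditions]
        else:
            values = [(iv.intervention_type, iv.name)
                      for iv in rec.interventions if iv.name]
        for itype, value in values:
            everything.append(value)
            if stratifier is not None:
                strata.setdefault(itype or "(untyped)", []).append(value)

    tables = [
        match_terms(vals, lexicons, restrict_to, strict_case, stratum=key)
        for key, vals in sorted(strata.items())
    ]
    tables.append(match_terms(everything, lexicons, restrict_to, strict_case,
                              stratum="all"))
    return tables
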