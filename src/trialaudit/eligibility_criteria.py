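"""Eligibility-criteria format classification, parsing and extrapolation.

The registry's expected format for the eligibility-criteria text block is a
bulleted list of criteria below the canonical headers ``Inclusion
Criteria`` and ``Exclusion Criteria``. Every block maps to exactly one of
four format classes:

``correct``
    both canonical headers present and every non-blank body line bulleted;
``headers_only``
    both canonical headers present but at least one non-bullet body line;
``malformed_headers``
    a canonical header missing, misspelled, or replaced by a variant
    (``"Key Inclusion Criteria"``, ``"INCLUSION:"``);
``missing``
    the block absent or whitespace-only.

The source registry does not publish the classifying expressions, so the
grammar here is this package's canonical definition and all class counts
are relative to it. A precision-oriented heuristic additionally flags
blocks that appear to define criteria for multiple participant sub-groups;
a Wilson-interval extrapolation utility scales sample review results to
corpus estimates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CriteriaClassification", "ParsedCriteria", "SampleExtrapolation",
    "FORMAT_CLASSES", "BULLET_MARKERS", "classify_criteria",
    "classify_headerless", "split_headers", "detect_multi_group",
    "extrapolate", "sample_size_for_margin", "round_sigfigs",
]

FORMAT_CLASSES = ("correct", "headers_only", "malformed_headers", "missing")

#: Error codes attached to classifications. ``header``-prefixed codes are
#: exactly those a separate-fields data model would eliminate.
CODE_NO_TEXT = "missing_criteria"
CODE_HEADER_MISSING = "header_missing"
CODE_HEADER_VARIANT = "header_variant"
CODE_NON_BULLETED = "non_bulleted_body"
HEADER_CODES = frozenset({CODE_HEADER_MISSING, CODE_HEADER_VARIANT})

#: Default bullet marker set: dash, asterisk, bullet character, or a
#: number followed by ``.`` or ``)`` (the form-prepopulated style plus
#: common variants).
BULLET_MARKERS = ("-", "*", "•")

_BULLET_RE = re.compile(r"^\s*(?:[-*•]+|\d+[.)])\s*(?P<text>.*)$")
_CANONICAL_HEADER_RE = re.compile(
    r"^(?P<kind>inclusion|exclusion)\s+criteria\s*:?$", re.IGNORECASE)
# header-like: up to two leading words before the stem, anything after it
_HEADER_LIKE_RE = re.compile(
    r"^\s*(?:[\w()]+[ \t]+){0,2}(?P<kind>inclusion|exclusion)[ \t]+"
    r"criteria(?P<qualifier>[^\n]*)$", re.IGNORECASE)


@dataclass
class ParsedCriteria:
    inclusion: list[str] = field(default_factory=list)
    exclusion: list[str] = field(default_factory=list)


@dataclass
class CriteriaClassification:
    format_class: str
    multi_group_suspected: bool = False
    parsed: ParsedCriteria | None = None
    error_codes: frozenset[str] = frozenset()
    record_id: str | None = None


def _norm_line(line: str) -> str:
    return " ".join(line.split())


def _is_canonical_header(line: str, kind: str | None = None) -> bool:
    m = _CANONICAL_HEADER_RE.match(_norm_line(line))
    return m is not None and (kind is None or m.group("kind").lower() == kind)


def classify_criteria(text: str | None,
                      record_id: str | None = None) -> CriteriaClassification:
    """Classify one eligibility-criteria block into its format class.

    Total: every input maps to exactly one class. Blank lines are ignored;
    header matching tolerates surrounding whitespace and a trailing colon
    only. When the class is ``correct`` the bulleted criteria are parsed
    into separate inclusion/exclusion lists with markers stripped.
    """
    multi = detect_multi_group(text) if text else False
    if text is None or not text.strip():
        return CriteriaClassification(
            format_class="missing", multi_group_suspected=False,
            error_codes=frozenset({CODE_NO_TEXT}), record_id=record_id)

    lines = [l for l in text.splitlines() if l.strip()]
    has_inclusion = any(_is_canonical_header(l, "inclusion") for l in lines)
    has_exclusion = any(_is_canonical_header(l, "exclusion") for l in lines)

    if has_inclusion and has_exclusion:
        body = [l for l in lines if not _is_canonical_header(l)]
        if all(_BULLET_RE.match(l) for l in body):
            return CriteriaClassification(
                format_class="correct", multi_group_suspected=multi,
                parsed=_parse_correct(lines), record_id=record_id)
        return CriteriaClassification(
            format_class="headers_only", multi_group_suspected=multi,
            error_codes=frozenset({CODE_NON_BULLETED}), record_id=record_id)

    codes = set()
    header_like = [l for l in lines if _HEADER_LIKE_RE.match(_norm_line(l))]
    codes.add(CODE_HEADER_VARIANT if header_like else CODE_HEADER_MISSING)
    body = [l for l in lines
            if not _HEADER_LIKE_RE.match(_norm_line(l))]
    if not all(_BULLET_RE.match(l) for l in body):
        codes.add(CODE_NON_BULLETED)
    return CriteriaClassification(
        format_class="malformed_headers", multi_group_suspected=multi,
        error_codes=frozenset(codes), record_id=record_id)


def _parse_correct(lines: list[str]) -> ParsedCriteria:
    parsed = ParsedCriteria()
    current: list[str] | None = None
    for line in lines:
        if _is_canonical_header(line, "inclusion"):
            current = parsed.inclusion
        elif _is_canonical_header(line, "exclusion"):
            current = parsed.exclusion
        else:
            m = _BULLET_RE.match(line)
            if m and current is not None:
                item = m.group("text").strip()
                if item:
                    current.append(item)
    return parsed


def detect_multi_group(text: str | None) -> bool:
    """Heuristic flag for criteria defined for multiple participant groups.

    True iff more than two header-like lines occur, or any header-like line
    carries a qualifier phrase after the ``... Criteria`` stem (e.g.
    ``"Inclusion Criteria - Cohort A"``). Precision-oriented: an assist for
    manual review, not a replacement for it.
    """
    if not text:
        return False
    header_like = []
    for line in text.splitlines():
        m = _HEADER_LIKE_RE.match(_norm_line(line))
        if m:
            header_like.append(m)
    if len(header_like) > 2:
        return True
    for m in header_like:
        qualifier = m.group("qualifier").strip().strip(":").strip()
        if qualifier:
            return True
    return False


# ---------------------------------------------------------------------------
# separate-field (headerless) mode


def split_headers(text: str) -> tuple[str, str]:
    """Split a block at its inclusion/exclusion headers.

    Returns the body text under the inclusion header(s) and under the
    exclusion header(s); header lines themselves (canonical or variant) are
    consumed by the split. Text before any header goes to the inclusion
    side.
    """
    inclusion: list[str] = []
    exclusion: list[str] = []
    current = inclusion
    for line in text.splitlines():
        m = _HEADER_LIKE_RE.match(_norm_line(line))
        if m:
            current = (inclusion if m.group("kind").lower() == "inclusion"
                       else exclusion)
            continue
        current.append(line)
    return "\n".join(inclusion), "\n".join(exclusion)


def classify_headerless(text: str | None,
                        record_id: str | None = None) -> CriteriaClassification:
    """Classify a criteria list that lives in its own field (no headers).

    In a data model with separate inclusion/exclusion fields there are no
    user-defined headers, so only bulleting can go wrong: the class is
    ``correct`` (all bullets), ``headers_only``-equivalent
    (``non_bulleted_body``) or ``missing``.
    """
    if text is None or not text.strip():
        return CriteriaClassification(
            format_class="missing", error_codes=frozenset({CODE_NO_TEXT}),
            record_id=record_id)
    lines = [l for l in text.splitlines() if l.strip()]
    items = []
    for line in lines:
        m = _BULLET_RE.match(line)
        if not m:
            return CriteriaClassification(
                format_class="headers_only",
                error_codes=frozenset({CODE_NON_BULLETED}),
                record_id=record_id)
        items.append(m.group("text").strip())
    return CriteriaClassification(
        format_class="correct",
        parsed=ParsedCriteria(inclusion=[i for i in items if i]),
        record_id=record_id)


# ---------------------------------------------------------------------------
# sample extrapolation


@dataclass(frozen=True)
class SampleExtrapolation:
    sample_positive: int
    sample_size: int
    population_size: int
    proportion: float
    point_estimate: int
    ci_low: float
    ci_high: float


def extrapolate(sample_positive: int, sample_size: int,
                population_size: int) -> SampleExtrapolation:
    """Scale a sample proportion to a population estimate with a 95% CI.

    The interval is the Wilson score interval; the point estimate is the
    rounded product of the sample proportion and the population size
    (present it at the precision of your report — e.g. 3 significant
    figures via :func:`round_sigfigs`).
    """
    if not (0 <= sample_positive <= sample_size):
        raise ValueError("need 0 <= sample_positive <= sample_size")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if population_size < sample_size:
        raise ValueError("population_size must be >= sample_size")
    proportion = sample_positive / sample_size
    ci_low, ci_high = proportion_confint(sample_positive, sample_size,
                                         alpha=0.05, method="wilson")
    return SampleExtrapolation(
        sample_positive=sample_positive,
        sample_size=sample_size,
        population_size=population_size,
        proportion=proportion,
        point_estimate=round(proportion * population_size),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def sample_size_for_margin(confidence: float, margin: float,
                           worst_case_proportion: float = 0.5) -> int:
    """Smallest n with ``z^2 p(1-p)/n <= margin^2``.

    ``z`` is the two-sided standard-normal quantile for the given
    confidence level. At 95% confidence and a +/-5 point margin the answer
    is 385 (on the worst-case p = 0.5).
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    if not (0 < margin < 1):
        raise ValueError("margin must be in (0, 1)")
    if not (0 <= worst_case_proportion <= 1):
        raise ValueError("worst_case_proportion must be in [0, 1]")
    z = norm.ppf((1 + confidence) / 2)
    p = worst_case_proportion
    return math.ceil(z * z * p * (1 - p) / (margin * margin))


def round_sigfigs(value: float, figures: int) -> float:
    """Round to a number of significant figures (16212 -> 16200 at 3)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    factor = 10 ** (exponent - figures + 1)
    return round(value / factor) * factor
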