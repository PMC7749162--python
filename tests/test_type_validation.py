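"""Type grammars, age normalization, enumerated validation."""

import pytest

from trialaudit.record_io import read_record
from trialaudit.synthetic_corpus import GeneratorConfig, generate
from trialaudit.type_validation import (
    CanonicalizationError,
    age_matches,
    canonicalize_enumerated,
    date_matches,
    normalize_age,
    validate_enumerated,
    validate_simple,
)

from _oracles import (
    age_acceptable,
    age_domain,
    date_acceptable,
    date_domain,
)


@pytest.mark.parametrize("raw, ok", [
    ("January 3, 2004", True),
    ("March, 2005", True),
    ("Unknown", True),
    ("December 31, 2999", True),
    ("January 0, 2004", False),
    ("January 32, 2004", False),
    ("January 03, 2004", False),
    ("Jan 3, 2004", False),
    ("January 3 2004", False),
    ("March,2005", False),
    ("January 3, 04", False),
    ("unknown", False),
])
def test_date_grammar_examples(raw, ok):
    assert date_matches(raw) is ok


def test_strict_mode_rejects_impossible_calendar_dates():
    assert date_matches("February 31, 2010")          # grammar-faithful
    assert not date_matches("February 31, 2010", strict=True)
    assert date_matches("February 29, 2016", strict=True)   # leap year
    assert not date_matches("February 29, 2015", strict=True)


def test_date_grammar_agrees_with_brute_force_oracle():
    """Regex acceptance equals an explicit rule checker on a full grid."""
    for candidate in date_domain():
        assert date_matches(candidate) is date_acceptable(candidate), candidate


def test_age_grammar_agrees_with_brute_force_oracle():
    for candidate in age_domain():
        assert age_matches(candidate) is age_acceptable(candidate), candidate


def test_equivalent_ages_normalize_to_equal_minutes():
    two_years = normalize_age("2 Years")
    assert two_years.minutes_equivalent == 1_051_200
    assert normalize_age("24 Months").minutes_equivalent == 1_051_200
    assert normalize_age("90 Minutes").minutes_equivalent == 90
    assert normalize_age("1 Week").minutes_equivalent == \
        normalize_age("7 Days").minutes_equivalent
    assert normalize_age("12 Months").minutes_equivalent == \
        normalize_age("1 Year").minutes_equivalent


def test_not_applicable_age_has_no_minute_equivalent():
    na = normalize_age("N/A")
    assert na.not_applicable and na.minutes_equivalent is None
    with pytest.raises(ValueError):
        normalize_age("0 Years")


def test_age_normalization_is_order_preserving():
    """Larger true durations never get smaller minute equivalents."""
    units = ("Minute", "Hour", "Day", "Week", "Month", "Year")
    factors = {"Minute": 1, "Hour": 60, "Day": 1440, "Week": 10080,
               "Month": 43800, "Year": 525600}
    grid = [(m, u) for m in range(1, 61) for u in units]
    by_truth = sorted(grid, key=lambda mu: mu[0] * factors[mu[1]])
    minutes = [normalize_age(f"{m} {u}s" if m > 1 else f"{m} {u}")
               .minutes_equivalent for m, u in by_truth]
    assert minutes == sorted(minutes)


def _record(inner: bytes):
    return read_record(b"<clinical_study><nct_id>NCTX</nct_id>"
                       + inner + b"</clinical_study>")


def test_validate_simple_flags_each_violating_occurrence(registry):
    rec = _record(
        b"<start_date>January 3, 2004</start_date>"
        b"<completion_date>Unknown</completion_date>"
        b'<primary_completion_date type="Estimated">March, 2005'
        b"</primary_completion_date>"
        b"<number_of_arms>two</number_of_arms>"
        b"<enrollment>-5</enrollment>"
        b"<oversight_info><has_dmc>TRUE</has_dmc></oversight_info>"
        b"<eligibility><minimum_age>0 Years</minimum_age>"
        b"<maximum_age>65 Years</maximum_age></eligibility>")
    findings = validate_simple(rec, registry)
    assert all(f.code == "TYPE_MISMATCH" and f.severity == "error"
               for f in findings)
    flagged = sorted((f.dictionary_name, f.observed) for f in findings)
    assert flagged == [
        ("data monitoring committee", "TRUE"),
        ("enrollment", "-5"),
        ("minimum age", "0 Years"),
        ("number of arms", "two"),
        ("primary completion date", "Estimated"),
    ]


def test_validate_enumerated_rogues_variants_and_members(registry):
    rec = _record(
        b"<study_type>Interventional</study_type>"
        b"<study_design_info>"
        b"<allocation>Random Sample</allocation>"
        b"<intervention_model>Single Group Assignment</intervention_model>"
        b"<primary_purpose>Educational/Counseling/Training</primary_purpose>"
        b"<masking>Double(Participant, Care Provider)</masking>"
        b"</study_design_info>")
    findings = validate_enumerated(rec, registry)
    by_code = {}
    for f in findings:
        by_code.setdefault(f.code, []).append(f.dictionary_name)
    assert sorted(by_code["ROGUE_VALUE"]) == ["allocation", "primary purpose"]
    assert sorted(by_code["FORMAT_VARIANT"]) == [
        "interventional study model", "masking"]
    assert all(f.severity == "warning" for f in findings
               if f.code == "ROGUE_VALUE")
    assert all(f.severity == "note" for f in findings
               if f.code == "FORMAT_VARIANT")


def test_masking_count_word_must_match_role_count(registry):
    rec = _record(b"<study_design_info>"
                  b"<masking>Double(Investigator)</masking>"
                  b"</study_design_info>")
    findings = validate_enumerated(rec, registry)
    assert [f.code for f in findings] == ["ROGUE_VALUE"]


def test_canonicalize_study_model_and_masking(registry):
    model = registry.get("interventional study model")
    assert canonicalize_enumerated(model, "Parallel Group Assignment") == \
        "Parallel"
    assert canonicalize_enumerated(model, "Single Group Assignment") == \
        "Single Group"
    masking = registry.get("masking")
    assert canonicalize_enumerated(masking, "Single(Investigator)") == \
        frozenset({"Investigator"})
    assert canonicalize_enumerated(
        masking, "Double(Participant, Care Provider)") == \
        frozenset({"Participant", "Care Provider"})
    with pytest.raises(CanonicalizationError, match="count word"):
        canonicalize_enumerated(masking, "Double(Investigator)")
    with pytest.raises(CanonicalizationError):
        canonicalize_enumerated(model, "Parallel Groups Assignment")


def test_clean_generated_records_carry_no_errors_or_warnings(registry):
    """Zero-defect records pass both validators (notes annotate the known
    record-form syntax divergence and are not defects)."""
    records, _ = generate(GeneratorConfig(n_records=30, seed=21))
    for rec in records:
        findings = (validate_simple(rec, registry)
                    + validate_enumerated(rec, registry))
        assert [f for f in findings if f.severity != "note"] == []
        assert all(f.code == "FORMAT_VARIANT" for f in findings)
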