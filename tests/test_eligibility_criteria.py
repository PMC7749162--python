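"""Criteria classification, multi-group heuristic, extrapolation."""

import pytest
from hypothesis import given, settings, strategies as st

from trialaudit.eligibility_criteria import (
    FORMAT_CLASSES,
    HEADER_CODES,
    classify_criteria,
    classify_headerless,
    detect_multi_group,
    extrapolate,
    round_sigfigs,
    sample_size_for_margin,
    split_headers,
)

from _oracles import wilson_interval

CORRECT = ("Inclusion Criteria:\n- age > 18\n"
           "Exclusion Criteria:\n- pregnancy")
HEADERS_ONLY = ("Inclusion Criteria:\n"
                "Patients will be eligible if they are over 18.\n"
                "Exclusion Criteria:\n- pregnancy")
VARIANT = ("Key Inclusion Criteria:\n- age > 18\n"
           "Key Exclusion Criteria:\n- pregnancy")
MULTI_GROUP = ("Inclusion criteria for healthy volunteers:\n- no illness\n"
               "Inclusion criteria for patients:\n- confirmed diagnosis")


@pytest.mark.parametrize("text, expected", [
    (CORRECT, "correct"),
    (HEADERS_ONLY, "headers_only"),
    (VARIANT, "malformed_headers"),
    (MULTI_GROUP, "malformed_headers"),
    ("", "missing"),
    (None, "missing"),
    ("   \n  ", "missing"),
    ("inclusion criteria:\n- a\nEXCLUSION CRITERIA\n- b", "correct"),
    ("Inclusion Criteria:\n- a", "malformed_headers"),   # one header only
    ("1. adults\n2. consent", "malformed_headers"),
])
def test_format_classification(text, expected):
    assert classify_criteria(text).format_class == expected


def test_correct_blocks_parse_into_trimmed_lists():
    cls = classify_criteria(CORRECT)
    assert cls.parsed.inclusion == ["age > 18"]
    assert cls.parsed.exclusion == ["pregnancy"]
    mixed = ("Inclusion Criteria:\n- a\n* b\n• c\n1. d\n2) e\n"
             "Exclusion Criteria:\n- f")
    assert classify_criteria(mixed).parsed.inclusion == list("abcde")


def test_parsed_present_iff_correct():
    for text in (CORRECT, HEADERS_ONLY, VARIANT, None):
        cls = classify_criteria(text)
        assert (cls.parsed is not None) == (cls.format_class == "correct")


def test_multi_group_detection():
    assert detect_multi_group(MULTI_GROUP)
    assert classify_criteria(MULTI_GROUP).multi_group_suspected
    assert not detect_multi_group(CORRECT)
    assert detect_multi_group(
        "Inclusion Criteria - Cohort A:\n- a\n"
        "Inclusion Criteria - Cohort B:\n- b")
    four_headers = ("Inclusion Criteria:\n- a\nExclusion Criteria:\n- b\n"
                    "Inclusion Criteria:\n- c\nExclusion Criteria:\n- d")
    assert detect_multi_group(four_headers)   # >2 header-like lines
    # body bullets mentioning the stem are not headers
    assert not detect_multi_group(
        "Inclusion Criteria:\n- meets the inclusion criteria of the parent "
        "study\nExclusion Criteria:\n- none")


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet=st.characters(codec="utf-8",
                                      exclude_categories=("Cs",)),
               max_size=300))
def test_classification_is_total(text):
    cls = classify_criteria(text)
    assert cls.format_class in FORMAT_CLASSES
    assert (cls.format_class == "missing") == (not text.strip())
    assert (cls.parsed is not None) == (cls.format_class == "correct")


@pytest.mark.parametrize("text", [CORRECT, HEADERS_ONLY])
def test_splitting_into_separate_fields_removes_header_errors(text):
    """Separate inclusion/exclusion fields need no user-typed headers, so
    reclassifying the split halves can carry no header-related codes."""
    inclusion, exclusion = split_headers(text)
    for side in (inclusion, exclusion):
        cls = classify_headerless(side)
        assert cls.error_codes & HEADER_CODES == frozenset()


def test_extrapolation_of_the_sample_review():
    ext = extrapolate(55, 400, 117906)
    assert ext.proportion == pytest.approx(0.1375)
    assert ext.point_estimate == 16212
    assert round_sigfigs(ext.point_estimate, 3) == 16200
    assert 0 <= ext.ci_low <= ext.proportion <= ext.ci_high <= 1


def test_extrapolation_zero_successes():
    ext = extrapolate(0, 400, 117906)
    assert ext.point_estimate == 0
    assert ext.ci_low == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("k, n", [(55, 400), (1, 400), (399, 400),
                                  (200, 400), (7, 29)])
def test_wilson_interval_matches_closed_form_oracle(k, n):
    ext = extrapolate(k, n, 1_000_000)
    low, high = wilson_interval(k, n)
    assert ext.ci_low == pytest.approx(low, abs=1e-6)
    assert ext.ci_high == pytest.approx(high, abs=1e-6)


def test_extrapolation_preconditions():
    with pytest.raises(ValueError):
        extrapolate(5, 4, 100)
    with pytest.raises(ValueError):
        extrapolate(1, 400, 300)
    with pytest.raises(ValueError):
        extrapolate(-1, 400, 500)


def test_sample_size_for_95_5_is_385():
    assert sample_size_for_margin(0.95, 0.05, 0.5) == 385


def test_sample_size_shrinks_away_from_half_and_grows_with_precision():
    base = sample_size_for_margin(0.95, 0.05, 0.5)
    assert sample_size_for_margin(0.95, 0.05, 0.14) < base
    sizes = [sample_size_for_margin(0.95, m, 0.5)
             for m in (0.10, 0.05, 0.02, 0.01)]
    assert sizes == sorted(sizes) and sizes[-1] > sizes[0]
    with pytest.raises(ValueError):
        sample_size_for_margin(1.0, 0.05)
    with pytest.raises(ValueError):
        sample_size_for_margin(0.95, 0.0)
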