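"""Generator determinism, plan feasibility, recovery, corpus writing."""

import json

import numpy as np
import pytest

from trialaudit.record_io import write_record
from trialaudit.reporting import run_audit
from trialaudit.synthetic_corpus import (
    ConfigError,
    GeneratorConfig,
    generate,
    paper_profile,
    verify_manifest,
    write_corpus,
)


def test_same_config_and_seed_give_byte_identical_corpora():
    config = GeneratorConfig(
        n_records=30, seed=42,
        missing_plan={"allocation": 3},
        criteria_class_plan={"correct": 20, "headers_only": 5,
                             "malformed_headers": 4, "missing": 1})
    a, truth_a = generate(config)
    b, truth_b = generate(config)
    assert [write_record(r) for r in a] == [write_record(r) for r in b]
    assert truth_a.to_json() == truth_b.to_json()
    c, _ = generate(GeneratorConfig(n_records=30, seed=43))
    assert [write_record(r) for r in a] != [write_record(r) for r in c]


def test_exact_counts_apportionment_matches_mixes():
    records, truth = generate(GeneratorConfig(n_records=250, seed=3))
    types = [a["study_type"] for a in truth.records.values()]
    assert abs(types.count("Interventional") - 0.792 * 250) <= 1
    assert abs(types.count("Observational") - 0.198 * 250) <= 1
    eras = [a["era"] for a in truth.records.values()]
    assert abs(eras.count("pre_final_rule") - 0.806 * 250) <= 1


def test_infeasible_plan_names_the_entry():
    with pytest.raises(ConfigError, match="missing_plan.allocation"):
        generate(GeneratorConfig(n_records=10, seed=1,
                                 missing_plan={"allocation": 100}))
    with pytest.raises(ConfigError, match="multi_group_count"):
        generate(GeneratorConfig(n_records=10, seed=1, multi_group_count=5))
    with pytest.raises(ConfigError, match="unknown field"):
        generate(GeneratorConfig(n_records=10, seed=1,
                                 missing_plan={"no such field": 1}))


def test_mix_probabilities_must_sum_to_one():
    with pytest.raises(ConfigError, match="era_mix"):
        generate(GeneratorConfig(n_records=5, seed=1,
                                 era_mix={"pre_final_rule": 0.9,
                                          "post_final_rule": 0.2}))


def test_exact_mode_rejects_fractional_counts():
    with pytest.raises(ConfigError, match="exact_counts"):
        generate(GeneratorConfig(n_records=10, seed=1,
                                 missing_plan={"allocation": 0.5}))


def test_planted_counts_are_recovered_exactly(registry, lexicons):
    config = GeneratorConfig(
        n_records=300, seed=23,
        missing_plan={"allocation": 12, "masking": 7, "official title": 9,
                      "arm information": 6, "why study stopped": 5,
                      "individual site status": 4, "study start date": 3},
        rogue_plan={"allocation": ("Random Sample", 5),
                    "arm type": ("Control", 4),
                    "observational study model": ("Defined Population", 3)},
        criteria_class_plan={"correct": 200, "headers_only": 50,
                             "malformed_headers": 40, "missing": 10},
        multi_group_count=15,
        lexicon_membership={"condition": 186},
        contact_plan={"no_overall_contact": 60, "missing_phone": 20,
                      "missing_email": 25})
    records, truth = generate(config)
    summary, _ = run_audit(records, registry, lexicons)
    exp = truth.expected
    assert {k: v["total"] for k, v in exp["missing"].items()} == \
        {k: v["all"] for k, v in summary.missing_fields.items()}
    assert exp["rogue"] == {k: v["count"]
                            for k, v in summary.rogue_values.items()}
    assert exp["criteria_classes"] == summary.criteria_classes
    assert exp["multi_group"] == summary.multi_group_suspected
    assert exp["pi_partition"] == summary.pi_partition
    assert exp["contacts"] == summary.contact_summary
    cond = [t for f, t in summary.coverage_tables if f == "condition"][0]
    assert cond.union_matched == exp["condition_coverage"]["in_lexicon"]


def test_rates_mode_stays_within_four_binomial_sd(registry, lexicons):
    n = 400
    rate = 0.2
    config = GeneratorConfig(n_records=n, seed=29, mode="rates",
                             missing_plan={"allocation": rate},
                             contact_plan={"no_overall_contact": 0.74})
    records, truth = generate(config)
    summary, _ = run_audit(records, registry, lexicons)
    n_int = truth.expected["n_interventional"]
    observed = summary.missing_fields.get("allocation", {}).get("all", 0)
    sd = np.sqrt(n_int * rate * (1 - rate))
    assert abs(observed - n_int * rate) <= 4 * sd
    no_overall = summary.contact_summary["records_without_overall_contact"]
    sd = np.sqrt(n * 0.74 * 0.26)
    assert abs(no_overall - n * 0.74) <= 4 * sd
    # audit totals still equal the realized (truth) totals exactly
    assert truth.expected["missing"].get("allocation", {}).get("total", 0) \
        == observed


def test_paper_profile_preset_is_rates_mode():
    config = paper_profile(n_records=100, seed=1)
    assert config.mode == "rates"
    records, truth = generate(config)
    assert len(records) == 100


def test_write_corpus_manifest_and_integrity(tmp_path):
    records, truth = generate(GeneratorConfig(n_records=3, seed=8))
    dest = tmp_path / "corpus"
    manifest = write_corpus(records, truth, dest)
    xml_files = sorted(p.name for p in dest.glob("*.xml"))
    assert len(xml_files) == 3
    assert (dest / "ground_truth.json").exists()
    assert (dest / "manifest.json").exists()
    assert verify_manifest(dest)

    again = write_corpus(*generate(GeneratorConfig(n_records=3, seed=8)),
                         tmp_path / "corpus2")
    assert again["corpus_checksum"] == manifest["corpus_checksum"]

    # tampering and deletion are detected
    victim = dest / xml_files[0]
    victim.write_bytes(victim.read_bytes() + b" ")
    assert not verify_manifest(dest)
    victim.unlink()
    assert not verify_manifest(dest)


def test_ground_truth_is_json_serializable(tmp_path):
    _, truth = generate(GeneratorConfig(
        n_records=10, seed=5, missing_plan={"allocation": 2}))
    path = tmp_path / "truth.json"
    truth.save(path)
    loaded = json.loads(path.read_text())
    assert loaded["n_records"] == 10
    assert len(loaded["records"]) == 10
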