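"""Record reading/writing: round-trips, corpus streaming, exports."""

import tracemalloc
import zipfile

import pytest

from trialaudit.record_io import (
    ParseError,
    StructuralError,
    export_jsonl,
    read_corpus,
    read_record,
    write_record,
)
from trialaudit.synthetic_corpus import GeneratorConfig, generate


def test_minimal_record_parses_with_empty_collections():
    rec = read_record(
        b"<clinical_study><nct_id>NCT00000001</nct_id>"
        b"<study_type>Interventional</study_type></clinical_study>")
    assert rec.record_id == "NCT00000001"
    assert rec.study_type == "Interventional"
    assert rec.conditions == [] and rec.interventions == []
    assert rec.start_date_raw is None and rec.eligibility_text is None
    assert rec.contacts.locations == []


def test_full_name_and_degrees_live_in_last_name():
    rec = read_record(
        b"<clinical_study><id_info><nct_id>NCT00000002</nct_id></id_info>"
        b"<overall_official><last_name>Sarah Smith, M.D.</last_name>"
        b"<role>Study Principal Investigator</role></overall_official>"
        b"</clinical_study>")
    assert [o.last_name_raw for o in rec.parties.overall_officials] == [
        "Sarah Smith, M.D."]


def test_date_attribute_and_raw_values_are_retained():
    rec = read_record(
        b"<clinical_study><nct_id>NCT00000003</nct_id>"
        b'<start_date type="Actual">March, 2005</start_date>'
        b"<condition>Asthma</condition><condition>Asthma</condition>"
        b"</clinical_study>")
    assert rec.start_date_raw == "March, 2005"
    assert rec.start_date_attr == "Actual"
    # bag semantics: duplicates and order preserved
    assert rec.raw_values["condition"] == ["Asthma", "Asthma"]
    assert rec.raw_values["start_date@type"] == ["Actual"]
    out = write_record(rec)
    assert b"<start_date type=\"Actual\">March, 2005</start_date>" in out


def test_malformed_xml_and_missing_id_raise():
    with pytest.raises(ParseError):
        read_record(b"<clinical_study><unclosed></clinical_study>")
    with pytest.raises(StructuralError):
        read_record(b"<clinical_study><brief_title>x</brief_title>"
                    b"</clinical_study>")


def test_empty_arm_list_emits_no_arm_group_elements():
    rec = read_record(b"<clinical_study><nct_id>NCT1</nct_id></clinical_study>")
    assert b"arm_group" not in write_record(rec)


def test_write_read_round_trip_on_defected_corpus():
    """write o read is the identity on the retained field set."""
    config = GeneratorConfig(
        n_records=40, seed=11,
        missing_plan={"allocation": 4, "facility information": 3,
                      "outcome description": 5},
        rogue_plan={"primary purpose": ("Educational/Counseling/Training", 3)},
        criteria_class_plan={"correct": 20, "headers_only": 10,
                             "malformed_headers": 8, "missing": 2},
        contact_plan={"no_overall_contact": 6, "missing_phone": 4})
    records, _ = generate(config)
    for rec in records:
        data = write_record(rec)
        again = read_record(data)
        assert again == rec
        assert write_record(again) == data


def _write_corpus_dir(tmp_path, n=3, junk=False, broken=False):
    tmp_path.mkdir(exist_ok=True)
    records, _ = generate(GeneratorConfig(n_records=n, seed=2))
    for rec in records:
        (tmp_path / f"{rec.record_id}.xml").write_bytes(write_record(rec))
    if junk:
        (tmp_path / "README.txt").write_text("not a record")
    if broken:
        (tmp_path / "NCT99999999.xml").write_bytes(b"<clinical_study>")
    return records


def test_corpus_streams_in_filename_order(tmp_path):
    records = _write_corpus_dir(tmp_path, n=3, junk=True)
    reader = read_corpus(tmp_path)
    ids = [r.record_id for r in reader]
    assert ids == sorted(r.record_id for r in records)
    assert reader.errors == []


def test_corpus_parse_failures_are_isolated(tmp_path):
    _write_corpus_dir(tmp_path, n=2, broken=True)
    reader = read_corpus(tmp_path)
    assert len(list(reader)) == 2
    assert len(reader.errors) == 1
    assert reader.errors[0][0] == "NCT99999999.xml"


def test_corpus_zip_container(tmp_path):
    records = _write_corpus_dir(tmp_path / "dir", n=3)
    archive = tmp_path / "corpus.zip"
    with zipfile.ZipFile(archive, "w") as zf:
        for p in sorted((tmp_path / "dir").iterdir()):
            zf.write(p, p.name)
    ids = [r.record_id for r in read_corpus(archive)]
    assert ids == [r.record_id for r in records]


def test_missing_container_raises(tmp_path):
    with pytest.raises(IOError):
        read_corpus(tmp_path / "nope")


def test_streaming_memory_is_independent_of_corpus_size(tmp_path):
    """Peak memory while streaming does not scale with corpus size."""
    peaks = {}
    for n in (40, 200):
        d = tmp_path / str(n)
        d.mkdir()
        records, _ = generate(GeneratorConfig(n_records=n, seed=4))
        for rec in records:
            (d / f"{rec.record_id}.xml").write_bytes(write_record(rec))
        del records
        tracemalloc.start()
        count = sum(1 for _ in read_corpus(d))
        _, peaks[n] = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        assert count == n
    assert peaks[200] < 3 * peaks[40] + 200_000


def test_jsonl_export_counts_records(tmp_path):
    records, _ = generate(GeneratorConfig(n_records=5, seed=9))
    path = tmp_path / "records.jsonl"
    assert export_jsonl(records, path) == 5
    assert len(path.read_text().splitlines()) == 5
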