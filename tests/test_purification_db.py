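"""Database schema rules: merging, dedup counting, tag classes, binning."""

import pytest

from purmine.extraction import ExtractionRecord, RawExtraction
from purmine.name_resolution import UniprotRecord
from purmine.purification_db import (
    BufferComponent,
    BufferRecord,
    CultureConditions,
    PurificationDatabase,
    PurificationEntry,
    TagClassificationError,
    bin_conditions,
    classify_tags,
    count_buffer_cases,
    ingest_extraction,
)


def _entry(uid, doi, buffers=(), tags=(), annotations=(), **kw):
    return PurificationEntry(
        uniprot_id=uid,
        doi=doi,
        buffers=list(buffers),
        fusion_tags=list(tags),
        annotations=list(annotations),
        **kw,
    )


def _buffer(btype, ph=None, stage="unknown"):
    return BufferRecord(buffer_type=btype, pH=ph, stage=stage)


def _raw(records, doi="10.1/a", question="q_buffers"):
    return RawExtraction(
        question_id=question,
        article_id=doi,
        quoted_evidence=("evidence",),
        records=tuple(records),
        response_text="",
        status="accepted",
    )


UP = [UniprotRecord(accession="P1", recommended_name="Kinase A",
                    annotation_keywords=("Membrane",))]


class TestIngest:
    def test_two_questions_merge_into_one_entry(self):
        db = PurificationDatabase()
        buffers = _raw([ExtractionRecord("Kinase A", {"buffers": [
            {"buffer_type": "Tris", "pH": 8.0, "stage": "lysis",
             "components": [{"name": "Tris", "concentration": [20.0, "mM"]}]}
        ]})])
        tags = _raw([ExtractionRecord("Kinase A", {"fusion_tags": ["His"]})],
                    question="q_tags")
        ingest_extraction(buffers, UP, db)
        ingest_extraction(tags, UP, db)
        assert len(db) == 1
        entry = db.entries[("P1", "10.1/a")]
        assert entry.fusion_tags == ["His"]
        assert entry.buffers[0].buffer_type == "Tris"
        assert entry.annotations == ["Membrane"]

    def test_unknown_accession_skipped_and_logged(self):
        db = PurificationDatabase()
        raw = _raw([ExtractionRecord("Mystery protein", {"fusion_tags": ["His"]})])
        ingest_extraction(raw, UP, db)
        assert len(db) == 0
        assert len(db.skip_log) == 1

    def test_dedup_idempotence(self):
        db = PurificationDatabase()
        raw = _raw([ExtractionRecord("Kinase A", {"buffers": [
            {"buffer_type": "Tris", "pH": 8.0, "stage": "lysis", "components": []}
        ]})])
        ingest_extraction(raw, UP, db)
        once = db.dumps()
        ingest_extraction(raw, UP, db)
        assert db.dumps() == once

    def test_conflicting_scalar_keeps_first_and_logs(self):
        db = PurificationDatabase()
        db.add_or_merge(_entry("P1", "10.1/a", expression_system="Escherichia coli"))
        db.add_or_merge(_entry("P1", "10.1/a", expression_system="Sf9 insect cells"))
        assert db.entries[("P1", "10.1/a")].expression_system == "Escherichia coli"
        assert len(db.conflict_log) == 1

    def test_rejected_extraction_not_ingestable(self):
        db = PurificationDatabase()
        raw = RawExtraction("q_tags", "10.1/a", (), (), "", "rejected")
        with pytest.raises(ValueError):
            ingest_extraction(raw, UP, db)

    def test_entry_requires_accession_or_pdb_id(self):
        with pytest.raises(ValueError):
            PurificationEntry(uniprot_id="", doi="10.1/a")


class TestCountBufferCases:
    def test_repeats_for_same_protein_count_once(self):
        db = PurificationDatabase()
        db.add_or_merge(_entry("U1", "10.1/a", [_buffer("Tris"), _buffer("Tris", stage="wash")]))
        db.add_or_merge(_entry("U1", "10.1/b", [_buffer("Tris"), _buffer("HEPES")]))
        assert count_buffer_cases(db) == {"Tris": 1, "HEPES": 1}

    def test_three_proteins_same_buffer(self):
        db = PurificationDatabase()
        for i in range(3):
            db.add_or_merge(_entry(f"U{i}", "10.1/a", [_buffer("Tris")]))
        assert count_buffer_cases(db) == {"Tris": 3}

    def test_empty_db(self):
        assert count_buffer_cases(PurificationDatabase()) == {}

    def test_total_bounded_by_protein_buffer_product(self):
        db = PurificationDatabase()
        db.add_or_merge(_entry("U1", "10.1/a", [_buffer("Tris"), _buffer("HEPES")]))
        db.add_or_merge(_entry("U2", "10.1/a", [_buffer("Tris")]))
        counts = count_buffer_cases(db)
        assert sum(counts.values()) <= 2 * 2


class TestClassifyTags:
    def test_large_wins_over_small(self):
        cls, large, small = classify_tags(_entry("U1", "d", tags=["His", "MBP"]))
        assert cls == "large" and large == ["MBP"] and small == ["His"]

    def test_small_only(self):
        assert classify_tags(_entry("U1", "d", tags=["His"]))[0] == "small"

    def test_none(self):
        assert classify_tags(_entry("U1", "d"))[0] == "none"

    def test_alias_normalized(self):
        assert classify_tags(_entry("U1", "d", tags=["polyhistidine"]))[0] == "small"

    def test_unknown_tag_raises_with_name(self):
        with pytest.raises(TagClassificationError, match="GLORP"):
            classify_tags(_entry("U1", "d", tags=["GLORP"]))


class TestBinConditions:
    def _db(self, temps=(), times=(), phs=()):
        db = PurificationDatabase()
        for i, t in enumerate(temps):
            db.add_or_merge(_entry(f"T{i}", "d", culture=CultureConditions(induction_temperature_C=t)))
        for i, h in enumerate(times):
            db.add_or_merge(_entry(f"H{i}", "d", culture=CultureConditions(induction_time_h=h)))
        for i, p in enumerate(phs):
            db.add_or_merge(_entry(f"P{i}", "d", buffers=[_buffer("Tris", ph=p)]))
        return db

    def test_closed_interval_bins(self):
        db = self._db(temps=(16, 18, 20))
        out = bin_conditions(db, temperature_bins=((16, 20),))
        assert out["temperature"]["count"].tolist() == [3]
        assert out["temperature"]["percent"].tolist() == [100.0]

    def test_percentages_sum_to_100_over_known(self):
        db = self._db(times=(4, 14, 15, 30), temps=(18,))
        out = bin_conditions(db)
        assert out["time"]["percent"].sum() == pytest.approx(100.0)
        assert out["time"].attrs["unknown"] > 0  # temp-only entries lack times

    def test_overlapping_bins_rejected(self):
        db = self._db(temps=(18,))
        with pytest.raises(ValueError):
            bin_conditions(db, temperature_bins=((10, 20), (20, 30)))

    def test_ph_histogram_counts_all_buffers(self):
        db = self._db(phs=(7.0, 8.0, 4.5))
        out = bin_conditions(db)
        assert out["pH"]["count"].sum() == 3


class TestPersistence:
    def test_roundtrip_identical(self, tmp_path):
        db = PurificationDatabase()
        db.add_or_merge(
            _entry(
                "U1",
                "10.1/a",
                buffers=[
                    BufferRecord(
                        buffer_type="Tris",
                        pH=8.0,
                        stage="lysis",
                        components=(
                            BufferComponent("Tris", (20.0, "mM"), "buffer"),
                            BufferComponent("NaCl", (150.0, "mM"), "salt"),
                        ),
                    )
                ],
                tags=["His"],
                annotations=["Membrane"],
                culture=CultureConditions(18.0, 16.0, "IPTG", 0.5),
            )
        )
        path = tmp_path / "db.jsonl"
        db.save(path)
        again = PurificationDatabase.load(path)
        assert again.entries == db.entries
        assert again.dumps() == db.dumps()

    def test_wrong_schema_version_rejected(self, tmp_path):
        path = tmp_path / "db.jsonl"
        path.write_text('{"schema_version": 99}\n')
        with pytest.raises(ValueError):
            PurificationDatabase.load(path)


def test_buffer_ph_bounds_enforced():
    with pytest.raises(ValueError):
        BufferRecord(buffer_type="Tris", pH=15.0)
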