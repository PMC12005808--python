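"""Prompt construction, mock-backend extraction, and the quality checker."""

import pytest

from purmine.corpus_io import ArticleDocument, DocumentElement
from purmine.extraction import (
    ExtractionRecord,
    RawExtraction,
    build_prompt,
    parse_concentration,
    quality_check,
    resolve_targets,
    run_extraction,
)
from purmine.name_resolution import UniprotRecord, build_name_dictionary
from purmine.retrieval import QuestionTemplate, default_questions
from purmine.synthetic import MockEmbedding, MockLlm


def _doc(*paragraphs, article_id="10.1/test"):
    elements = [DocumentElement("heading", "Protein expression and purification", 0)]
    elements += [
        DocumentElement("paragraph", p, i + 1) for i, p in enumerate(paragraphs)
    ]
    return ArticleDocument(article_id, elements)


def _name_dict(*names):
    records = [
        UniprotRecord(accession=f"P{i}", recommended_name=name)
        for i, name in enumerate(names)
    ]
    return build_name_dictionary([], records)


BUFFER_Q = default_questions()[0]


class TestPrompt:
    def test_three_steps_in_order_and_context_included(self):
        prompt = build_prompt(BUFFER_Q, ["Probable kinase 1"], "some context text")
        text = prompt.render()
        s1, s2, s3 = text.index("Step 1"), text.index("Step 2"), text.index("Step 3")
        assert s1 < s2 < s3
        assert "copied" in text.lower() or "copy" in text.lower()
        assert "some context text" in text
        assert "- Probable kinase 1" in text

    def test_context_within_budget_invariant(self):
        prompt = build_prompt(BUFFER_Q, [], "x" * 500)
        assert len(prompt.context) <= 12_000


class TestResolveTargets:
    def test_only_mentioned_candidate_confirmed(self):
        candidates = [
            ("KINA1", "P1", "Kinase A", 2),
            ("KINB2", "P2", "Kinase B", 1),
        ]
        context = "Kinase A was expressed in Escherichia coli BL21(DE3)."
        assert resolve_targets(candidates, context, MockLlm()) == ["Kinase A"]

    def test_empty_candidates_no_backend_call(self):
        class Exploding:
            name = "boom"

            def generate(self, prompt, max_output_chars=0):
                raise AssertionError("backend must not be called")

        assert resolve_targets([], "context", Exploding()) == []


class TestRunExtraction:
    def test_planted_buffer_roundtrips(self):
        doc = _doc(
            "Probable kinase 1 was purified in 20 mM Tris pH 8.0, "
            "150 mM NaCl and 1 mM DTT."
        )
        raw = run_extraction(
            doc, BUFFER_Q, MockLlm(), MockEmbedding(), _name_dict("Probable kinase 1")
        )
        assert raw.status == "accepted"
        (record,) = raw.records
        assert record.protein_name == "Probable kinase 1"
        (buffer,) = record.fields["buffers"]
        assert buffer["pH"] == 8.0
        comps = {c["name"]: c["concentration"] for c in buffer["components"]}
        assert comps == {"Tris": "20 mM", "NaCl": "150 mM", "DTT": "1 mM"}

    def test_two_proteins_assigned_to_their_paragraphs(self):
        doc = _doc(
            "Probable kinase 1 was expressed in Escherichia coli BL21(DE3). "
            "The lysis buffer contained 50 mM HEPES pH 7.4 and 100 mM KCl.",
            "Putative ligase 2 was expressed in Sf9 insect cells. "
            "Putative ligase 2 was purified in 25 mM Tris pH 7.5 and 200 mM NaCl.",
        )
        raw = run_extraction(
            doc,
            BUFFER_Q,
            MockLlm(),
            MockEmbedding(),
            _name_dict("Probable kinase 1", "Putative ligase 2"),
        )
        by_name = {r.protein_name: r.fields for r in raw.records}
        assert set(by_name) == {"Probable kinase 1", "Putative ligase 2"}
        assert by_name["Probable kinase 1"]["buffers"][0]["pH"] == 7.4
        assert by_name["Putative ligase 2"]["buffers"][0]["pH"] == 7.5

    def test_article_without_methods_content_is_empty(self):
        doc = _doc("Crystals diffracted nicely on the beamline.")
        raw = run_extraction(
            doc, BUFFER_Q, MockLlm(), MockEmbedding(), _name_dict("Probable kinase 1")
        )
        assert raw.status == "accepted-empty"
        assert raw.records == ()

    def test_unparseable_backend_rejected_after_retry(self):
        class Garbage:
            name = "garbage"
            calls = 0

            def generate(self, prompt, max_output_chars=20_000):
                if "resolve_targets" in prompt:
                    return MockLlm().generate(prompt)
                Garbage.calls += 1
                return "no fenced block here"

        doc = _doc("Probable kinase 1 was purified in 20 mM Tris pH 8.0.")
        raw = run_extraction(
            doc, BUFFER_Q, Garbage(), MockEmbedding(), _name_dict("Probable kinase 1")
        )
        assert raw.status == "rejected"
        assert Garbage.calls == 2  # one retry with the format reminder


def _raw(fields, evidence, protein="Probable kinase 1", question="q_buffers"):
    return RawExtraction(
        question_id=question,
        article_id="10.1/test",
        quoted_evidence=tuple(evidence),
        records=(ExtractionRecord(protein, fields),),
        response_text="",
        status="accepted",
    )


class TestQualityChecker:
    RESOLVED = ["Probable kinase 1"]

    def test_clean_record_accepted(self, chem_dict):
        raw = _raw(
            {
                "buffers": [
                    {
                        "buffer_type": None,
                        "pH": 8.0,
                        "stage": "lysis",
                        "components": [{"name": "Tris", "concentration": "150 mM"}],
                    }
                ]
            },
            ["The lysis buffer contained 150 mM Tris pH 8.0."],
        )
        report = quality_check(raw, chem_dict, self.RESOLVED)
        assert report.status == "accepted"
        assert report.violations == []
        assert len(report.records) == 1

    def test_ph_out_of_bounds_rejected(self, chem_dict):
        raw = _raw(
            {"buffers": [{"pH": 19.0, "stage": "lysis", "components": []}]},
            ["The lysis buffer was at pH 19."],
        )
        report = quality_check(raw, chem_dict, self.RESOLVED)
        assert report.status == "rejected"
        assert any(rule == "q2" for rule, _ in report.violations)
        assert report.records == ()

    def test_transcription_slip_repaired_from_evidence(self, chem_dict):
        # "Trsi" scores 1 - 2/4 = 0.5 against "Tris": below threshold (q1),
        # but the evidence contains "Tris" verbatim, so the repair path fires.
        raw = _raw(
            {
                "buffers": [
                    {"pH": None, "stage": "unknown",
                     "components": [{"name": "Trsi", "concentration": "20 mM"}]}
                ]
            },
            ["Purified in 20 mM Tris."],
        )
        report = quality_check(raw, chem_dict, self.RESOLVED)
        assert any(rule == "q1" for rule, _ in report.violations)
        assert report.status == "repaired"
        comp = report.records[0].fields["buffers"][0]["components"][0]
        assert comp["name"] == "Tris"

    def test_hallucinated_chemical_rejected_by_evidence_rule(self, chem_dict):
        # "imidazole" is a perfect dictionary match (q1 passes) but appears
        # nowhere in the evidence: the anti-hallucination rule must fire.
        raw = _raw(
            {
                "buffers": [
                    {"pH": None, "stage": "unknown",
                     "components": [{"name": "imidazole", "concentration": "250 mM"}]}
                ]
            },
            ["Purified in 250 mM NaCl."],
        )
        report = quality_check(raw, chem_dict, self.RESOLVED)
        assert report.status == "rejected"
        assert any(rule == "q5" for rule, _ in report.violations)

    def test_unit_spelling_repaired(self, chem_dict):
        raw = _raw(
            {
                "buffers": [
                    {"pH": None, "stage": "unknown",
                     "components": [{"name": "NaCl", "concentration": "150 millimolar"}]}
                ]
            },
            ["Purified in 150 millimolar NaCl."],
        )
        report = quality_check(raw, chem_dict, self.RESOLVED)
        assert report.status == "repaired"
        comp = report.records[0].fields["buffers"][0]["components"][0]
        assert comp["concentration"] == [150.0, "mM"]

    def test_unresolved_protein_rejected(self, chem_dict):
        raw = _raw({"fusion_tags": ["His"]}, ["Fused to a His tag."],
                   protein="Somebody else", question="q_tags")
        report = quality_check(raw, chem_dict, self.RESOLVED)
        assert report.status == "rejected"
        assert any(rule == "q4" for rule, _ in report.violations)

    def test_unparseable_concentration_rejected(self, chem_dict):
        raw = _raw(
            {
                "buffers": [
                    {"pH": None, "stage": "unknown",
                     "components": [{"name": "NaCl", "concentration": "150 bogons"}]}
                ]
            },
            ["Purified in 150 bogons NaCl."],
        )
        report = quality_check(raw, chem_dict, self.RESOLVED)
        assert report.status == "rejected"
        assert any(rule == "q3" for rule, _ in report.violations)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("150 mM", (150.0, "mM", False)),
        ("0.5 millimolar", (0.5, "mM", True)),
        ("10 uM", (10.0, "µM", True)),
        ("5 %", (5.0, "%", False)),
        ("2 mg/mL", (2.0, "mg/mL", False)),
        ("fast", None),
    ],
)
def test_parse_concentration(text, expected):
    assert parse_concentration(text) == expected
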