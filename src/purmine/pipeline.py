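"""End-to-end orchestration: corpus in, purification database out.

Per article: chunk and index once; per question: rank chunks against the
question template, select a bounded context, resolve target names (LLM step
1), run the three-step extraction (LLM step 2), quality-check the parsed
output, and merge surviving records into the database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import ArticleDocument, chunk_document
from .extraction import (
    LlmBackend,
    apply_quality_report,
    build_prompt,
    parse_response,
    quality_check,
    resolve_targets,
    FORMAT_REMINDER,
)
from .name_resolution import (
    NameDictionary,
    PdbRecord,
    UniprotRecord,
    build_name_dictionary,
    candidate_names,
)
from .normalization import ChemicalDictionary, default_chemical_dictionary
from .purification_db import PurificationDatabase, ingest_extraction
from .retrieval import (
    EmbeddingBackend,
    QuestionTemplate,
    VectorIndex,
    default_questions,
    rank_chunks,
    select_segments,
)

__all__ = ["PipelineResult", "extract_corpus"]


@dataclass
class PipelineResult:
    database: PurificationDatabase
    quality_statuses: dict = field(default_factory=dict)  # (article, question) -> status
    rejected: list = field(default_factory=list)


def extract_corpus(
    docs: Sequence[ArticleDocument],
    uniprot_records: Sequence[UniprotRecord],
    pdb_records: Sequence[PdbRecord] = (),
    questions: Sequence[QuestionTemplate] | None = None,
    llm_backend: LlmBackend | None = None,
    embedding_backend: EmbeddingBackend | None = None,
    chemical_dictionary: ChemicalDictionary | None = None,
    max_chunk_chars: int = 2500,
    max_total_chars: int = 12_000,
) -> PipelineResult:
    """Run the full extraction workflow over a corpus.

    Backends default to the deterministic mocks, so a dry run needs no model
    weights; pass real adapters for production extraction.
    """
    from .synthetic import MockEmbedding, MockLlm  # mocks are the default backends

    questions = list(questions) if questions is not None else default_questions()
    llm = llm_backend if llm_backend is not None else MockLlm()
    emb = embedding_backend if embedding_backend is not None else MockEmbedding()
    chem_dict = (
        chemical_dictionary
        if chemical_dictionary is not None
        else default_chemical_dictionary()
    )
    name_dict = build_name_dictionary(list(pdb_records), list(uniprot_records))
    pdb_ids_by_doi: dict[str, list[str]] = {}
    for rec in pdb_records:
        if rec.doi:
            pdb_ids_by_doi.setdefault(rec.doi, []).append(rec.pdb_id)

    result = PipelineResult(database=PurificationDatabase())
    for doc in docs:
        chunks = chunk_document(doc, max_chunk_chars=max_chunk_chars)
        chunk_map = {c.chunk_id: c for c in chunks}
        index = VectorIndex(dim=emb.dim)
        index.add_chunks(chunks, emb)
        candidates = candidate_names(doc, name_dict)
        for question in questions:
            ranked = rank_chunks(question, index, doc.article_id, emb)
            context = select_segments(ranked, chunk_map, max_total_chars)
            resolved = resolve_targets(candidates, context, llm)
            prompt = build_prompt(question, resolved, context)
            response = llm.generate(prompt.render())
            raw = parse_response(question.question_id, doc.article_id, response)
            if raw is None:
                response = llm.generate(prompt.render() + FORMAT_REMINDER)
                raw = parse_response(question.question_id, doc.article_id, response)
            key = (doc.article_id, question.question_id)
            if raw is None:
                result.quality_statuses[key] = "rejected"
                result.rejected.append(key)
                continue
            report = quality_check(raw, chem_dict, resolved)
            result.quality_statuses[key] = report.status
            if report.status == "rejected":
                result.rejected.append(key)
            validated = apply_quality_report(raw, report)
            ingest_extraction(
                validated,
                uniprot_records,
                result.database,
                dictionary=chem_dict,
                pdb_ids_by_doi=pdb_ids_by_doi,
            )
    return result
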