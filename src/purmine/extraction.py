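"""Two-step LLM extraction with a three-step prompt and a quality checker.

Step one of the LLM protocol disambiguates the candidate target-protein
names against the selected article context; step two extracts the
question's fields.  The extraction prompt enforces an evidence-first
scaffold: (1) copy verbatim the sentences containing the answer, (2)
extract entities and values from only those sentences, (3) assign each
record to one resolved protein.  Responding with copied evidence first
measurably suppresses hallucinated values, and the quality checker makes
the guarantee hard: no extracted value that is absent from the quoted
evidence reaches the database.

Backends are pluggable contracts; tests run against a deterministic mock
(see the synthetic-corpus module).  Real backends must honour temperature-0
semantics (same prompt, same response) for reproducible runs.
"""

from __future__ import annotations

import json
import re
import subprocess
import urllib.request
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence, runtime_checkable

from .corpus_io import ArticleDocument, chunk_document
from .name_resolution import NameDictionary, candidate_names
from .normalization import (
    ChemicalDictionary,
    match_score,
    normalize_chemical,
    normalize_string,
)
from .retrieval import (
    EmbeddingBackend,
    QuestionTemplate,
    VectorIndex,
    rank_chunks,
    select_segments,
)

__all__ = [
    "LlmBackend",
    "CommandBackend",
    "HttpBackend",
    "ExtractionPrompt",
    "ExtractionRecord",
    "RawExtraction",
    "QualityReport",
    "ResolutionError",
    "build_prompt",
    "build_resolution_prompt",
    "resolve_targets",
    "parse_response",
    "run_extraction",
    "quality_check",
    "apply_quality_report",
    "parse_concentration",
    "VALID_UNITS",
]

VALID_UNITS = ("M", "mM", "µM", "%", "mg/mL")
_UNIT_REPAIRS = {"millimolar": "mM", "uM": "µM", "molar": "M", "micromolar": "µM"}

THREE_STEP_INSTRUCTIONS = (
    "Step 1: Copy verbatim every sentence from the context that contains the answer.\n"
    "Step 2: Extract the entities and values from only those copied sentences.\n"
    "Step 3: Assign each extracted record to exactly one of the target proteins "
    'listed above, or to "unassigned".\n'
    "Respond with a single fenced ```json block of the form\n"
    '{"quotes": ["..."], "records": [{"protein_name": "...", "fields": {...}}]}'
)

FORMAT_REMINDER = (
    "\n\nREMINDER: respond ONLY with one fenced ```json block containing the "
    'keys "quotes" and "records".'
)


class ResolutionError(RuntimeError):
    """Step-1 response could not be parsed; carries the raw backend text."""

    def __init__(self, message: str, raw_text: str):
        super().__init__(message)
        self.raw_text = raw_text


@runtime_checkable
class LlmBackend(Protocol):
    name: str

    def generate(self, prompt: str, max_output_chars: int = 20_000) -> str: ...


class CommandBackend:
    """Pipe the prompt into a local command; its stdout is the response."""

    def __init__(self, command: Sequence[str], name: str = "cmd"):
        self.command = list(command)
        self.name = name

    def generate(self, prompt: str, max_output_chars: int = 20_000) -> str:
        proc = subprocess.run(
            self.command, input=prompt, capture_output=True, text=True, check=True
        )
        return proc.stdout[:max_output_chars]


class HttpBackend:
    """POST {"prompt": ...} to an endpoint returning {"response": ...}."""

    def __init__(self, url: str, name: str = "http", timeout: float = 120.0):
        self.url = url
        self.name = name
        self.timeout = timeout

    def generate(self, prompt: str, max_output_chars: int = 20_000) -> str:
        req = urllib.request.Request(
            self.url,
            data=json.dumps({"prompt": prompt}).encode("utf-8"),
            headers={"Content-Type": "application/json"},
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            payload = json.loads(resp.read().decode("utf-8"))
        return payload["response"][:max_output_chars]


# ---------------------------------------------------------------------------
# prompts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtractionPrompt:
    question_id: str
    resolved_protein_names: tuple[str, ...]
    context: str
    instructions: str = THREE_STEP_INSTRUCTIONS
    question_text: str = ""
    output_schema: tuple[str, ...] = ()

    def render(self) -> str:
        targets = "\n".join(f"- {n}" for n in self.resolved_protein_names) or "- (none)"
        return (
            f"### QUESTION_ID\n{self.question_id}\n"
            f"### TASK\nextract\n"
            f"### QUESTION\n{self.question_text}\n"
            f"### TARGET PROTEINS\n{targets}\n"
            f"### OUTPUT FIELDS\n{', '.join(self.output_schema)}\n"
            f"### INSTRUCTIONS\n{self.instructions}\n"
            f"### CONTEXT\n{self.context}\n"
        )


def build_prompt(
    question: QuestionTemplate, resolved: Sequence[str], context: str
) -> ExtractionPrompt:
    """Assemble the three-step extraction prompt for one article and question."""
    return ExtractionPrompt(
        question_id=question.question_id,
        resolved_protein_names=tuple(resolved),
        context=context,
        question_text=question.question_text,
        output_schema=question.output_schema,
    )


def build_resolution_prompt(
    candidates: Sequence[tuple[str, str, str, int]], context: str
) -> str:
    lines = "\n".join(
        f"- {alias}\t{accession}\t{rec_name}" for alias, accession, rec_name, _ in candidates
    )
    return (
        "### TASK\nresolve_targets\n"
        "### CANDIDATES\n"
        f"{lines}\n"
        "### INSTRUCTIONS\n"
        "From the candidate protein names above, list the recommended names of the "
        "proteins that are actual study targets in the context. Respond with a "
        "single fenced ```json list of recommended names.\n"
        f"### CONTEXT\n{context}\n"
    )


def resolve_targets(
    candidates: Sequence[tuple[str, str, str, int]],
    context: str,
    backend: LlmBackend,
) -> list[str]:
    """LLM step 1: confirm which candidate names are the article's targets."""
    if not candidates:
        return []
    prompt = build_resolution_prompt(candidates, context)
    response = backend.generate(prompt)
    block = _fenced_json(response)
    if block is None:
        raise ResolutionError("no fenced json block in resolution response", response)
    try:
        names = json.loads(block)
    except json.JSONDecodeError as exc:
        raise ResolutionError(f"bad json in resolution response: {exc}", response)
    if not isinstance(names, list) or not all(isinstance(n, str) for n in names):
        raise ResolutionError("resolution response is not a list of names", response)
    ordered: list[str] = []
    for _, _, rec_name, _ in candidates:
        if rec_name and rec_name in names and rec_name not in ordered:
            ordered.append(rec_name)
    return ordered


# ---------------------------------------------------------------------------
# response parsing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtractionRecord:
    protein_name: str
    fields: dict


@dataclass(frozen=True)
class RawExtraction:
    question_id: str
    article_id: str
    quoted_evidence: tuple[str, ...]
    records: tuple[ExtractionRecord, ...]
    response_text: str
    status: str  # accepted | accepted-empty | repaired | rejected


_FENCE = re.compile(r"```json\s*(.*?)```", re.DOTALL)


def _fenced_json(text: str) -> str | None:
    m = _FENCE.search(text)
    return m.group(1) if m else None


def parse_response(
    question_id: str, article_id: str, response: str
) -> RawExtraction | None:
    """Parse one backend response; None signals a format failure (retry)."""
    block = _fenced_json(response)
    if block is None:
        return None
    try:
        payload = json.loads(block)
        quotes = tuple(str(q) for q in payload["quotes"])
        records = tuple(
            ExtractionRecord(protein_name=str(r["protein_name"]), fields=dict(r["fields"]))
            for r in payload["records"]
        )
    except (json.JSONDecodeError, KeyError, TypeError):
        return None
    return RawExtraction(
        question_id=question_id,
        article_id=article_id,
        quoted_evidence=quotes,
        records=records,
        response_text=response,
        status="accepted" if records else "accepted-empty",
    )


def run_extraction(
    doc: ArticleDocument,
    question: QuestionTemplate,
    llm_backend: LlmBackend,
    embedding_backend: EmbeddingBackend,
    name_dictionary: NameDictionary,
    max_chunk_chars: int = 2500,
    max_total_chars: int = 12_000,
) -> RawExtraction:
    """Full workflow for one article and one question: chunk, index, rank,
    select context, resolve targets, prompt, parse (one retry on format
    failure, then rejected)."""
    chunks = chunk_document(doc, max_chunk_chars=max_chunk_chars)
    index = VectorIndex(dim=embedding_backend.dim)
    index.add_chunks(chunks, embedding_backend)
    ranked = rank_chunks(question, index, doc.article_id, embedding_backend)
    context = select_segments(ranked, {c.chunk_id: c for c in chunks}, max_total_chars)

    candidates = candidate_names(doc, name_dictionary)
    resolved = resolve_targets(candidates, context, llm_backend)

    prompt = build_prompt(question, resolved, context)
    response = llm_backend.generate(prompt.render())
    parsed = parse_response(question.question_id, doc.article_id, response)
    if parsed is None:
        response = llm_backend.generate(prompt.render() + FORMAT_REMINDER)
        parsed = parse_response(question.question_id, doc.article_id, response)
    if parsed is None:
        return RawExtraction(
            question_id=question.question_id,
            article_id=doc.article_id,
            quoted_evidence=(),
            records=(),
            response_text=response,
            status="rejected",
        )
    return parsed


# ---------------------------------------------------------------------------
# quality checker
#
# q1  every chemical normalizes against the dictionary at score >= threshold
#     (fallback: a dictionary alias present verbatim in the evidence repairs
#     the value);
# q2  pH values lie in [0, 14];
# q3  concentrations parse as number + unit from {M, mM, µM, %, mg/mL}
#     (unit spelling variants are repaired);
# q4  record protein names are resolved names or "unassigned";
# q5  every extracted value appears, after normalization, as a substring of
#     the quoted evidence — the anti-hallucination rule.
# ---------------------------------------------------------------------------


@dataclass
class QualityReport:
    status: str  # accepted | repaired | rejected
    violations: list[tuple[str, str]] = field(default_factory=list)
    repaired_fields: list[str] = field(default_factory=list)
    records: tuple[ExtractionRecord, ...] = ()  # surviving, repaired records


_CONC = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*([A-Za-zµ%/]+)\s*$")


def parse_concentration(text: str) -> tuple[float, str, bool] | None:
    """Parse "150 mM" → (150.0, "mM", repaired?); None when unparseable."""
    m = _CONC.match(text)
    if not m:
        return None
    value = float(m.group(1))
    unit = m.group(2)
    repaired = False
    if unit not in VALID_UNITS:
        fixed = _UNIT_REPAIRS.get(unit) or _UNIT_REPAIRS.get(unit.lower())
        if fixed is None:
            return None
        unit, repaired = fixed, True
    return value, unit, repaired


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


class _Checker:
    def __init__(
        self,
        evidence: str,
        dictionary: ChemicalDictionary,
        threshold: float,
        report: QualityReport,
    ):
        self.evidence_norm = normalize_string(evidence)
        self.dictionary = dictionary
        self.threshold = threshold
        self.report = report
        self.record_ok = True

    def fail(self, rule: str, message: str) -> None:
        self.report.violations.append((rule, message))
        self.record_ok = False

    def in_evidence(self, value: str, label: str) -> bool:
        if normalize_string(str(value)) in self.evidence_norm:
            return True
        self.fail("q5", f"{label} {value!r} not found in quoted evidence")
        return False

    def chemical(self, surface: str, label: str) -> str | None:
        """q1 (dictionary normalization, with the evidence-substring repair
        path) followed by q5 (the value must be substantiated by evidence)."""
        match = normalize_chemical(surface, self.dictionary, self.threshold)
        if match.canonical is not None:
            canonical = match.canonical
            if normalize_string(canonical) != normalize_string(surface):
                self.report.repaired_fields.append(f"{label}: {surface!r} -> {canonical!r}")
        else:
            self.report.violations.append(
                ("q1", f"{label} {surface!r} best score {match.score:.3f} < {self.threshold}")
            )
            # repair path: the closest dictionary alias present verbatim in
            # the quoted evidence (a transcription slip, not a hallucination)
            best: tuple[float, str] | None = None
            for alias, alias_canonical in self.dictionary.aliases():
                if normalize_string(alias) in self.evidence_norm:
                    s = match_score(surface, alias)
                    if best is None or s > best[0]:
                        best = (s, alias_canonical)
            if best is None or best[0] < 0.5:
                self.record_ok = False
                return None
            canonical = best[1]
            self.report.repaired_fields.append(f"{label}: {surface!r} -> {canonical!r} (evidence)")
        # q5: either the surface form or the repaired canonical must appear
        # in the quoted evidence (typo'd surfaces are quoted as printed)
        if (
            normalize_string(surface) in self.evidence_norm
            or normalize_string(canonical) in self.evidence_norm
        ):
            return canonical
        self.fail("q5", f"{label} {surface!r} not found in quoted evidence")
        return None


def quality_check(
    raw: RawExtraction,
    dictionary: ChemicalDictionary,
    resolved: Sequence[str],
    threshold: float = 0.85,
) -> QualityReport:
    """Validate and repair one parsed extraction; violating records are
    dropped from the surviving set."""
    report = QualityReport(status="accepted")
    evidence = " ".join(raw.quoted_evidence)
    surviving: list[ExtractionRecord] = []
    for idx, record in enumerate(raw.records):
        checker = _Checker(evidence, dictionary, threshold, report)
        label = f"record[{idx}]"
        if record.protein_name not in resolved and record.protein_name != "unassigned":
            checker.fail("q4", f"{label}: protein {record.protein_name!r} not resolved")
        fields = _check_fields(checker, label, dict(record.fields))
        if checker.record_ok:
            surviving.append(ExtractionRecord(record.protein_name, fields))
    rejected = len(surviving) < len(raw.records)
    if rejected:
        report.status = "rejected"
    elif report.repaired_fields:
        report.status = "repaired"
    report.records = tuple(surviving)
    return report


def _check_fields(checker: _Checker, label: str, fields: dict) -> dict:
    if "buffers" in fields:
        new_buffers = []
        for j, buf in enumerate(fields["buffers"]):
            buf = dict(buf)
            blabel = f"{label}.buffers[{j}]"
            ph = buf.get("pH")
            if ph is not None:
                if not (0.0 <= float(ph) <= 14.0):
                    checker.fail("q2", f"{blabel}: pH {ph} out of [0, 14]")
                else:
                    checker.in_evidence(_fmt_number(ph), f"{blabel}.pH")
            comps = []
            for k, comp in enumerate(buf.get("components", [])):
                comp = dict(comp)
                clabel = f"{blabel}.components[{k}]"
                canonical = checker.chemical(comp["name"], clabel)
                if canonical is not None:
                    comp["surface"] = comp["name"]
                    comp["name"] = canonical
                conc = comp.get("concentration")
                if isinstance(conc, str):
                    checker.in_evidence(conc.split()[0], f"{clabel}.concentration")
                    parsed = parse_concentration(conc)
                    if parsed is None:
                        checker.fail("q3", f"{clabel}: unparseable concentration {conc!r}")
                    else:
                        value, unit, repaired = parsed
                        comp["concentration"] = [value, unit]
                        if repaired:
                            checker.report.repaired_fields.append(
                                f"{clabel}: unit spelling {conc!r} -> {unit!r}"
                            )
                comps.append(comp)
            buf["components"] = comps
            btype = buf.get("buffer_type")
            if btype is not None:
                fixed = checker.chemical(btype, f"{blabel}.buffer_type")
                buf["buffer_type"] = fixed if fixed is not None else btype
            new_buffers.append(buf)
        fields["buffers"] = new_buffers
    for key in ("detergents", "crosslinkers"):
        if key in fields:
            fixed_list = []
            for i, name in enumerate(fields[key]):
                fixed = checker.chemical(name, f"{label}.{key}[{i}]")
                fixed_list.append(fixed if fixed is not None else name)
            fields[key] = fixed_list
    if fields.get("inducer"):
        fixed = checker.chemical(fields["inducer"], f"{label}.inducer")
        if fixed is not None:
            fields["inducer"] = fixed
    for key in ("induction_temperature_C", "induction_time_h", "inducer_concentration_mM"):
        if fields.get(key) is not None:
            checker.in_evidence(_fmt_number(fields[key]), f"{label}.{key}")
    if fields.get("expression_system"):
        checker.in_evidence(fields["expression_system"], f"{label}.expression_system")
    if "fusion_tags" in fields:
        for tag in fields["fusion_tags"]:
            checker.in_evidence(tag, f"{label}.fusion_tags")
    return fields


def apply_quality_report(raw: RawExtraction, report: QualityReport) -> RawExtraction:
    """The validated extraction: surviving records only, ready for ingest."""
    status = "accepted-empty" if not report.records else (
        "repaired" if report.status == "repaired" else "accepted"
    )
    return replace(raw, records=report.records, status=status)
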