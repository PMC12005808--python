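"""Sectioned article documents and their retrieval chunks.

Structural-biology articles arrive as an ordered sequence of headings and
paragraphs (the output contract of upstream OCR / PDF parsing).  Retrieval
operates on bounded chunks: every heading starts a new chunk, and a section
whose text exceeds the chunk budget is split greedily at sentence
boundaries, so that the "Protein expression and purification" subsection —
where purification facts live — survives as a coherent retrieval unit.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "DocumentElement",
    "ArticleDocument",
    "Chunk",
    "ArticleParseError",
    "EmptyDocumentError",
    "load_article",
    "write_article",
    "chunk_document",
]

DEFAULT_MAX_CHUNK_CHARS = 2500


class ArticleParseError(ValueError):
    """Raised when an article fixture file is malformed."""


class EmptyDocumentError(ArticleParseError):
    """Raised when an article file contains no elements."""


@dataclass(frozen=True)
class DocumentElement:
    """One heading or paragraph, in document order."""

    kind: str  # "heading" | "paragraph"
    text: str
    order: int

    def __post_init__(self) -> None:
        if self.kind not in ("heading", "paragraph"):
            raise ValueError(f"unknown element kind: {self.kind!r}")
        if not self.text.strip():
            raise ValueError("element text empty after whitespace normalization")


@dataclass
class ArticleDocument:
    """A sectioned article: ordered elements under a stable identifier (DOI when known)."""

    article_id: str
    elements: list[DocumentElement]

    def __post_init__(self) -> None:
        if not self.elements:
            raise EmptyDocumentError(f"article {self.article_id!r} has no elements")
        orders = [e.order for e in self.elements]
        if orders != sorted(orders) or len(set(orders)) != len(orders):
            raise ValueError("element orders must be strictly increasing and unique")

    @property
    def token_estimate(self) -> int:
        """Rough LLM token count: ceil(total characters / 4). Informational only."""
        return math.ceil(sum(len(e.text) for e in self.elements) / 4)

    def body_text(self) -> str:
        """Paragraph texts joined by single spaces; chunk char spans index into this."""
        return " ".join(e.text for e in self.elements if e.kind == "paragraph")

    def full_text(self) -> str:
        """All element texts (headings included), newline joined; used for alias scans."""
        return "\n".join(e.text for e in self.elements)


@dataclass(frozen=True)
class Chunk:
    """A bounded retrieval unit carrying its nearest preceding section heading."""

    chunk_id: str
    article_id: str
    section_title: str
    text: str
    char_span: tuple[int, int]  # half-open offsets into ArticleDocument.body_text()
    order: int

    def __post_init__(self) -> None:
        if self.char_span[1] <= self.char_span[0]:
            raise ValueError("char_span end must exceed start")


# ---------------------------------------------------------------------------
# fixture I/O
#
# Two dialects share the ArticleDocument contract:
#   * markdown-ish plain text: "# Heading" lines, blank-line separated paragraphs;
#   * line-delimited JSON records: {"kind": ..., "text": ...} per line.
# Real-PDF ingestion is an optional adapter producing the same structure.
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def _norm(text: str) -> str:
    return _WS.sub(" ", text).strip()


def load_article(path: str | Path, article_id: str | None = None) -> ArticleDocument:
    """Read an article fixture (markdown-style text or JSONL records).

    Raises :class:`ArticleParseError` naming the offending line on malformed
    input and :class:`EmptyDocumentError` on files with no elements.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    aid = article_id if article_id is not None else path.stem
    stripped = raw.lstrip()
    if path.suffix == ".jsonl" or stripped.startswith("{"):
        elements = list(_parse_jsonl(raw))
    else:
        elements = list(_parse_markdown(raw))
    if not elements:
        raise EmptyDocumentError(f"no elements in {path}")
    return ArticleDocument(article_id=aid, elements=elements)


def _parse_jsonl(raw: str) -> Iterator[DocumentElement]:
    order = 0
    for lineno, line in enumerate(raw.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            kind, text = rec["kind"], _norm(rec["text"])
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ArticleParseError(f"line {lineno}: bad record ({exc})") from exc
        if kind not in ("heading", "paragraph"):
            raise ArticleParseError(f"line {lineno}: unknown kind {kind!r}")
        if not text:
            raise ArticleParseError(f"line {lineno}: empty text")
        yield DocumentElement(kind=kind, text=text, order=order)
        order += 1


def _parse_markdown(raw: str) -> Iterator[DocumentElement]:
    order = 0
    para: list[str] = []

    def flush() -> Iterator[DocumentElement]:
        nonlocal order, para
        if para:
            yield DocumentElement("paragraph", _norm(" ".join(para)), order)
            order += 1
            para = []

    for line in raw.splitlines():
        if line.startswith("#"):
            yield from flush()
            title = _norm(line.lstrip("#"))
            if title:
                yield DocumentElement("heading", title, order)
                order += 1
        elif not line.strip():
            yield from flush()
        else:
            para.append(line.strip())
    yield from flush()


def write_article(doc: ArticleDocument, path: str | Path) -> None:
    """Write the markdown-style fixture form; round-trips through load_article."""
    lines: list[str] = []
    for el in doc.elements:
        if el.kind == "heading":
            lines.append(f"# {el.text}")
        else:
            lines.append(el.text)
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# chunking
# ---------------------------------------------------------------------------

_SENTENCE_END = re.compile(r"(?<=\.)\s+")


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    """Partition [0, len(text)) at ". " boundaries; the split whitespace stays
    with the preceding sentence so spans tile the section exactly."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENTENCE_END.finditer(text):
        spans.append((start, m.end()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def chunk_document(
    doc: ArticleDocument, max_chunk_chars: int = DEFAULT_MAX_CHUNK_CHARS
) -> list[Chunk]:
    """Split a document into retrieval chunks of at most ``max_chunk_chars``.

    Every heading starts a new chunk and is prepended to its section's first
    chunk (the subtitle carries the retrieval signal).  Oversized sections are
    split by greedy sentence packing; a single sentence longer than the budget
    is hard-cut at whitespace.  Chunk char spans tile the paragraph body text,
    so coverage is lossless and the chunking is deterministic.
    """
    if max_chunk_chars < 100:
        raise ValueError("max_chunk_chars must be >= 100")

    # sections: (heading text or "", [(body_start, body_end) per paragraph])
    sections: list[tuple[str, list[tuple[int, int]]]] = []
    offset = 0
    current_title = ""
    current_paras: list[tuple[int, int]] = []
    started = False
    for el in doc.elements:
        if el.kind == "heading":
            if started:
                sections.append((current_title, current_paras))
            current_title = el.text
            current_paras = []
            started = True
        else:
            start = offset
            end = offset + len(el.text)
            offset = end + 1  # single-space join in body_text
            current_paras.append((start, end))
            started = True
    sections.append((current_title, current_paras))

    body = doc.body_text()
    chunks: list[Chunk] = []
    order = 0
    for title, paras in sections:
        if not paras:
            continue
        sec_start, sec_end = paras[0][0], paras[-1][1]
        sec_text = body[sec_start:sec_end]
        sent = _sentence_spans(sec_text)
        groups = _pack_sentences(sec_text, sent, title, max_chunk_chars)
        first = True
        for a, b in groups:
            prefix = f"{title}\n" if (first and title) else ""
            text = prefix + sec_text[a:b].rstrip()
            chunks.append(
                Chunk(
                    chunk_id=f"{doc.article_id}::c{order}",
                    article_id=doc.article_id,
                    section_title=title,
                    text=text,
                    char_span=(sec_start + a, sec_start + b),
                    order=order,
                )
            )
            order += 1
            first = False
    return chunks


def _pack_sentences(
    sec_text: str,
    sentences: Sequence[tuple[int, int]],
    title: str,
    max_chunk_chars: int,
) -> list[tuple[int, int]]:
    """Greedy sentence packing into contiguous spans, budget-aware of the
    heading prefix on the first chunk."""
    groups: list[tuple[int, int]] = []
    cur_start: int | None = None
    cur_end = 0
    for (a, b) in sentences:
        budget = max_chunk_chars - (len(title) + 1 if (not groups and title) else 0)
        sent_len = len(sec_text[a:b].rstrip())
        if sent_len > budget:
            # flush, then hard-cut the oversized sentence
            if cur_start is not None:
                groups.append((cur_start, cur_end))
                cur_start = None
            groups.extend(_hard_cut(sec_text, a, b, title, max_chunk_chars, groups))
            continue
        if cur_start is None:
            cur_start, cur_end = a, b
        elif len(sec_text[cur_start:b].rstrip()) <= budget:
            cur_end = b
        else:
            groups.append((cur_start, cur_end))
            cur_start, cur_end = a, b
    if cur_start is not None:
        groups.append((cur_start, cur_end))
    return groups


def _hard_cut(
    sec_text: str,
    a: int,
    b: int,
    title: str,
    max_chunk_chars: int,
    existing: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    pieces: list[tuple[int, int]] = []
    pos = a
    while pos < b:
        budget = max_chunk_chars - (
            len(title) + 1 if (not existing and not pieces and title) else 0
        )
        end = min(pos + budget, b)
        if end < b:
            ws = sec_text.rfind(" ", pos + 1, end)
            if ws > pos:
                end = ws + 1  # keep the space with the earlier piece
        pieces.append((pos, end))
        pos = end
    return pieces
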