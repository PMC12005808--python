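"""Embedding-based passage selection for question answering over one article.

Each chunk is embedded once into a vector index.  A question of interest
carries a *template paragraph* — an exemplar passage of the kind that answers
it — whose embedding is compared against the article's chunk embeddings by
cosine similarity; similarity correlates with the probability that the answer
lives in the chunk.  The top-ranked chunks are reassembled, in document
order, into a context bounded at 12 000 characters.

The production embedding backend is a sentence-embedding model producing
1024-dimensional vectors; any callable honouring the
:class:`EmbeddingBackend` contract plugs in.  The default test backend is a
hashed bag-of-words term-frequency embedding: deterministic, download-free,
and preserving the lexical-overlap → high-cosine behaviour the selection
relies on.
"""

from __future__ import annotations

import json
import re
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus_io import Chunk

__all__ = [
    "EmbeddingBackend",
    "HashedBagEmbedding",
    "QuestionTemplate",
    "VectorIndex",
    "RetrievalError",
    "embed",
    "cosine_similarity",
    "rank_chunks",
    "select_segments",
    "default_questions",
]

DEFAULT_MAX_CONTEXT_CHARS = 12_000


class RetrievalError(RuntimeError):
    pass


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract: any deterministic function string -> fixed-dim real vector."""

    dim: int

    def embed_text(self, text: str) -> np.ndarray: ...


_TOKEN = re.compile(r"[a-z0-9]+")


class HashedBagEmbedding:
    """Hashed term-frequency embedding (lowercased, punctuation stripped).

    Token index = crc32(token) mod dim, value = term count.  Disjoint
    vocabularies yield orthogonal vectors absent hash collisions, so lexical
    overlap with the template paragraph drives the cosine score.
    """

    def __init__(self, dim: int = 256):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim

    def embed_text(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        for tok in _TOKEN.findall(text.lower()):
            vec[zlib.crc32(tok.encode("utf-8")) % self.dim] += 1.0
        return vec


@dataclass(frozen=True)
class QuestionTemplate:
    """A question of interest with its exemplar passage and output schema."""

    question_id: str
    question_text: str
    template_paragraph: str
    output_schema: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.template_paragraph.strip():
            raise ValueError("template_paragraph must be non-empty")


def default_questions() -> list[QuestionTemplate]:
    """The shipped questions: buffers, fusion tags, expression/induction, and
    detergent/crosslinker usage in cryo-EM grid preparation.  The template
    paragraphs are editable exemplars, not fixed prompts."""
    return [
        QuestionTemplate(
            "q_buffers",
            "Which buffers (type, pH, components and their concentrations) were "
            "used to purify each target?",
            "The lysis buffer contained 20 mM Tris pH 8.0, 150 mM NaCl, 1 mM DTT "
            "and 5 % glycerol. The sample was purified by affinity chromatography "
            "and eluted in buffer with 250 mM imidazole.",
            ("buffers",),
        ),
        QuestionTemplate(
            "q_tags",
            "Which fusion tags were fused to each target?",
            "The construct was fused to an N-terminal His tag followed by a TEV "
            "cleavage site; an MBP tag was fused to improve solubility.",
            ("fusion_tags",),
        ),
        QuestionTemplate(
            "q_expression",
            "In which expression system was each target expressed, and under "
            "which induction conditions (inducer, concentration, temperature, time)?",
            "The gene was expressed in E. coli BL21(DE3). Expression was induced "
            "with 0.5 mM IPTG at 18 °C for 16 h.",
            (
                "expression_system",
                "inducer",
                "inducer_concentration_mM",
                "induction_temperature_C",
                "induction_time_h",
            ),
        ),
        QuestionTemplate(
            "q_grid_prep",
            "Which detergents and crosslinkers were used while preparing the "
            "sample for cryo-EM grids?",
            "Before grid preparation the sample was supplemented with 0.01 % LMNG "
            "and 0.002 % CHS. The complex was crosslinked with 0.05 % "
            "glutaraldehyde prior to grid preparation.",
            ("detergents", "crosslinkers"),
        ),
    ]


# ---------------------------------------------------------------------------
# embedding and similarity
# ---------------------------------------------------------------------------


def embed(text: str, backend: EmbeddingBackend) -> np.ndarray:
    """Embed ``text`` with ``backend``; deterministic per backend contract."""
    if not text:
        raise ValueError("cannot embed empty text")
    try:
        vec = np.asarray(backend.embed_text(text), dtype=np.float64)
    except Exception as exc:  # propagate with context
        raise RetrievalError(f"embedding backend failed on text {text[:40]!r}…") from exc
    if vec.ndim != 1 or vec.shape[0] != backend.dim:
        raise RetrievalError(
            f"backend returned shape {vec.shape}, expected ({backend.dim},)"
        )
    return vec


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for an all-zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class VectorIndex:
    """Per-corpus chunk embedding store: chunk_id -> (vector, article_id, order)."""

    dim: int
    entries: dict[str, tuple[np.ndarray, str, int]] = field(default_factory=dict)

    def add_chunks(self, chunks: Sequence[Chunk], backend: EmbeddingBackend) -> None:
        if backend.dim != self.dim:
            raise ValueError("backend dim does not match index dim")
        for ch in chunks:
            if ch.chunk_id in self.entries:
                raise ValueError(f"duplicate chunk_id {ch.chunk_id!r}")
            self.entries[ch.chunk_id] = (embed(ch.text, backend), ch.article_id, ch.order)

    def article_chunk_ids(self, article_id: str) -> list[str]:
        ids = [cid for cid, (_, aid, _) in self.entries.items() if aid == article_id]
        if not ids:
            raise KeyError(f"no indexed chunks for article {article_id!r}")
        return ids

    # -- persistence: one JSON record per chunk, exact round-trip ------------

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for cid in sorted(self.entries):
                vec, aid, order = self.entries[cid]
                fh.write(
                    json.dumps(
                        {
                            "chunk_id": cid,
                            "article_id": aid,
                            "order": order,
                            "dim": self.dim,
                            "values": vec.tolist(),
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "VectorIndex":
        index: VectorIndex | None = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                if index is None:
                    index = cls(dim=rec["dim"])
                elif rec["dim"] != index.dim:
                    raise ValueError("inconsistent dims in index file")
                index.entries[rec["chunk_id"]] = (
                    np.asarray(rec["values"], dtype=np.float64),
                    rec["article_id"],
                    rec["order"],
                )
        if index is None:
            raise ValueError("empty index file")
        return index


def rank_chunks(
    template: QuestionTemplate,
    index: VectorIndex,
    article_id: str,
    backend: EmbeddingBackend,
) -> list[tuple[str, float]]:
    """Rank one article's chunks against the question's template paragraph.

    Descending cosine similarity; ties broken by ascending document position.
    """
    qvec = embed(template.template_paragraph, backend)
    scored: list[tuple[str, float, int]] = []
    for cid in index.article_chunk_ids(article_id):
        vec, _, order = index.entries[cid]
        if not vec.any():
            sim = 0.0  # chunk with no token mass carries no signal
        else:
            sim = cosine_similarity(qvec, vec)
        scored.append((cid, sim, order))
    scored.sort(key=lambda t: (-t[1], t[2]))
    return [(cid, sim) for cid, sim, _ in scored]


def select_segments(
    ranked: Sequence[tuple[str, float]],
    chunks: Mapping[str, Chunk],
    max_total_chars: int = DEFAULT_MAX_CONTEXT_CHARS,
) -> str:
    """Greedily take ranked chunks under the character budget and reassemble
    them in original document order, separated by section-title lines.

    A chunk that would overflow the budget is skipped (greedy skip, not stop),
    maximising information under the stated budget.  If even the top chunk
    exceeds the budget it is truncated with a warning.
    """
    if not ranked:
        raise ValueError("ranked list must be non-empty")
    taken: list[Chunk] = []
    used = 0
    for cid, _ in ranked:
        ch = chunks[cid]
        if used + len(ch.text) <= max_total_chars:
            taken.append(ch)
            used += len(ch.text)
    if not taken:
        top = chunks[ranked[0][0]]
        warnings.warn(
            f"top chunk ({len(top.text)} chars) exceeds budget {max_total_chars}; truncating",
            stacklevel=2,
        )
        taken = [
            Chunk(
                chunk_id=top.chunk_id,
                article_id=top.article_id,
                section_title=top.section_title,
                text=top.text[:max_total_chars],
                char_span=(top.char_span[0], top.char_span[0] + max_total_chars),
                order=top.order,
            )
        ]
    taken.sort(key=lambda c: c.order)
    parts: list[str] = []
    for ch in taken:
        parts.append(f"## {ch.section_title}" if ch.section_title else "##")
        parts.append(ch.text)
    return "\n".join(parts)
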