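"""Protein-name dictionary from PDB and UniProt records.

Articles name their targets by recommended name, alternative name, gene
symbol, or an abbreviation introduced in the structure entry title
("Maltose-binding protein (MBP)").  A per-corpus dictionary maps each alias
to the UniProt accessions it may denote; scanning an article against the
dictionary yields the candidate targets that the first LLM step then
disambiguates.  Record fixtures are exported files (tab-separated), never
live webpages, so the whole step is reproducible offline.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import ArticleDocument

__all__ = [
    "PdbRecord",
    "UniprotRecord",
    "NameDictionary",
    "build_name_dictionary",
    "candidate_names",
    "read_pdb_records",
    "write_pdb_records",
    "read_uniprot_records",
    "write_uniprot_records",
]

_PDB_ID = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
STRUCTURE_METHODS = ("xray", "nmr", "em", "other")


@dataclass(frozen=True)
class PdbRecord:
    """Metadata parsed from one PDB entry (as exported from PDBML/XML)."""

    pdb_id: str
    article_title: str = ""
    doi: str = ""
    entry_title: str = ""
    sequences: tuple[str, ...] = ()
    expression_system: str = ""
    structure_method: str = "other"
    uniprot_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _PDB_ID.match(self.pdb_id):
            raise ValueError(f"invalid PDB id {self.pdb_id!r}")
        if self.structure_method not in STRUCTURE_METHODS:
            raise ValueError(f"unknown structure method {self.structure_method!r}")


@dataclass(frozen=True)
class UniprotRecord:
    """Name and annotation fields for one UniProt protein record."""

    accession: str
    recommended_name: str
    alternative_names: tuple[str, ...] = ()
    gene_names: tuple[str, ...] = ()
    annotation_keywords: tuple[str, ...] = ()
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.recommended_name:
            raise ValueError(f"{self.accession}: recommended_name must be non-empty")


# "Long Name (ABBR)" in entry titles: a short parenthesized token containing
# at least one uppercase letter, preceded by a multi-word name.
_ABBREV = re.compile(r"[A-Za-z0-9][\w\-]*(?:\s+[\w\-]+)+\s+\(([A-Za-z][A-Za-z0-9\-]{1,9})\)")


class NameDictionary:
    """alias -> set of (accession, recommended_name); lookup case-insensitive."""

    def __init__(self) -> None:
        self._by_alias: dict[str, set[tuple[str, str]]] = {}
        self._alias_forms: dict[str, set[str]] = {}  # lower alias -> original spellings

    def add(self, alias: str, accession: str, recommended_name: str) -> None:
        alias = alias.strip()
        if not alias:
            return
        key = alias.lower()
        self._by_alias.setdefault(key, set()).add((accession, recommended_name))
        self._alias_forms.setdefault(key, set()).add(alias)

    def lookup(self, alias: str) -> set[tuple[str, str]]:
        return set(self._by_alias.get(alias.lower(), set()))

    def aliases(self) -> list[str]:
        """One representative original spelling per alias."""
        return [sorted(forms)[0] for forms in self._alias_forms.values()]

    def __len__(self) -> int:
        return len(self._by_alias)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NameDictionary) and self._by_alias == other._by_alias


def build_name_dictionary(
    pdb: list[PdbRecord], uniprot: list[UniprotRecord]
) -> NameDictionary:
    """Aliases: recommended names, alternative names, gene names, and
    parenthesized abbreviations harvested from PDB entry titles.  Ambiguous
    aliases (several accessions) are kept with all their targets."""
    d = NameDictionary()
    by_accession = {u.accession: u for u in uniprot}
    for u in uniprot:
        for alias in (u.recommended_name, *u.alternative_names, *u.gene_names):
            d.add(alias, u.accession, u.recommended_name)
    for rec in pdb:
        for m in _ABBREV.finditer(rec.entry_title):
            abbr = m.group(1)
            for acc in rec.uniprot_ids:
                rec_name = by_accession[acc].recommended_name if acc in by_accession else ""
                d.add(abbr, acc, rec_name)
    return d


def candidate_names(
    doc: ArticleDocument, dictionary: NameDictionary
) -> list[tuple[str, str, str, int]]:
    """Scan the document for alias occurrences and propose candidate targets.

    Word-boundary matching; aliases of <= 3 characters are matched
    case-sensitively (an alias like "CAT" must not fire on the word "cat").
    Returns (alias, accession, recommended_name, mention_count) sorted by
    mention count descending; LLM step 1 disambiguates this list.
    """
    text = doc.full_text()
    counts: Counter[tuple[str, str, str]] = Counter()
    for alias in dictionary.aliases():
        flags = 0 if len(alias) <= 3 else re.IGNORECASE
        pattern = re.compile(rf"(?<![\w-]){re.escape(alias)}(?![\w-])", flags)
        n = len(pattern.findall(text))
        if n == 0:
            continue
        for accession, rec_name in dictionary.lookup(alias):
            counts[(alias, accession, rec_name)] += n
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(a, acc, rn, n) for (a, acc, rn), n in ranked]


# ---------------------------------------------------------------------------
# tab-separated record fixtures (list fields joined with "|")
# ---------------------------------------------------------------------------

_PDB_FIELDS = (
    "pdb_id",
    "article_title",
    "doi",
    "entry_title",
    "sequences",
    "expression_system",
    "structure_method",
    "uniprot_ids",
)
_UP_FIELDS = (
    "accession",
    "recommended_name",
    "alternative_names",
    "gene_names",
    "annotation_keywords",
    "sequence",
)


def write_pdb_records(records: list[PdbRecord], path: str | Path) -> None:
    lines = ["\t".join(_PDB_FIELDS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.pdb_id,
                    r.article_title,
                    r.doi,
                    r.entry_title,
                    "|".join(r.sequences),
                    r.expression_system,
                    r.structure_method,
                    "|".join(r.uniprot_ids),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pdb_records(path: str | Path) -> list[PdbRecord]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != _PDB_FIELDS:
        raise ValueError(f"{path}: missing or wrong PDB record header")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(
            PdbRecord(
                pdb_id=f[0],
                article_title=f[1],
                doi=f[2],
                entry_title=f[3],
                sequences=tuple(s for s in f[4].split("|") if s),
                expression_system=f[5],
                structure_method=f[6],
                uniprot_ids=tuple(s for s in f[7].split("|") if s),
            )
        )
    return out


def write_uniprot_records(records: list[UniprotRecord], path: str | Path) -> None:
    lines = ["\t".join(_UP_FIELDS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.accession,
                    r.recommended_name,
                    "|".join(r.alternative_names),
                    "|".join(r.gene_names),
                    "|".join(r.annotation_keywords),
                    r.sequence,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_uniprot_records(path: str | Path) -> list[UniprotRecord]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != _UP_FIELDS:
        raise ValueError(f"{path}: missing or wrong UniProt record header")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(
            UniprotRecord(
                accession=f[0],
                recommended_name=f[1],
                alternative_names=tuple(s for s in f[2].split("|") if s),
                gene_names=tuple(s for s in f[3].split("|") if s),
                annotation_keywords=tuple(s for s in f[4].split("|") if s),
                sequence=f[5] if len(f) > 5 else "",
            )
        )
    return out
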