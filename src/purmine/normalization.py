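"""Chemical-name normalization by Levenshtein similarity.

Articles refer to the same chemical by abbreviation ("DTT"), synonym
("dithiothreitol"), spelling variant ("β-mercaptoethanol" vs
"beta-mercaptoethanol"), or with OCR letter-level typos ("glyerol").  A
curated dictionary maps canonical chemicals to their synonyms; a query is
matched to the alias with the highest similarity score

    score(a, b) = 1 - Lev(a, b) / max(|a|, |b|)

computed on case-folded, hyphen/whitespace-collapsed strings, and accepted
only when the best score reaches the threshold (default 0.85).  The
threshold guarantees that a single-edit typo of any alias of length >= 7 is
still recovered (1 - 1/7 ≈ 0.857).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

try:
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

import edlib

__all__ = [
    "ChemicalInfo",
    "ChemicalDictionary",
    "MatchResult",
    "levenshtein",
    "match_score",
    "normalize_chemical",
    "normalize_string",
    "default_chemical_dictionary",
    "CATEGORIES",
]

CATEGORIES = frozenset(
    {
        "buffer",
        "salt",
        "reducing_agent",
        "detergent",
        "chelator",
        "inhibitor",
        "additive",
        "crosslinker",
        "other",
    }
)

DEFAULT_THRESHOLD = 0.85

_GREEK = {"β": "beta", "α": "alpha", "γ": "gamma", "µ": "u", "μ": "u"}
_COLLAPSE = re.compile(r"[\s\-_]+")


def normalize_string(s: str) -> str:
    """Pre-matching normalization: case-fold, spell out Greek letters, and
    collapse runs of whitespace/hyphens/underscores to single spaces."""
    s = s.casefold()
    for greek, latin in _GREEK.items():
        s = s.replace(greek, latin)
    return _COLLAPSE.sub(" ", s).strip()


def levenshtein(a: str, b: str) -> int:
    """Minimal insert/delete/substitute edit count between two strings."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(edlib.align(a, b, task="distance")["editDistance"])


def match_score(a: str, b: str) -> float:
    """Similarity in [0, 1]: 1 - Lev(a', b') / max(|a'|, |b'|) on normalized
    strings; 1.0 iff the normalized strings are identical."""
    na, nb = normalize_string(a), normalize_string(b)
    if not na and not nb:
        raise ValueError("match score undefined for two empty strings")
    if na == nb:
        return 1.0
    return 1.0 - levenshtein(na, nb) / max(len(na), len(nb))


@dataclass(frozen=True)
class ChemicalInfo:
    canonical: str
    category: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.canonical!r}")


@dataclass(frozen=True)
class MatchResult:
    query: str
    canonical: str | None
    score: float
    candidate_scores: tuple[tuple[str, str, float], ...] = ()  # (alias, canonical, score)
    ambiguous: bool = False


class ChemicalDictionary:
    """Canonical chemical names with synonyms and functional categories."""

    def __init__(self, entries: list[ChemicalInfo] | None = None):
        self._entries: dict[str, ChemicalInfo] = {}
        # normalized alias -> (original alias, canonical)
        self._aliases: dict[str, tuple[str, str]] = {}
        for info in entries or []:
            self.add(info)

    def add(self, info: ChemicalInfo) -> None:
        if info.canonical in self._entries:
            raise ValueError(f"duplicate canonical name {info.canonical!r}")
        self._entries[info.canonical] = info
        for alias in (info.canonical, *info.synonyms):
            key = normalize_string(alias)
            if not key:
                raise ValueError(f"empty alias under {info.canonical!r}")
            prev = self._aliases.get(key)
            if prev is not None and prev[1] != info.canonical:
                raise ValueError(
                    f"alias {alias!r} listed under both {prev[1]!r} and {info.canonical!r}"
                )
            self._aliases.setdefault(key, (alias, info.canonical))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, canonical: str) -> bool:
        return canonical in self._entries

    def canonicals(self) -> list[str]:
        return list(self._entries)

    def category(self, canonical: str) -> str:
        return self._entries[canonical].category

    def aliases(self) -> list[tuple[str, str]]:
        """All (alias, canonical) pairs, canonical names included."""
        return [(alias, canon) for alias, canon in self._aliases.values()]

    # -- file form: one record per canonical, human editable -----------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChemicalDictionary":
        d = cls()
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            canonical, category = parts[0].strip(), parts[1].strip()
            synonyms = tuple(
                s.strip() for s in (parts[2].split("|") if len(parts) > 2 else []) if s.strip()
            )
            d.add(ChemicalInfo(canonical, category, synonyms))
        return d

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# canonical\tcategory\tsynonyms (| separated; may be empty)"]
        for info in self._entries.values():
            lines.append("\t".join([info.canonical, info.category, "|".join(info.synonyms)]))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_chemical_dictionary() -> ChemicalDictionary:
    """The shipped dictionary of common purification-buffer chemicals."""
    data = _pkg_files("purmine").joinpath("data/chemicals.tsv")
    return ChemicalDictionary.from_tsv(str(data))


def normalize_chemical(
    query: str,
    dictionary: ChemicalDictionary,
    threshold: float = DEFAULT_THRESHOLD,
    top_k: int = 5,
) -> MatchResult:
    """Match ``query`` against every dictionary alias and return the best hit.

    The canonical name is returned only when the best score reaches
    ``threshold``; ties across different canonical names are broken by longer
    alias, then lexicographically, and flagged ambiguous.
    """
    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    scored: list[tuple[str, str, float]] = []
    for alias, canonical in dictionary.aliases():
        scored.append((alias, canonical, match_score(query, alias)))
    # best first; ties by longer alias then lexicographic alias
    scored.sort(key=lambda t: (-t[2], -len(t[0]), t[0]))
    best_alias, best_canonical, best_score = scored[0]
    ambiguous = any(
        abs(s - best_score) < 1e-12 and c != best_canonical for _, c, s in scored[1:]
    )
    accepted = best_score >= threshold
    return MatchResult(
        query=query,
        canonical=best_canonical if accepted else None,
        score=best_score,
        candidate_scores=tuple(scored[:top_k]),
        ambiguous=ambiguous and accepted,
    )
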