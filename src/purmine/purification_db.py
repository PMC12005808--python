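"""The purification-strategy database.

One entry per (UniProt accession, article DOI): fusion tags, expression
system, culture/induction conditions, purification buffers, and the UniProt
annotation keywords of the protein.  Incomplete articles leave fields
unknown — only an accession (or at least one PDB id) is mandatory.

Counting conventions follow the frequency summaries: a buffer type used for
a protein with a unique UniProt accession counts as one case regardless of
how many articles or purification stages repeat it; a protein carrying both
a large and a small fusion tag is classified under the large tag only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .extraction import RawExtraction
from .name_resolution import UniprotRecord
from .normalization import ChemicalDictionary

__all__ = [
    "BufferComponent",
    "BufferRecord",
    "CultureConditions",
    "PurificationEntry",
    "PurificationDatabase",
    "TagClassificationError",
    "LARGE_TAGS",
    "SMALL_TAGS",
    "TAG_ALIASES",
    "classify_tags",
    "count_buffer_cases",
    "bin_conditions",
    "ingest_extraction",
    "DEFAULT_PH_BINS",
    "DEFAULT_TEMPERATURE_BINS",
    "DEFAULT_TIME_BINS",
]

SCHEMA_VERSION = 1

LARGE_TAGS = frozenset({"GST", "MBP", "SUMO", "Trx", "CBD", "GB1", "TAP"})
SMALL_TAGS = frozenset({"His", "FLAG", "Strep", "HA", "Myc", "AviTag", "Fc"})
CANONICAL_TAGS = LARGE_TAGS | SMALL_TAGS

# common surface variants -> canonical tag name
TAG_ALIASES = {
    "polyhistidine": "His",
    "poly-histidine": "His",
    "his6": "His",
    "6xhis": "His",
    "hexahistidine": "His",
    "avi-tag": "AviTag",
    "avi": "AviTag",
    "avitag": "AviTag",
    "strep-tag": "Strep",
    "strepii": "Strep",
    "thioredoxin": "Trx",
    "trx-1": "Trx",
    "hemagglutinin": "HA",
    "c-myc": "Myc",
}

# closed [lo, hi] bins; values in no bin are reported as "unbinned"
DEFAULT_PH_BINS = ((0.0, 3.5), (3.6, 6.5), (6.6, 7.5), (7.6, 9.5), (9.6, 14.0))
DEFAULT_TEMPERATURE_BINS = ((4, 12), (13, 15), (16, 20), (21, 27), (28, 30), (31, 37))
DEFAULT_TIME_BINS = ((0, 2), (3, 6), (7, 11), (12, 16), (17, 24), (25, 72))


class TagClassificationError(ValueError):
    pass


def canonical_tag(name: str) -> str:
    """Map a tag surface form to its canonical name; unknown names raise."""
    stripped = name.strip().removesuffix(" tag").removesuffix("-tag").strip()
    if stripped in CANONICAL_TAGS:
        return stripped
    mapped = TAG_ALIASES.get(stripped.lower())
    if mapped is None:
        raise TagClassificationError(f"unknown fusion tag {name!r}")
    return mapped


@dataclass(frozen=True)
class BufferComponent:
    canonical_name: str
    concentration: tuple[float, str] | None = None  # (value, unit) or unknown
    role: str = "other"


@dataclass(frozen=True)
class BufferRecord:
    buffer_type: str | None  # canonical buffering-agent name
    pH: float | None
    components: tuple[BufferComponent, ...] = ()
    stage: str = "unknown"  # lysis / wash / elution / ... / unknown

    def __post_init__(self) -> None:
        if self.pH is not None and not (0.0 <= self.pH <= 14.0):
            raise ValueError(f"pH {self.pH} out of [0, 14]")


@dataclass(frozen=True)
class CultureConditions:
    induction_temperature_C: float | None = None
    induction_time_h: float | None = None
    inducer: str | None = None
    inducer_concentration_mM: float | None = None


@dataclass
class PurificationEntry:
    uniprot_id: str
    doi: str
    recommended_name: str = ""
    pdb_ids: list[str] = field(default_factory=list)
    sequence: str = ""
    fusion_tags: list[str] = field(default_factory=list)
    expression_system: str = ""
    culture: CultureConditions = field(default_factory=CultureConditions)
    buffers: list[BufferRecord] = field(default_factory=list)
    structure_method: str = "other"
    annotations: list[str] = field(default_factory=list)
    detergents: list[str] = field(default_factory=list)
    crosslinkers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.uniprot_id and not self.pdb_ids:
            raise ValueError("entry needs a UniProt accession or at least one PDB id")

    @property
    def chemicals(self) -> set[str]:
        """All canonical chemicals this entry touches (components, buffer
        agents, detergents, crosslinkers)."""
        out: set[str] = set()
        for buf in self.buffers:
            if buf.buffer_type:
                out.add(buf.buffer_type)
            out.update(c.canonical_name for c in buf.components)
        out.update(self.detergents)
        out.update(self.crosslinkers)
        return out


def classify_tags(entry: PurificationEntry) -> tuple[str, list[str], list[str]]:
    """Classify an entry as using a large tag, only small tags, or none.

    An entry with at least one large tag is "large" even when small tags are
    also present.  Returns (class, large_tags, small_tags).
    """
    large, small = [], []
    for tag in entry.fusion_tags:
        canon = canonical_tag(tag)
        (large if canon in LARGE_TAGS else small).append(canon)
    if large:
        return "large", large, small
    if small:
        return "small", large, small
    return "none", large, small


class PurificationDatabase:
    """Entries keyed by (uniprot_id, doi), with skip and conflict logs."""

    def __init__(self) -> None:
        self.entries: dict[tuple[str, str], PurificationEntry] = {}
        self.skip_log: list[str] = []
        self.conflict_log: list[str] = []

    def __len__(self) -> int:
        return len(self.entries)

    def add_or_merge(self, entry: PurificationEntry) -> None:
        key = (entry.uniprot_id, entry.doi)
        if key not in self.entries:
            self.entries[key] = entry
            return
        self._merge(self.entries[key], entry)

    def _merge(self, base: PurificationEntry, new: PurificationEntry) -> None:
        for attr in ("recommended_name", "sequence", "expression_system"):
            old, val = getattr(base, attr), getattr(new, attr)
            if val and not old:
                setattr(base, attr, val)
            elif val and old and val != old:
                self.conflict_log.append(
                    f"{base.uniprot_id}/{base.doi}: {attr} conflict {old!r} vs {val!r}; kept first"
                )
        if new.structure_method != "other":
            if base.structure_method == "other":
                base.structure_method = new.structure_method
            elif base.structure_method != new.structure_method:
                self.conflict_log.append(
                    f"{base.uniprot_id}/{base.doi}: structure_method conflict; kept first"
                )
        for attr in ("pdb_ids", "fusion_tags", "annotations", "detergents", "crosslinkers"):
            seen = list(getattr(base, attr))
            for v in getattr(new, attr):
                if v not in seen:
                    seen.append(v)
            setattr(base, attr, seen)
        for buf in new.buffers:
            if buf not in base.buffers:
                base.buffers.append(buf)
        merged = {}
        for cond_attr in (
            "induction_temperature_C",
            "induction_time_h",
            "inducer",
            "inducer_concentration_mM",
        ):
            old = getattr(base.culture, cond_attr)
            val = getattr(new.culture, cond_attr)
            if old is None:
                merged[cond_attr] = val
            else:
                merged[cond_attr] = old
                if val is not None and val != old:
                    self.conflict_log.append(
                        f"{base.uniprot_id}/{base.doi}: culture {cond_attr} conflict; kept first"
                    )
        base.culture = CultureConditions(**merged)

    # -- unique-protein views ------------------------------------------------

    def protein_usage(self) -> dict[str, dict[str, set]]:
        """uniprot_id -> annotations / chemicals / tags, unioned over entries."""
        out: dict[str, dict[str, set]] = {}
        for (uid, _), entry in self.entries.items():
            if not uid:
                continue
            rec = out.setdefault(
                uid, {"annotations": set(), "chemicals": set(), "tags": set()}
            )
            rec["annotations"].update(entry.annotations)
            rec["chemicals"].update(entry.chemicals)
            for tag in entry.fusion_tags:
                rec["tags"].add(canonical_tag(tag))
        return out

    def article_category_usage(
        self, category: str, scope: str | None = None
    ) -> dict[str, set[str]]:
        """article DOI -> chemicals of one category used anywhere in it.

        ``category`` "detergent"/"crosslinker" uses the dedicated fields the
        grid-preparation question fills; anything else filters buffer
        components by their role.
        """
        out: dict[str, set[str]] = {}
        for (_, doi), entry in self.entries.items():
            chems = out.setdefault(doi, set())
            if category == "detergent":
                chems.update(entry.detergents)
            elif category == "crosslinker":
                chems.update(entry.crosslinkers)
            if category not in ("detergent", "crosslinker"):
                for buf in entry.buffers:
                    chems.update(
                        c.canonical_name for c in buf.components if c.role == category
                    )
        return {doi: chems for doi, chems in out.items() if chems}

    # -- persistence: line-delimited records, exact round-trip ---------------

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"schema_version": SCHEMA_VERSION}) + "\n")
            for key in sorted(self.entries):
                fh.write(json.dumps(_entry_to_json(self.entries[key]), sort_keys=True) + "\n")

    def dumps(self) -> str:
        """Canonical serialized form (used for determinism checks)."""
        lines = [json.dumps({"schema_version": SCHEMA_VERSION})]
        for key in sorted(self.entries):
            lines.append(json.dumps(_entry_to_json(self.entries[key]), sort_keys=True))
        return "\n".join(lines) + "\n"

    @classmethod
    def load(cls, path: str | Path) -> "PurificationDatabase":
        db = cls()
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            if header.get("schema_version") != SCHEMA_VERSION:
                raise ValueError(f"unsupported schema version {header.get('schema_version')}")
            for line in fh:
                if line.strip():
                    entry = _entry_from_json(json.loads(line))
                    db.entries[(entry.uniprot_id, entry.doi)] = entry
        return db


def _entry_to_json(e: PurificationEntry) -> dict:
    d = asdict(e)
    d["culture"] = asdict(e.culture)
    d["buffers"] = [
        {
            "buffer_type": b.buffer_type,
            "pH": b.pH,
            "stage": b.stage,
            "components": [
                {
                    "canonical_name": c.canonical_name,
                    "concentration": list(c.concentration) if c.concentration else None,
                    "role": c.role,
                }
                for c in b.components
            ],
        }
        for b in e.buffers
    ]
    return d


def _entry_from_json(d: dict) -> PurificationEntry:
    buffers = [
        BufferRecord(
            buffer_type=b["buffer_type"],
            pH=b["pH"],
            stage=b["stage"],
            components=tuple(
                BufferComponent(
                    canonical_name=c["canonical_name"],
                    concentration=tuple(c["concentration"]) if c["concentration"] else None,
                    role=c["role"],
                )
                for c in b["components"]
            ),
        )
        for b in d["buffers"]
    ]
    return PurificationEntry(
        uniprot_id=d["uniprot_id"],
        doi=d["doi"],
        recommended_name=d["recommended_name"],
        pdb_ids=list(d["pdb_ids"]),
        sequence=d["sequence"],
        fusion_tags=list(d["fusion_tags"]),
        expression_system=d["expression_system"],
        culture=CultureConditions(**d["culture"]),
        buffers=buffers,
        structure_method=d["structure_method"],
        annotations=list(d["annotations"]),
        detergents=list(d["detergents"]),
        crosslinkers=list(d["crosslinkers"]),
    )


# ---------------------------------------------------------------------------
# counting and binning rules
# ---------------------------------------------------------------------------


def count_buffer_cases(db: PurificationDatabase) -> dict[str, int]:
    """Buffer-type case counts: one case per distinct (protein, buffer type).

    Repeats of the same buffer type for the same accession — across articles
    or purification stages — count once.
    """
    cases: set[tuple[str, str]] = set()
    for (uid, _), entry in db.entries.items():
        if not uid:
            continue
        for buf in entry.buffers:
            if buf.buffer_type:
                cases.add((uid, buf.buffer_type))
    counts: dict[str, int] = {}
    for _, btype in cases:
        counts[btype] = counts.get(btype, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def _validate_bins(bins: Sequence[tuple[float, float]]) -> None:
    prev_hi = None
    for lo, hi in bins:
        if lo > hi:
            raise ValueError(f"bin ({lo}, {hi}) has lo > hi")
        if prev_hi is not None and lo <= prev_hi:
            raise ValueError("bins must be disjoint and ordered")
        prev_hi = hi


def _bin_values(
    values: list[float], bins: Sequence[tuple[float, float]]
) -> pd.DataFrame:
    counts = [0] * len(bins)
    unbinned = 0
    for v in values:
        for i, (lo, hi) in enumerate(bins):
            if lo <= v <= hi:
                counts[i] += 1
                break
        else:
            unbinned += 1
    known = sum(counts)
    rows = [
        {
            "bin": f"[{lo}, {hi}]",
            "count": c,
            "percent": (100.0 * c / known) if known else 0.0,
        }
        for (lo, hi), c in zip(bins, counts)
    ]
    frame = pd.DataFrame(rows)
    frame.attrs["unbinned"] = unbinned
    return frame


def bin_conditions(
    db: PurificationDatabase,
    temperature_bins: Sequence[tuple[float, float]] = DEFAULT_TEMPERATURE_BINS,
    time_bins: Sequence[tuple[float, float]] = DEFAULT_TIME_BINS,
    ph_bins: Sequence[tuple[float, float]] = DEFAULT_PH_BINS,
) -> dict[str, pd.DataFrame]:
    """Histogram induction temperature, induction time, and buffer pH.

    Percentages are over entries with known values; unknowns are reported
    separately (``attrs["unknown"]``) and excluded from percentages.
    """
    for bins in (temperature_bins, time_bins, ph_bins):
        _validate_bins(bins)
    temps, times, phs = [], [], []
    unknown = {"temperature": 0, "time": 0, "pH": 0}
    for entry in db.entries.values():
        t = entry.culture.induction_temperature_C
        if t is not None:
            temps.append(t)
        else:
            unknown["temperature"] += 1
        h = entry.culture.induction_time_h
        if h is not None:
            times.append(h)
        else:
            unknown["time"] += 1
        ph_values = [b.pH for b in entry.buffers if b.pH is not None]
        if ph_values:
            phs.extend(ph_values)
        else:
            unknown["pH"] += 1
    out = {
        "temperature": _bin_values(temps, temperature_bins),
        "time": _bin_values(times, time_bins),
        "pH": _bin_values(phs, ph_bins),
    }
    for name, frame in out.items():
        frame.attrs["unknown"] = unknown[name]
    return out


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------


def ingest_extraction(
    raw: RawExtraction,
    uniprot: Sequence[UniprotRecord],
    db: PurificationDatabase,
    dictionary: ChemicalDictionary | None = None,
    pdb_ids_by_doi: Mapping[str, Sequence[str]] | None = None,
) -> PurificationDatabase:
    """Merge one quality-checked extraction into the database.

    Records resolve to accessions through the recommended name; a record
    with no resolvable accession and no PDB id is skipped with a logged
    reason.  Re-ingesting the same extraction is a no-op (dedup idempotence).
    """
    if raw.status not in ("accepted", "repaired", "accepted-empty"):
        raise ValueError(f"cannot ingest extraction with status {raw.status!r}")
    by_name = {u.recommended_name: u for u in uniprot}
    for record in raw.records:
        up = by_name.get(record.protein_name)
        pdbs = list((pdb_ids_by_doi or {}).get(raw.article_id, ()))
        if up is None and not pdbs:
            db.skip_log.append(
                f"{raw.article_id}: record {record.protein_name!r} has no accession or PDB id"
            )
            continue
        entry = _record_to_entry(raw, record, up, pdbs, dictionary)
        db.add_or_merge(entry)
    return db


def _record_to_entry(
    raw: RawExtraction,
    record,
    up: UniprotRecord | None,
    pdb_ids: list[str],
    dictionary: ChemicalDictionary | None,
) -> PurificationEntry:
    f = record.fields

    def role_of(name: str) -> str:
        if dictionary is not None and name in dictionary:
            return dictionary.category(name)
        return "other"

    buffers = []
    for b in f.get("buffers", []):
        comps = []
        for comp in b.get("components", []):
            conc = comp.get("concentration")
            comps.append(
                BufferComponent(
                    canonical_name=comp["name"],
                    concentration=tuple(conc) if conc else None,
                    role=role_of(comp["name"]),
                )
            )
        btype = b.get("buffer_type")
        if btype is None:
            agents = [c.canonical_name for c in comps if c.role == "buffer"]
            btype = agents[0] if agents else None
        buffers.append(
            BufferRecord(
                buffer_type=btype,
                pH=b.get("pH"),
                components=tuple(comps),
                stage=b.get("stage", "unknown"),
            )
        )
    culture = CultureConditions(
        induction_temperature_C=f.get("induction_temperature_C"),
        induction_time_h=f.get("induction_time_h"),
        inducer=f.get("inducer"),
        inducer_concentration_mM=f.get("inducer_concentration_mM"),
    )
    return PurificationEntry(
        uniprot_id=up.accession if up else "",
        doi=raw.article_id,
        recommended_name=up.recommended_name if up else record.protein_name,
        pdb_ids=pdb_ids,
        sequence=up.sequence if up else "",
        fusion_tags=[canonical_tag(t) for t in f.get("fusion_tags", [])],
        expression_system=f.get("expression_system", "") or "",
        culture=culture,
        buffers=buffers,
        annotations=list(up.annotation_keywords) if up else [],
        detergents=list(f.get("detergents", [])),
        crosslinkers=list(f.get("crosslinkers", [])),
    )
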