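"""Ground-truthed synthetic corpus, database generator, and mock backends.

Every other module is testable offline against this one.  The article
generator emits documents with the layout of a structural-biology article —
title, abstract, introduction, results, and a methods section whose
"Protein expression and purification" subsection encodes planted facts
(buffer recipes, fusion tags, induction conditions, grid-preparation
detergents) in deliberately varied sentence templates (active/passive
voice, "mM" vs "millimolar").  Distractor sections contain chemical-free
prose sharing no content vocabulary with the question templates.

The mock LLM parses prompt contexts with the same sentence grammar the
generator uses and answers in the three-step response format, so planted
facts round-trip exactly; the mock embedding is the hashed term-frequency
backend.  Both are pure functions of their input: the whole pipeline is
deterministic under a fixed seed.

OCR-style typos can be injected into chemical tokens at a per-character
rate.  Typos are restricted to names whose normalized form has >= 7
characters, where the 0.85 match threshold analytically guarantees
recovery (1 - 1/7 ≈ 0.857); shorter tokens are left intact and serve as
negative-test material elsewhere.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus_io import ArticleDocument, DocumentElement
from .name_resolution import PdbRecord, UniprotRecord
from .normalization import (
    ChemicalDictionary,
    default_chemical_dictionary,
    normalize_string,
)
from .retrieval import HashedBagEmbedding
from .purification_db import (
    BufferComponent,
    BufferRecord,
    PurificationDatabase,
    PurificationEntry,
)

__all__ = [
    "PlantedComponent",
    "PlantedBuffer",
    "PlantedCulture",
    "PlantedProtein",
    "ArticleGroundTruth",
    "CorpusGroundTruth",
    "DatabaseGroundTruth",
    "generate_article",
    "generate_corpus",
    "generate_database",
    "sample_article_spec",
    "MockLlm",
    "mock_llm",
    "MockEmbedding",
    "mock_embedding",
    "write_corpus",
]


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedComponent:
    name: str  # canonical chemical name (always, even when a typo is rendered)
    value: float
    unit: str


@dataclass(frozen=True)
class PlantedBuffer:
    buffer_type: str
    pH: float
    stage: str  # lysis / wash / elution / storage / unknown
    components: tuple[PlantedComponent, ...]


@dataclass(frozen=True)
class PlantedCulture:
    induction_temperature_C: float
    induction_time_h: float
    inducer: str
    inducer_concentration_mM: float


@dataclass(frozen=True)
class PlantedProtein:
    accession: str
    recommended_name: str
    alias: str
    expression_system: str
    tags: tuple[str, ...]
    culture: PlantedCulture | None
    buffers: tuple[PlantedBuffer, ...]
    detergents: tuple[str, ...] = ()
    crosslinkers: tuple[str, ...] = ()

    @property
    def chemicals(self) -> set[str]:
        out: set[str] = set()
        for buf in self.buffers:
            out.update(c.name for c in buf.components)
        out.update(self.detergents)
        out.update(self.crosslinkers)
        return out


@dataclass(frozen=True)
class ArticleGroundTruth:
    doi: str
    pdb_id: str
    proteins: tuple[PlantedProtein, ...]


@dataclass(frozen=True)
class CorpusGroundTruth:
    articles: tuple[ArticleGroundTruth, ...]
    seed: int
    params: dict


@dataclass(frozen=True)
class DatabaseGroundTruth:
    seed: int
    group_members: dict  # group name -> tuple of uniprot ids
    usage_probabilities: dict  # group name -> {chemical: p}
    baseline_usage: dict  # {chemical: p}
    true_log_folds: dict  # (group, chemical) -> ln(p_group / p_baseline)


# ---------------------------------------------------------------------------
# sentence grammar (shared by the generator and the mock LLM)
# ---------------------------------------------------------------------------

_EXPR_TEMPLATES = (
    "{name} was expressed in {system}.",
    "We expressed {name} in {system}.",
)
_INDUCTION_TEMPLATES = (
    "Expression was induced with {conc} {unit} {inducer} at {temp} °C for {time} h.",
    "Protein expression was induced by adding {conc} {unit} {inducer} at {temp} °C for {time} h.",
)
_TAG_TEMPLATES = (
    "{name} was fused to an N-terminal {tag} tag.",
    "A {tag} tag was fused to {name} to aid purification.",
    "{name} carried a C-terminal {tag} tag.",
)
_BUFFER_TEMPLATES = (
    "The {stage} buffer contained {components}.",
    "{name} was purified in {components}.",
)
_DETERGENT_TEMPLATE = "Before grid preparation, the sample was supplemented with {components}."
_CROSSLINK_TEMPLATE = "Prior to grid preparation, the complex was crosslinked with {conc} % {name}."

RE_EXPR_PASSIVE = re.compile(r"was expressed in ([^.]+)\.")
RE_EXPR_ACTIVE = re.compile(r"We expressed .+? in ([^.]+)\.")
RE_INDUCTION = re.compile(
    r"induced (?:with|by adding) (\d+(?:\.\d+)?) (mM|millimolar) (\S+) "
    r"at (\d+(?:\.\d+)?) °C for (\d+(?:\.\d+)?) h\."
)
RE_TAG = re.compile(
    r"(?:fused to an? [NC]-terminal (\w+) tag|An? (\w+) tag was fused|carried an? [NC]-terminal (\w+) tag)"
)
RE_BUFFER_STAGE = re.compile(r"The (\w+) buffer contained (.+)\.$")
RE_BUFFER_PURIFIED = re.compile(r"was purified in (.+)\.$")
RE_COMPONENT = re.compile(
    r"(\d+(?:\.\d+)?) (mM|millimolar|µM|uM|M|%|mg/mL) ([A-Za-z(][\w()\- ]*?)(?=,| and | pH |\.|$)"
)
RE_PH = re.compile(r" pH (\d+(?:\.\d+)?)")
# sentence boundary: period, whitespace, then an uppercase start (keeps
# abbreviations like "N." intact and never splits inside "pH 8.0")
SENTENCE_SPLIT = re.compile(r"(?<=\.)\s+(?=[A-Z0-9])")

_DISTRACTOR_POOL = (
    "Crystals diffracted beyond two angstrom resolution on beamline thirteen.",
    "Diffraction images were processed using automated software pipelines.",
    "Phases came from molecular replacement against homologous search models.",
    "Model rebuilding employed interactive graphics, then iterative refinement cycles.",
    "Native gels showed monodisperse particles across several freezing conditions.",
    "Negative stain micrographs revealed homogeneous particle distributions.",
    "Electron micrograph movies underwent motion correction, then contrast transfer estimation.",
    "Particle classes converged after repeated rounds of heterogeneous refinement.",
    "Thermal stability assays employed differential scanning fluorimetry readouts.",
    "Sequence alignments highlighted conserved residues among distant orthologs.",
    "Phylogenetic trees grouped vertebrate homologs into three separate clades.",
    "Final figures were drawn using vector graphics software packages.",
)

_FAMILIES = (
    "kinase",
    "transferase",
    "hydrolase",
    "isomerase",
    "ligase",
    "synthase",
    "reductase",
    "oxidase",
    "phosphatase",
    "helicase",
)
_ADJECTIVES = ("Putative", "Probable", "Mitochondrial", "Cytosolic", "Nuclear")
_SYSTEMS = (
    "Escherichia coli BL21(DE3)",
    "Escherichia coli Rosetta(DE3)",
    "Sf9 insect cells",
    "HEK293F cells",
)
_ANNOTATION_POOL = (
    "Membrane",
    "Kinase",
    "Cytoplasm",
    "Nucleus",
    "Metal-binding",
    "ATP-binding",
    "Transport",
    "Disulfide bond",
    "Acetylation",
    "Isopeptide bond",
)

# buffer-agent frequencies mirroring the reported corpus-level shares
# (Tris 49.2 %, HEPES and phosphate next, a long tail of minor agents)
_BUFFER_AGENTS = ("Tris", "HEPES", "phosphate", "MOPS", "acetate", "citrate", "CAPS")
_BUFFER_WEIGHTS = (0.492, 0.189, 0.152, 0.05, 0.05, 0.034, 0.033)
_AGENT_PH = {
    "Tris": (7.5, 8.0, 8.5),
    "HEPES": (7.0, 7.4, 7.5),
    "phosphate": (6.5, 7.0, 7.4),
    "MOPS": (6.5, 7.0, 7.2),
    "acetate": (4.5, 5.0, 5.5),
    "citrate": (5.5, 6.0, 6.5),
    "CAPS": (10.0, 10.5, 11.0),
}
_EXTRA_COMPONENTS = (
    ("DTT", (1.0, 2.0, 5.0), "mM"),
    ("glycerol", (5.0, 10.0), "%"),
    ("EDTA", (1.0, 2.0), "mM"),
    ("imidazole", (20.0, 250.0, 300.0), "mM"),
    ("KCl", (50.0, 100.0), "mM"),
    ("MgCl2", (1.0, 5.0), "mM"),
    ("TCEP", (0.5, 1.0), "mM"),
    ("beta-mercaptoethanol", (2.0, 5.0), "mM"),
)
_STAGES = ("lysis", "wash", "elution", "storage")
_DETERGENT_POOL = ("DDM", "LMNG", "GDN", "CHS", "digitonin")
_CROSSLINKER_POOL = ("glutaraldehyde", "BS3", "DSS", "formaldehyde")
_TAG_POOL = ("GST", "MBP", "SUMO", "Strep", "FLAG", "Trx", "HA", "Myc")

# induction-condition mixtures matching the reported corpus shares:
# temperatures 18/20/16 °C most common; times clustered at 12-16 h (69 %)
# then 3-6 h (14.3 %); inducer concentration mostly 1 or 0.5 mM.
_TEMP_CHOICES = (18, 20, 16, 25, 30, 37)
_TEMP_WEIGHTS = (0.191, 0.156, 0.136, 0.217, 0.15, 0.15)
_TIME_RANGES = (((12, 13, 14, 15, 16), 0.69), ((3, 4, 5, 6), 0.143), ((2, 8, 20, 24), 0.167))
_IPTG_CONC = ((1.0, 0.5), (0.5, 0.35), (0.1, 0.15))


def _fmt(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# article specs and generation
# ---------------------------------------------------------------------------


def sample_article_spec(
    index: int,
    rng: np.random.Generator,
    n_proteins: int | None = None,
    with_grid_prep_probability: float = 0.25,
) -> ArticleGroundTruth:
    """Draw one article's planted facts from the study-condition mixtures."""
    if n_proteins is None:
        n_proteins = int(rng.integers(1, 3))
    doi = f"10.5555/synthetic.{index:04d}"
    pdb_id = _pdb_id(index)
    proteins = []
    for j in range(n_proteins):
        pid = index * 4 + j
        family = _FAMILIES[pid % len(_FAMILIES)]
        name = f"{_ADJECTIVES[pid % len(_ADJECTIVES)]} {family} {pid}"
        alias = f"{family[:3].upper()}{pid}"
        system = _SYSTEMS[int(rng.choice(len(_SYSTEMS), p=(0.55, 0.15, 0.15, 0.15)))]
        culture = None
        if system.startswith("Escherichia"):
            times, _ = _TIME_RANGES[
                int(rng.choice(3, p=[w for _, w in _TIME_RANGES]))
            ]
            culture = PlantedCulture(
                induction_temperature_C=float(rng.choice(_TEMP_CHOICES, p=_TEMP_WEIGHTS)),
                induction_time_h=float(rng.choice(times)),
                inducer="IPTG",
                inducer_concentration_mM=float(
                    rng.choice([c for c, _ in _IPTG_CONC], p=[w for _, w in _IPTG_CONC])
                ),
            )
        tags: list[str] = []
        if rng.random() < 0.825:
            tags.append("His")
        if rng.random() < 0.3 or not tags:
            tags.append(str(rng.choice(_TAG_POOL)))
        buffers = []
        for stage in rng.choice(_STAGES, size=int(rng.integers(1, 3)), replace=False):
            if rng.random() < 0.4:
                stage = "unknown"  # article will not state the stage
            agent = str(rng.choice(_BUFFER_AGENTS, p=_BUFFER_WEIGHTS))
            ph = float(rng.choice(_AGENT_PH[agent]))
            comps = [PlantedComponent(agent, float(rng.choice([20.0, 25.0, 50.0, 100.0])), "mM")]
            comps.append(
                PlantedComponent("NaCl", float(rng.choice([100.0, 150.0, 200.0, 300.0])), "mM")
            )
            n_extra = int(rng.integers(0, 4))
            for k in rng.choice(len(_EXTRA_COMPONENTS), size=n_extra, replace=False):
                chem, values, unit = _EXTRA_COMPONENTS[k]
                comps.append(PlantedComponent(chem, float(rng.choice(values)), unit))
            buffers.append(PlantedBuffer(agent, ph, str(stage), tuple(comps)))
        detergents: tuple[str, ...] = ()
        crosslinkers: tuple[str, ...] = ()
        if rng.random() < with_grid_prep_probability:
            n_det = int(rng.integers(1, 3))
            detergents = tuple(
                str(d) for d in rng.choice(_DETERGENT_POOL, size=n_det, replace=False)
            )
            if rng.random() < 0.4:
                crosslinkers = (str(rng.choice(_CROSSLINKER_POOL)),)
        proteins.append(
            PlantedProtein(
                accession=f"P{10000 + pid}",
                recommended_name=name,
                alias=alias,
                expression_system=system,
                tags=tuple(tags),
                culture=culture,
                buffers=tuple(buffers),
                detergents=detergents,
                crosslinkers=crosslinkers,
            )
        )
    return ArticleGroundTruth(doi=doi, pdb_id=pdb_id, proteins=tuple(proteins))


def _pdb_id(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return (
        f"{(i % 9) + 1}"
        f"{letters[(i // 676) % 26]}{letters[(i // 26) % 26]}{letters[i % 26]}"
    )


def _maybe_typo(name: str, rng: np.random.Generator, typo_rate: float) -> str:
    """One random letter-level edit, applied with per-character probability,
    only to names long enough for the match threshold to recover them."""
    if typo_rate <= 0 or len(normalize_string(name)) < 7:
        return name
    if rng.random() >= typo_rate * len(name):
        return name
    letter_positions = [i for i, ch in enumerate(name) if ch.isalpha()]
    pos = int(rng.choice(letter_positions))
    kind = int(rng.integers(0, 3))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if kind == 0:  # substitute
        repl = alphabet[int(rng.integers(0, 26))]
        while repl == name[pos].lower():
            repl = alphabet[int(rng.integers(0, 26))]
        return name[:pos] + repl + name[pos + 1 :]
    if kind == 1:  # delete
        return name[:pos] + name[pos + 1 :]
    return name[: pos + 1] + alphabet[int(rng.integers(0, 26))] + name[pos + 1 :]


def _render_components(
    comps: tuple[PlantedComponent, ...],
    ph: float | None,
    rng: np.random.Generator,
    typo_rate: float,
) -> str:
    parts = []
    for i, comp in enumerate(comps):
        unit = comp.unit
        if unit == "mM" and rng.random() < 0.15:
            unit = "millimolar"
        surface = _maybe_typo(comp.name, rng, typo_rate)
        text = f"{_fmt(comp.value)} {unit} {surface}"
        if i == 0 and ph is not None:
            text += f" pH {ph:.1f}"
        parts.append(text)
    if len(parts) == 1:
        return parts[0]
    return ", ".join(parts[:-1]) + " and " + parts[-1]


def generate_article(
    spec: ArticleGroundTruth,
    seed: int,
    typo_rate: float = 0.0,
    distractor_chars: int = 3000,
) -> tuple[ArticleDocument, ArticleGroundTruth]:
    """Emit a synthetic article encoding ``spec``; ground truth is ``spec``."""
    rng = np.random.default_rng(seed)
    elements: list[DocumentElement] = []
    order = 0

    def add(kind: str, text: str) -> None:
        nonlocal order
        elements.append(DocumentElement(kind, text, order))
        order += 1

    names = ", ".join(f"{p.recommended_name} ({p.alias})" for p in spec.proteins)
    add("heading", f"Structural characterization of {names}" if names else "A structural study")
    add("heading", "Abstract")
    aliases = ", ".join(p.alias for p in spec.proteins)
    abstract = [
        f"Here we describe crystallographic analysis of {aliases}."
        if aliases
        else "Here we describe crystallographic analysis of a macromolecular assembly."
    ]
    abstract += _filler(rng, 2)
    add("paragraph", " ".join(abstract))
    add("heading", "Introduction")
    intro = [
        f"{p.recommended_name} ({p.alias}) regulates essential cellular signalling events."
        for p in spec.proteins
    ] or ["Macromolecular assemblies regulate essential cellular signalling events."]
    intro += _filler(rng, 2)
    add("paragraph", " ".join(intro))

    add("heading", "Results")
    used = 0
    while used < distractor_chars:
        sentences = _filler(rng, 5)
        para = " ".join(sentences)
        add("paragraph", para)
        used += len(para)

    add("heading", "Materials and methods")
    add("paragraph", "Standard cloning procedures followed published protocols.")
    add("heading", "Protein expression and purification")
    for protein in spec.proteins:
        add("paragraph", _methods_paragraph(protein, rng, typo_rate))
    if not spec.proteins:
        add("paragraph", "No recombinant production steps were required.")
    add("heading", "Data availability")
    add("paragraph", " ".join(_filler(rng, 2)))

    return ArticleDocument(article_id=spec.doi, elements=elements), spec


def _filler(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.choice(len(_DISTRACTOR_POOL), size=n, replace=n > len(_DISTRACTOR_POOL))
    return [_DISTRACTOR_POOL[int(i)] for i in idx]


def _methods_paragraph(
    p: PlantedProtein, rng: np.random.Generator, typo_rate: float
) -> str:
    sentences = [
        _EXPR_TEMPLATES[int(rng.integers(0, 2))].format(
            name=p.recommended_name, system=p.expression_system
        )
    ]
    if p.culture is not None:
        unit = "millimolar" if rng.random() < 0.3 else "mM"
        sentences.append(
            _INDUCTION_TEMPLATES[int(rng.integers(0, 2))].format(
                conc=_fmt(p.culture.inducer_concentration_mM),
                unit=unit,
                inducer=p.culture.inducer,
                temp=_fmt(p.culture.induction_temperature_C),
                time=_fmt(p.culture.induction_time_h),
            )
        )
    for tag in p.tags:
        sentences.append(
            _TAG_TEMPLATES[int(rng.integers(0, 3))].format(name=p.recommended_name, tag=tag)
        )
    for buf in p.buffers:
        comps = _render_components(buf.components, buf.pH, rng, typo_rate)
        if buf.stage == "unknown":
            sentences.append(
                _BUFFER_TEMPLATES[1].format(name=p.recommended_name, components=comps)
            )
        else:
            sentences.append(_BUFFER_TEMPLATES[0].format(stage=buf.stage, components=comps))
    if p.detergents:
        parts = [f"0.0{i + 1} % {d}" for i, d in enumerate(p.detergents)]
        comps = parts[0] if len(parts) == 1 else ", ".join(parts[:-1]) + " and " + parts[-1]
        sentences.append(_DETERGENT_TEMPLATE.format(components=comps))
    for xl in p.crosslinkers:
        sentences.append(_CROSSLINK_TEMPLATE.format(conc="0.05", name=xl))
    return " ".join(sentences)


def generate_corpus(
    n_articles: int,
    seed: int,
    typo_rate: float = 0.0,
    distractor_chars: int = 3000,
    n_proteins: int | None = None,
    with_grid_prep_probability: float = 0.25,
) -> tuple[
    list[ArticleDocument], list[PdbRecord], list[UniprotRecord], CorpusGroundTruth
]:
    """A consistent corpus: every planted protein has a UniProt record and a
    PDB record pointing at the article's DOI."""
    rng = np.random.default_rng(seed)
    docs: list[ArticleDocument] = []
    specs: list[ArticleGroundTruth] = []
    pdb_records: list[PdbRecord] = []
    uniprot_records: list[UniprotRecord] = []
    ann_rng = np.random.default_rng(seed + 1)
    for i in range(n_articles):
        spec = sample_article_spec(
            i, rng, n_proteins=n_proteins,
            with_grid_prep_probability=with_grid_prep_probability,
        )
        doc, _ = generate_article(
            spec,
            seed=seed + 1000 + i,
            typo_rate=typo_rate,
            distractor_chars=distractor_chars,
        )
        docs.append(doc)
        specs.append(spec)
        entry_names = " and ".join(
            f"{p.recommended_name} ({p.alias})" for p in spec.proteins
        )
        pdb_records.append(
            PdbRecord(
                pdb_id=spec.pdb_id,
                article_title=doc.elements[0].text,
                doi=spec.doi,
                entry_title=f"Crystal structure of {entry_names}" if entry_names else "Apo structure",
                sequences=tuple("MSYNTHETIC" for _ in spec.proteins),
                expression_system=spec.proteins[0].expression_system if spec.proteins else "",
                structure_method="xray",
                uniprot_ids=tuple(p.accession for p in spec.proteins),
            )
        )
        for p in spec.proteins:
            n_ann = int(ann_rng.integers(1, 4))
            keywords = tuple(
                str(a)
                for a in ann_rng.choice(_ANNOTATION_POOL, size=n_ann, replace=False)
            )
            uniprot_records.append(
                UniprotRecord(
                    accession=p.accession,
                    recommended_name=p.recommended_name,
                    alternative_names=(),
                    gene_names=(p.alias,),
                    annotation_keywords=keywords,
                    sequence="MSYNTHETIC",
                )
            )
    truth = CorpusGroundTruth(
        articles=tuple(specs),
        seed=seed,
        params={
            "n_articles": n_articles,
            "typo_rate": typo_rate,
            "distractor_chars": distractor_chars,
        },
    )
    return docs, pdb_records, uniprot_records, truth


def write_corpus(
    out_dir: str | Path,
    docs: list[ArticleDocument],
    pdb_records: list[PdbRecord],
    uniprot_records: list[UniprotRecord],
    truth: CorpusGroundTruth,
) -> None:
    """Write articles, record fixtures, and the ground-truth file."""
    from .corpus_io import write_article
    from .name_resolution import write_pdb_records, write_uniprot_records

    out = Path(out_dir)
    (out / "articles").mkdir(parents=True, exist_ok=True)
    for doc in docs:
        safe = doc.article_id.replace("/", "_")
        write_article(doc, out / "articles" / f"{safe}.txt")
    write_pdb_records(pdb_records, out / "pdb_records.tsv")
    write_uniprot_records(uniprot_records, out / "uniprot_records.tsv")
    (out / "ground_truth.json").write_text(
        json.dumps(asdict(truth), indent=1, sort_keys=True), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# synthetic databases (drive the statistics parameter-recovery tests)
# ---------------------------------------------------------------------------


def generate_database(
    n_proteins: int,
    annotation_groups: list[dict],
    seed: int,
    baseline_usage: float | dict = 0.0,
    chemicals: list[str] | None = None,
    dictionary: ChemicalDictionary | None = None,
) -> tuple[PurificationDatabase, DatabaseGroundTruth]:
    """Bernoulli chemical usage with group-specific probabilities.

    ``annotation_groups`` entries: {"name": str, "size": int,
    "usage": {chemical: probability}}.  Proteins outside a group use the
    baseline probability.  The true log fold for each (group, chemical) is
    ln(p_group / p_baseline), recorded in the ground truth.
    """
    rng = np.random.default_rng(seed)
    if dictionary is None:
        dictionary = default_chemical_dictionary()
    if chemicals is None:
        chemicals = sorted(
            {c for g in annotation_groups for c in g.get("usage", {})}
        ) or dictionary.canonicals()
    chem_index = {c: i for i, c in enumerate(chemicals)}
    base = (
        np.full(len(chemicals), float(baseline_usage))
        if np.isscalar(baseline_usage)
        else np.array([baseline_usage.get(c, 0.0) for c in chemicals])
    )

    uids = [f"U{i:05d}" for i in range(n_proteins)]
    prob = np.tile(base, (n_proteins, 1))
    membership: dict[str, np.ndarray] = {}
    for group in annotation_groups:
        size = int(group["size"])
        if size > n_proteins:
            raise ValueError(f"group {group['name']!r} larger than protein count")
        members = rng.choice(n_proteins, size=size, replace=False)
        membership[group["name"]] = members
        for chem, p in group.get("usage", {}).items():
            prob[members, chem_index[chem]] = float(p)
    usage = rng.random((n_proteins, len(chemicals))) < prob

    db = PurificationDatabase()
    member_sets = {g: set(m.tolist()) for g, m in membership.items()}
    for i, uid in enumerate(uids):
        comps = tuple(
            BufferComponent(
                canonical_name=chem,
                concentration=None,
                role=dictionary.category(chem) if chem in dictionary else "other",
            )
            for j, chem in enumerate(chemicals)
            if usage[i, j]
        )
        annotations = [g for g in membership if i in member_sets[g]]
        db.add_or_merge(
            PurificationEntry(
                uniprot_id=uid,
                doi=f"10.5555/syndb.{i:05d}",
                recommended_name=f"Synthetic protein {i}",
                buffers=[BufferRecord(buffer_type=None, pH=None, components=comps)]
                if comps
                else [],
                annotations=annotations,
            )
        )
    true_log_folds = {}
    for group in annotation_groups:
        for chem, p in group.get("usage", {}).items():
            p0 = base[chem_index[chem]]
            if p > 0 and p0 > 0:
                true_log_folds[(group["name"], chem)] = float(np.log(p / p0))
    truth = DatabaseGroundTruth(
        seed=seed,
        group_members={g: tuple(uids[i] for i in sorted(member_sets[g])) for g in membership},
        usage_probabilities={
            g["name"]: dict(g.get("usage", {})) for g in annotation_groups
        },
        baseline_usage={c: float(p) for c, p in zip(chemicals, base)},
        true_log_folds=true_log_folds,
    )
    return db, truth


# ---------------------------------------------------------------------------
# mock backends
# ---------------------------------------------------------------------------

MockEmbedding = HashedBagEmbedding

_DEFAULT_EMBEDDING = HashedBagEmbedding()


def mock_embedding(text: str) -> np.ndarray:
    """Hashed term-frequency vector (see the retrieval module)."""
    return _DEFAULT_EMBEDDING.embed_text(text)


class MockLlm:
    """Deterministic stand-in language model for tests and dry runs.

    Step-1 prompts are answered by confirming every candidate whose alias or
    recommended name occurs in the context.  Extraction prompts are answered
    by running the generator's sentence grammar over the context and emitting
    the three-step response: quoted fact sentences first, then per-protein
    records in the fenced JSON format.
    """

    name = "mock"

    def generate(self, prompt: str, max_output_chars: int = 20_000) -> str:
        if "### TASK\nresolve_targets" in prompt:
            return self._resolve(prompt)
        return self._extract(prompt)[:max_output_chars]

    # -- step 1 --------------------------------------------------------------

    @staticmethod
    def _section(prompt: str, header: str) -> str:
        marker = f"### {header}\n"
        start = prompt.index(marker) + len(marker)
        end = prompt.find("\n### ", start)
        return prompt[start:] if end == -1 else prompt[start:end]

    @staticmethod
    def _mentioned(name: str, context: str) -> bool:
        flags = 0 if len(name) <= 3 else re.IGNORECASE
        return re.search(rf"(?<![\w-]){re.escape(name)}(?![\w-])", context, flags) is not None

    def _resolve(self, prompt: str) -> str:
        context = self._section(prompt, "CONTEXT")
        confirmed: list[str] = []
        for line in self._section(prompt, "CANDIDATES").splitlines():
            if not line.startswith("- "):
                continue
            alias, _, rec_name = line[2:].split("\t")
            if not rec_name or rec_name in confirmed:
                continue
            if self._mentioned(alias, context) or (
                rec_name and self._mentioned(rec_name, context)
            ):
                confirmed.append(rec_name)
        return "```json\n" + json.dumps(confirmed) + "\n```"

    # -- step 2: the three-step extraction ------------------------------------

    def _extract(self, prompt: str) -> str:
        question_id = self._section(prompt, "QUESTION_ID").strip()
        targets = [
            line[2:]
            for line in self._section(prompt, "TARGET PROTEINS").splitlines()
            if line.startswith("- ") and line[2:] != "(none)"
        ]
        context = self._section(prompt, "CONTEXT")
        sentences: list[str] = []
        for line in context.splitlines():
            if line.startswith("## ") or not line.strip():
                continue
            sentences.extend(SENTENCE_SPLIT.split(line))

        quotes: list[str] = []
        facts: dict[str, dict] = {}
        current: str | None = None
        for sentence in sentences:
            for t in targets:
                if self._mentioned(t, sentence):
                    current = t
            extracted = self._facts_from_sentence(sentence, question_id)
            if not extracted:
                continue
            owner = current if current is not None else "unassigned"
            if owner not in facts:
                facts[owner] = {}
            self._merge_fields(facts[owner], extracted)
            if sentence not in quotes:
                quotes.append(sentence)
        if not targets:
            facts = {}
        records = [
            {"protein_name": name, "fields": fields}
            for name, fields in facts.items()
            if fields
        ]
        return "```json\n" + json.dumps({"quotes": quotes, "records": records}) + "\n```"

    @staticmethod
    def _merge_fields(into: dict, new: dict) -> None:
        for key, value in new.items():
            if key in ("buffers",):
                into.setdefault(key, []).extend(value)
            elif key in ("fusion_tags", "detergents", "crosslinkers"):
                seen = into.setdefault(key, [])
                for v in value:
                    if v not in seen:
                        seen.append(v)
            else:
                into.setdefault(key, value)

    def _facts_from_sentence(self, sentence: str, question_id: str) -> dict:
        sentence = sentence.strip()
        if question_id == "q_buffers":
            return self._buffer_facts(sentence)
        if question_id == "q_tags":
            tags = [next(g for g in m.groups() if g) for m in RE_TAG.finditer(sentence)]
            return {"fusion_tags": tags} if tags else {}
        if question_id == "q_expression":
            return self._expression_facts(sentence)
        if question_id == "q_grid_prep":
            return self._grid_facts(sentence)
        return {}

    @staticmethod
    def _buffer_facts(sentence: str) -> dict:
        stage = "unknown"
        m = RE_BUFFER_STAGE.search(sentence)
        if m:
            stage, body = m.group(1), m.group(2)
        else:
            m = RE_BUFFER_PURIFIED.search(sentence)
            if not m:
                return {}
            body = m.group(1)
        components = [
            {"name": name.strip(), "concentration": f"{value} {unit}"}
            for value, unit, name in RE_COMPONENT.findall(body + ".")
        ]
        if not components:
            return {}
        ph_match = RE_PH.search(sentence)
        buffer = {
            "buffer_type": None,
            "pH": float(ph_match.group(1)) if ph_match else None,
            "stage": stage,
            "components": components,
        }
        return {"buffers": [buffer]}

    @staticmethod
    def _expression_facts(sentence: str) -> dict:
        fields: dict = {}
        m = RE_EXPR_PASSIVE.search(sentence) or RE_EXPR_ACTIVE.search(sentence)
        if m:
            fields["expression_system"] = m.group(1).strip()
        m = RE_INDUCTION.search(sentence)
        if m:
            conc, _unit, inducer, temp, time = m.groups()
            fields.update(
                inducer=inducer,
                inducer_concentration_mM=float(conc),
                induction_temperature_C=float(temp),
                induction_time_h=float(time),
            )
        return fields

    @staticmethod
    def _grid_facts(sentence: str) -> dict:
        if "grid preparation" not in sentence:
            return {}
        names = [name.strip() for _, _, name in RE_COMPONENT.findall(sentence)]
        if not names:
            return {}
        if "crosslinked" in sentence:
            return {"crosslinkers": names}
        return {"detergents": names}


_DEFAULT_LLM = MockLlm()


def mock_llm(prompt: str) -> str:
    """Module-level convenience wrapper around a shared :class:`MockLlm`."""
    return _DEFAULT_LLM.generate(prompt)
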