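# Methods

This note documents the models, defaults, and numerical choices behind
`purmine`, and what the test suite does and does not establish.

## Chunking

Articles are ordered sequences of headings and paragraphs. Chunking is
title-driven: every heading starts a new chunk, because sections of
biological articles are relatively self-contained and the subtitle itself
("Protein expression and purification") carries retrieval signal — the
heading is therefore prepended to its section's first chunk. A section
exceeding the chunk budget (default 2 500 characters) is split by greedy
sentence packing at ". " boundaries (followed by an uppercase start);
only a single sentence longer than the budget is hard-cut at whitespace.
Chunk character spans tile the paragraph text exactly, so no content can be
silently dropped, and chunking is a pure function of the document. Adjacent
short sections are never merged across headings. `token_estimate` is
ceil(characters/4), informational only.

## Retrieval

Each question of interest ships with a *template paragraph* — an editable
exemplar of the passage kind that answers it. Chunks are ranked by cosine
similarity between embeddings; ties break toward earlier document position.
Selection is greedy in rank order under a 12 000-character budget,
*skipping* any chunk that would overflow (rather than stopping), which
maximizes retained information under the budget. Selected chunks are
reassembled in document order — not similarity order — so the extractor
sees a coherent narrative; each is preceded by a `## <section title>` line.

The production embedding contract is any deterministic map from text to a
fixed-dimension vector (1024 dimensions with the intended sentence-encoder
backend). The default test backend is a hashed bag-of-words term-frequency
embedding (crc32 hashing into 256 bins, lowercased, punctuation stripped):
deterministic and download-free, it preserves the property the pipeline
actually relies on — lexical overlap with the template raises the cosine —
while sacrificing true semantic similarity. Consequently, retrieval tests
demonstrate that ranking, budgeting, and reassembly are correct, not that
any particular neural encoder retrieves well.

## Name resolution

The alias dictionary merges UniProt recommended names, alternative names,
and gene symbols with abbreviations harvested from PDB entry titles via the
pattern "Long Name (ABBR)". Aliases of ≤ 3 characters match
case-sensitively (an alias like "CAT" must not fire on the word "cat");
longer aliases match case-insensitively at word boundaries. Ambiguous
aliases keep all accessions and are passed to LLM step 1, which — rather
than any heuristic weighting — decides which candidates the article
actually studies.

## Extraction and quality checking

The three-step prompt (copy evidence verbatim → extract from copied
sentences only → assign to resolved proteins) is enforced structurally; the
exact wording is configuration, not code. One retry with a format reminder
is allowed on unparseable responses, then the extraction is rejected.
Backends must be deterministic (temperature-0 semantics) for reproducible
runs.

Quality rules: (q1) every chemical must normalize against the dictionary at
score ≥ 0.85, with a repair path that substitutes the closest dictionary
alias found verbatim in the quoted evidence (a transcription slip such as
"Trsi" next to evidence saying "Tris"), requiring at least 0.5 similarity
so arbitrary tokens are not "repaired"; (q2) pH ∈ [0, 14]; (q3)
concentrations must parse as number + unit from {M, mM, µM, %, mg/mL},
with spelling variants ("millimolar", "uM") repaired; (q4) record protein
names must be resolved names or "unassigned"; (q5) every extracted value
must appear — surface form or repaired canonical, after case folding and
whitespace collapsing — in the quoted evidence. Rule q5 is the
anti-hallucination guarantee: a perfectly dictionary-valid chemical that
the evidence never mentions is rejected. Records violating an unrepairable
rule are dropped; surviving records are ingested.

## Database conventions

Entries are keyed by (UniProt accession, article DOI); merging keeps the
first value of conflicting scalars and logs the conflict, unions list
fields, and deduplicates identical buffer records, making ingestion
idempotent. Unknowns are allowed everywhere except that an entry needs an
accession or at least one PDB id. Counting rules: a buffer type used for a
unique protein counts as one case regardless of repeats; an entry with both
large ({GST, MBP, SUMO, Trx, CBD, GB1, TAP}) and small ({His, FLAG, Strep,
HA, Myc, AviTag, Fc}) tags classifies as large. Condition histograms use
closed [lo, hi] bins (pH defaults ≤3.5, 3.6–6.5, 6.6–7.5, 7.6–9.5, ≥9.6;
bins are configuration); values outside all bins are reported separately as
unbinned, and percentages are over known values only.

## Statistics

* Average error rate of an extraction run: (1/n) Σᵢ (FPᵢ + FNᵢ)/(P + N)
  over the n chemicals of the evaluation vocabulary, with P/N the
  dataset-level positive/negative label totals.
* Log fold difference ln[(P₁/N₁)/(P₂/N₂)] with ±∞ sentinels when only one
  group uses the chemical and NaN when neither does; reported values are
  capped at ±3 with a flag.
* Pooled two-proportion z-test; the two-sided p-value is computed as
  erfc(|z|/√2) via the complementary error function (accurate far into the
  tail), and a degenerate pooled proportion (0 or 1) returns p = 1. This
  test is algebraically identical to the 1-df chi-square test without
  continuity correction, which the suite verifies to 1×10⁻¹⁰.
* "Uses a chemical" is resolved at unique-protein level — a protein uses a
  chemical if any of its entries does — consistent with the case-counting
  rule. Annotation scans keep annotations carried by more than 500 unique
  proteins (300 for induction-condition scans) to limit outlier influence.
  Significance is raw p < 0.05 by default; a Benjamini–Hochberg switch
  exists but is off, matching the raw-p convention of the analyses the
  package reproduces.

## Synthetic corpus: what it emulates, and what it does not

The generator emits articles with a structural-biology layout whose methods
subsection encodes planted facts in varied sentence templates
(active/passive voice, "mM" vs "millimolar", stage-naming vs stage-less
buffer sentences) so the extractor is exercised beyond a single pattern.
Generator mixtures follow the corpus-level shares the analyses report:
buffer agents led by Tris (49.2 %), then HEPES and phosphate; His tags at
82.5 %; induction times clustered at 12–16 h (69 %) then 3–6 h (14.3 %);
temperatures led by 18/20/16 °C; IPTG at 1 or 0.5 mM. OCR typos are
injected at a per-character rate, restricted to chemical tokens whose
normalized length is ≥ 7, where the 0.85 threshold analytically guarantees
recovery (1 − 1/7 ≈ 0.857); shorter tokens are exercised as negative cases
in the unit tests instead.

The mock LLM parses contexts with the same sentence grammar and emits the
three-step response format; the mock embedding is the hashed
term-frequency backend. A passing closed loop therefore shows that
chunking, retrieval, prompting, parsing, quality checking, ingestion, and
evaluation compose losslessly and deterministically — it does not measure
the extraction error of any real language model on real prose, which is
irreducibly a property of the model and corpus.

Synthetic databases draw per-(protein, chemical) Bernoulli usage with
group-specific probabilities, recording true log folds ln(p₁/p₀). The
calibration study conditions, fixed once: 500 proteins per database (250
annotated), usage probability 0.3 everywhere under the null — sizes at
which the pooled z-test's normal approximation is sound — and 1 000
proteins (300 annotated) with usage 0.6 vs 0.2 for recovery of a planted
ln 3 association. Problem sizes throughout (50-article closed loop,
100-article recall study, ≥10 000 null pairs, 200 recovery replicates)
were chosen to make sampling error small relative to the assertion bands
while keeping the default suite fast on one CPU.

## Numerical and design notes

* The matching score is implemented in the similarity orientation
  1 − Lev/max(L): the acceptance rule "highest score, at least 0.85" is
  only coherent for a similarity, not a distance.
* Pre-matching normalization: case folding, Greek-letter spelling (β →
  beta), and collapsing whitespace/hyphens/underscores — the variants OCR
  and typesetting actually produce. Edit distance itself comes from edlib
  (exact Needleman-Wunsch distance); the test oracle is an independent
  brute-force memoized recursion.
* Tie-breaking in normalization (equal scores across canonical names):
  longer alias first, then lexicographic, flagged ambiguous.
* The single-edit typo guarantee applies to edits that survive
  normalization as a single edit; deleting a letter that is flanked by
  spaces collapses two edits into the normalized form and is legitimately
  unrecoverable at the 0.85 threshold.
* Resolution (LLM step 1) sees the same selected segments as extraction,
  not the full article.

## Limitations

* Real-PDF ingestion (OCR, layout analysis) is an external contract; the
  package consumes sectioned text.
* The shipped chemical dictionary covers the ~50 components common in
  purification protocols and is user-extensible; it is not a chemical
  ontology (no InChI/SMILES, no unit conversion beyond parsing).
* Corpus-scale usage percentages cannot be reproduced without the
  underlying article corpus; all quantitative claims here are properties of
  the method, verified on synthetic ground truth.
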