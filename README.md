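# purmine

Mining protein expression and purification strategies from
structural-biology articles.

Choosing expression and purification conditions for a new protein — buffer
system and pH, salts and additives, fusion tag, host, induction regime — is
still largely trial and error. Yet tens of thousands of articles backing
Protein Data Bank depositions describe conditions that demonstrably worked.
`purmine` implements a retrieval-augmented extraction pipeline that turns
such articles into a structured *purification-strategy database*, plus the
statistics used to ask which strategies go with which kinds of proteins.

## What the pipeline does

1. **Chunking** — a sectioned article (headings + paragraphs, as produced by
   OCR/PDF preprocessing) is split at subtitles into retrieval chunks of at
   most 2 500 characters; oversized sections are split greedily at sentence
   boundaries.
2. **Retrieval** — chunks are embedded (production: a 1024-dimensional
   sentence-embedding model; tests: a deterministic hashed bag-of-words
   backend) and ranked by cosine similarity against a *template paragraph*
   exemplifying the passage that answers each question of interest. Chunks
   are selected greedily under a 12 000-character budget and reassembled in
   document order.
3. **Name resolution** — a dictionary built from PDB and UniProt records
   (recommended/alternative names, gene symbols, abbreviations harvested
   from entry titles) proposes candidate targets; LLM step 1 confirms which
   candidates the article actually studies.
4. **Extraction** — LLM step 2 runs a three-step, evidence-first prompt:
   copy the answering sentences verbatim, extract entities from only those
   sentences, assign each record to one resolved protein. A quality checker
   enforces dictionary normalization, pH and concentration sanity, and the
   anti-hallucination rule that every value must appear in the quoted
   evidence.
5. **Database + statistics** — validated records merge into one entry per
   (UniProt accession, DOI). Analyses count unique proteins: buffer-type
   cases, large/small fusion-tag classes, induction-condition histograms,
   and annotation-contrast tests.

Chemical surface forms (synonyms, abbreviations, OCR typos) are normalized
with the similarity

    score(a, b) = 1 − Lev(a, b) / max(|a|, |b|)

accepting the best-scoring dictionary alias when score ≥ 0.85 — a threshold
that provably absorbs any single-edit typo in a name of ≥ 7 characters.

Annotation contrasts use the log fold difference and the pooled
two-proportion z-test between proteins with and without an annotation
(group 1 vs group 2, usage counts P over totals N):

    log fold = ln[(P₁/N₁) / (P₂/N₂)]            (capped at ±3 for reporting)
    z = (P₁/N₁ − P₂/N₂) / √(p̂(1−p̂)(1/N₁ + 1/N₂)),   p̂ = (P₁+P₂)/(N₁+N₂)
    p = 2(1 − Φ(|z|))

LLM and embedding backends are pluggable contracts. The shipped mock
backends are deterministic and model-free, so the full method runs — and is
tested end to end against planted ground truth — without weights or
downloads. The synthetic-corpus module generates ground-truthed articles
with realistic layout (methods subsection "Protein expression and
purification", distractor sections, optional OCR typos).

## Worked example

```python
from purmine.synthetic import generate_corpus
from purmine.pipeline import extract_corpus
from purmine.purification_db import count_buffer_cases

docs, pdb, uniprot, truth = generate_corpus(8, seed=2)
result = extract_corpus(docs, uniprot, pdb)   # mock backends by default
print(len(result.database))
print(count_buffer_cases(result.database))
```

prints

```
14
{'Tris': 7, 'HEPES': 4, 'phosphate': 3, 'citrate': 2, 'CAPS': 1, 'acetate': 1}
```

— 14 database entries (one per planted protein–article pair) and
buffer-type case counts in which each buffer used for a unique protein
counts once, with Tris dominating as the generator's buffer mixture
dictates. The same flow is available from the shell:

```bash
purmine simulate --n-articles 8 --seed 2 --out corpus/
purmine extract  --corpus corpus/ --out db.jsonl --llm mock
purmine analyze  --db db.jsonl --out tables/
```

`analyze` writes plot-ready CSVs: buffer cases, pH/temperature/time
histograms, the annotation×chemical scan, a group contrast (default
"Membrane" vs rest), and the detergent co-usage matrix.

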