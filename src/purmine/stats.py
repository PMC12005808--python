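"""Statistics over the purification-strategy database.

Three primitives drive every comparative analysis here:

* the **average error rate** of an extraction run against a labelled test
  set, ``(1/n) Σ_i (FP_i + FN_i) / (P + N)`` over the ``n`` chemicals;
* the **log fold difference** ``ln((P1/N1) / (P2/N2))`` between the usage
  rate of a chemical among proteins carrying an annotation and among those
  without it (capped at ±3 for reporting);
* the **two-proportion z-test** with pooled variance,
  ``z = (P1/N1 − P2/N2) / sqrt(p̂(1−p̂)(1/N1 + 1/N2))`` with
  ``p̂ = (P1+P2)/(N1+N2)`` and two-sided ``p = 2(1 − Φ(|z|))``.

"Uses a chemical" is resolved at the unique-protein level: a protein uses a
chemical if any of its database entries does, matching the case-counting
rule of the frequency summaries.  Raw ``p < 0.05`` denotes significance by
default; a Benjamini–Hochberg switch exists but is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyInput",
    "EvaluationCounts",
    "AnnotationTestResult",
    "average_error_rate",
    "log_fold_difference",
    "cap_log_fold",
    "two_proportion_z_test",
    "annotation_chemical_scan",
    "group_contrast",
    "co_usage",
    "evaluation_counts",
    "results_to_frame",
    "benjamini_hochberg",
    "DEFAULT_LOG_FOLD_CAP",
]

DEFAULT_LOG_FOLD_CAP = 3.0
DEFAULT_ALPHA = 0.05
# annotation floors: chemical scans keep annotations with > 500 unique
# proteins; induction-condition scans with > 300.
MIN_ENTRIES_CHEMICAL = 500
MIN_ENTRIES_CONDITION = 300


@dataclass(frozen=True)
class ContingencyInput:
    """Usage counts of one chemical in annotated (1) vs non-annotated (2) proteins."""

    P1: int
    N1: int
    P2: int
    N2: int

    def __post_init__(self) -> None:
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError("group totals N1, N2 must be >= 1")
        if not (0 <= self.P1 <= self.N1 and 0 <= self.P2 <= self.N2):
            raise ValueError("usage counts must satisfy 0 <= P <= N")


@dataclass(frozen=True)
class EvaluationCounts:
    """Per-chemical false positives/negatives against a labelled test set."""

    fp: tuple[int, ...]
    fn: tuple[int, ...]
    positives: int
    negatives: int

    def __post_init__(self) -> None:
        if len(self.fp) != len(self.fn) or not self.fp:
            raise ValueError("fp and fn must be non-empty and equal-length")
        if self.positives + self.negatives < 1:
            raise ValueError("P + N must be >= 1")
        if any(v < 0 for v in (*self.fp, *self.fn)):
            raise ValueError("counts must be non-negative")

    @property
    def n_chemicals(self) -> int:
        return len(self.fp)


@dataclass(frozen=True)
class AnnotationTestResult:
    annotation: str
    chemical: str
    input: ContingencyInput
    log_fold: float  # ±inf / nan sentinels allowed
    log_fold_capped: float
    p_value: float
    direction: str  # "higher" | "lower" | "none"
    capped: bool = False


def average_error_rate(counts: EvaluationCounts) -> float:
    """Mean per-chemical error rate of an extraction run (0 = perfect)."""
    total = counts.positives + counts.negatives
    return sum(fp + fn for fp, fn in zip(counts.fp, counts.fn)) / (
        counts.n_chemicals * total
    )


def log_fold_difference(c: ContingencyInput) -> float:
    """ln of the usage-rate ratio between the two groups.

    Sentinels instead of exceptions: +inf when only group 1 uses the
    chemical, -inf when only group 2 does, nan when neither does.
    """
    if c.P1 == 0 and c.P2 == 0:
        return math.nan
    if c.P2 == 0:
        return math.inf
    if c.P1 == 0:
        return -math.inf
    return math.log((c.P1 / c.N1) / (c.P2 / c.N2))


def cap_log_fold(x: float, cap: float = DEFAULT_LOG_FOLD_CAP) -> tuple[float, bool]:
    """Clamp a log fold difference to [-cap, cap] for reporting.

    Returns (value, capped_flag); ±inf sentinels clamp to ±cap flagged, nan
    passes through unflagged.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if math.isnan(x):
        return x, False
    if x > cap:
        return cap, True
    if x < -cap:
        return -cap, True
    return x, False


def two_proportion_z_test(c: ContingencyInput) -> float:
    """Two-sided p-value of the pooled two-proportion z-test.

    The normal tail is evaluated through the complementary error function:
    2(1 − Φ(|z|)) = erfc(|z|/√2).  Degenerate pooled proportions (0 or 1)
    mean both group proportions are equal, hence p = 1.
    """
    pooled = (c.P1 + c.P2) / (c.N1 + c.N2)
    if pooled in (0.0, 1.0):
        return 1.0
    z = (c.P1 / c.N1 - c.P2 / c.N2) / math.sqrt(
        pooled * (1.0 - pooled) * (1.0 / c.N1 + 1.0 / c.N2)
    )
    return math.erfc(abs(z) / math.sqrt(2.0))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted q-values (monotone step-up); optional, off by default."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, p_values[idx] * m / rank)
        q[idx] = prev
    return q


# ---------------------------------------------------------------------------
# database-level scans
#
# ``usage`` is the unique-protein view the database exposes:
#   uniprot_id -> {"annotations": set[str], "chemicals": set[str], "tags": set[str]}
# ---------------------------------------------------------------------------

UsageTable = Mapping[str, Mapping[str, set]]


def _usage_table(db) -> UsageTable:
    if hasattr(db, "protein_usage"):
        return db.protein_usage()
    return db


def _test_pair(
    annotation: str, chemical: str, c: ContingencyInput, alpha: float
) -> AnnotationTestResult:
    lf = log_fold_difference(c)
    capped_value, was_capped = cap_log_fold(lf)
    p = two_proportion_z_test(c)
    if p < alpha and c.P1 / c.N1 > c.P2 / c.N2:
        direction = "higher"
    elif p < alpha and c.P1 / c.N1 < c.P2 / c.N2:
        direction = "lower"
    else:
        direction = "none"
    return AnnotationTestResult(
        annotation=annotation,
        chemical=chemical,
        input=c,
        log_fold=lf,
        log_fold_capped=capped_value,
        p_value=p,
        direction=direction,
        capped=was_capped,
    )


def annotation_chemical_scan(
    db,
    min_annotation_entries: int = MIN_ENTRIES_CHEMICAL,
    alpha: float = DEFAULT_ALPHA,
    chemicals: Iterable[str] | None = None,
    adjust: bool = False,
) -> list[AnnotationTestResult]:
    """Test every (annotation, chemical) pair for differential usage.

    Annotations are kept only when carried by more than
    ``min_annotation_entries`` unique proteins (outlier guard).  When
    ``adjust`` is set, directions are assigned on BH-adjusted p-values;
    reported p-values stay raw either way.
    """
    usage = _usage_table(db)
    n_total = len(usage)
    annotations: dict[str, set[str]] = {}
    seen_chems: set[str] = set()
    for uid, rec in usage.items():
        for ann in rec["annotations"]:
            annotations.setdefault(ann, set()).add(uid)
        seen_chems.update(rec["chemicals"])
    chem_list = sorted(seen_chems) if chemicals is None else list(chemicals)

    results: list[AnnotationTestResult] = []
    for ann in sorted(annotations):
        members = annotations[ann]
        n1 = len(members)
        n2 = n_total - n1
        if n1 <= min_annotation_entries or n2 < 1:
            continue
        for chem in chem_list:
            p1 = sum(1 for uid in members if chem in usage[uid]["chemicals"])
            p2 = sum(
                1
                for uid, rec in usage.items()
                if uid not in members and chem in rec["chemicals"]
            )
            results.append(
                _test_pair(ann, chem, ContingencyInput(p1, n1, p2, n2), alpha)
            )
    if adjust and results:
        qs = benjamini_hochberg([r.p_value for r in results])
        adjusted = []
        for r, q in zip(results, qs):
            c = r.input
            if q < alpha and c.P1 / c.N1 > c.P2 / c.N2:
                direction = "higher"
            elif q < alpha and c.P1 / c.N1 < c.P2 / c.N2:
                direction = "lower"
            else:
                direction = "none"
            adjusted.append(
                AnnotationTestResult(
                    r.annotation, r.chemical, c, r.log_fold, r.log_fold_capped,
                    r.p_value, direction, r.capped,
                )
            )
        results = adjusted
    return results


def group_contrast(db, group_annotation: str, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Contrast chemical and fusion-tag usage between proteins with and
    without ``group_annotation`` (e.g. "Membrane").

    One row per item with usage counts, log fold difference (group vs rest)
    and the pooled z-test p-value; ``kind`` distinguishes chemicals from
    tags.  This generic contrast realizes the membrane-protein case study.
    """
    usage = _usage_table(db)
    members = {uid for uid, rec in usage.items() if group_annotation in rec["annotations"]}
    if not members:
        raise ValueError(f"no proteins carry annotation {group_annotation!r}")
    others = set(usage) - members
    if not others:
        raise ValueError(f"all proteins carry annotation {group_annotation!r}")

    rows = []
    for kind, key in (("chemical", "chemicals"), ("tag", "tags")):
        items = sorted({x for rec in usage.values() for x in rec.get(key, set())})
        for item in items:
            p1 = sum(1 for uid in members if item in usage[uid].get(key, set()))
            p2 = sum(1 for uid in others if item in usage[uid].get(key, set()))
            res = _test_pair(
                group_annotation,
                item,
                ContingencyInput(p1, len(members), p2, len(others)),
                alpha,
            )
            rows.append(
                {
                    "kind": kind,
                    "item": item,
                    "P1": p1,
                    "N1": len(members),
                    "P2": p2,
                    "N2": len(others),
                    "log_fold": res.log_fold,
                    "log_fold_capped": res.log_fold_capped,
                    "p_value": res.p_value,
                    "direction": res.direction,
                }
            )
    return pd.DataFrame(rows)


def co_usage(db, category: str, scope: str | None = None) -> pd.DataFrame:
    """Symmetric article-level co-usage counts of chemicals in one category.

    Each article counts once per unordered chemical pair (entries of the
    same protein/article deduplicate to a single case); the diagonal holds
    single-chemical article counts.  ``scope`` restricts to chemicals
    extracted for one question (e.g. the grid-preparation detergents).
    """
    per_article = _usage_by_article(db, category, scope)
    chems = sorted({c for chems in per_article.values() for c in chems})
    table = pd.DataFrame(0, index=chems, columns=chems, dtype=int)
    for chems_used in per_article.values():
        used = sorted(chems_used)
        for i, a in enumerate(used):
            table.loc[a, a] += 1
            for b in used[i + 1 :]:
                table.loc[a, b] += 1
                table.loc[b, a] += 1
    return table


def _usage_by_article(db, category: str, scope: str | None) -> dict[str, set[str]]:
    if hasattr(db, "article_category_usage"):
        return db.article_category_usage(category, scope)
    return db  # pre-computed mapping article_id -> set of chemicals


# ---------------------------------------------------------------------------
# extraction evaluation (test-set scoring)
# ---------------------------------------------------------------------------


def evaluation_counts(
    predicted: Mapping[object, set],
    truth: Mapping[object, set],
    vocabulary: Sequence[str],
) -> EvaluationCounts:
    """Score predicted chemical sets against ground truth over a fixed
    chemical vocabulary.

    Keys identify evaluation units (protein within article); every
    (unit, chemical) cell is one binary label.  P/N are the dataset-level
    positive/negative label totals shared by all per-chemical terms.
    """
    units = sorted(set(predicted) | set(truth), key=repr)
    vocab = list(vocabulary)
    if not vocab:
        raise ValueError("vocabulary must be non-empty")
    fp = [0] * len(vocab)
    fn = [0] * len(vocab)
    positives = 0
    for unit in units:
        pred = predicted.get(unit, set())
        true = truth.get(unit, set())
        for i, chem in enumerate(vocab):
            is_true = chem in true
            is_pred = chem in pred
            positives += is_true
            if is_pred and not is_true:
                fp[i] += 1
            elif is_true and not is_pred:
                fn[i] += 1
    negatives = len(units) * len(vocab) - positives
    return EvaluationCounts(tuple(fp), tuple(fn), positives, negatives)


def results_to_frame(results: Sequence[AnnotationTestResult]) -> pd.DataFrame:
    """Tidy table (one row per annotation×chemical) ready for plotting."""
    return pd.DataFrame(
        [
            {
                "annotation": r.annotation,
                "chemical": r.chemical,
                "P1": r.input.P1,
                "N1": r.input.N1,
                "P2": r.input.P2,
                "N2": r.input.N2,
                "log_fold": r.log_fold,
                "log_fold_capped": r.log_fold_capped,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for r in results
        ]
    )
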