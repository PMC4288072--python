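"""Measurement machinery: span matching, P/R/F1, Cohen's kappa,
cross-validation, and the statistics used to relate them.

Two matching regimes are supported throughout.  *Strict* requires the
predicted and gold span to agree exactly in both extent and class;
*unstrict* requires the same class and an overlap of at least one token,
so boundary disagreements do not count as errors.  Tagger scores use
strict matching by default; unstrict matters mostly for inter-annotator
agreement.

Kappa is computed at token level per class: each token is binary
in-class / out-of-class for each annotator, and agreement is
chance-corrected over the resulting 2×2 table.  Overall P/R/F1 is
micro-averaged over the nine classes (macro is reported alongside).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .corpus import AnnotationSet, Document, EntityMention, ENTITY_CLASSES

logger = logging.getLogger(__name__)

MATCH_MODES = ("strict", "unstrict")


def _check_mode(mode: str) -> None:
    if mode not in MATCH_MODES:
        raise ValueError(f"match mode must be one of {MATCH_MODES}, got {mode!r}")


# ---------------------------------------------------------------------------
# Mention matching and P/R/F1
# ---------------------------------------------------------------------------

def match_mentions(gold: Sequence[EntityMention], pred: Sequence[EntityMention],
                   mode: str = "strict") -> tuple[int, int, int]:
    """One-to-one matching of one document's mentions: (TP, FP, FN).

    Strict: span and class identical.  Unstrict: class identical and at
    least one token shared (token-aligned spans overlap in characters
    iff they share a token).  Matching is greedy by position; each gold
    mention consumes at most one prediction.
    """
    _check_mode(mode)
    gold_sorted = sorted(gold, key=lambda m: (m.start, m.end))
    pred_sorted = sorted(pred, key=lambda m: (m.start, m.end))
    used = [False] * len(pred_sorted)
    tp = 0
    for g in gold_sorted:
        for i, p in enumerate(pred_sorted):
            if used[i] or p.entity_class is not g.entity_class:
                continue
            hit = (p.start == g.start and p.end == g.end) if mode == "strict" \
                else g.overlaps(p)
            if hit:
                used[i] = True
                tp += 1
                break
    return tp, len(pred_sorted) - tp, len(gold_sorted) - tp


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def prf(gold: AnnotationSet, pred: AnnotationSet, mode: str = "strict",
        doc_ids: Sequence[str] | None = None) -> dict[str, PRF]:
    """Per-class and overall precision/recall/F1 over a corpus.

    ``overall`` is micro-averaged (pooled counts); ``macro`` is the
    unweighted mean over classes that occur in gold or predictions,
    reported for transparency.
    """
    _check_mode(mode)
    if doc_ids is None:
        doc_ids = sorted(set(gold.doc_ids()) | set(pred.doc_ids()))
    counts = {cls.value: [0, 0, 0] for cls in ENTITY_CLASSES}
    for doc_id in doc_ids:
        g_doc = gold.for_doc(doc_id)
        p_doc = pred.for_doc(doc_id)
        for cls in ENTITY_CLASSES:
            g_cls = [m for m in g_doc if m.entity_class is cls]
            p_cls = [m for m in p_doc if m.entity_class is cls]
            if not g_cls and not p_cls:
                continue
            tp, fp, fn = match_mentions(g_cls, p_cls, mode)
            bucket = counts[cls.value]
            bucket[0] += tp
            bucket[1] += fp
            bucket[2] += fn
    report = {cls: PRF(*c) for cls, c in counts.items()}
    pooled = PRF(sum(c[0] for c in counts.values()),
                 sum(c[1] for c in counts.values()),
                 sum(c[2] for c in counts.values()))
    report["overall"] = pooled
    return report


def macro_f1(report: dict[str, PRF]) -> float:
    """Unweighted mean F1 over classes with any gold or predicted mention."""
    scores = [
        r.f1 for cls, r in report.items()
        if cls != "overall" and (r.tp + r.fp + r.fn) > 0
    ]
    return float(np.mean(scores)) if scores else 0.0


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def _class_coverage(doc: Document, mentions: Sequence[EntityMention],
                    cls) -> tuple[np.ndarray, list[EntityMention]]:
    vec = np.zeros(len(doc.tokens), dtype=bool)
    own = [m for m in mentions if m.entity_class is cls]
    for m in own:
        for tok in doc.tokens:
            if tok.start >= m.start and tok.end <= m.end:
                vec[tok.index] = True
    return vec, own


def cohens_kappa(docs: Sequence[Document], ann_a: AnnotationSet,
                 ann_b: AnnotationSet, entity_class, mode: str = "strict"
                 ) -> float:
    """Token-level Cohen's kappa for one class between two annotators.

    Each token is binary in-class/out for each annotator; kappa is
    (p_o − p_e)/(1 − p_e) over the pooled 2×2 table.  In unstrict mode a
    token covered by only one annotator still counts as agreement when
    the covering mention overlaps a same-class mention of the other
    annotator (boundary differences are forgiven).
    """
    _check_mode(mode)
    n_tokens = 0
    table = np.zeros((2, 2), dtype=np.int64)  # [a][b]
    for doc in docs:
        n_tokens += len(doc.tokens)
        vec_a, own_a = _class_coverage(doc, ann_a.for_doc(doc.doc_id), entity_class)
        vec_b, own_b = _class_coverage(doc, ann_b.for_doc(doc.doc_id), entity_class)
        if mode == "unstrict":
            vec_a, vec_b = vec_a.copy(), vec_b.copy()
            for tok in doc.tokens:
                i = tok.index
                if vec_a[i] and not vec_b[i]:
                    cover = next(m for m in own_a
                                 if m.start <= tok.start and tok.end <= m.end)
                    if any(cover.overlaps(m) for m in own_b):
                        vec_b[i] = True
                elif vec_b[i] and not vec_a[i]:
                    cover = next(m for m in own_b
                                 if m.start <= tok.start and tok.end <= m.end)
                    if any(cover.overlaps(m) for m in own_a):
                        vec_a[i] = True
        for a_val in (0, 1):
            for b_val in (0, 1):
                table[a_val, b_val] += int(np.sum((vec_a == a_val) & (vec_b == b_val)))
    if n_tokens == 0:
        raise ValueError("kappa undefined over zero tokens")
    n = table.sum()
    p_o = (table[0, 0] + table[1, 1]) / n
    p_e = float(table[0].sum() * table[:, 0].sum()
                + table[1].sum() * table[:, 1].sum()) / (n * n)
    if math.isclose(p_e, 1.0):
        logger.warning("degenerate kappa (p_e = 1); defining kappa = %s",
                       1.0 if math.isclose(p_o, 1.0) else 0.0)
        return 1.0 if math.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1 - p_e))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    k: int
    assignment: dict[str, int]
    seed: int

    def fold_doc_ids(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.assignment.items() if f == fold)


def kfold_split(doc_ids: Sequence[str], k: int, seed: int = 0) -> FoldAssignment:
    """Shuffle by seed, deal round-robin; fold sizes differ by at most 1."""
    if k < 1 or k > len(doc_ids):
        raise ValueError(f"k={k} invalid for {len(doc_ids)} documents")
    ids = list(doc_ids)
    rng = np.random.RandomState(seed)
    rng.shuffle(ids)
    return FoldAssignment(k, {d: i % k for i, d in enumerate(ids)}, seed)


@dataclass
class CrossValReport:
    """Per-fold strict/unstrict evaluation plus mean and population SD."""

    folds: FoldAssignment
    per_fold: list[dict[str, PRF]]
    mode: str

    def fold_values(self, key: str, metric: str) -> np.ndarray:
        return np.array([getattr(rep[key], metric) for rep in self.per_fold])

    def mean_sd(self, key: str, metric: str) -> tuple[float, float]:
        v = self.fold_values(key, metric)
        return float(v.mean()), float(v.std(ddof=0))

    def summary(self) -> dict[str, dict[str, tuple[float, float]]]:
        keys = [cls.value for cls in ENTITY_CLASSES] + ["overall"]
        return {
            key: {m: self.mean_sd(key, m) for m in ("precision", "recall", "f1")}
            for key in keys
        }


TaggerFactory = Callable[[Sequence[Document], AnnotationSet],
                         Callable[[Document], list[EntityMention]]]


def cross_validate(docs: Sequence[Document], gold: AnnotationSet,
                   tagger_factory: TaggerFactory, k: int = 10, seed: int = 0,
                   mode: str = "strict") -> CrossValReport:
    """Document-level k-fold cross-validation of a tagger.

    ``tagger_factory(train_docs, gold)`` must return a ``doc ->
    mentions`` predictor trained on those documents only.  Deterministic
    given the seed and corpus order.
    """
    _check_mode(mode)
    by_id = {d.doc_id: d for d in docs}
    folds = kfold_split(sorted(by_id), k, seed)
    per_fold: list[dict[str, PRF]] = []
    for fold in range(k):
        held_out = folds.fold_doc_ids(fold)
        train_docs = [by_id[d] for d in sorted(by_id) if d not in set(held_out)]
        predict = tagger_factory(train_docs, gold)
        pred = AnnotationSet(f"fold{fold}")
        for doc_id in held_out:
            for m in predict(by_id[doc_id]):
                pred.add(doc_id, m)
        per_fold.append(prf(_subset(gold, held_out), pred, mode, held_out))
    return CrossValReport(folds, per_fold, mode)


def _subset(annset: AnnotationSet, doc_ids: Sequence[str]) -> AnnotationSet:
    sub = AnnotationSet(annset.annotator_id)
    for d in doc_ids:
        sub.mentions[d] = annset.for_doc(d)
    return sub


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def paired_t_test(scores_a: Sequence[float], scores_b: Sequence[float]
                  ) -> tuple[float, float]:
    """Two-sided paired t-test on fold-wise differences.

    Degenerate limits: identical vectors give (0, 1); a constant nonzero
    difference gives (±inf, 0) — the zero-variance limit of the t
    statistic.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length vectors, n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, diff.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 2")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise ValueError("pearson_r undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Disagreement taxonomy
# ---------------------------------------------------------------------------

@dataclass
class DisagreementReport:
    """Token counts for the three disagreement categories.

    ``boundary``: both annotators mark overlapping same-class mentions
    but with different extents.  ``missed``: one annotator marks a
    mention the other does not touch.  ``category``: both mark the token
    but with different classes.  Every disagreeing token falls in
    exactly one category.
    """

    boundary: int = 0
    missed: int = 0
    category: int = 0

    @property
    def total(self) -> int:
        return self.boundary + self.missed + self.category

    def shares(self) -> dict[str, float]:
        """Category shares in percent (zero when there is no disagreement)."""
        if self.total == 0:
            return {"boundary": 0.0, "missed": 0.0, "category": 0.0}
        return {
            "boundary": 100.0 * self.boundary / self.total,
            "missed": 100.0 * self.missed / self.total,
            "category": 100.0 * self.category / self.total,
        }


def _covering(mentions: Sequence[EntityMention], tok) -> EntityMention | None:
    for m in mentions:
        if m.start <= tok.start and tok.end <= m.end:
            return m
    return None


def disagreement_report(docs: Sequence[Document], ann_a: AnnotationSet,
                        ann_b: AnnotationSet) -> DisagreementReport:
    """Categorize every token on which the two annotators disagree."""
    report = DisagreementReport()
    for doc in docs:
        ms_a = ann_a.for_doc(doc.doc_id)
        ms_b = ann_b.for_doc(doc.doc_id)
        for tok in doc.tokens:
            m_a = _covering(ms_a, tok)
            m_b = _covering(ms_b, tok)
            if m_a is None and m_b is None:
                continue
            if m_a is not None and m_b is not None:
                if m_a.entity_class is not m_b.entity_class:
                    report.category += 1
                continue
            present, absent_side = (m_a, ms_b) if m_a is not None else (m_b, ms_a)
            if any(m.entity_class is present.entity_class and m.overlaps(present)
                   for m in absent_side):
                report.boundary += 1
            else:
                report.missed += 1
    return report
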