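"""Matching, P/R/F1, kappa, cross-validation and statistics."""

import math

import numpy as np
import pytest
from scipy import stats

import adetag as a
from adetag.evaluation import PRF

from conftest import make_doc


AE = a.EntityClass.ADVERSE_EVENT
OSSD = a.EntityClass.OSSD
MED = a.EntityClass.MEDICATION


def m(cls, start, end):
    return a.EntityMention(cls, start, end, "x" * (end - start))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_exact_match_both_modes():
    for mode in ("strict", "unstrict"):
        assert a.match_mentions([m(AE, 10, 25)], [m(AE, 10, 25)], mode) == (1, 0, 0)


def test_partial_overlap_strict_vs_unstrict():
    gold, pred = [m(AE, 10, 25)], [m(AE, 10, 20)]
    assert a.match_mentions(gold, pred, "strict") == (0, 1, 1)
    assert a.match_mentions(gold, pred, "unstrict") == (1, 0, 0)


def test_class_must_agree():
    gold, pred = [m(AE, 10, 25)], [m(OSSD, 10, 25)]
    for mode in ("strict", "unstrict"):
        assert a.match_mentions(gold, pred, mode) == (0, 1, 1)


def test_unstrict_one_to_one():
    # two predictions overlap one gold: only one may match
    gold = [m(AE, 10, 30)]
    pred = [m(AE, 10, 15), m(AE, 20, 30)]
    assert a.match_mentions(gold, pred, "unstrict") == (1, 1, 0)


def test_strict_tp_never_exceeds_unstrict(noisy_corpus):
    docs, gold, _ = noisy_corpus
    sim = a.perturb(docs, gold, a.PerturbConfig(0.3, 0.2, 0.1, seed=1))
    for d in docs:
        ts, _, _ = a.match_mentions(gold.for_doc(d.doc_id), sim.for_doc(d.doc_id),
                                    "strict")
        tu, _, _ = a.match_mentions(gold.for_doc(d.doc_id), sim.for_doc(d.doc_id),
                                    "unstrict")
        assert ts <= tu


# ---------------------------------------------------------------------------
# P / R / F1
# ---------------------------------------------------------------------------

def test_prf_formula():
    r = PRF(tp=3, fp=2, fn=1)
    assert r.precision == 0.6 and r.recall == 0.75
    assert r.f1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)


def test_f1_harmonic_mean_rounds_like_reference():
    """P = 0.81 and R = 0.66 give F1 that prints as 0.73."""
    p, r = 0.81, 0.66
    assert round(2 * p * r / (p + r), 2) == 0.73


def test_prf_identities(noisy_corpus):
    """TP + FN = |gold| and TP + FP = |pred| per class."""
    docs, gold, _ = noisy_corpus
    pred = a.perturb(docs, gold, a.PerturbConfig(0.2, 0.3, 0.05, seed=2))
    for mode in ("strict", "unstrict"):
        rep = a.prf(gold, pred, mode)
        for cls in a.EntityClass:
            n_gold = sum(1 for ms in gold.mentions.values()
                         for x in ms if x.entity_class is cls)
            n_pred = sum(1 for ms in pred.mentions.values()
                         for x in ms if x.entity_class is cls)
            assert rep[cls.value].tp + rep[cls.value].fn == n_gold
            assert rep[cls.value].tp + rep[cls.value].fp == n_pred


def test_perfect_prediction_scores_one(noisy_corpus):
    docs, gold, _ = noisy_corpus
    rep = a.prf(gold, gold, "strict")
    assert rep["overall"].precision == rep["overall"].recall == 1.0


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def _single_token_annset(doc, name, token_indices, cls=AE):
    annset = a.AnnotationSet(name)
    for i in token_indices:
        tok = doc.tokens[i]
        annset.add(doc.doc_id, a.EntityMention(cls, tok.start, tok.end, tok.surface))
    return annset


def test_kappa_identity(noisy_corpus):
    docs, gold, _ = noisy_corpus
    for mode in ("strict", "unstrict"):
        for cls in (AE, MED):
            assert a.cohens_kappa(docs, gold, gold, cls, mode) == pytest.approx(1.0)


def test_kappa_hand_computed_table():
    """45/5/5/45 token agreement table gives kappa = 0.8."""
    doc = make_doc(" ".join(f"w{i}" for i in range(100)))
    ann_a = _single_token_annset(doc, "A", range(0, 50))
    ann_b = _single_token_annset(doc, "B", range(5, 55))
    # table: both=45, A-only=5, B-only=5, neither=45 -> p_o=0.9, p_e=0.5
    assert a.cohens_kappa([doc], ann_a, ann_b, AE, "strict") == pytest.approx(0.8)


def test_kappa_negative_for_systematic_disagreement():
    doc = make_doc(" ".join(f"w{i}" for i in range(100)))
    ann_a = _single_token_annset(doc, "A", range(0, 50))
    ann_b = _single_token_annset(doc, "B", range(50, 100))
    assert a.cohens_kappa([doc], ann_a, ann_b, AE, "strict") < 0


def test_kappa_symmetric(noisy_corpus):
    docs, gold, _ = noisy_corpus
    sim = a.perturb(docs, gold, a.PerturbConfig(seed=4))
    for mode in ("strict", "unstrict"):
        k1 = a.cohens_kappa(docs, gold, sim, AE, mode)
        k2 = a.cohens_kappa(docs, sim, gold, AE, mode)
        assert k1 == pytest.approx(k2)


def test_kappa_unstrict_forgives_boundaries():
    doc = make_doc("a b c d e f")
    ann_a = a.AnnotationSet("A")
    ann_a.add(doc.doc_id, a.EntityMention(AE, 0, 3, doc.text[0:3]))       # "a b"
    ann_b = a.AnnotationSet("B")
    ann_b.add(doc.doc_id, a.EntityMention(AE, 0, 5, doc.text[0:5]))       # "a b c"
    strict = a.cohens_kappa([doc], ann_a, ann_b, AE, "strict")
    unstrict = a.cohens_kappa([doc], ann_a, ann_b, AE, "unstrict")
    assert strict < 1.0
    assert unstrict == pytest.approx(1.0)


def test_kappa_zero_tokens_rejected():
    with pytest.raises(ValueError):
        a.cohens_kappa([], a.AnnotationSet("A"), a.AnnotationSet("B"), AE)


# ---------------------------------------------------------------------------
# folds and cross-validation
# ---------------------------------------------------------------------------

def test_kfold_sizes_122_by_10():
    ids = [f"d{i:03d}" for i in range(122)]
    folds = a.kfold_split(ids, 10, seed=0)
    sizes = sorted(len(folds.fold_doc_ids(f)) for f in range(10))
    assert sizes == [12] * 8 + [13] * 2


def test_kfold_partition_and_determinism():
    ids = [f"d{i}" for i in range(17)]
    f1 = a.kfold_split(ids, 5, seed=3)
    f2 = a.kfold_split(ids, 5, seed=3)
    assert f1 == f2
    all_ids = [d for f in range(5) for d in f1.fold_doc_ids(f)]
    assert sorted(all_ids) == sorted(ids)
    single = a.kfold_split(ids, 1, seed=0)
    assert single.fold_doc_ids(0) == sorted(ids)


def test_cross_validate_gold_passthrough(noisy_corpus):
    """A perfect tagger scores mean F1 = 1, SD = 0; the SD equals the
    population SD of the per-fold vector."""
    docs, gold, _ = noisy_corpus

    def factory(train_docs, ann):
        return lambda doc: ann.for_doc(doc.doc_id)

    rep = a.cross_validate(docs, gold, factory, k=5, seed=0)
    mean, sd = rep.mean_sd("overall", "f1")
    assert mean == 1.0 and sd == 0.0
    per_fold = rep.fold_values("overall", "f1")
    assert sd == pytest.approx(float(np.std(per_fold, ddof=0)))


def test_cross_validate_deterministic(noisy_corpus, resources):
    docs, gold, _ = noisy_corpus
    from adetag.crf import make_tagger_factory
    kw = dict(l2=1.0, max_iter=15, seed=1)
    reps = [
        a.cross_validate(
            docs, gold,
            make_tagger_factory(a.FeatureConfig.default_only(), resources, **kw),
            k=3, seed=1)
        for _ in range(2)
    ]
    assert np.array_equal(reps[0].fold_values("overall", "f1"),
                          reps[1].fold_values("overall", "f1"))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_paired_t_identical_and_constant_shift():
    x = [0.5, 0.6, 0.7, 0.55]
    assert a.paired_t_test(x, x) == (0.0, 1.0)
    t, p = a.paired_t_test([v + 0.1 for v in x], x)
    assert math.isinf(t) and t > 0 and p == 0.0


def test_paired_t_matches_textbook_formula():
    rng = np.random.default_rng(8)
    x = rng.random(10)
    y = rng.random(10)
    t, p = a.paired_t_test(x, y)
    d = x - y
    t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    p_ref = 2 * stats.t.sf(abs(t_ref), df=len(d) - 1)
    assert t == pytest.approx(t_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=1e-10)


def test_pearson_identity_and_guards():
    assert a.pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        a.pearson_r([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        a.pearson_r([1], [2])


def test_pearson_class_frequency_vs_f1_reference_vectors():
    """Published per-class mention counts correlate with per-class F1 at
    r ~ 0.64, and per-class strict kappa at r ~ 0.73."""
    counts = [1646, 1152, 137, 21, 107, 24, 126, 90, 62]
    f1 = [0.72, 0.83, 0.61, 0.59, 0.32, 0.34, 0.65, 0.55, 0.60]
    kappa = [0.83, 0.92, 0.59, 0.58, 0.59, 0.34, 0.76, 0.50, 0.39]
    assert round(a.pearson_r(counts, f1), 2) == 0.64
    assert round(a.pearson_r(kappa, f1), 2) == 0.73


# ---------------------------------------------------------------------------
# disagreement taxonomy
# ---------------------------------------------------------------------------

def test_disagreement_identity_is_zero(noisy_corpus):
    docs, gold, _ = noisy_corpus
    rep = a.disagreement_report(docs, gold, gold)
    assert rep.total == 0


def test_disagreement_three_case_document():
    doc = make_doc("w0 w1 w2 w3 w4 w5 w6 w7")
    t = doc.tokens
    ann_a = a.AnnotationSet("A")
    ann_b = a.AnnotationSet("B")
    # category confusion on w0
    ann_a.add(doc.doc_id, a.EntityMention(AE, t[0].start, t[0].end, "w0"))
    ann_b.add(doc.doc_id, a.EntityMention(OSSD, t[0].start, t[0].end, "w0"))
    # boundary on w2-w3 (A longer than B)
    ann_a.add(doc.doc_id, a.EntityMention(AE, t[2].start, t[3].end, "w2 w3"))
    ann_b.add(doc.doc_id, a.EntityMention(AE, t[2].start, t[2].end, "w2"))
    # missed on w5
    ann_a.add(doc.doc_id, a.EntityMention(MED, t[5].start, t[5].end, "w5"))
    rep = a.disagreement_report([doc], ann_a, ann_b)
    assert (rep.boundary, rep.missed, rep.category) == (1, 1, 1)


def test_disagreement_partitions_disagreeing_tokens(noisy_corpus):
    docs, gold, _ = noisy_corpus
    sim = a.perturb(docs, gold, a.PerturbConfig(0.2, 0.3, 0.1, seed=9))
    rep = a.disagreement_report(docs, gold, sim)
    # recount disagreeing tokens directly
    n_disagree = 0
    for doc in docs:
        for tok in doc.tokens:
            ca = next((x.entity_class for x in gold.for_doc(doc.doc_id)
                       if x.start <= tok.start and tok.end <= x.end), None)
            cb = next((x.entity_class for x in sim.for_doc(doc.doc_id)
                       if x.start <= tok.start and tok.end <= x.end), None)
            if ca is not cb:
                n_disagree += 1
    assert rep.total == n_disagree
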