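"""CRF inference against exhaustive enumeration, gradient correctness,
and training behaviour."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

import adetag as a
from adetag.corpus import LABEL_STRINGS, BioLabel
from adetag.crf import (
    CRFModel,
    Lattice,
    TrainingError,
    bio_transition_mask,
    build_lattice,
    log_partition,
    marginals,
    nll_and_gradient,
    viterbi,
)
from adetag.features import FeatureConfig, FeatureVector

from conftest import make_doc


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_lattice(lat: Lattice):
    """Exhaustive path enumeration: log Z, best path, node/pair marginals."""
    T, L = lat.unary.shape
    scores = {}
    for path in itertools.product(range(L), repeat=T):
        s = lat.begin[path[0]] + lat.end[path[-1]]
        for t, y in enumerate(path):
            s += lat.unary[t, y]
            if t:
                s += lat.trans[path[t - 1], y]
        scores[path] = s
    vals = np.array(list(scores.values()))
    log_z = logsumexp(vals)
    best_path = min((p for p, s in scores.items()
                     if math.isclose(s, max(vals), abs_tol=1e-12)))
    node = np.zeros((T, L))
    pair = np.zeros((max(T - 1, 0), L, L))
    for path, s in scores.items():
        w = np.exp(s - log_z)
        for t, y in enumerate(path):
            node[t, y] += w
            if t:
                pair[t - 1, path[t - 1], y] += w
    return log_z, best_path, max(vals), node, pair


def random_lattice(rng, T, L, mask_frac=0.0):
    # continuous scores: optimal paths are unique almost surely, so the
    # enumeration argmax is well-defined for comparison
    unary = rng.normal(size=(T, L))
    trans = rng.normal(size=(L, L))
    begin = rng.normal(size=L)
    end = rng.normal(size=L)
    if mask_frac:
        m = rng.random(size=(L, L)) < mask_frac
        # keep at least one incoming transition per label
        for j in range(L):
            if m[:, j].all():
                m[rng.integers(L), j] = False
        trans[m] = -np.inf
    return Lattice(unary, trans, begin, end)


def test_oracle_equivalence_random_lattices():
    """log Z, Viterbi and marginals match enumeration on 200 random
    lattices of up to 4 positions x 4 labels."""
    rng = np.random.default_rng(42)
    for i in range(200):
        T = int(rng.integers(1, 5))
        L = int(rng.integers(2, 5))
        lat = random_lattice(rng, T, L, mask_frac=0.2 if i % 3 == 0 else 0.0)
        log_z_ref, best_ref, best_score_ref, node_ref, pair_ref = enumerate_lattice(lat)
        assert abs(log_partition(lat) - log_z_ref) < 1e-9
        path, score = viterbi(lat)
        assert abs(score - best_score_ref) < 1e-9
        assert tuple(path) == best_ref
        node, pair = marginals(lat)
        assert np.abs(node - node_ref).max() < 1e-9
        assert np.abs(pair - pair_ref).max(initial=0.0) < 1e-9


def test_log_partition_closed_forms():
    lat = Lattice(np.zeros((1, 2)), np.zeros((2, 2)), np.zeros(2), np.zeros(2))
    assert abs(log_partition(lat) - math.log(2)) < 1e-12
    rng = np.random.default_rng(0)
    lat2 = random_lattice(rng, 2, 2)
    # brute force over the 4 paths
    ref = logsumexp([lat2.begin[i] + lat2.unary[0, i] + lat2.trans[i, j]
                     + lat2.unary[1, j] + lat2.end[j]
                     for i in range(2) for j in range(2)])
    assert abs(log_partition(lat2) - ref) < 1e-12
    _, vit = viterbi(lat2)
    assert log_partition(lat2) >= vit


def test_marginals_uniform_and_normalized():
    lat = Lattice(np.zeros((3, 4)), np.zeros((4, 4)), np.zeros(4), np.zeros(4))
    node, pair = marginals(lat)
    assert np.allclose(node, 0.25)
    assert np.allclose(node.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(pair.sum(axis=(1, 2)), 1.0, atol=1e-9)


def test_masked_cells_have_zero_posterior():
    trans = np.zeros((2, 2))
    trans[0, 1] = -np.inf
    lat = Lattice(np.zeros((2, 2)), trans, np.zeros(2), np.zeros(2))
    _, pair = marginals(lat)
    assert pair[0, 0, 1] == 0.0


# ---------------------------------------------------------------------------
# lattice construction and decoding contracts
# ---------------------------------------------------------------------------

def _fv(*feats):
    return [FeatureVector(i, frozenset(fs)) for i, fs in enumerate(feats)]


def test_build_lattice_dot_product():
    model = CRFModel.empty(["f1", "f2"], mask_illegal=False)
    model.w_unary[model.feature_index["f1"]][LABEL_STRINGS.index("B-AdverseEvent")] = 2.0
    lat = build_lattice(_fv({"f1"}, {"f1", "f2"}, {"unseen"}), model)
    j = LABEL_STRINGS.index("B-AdverseEvent")
    assert lat.unary[0, j] == 2.0 and lat.unary[1, j] == 2.0
    assert np.all(lat.unary[2] == 0.0)


def test_zero_model_decodes_all_o(resources):
    doc = make_doc("The patient received paclitaxel .")
    model = CRFModel.empty([], feature_config=FeatureConfig.default_only())
    assert a.tag(doc, model, resources) == []  # all-O via the O-first tie break


def test_masked_lattice_forbids_illegal_bigrams():
    rng = np.random.default_rng(5)
    model = CRFModel.empty(["f"], mask_illegal=True)
    model.set_weights(rng.normal(size=model.n_parameters))
    lat = build_lattice(_fv({"f"}, {"f"}, {"f"}, {"f"}), model)
    path, _ = viterbi(lat)
    allowed, start = bio_transition_mask(LABEL_STRINGS)
    assert start[path[0]]
    for prev, cur in zip(path, path[1:]):
        assert allowed[prev, cur]


# ---------------------------------------------------------------------------
# objective and gradient
# ---------------------------------------------------------------------------

def _random_valid_labels(rng, n):
    allowed, start = bio_transition_mask(LABEL_STRINGS)
    seq = []
    prev = None
    for t in range(n):
        opts = [i for i in range(len(LABEL_STRINGS))
                if (start[i] if prev is None else allowed[prev, i])]
        prev = int(rng.choice(opts))
        seq.append(prev)
    return [BioLabel.parse(LABEL_STRINGS[i]) for i in seq]


def _random_instance(rng, n_feats=5, n_tok=3, mask=True, l2=0.0):
    feats = [f"f{i}" for i in range(n_feats)]
    model = CRFModel.empty(feats, l2=l2, mask_illegal=mask)
    model.set_weights(rng.normal(scale=0.5, size=model.n_parameters))
    fvs = _fv(*[{f for f in feats if rng.random() < 0.5} for _ in range(n_tok)])
    labels = _random_valid_labels(rng, n_tok)
    return model, [(fvs, labels)]


def test_objective_at_zero_weights_closed_form():
    rng = np.random.default_rng(1)
    model, batch = _random_instance(rng, mask=False)
    model.set_weights(np.zeros(model.n_parameters))
    val, _ = nll_and_gradient(model, batch)
    n_tok = len(batch[0][0])
    assert abs(val - n_tok * math.log(len(LABEL_STRINGS))) < 1e-9


def test_gradient_matches_central_differences():
    """Analytic gradient vs central differences on 50 random instances."""
    rng = np.random.default_rng(2024)
    h = 1e-6
    for i in range(50):
        model, batch = _random_instance(
            rng, n_feats=int(rng.integers(2, 6)), n_tok=int(rng.integers(1, 5)),
            mask=bool(i % 2), l2=float(rng.choice([0.0, 0.7])))
        val, grad = nll_and_gradient(model, batch)
        w0 = model.get_weights()
        coords = rng.choice(w0.size, size=min(25, w0.size), replace=False)
        for j in coords:
            wp = w0.copy(); wp[j] += h
            wm = w0.copy(); wm[j] -= h
            model.set_weights(wp)
            fp, _ = nll_and_gradient(model, batch)
            model.set_weights(wm)
            fm, _ = nll_and_gradient(model, batch)
            num = (fp - fm) / (2 * h)
            assert abs(grad[j] - num) / (1 + abs(num)) < 1e-5
            model.set_weights(w0)


def test_gold_label_outside_alphabet_rejected():
    model = CRFModel.empty(["f"], labels=("O", "B-Medication"))
    fvs = _fv({"f"})
    labels = [BioLabel.parse("B-AdverseEvent")]
    with pytest.raises(TrainingError):
        nll_and_gradient(model, [(fvs, labels)])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_train_zero_iterations_is_zero_model(small_corpus, resources):
    docs, gold, _ = small_corpus
    model = a.train(docs[:2], gold, FeatureConfig.default_only(), resources,
                    max_iter=0)
    assert not model.get_weights().any()
    assert a.tag(docs[0], model, resources) == []


def test_train_requires_documents(resources):
    with pytest.raises(TrainingError):
        a.train([], a.AnnotationSet("gold"), FeatureConfig.default_only(),
                resources)


def test_training_fits_separable_corpus(small_corpus, resources):
    """On noise-free template data the trained tagger reproduces its
    training annotations exactly."""
    docs, gold, _ = small_corpus
    model = a.train(docs, gold, FeatureConfig.all_families(), resources)
    pred = a.AnnotationSet("pred")
    for d in docs:
        for m in a.tag(d, model, resources):
            pred.add(d.doc_id, m)
    assert a.prf(gold, pred)["overall"].f1 == 1.0
    # objective decreased from its zero-weight starting value
    zero = CRFModel.empty([], feature_config=model.feature_config)
    assert model.metadata["final_objective"] < sum(
        len(d.tokens) for d in docs) * math.log(19)


def test_training_deterministic(tmp_path, small_corpus, resources):
    docs, gold, _ = small_corpus
    kw = dict(l2=1.0, max_iter=30, seed=5)
    m1 = a.train(docs[:4], gold, FeatureConfig.default_only(), resources, **kw)
    m2 = a.train(docs[:4], gold, FeatureConfig.default_only(), resources, **kw)
    m1.save(tmp_path / "m1.json")
    m2.save(tmp_path / "m2.json")
    assert (tmp_path / "m1.json").read_bytes() == (tmp_path / "m2.json").read_bytes()


def test_model_serialization_round_trip(tmp_path, small_corpus, resources):
    docs, gold, _ = small_corpus
    model = a.train(docs[:3], gold, FeatureConfig.default_only(), resources,
                    max_iter=20)
    model.save(tmp_path / "model.json")
    loaded = CRFModel.load(tmp_path / "model.json")
    assert loaded.labels == model.labels
    assert np.array_equal(loaded.w_unary, model.w_unary)
    assert [m.surface for m in a.tag(docs[0], loaded, resources)] == \
           [m.surface for m in a.tag(docs[0], model, resources)]


def test_tagged_mentions_never_overlap(noisy_corpus, resources):
    docs, gold, _ = noisy_corpus
    model = a.train(docs[:8], gold, FeatureConfig.default_only(), resources,
                    max_iter=40)
    for d in docs:
        pred = a.AnnotationSet("p")
        for m in a.tag(d, model, resources):
            pred.add(d.doc_id, m)  # AnnotationSet.add raises on overlap


def test_heldout_f1_grows_with_training_size(resources):
    """More training documents help held-out F1 on generated corpora."""
    docs, gold, _ = a.generate(a.GeneratorConfig(n_docs=60, seed=11))
    test_docs = docs[48:]
    scores = []
    for n_train in (8, 48):
        model = a.train(docs[:n_train], gold, FeatureConfig.default_only(),
                        resources, max_iter=80)
        pred = a.AnnotationSet("p")
        for d in test_docs:
            for m in a.tag(d, model, resources):
                pred.add(d.doc_id, m)
        scores.append(a.prf(_subset(gold, [d.doc_id for d in test_docs]),
                            pred)["overall"].f1)
    assert scores[1] > scores[0]


def _subset(annset, doc_ids):
    sub = a.AnnotationSet(annset.annotator_id)
    for d in doc_ids:
        sub.mentions[d] = annset.for_doc(d)
    return sub
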