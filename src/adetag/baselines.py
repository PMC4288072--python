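"""Reference taggers: dictionary matching and a per-token Naive Bayes.

The dictionary baseline tags every longest lexicon match whose semantic
type maps to an entity class — in practice Medication (T200) and
AdverseEvent (T047) — and never emits the other seven classes.  It marks
the floor that context-free term lookup achieves on this task.

The Naive-Bayes baseline classifies each token independently from its
indicator features (multinomial model, add-one smoothing), then repairs
the label sequence into valid BIO; it shows what dropping the sequence
model costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.naive_bayes import MultinomialNB

from .corpus import (
    LABEL_STRINGS,
    BioLabel,
    Document,
    EntityMention,
    decode_bio,
)
from .features import FeatureConfig, FeatureVector, Resources, extract
from .lexicons import SemanticLexicon, longest_match


def basedict_tag(doc: Document, lexicon: SemanticLexicon) -> list[EntityMention]:
    """Tag all longest lexicon matches whose type maps to an entity class."""
    mentions: list[EntityMention] = []
    for (first, stop), code in longest_match(doc.tokens, lexicon):
        cls = lexicon.type_to_class.get(code)
        if cls is None:
            continue
        start = doc.tokens[first].start
        end = doc.tokens[stop - 1].end
        mentions.append(EntityMention(cls, start, end, doc.text[start:end]))
    return mentions


@dataclass
class NBModel:
    """Per-token multinomial Naive Bayes over indicator features."""

    classifier: MultinomialNB
    feature_index: dict[str, int]
    labels: tuple[str, ...]
    #: column permutation mapping classifier class order to ``labels`` order
    class_order: np.ndarray
    feature_config: FeatureConfig


def _vectorize(batch: Sequence[Sequence[FeatureVector]],
               feature_index: dict[str, int]) -> sparse.csr_matrix:
    rows, cols = [], []
    n_tok = 0
    for fvs in batch:
        for fv in fvs:
            for f in fv.features:
                j = feature_index.get(f)
                if j is not None:
                    rows.append(n_tok)
                    cols.append(j)
            n_tok += 1
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(n_tok, max(len(feature_index), 1))
    )


def nb_train(batch: Sequence[tuple[Sequence[FeatureVector], Sequence[BioLabel]]],
             alpha: float = 1.0,
             feature_config: FeatureConfig | None = None) -> NBModel:
    """Fit the NB baseline on (features, BIO labels) pairs.

    ``alpha`` is the additive smoothing constant; 1.0 is add-one
    smoothing and the constant must be positive.
    """
    if alpha <= 0:
        raise ValueError("smoothing constant must be > 0")
    if not batch:
        raise ValueError("empty training set")
    feature_index: dict[str, int] = {}
    y: list[str] = []
    for fvs, labels in batch:
        if len(fvs) != len(labels):
            raise ValueError("feature/label length mismatch")
        for fv, lab in zip(fvs, labels):
            for f in sorted(fv.features):
                feature_index.setdefault(f, len(feature_index))
            y.append(str(lab))
    X = _vectorize([fvs for fvs, _ in batch], feature_index)
    clf = MultinomialNB(alpha=alpha)
    clf.fit(X, np.asarray(y))
    # permutation from sklearn's class order into the canonical label order;
    # absent labels map to column -1 (filled with -inf at predict time)
    order = np.full(len(LABEL_STRINGS), -1, dtype=int)
    for j, cls in enumerate(clf.classes_):
        order[LABEL_STRINGS.index(cls)] = j
    return NBModel(clf, feature_index, LABEL_STRINGS, order,
                   feature_config or FeatureConfig())


def nb_predict_labels(model: NBModel, fvs: Sequence[FeatureVector]) -> list[BioLabel]:
    """Per-token argmax of class log-posteriors; ties break to the first
    label in the canonical alphabet (O)."""
    if not fvs:
        return []
    X = _vectorize([fvs], model.feature_index)
    log_proba = model.classifier.predict_log_proba(X)
    full = np.full((X.shape[0], len(model.labels)), -np.inf)
    present = model.class_order >= 0
    full[:, present] = log_proba[:, model.class_order[present]]
    return [BioLabel.parse(model.labels[i]) for i in np.argmax(full, axis=1)]


def nb_tag(doc: Document, model: NBModel, resources: Resources | None = None
           ) -> list[EntityMention]:
    """Tag one document with the NB baseline (BIO repair at decode time)."""
    if not doc.tokens:
        return []
    fvs = extract(doc, model.feature_config, resources or Resources())
    return decode_bio(doc, nb_predict_labels(model, fvs))
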