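"""Linear-chain conditional random field, implemented from first principles.

The model scores a label sequence y for a token sequence x as

    score(y | x) = b[y_1] + sum_t U(t, y_t) + sum_t T[y_{t-1}, y_t] + e[y_T]

where the unary score U(t, y) is the sum of weights of the indicator
features active at position t paired with label y, T holds
label-bigram weights and b/e are begin/end potentials.  Training
maximizes the l2-regularized conditional log-likelihood with L-BFGS;
inference (forward recursion for the partition function,
forward-backward for posteriors, Viterbi for decoding) runs entirely in
log space.

Transitions that violate the BIO grammar (O→I-X, B-Y→I-X and I-Y→I-X
for Y≠X, and I-X at sequence start) are hard-masked to −∞ by default so
decoded sequences are always well-formed; the mask can be switched off
to mimic unconstrained taggers, in which case the decoder's repair rule
picks up any stray I labels.

All dynamic-programming kernels are numba-compiled; they are generic in
the number of labels, which the enumeration-based tests exploit on tiny
lattices.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .corpus import (
    LABEL_STRINGS,
    AnnotationSet,
    BioLabel,
    Document,
    EntityMention,
    decode_bio,
    encode_bio,
)
from .features import FeatureConfig, FeatureVector, Resources, extract

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: internal always-on feature so every position has at least one active
#: indicator (acts as a per-label bias)
_BIAS = "__bias__"


class TrainingError(RuntimeError):
    """Training cannot proceed (empty data, bad labels, diverging objective)."""


# ---------------------------------------------------------------------------
# Label grammar mask
# ---------------------------------------------------------------------------

def bio_transition_mask(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(allowed label-bigram matrix, allowed start vector) for a BIO alphabet."""
    n = len(labels)
    allowed = np.ones((n, n), dtype=bool)
    start = np.ones(n, dtype=bool)
    for j, lab in enumerate(labels):
        if not lab.startswith("I-"):
            continue
        cls = lab[2:]
        start[j] = False
        for i, prev in enumerate(labels):
            if prev not in (f"B-{cls}", f"I-{cls}"):
                allowed[i, j] = False
    return allowed, start


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class CRFModel:
    """A trained (or freshly initialized) CRF.

    ``feature_index`` maps feature strings to rows of the unary weight
    matrix ``w_unary`` (one column per label); ``w_trans`` holds
    label-bigram weights and ``w_begin``/``w_end`` the boundary
    potentials.  Together these realize one weight per (feature, label)
    pair and per (label, label) pair.
    """

    labels: tuple[str, ...]
    feature_index: dict[str, int]
    w_unary: np.ndarray
    w_trans: np.ndarray
    w_begin: np.ndarray
    w_end: np.ndarray
    l2: float = 1.0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    mask_illegal: bool = True
    metadata: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, feature_strings: Sequence[str],
              labels: Sequence[str] = LABEL_STRINGS,
              l2: float = 1.0,
              feature_config: FeatureConfig | None = None,
              mask_illegal: bool = True) -> "CRFModel":
        index = {_BIAS: 0}
        for f in feature_strings:
            if f not in index:
                index[f] = len(index)
        n_lab = len(labels)
        return cls(
            labels=tuple(labels),
            feature_index=index,
            w_unary=np.zeros((len(index), n_lab)),
            w_trans=np.zeros((n_lab, n_lab)),
            w_begin=np.zeros(n_lab),
            w_end=np.zeros(n_lab),
            l2=l2,
            feature_config=feature_config or FeatureConfig(),
            mask_illegal=mask_illegal,
        )

    @property
    def n_parameters(self) -> int:
        n = len(self.labels)
        return self.w_unary.size + n * n + 2 * n

    # -- parameter vector <-> structured weights ----------------------------

    def get_weights(self) -> np.ndarray:
        return np.concatenate([
            self.w_unary.ravel(), self.w_trans.ravel(),
            self.w_begin, self.w_end,
        ])

    def set_weights(self, w: np.ndarray) -> None:
        n = len(self.labels)
        f = self.w_unary.shape[0]
        if w.size != self.n_parameters:
            raise ValueError("weight vector length mismatch")
        self.w_unary = w[: f * n].reshape(f, n).copy()
        off = f * n
        self.w_trans = w[off : off + n * n].reshape(n, n).copy()
        off += n * n
        self.w_begin = w[off : off + n].copy()
        self.w_end = w[off + n :].copy()

    # -- serialization -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "labels": list(self.labels),
            "feature_index": self.feature_index,
            "w_unary": self.w_unary.tolist(),
            "w_trans": self.w_trans.tolist(),
            "w_begin": self.w_begin.tolist(),
            "w_end": self.w_end.tolist(),
            "l2": self.l2,
            "feature_config": {
                "families": sorted(self.feature_config.families),
                "window": self.feature_config.window,
            },
            "mask_illegal": self.mask_illegal,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CRFModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        return cls(
            labels=tuple(payload["labels"]),
            feature_index={k: int(v) for k, v in payload["feature_index"].items()},
            w_unary=np.asarray(payload["w_unary"], dtype=float),
            w_trans=np.asarray(payload["w_trans"], dtype=float),
            w_begin=np.asarray(payload["w_begin"], dtype=float),
            w_end=np.asarray(payload["w_end"], dtype=float),
            l2=float(payload["l2"]),
            feature_config=FeatureConfig(
                frozenset(payload["feature_config"]["families"]),
                int(payload["feature_config"]["window"]),
            ),
            mask_illegal=bool(payload["mask_illegal"]),
            metadata=payload.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

@dataclass
class Lattice:
    """Log-space scores: per-position unary, shared transition, boundary."""

    unary: np.ndarray   # (T, L)
    trans: np.ndarray   # (L, L), −inf where masked
    begin: np.ndarray   # (L,)
    end: np.ndarray     # (L,)

    @property
    def n_positions(self) -> int:
        return self.unary.shape[0]

    @property
    def n_labels(self) -> int:
        return self.unary.shape[1]


def build_lattice(features: Sequence[FeatureVector], model: CRFModel) -> Lattice:
    """Score a feature-extracted token sequence under the model.

    Unseen feature strings contribute 0; duplicate features cannot occur
    (feature sets).  Masked transitions score −∞.
    """
    n_lab = len(model.labels)
    unary = np.zeros((len(features), n_lab))
    for t, fv in enumerate(features):
        unary[t] += model.w_unary[0]  # bias row
        for f in fv.features:
            row = model.feature_index.get(f)
            if row is not None:
                unary[t] += model.w_unary[row]
    trans = model.w_trans.copy()
    begin = model.w_begin.copy()
    if model.mask_illegal:
        allowed, start = bio_transition_mask(model.labels)
        trans[~allowed] = -np.inf
        begin[~start] = -np.inf
    return Lattice(unary, trans, begin, model.w_end.copy())


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lse(v):  # log-sum-exp of a 1-d array, −inf-safe
    m = -np.inf
    for x in v:
        if x > m:
            m = x
    if m == -np.inf:
        return -np.inf
    s = 0.0
    for x in v:
        s += np.exp(x - m)
    return m + np.log(s)


@njit(cache=True)
def _forward(unary, trans, begin, end):
    T, L = unary.shape
    alpha = np.empty((T, L))
    for y in range(L):
        alpha[0, y] = begin[y] + unary[0, y]
    tmp = np.empty(L)
    for t in range(1, T):
        for y in range(L):
            for yp in range(L):
                tmp[yp] = alpha[t - 1, yp] + trans[yp, y]
            alpha[t, y] = _lse(tmp) + unary[t, y]
    for y in range(L):
        tmp[y] = alpha[T - 1, y] + end[y]
    return alpha, _lse(tmp)


@njit(cache=True)
def _backward(unary, trans, end):
    T, L = unary.shape
    beta = np.empty((T, L))
    for y in range(L):
        beta[T - 1, y] = end[y]
    tmp = np.empty(L)
    for t in range(T - 2, -1, -1):
        for y in range(L):
            for yn in range(L):
                tmp[yn] = trans[y, yn] + unary[t + 1, yn] + beta[t + 1, yn]
            beta[t, y] = _lse(tmp)
    return beta


@njit(cache=True)
def _viterbi(unary, trans, begin, end):
    T, L = unary.shape
    delta = np.empty((T, L))
    back = np.zeros((T, L), dtype=np.int64)
    for y in range(L):
        delta[0, y] = begin[y] + unary[0, y]
    for t in range(1, T):
        for y in range(L):
            best = -np.inf
            arg = 0
            for yp in range(L):
                s = delta[t - 1, yp] + trans[yp, y]
                if s > best:  # strict: ties keep the lowest label index
                    best = s
                    arg = yp
            delta[t, y] = best + unary[t, y]
            back[t, y] = arg
    best = -np.inf
    arg = 0
    for y in range(L):
        s = delta[T - 1, y] + end[y]
        if s > best:
            best = s
            arg = y
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = arg
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, best


@njit(cache=True)
def _doc_nll_grad(w_unary, trans, begin, end, feat_flat, feat_off, gold,
                  g_unary, g_trans, g_begin, g_end):
    """NLL of one sequence plus in-place gradient accumulation.

    ``feat_flat``/``feat_off`` give each position's feature rows of
    ``w_unary`` (CSR style; row 0 is the implicit always-on bias).
    ``g_unary`` receives expected-minus-observed counts.
    """
    T = len(feat_off) - 1
    L = trans.shape[0]
    unary = np.empty((T, L))
    for t in range(T):
        for y in range(L):
            unary[t, y] = w_unary[0, y]
        for k in range(feat_off[t], feat_off[t + 1]):
            row = feat_flat[k]
            for y in range(L):
                unary[t, y] += w_unary[row, y]
    alpha, log_z = _forward(unary, trans, begin, end)
    if log_z == -np.inf:
        return np.inf
    beta = _backward(unary, trans, end)

    # node posteriors and unary/bias/boundary gradients
    for t in range(T):
        for y in range(L):
            p = np.exp(alpha[t, y] + beta[t, y] - log_z)
            g_unary[0, y] += p
            for k in range(feat_off[t], feat_off[t + 1]):
                g_unary[feat_flat[k], y] += p
            if t == 0:
                g_begin[y] += p
            if t == T - 1:
                g_end[y] += p
        yg = gold[t]
        g_unary[0, yg] -= 1.0
        for k in range(feat_off[t], feat_off[t + 1]):
            g_unary[feat_flat[k], yg] -= 1.0
    g_begin[gold[0]] -= 1.0
    g_end[gold[T - 1]] -= 1.0

    # pairwise posteriors and transition gradient
    for t in range(1, T):
        for yp in range(L):
            a = alpha[t - 1, yp]
            if a == -np.inf:
                continue
            for y in range(L):
                s = trans[yp, y]
                if s == -np.inf:
                    continue
                g_trans[yp, y] += np.exp(a + s + unary[t, y] + beta[t, y] - log_z)
        g_trans[gold[t - 1], gold[t]] -= 1.0

    # gold path score
    score = begin[gold[0]] + end[gold[T - 1]]
    for t in range(T):
        score += unary[t, gold[t]]
        if t > 0:
            score += trans[gold[t - 1], gold[t]]
    return log_z - score


# ---------------------------------------------------------------------------
# Public inference API
# ---------------------------------------------------------------------------

def log_partition(lattice: Lattice) -> float:
    """log Z: log of the summed exponentiated scores of all label paths."""
    if lattice.n_positions < 1:
        raise ValueError("lattice must have at least one position")
    _, log_z = _forward(lattice.unary, lattice.trans, lattice.begin, lattice.end)
    if log_z == -np.inf:
        warnings.warn("all label paths are masked; log partition is -inf")
    return float(log_z)


def viterbi(lattice: Lattice) -> tuple[list[int], float]:
    """An argmax label path and its score; ties break to the lowest label index."""
    if lattice.n_positions < 1:
        raise ValueError("lattice must have at least one position")
    path, score = _viterbi(lattice.unary, lattice.trans, lattice.begin, lattice.end)
    if score == -np.inf:
        warnings.warn("all label paths are masked; Viterbi score is -inf")
    return [int(y) for y in path], float(score)


def marginals(lattice: Lattice) -> tuple[np.ndarray, np.ndarray]:
    """(node posteriors (T, L), transition posteriors (T−1, L, L))."""
    unary, trans = lattice.unary, lattice.trans
    alpha, log_z = _forward(unary, trans, lattice.begin, lattice.end)
    if log_z == -np.inf:
        raise ValueError("all label paths are masked; marginals undefined")
    beta = _backward(unary, trans, lattice.end)
    node = np.exp(alpha + beta - log_z)
    T, L = unary.shape
    pair = np.zeros((max(T - 1, 0), L, L))
    for t in range(1, T):
        with np.errstate(invalid="ignore"):
            logp = (alpha[t - 1][:, None] + trans
                    + unary[t][None, :] + beta[t][None, :] - log_z)
        pair[t - 1] = np.where(np.isneginf(trans), 0.0, np.exp(logp))
    return node, pair


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _compile_sequence(model: CRFModel,
                      features: Sequence[FeatureVector],
                      labels: Sequence[BioLabel] | None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map one document's features (and gold labels) to index arrays."""
    flat: list[int] = []
    off = [0]
    for fv in features:
        rows = sorted(
            r for r in (model.feature_index.get(f) for f in fv.features)
            if r is not None
        )
        flat.extend(rows)
        off.append(len(flat))
    gold = np.zeros(len(features), dtype=np.int64)
    if labels is not None:
        for t, lab in enumerate(labels):
            s = str(lab)
            if s not in model.labels:
                raise TrainingError(f"label {s} outside the model alphabet")
            gold[t] = model.labels.index(s)
    return (np.asarray(flat, dtype=np.int64), np.asarray(off, dtype=np.int64), gold)


def nll_and_gradient(model: CRFModel,
                     batch: Sequence[tuple[Sequence[FeatureVector], Sequence[BioLabel]]],
                     ) -> tuple[float, np.ndarray]:
    """l2-regularized negative conditional log-likelihood and its gradient.

    objective = Σ_docs (log Z − gold path score) + (l2/2)·‖w‖²;
    gradient = expected − observed feature counts + l2·w.
    """
    compiled = [_compile_sequence(model, fvs, labels) for fvs, labels in batch]
    return _nll_grad_compiled(model, compiled)


def _nll_grad_compiled(model: CRFModel,
                       compiled: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
                       ) -> tuple[float, np.ndarray]:
    n_lab = len(model.labels)
    trans = model.w_trans.copy()
    begin = model.w_begin.copy()
    if model.mask_illegal:
        allowed, start = bio_transition_mask(model.labels)
        trans[~allowed] = -np.inf
        begin[~start] = -np.inf

    g_unary = np.zeros_like(model.w_unary)
    g_trans = np.zeros((n_lab, n_lab))
    g_begin = np.zeros(n_lab)
    g_end = np.zeros(n_lab)
    nll = 0.0
    for flat, off, gold in compiled:
        if len(off) - 1 == 0:
            continue
        nll += _doc_nll_grad(model.w_unary, trans, begin, model.w_end,
                             flat, off, gold,
                             g_unary, g_trans, g_begin, g_end)
    if not np.isfinite(nll):
        raise TrainingError("non-finite training objective")

    w = model.get_weights()
    grad = np.concatenate([g_unary.ravel(), g_trans.ravel(), g_begin, g_end])
    # masked transition/begin weights are unused by the lattice; freeze them
    if model.mask_illegal:
        allowed, start = bio_transition_mask(model.labels)
        gt = grad[model.w_unary.size : model.w_unary.size + n_lab * n_lab]
        gt[~allowed.ravel()] = 0.0
        gb = grad[model.w_unary.size + n_lab * n_lab :
                  model.w_unary.size + n_lab * n_lab + n_lab]
        gb[~start] = 0.0
        reg_mask = np.ones_like(w)
        reg_mask[model.w_unary.size : model.w_unary.size + n_lab * n_lab] = allowed.ravel()
        reg_mask[model.w_unary.size + n_lab * n_lab :
                 model.w_unary.size + n_lab * n_lab + n_lab] = start
        nll += 0.5 * model.l2 * float(np.sum((w * reg_mask) ** 2))
        grad += model.l2 * w * reg_mask
    else:
        nll += 0.5 * model.l2 * float(w @ w)
        grad += model.l2 * w
    return float(nll), grad


def train(docs: Sequence[Document],
          annotations: AnnotationSet,
          feature_config: FeatureConfig | None = None,
          resources: Resources | None = None,
          *,
          l2: float = 1.0,
          max_iter: int = 200,
          tol: float = 1e-5,
          seed: int = 0,
          mask_illegal: bool = True,
          precomputed_features: Sequence[Sequence[FeatureVector]] | None = None,
          ) -> CRFModel:
    """Fit a CRF on annotated documents.

    Deterministic given the corpus order, configuration and seed.  The
    optimizer is L-BFGS-B on the full-batch objective, stopped when the
    projected gradient's max-norm falls below ``tol`` or after
    ``max_iter`` iterations.
    """
    if not docs:
        raise TrainingError("training requires at least one annotated document")
    if l2 < 0:
        raise TrainingError("l2 must be >= 0")
    feature_config = feature_config or FeatureConfig()
    resources = resources or Resources()

    if precomputed_features is None:
        precomputed_features = [extract(d, feature_config, resources) for d in docs]
    gold_labels = [encode_bio(d, annotations.for_doc(d.doc_id)) for d in docs]

    vocab: list[str] = []
    seen: set[str] = set()
    for fvs in precomputed_features:
        for fv in fvs:
            for f in sorted(fv.features):
                if f not in seen:
                    seen.add(f)
                    vocab.append(f)
    model = CRFModel.empty(vocab, l2=l2, feature_config=feature_config,
                           mask_illegal=mask_illegal)
    model.metadata = {"seed": seed, "n_docs": len(docs), "iterations": 0,
                      "final_objective": None}
    if max_iter == 0:
        return model

    compiled = [
        _compile_sequence(model, fvs, labels)
        for fvs, labels in zip(precomputed_features, gold_labels)
    ]

    trace: list[float] = []

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        model.set_weights(w)
        val, grad = _nll_grad_compiled(model, compiled)
        trace.append(val)
        return val, grad

    result = minimize(
        objective,
        model.get_weights(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "maxfun": 10 * max_iter + 50,
                 "maxls": 40},
    )
    model.set_weights(result.x)
    model.metadata.update(
        iterations=int(result.nit),
        final_objective=float(result.fun),
        converged=bool(result.success),
    )
    logger.info("CRF training: %d iterations, objective %.4f (%s)",
                result.nit, result.fun, result.message)
    return model


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

def make_tagger_factory(feature_config: FeatureConfig,
                        resources: Resources,
                        *,
                        l2: float = 1.0,
                        max_iter: int = 200,
                        tol: float = 1e-5,
                        seed: int = 0,
                        mask_illegal: bool = True,
                        feature_cache: dict | None = None):
    """A ``(train_docs, gold) -> (doc -> mentions)`` factory for
    cross-validation, with per-document feature caching across folds
    (feature extraction does not depend on the fold split)."""
    cache: dict[str, list[FeatureVector]] = feature_cache if feature_cache is not None else {}

    def features_for(doc: Document) -> list[FeatureVector]:
        if doc.doc_id not in cache:
            cache[doc.doc_id] = extract(doc, feature_config, resources)
        return cache[doc.doc_id]

    def factory(train_docs: Sequence[Document], gold: AnnotationSet):
        model = train(
            train_docs, gold, feature_config, resources,
            l2=l2, max_iter=max_iter, tol=tol, seed=seed,
            mask_illegal=mask_illegal,
            precomputed_features=[features_for(d) for d in train_docs],
        )
        return lambda doc: tag(doc, model, resources,
                               precomputed_features=features_for(doc))

    return factory


def tag(doc: Document, model: CRFModel, resources: Resources | None = None,
        precomputed_features: Sequence[FeatureVector] | None = None,
        ) -> list[EntityMention]:
    """Tag one document: extract → lattice → Viterbi → BIO decode."""
    if not doc.tokens:
        return []
    features = precomputed_features
    if features is None:
        features = extract(doc, model.feature_config, resources or Resources())
    lattice = build_lattice(features, model)
    path, _ = viterbi(lattice)
    labels = [BioLabel.parse(model.labels[y]) for y in path]
    return decode_bio(doc, labels)
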