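"""FAERS-style synthetic narratives with gold annotations.

The real spontaneous-report corpora this package targets are private, so
experiments run on generated narratives that reproduce the measurable
surface statistics of such corpora: document lengths drawn from a
truncated normal (mean 190.2 words, SD 130.3), nine entity classes with
frequencies proportional to the class distribution of a double-annotated
122-narrative reference corpus (adverse events and medications dominate;
frequency and duration are rare), singleton mention surfaces that create
data sparseness, and inconsistent attachment of trailing punctuation to
mention spans.

Generation is template-based: sentences are assembled from slot
templates ("The patient received <Medication> <Dosage> ... and developed
<AdverseEvent>"), so gold spans are exact by construction and every
mention is recorded in a generation ledger with its surface provenance
(packaged lexicon/pool vs. invented singleton) and its pre-noise core
span.  A perturbation model simulates a second annotator whose
disagreements follow the three-category taxonomy observed in such
corpora: boundary shifts, missed mentions, and class confusions
(adverse event vs. other-sign-symptom being the most confusable pair).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .corpus import (
    AnnotationSet,
    Document,
    EntityClass,
    EntityMention,
    tokenize,
)
from .lexicons import SemanticLexicon, default_lexicon, generator_pools, longest_match


class GenerationError(RuntimeError):
    """The generator cannot satisfy the requested configuration."""


#: per-class mention-frequency weights, proportional to the class
#: distribution of the double-annotated reference corpus
DEFAULT_CLASS_WEIGHTS: dict[EntityClass, float] = {
    EntityClass.ADVERSE_EVENT: 1646,
    EntityClass.MEDICATION: 1152,
    EntityClass.DOSAGE: 137,
    EntityClass.INDICATION: 126,
    EntityClass.ROUTE: 107,
    EntityClass.OSSD: 90,
    EntityClass.TREATMENT: 62,
    EntityClass.DURATION: 24,
    EntityClass.FREQUENCY: 21,
}

#: mentions per word: 3365 mentions over ~23,000 words in the reference corpus
DEFAULT_MENTION_DENSITY = 3365 / 23000


@dataclass(frozen=True)
class GeneratorConfig:
    n_docs: int = 122
    seed: int = 0
    words_mean: float = 190.2
    words_sd: float = 130.3
    words_min: int = 30
    class_weights: tuple[tuple[EntityClass, float], ...] = tuple(
        DEFAULT_CLASS_WEIGHTS.items()
    )
    mention_density: float = DEFAULT_MENTION_DENSITY
    singleton_rate: float = 0.2
    punct_attach_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise GenerationError("n_docs must be >= 1")
        if any(w <= 0 for _, w in self.class_weights):
            raise GenerationError("class weights must be positive")
        for rate in (self.singleton_rate, self.punct_attach_rate):
            if not 0.0 <= rate <= 1.0:
                raise GenerationError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class PerturbConfig:
    """Per-mention probabilities of the three disagreement events,
    sampled mutually exclusively in the order boundary → miss →
    confusion.

    The defaults make the expected *token*-level category mixture track
    the reference taxonomy (≈14% boundary / 80% missed / 6% category)
    at a total event rate of ~0.25 per mention, given a mean mention
    length of ~1.6 tokens (a missed or confused mention contributes all
    its tokens to the disagreement count, a boundary shift one token).
    """

    boundary_rate: float = 0.05
    miss_rate: float = 0.18
    confusion_rate: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.boundary_rate, self.miss_rate, self.confusion_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates) or sum(rates) > 1.0:
            raise GenerationError("perturbation rates must be in [0,1] and sum <= 1")


def rates_for_token_shares(boundary_pct: float, missed_pct: float,
                           category_pct: float, total_rate: float,
                           mean_mention_tokens: float, seed: int = 0
                           ) -> PerturbConfig:
    """Per-mention event rates whose expected token-level category
    mixture matches the given percentage shares.

    Boundary events touch one token; miss and confusion events touch a
    whole mention (``mean_mention_tokens`` on average), so per-mention
    rates are the shares divided by tokens-per-event, rescaled to
    ``total_rate``.
    """
    raw = np.array([
        boundary_pct / 1.0,
        missed_pct / mean_mention_tokens,
        category_pct / mean_mention_tokens,
    ])
    b, m, c = total_rate * raw / raw.sum()
    return PerturbConfig(float(b), float(m), float(c), seed)


@dataclass(frozen=True)
class LedgerEntry:
    """Provenance of one gold mention."""

    doc_id: str
    entity_class: EntityClass
    start: int
    end: int
    surface: str
    source: str          # "lexicon", "pool", or "novel"
    core_start: int      # span before punctuation-attachment noise
    core_end: int


# ---------------------------------------------------------------------------
# Surface suppliers
# ---------------------------------------------------------------------------

_DRUG_PREFIXES = ["Zal", "Ver", "Lom", "Bex", "Dal", "Tev", "Quor", "Nir",
                  "Xel", "Pov", "Gur", "Hax", "Jaz", "Kov", "Wex", "Yol"]
_DRUG_STEMS = ["ati", "emi", "olu", "ibu", "axo", "uri", "eza", "ovi"]
_DRUG_SUFFIXES = ["tin", "mab", "nib", "zole", "pril", "micin", "parin",
                  "fenib", "dar", "lix"]

_AE_MODIFIERS = ["pulmonary", "neurologic", "cutaneous", "ocular", "vascular",
                 "metabolic", "auditory", "endocrine", "articular", "gingival",
                 "vestibular", "biliary", "pleural", "adrenal", "urogenital",
                 "lingual"]
_AE_HEADS = ["toxicity", "impairment", "deterioration", "intolerance",
             "dysregulation", "compromise", "instability", "depletion",
             "hyperactivity", "exhaustion"]
_AE_GRADES = ["grade 1", "grade 2", "grade 3", "grade 4", "mild", "severe",
              "transient", "persistent", "recurrent", "progressive"]


class _SurfaceSupplier:
    """Deterministic per-class surface sampling.

    Each class has a small *common* pool (surfaces that recur, the
    normal case) and a stream of *fresh* surfaces that are handed out at
    most once each (the singleton case).  Fresh surfaces come first from
    unused pool/lexicon terms, then — for classes with productive naming
    (drugs, adverse events, dosages, durations, frequencies) — from
    invented forms verified not to contain any lexicon term.
    """

    def __init__(self, lexicon: SemanticLexicon, rng: np.random.Generator):
        self.lexicon = lexicon
        self.rng = rng
        pools = generator_pools()
        self.common: dict[EntityClass, list[str]] = {}
        self.fresh: dict[EntityClass, list[str]] = {}
        self.sources: dict[str, str] = {}

        def split(cls: EntityClass, items: list[str], n_common: int,
                  source: str) -> None:
            items = list(items)
            rng.shuffle(items)
            self.common[cls] = items[:n_common]
            self.fresh[cls] = items[n_common:]
            for s in items:
                self.sources[s.lower()] = source

        split(EntityClass.MEDICATION, self.lexicon.terms_of_type("T200"), 50, "lexicon")
        split(EntityClass.ADVERSE_EVENT, self.lexicon.terms_of_type("T047"), 50, "lexicon")
        split(EntityClass.INDICATION, pools["indication"], 15, "pool")
        split(EntityClass.OSSD, pools["ossd"], 15, "pool")
        split(EntityClass.TREATMENT, pools["treatment"], 15, "pool")
        split(EntityClass.ROUTE, pools["route"], 12, "pool")
        split(EntityClass.FREQUENCY, pools["frequency"], 10, "pool")
        split(EntityClass.DURATION, pools["duration"], 10, "pool")
        self.common[EntityClass.DOSAGE] = [
            f"{n} mg" for n in (50, 100, 150, 200, 250, 280, 300, 500, 750, 1000)
        ]
        self.fresh[EntityClass.DOSAGE] = []
        for s in self.common[EntityClass.DOSAGE]:
            self.sources[s.lower()] = "pool"
        self._fresh_serial = 0
        self._used_fresh: set[str] = set()

    def _contains_lexicon_term(self, surface: str) -> bool:
        return bool(longest_match(tokenize(surface), self.lexicon))

    def _invent(self, cls: EntityClass) -> str | None:
        """An invented surface for productive classes, else None."""
        for _ in range(200):
            self._fresh_serial += 1
            if cls is EntityClass.MEDICATION:
                s = (self.rng.choice(_DRUG_PREFIXES)
                     + self.rng.choice(_DRUG_STEMS)
                     + self.rng.choice(_DRUG_SUFFIXES))
            elif cls is EntityClass.ADVERSE_EVENT:
                s = " ".join([
                    str(self.rng.choice(_AE_GRADES)),
                    str(self.rng.choice(_AE_MODIFIERS)),
                    str(self.rng.choice(_AE_HEADS)),
                ])
            elif cls is EntityClass.DOSAGE:
                s = f"{int(self.rng.integers(10, 2000))} mg"
            elif cls is EntityClass.DURATION:
                s = f"{int(self.rng.integers(2, 400))} day"
            elif cls is EntityClass.FREQUENCY:
                s = f"every {int(self.rng.integers(2, 200))} hours"
            elif cls is EntityClass.ROUTE:
                s = f"via infusion line {int(self.rng.integers(1, 500))}"
            else:
                return None
            if (s.lower() not in self.sources and s not in self._used_fresh
                    and not self._contains_lexicon_term(s)):
                return s
        return None  # pragma: no cover - astronomically unlikely

    def draw(self, cls: EntityClass, singleton: bool) -> tuple[str, str]:
        """(surface, provenance); singleton surfaces are never reused."""
        if singleton:
            while self.fresh[cls]:
                s = self.fresh[cls].pop()
                if s not in self._used_fresh:
                    self._used_fresh.add(s)
                    return s, self.sources[s.lower()]
            s = self._invent(cls)
            if s is None:
                raise GenerationError(
                    f"insufficient lexicon/pool entries for singleton "
                    f"{cls.value} surfaces at the requested singleton rate"
                )
            self._used_fresh.add(s)
            return s, "novel"
        pool = self.common[cls]
        surface = str(pool[int(self.rng.integers(len(pool)))])
        source = "lexicon" if cls in (EntityClass.MEDICATION,
                                      EntityClass.ADVERSE_EVENT) else "pool"
        return surface, source


# ---------------------------------------------------------------------------
# Sentence assembly
# ---------------------------------------------------------------------------

_FILLER_SENTENCES = [
    "The report was submitted by the treating physician .",
    "No further information was available at the time of this report .",
    "Follow up information has been requested from the reporter .",
    "The reporter did not provide additional details .",
    "Laboratory values were reviewed by the clinical team .",
    "The case was assessed as serious by the company .",
    "The outcome was reported as recovering .",
    "Causality assessment could not be completed .",
    "The narrative was transcribed from the original report .",
    "Relevant dates were not specified in the source document .",
    "The physician considered the course to be uneventful otherwise .",
    "Additional records were requested but not received .",
]

def _detokenize(words: Sequence[str]) -> str:
    """Join token surfaces into natural text (no space before trailing
    punctuation, none after an opening bracket)."""
    out: list[str] = []
    for w in words:
        if out and w in {".", ",", ";", ":", "!", "?", ")"}:
            out[-1] = out[-1] + w
        elif out and out[-1].endswith("("):
            out[-1] = out[-1] + w
        else:
            out.append(w)
    return " ".join(out)


class _DocBuilder:
    """Accumulates token surfaces plus mention token-ranges for one doc."""

    def __init__(self) -> None:
        self.words: list[str] = []
        self.mentions: list[tuple[EntityClass, int, int, str]] = []

    @property
    def n_words(self) -> int:
        return len(self.words)

    def add_sentence(self, parts: Sequence) -> None:
        """parts: strings (split on spaces) or (class, surface, source) slots."""
        for part in parts:
            if isinstance(part, str):
                self.words.extend(part.split())
            else:
                cls, surface, source = part
                toks = surface.split()
                first = len(self.words)
                self.words.extend(toks)
                self.mentions.append((cls, first, len(self.words), source))


def _pop(bag: dict[EntityClass, int], cls: EntityClass) -> bool:
    if bag.get(cls, 0) > 0:
        bag[cls] -= 1
        return True
    return False


def _build_sentence(bag: dict[EntityClass, int], supplier: _SurfaceSupplier,
                    rng: np.random.Generator, singleton_rate: float) -> list:
    """Consume mentions from the bag into one templated sentence."""

    def slot(cls: EntityClass):
        singleton = bool(rng.random() < singleton_rate)
        surface, source = supplier.draw(cls, singleton)
        return (cls, surface, source)

    C = EntityClass
    # choose the sentence family by what is left, AE/medication first
    if bag.get(C.MEDICATION, 0) and _pop(bag, C.MEDICATION):
        parts: list = [str(rng.choice(["The patient received", "She was given",
                                       "He was started on", "Treatment included"]))]
        parts.append(slot(C.MEDICATION))
        if _pop(bag, C.DOSAGE):
            parts.append(slot(C.DOSAGE))
        if _pop(bag, C.ROUTE):
            parts.append(slot(C.ROUTE))
        if _pop(bag, C.FREQUENCY):
            parts.append(slot(C.FREQUENCY))
        if _pop(bag, C.DURATION):
            parts.append("over a")
            parts.append(slot(C.DURATION))
            parts.append("course")
        if _pop(bag, C.INDICATION):
            parts.append(str(rng.choice(["for", "for the treatment of"])))
            parts.append(slot(C.INDICATION))
        if bag.get(C.ADVERSE_EVENT, 0) and rng.random() < 0.6 and _pop(bag, C.ADVERSE_EVENT):
            parts.append("and subsequently developed")
            parts.append(slot(C.ADVERSE_EVENT))
        parts.append(".")
        return parts
    if bag.get(C.ADVERSE_EVENT, 0) and _pop(bag, C.ADVERSE_EVENT):
        opener = str(rng.choice([
            "The patient developed", "The patient experienced",
            "She subsequently developed", "He presented with",
            "The event was reported as", "Examination revealed",
        ]))
        parts = [opener, slot(C.ADVERSE_EVENT)]
        if bag.get(C.ADVERSE_EVENT, 0) and rng.random() < 0.5 and _pop(bag, C.ADVERSE_EVENT):
            parts.append("and")
            parts.append(slot(C.ADVERSE_EVENT))
        if bag.get(C.OSSD, 0) and rng.random() < 0.3 and _pop(bag, C.OSSD):
            parts.append("without")
            parts.append(slot(C.OSSD))
        parts.append(".")
        return parts
    if bag.get(C.OSSD, 0) and _pop(bag, C.OSSD):
        return [str(rng.choice(["Medical history included",
                                "The patient was previously noted for",
                                "Baseline findings included"])),
                slot(C.OSSD), "."]
    if bag.get(C.TREATMENT, 0) and _pop(bag, C.TREATMENT):
        return [str(rng.choice(["The event was managed with",
                                "The patient required",
                                "Supportive management consisted of"])),
                slot(C.TREATMENT), "."]
    if bag.get(C.INDICATION, 0) and _pop(bag, C.INDICATION):
        return ["Therapy was indicated for", slot(C.INDICATION), "."]
    if bag.get(C.DOSAGE, 0) and _pop(bag, C.DOSAGE):
        return ["The administered dose was", slot(C.DOSAGE), "."]
    if bag.get(C.ROUTE, 0) and _pop(bag, C.ROUTE):
        return ["The product was administered", slot(C.ROUTE), "."]
    if bag.get(C.FREQUENCY, 0) and _pop(bag, C.FREQUENCY):
        return ["Dosing was scheduled", slot(C.FREQUENCY), "."]
    if bag.get(C.DURATION, 0) and _pop(bag, C.DURATION):
        return ["Therapy continued over a", slot(C.DURATION), "period", "."]
    raise AssertionError("empty bag")  # pragma: no cover


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig | None = None,
             lexicon: SemanticLexicon | None = None,
             ) -> tuple[list[Document], AnnotationSet, list[LedgerEntry]]:
    """Generate a corpus: documents, gold annotations, generation ledger.

    Deterministic: the same configuration (including seed) yields a
    byte-identical corpus.
    """
    config = config or GeneratorConfig()
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(config.seed)
    supplier = _SurfaceSupplier(lexicon, rng)
    classes = [c for c, _ in config.class_weights]
    weights = np.array([w for _, w in config.class_weights], dtype=float)
    weights /= weights.sum()

    docs: list[Document] = []
    gold = AnnotationSet("gold")
    ledger: list[LedgerEntry] = []
    width = len(str(config.n_docs))
    for d in range(config.n_docs):
        doc_id = f"doc{d:0{width}d}"
        target_words = 0
        while target_words < config.words_min:
            target_words = int(round(rng.normal(config.words_mean, config.words_sd)))
        n_mentions = max(1, int(round(target_words * config.mention_density)))
        counts = rng.multinomial(n_mentions, weights)
        bag = {cls: int(n) for cls, n in zip(classes, counts)}

        builder = _DocBuilder()
        while sum(bag.values()) > 0:
            builder.add_sentence(
                _build_sentence(bag, supplier, rng, config.singleton_rate)
            )
            if rng.random() < 0.25:
                builder.add_sentence(
                    [str(rng.choice(_FILLER_SENTENCES))]
                )
        while builder.n_words < target_words:
            builder.add_sentence([str(rng.choice(_FILLER_SENTENCES))])

        text = _detokenize(builder.words)
        doc = Document(doc_id, text)
        if [t.surface for t in doc.tokens] != builder.words:
            raise GenerationError(
                f"tokenization does not reproduce the planned tokens in {doc_id}"
            )
        docs.append(doc)
        for cls, first, stop, source in builder.mentions:
            start = doc.tokens[first].start
            end = doc.tokens[stop - 1].end
            core = (start, end)
            # punctuation-attachment noise: extend the gold span over an
            # immediately following punctuation token
            if (stop < len(doc.tokens)
                    and doc.tokens[stop].surface in (".", ",", ";", ":")
                    and rng.random() < config.punct_attach_rate):
                end = doc.tokens[stop].end
            mention = EntityMention(cls, start, end, doc.text[start:end])
            gold.add(doc_id, mention)
            ledger.append(LedgerEntry(doc_id, cls, start, end, mention.surface,
                                      source, core[0], core[1]))
    return docs, gold, ledger


def ledger_basedict_recall(ledger: Sequence[LedgerEntry],
                           lexicon: SemanticLexicon) -> float:
    """Expected strict dictionary-baseline recall, from bookkeeping alone.

    A gold mention is recoverable iff its class is dictionary-tagged,
    its surface is a lexicon term, and no punctuation noise moved its
    span off the lexicon-exact core.
    """
    dict_classes = set(lexicon.type_to_class.values())
    relevant = [e for e in ledger if e.entity_class in dict_classes]
    if not relevant:
        return 0.0
    hit = sum(
        1 for e in relevant
        if e.source == "lexicon" and (e.start, e.end) == (e.core_start, e.core_end)
    )
    return hit / len(relevant)


# ---------------------------------------------------------------------------
# Simulated second annotator
# ---------------------------------------------------------------------------

def perturb(docs: Sequence[Document], gold: AnnotationSet,
            config: PerturbConfig | None = None,
            annotator_id: str = "simulated") -> AnnotationSet:
    """Simulate a second annotator by perturbing gold mentions.

    Per mention, mutually exclusive events in the order boundary → miss
    → confusion: a boundary event grows or shrinks the span by one
    token, a miss deletes the mention, a confusion relabels it (adverse
    event and OSSD confuse each other preferentially).  Events that
    would create an overlap or an empty span fall back to copying the
    mention unchanged.
    """
    config = config or PerturbConfig()
    rng = np.random.default_rng(config.seed)
    out = AnnotationSet(annotator_id)
    by_id = {d.doc_id: d for d in docs}
    b, m, c = config.boundary_rate, config.miss_rate, config.confusion_rate
    for doc_id in gold.doc_ids():
        doc = by_id[doc_id]
        mentions = gold.for_doc(doc_id)
        kept: list[EntityMention] = []
        for i, mention in enumerate(mentions):
            u = rng.random()
            if u < b:
                # avoid overlap with both already-perturbed and upcoming spans
                neighbours = kept + mentions[i + 1 :]
                kept.append(_shift_boundary(doc, mention, neighbours, rng))
            elif u < b + m:
                continue  # missed
            elif u < b + m + c:
                kept.append(replace_class(mention, rng))
            else:
                kept.append(mention)
        for mention in kept:
            out.add(doc_id, mention)
    return out


def replace_class(mention: EntityMention,
                  rng: np.random.Generator) -> EntityMention:
    """Relabel a mention; AE↔OSSD is the dominant confusion."""
    cls = mention.entity_class
    if cls is EntityClass.ADVERSE_EVENT:
        target = EntityClass.OSSD if rng.random() < 0.7 else _uniform_other(cls, rng)
    elif cls is EntityClass.OSSD:
        target = EntityClass.ADVERSE_EVENT if rng.random() < 0.7 \
            else _uniform_other(cls, rng)
    else:
        target = _uniform_other(cls, rng)
    return replace(mention, entity_class=target)


def _uniform_other(cls: EntityClass, rng: np.random.Generator) -> EntityClass:
    others = [o for o in EntityClass if o is not cls]
    return others[int(rng.integers(len(others)))]


def _shift_boundary(doc: Document, mention: EntityMention,
                    neighbours: Sequence[EntityMention],
                    rng: np.random.Generator) -> EntityMention:
    first, stop = doc.token_span(mention.start, mention.end)
    ops = ["extend_right", "extend_left", "trim_right", "trim_left"]
    rng.shuffle(ops)
    for op in ops:
        nf, ns = first, stop
        if op == "extend_right" and stop < len(doc.tokens):
            ns = stop + 1
        elif op == "extend_left" and first > 0:
            nf = first - 1
        elif op == "trim_right" and stop - first >= 2:
            ns = stop - 1
        elif op == "trim_left" and stop - first >= 2:
            nf = first + 1
        else:
            continue
        start = doc.tokens[nf].start
        end = doc.tokens[ns - 1].end
        candidate = EntityMention(mention.entity_class, start, end,
                                  doc.text[start:end])
        if not any(candidate.overlaps(o) for o in neighbours):
            return candidate
    return mention

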