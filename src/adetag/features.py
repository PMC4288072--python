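"""Per-token feature extraction for the sequence taggers.

Seven independently switchable feature families:

``default``
    lowercased word identity and word shape for the token and its
    neighbours inside a small context window — the workhorse
    bag-of-words/orthographic family every tagger variant gets.
``affix``
    3- and 4-character prefixes and suffixes.
``morphological``
    character-class properties: digit, capitalization, alphanumeric
    order, hyphen/comma/punctuation presence.
``syntactic``
    POS tag, phrasal class and left-neighbour POS from a pluggable
    annotator (a lightweight rule-and-lexicon tagger ships by default).
``semantic``
    semantic-type codes from longest-match lexicon hits.
``neghedge``
    negation and hedge cues with a forward scope.
``connective``
    discourse-connective cues and a sentence-level presence flag.

Each family can be removed (or added to the default alone) for ablation
runs; the union of per-family extractions equals the all-families
extraction exactly, so ablations compose.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol, Sequence

from .corpus import Document, Token
from .lexicons import CueList, SemanticLexicon, longest_match, match_cues

FAMILIES: tuple[str, ...] = (
    "default", "affix", "connective", "morphological",
    "neghedge", "semantic", "syntactic",
)

#: forward scope length (tokens) for negation/hedge cues when no
#: terminator or sentence boundary intervenes
SCOPE_WINDOW = 6


class FeatureError(ValueError):
    """A requested feature family is missing its resource."""


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families are on, and the context half-width."""

    families: frozenset[str] = frozenset(FAMILIES)
    window: int = 1

    def __post_init__(self) -> None:
        unknown = self.families - set(FAMILIES)
        if unknown:
            raise FeatureError(f"unknown feature families: {sorted(unknown)}")
        if self.window < 0:
            raise FeatureError("window must be >= 0")

    @classmethod
    def default_only(cls, window: int = 1) -> "FeatureConfig":
        return cls(frozenset({"default"}), window)

    @classmethod
    def all_families(cls, window: int = 1) -> "FeatureConfig":
        return cls(frozenset(FAMILIES), window)

    @classmethod
    def parse(cls, spec: str, window: int = 1) -> "FeatureConfig":
        """Parse a CLI feature spec: ``default``, ``all``, ``+family`` /
        ``-family`` modifiers joined by commas (e.g. ``default,+affix``
        or ``all,-semantic``)."""
        fams: set[str] = {"default"}
        for part in spec.split(","):
            part = part.strip()
            if not part:
                continue
            if part == "default":
                fams = {"default"}
            elif part == "all":
                fams = set(FAMILIES)
            elif part.startswith("+"):
                fams.add(part[1:])
            elif part.startswith("-"):
                fams.discard(part[1:])
                fams.add("default")  # default family is always available
            else:
                raise FeatureError(f"bad feature spec component {part!r}")
        return cls(frozenset(fams), window)

    def spec_string(self) -> str:
        if self.families == set(FAMILIES):
            return "all"
        extra = sorted(self.families - {"default"})
        return ",".join(["default"] + [f"+{f}" for f in extra])


@dataclass(frozen=True)
class FeatureVector:
    token_index: int
    features: frozenset[str]


@dataclass
class Resources:
    """External resources the optional families draw on."""

    lexicon: SemanticLexicon | None = None
    negation: CueList | None = None
    hedge: CueList | None = None
    connectives: CueList | None = None
    pos_annotator: "PosAnnotator | None" = None


class PosAnnotator(Protocol):
    """Contract for POS/chunk annotation: per token a POS tag and a
    phrasal class (NP/VP/O)."""

    def annotate(self, doc: Document) -> list[tuple[str, str]]: ...


# ---------------------------------------------------------------------------
# Bundled rule-and-lexicon POS tagger
# ---------------------------------------------------------------------------

_DETERMINERS = {"a", "an", "the", "this", "that", "these", "those", "each",
                "every", "any", "some", "no"}
_PREPOSITIONS = {"of", "in", "on", "at", "to", "for", "with", "without", "by",
                 "from", "into", "during", "after", "before", "via", "per",
                 "over", "under", "between"}
_PRONOUNS = {"he", "she", "it", "they", "him", "her", "them", "his", "its",
             "their", "who", "which", "patient's"}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_MODALS = {"may", "might", "could", "can", "should", "would", "will", "must"}
_ADJECTIVES = {"female", "male", "severe", "mild", "moderate", "acute",
               "chronic", "intravenous", "oral", "subcutaneous", "topical",
               "normal", "abnormal", "high", "low", "elevated", "concomitant",
               "previous", "further", "several", "multiple", "possible",
               "probable", "unlikely", "same", "first", "second", "last",
               "non-therapeutic", "life", "threatening", "grade", "daily"}
_VERBS = {"received", "administered", "developed", "experienced", "reported",
          "noted", "observed", "occurred", "appeared", "recovered", "resolved",
          "started", "stopped", "discontinued", "continued", "treated",
          "hospitalized", "admitted", "discharged", "died", "expired",
          "denies", "denied", "presented", "prescribed", "given", "elicited",
          "considers", "was", "were", "is", "are", "been", "be", "had", "has",
          "have", "became", "become", "required", "underwent", "improved",
          "worsened", "persisted", "subsided", "tolerated"}
_ADVERBS = {"approximately", "subsequently", "possibly", "presumably",
            "initially", "later", "previously", "again", "well", "not",
            "never", "also", "then", "however", "therefore", "apparently"}

_NUM_RE = re.compile(r"^\d[\d.,]*%?$")


class RulePosTagger:
    """Closed-class lists + suffix heuristics + a flat NP/VP chunk rule.

    Intentionally lightweight: the taggers only consume the POS tag, the
    phrasal class and the left-neighbour POS, so a full parser is not
    required to satisfy the annotator contract.
    """

    def tag_token(self, surface: str) -> str:
        low = surface.lower()
        if _NUM_RE.match(surface):
            return "CD"
        if not any(ch.isalnum() for ch in surface):
            return "PUNCT"
        if low in _DETERMINERS:
            return "DT"
        if low in _PREPOSITIONS:
            return "IN"
        if low in _PRONOUNS:
            return "PRP"
        if low in _CONJUNCTIONS:
            return "CC"
        if low in _MODALS:
            return "MD"
        if low in _ADVERBS or (low.endswith("ly") and len(low) > 4):
            return "RB"
        if low in _VERBS:
            return "VBD"
        if low in _ADJECTIVES or low.endswith(("ous", "ic", "al", "ive", "able")):
            return "JJ"
        if low.endswith("ing") and len(low) > 5:
            return "VBG"
        if low.endswith("ed") and len(low) > 4:
            return "VBD"
        return "NN"

    def annotate(self, doc: Document) -> list[tuple[str, str]]:
        pos = [self.tag_token(tok.surface) for tok in doc.tokens]
        phrase = ["O"] * len(pos)
        # NP chunk: optional DT, any JJ/CD run, NN/PRP head run
        i = 0
        n = len(pos)
        while i < n:
            j = i
            if j < n and pos[j] == "DT":
                j += 1
            while j < n and pos[j] in ("JJ", "CD"):
                j += 1
            k = j
            while k < n and pos[k] in ("NN", "PRP"):
                k += 1
            if k > j and (k > i):
                for t in range(i, k):
                    phrase[t] = "NP"
                i = k
            elif pos[i] in ("VBD", "VBG", "MD"):
                phrase[i] = "VP"
                i += 1
            else:
                i += 1
        return list(zip(pos, phrase))


# ---------------------------------------------------------------------------
# Feature families
# ---------------------------------------------------------------------------

def word_shape(surface: str) -> str:
    """Collapse characters to X/x/d classes, squeezing repeats beyond 4."""
    shape = []
    for ch in surface:
        if ch.isupper():
            shape.append("X")
        elif ch.islower():
            shape.append("x")
        elif ch.isdigit():
            shape.append("d")
        else:
            shape.append(ch)
    s = "".join(shape)
    return s if len(s) <= 4 else re.sub(r"(.)\1{3,}", r"\1\1\1\1", s)


def morphological_features(token: Token) -> set[str]:
    s = token.surface
    out: set[str] = set()
    if s.isdigit():
        out.add("morph:is_digit")
    if s[0].isupper():
        out.add("morph:is_capitalized")
    if len(s) > 1 and s.isupper():
        out.add("morph:all_caps")
    has_alpha = any(c.isalpha() for c in s)
    has_digit = any(c.isdigit() for c in s)
    if has_alpha and has_digit:
        if s[0].isalpha() and s[-1].isdigit():
            out.add("morph:alnum_pattern=letters_digits")
        elif s[0].isdigit() and s[-1].isalpha():
            out.add("morph:alnum_pattern=digits_letters")
        else:
            out.add("morph:alnum_pattern=mixed")
    if "-" in s:
        out.add("morph:has_hyphen")
    if "," in s:
        out.add("morph:has_comma")
    if not any(c.isalnum() for c in s):
        out.add("morph:is_punct")
    return out


def affix_features(token: Token) -> set[str]:
    low = token.surface.lower()
    return {
        f"affix:pre3={low[:3]}",
        f"affix:pre4={low[:4]}",
        f"affix:suf3={low[-3:]}",
        f"affix:suf4={low[-4:]}",
    }


def default_features(doc: Document, window: int = 1) -> list[set[str]]:
    per_tok = [
        {f"w={tok.surface.lower()}", f"shape={word_shape(tok.surface)}"}
        for tok in doc.tokens
    ]
    out: list[set[str]] = []
    n = len(doc.tokens)
    for i in range(n):
        feats = {f"default:{f}" for f in per_tok[i]}
        for off in range(1, window + 1):
            if i - off >= 0:
                feats |= {f"default:w[-{off}]={doc.tokens[i-off].surface.lower()}",
                          f"default:shape[-{off}]={word_shape(doc.tokens[i-off].surface)}"}
            if i + off < n:
                feats |= {f"default:w[+{off}]={doc.tokens[i+off].surface.lower()}",
                          f"default:shape[+{off}]={word_shape(doc.tokens[i+off].surface)}"}
        out.append(feats)
    return out


def syntactic_features(doc: Document, pos_annotator: PosAnnotator) -> list[set[str]]:
    ann = pos_annotator.annotate(doc)
    if len(ann) != len(doc.tokens):
        raise FeatureError(
            f"POS annotator returned {len(ann)} tags for {len(doc.tokens)} tokens"
        )
    sentence_starts = {s for s, _ in doc.sentence_spans()}
    out: list[set[str]] = []
    for i, (pos, phrase) in enumerate(ann):
        left = "NONE" if i in sentence_starts or i == 0 else ann[i - 1][0]
        out.append({f"syn:pos={pos}", f"syn:phrase={phrase}", f"syn:left_pos={left}"})
    return out


def semantic_features(doc: Document, lexicon: SemanticLexicon) -> list[set[str]]:
    out: list[set[str]] = [set() for _ in doc.tokens]
    for (first, stop), code in longest_match(doc.tokens, lexicon):
        for i in range(first, stop):
            out[i].add(f"sem:type={code}")
            out[i].add(f"sem:match_position={'B' if i == first else 'I'}")
    return out


def _cue_scope_features(doc: Document, cues: CueList, prefix: str) -> list[set[str]]:
    out: list[set[str]] = [set() for _ in doc.tokens]
    terminator_starts = (
        {first for first, _ in match_cues(doc.tokens, cues.terminators)}
        if cues.terminators else set()
    )
    sentences = doc.sentence_spans()
    sent_end = {}
    for s, e in sentences:
        for i in range(s, e):
            sent_end[i] = e
    for first, stop in match_cues(doc.tokens, cues.cues):
        for i in range(first, stop):
            out[i].add(f"{prefix}:cue")
        limit = min(stop + SCOPE_WINDOW, sent_end.get(first, len(doc.tokens)))
        for i in range(stop, limit):
            if i in terminator_starts:
                break
            out[i].add(f"{prefix}:in_scope")
    return out


def neghedge_features(doc: Document, negation: CueList, hedge: CueList
                      ) -> list[set[str]]:
    neg = _cue_scope_features(doc, negation, "neg")
    hed = _cue_scope_features(doc, hedge, "hedge")
    return [a | b for a, b in zip(neg, hed)]


def connective_features(doc: Document, connectives: CueList) -> list[set[str]]:
    out: list[set[str]] = [set() for _ in doc.tokens]
    matches = match_cues(doc.tokens, connectives.cues)
    for first, stop in matches:
        surface = "_".join(doc.tokens[i].surface.lower() for i in range(first, stop))
        out[first].add(f"conn:cue={surface}")
    if matches:
        match_starts = [m[0] for m in matches]
        for s, e in doc.sentence_spans():
            if any(s <= first < e for first in match_starts):
                for i in range(s, e):
                    out[i].add("conn:present")
    return out


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract(doc: Document, config: FeatureConfig, resources: Resources
            ) -> list[FeatureVector]:
    """Union of the enabled families, one :class:`FeatureVector` per token."""
    per_token: list[set[str]] = [set() for _ in doc.tokens]

    def merge(columns: list[set[str]]) -> None:
        for bucket, feats in zip(per_token, columns):
            bucket |= feats

    if "default" in config.families:
        merge(default_features(doc, config.window))
    if "affix" in config.families:
        merge([affix_features(tok) for tok in doc.tokens])
    if "morphological" in config.families:
        merge([morphological_features(tok) for tok in doc.tokens])
    if "syntactic" in config.families:
        annotator = resources.pos_annotator or RulePosTagger()
        merge(syntactic_features(doc, annotator))
    if "semantic" in config.families:
        if resources.lexicon is None:
            raise FeatureError("semantic family enabled but no lexicon provided")
        merge(semantic_features(doc, resources.lexicon))
    if "neghedge" in config.families:
        if resources.negation is None or resources.hedge is None:
            raise FeatureError("neghedge family enabled but cue lists missing")
        merge(neghedge_features(doc, resources.negation, resources.hedge))
    if "connective" in config.families:
        if resources.connectives is None:
            raise FeatureError("connective family enabled but cue list missing")
        merge(connective_features(doc, resources.connectives))

    return [FeatureVector(i, frozenset(feats)) for i, feats in enumerate(per_token)]


def default_resources() -> Resources:
    """Resources backed by the packaged lexicon and cue lists."""
    from . import lexicons

    return Resources(
        lexicon=lexicons.default_lexicon(),
        negation=lexicons.default_cues("negation"),
        hedge=lexicons.default_cues("hedge"),
        connectives=lexicons.default_cues("connective"),
        pos_annotator=RulePosTagger(),
    )
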