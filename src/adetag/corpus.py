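"""Core data model for adverse-event narratives and their annotations.

A narrative is a plain-text document; annotations are typed character
spans over it (one of nine entity classes covering medication
information, adverse events, and related clinical findings).  This
module owns tokenization, the BIO span encoding used by the sequence
taggers, and the on-disk formats: standoff annotation files next to the
raw text, and token-per-line TSV for tagger input/output.

Character offsets are 0-based and half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class CorpusError(ValueError):
    """Malformed corpus data (bad offsets, unknown classes, bad labels)."""


class AlignmentError(CorpusError):
    """A mention span does not align with token boundaries or overlaps."""


# ---------------------------------------------------------------------------
# Entity classes and labels
# ---------------------------------------------------------------------------

class EntityClass(str, Enum):
    """The nine entity classes annotated in spontaneous-report narratives.

    ``OSSD`` is "other signs, symptoms and diseases": clinical findings
    that are not the reported adverse event itself.
    """

    MEDICATION = "Medication"
    DOSAGE = "Dosage"
    ROUTE = "Route"
    FREQUENCY = "Frequency"
    DURATION = "Duration"
    INDICATION = "Indication"
    ADVERSE_EVENT = "AdverseEvent"
    OSSD = "OSSD"
    TREATMENT = "Treatment"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ENTITY_CLASSES: tuple[EntityClass, ...] = tuple(EntityClass)


@dataclass(frozen=True)
class BioLabel:
    """A per-token BIO label: O, or B-/I- plus an entity class."""

    tag: str  # one of "O", "B", "I"
    entity_class: EntityClass | None = None

    def __post_init__(self) -> None:
        if self.tag not in ("O", "B", "I"):
            raise CorpusError(f"bad BIO tag {self.tag!r}")
        if (self.entity_class is None) != (self.tag == "O"):
            raise CorpusError("entity_class must be set iff tag is B or I")

    def __str__(self) -> str:
        if self.tag == "O":
            return "O"
        return f"{self.tag}-{self.entity_class.value}"

    @classmethod
    def parse(cls, s: str) -> "BioLabel":
        if s == "O":
            return cls("O")
        if len(s) > 2 and s[1] == "-" and s[0] in "BI":
            try:
                return cls(s[0], EntityClass(s[2:]))
            except ValueError:
                pass
        raise CorpusError(f"label {s!r} is not in the BIO label alphabet")


#: The 19-label alphabet, O first, then B-/I- per class in canonical order.
#: The ordering is load-bearing: ties in Viterbi decoding are broken by
#: lowest label index, so an untrained model backs off to all-O.
LABELS: tuple[BioLabel, ...] = (BioLabel("O"),) + tuple(
    BioLabel(tag, c) for c in ENTITY_CLASSES for tag in ("B", "I")
)
LABEL_STRINGS: tuple[str, ...] = tuple(str(l) for l in LABELS)
LABEL_INDEX: dict[str, int] = {s: i for i, s in enumerate(LABEL_STRINGS)}


# ---------------------------------------------------------------------------
# Tokens and documents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    index: int
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise CorpusError(f"empty token span {self.start}:{self.end}")
        if any(ch.isspace() for ch in self.surface):
            raise CorpusError(f"token surface contains whitespace: {self.surface!r}")


@dataclass(frozen=True)
class EntityMention:
    entity_class: EntityClass
    start: int
    end: int
    surface: str

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Document:
    doc_id: str
    text: str
    tokens: list[Token] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tokens:
            self.tokens = tokenize(self.text)
        self._check_tokens()

    def _check_tokens(self) -> None:
        prev_end = -1
        for tok in self.tokens:
            if tok.start < prev_end:
                raise CorpusError(f"token spans overlap or regress at {tok}")
            if self.text[tok.start : tok.end] != tok.surface:
                raise CorpusError(
                    f"token surface {tok.surface!r} does not match text at "
                    f"{tok.start}:{tok.end}"
                )
            prev_end = tok.end

    # -- span/token arithmetic ------------------------------------------------

    def token_span(self, start: int, end: int) -> tuple[int, int]:
        """Map a character span to a half-open token-index range.

        Raises :class:`AlignmentError` if the span does not begin and end
        exactly on token boundaries.
        """
        first = last = None
        for tok in self.tokens:
            if tok.start == start:
                first = tok.index
            if tok.end == end:
                last = tok.index
        if first is None or last is None or last < first:
            raise AlignmentError(
                f"span {start}:{end} ({self.text[start:end]!r}) is not "
                f"token-aligned in document {self.doc_id}"
            )
        return first, last + 1

    def sentence_spans(self) -> list[tuple[int, int]]:
        """Half-open token-index ranges of sentences.

        A sentence ends after a ``.``, ``!`` or ``?`` token; the trailing
        punctuation token belongs to the sentence it terminates.
        """
        spans: list[tuple[int, int]] = []
        begin = 0
        for tok in self.tokens:
            if tok.surface in (".", "!", "?"):
                spans.append((begin, tok.index + 1))
                begin = tok.index + 1
        if begin < len(self.tokens):
            spans.append((begin, len(self.tokens)))
        return spans


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Punctuation detached from word edges.  A leading set and a trailing set:
# narratives attach periods, commas and brackets to clinical terms
# ("neutropenia.", "(paclitaxel)"), and span agreement is sensitive to
# exactly where these split.
_LEAD_PUNCT = set("(\"'[{")
_TRAIL_PUNCT = set(".,;:!?)\"'}]")
_WORD_RE = re.compile(r"\S+")
_ALPHA_RE = re.compile(r"[A-Za-z]+$")


def _split_chunk(chunk: str) -> list[str]:
    """Split one whitespace-delimited chunk into token surfaces."""
    if not chunk:
        return []
    # pure punctuation: one token per character
    if all(ch in _LEAD_PUNCT | _TRAIL_PUNCT | set("/%") for ch in chunk):
        return list(chunk)
    lead: list[str] = []
    trail: list[str] = []
    core = chunk
    while core and core[0] in _LEAD_PUNCT:
        lead.append(core[0])
        core = core[1:]
    while core:
        ch = core[-1]
        if ch in _TRAIL_PUNCT:
            trail.append(ch)
            core = core[:-1]
        elif ch == "%" and not (len(core) >= 2 and core[-2].isdigit()):
            # "%" sticks to a numeric quantity ("0.9%") but is detached
            # anywhere else
            trail.append(ch)
            core = core[:-1]
        else:
            break
    parts = _split_slashes(core) if core else []
    return lead + parts + list(reversed(trail))


def _split_slashes(core: str) -> list[str]:
    """Split "/" between plain alphabetic words ("and/or") but keep
    code-like alphanumerics ("NCI/CTC", "mg/kg" stays only if code-like)
    intact."""
    if "/" not in core:
        return [core]
    sides = core.split("/")
    def plain_word(s: str) -> bool:
        return bool(_ALPHA_RE.match(s)) and not s.isupper()
    if all(plain_word(s) for s in sides if s):
        out: list[str] = []
        for i, s in enumerate(sides):
            if i:
                out.append("/")
            if s:
                out.append(s)
        return out
    return [core]


def tokenize(text: str) -> list[Token]:
    """Tokenize a narrative.

    Whitespace delimits chunks; leading/trailing punctuation is detached
    into separate tokens; slashes between plain alphabetic words are
    split; digit-bearing forms ("0.9%", "280", "T200") and hyphenated or
    all-caps slashed codes ("G-CSF", "NCI/CTC") stay intact.
    Deterministic and idempotent on its own output surfaces.
    """
    tokens: list[Token] = []
    for m in _WORD_RE.finditer(text):
        pos = m.start()
        for surface in _split_chunk(m.group()):
            start = text.index(surface, pos)
            tokens.append(Token(len(tokens), start, start + len(surface), surface))
            pos = start + len(surface)
    return tokens


# ---------------------------------------------------------------------------
# BIO encoding / decoding
# ---------------------------------------------------------------------------

def encode_bio(doc: Document, mentions: Sequence[EntityMention]) -> list[BioLabel]:
    """Encode non-overlapping, token-aligned mentions as per-token BIO labels.

    The first token of each mention gets ``B-<class>``, subsequent tokens
    ``I-<class>``; all other tokens get ``O``.  Adjacent same-class
    mentions stay distinguishable (``B`` restarts).
    """
    labels = [BioLabel("O")] * len(doc.tokens)
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    prev_end = -1
    for mention in ordered:
        if mention.start < prev_end:
            raise AlignmentError(
                f"overlapping mention {mention.surface!r} at "
                f"{mention.start}:{mention.end} in {doc.doc_id}"
            )
        first, stop = doc.token_span(mention.start, mention.end)
        labels[first] = BioLabel("B", mention.entity_class)
        for i in range(first + 1, stop):
            labels[i] = BioLabel("I", mention.entity_class)
        prev_end = mention.end
    return labels


def decode_bio(doc: Document, labels: Sequence[BioLabel]) -> list[EntityMention]:
    """Decode BIO labels into mentions; inverse of :func:`encode_bio`.

    Repair rule: an ``I-X`` whose predecessor is neither ``B-X`` nor
    ``I-X`` is treated as ``B-X`` (a fresh mention), so no labelled token
    is ever dropped.
    """
    if len(labels) != len(doc.tokens):
        raise CorpusError(
            f"got {len(labels)} labels for {len(doc.tokens)} tokens in {doc.doc_id}"
        )
    mentions: list[EntityMention] = []
    run_class: EntityClass | None = None
    run_start = 0
    def flush(upto: int) -> None:
        nonlocal run_class
        if run_class is not None:
            start = doc.tokens[run_start].start
            end = doc.tokens[upto].end
            mentions.append(
                EntityMention(run_class, start, end, doc.text[start:end])
            )
            run_class = None
    for i, label in enumerate(labels):
        if label.tag == "O":
            flush(i - 1)
        elif label.tag == "B" or label.entity_class is not run_class:
            flush(i - 1)
            run_class = label.entity_class
            run_start = i
        # I continuing the current run: nothing to do
    flush(len(labels) - 1)
    return mentions


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """All mentions produced by one annotator or system over a corpus."""

    annotator_id: str
    mentions: dict[str, list[EntityMention]] = field(default_factory=dict)

    def add(self, doc_id: str, mention: EntityMention) -> None:
        bucket = self.mentions.setdefault(doc_id, [])
        for other in bucket:
            if mention.overlaps(other):
                raise AlignmentError(
                    f"mention {mention.surface!r} {mention.start}:{mention.end} "
                    f"overlaps {other.surface!r} in {doc_id} ({self.annotator_id})"
                )
        bucket.append(mention)
        bucket.sort(key=lambda m: m.start)

    def for_doc(self, doc_id: str) -> list[EntityMention]:
        return list(self.mentions.get(doc_id, []))

    def doc_ids(self) -> list[str]:
        return sorted(self.mentions)

    def total(self) -> int:
        return sum(len(v) for v in self.mentions.values())


# ---------------------------------------------------------------------------
# Standoff format
# ---------------------------------------------------------------------------

_STANDOFF_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_standoff(text_path: str | Path, ann_path: str | Path) -> tuple[Document, list[EntityMention]]:
    """Read a narrative plus its standoff annotation file.

    Each annotation line is ``T<n>\\t<Class> <start> <end>\\t<surface>``.
    Offsets refer to the text file; surfaces are checked against it.
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    text = text_path.read_text(encoding="utf-8")
    doc = Document(text_path.stem, text)
    mentions: list[EntityMention] = []
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        m = _STANDOFF_RE.match(line)
        if m is None:
            raise CorpusError(f"{ann_path}:{lineno}: malformed standoff line {line!r}")
        _, cls_name, start_s, end_s, surface = m.groups()
        try:
            cls = EntityClass(cls_name)
        except ValueError:
            raise CorpusError(
                f"{ann_path}:{lineno}: unknown entity class {cls_name!r}"
            ) from None
        start, end = int(start_s), int(end_s)
        if not (0 <= start < end <= len(text)):
            raise CorpusError(f"{ann_path}:{lineno}: span {start}:{end} out of range")
        covered = text[start:end]
        if covered.strip() != surface.strip():
            raise CorpusError(
                f"{ann_path}:{lineno}: surface {surface!r} does not match "
                f"text {covered!r}"
            )
        mentions.append(EntityMention(cls, start, end, covered))
    mentions.sort(key=lambda m: m.start)
    return doc, mentions


def write_standoff(doc: Document, mentions: Sequence[EntityMention],
                   text_path: str | Path, ann_path: str | Path) -> None:
    Path(text_path).write_text(doc.text, encoding="utf-8")
    lines = [
        f"T{i}\t{m.entity_class.value} {m.start} {m.end}\t{m.surface}"
        for i, m in enumerate(sorted(mentions, key=lambda m: m.start), 1)
    ]
    Path(ann_path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# CoNLL-style token-per-line TSV
# ---------------------------------------------------------------------------

def write_conll(path: str | Path,
                docs: Sequence[Document],
                labels_per_doc: Sequence[Sequence[BioLabel]]) -> None:
    """Write documents as token-per-line TSV.

    Each document block starts with ``#doc\\t<doc_id>``, followed by one
    ``surface\\tstart\\tend\\tlabel`` line per token; blank line between
    documents.
    """
    if len(docs) != len(labels_per_doc):
        raise CorpusError("docs and label sequences differ in length")
    out: list[str] = []
    for doc, labels in zip(docs, labels_per_doc):
        if len(labels) != len(doc.tokens):
            raise CorpusError(f"label/token length mismatch in {doc.doc_id}")
        out.append(f"#doc\t{doc.doc_id}")
        for tok, label in zip(doc.tokens, labels):
            out.append(f"{tok.surface}\t{tok.start}\t{tok.end}\t{label}")
        out.append("")
    Path(path).write_text("".join(line + "\n" for line in out), encoding="utf-8")


def read_conll(path: str | Path) -> tuple[list[Document], list[list[BioLabel]]]:
    """Read token-per-line TSV written by :func:`write_conll`.

    The document text is reconstructed by placing token surfaces at their
    recorded offsets, padding gaps with spaces — a lossless round trip
    for the label sequences and token geometry.
    """
    docs: list[Document] = []
    labels_out: list[list[BioLabel]] = []
    cur_id: str | None = None
    cur_toks: list[tuple[str, int, int]] = []
    cur_labels: list[BioLabel] = []

    def flush() -> None:
        nonlocal cur_id, cur_toks, cur_labels
        if cur_id is None:
            return
        length = max((end for _, _, end in cur_toks), default=0)
        chars = [" "] * length
        tokens = []
        for i, (surface, start, end) in enumerate(cur_toks):
            if end - start != len(surface):
                raise CorpusError(f"offsets disagree with surface {surface!r}")
            chars[start:end] = list(surface)
            tokens.append(Token(i, start, end, surface))
        docs.append(Document(cur_id, "".join(chars), tokens))
        labels_out.append(cur_labels)
        cur_id, cur_toks, cur_labels = None, [], []

    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            flush()
            continue
        fields = line.split("\t")
        if fields[0] == "#doc":
            if len(fields) != 2:
                raise CorpusError(f"{path}:{lineno}: malformed document header")
            flush()
            cur_id = fields[1]
            continue
        if len(fields) != 4:
            raise CorpusError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        if cur_id is None:
            raise CorpusError(f"{path}:{lineno}: token line before #doc header")
        surface, start_s, end_s, label_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise CorpusError(f"{path}:{lineno}: bad offsets {start_s!r} {end_s!r}") from None
        cur_toks.append((surface, start, end))
        cur_labels.append(BioLabel.parse(label_s))
    flush()
    return docs, labels_out


def load_corpus_dir(corpus_dir: str | Path, annotator: str = "gold"
                    ) -> tuple[list[Document], AnnotationSet]:
    """Load the standard corpus layout: ``texts/*.txt`` + ``ann/<annotator>/*.ann``."""
    corpus_dir = Path(corpus_dir)
    text_dir = corpus_dir / "texts"
    ann_dir = corpus_dir / "ann" / annotator
    docs: list[Document] = []
    annset = AnnotationSet(annotator)
    for text_path in sorted(text_dir.glob("*.txt")):
        ann_path = ann_dir / (text_path.stem + ".ann")
        if not ann_path.exists():
            raise CorpusError(f"missing annotation file {ann_path}")
        doc, mentions = read_standoff(text_path, ann_path)
        docs.append(doc)
        for m in mentions:
            annset.add(doc.doc_id, m)
    return docs, annset


def save_corpus_dir(corpus_dir: str | Path, docs: Sequence[Document],
                    annsets: Iterable[AnnotationSet]) -> None:
    """Write the standard corpus layout used by the CLI."""
    corpus_dir = Path(corpus_dir)
    (corpus_dir / "texts").mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (corpus_dir / "texts" / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    for annset in annsets:
        ann_dir = corpus_dir / "ann" / annset.annotator_id
        ann_dir.mkdir(parents=True, exist_ok=True)
        for doc in docs:
            lines = [
                f"T{i}\t{m.entity_class.value} {m.start} {m.end}\t{m.surface}"
                for i, m in enumerate(annset.for_doc(doc.doc_id), 1)
            ]
            (ann_dir / f"{doc.doc_id}.ann").write_text(
                "".join(line + "\n" for line in lines), encoding="utf-8"
            )
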