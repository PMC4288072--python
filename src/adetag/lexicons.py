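"""File-backed term resources: a semantic lexicon and cue lists.

The semantic lexicon maps case-normalized (possibly multi-word) terms to
semantic type codes, and type codes to entity classes; it plays the role
a licensed terminology server would in a production pipeline.  Type
``T200`` (clinical drug) maps to Medication and ``T047`` (disease or
symptom) to AdverseEvent — the two classes the dictionary baseline tags.

Cue lists hold negation, hedge and discourse-connective triggers (plus
scope terminators for negation/hedging), one cue per line in plain text
so deployments can swap in their own lists without touching code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .corpus import EntityClass, Token

logger = logging.getLogger(__name__)

#: semantic type codes that always map to an entity class
_BUILTIN_TYPE_TO_CLASS: dict[str, EntityClass] = {
    "T200": EntityClass.MEDICATION,
    "T047": EntityClass.ADVERSE_EVENT,
}


class LexiconError(ValueError):
    """Malformed or empty lexicon/cue file."""


def _norm(term: str) -> tuple[str, ...]:
    """Case-normalized word-sequence key for a term."""
    return tuple(term.lower().split())


@dataclass
class SemanticLexicon:
    """Multi-word term → semantic type code, with type → class mapping.

    Lookup is case-insensitive and whitespace-normalized.
    """

    entries: dict[tuple[str, ...], str] = field(default_factory=dict)
    type_to_class: dict[str, EntityClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, cls in _BUILTIN_TYPE_TO_CLASS.items():
            self.type_to_class.setdefault(code, cls)
        self._max_len = max((len(k) for k in self.entries), default=0)

    def add(self, term: str, type_code: str) -> None:
        key = _norm(term)
        if not key:
            raise LexiconError("empty lexicon term")
        if key in self.entries and self.entries[key] != type_code:
            logger.warning(
                "duplicate lexicon term %r: %s overrides %s",
                term, type_code, self.entries[key],
            )
        self.entries[key] = type_code
        self._max_len = max(self._max_len, len(key))

    def lookup(self, term: str) -> str | None:
        return self.entries.get(_norm(term))

    def __len__(self) -> int:
        return len(self.entries)

    def terms_of_type(self, type_code: str) -> list[str]:
        return sorted(" ".join(k) for k, v in self.entries.items() if v == type_code)


def load_lexicon(path: str | Path) -> SemanticLexicon:
    """Load a lexicon TSV: ``term \\t type-code [\\t entity-class]``.

    An explicit third column extends the type → class mapping.
    Duplicate terms resolve last-wins with a logged warning.
    """
    path = Path(path)
    lex = SemanticLexicon()
    n_rows = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) not in (2, 3) or not fields[0].strip() or not fields[1].strip():
            raise LexiconError(f"{path}:{lineno}: malformed lexicon row {line!r}")
        term, code = fields[0].strip(), fields[1].strip()
        lex.add(term, code)
        if len(fields) == 3 and fields[2].strip():
            try:
                cls = EntityClass(fields[2].strip())
            except ValueError:
                raise LexiconError(
                    f"{path}:{lineno}: unknown entity class {fields[2]!r}"
                ) from None
            lex.type_to_class[code] = cls
        n_rows += 1
    if n_rows == 0:
        raise LexiconError(f"{path}: empty lexicon")
    return lex


@dataclass
class CueList:
    """A set of lowercase cue word-sequences, with optional scope terminators."""

    kind: str  # negation | hedge | connective
    cues: set[tuple[str, ...]] = field(default_factory=set)
    terminators: set[tuple[str, ...]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in ("negation", "hedge", "connective"):
            raise LexiconError(f"unknown cue list kind {self.kind!r}")
        clash = self.cues & self.terminators
        if clash:
            raise LexiconError(f"cues also listed as terminators: {sorted(clash)}")


def load_cues(kind: str, path: str | Path,
              terminator_path: str | Path | None = None) -> CueList:
    """Load a cue list: one cue (possibly multi-word) per line."""
    def read(p: str | Path) -> set[tuple[str, ...]]:
        out = set()
        for line in Path(p).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(_norm(line))
        return out

    cues = read(path)
    if not cues:
        raise LexiconError(f"{path}: empty cue list")
    terminators = read(terminator_path) if terminator_path else set()
    return CueList(kind, cues, terminators)


# ---------------------------------------------------------------------------
# Longest matching
# ---------------------------------------------------------------------------

def longest_match(tokens: Sequence[Token], lexicon: SemanticLexicon
                  ) -> list[tuple[tuple[int, int], str]]:
    """Greedy left-to-right longest match of lexicon terms over tokens.

    Returns ``((first_token, stop_token), type_code)`` pairs with
    non-overlapping, strictly increasing token ranges.  At each position
    the longest matching window wins; the scan then resumes after it.
    """
    surfaces = [tok.surface.lower() for tok in tokens]
    out: list[tuple[tuple[int, int], str]] = []
    i = 0
    n = len(tokens)
    max_len = getattr(lexicon, "_max_len", 0)
    while i < n:
        best = 0
        best_code = None
        for length in range(min(max_len, n - i), 0, -1):
            code = lexicon.entries.get(tuple(surfaces[i : i + length]))
            if code is not None:
                best, best_code = length, code
                break
        if best:
            out.append(((i, i + best), best_code))
            i += best
        else:
            i += 1
    return out


def match_cues(tokens: Sequence[Token], cues: set[tuple[str, ...]]
               ) -> list[tuple[int, int]]:
    """Longest-match cue occurrences as half-open token ranges.

    Shares the matching discipline of :func:`longest_match` via a
    throwaway lexicon, so multiword cues behave exactly like multiword
    lexicon terms.
    """
    lex = SemanticLexicon(entries={c: "CUE" for c in cues})
    return [span for span, _ in longest_match(tokens, lex)]


# ---------------------------------------------------------------------------
# Bundled default resources
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("adetag").joinpath("data", name)))


def default_lexicon() -> SemanticLexicon:
    """The packaged drug/adverse-event lexicon."""
    return load_lexicon(_data_path("semantic_lexicon.tsv"))


def default_cues(kind: str) -> CueList:
    """Packaged negation/hedge/connective cue lists."""
    files = {
        "negation": ("negation_cues.txt", "scope_terminators.txt"),
        "hedge": ("hedge_cues.txt", "scope_terminators.txt"),
        "connective": ("connective_cues.txt", None),
    }
    try:
        cue_file, term_file = files[kind]
    except KeyError:
        raise LexiconError(f"unknown cue list kind {kind!r}") from None
    return load_cues(kind, _data_path(cue_file),
                     _data_path(term_file) if term_file else None)


def generator_pools() -> dict[str, list[str]]:
    """Surface pools for the synthetic-corpus generator, keyed by pool name.

    Pools are disjoint from the semantic lexicon so that dictionary
    matches in generated text always coincide with gold drug/AE mentions.
    """
    pools: dict[str, list[str]] = {}
    for line in _data_path("generator_pools.tsv").read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise LexiconError(f"malformed generator pool row {line!r}")
        pools.setdefault(fields[0], []).append(fields[1])
    return pools
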