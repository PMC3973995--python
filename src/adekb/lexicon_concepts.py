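"""Dictionary-based concept recognition and normalization.

Terms are normalized (case folding, possessive removal, punctuation to
space, whitespace collapse, simple plural stripping), indexed by
concept unique identifier (CUI), and matched against sentences with a
leftmost-longest policy over the token stream.  Concepts are restricted
to the two semantic groups relevant to adverse-event extraction,
"Chemicals & Drugs" (drug role) and "Disorders" (adverse-effect role).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from adekb.corpus_io import SentenceRecord, TextSpan

CHEMICALS_AND_DRUGS = "CHEMICALS_AND_DRUGS"
DISORDERS = "DISORDERS"
OTHER = "OTHER"

GROUPS = (CHEMICALS_AND_DRUGS, DISORDERS, OTHER)

#: mention provenance labels
DICTIONARY = "DICTIONARY"
COORDINATION = "COORDINATION"
ABBREVIATION = "ABBREVIATION"
VARIATION = "VARIATION"
BOUNDARY_ADJUSTED = "BOUNDARY_ADJUSTED"

_GROUP_ALIASES = {
    "chemicals & drugs": CHEMICALS_AND_DRUGS,
    "chemicals and drugs": CHEMICALS_AND_DRUGS,
    "chem": CHEMICALS_AND_DRUGS,
    "chemicals_and_drugs": CHEMICALS_AND_DRUGS,
    "disorders": DISORDERS,
    "diso": DISORDERS,
    "other": OTHER,
}

_POSSESSIVE = re.compile(r"'s\b|(?<=s)'(?=\s|$)")
_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")

# plural endings that strip to a stem the rules leave alone on a second pass
_PLURAL_KEEP = ("ss", "us", "is")


def _singularize(token: str) -> str:
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 4 and token.endswith(("ches", "shes", "xes", "zes", "sses")):
        return token[:-2]
    if len(token) > 3 and token.endswith("s") and not token.endswith(_PLURAL_KEEP):
        return token[:-1]
    return token


def normalize_term(text: str) -> str:
    """Normalize a term or candidate phrase.

    Applies, in order: case folding, possessive removal, punctuation to
    space, whitespace collapse, and simple plural stripping on the final
    token.  Deterministic and idempotent.
    """
    text = text.casefold()
    text = _POSSESSIVE.sub(" ", text)
    text = _PUNCT.sub(" ", text)
    text = _WS.sub(" ", text).strip()
    if not text:
        return ""
    head, _, last = text.rpartition(" ")
    last = _singularize(last)
    return f"{head} {last}" if head else last


@dataclass(frozen=True)
class ConceptEntry:
    cui: str
    preferred_term: str
    semantic_group: str = OTHER


@dataclass
class Lexicon:
    """Normalized-term index over concept entries.

    ``term_index`` maps a normalized term to every CUI it names
    (ambiguity is preserved); ``suppress_list`` holds normalized terms
    that never produce matches.
    """

    entries: dict[str, ConceptEntry] = field(default_factory=dict)
    term_index: dict[str, frozenset[str]] = field(default_factory=dict)
    suppress_list: set[str] = field(default_factory=set)
    max_term_tokens: int = 8

    def add_term(self, term: str, cui: str) -> None:
        key = normalize_term(term)
        if not key:
            return
        cuis = set(self.term_index.get(key, frozenset()))
        cuis.add(cui)
        self.term_index[key] = frozenset(cuis)

    def group_of(self, cui: str) -> str:
        entry = self.entries.get(cui)
        return entry.semantic_group if entry else OTHER

    def lookup(self, phrase: str) -> frozenset[str]:
        """CUIs for a (not necessarily normalized) phrase; empty if
        suppressed or unknown."""
        key = normalize_term(phrase)
        if key in self.suppress_list:
            return frozenset()
        return self.term_index.get(key, frozenset())


@dataclass(frozen=True)
class EntityMention:
    """A concept occurrence in a sentence (document-level span)."""

    span: TextSpan
    surface: str
    cui: str
    semantic_group: str
    provenance: str = DICTIONARY

    @property
    def width(self) -> int:
        return self.span.end - self.span.start


def normalize_group(label: str) -> str:
    return _GROUP_ALIASES.get(label.strip().casefold(), OTHER)


def load_group_table(stream: Iterable[str]) -> dict[str, str]:
    """TSV: cui TAB group-label."""
    table: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cui, label = line.split("\t")[:2]
        table[cui] = normalize_group(label)
    return table


def load_lexicon(
    vocab_stream: Iterable[str],
    group_table: dict[str, str] | None = None,
    *,
    rrf: bool = False,
    cui_col: int = 0,
    term_col: int = 14,
    keep_all_groups: bool = False,
    suppress_terms: Iterable[str] = (),
    warnings: list[str] | None = None,
) -> Lexicon:
    """Load a lexicon from a `term TAB cui` TSV or an RRF-style
    pipe-delimited concept-names table (column positions configurable).

    Entries outside the Chemicals & Drugs / Disorders groups are dropped
    unless *keep_all_groups*; a CUI missing from *group_table* is warned
    about and assigned OTHER.
    """
    group_table = group_table or {}
    lexicon = Lexicon()
    lexicon.suppress_list = {normalize_term(t) for t in suppress_terms}
    for line in stream_nonblank(vocab_stream):
        if rrf:
            cols = line.split("|")
            cui, term = cols[cui_col], cols[term_col]
        else:
            term, cui = line.split("\t")[:2]
        group = group_table.get(cui)
        if group is None:
            if warnings is not None:
                warnings.append(f"cui {cui} has no semantic-group assignment; set to OTHER")
            group = OTHER
        if not keep_all_groups and group not in (CHEMICALS_AND_DRUGS, DISORDERS):
            continue
        if cui not in lexicon.entries:
            lexicon.entries[cui] = ConceptEntry(cui, term, group)
        lexicon.add_term(term, cui)
    return lexicon


def stream_nonblank(stream: Iterable[str]) -> Iterable[str]:
    for line in stream:
        line = line.rstrip("\n")
        if line.strip() and not line.startswith("#"):
            yield line


_TOKEN = re.compile(r"\w+")


def tokenize(text: str, offset: int = 0) -> list[tuple[str, TextSpan]]:
    """Split on whitespace and punctuation (internal hyphens are split
    points); returns (token, document-level span) pairs."""
    return [(m.group(), TextSpan(m.start() + offset, m.end() + offset)) for m in _TOKEN.finditer(text)]


def match_tokens(
    tokens: Sequence[tuple[str, TextSpan]],
    lexicon: Lexicon,
    text: str,
    text_offset: int,
) -> list[EntityMention]:
    """Leftmost-longest dictionary matching over a token stream.

    At each position the longest normalized token n-gram (n up to
    ``lexicon.max_term_tokens``) found in the term index is emitted and
    scanning resumes after it.  One mention per CUI is emitted for an
    ambiguous term, all on the same span.
    """
    mentions: list[EntityMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        found: frozenset[str] | None = None
        found_len = 0
        for length in range(min(lexicon.max_term_tokens, n - i), 0, -1):
            span = TextSpan(tokens[i][1].start, tokens[i + length - 1][1].end)
            phrase = text[span.start - text_offset : span.end - text_offset]
            cuis = lexicon.lookup(phrase)
            if cuis:
                found, found_len, found_span = cuis, length, span
                break
        if found:
            surface = text[found_span.start - text_offset : found_span.end - text_offset]
            for cui in sorted(found):
                mentions.append(
                    EntityMention(found_span, surface, cui, lexicon.group_of(cui), DICTIONARY)
                )
            i += found_len
        else:
            i += 1
    return mentions


def match_mentions(sentence: SentenceRecord, lexicon: Lexicon) -> list[EntityMention]:
    """Dictionary concept recognition for one sentence; mentions are
    non-overlapping (except same-span multi-CUI copies) and ordered."""
    tokens = tokenize(sentence.text, sentence.span.start)
    return match_tokens(tokens, lexicon, sentence.text, sentence.span.start)
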