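"""Rule-based post-processing of dictionary concept annotations.

Five submodules refine the raw dictionary output using part-of-speech
and chunk information: coordination resolution, abbreviation expansion,
term variation, boundary correction, and concept filtering.  Each
submodule is individually switchable; the whole pipeline only touches
system mentions, never gold annotations, and is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from adekb.corpus_io import SentenceRecord, TextSpan
from adekb.lexicon_concepts import (
    ABBREVIATION,
    BOUNDARY_ADJUSTED,
    COORDINATION,
    DICTIONARY,
    VARIATION,
    EntityMention,
    Lexicon,
    match_mentions,
    normalize_term,
    tokenize,
)
from adekb.tagging import DEFAULT_TAGGER, Tagger

_PROVENANCE_RANK = {DICTIONARY: 0, BOUNDARY_ADJUSTED: 1, ABBREVIATION: 2, COORDINATION: 3, VARIATION: 4}


@dataclass(frozen=True)
class TokenAnnotation:
    token: str
    span: TextSpan  # document-level
    pos: str
    chunk: str  # IOB: B-NP / I-NP / O


@dataclass
class AnalyzedSentence:
    record: SentenceRecord
    tokens: list[TokenAnnotation]
    noun_phrases: list[TextSpan]

    def tokens_in(self, span: TextSpan) -> list[int]:
        return [i for i, t in enumerate(self.tokens) if span.overlaps(t.span)]


def analyze(record: SentenceRecord, tagger: Tagger = DEFAULT_TAGGER) -> AnalyzedSentence:
    """Tokenize and tag one sentence; noun phrases cover maximal
    B-NP/I-NP runs."""
    toks = tokenize(record.text, record.span.start)
    tags = tagger([t for t, _ in toks])
    tokens = [TokenAnnotation(t, s, pos, chunk) for (t, s), (pos, chunk) in zip(toks, tags)]
    nps: list[TextSpan] = []
    start = None
    for i, tok in enumerate(tokens):
        if tok.chunk == "B-NP":
            if start is not None:
                nps.append(TextSpan(start, tokens[i - 1].span.end))
            start = tok.span.start
        elif tok.chunk == "O" and start is not None:
            nps.append(TextSpan(start, tokens[i - 1].span.end))
            start = None
    if start is not None:
        nps.append(TextSpan(start, tokens[-1].span.end))
    return AnalyzedSentence(record, tokens, nps)


# --------------------------------------------------------------------------
# abbreviation expansion (parenthesis-anchored short-form/long-form pairing)

@dataclass(frozen=True)
class AbbreviationPair:
    short_form: str
    short_span: TextSpan
    long_form: str
    long_span: TextSpan


_PAREN = re.compile(r"\(([^()]+)\)")
_STOP_SHORT_FORMS = frozenset(
    "and or of the in for with not but on at by to from as is was".split()
)


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10):
        return False
    if len(sf.split()) > 2:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    if not sf[0].isalnum():
        return False
    if sf.islower() and sf in _STOP_SHORT_FORMS:
        return False
    return True


def find_long_form(short: str, candidate: str) -> str | None:
    """Right-to-left subsequence matching of the short form against the
    candidate long-form text.  Every character of the short form must
    appear in order; the first character must start a word.  Returns the
    matched long form (a suffix of *candidate* starting at a word
    boundary) or None."""
    s = len(short) - 1
    l = len(candidate) - 1
    while s >= 0:
        c = short[s].casefold()
        if not c.isalnum():
            s -= 1
            continue
        while l >= 0 and (
            candidate[l].casefold() != c
            or (s == 0 and l > 0 and candidate[l - 1].isalnum())
        ):
            l -= 1
        if l < 0:
            return None
        s -= 1
        l -= 1
    start = candidate.rfind(" ", 0, l + 2) + 1
    long_form = candidate[start:].strip()
    if not long_form or len(short) > len(long_form):
        return None
    n_words = len(long_form.split())
    if n_words > min(len(short) + 5, len(short) * 2):
        return None
    return long_form


def detect_abbreviations(sentence: AnalyzedSentence) -> list[AbbreviationPair]:
    """Find (long form, short form) definitions of shape "long form (SF)"."""
    rec = sentence.record
    pairs: list[AbbreviationPair] = []
    for m in _PAREN.finditer(rec.text):
        sf = m.group(1).strip()
        if not _valid_short_form(sf):
            continue
        before = rec.text[: m.start()].rstrip()
        max_words = min(len(sf) + 5, len(sf) * 2)
        words = before.split()
        candidate = " ".join(words[-max_words:]) if words else ""
        if not candidate:
            continue
        long_form = find_long_form(sf, candidate)
        if long_form is None:
            continue
        lf_start = before.rfind(long_form)
        if lf_start < 0:
            continue
        sf_off = rec.text.index(sf, m.start(1))
        pairs.append(
            AbbreviationPair(
                sf,
                TextSpan(rec.span.start + sf_off, rec.span.start + sf_off + len(sf)),
                long_form,
                TextSpan(rec.span.start + lf_start, rec.span.start + lf_start + len(long_form)),
            )
        )
    return pairs


def propagate_abbreviations(
    sentences: Sequence[AnalyzedSentence],
    mentions_by_sentence: dict[int, list[EntityMention]],
    pairs: Sequence[AbbreviationPair],
    lexicon: Lexicon,
    warnings: list[str] | None = None,
) -> dict[int, list[EntityMention]]:
    """Document-level abbreviation handling.

    If a long form maps to a concept, every later occurrence of its
    short form is annotated with that concept (provenance ABBREVIATION).
    A short form whose long form matches no concept is blocked from
    dictionary matching for the rest of the document.
    """
    defined: dict[str, AbbreviationPair] = {}
    for pair in pairs:
        if pair.short_form in defined:
            if defined[pair.short_form].long_form != pair.long_form and warnings is not None:
                warnings.append(
                    f"conflicting long forms for {pair.short_form!r}; keeping the first"
                )
            continue
        defined[pair.short_form] = pair

    expansions: dict[str, tuple[frozenset[str], int]] = {}  # SF -> (cuis, def position)
    blocked: dict[str, int] = {}  # SF -> def position
    for sf, pair in defined.items():
        cuis = lexicon.lookup(pair.long_form)
        if cuis:
            expansions[sf] = (cuis, pair.short_span.start)
        else:
            blocked[sf] = pair.long_span.start

    out: dict[int, list[EntityMention]] = {}
    for sent in sentences:
        idx = sent.record.sentence_index
        mentions = list(mentions_by_sentence.get(idx, []))
        # suppress dictionary matches of blocked short forms
        mentions = [
            m
            for m in mentions
            if not (
                m.provenance == DICTIONARY
                and m.surface in blocked
                and m.span.start >= blocked[m.surface]
            )
        ]
        # annotate later occurrences of expandable short forms
        for sf, (cuis, def_pos) in expansions.items():
            for tok in sent.tokens:
                if tok.token == sf and tok.span.start > def_pos:
                    for cui in sorted(cuis):
                        mentions.append(
                            EntityMention(tok.span, sf, cui, lexicon.group_of(cui), ABBREVIATION)
                        )
        out[idx] = mentions
    return out


# --------------------------------------------------------------------------
# coordination resolution

def _match_token_ngrams(
    token_texts: Sequence[str], lexicon: Lexicon
) -> list[tuple[int, int, frozenset[str]]]:
    """Leftmost-longest lexicon matching over a bare token list; returns
    (start index, length, cuis) triples."""
    out = []
    i, n = 0, len(token_texts)
    while i < n:
        hit = None
        for length in range(min(lexicon.max_term_tokens, n - i), 0, -1):
            cuis = lexicon.lookup(" ".join(token_texts[i : i + length]))
            if cuis:
                hit = (i, length, cuis)
                break
        if hit:
            out.append(hit)
            i += hit[1]
        else:
            i += 1
    return out


def resolve_coordination(
    sentence: AnalyzedSentence, lexicon: Lexicon, mentions: Sequence[EntityMention]
) -> list[EntityMention]:
    """Rewrite coordinated noun phrases "A and B H" as "A H" / "B H",
    re-match each rewrite, and anchor new matches on the minimal
    original span covering the conjunct."""
    new: list[EntityMention] = []
    for np in sentence.noun_phrases:
        idxs = sentence.tokens_in(np)
        cc_positions = [i for i in idxs if sentence.tokens[i].pos == "CC"]
        if not cc_positions:
            continue
        # segments of token indices between conjunctions
        segments: list[list[int]] = []
        seg: list[int] = []
        for i in idxs:
            if sentence.tokens[i].pos == "CC":
                if seg:
                    segments.append(seg)
                seg = []
            else:
                seg.append(i)
        if seg:
            segments.append(seg)
        if len(segments) < 2:
            continue
        final = segments[-1]
        if len(final) < 2:
            continue
        head = final[1:]  # shared head tokens after the first conjunct token
        conjuncts = [
            [i for i in s if sentence.tokens[i].pos != "DT"] for s in segments[:-1]
        ] + [[final[0]]]
        for conj in conjuncts:
            if not conj:
                continue
            rewrite = conj + head
            texts = [sentence.tokens[i].token for i in rewrite]
            for start, length, cuis in _match_token_ngrams(texts, lexicon):
                matched = rewrite[start : start + length]
                conj_matched = [i for i in matched if i in conj]
                if not conj_matched:
                    continue  # pure head match; contiguous, dictionary covers it
                if matched == list(range(matched[0], matched[0] + length)):
                    span = TextSpan(
                        sentence.tokens[matched[0]].span.start,
                        sentence.tokens[matched[-1]].span.end,
                    )
                else:
                    span = TextSpan(
                        sentence.tokens[conj_matched[0]].span.start,
                        sentence.tokens[conj_matched[-1]].span.end,
                    )
                off = sentence.record.span.start
                surface = sentence.record.text[span.start - off : span.end - off]
                for cui in sorted(cuis):
                    new.append(
                        EntityMention(span, surface, cui, lexicon.group_of(cui), COORDINATION)
                    )
    return list(mentions) + new


# --------------------------------------------------------------------------
# term variation

def vary_term(noun_phrase: str, lexicon: Lexicon) -> frozenset[str]:
    """Try ordered variants of a noun phrase against the lexicon: drop
    leading determiners/quantifiers, invert "H of M" to "M H", then
    strip premodifiers from the left.  Returns the CUIs of the first
    variant found, else an empty set."""
    for _, phrase in term_variants(noun_phrase):
        cuis = lexicon.lookup(phrase)
        if cuis:
            return cuis
    return frozenset()


def term_variants(noun_phrase: str) -> list[tuple[int, str]]:
    """Ordered (n_leading_tokens_dropped, variant) list; inversion
    variants report 0 dropped tokens (they keep the full span)."""
    from adekb.tagging import DETERMINERS

    words = noun_phrase.split()
    variants: list[tuple[int, str]] = []
    k = 0
    while k < len(words) and words[k].casefold() in DETERMINERS:
        k += 1
    if 0 < k < len(words):
        variants.append((k, " ".join(words[k:])))
    core = words[k:]
    if "of" in core:
        at = core.index("of")
        head, mod = core[:at], core[at + 1 :]
        while mod and mod[0].casefold() in DETERMINERS:
            mod = mod[1:]
        if head and mod:
            variants.append((0, " ".join(mod + head)))
    for strip in range(1, len(core)):
        variants.append((k + strip, " ".join(core[strip:])))
    return variants


def apply_term_variation(
    sentence: AnalyzedSentence, lexicon: Lexicon, mentions: Sequence[EntityMention]
) -> list[EntityMention]:
    """Run term variation on noun phrases that no mention fully covers."""
    new: list[EntityMention] = []
    off = sentence.record.span.start
    for np in sentence.noun_phrases:
        if any(m.span.contains(np) for m in mentions):
            continue
        idxs = sentence.tokens_in(np)
        phrase = " ".join(sentence.tokens[i].token for i in idxs)
        for dropped, variant in term_variants(phrase):
            cuis = lexicon.lookup(variant)
            if not cuis:
                continue
            kept = idxs[dropped:] if dropped else idxs
            span = TextSpan(sentence.tokens[kept[0]].span.start, sentence.tokens[kept[-1]].span.end)
            surface = sentence.record.text[span.start - off : span.end - off]
            for cui in sorted(cuis):
                new.append(EntityMention(span, surface, cui, lexicon.group_of(cui), VARIATION))
            break
    return list(mentions) + new


# --------------------------------------------------------------------------
# boundary correction

_TRIM_POS = frozenset({"DT", "PRP"})


def correct_boundaries(
    mention: EntityMention, sentence: AnalyzedSentence
) -> EntityMention | None:
    """Trim leading/trailing determiner, pronoun, and punctuation from a
    mention span; a mention trimmed to nothing is dropped."""
    off = sentence.record.span.start
    text = sentence.record.text
    start, end = mention.span.start, mention.span.end
    # punctuation trim at the edges
    while start < end and not text[start - off].isalnum():
        start += 1
    while end > start and not text[end - 1 - off].isalnum():
        end -= 1
    if start >= end:
        return None
    toks = [t for t in sentence.tokens if t.span.start >= start and t.span.end <= end]
    while toks and toks[0].pos in _TRIM_POS:
        toks = toks[1:]
    while toks and toks[-1].pos in _TRIM_POS:
        toks = toks[:-1]
    if toks:
        start = max(start, toks[0].span.start)
        end = min(end, toks[-1].span.end)
    elif any(t.span.start >= mention.span.start and t.span.end <= mention.span.end for t in sentence.tokens):
        return None  # only trimmable tokens inside
    if (start, end) == (mention.span.start, mention.span.end):
        return mention
    span = TextSpan(start, end)
    return EntityMention(
        span, text[start - off : end - off], mention.cui, mention.semantic_group, BOUNDARY_ADJUSTED
    )


# --------------------------------------------------------------------------
# concept filtering

@dataclass
class ConceptFilterList:
    """Concepts to suppress, by CUI or by normalized surface term."""

    cuis: set[str] = field(default_factory=set)
    terms: set[str] = field(default_factory=set)

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "ConceptFilterList":
        """One CUI or term per line; '#' starts a comment."""
        out = cls()
        for line in lines:
            entry = line.split("#", 1)[0].strip()
            if not entry:
                continue
            if re.fullmatch(r"C\d+", entry):
                out.cuis.add(entry)
            else:
                out.terms.add(normalize_term(entry))
        return out

    def matches(self, mention: EntityMention) -> bool:
        return mention.cui in self.cuis or normalize_term(mention.surface) in self.terms


def filter_concepts(
    mentions: Sequence[EntityMention],
    sentence: AnalyzedSentence,
    filter_list: ConceptFilterList | None = None,
) -> list[EntityMention]:
    """Remove a mention if it overlaps no noun phrase (abbreviation
    mentions are exempt: weak chunkers may tag short forms O) or if it
    is on the concept filter list.  Survivor order is preserved."""
    out = []
    for m in mentions:
        if filter_list is not None and filter_list.matches(m):
            continue
        if m.provenance != ABBREVIATION and not any(
            m.span.overlaps(np) for np in sentence.noun_phrases
        ):
            continue
        out.append(m)
    return out


def derive_concept_filter_list(
    false_positive_mentions: Iterable[EntityMention], min_count: int = 3
) -> ConceptFilterList:
    """Candidate filter-list entries from training-set false positives:
    the CUIs appearing at least *min_count* times."""
    counts: dict[str, int] = {}
    for m in false_positive_mentions:
        counts[m.cui] = counts.get(m.cui, 0) + 1
    return ConceptFilterList(cuis={c for c, n in counts.items() if n >= min_count})


# --------------------------------------------------------------------------
# pipeline

@dataclass
class NlpConfig:
    enable_abbreviation: bool = True
    enable_coordination: bool = True
    enable_variation: bool = True
    enable_boundary: bool = True
    enable_filtering: bool = True
    filter_list: ConceptFilterList = field(default_factory=ConceptFilterList)


def _dedup(mentions: Iterable[EntityMention]) -> list[EntityMention]:
    seen: dict[tuple[int, int, str], EntityMention] = {}
    for m in mentions:
        key = (m.span.start, m.span.end, m.cui)
        old = seen.get(key)
        if old is None or _PROVENANCE_RANK[m.provenance] < _PROVENANCE_RANK[old.provenance]:
            seen[key] = m
    return sorted(seen.values(), key=lambda m: (m.span.start, m.span.end, m.cui))


def _resolve_conflicts(mentions: list[EntityMention]) -> list[EntityMention]:
    """Overlapping mentions with different spans: the longer span wins;
    on equal length the dictionary-provenance mention wins."""
    mentions = _dedup(mentions)
    kept: list[EntityMention] = []
    for m in sorted(
        mentions,
        key=lambda m: (-m.width, _PROVENANCE_RANK[m.provenance], m.span.start, m.cui),
    ):
        clash = any(
            k.span.overlaps(m.span) and (k.span.start, k.span.end) != (m.span.start, m.span.end)
            for k in kept
        )
        if not clash:
            kept.append(m)
    return sorted(kept, key=lambda m: (m.span.start, m.span.end, m.cui))


def apply_nlp_rules(
    sentences: Sequence[AnalyzedSentence],
    mentions_by_sentence: dict[int, list[EntityMention]],
    lexicon: Lexicon,
    config: NlpConfig | None = None,
    warnings: list[str] | None = None,
) -> dict[int, list[EntityMention]]:
    """Run the five submodules over one document's dictionary mentions."""
    config = config or NlpConfig()
    current = {idx: list(ms) for idx, ms in mentions_by_sentence.items()}

    if config.enable_abbreviation:
        pairs = [p for sent in sentences for p in detect_abbreviations(sent)]
        current = propagate_abbreviations(sentences, current, pairs, lexicon, warnings)

    for sent in sentences:
        idx = sent.record.sentence_index
        mentions = current.get(idx, [])
        if config.enable_coordination:
            mentions = resolve_coordination(sent, lexicon, mentions)
        if config.enable_variation:
            mentions = apply_term_variation(sent, lexicon, mentions)
        if config.enable_boundary:
            mentions = [
                mm for m in mentions if (mm := correct_boundaries(m, sent)) is not None
            ]
        if config.enable_filtering:
            mentions = filter_concepts(mentions, sent, config.filter_list)
        current[idx] = _resolve_conflicts(mentions)
    return current


def annotate_document(
    records: Sequence[SentenceRecord],
    lexicon: Lexicon,
    config: NlpConfig | None = None,
    tagger: Tagger = DEFAULT_TAGGER,
    use_nlp: bool = True,
) -> dict[int, list[EntityMention]]:
    """Dictionary matching plus (optionally) the NLP rule pipeline for
    one document; returns mentions keyed by sentence index."""
    sentences = [analyze(r, tagger) for r in records]
    mentions = {r.sentence_index: match_mentions(r, lexicon) for r in records}
    if not use_nlp:
        return {idx: _dedup(ms) for idx, ms in mentions.items()}
    return apply_nlp_rules(sentences, mentions, lexicon, config)
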