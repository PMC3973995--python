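"""Deterministic part-of-speech and chunk tagging.

The pipeline only needs shallow analysis: closed-class word lists plus
suffix heuristics assign a coarse Penn-style POS tag, and a regular
chunker marks noun phrases with IOB tags.  The tagger is a plain
callable ``tokens -> [(pos, chunk), ...]`` so an external tagger can be
plugged in wherever a :class:`RuleTagger` is accepted.
"""

from __future__ import annotations

from typing import Callable, Sequence

Tagger = Callable[[Sequence[str]], list[tuple[str, str]]]

DETERMINERS = frozenset(
    """a an the this that these those some any no each every both several
    many much few all his her its their our your my""".split()
)
PRONOUNS = frozenset("he she it they we i you him them us me who whom which whose".split())
CONJUNCTIONS = frozenset("and or nor but".split())
PREPOSITIONS = frozenset(
    """of in on with for after to by from at during without before into
    through between under over against upon within while than since
    because as""".split()
)
VERBS = frozenset(
    """is was were are be been being am has have had having do does did
    can could may might must shall should will would develop develops
    present presents receive receives show shows cause causes occur
    occurs report reports remain remains include includes suffer suffers
    experience improve improves resolve resolves recover recovers take
    takes undergo underwent began begin begins become becomes became""".split()
)
ADVERBS = frozenset("not also however probably possibly then here there when where".split())
PARTICIPLES = frozenset("given taken seen shown known found made done born kept left".split())
NOUNS = frozenset(
    "patient case history course event treatment complication onset follow-up".split()
)

_ADJ_SUFFIXES = ("ous", "ive", "ary", "able", "ible", "ful", "less", "ant", "ent")
_NOUN_SUFFIXES = ("ment", "tion", "sion", "ness", "ity", "itis", "osis", "emia", "oma", "pathy")

# tags allowed inside a noun phrase
_NP_TAGS = frozenset({"DT", "JJ", "NN", "CD", "VBN"})


def pos_tag(token: str) -> str:
    low = token.casefold()
    if low in DETERMINERS:
        return "DT"
    if low in PRONOUNS:
        return "PRP"
    if low in CONJUNCTIONS:
        return "CC"
    if low in PREPOSITIONS:
        return "IN"
    if low in VERBS:
        return "VB"
    if low in ADVERBS:
        return "RB"
    if low in PARTICIPLES:
        return "VBN"
    if low in NOUNS:
        return "NN"
    if low.replace(".", "").replace(",", "").isdigit():
        return "CD"
    if low.endswith("ly"):
        return "RB"
    if low.endswith("ing"):
        return "VBG"
    if low.endswith(_NOUN_SUFFIXES):
        return "NN"
    if low.endswith("ed"):
        return "VBN"
    if low.endswith(_ADJ_SUFFIXES) or low.endswith(("al", "ic")):
        return "JJ"
    return "NN"


def chunk_tags(pos: Sequence[str]) -> list[str]:
    """IOB noun-phrase chunking over POS tags.

    A noun phrase is a maximal run of determiner/adjective/noun/number/
    participle tokens, possibly joined across a single coordinating
    conjunction when both sides are nominal, and must contain at least
    one noun.
    """
    n = len(pos)
    in_np = [False] * n
    i = 0
    while i < n:
        if pos[i] in _NP_TAGS:
            j = i
            while j < n and pos[j] in _NP_TAGS:
                j += 1
            # join "NP CC NP" into one coordinated noun phrase
            while j < n - 1 and pos[j] == "CC" and pos[j + 1] in _NP_TAGS:
                j += 1
                while j < n and pos[j] in _NP_TAGS:
                    j += 1
            if any(pos[k] == "NN" for k in range(i, j)):
                for k in range(i, j):
                    in_np[k] = True
            i = j
        else:
            i += 1
    tags = []
    for k in range(n):
        if not in_np[k]:
            tags.append("O")
        elif k == 0 or not in_np[k - 1]:
            tags.append("B-NP")
        else:
            tags.append("I-NP")
    return tags


class RuleTagger:
    """Lexicon + suffix rule tagger; deterministic, no external models."""

    def __call__(self, tokens: Sequence[str]) -> list[tuple[str, str]]:
        pos = [pos_tag(t) for t in tokens]
        return list(zip(pos, chunk_tags(pos)))


DEFAULT_TAGGER = RuleTagger()
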