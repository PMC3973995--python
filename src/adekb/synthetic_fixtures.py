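"""Seeded generators for a toy drug/disorder lexicon, a typed concept
graph with planted structure, and an annotated corpus in ADE format.

The generator emulates the study conditions end to end without any
license-gated resource:

* **true pairs** -- drug/disorder pairs wired into the graph at short
  distance (default <= 3) through clean relation types; rendered in
  positive sentences with exact gold offsets;
* **trap decoys** -- drug/disorder pairs at distance 2 whose every
  shortest path carries a planted noise relation type; rendered in
  negative sentences.  They pass the distance threshold and are only
  rejected once the relation-type filter has been trained;
* **far decoys** -- drug/disorder pairs at distance >= 5 (through the
  chain of other gadgets), rendered in negative sentences; the distance
  threshold rejects them.

Positive sentences optionally use coordinated effects ("renal and
hepatic failure") and abbreviation definitions ("thrombotic
microangiopathy (TMA)") so the NLP rule stage has measurable work.
Everything is a pure function of the spec (including its seed).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import TextIO

from adekb.corpus_io import Corpus, GoldEntity, GoldRelation, SentenceRecord, TextSpan
from adekb.corpus_io import ADVERSE_EFFECT, DRUG
from adekb.knowledge_graph import ConceptGraph
from adekb.lexicon_concepts import CHEMICALS_AND_DRUGS, DISORDERS, ConceptEntry, Lexicon
from adekb.nlp_rules import find_long_form

CLEAN_RELATION_TYPES = ("cause_of", "isa", "associated_with", "has_finding_site")

_DRUG_STEMS = (
    "ba", "ce", "do", "fe", "gi", "lo", "ma", "ni", "pra", "ru",
    "sta", "tu", "vi", "xa", "zo", "ke", "mi", "sa", "te", "ve",
)
_DRUG_SUFFIXES = ("mab", "nib", "cin", "pril", "olol", "statin", "micin", "fen", "zole", "idone")

_DISORDER_ADJECTIVES = (
    "acute", "chronic", "severe", "toxic", "renal", "hepatic",
    "cardiac", "gastric", "ocular", "neural", "focal", "diffuse",
)
_DISORDER_HEADS = (
    "nephritis", "hepatitis", "anemia", "neuropathy", "dermatitis",
    "colitis", "myopathy", "fibrosis", "alopecia", "thrombocytopenia",
    "pancreatitis", "encephalopathy", "failure", "toxicity", "rash",
    "seizure", "vasculitis", "myelitis", "edema", "syndrome",
)


class FixtureError(ValueError):
    """Raised when a fixture spec cannot be realized (e.g. the required
    planted distances are unachievable with the given concept budget)."""


@dataclass
class FixtureSpec:
    n_drugs: int = 28
    n_disorders: int = 32
    n_background_concepts: int = 70
    n_true_pairs: int = 24
    n_trap_decoys: int = 24
    n_far_decoys: int = 20
    true_pair_distance: int = 3
    decoy_pair_min_distance: int = 5
    noise_relation_type: str = "co_occurs_with"
    n_documents: int = 200
    negative_sentence_fraction: float = 0.64
    coordination_rate: float = 0.15
    abbreviation_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.true_pair_distance < self.decoy_pair_min_distance):
            raise FixtureError("decoy_pair_min_distance must exceed true_pair_distance")
        for rate in (self.negative_sentence_fraction, self.coordination_rate, self.abbreviation_rate):
            if not (0.0 <= rate <= 1.0):
                raise FixtureError("rates must lie in [0, 1]")
        if self.n_true_pairs > min(self.n_drugs, self.n_disorders):
            raise FixtureError("n_true_pairs exceeds the concept inventory")
        if max(self.n_trap_decoys, self.n_far_decoys) > self.n_true_pairs:
            raise FixtureError("decoy counts exceed n_true_pairs")
        if self.n_true_pairs >= 3 and self.n_trap_decoys > 0 and self.n_true_pairs <= 7:
            raise FixtureError("n_true_pairs too small to separate trap and far decoy offsets")


TRUE = "true"
TRAP = "trap"
FAR = "far"


@dataclass
class CoordinationGadget:
    drug_cui: str
    effect_cui: str  # "adjA head"
    sibling_cui: str  # "adjB head"
    adj_a: str
    adj_b: str
    head: str


@dataclass
class AbbreviationGadget:
    effect_cui: str
    long_form: str
    short_form: str


@dataclass
class TruthTable:
    """Planted ground truth: pair classes and rendering gadgets."""

    noise_relation_type: str
    true_pairs: list[tuple[str, str]] = field(default_factory=list)
    trap_pairs: list[tuple[str, str]] = field(default_factory=list)
    far_pairs: list[tuple[str, str]] = field(default_factory=list)
    drug_names: dict[str, str] = field(default_factory=dict)
    disorder_names: dict[str, str] = field(default_factory=dict)
    coordination_gadgets: list[CoordinationGadget] = field(default_factory=list)
    abbreviation_gadgets: list[AbbreviationGadget] = field(default_factory=list)

    def pair_class(self, drug_cui: str, effect_cui: str) -> str | None:
        if (drug_cui, effect_cui) in set(self.true_pairs):
            return TRUE
        if (drug_cui, effect_cui) in set(self.trap_pairs):
            return TRAP
        if (drug_cui, effect_cui) in set(self.far_pairs):
            return FAR
        return None

    def dump(self, stream: TextIO) -> None:
        json.dump(
            {
                "noise_relation_type": self.noise_relation_type,
                "true_pairs": self.true_pairs,
                "trap_pairs": self.trap_pairs,
                "far_pairs": self.far_pairs,
                "drug_names": self.drug_names,
                "disorder_names": self.disorder_names,
            },
            stream,
            indent=2,
        )


def _make_drug_names(n: int, rng: random.Random) -> list[str]:
    names: list[str] = []
    seen = set()
    while len(names) < n:
        name = rng.choice(_DRUG_STEMS) + rng.choice(_DRUG_STEMS) + rng.choice(_DRUG_SUFFIXES)
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _make_disorder_names(n: int, rng: random.Random, taken: set[str]) -> list[str]:
    names: list[str] = []
    while len(names) < n:
        if rng.random() < 0.4:
            name = rng.choice(_DISORDER_HEADS)
        else:
            name = f"{rng.choice(_DISORDER_ADJECTIVES)} {rng.choice(_DISORDER_HEADS)}"
        if name not in taken:
            taken.add(name)
            names.append(name)
    return names


def generate_resources(spec: FixtureSpec) -> tuple[Lexicon, ConceptGraph, TruthTable]:
    """Build the toy lexicon, the typed concept graph with planted
    structure, and the ground-truth table of pair classes."""
    rng = random.Random(spec.seed)
    truth = TruthTable(noise_relation_type=spec.noise_relation_type)

    drug_cuis = [f"C1{i:05d}" for i in range(spec.n_drugs)]
    drug_names = _make_drug_names(spec.n_drugs, rng)
    taken = set(drug_names)

    n_coord = min(round(spec.coordination_rate * spec.n_true_pairs), spec.n_true_pairs)
    if spec.n_true_pairs + n_coord > spec.n_disorders:
        raise FixtureError("n_disorders too small for the coordination gadgets")
    primary_names = _make_disorder_names(spec.n_true_pairs, rng, taken)
    extra_names = _make_disorder_names(
        spec.n_disorders - spec.n_true_pairs - n_coord, rng, taken
    )

    # coordination gadgets rename a primary disorder to "adjA head" and
    # add a sibling "adjB head" related to the same drug
    sibling_names: list[str] = []
    coord_indices = sorted(rng.sample(range(spec.n_true_pairs), n_coord))
    for k, idx in enumerate(coord_indices):
        head = primary_names[idx].split()[-1]
        adjs = [a for a in _DISORDER_ADJECTIVES if f"{a} {head}" not in taken]
        if len(adjs) < 2:
            raise FixtureError("no free adjectives left for a coordination gadget")
        adj_a, adj_b = rng.sample(adjs, 2)
        taken.discard(primary_names[idx])
        primary_names[idx] = f"{adj_a} {head}"
        taken.add(primary_names[idx])
        sibling_names.append(f"{adj_b} {head}")
        taken.add(sibling_names[-1])

    disorder_names = primary_names + sibling_names + extra_names
    disorder_cuis = [f"C2{i:05d}" for i in range(len(disorder_names))]

    lexicon = Lexicon()
    for cui, name in zip(drug_cuis, drug_names):
        lexicon.entries[cui] = ConceptEntry(cui, name, CHEMICALS_AND_DRUGS)
        lexicon.add_term(name, cui)
        truth.drug_names[cui] = name
    for cui, name in zip(disorder_cuis, disorder_names):
        lexicon.entries[cui] = ConceptEntry(cui, name, DISORDERS)
        lexicon.add_term(name, cui)
        truth.disorder_names[cui] = name

    graph = ConceptGraph()
    for cui in drug_cuis + disorder_cuis:
        graph.add_concept(cui)
        graph.term_tier[lexicon.entries[cui].preferred_term] = cui
    for cui in drug_cuis:
        graph.type_tier[cui] = frozenset({"T121"})
    for cui in disorder_cuis:
        graph.type_tier[cui] = frozenset({"T047"})

    background = [f"C3{i:05d}" for i in range(spec.n_background_concepts)]
    bg_iter = iter(background)

    def next_background() -> str:
        try:
            cui = next(bg_iter)
        except StopIteration:
            raise FixtureError("n_background_concepts too small for the planted chains")
        graph.add_concept(cui)
        graph.type_tier[cui] = frozenset({"T169"})
        return cui

    def wire_clean_chain(a: str, b: str, length: int) -> None:
        nodes = [a] + [next_background() for _ in range(length - 1)] + [b]
        for x, y in zip(nodes, nodes[1:]):
            graph.add_edge(x, y, rng.choice(CLEAN_RELATION_TYPES))

    # true pairs: drug i <-> primary disorder i at planted short distance
    for i in range(spec.n_true_pairs):
        length = rng.randint(1, spec.true_pair_distance)
        wire_clean_chain(drug_cuis[i], disorder_cuis[i], length)
        truth.true_pairs.append((drug_cuis[i], disorder_cuis[i]))

    # coordination siblings: second true effect for the same drug
    for k, idx in enumerate(coord_indices):
        sibling_cui = disorder_cuis[spec.n_true_pairs + k]
        length = rng.randint(1, spec.true_pair_distance)
        wire_clean_chain(drug_cuis[idx], sibling_cui, length)
        truth.true_pairs.append((drug_cuis[idx], sibling_cui))
        adj_a, head = primary_names[idx].split()[0], primary_names[idx].split()[-1]
        truth.coordination_gadgets.append(
            CoordinationGadget(
                drug_cuis[idx],
                disorder_cuis[idx],
                sibling_cui,
                adj_a,
                sibling_names[k].split()[0],
                head,
            )
        )

    # trap decoys: distance-2 noise-typed chain drug i -- t -- disorder i+7
    for i in range(spec.n_trap_decoys):
        target = disorder_cuis[(i + 7) % spec.n_true_pairs]
        t = next_background()
        graph.add_edge(drug_cuis[i], t, spec.noise_relation_type)
        graph.add_edge(t, target, spec.noise_relation_type)
        truth.trap_pairs.append((drug_cuis[i], target))

    # far decoys: no direct wiring; the shortest route threads several
    # gadgets and stays long
    for i in range(spec.n_far_decoys):
        target = disorder_cuis[(i + 3) % spec.n_true_pairs]
        truth.far_pairs.append((drug_cuis[i], target))

    # abbreviation gadgets: multiword primary effects get a short form
    n_abbr = round(spec.abbreviation_rate * spec.n_true_pairs)
    short_forms: set[str] = set()
    for idx in range(spec.n_true_pairs):
        if len(truth.abbreviation_gadgets) >= n_abbr:
            break
        if idx in coord_indices:
            continue
        name = primary_names[idx]
        words = name.split()
        if len(words) < 2:
            continue
        sf = "".join(w[0] for w in words).upper()
        if sf in short_forms:
            sf = sf + words[-1][1]  # still a subsequence of the long form
        if sf in short_forms:
            continue
        # plant only short forms the expansion algorithm resolves to the
        # full planted term (e.g. "AA" for "acute anemia" resolves to
        # just "anemia": the second 'a' also starts a word)
        resolved = find_long_form(sf, name)
        if resolved is None or resolved.casefold() != name.casefold():
            continue
        short_forms.add(sf)
        truth.abbreviation_gadgets.append(AbbreviationGadget(disorder_cuis[idx], name, sf))

    # remaining background concepts: a clean side component plus a few
    # isolated concepts, detached from every gadget
    side = []
    try:
        while True:
            side.append(next_background())
    except FixtureError:
        pass
    for i in range(len(side) - 2):
        if rng.random() < 0.7:
            graph.add_edge(side[i], side[i + 1], rng.choice(CLEAN_RELATION_TYPES))

    _validate_planted_distances(spec, graph, truth)
    return lexicon, graph, truth


def _validate_planted_distances(spec: FixtureSpec, graph: ConceptGraph, truth: TruthTable) -> None:
    for d, e in truth.true_pairs:
        if graph.distance(d, e) > spec.true_pair_distance:
            raise FixtureError(f"true pair {d}-{e} exceeds planted distance")
    for d, e in truth.trap_pairs:
        summary = graph.shortest_path_summary(d, e, horizon=spec.true_pair_distance + 1)
        if summary.distance > spec.true_pair_distance:
            raise FixtureError(f"trap pair {d}-{e} is not short")
        if not all(
            any(spec.noise_relation_type in hop for hop in path) for path in summary.paths
        ):
            raise FixtureError(f"trap pair {d}-{e} has a clean shortest path")
    for d, e in truth.far_pairs:
        if graph.distance(d, e, horizon=spec.decoy_pair_min_distance) < spec.decoy_pair_min_distance:
            raise FixtureError(f"far pair {d}-{e} is too close")


# --------------------------------------------------------------------------
# corpus generation

_NO_PAIR_SENTENCES = (
    "The patient recovered fully after discharge.",
    "No complications were observed during follow-up.",
    "Laboratory values returned to normal within two weeks.",
    "The clinical course was otherwise uneventful.",
)


def _maybe_plural(name: str, rng: random.Random) -> str:
    words = name.split()
    if len(words) == 1 and rng.random() < 0.3 and not name.endswith("s"):
        return name + "s"
    return name


@dataclass
class _Rendered:
    text: str
    relations: list[tuple[str, int, int, str, int, int]] = field(default_factory=list)
    # (drug surface, dstart, dend, effect surface, estart, eend) sentence-relative


def _find(text: str, surface: str) -> tuple[int, int]:
    start = text.index(surface)
    return start, start + len(surface)


def _simple_positive(truth: TruthTable, rng: random.Random, far_lookup: dict[str, str]) -> _Rendered:
    drug_cui, effect_cui = rng.choice(truth.true_pairs)
    drug = truth.drug_names[drug_cui]
    effect = _maybe_plural(truth.disorder_names[effect_cui], rng)
    choice = rng.random()
    other_cui = far_lookup.get(drug_cui)
    if choice < 0.3 and other_cui is not None:
        other = truth.disorder_names[other_cui]
        cap = effect[0].upper() + effect[1:]
        text = f"{cap} as a complication of {drug} treatment of {other}."
        estart, eend = 0, len(effect)
    elif choice < 0.6:
        text = f"A case of {drug}-induced {effect} is reported."
        estart, eend = _find(text, effect)
    else:
        cap = effect[0].upper() + effect[1:]
        text = f"{cap} developed after {drug} therapy."
        estart, eend = 0, len(effect)
    dstart, dend = _find(text, drug)
    return _Rendered(text, [(drug, dstart, dend, effect if estart else cap, estart, eend)])


def _coordination_positive(gadget: CoordinationGadget, truth: TruthTable, rng: random.Random) -> _Rendered:
    drug = truth.drug_names[gadget.drug_cui]
    adj_a_cap = gadget.adj_a[0].upper() + gadget.adj_a[1:]
    text = f"{adj_a_cap} and {gadget.adj_b} {gadget.head} occurred during {drug} therapy."
    dstart, dend = _find(text, drug)
    b_h = f"{gadget.adj_b} {gadget.head}"
    bstart, bend = _find(text, b_h)
    return _Rendered(
        text,
        [
            (drug, dstart, dend, adj_a_cap, 0, len(adj_a_cap)),
            (drug, dstart, dend, b_h, bstart, bend),
        ],
    )


def _abbreviation_positive(
    gadget: AbbreviationGadget, truth: TruthTable, rng: random.Random
) -> list[_Rendered]:
    lf = gadget.long_form
    lf_cap = lf[0].upper() + lf[1:]
    definition = _Rendered(f"{lf_cap} ({gadget.short_form}) is a recognized adverse event.")
    drug_cui = next(d for d, e in truth.true_pairs if e == gadget.effect_cui)
    drug = truth.drug_names[drug_cui]
    text = f"{gadget.short_form} was attributed to {drug} exposure."
    dstart, dend = _find(text, drug)
    use = _Rendered(text, [(drug, dstart, dend, gadget.short_form, 0, len(gadget.short_form))])
    return [definition, use]


def _negative(truth: TruthTable, rng: random.Random, trap_cycle: list[int]) -> _Rendered:
    choice = rng.random()
    if choice < 0.35 and truth.trap_pairs:
        i = trap_cycle[0] % len(truth.trap_pairs)
        trap_cycle[0] += 1
        drug_cui, effect_cui = truth.trap_pairs[i]
        drug = truth.drug_names[drug_cui]
        effect = truth.disorder_names[effect_cui]
        text = f"The patient received {drug} for {effect}."
    elif choice < 0.60 and truth.far_pairs:
        drug_cui, effect_cui = rng.choice(truth.far_pairs)
        drug = truth.drug_names[drug_cui]
        effect = truth.disorder_names[effect_cui]
        cap = drug[0].upper() + drug[1:]
        text = f"{cap} was administered to a patient with {effect}."
    elif choice < 0.75:
        drug_cui = rng.choice(list(truth.drug_names))
        text = f"Treatment with {truth.drug_names[drug_cui]} was well tolerated."
    elif choice < 0.90:
        effect_cui = rng.choice(list(truth.disorder_names))
        text = f"A history of {truth.disorder_names[effect_cui]} was noted."
    else:
        text = rng.choice(_NO_PAIR_SENTENCES)
    return _Rendered(text)


def generate_corpus(spec: FixtureSpec, lexicon: Lexicon, truth: TruthTable) -> Corpus:
    """Render the annotated corpus from sentence templates; every gold
    surface equals the document slice at its offsets (checked at
    emission via :meth:`Corpus.validate`)."""
    rng = random.Random(spec.seed + 1)
    far_lookup = dict(truth.far_pairs)
    trap_cycle = [0]
    corpus = Corpus()
    for d in range(spec.n_documents):
        doc_id = f"SYN{d:04d}"
        n_slots = rng.randint(2, 4)
        rendered: list[_Rendered] = []
        seen_text: set[str] = set()
        attempts = 0
        while len(rendered) < n_slots and attempts < 50:
            attempts += 1
            if rng.random() < spec.negative_sentence_fraction:
                batch = [_negative(truth, rng, trap_cycle)]
            else:
                r = rng.random()
                if r < spec.abbreviation_rate and truth.abbreviation_gadgets:
                    batch = _abbreviation_positive(
                        rng.choice(truth.abbreviation_gadgets), truth, rng
                    )
                elif (
                    r < spec.abbreviation_rate + spec.coordination_rate
                    and truth.coordination_gadgets
                ):
                    batch = [_coordination_positive(rng.choice(truth.coordination_gadgets), truth, rng)]
                else:
                    batch = [_simple_positive(truth, rng, far_lookup)]
            # duplicate sentence text within a document would be merged
            # into one record on read-back; skip such renderings
            if any(b.text in seen_text for b in batch):
                continue
            seen_text.update(b.text for b in batch)
            rendered.extend(batch)
        records = []
        offset = 0
        for idx, r in enumerate(rendered):
            span = TextSpan(offset, offset + len(r.text))
            relations = tuple(
                GoldRelation(
                    doc_id,
                    idx,
                    GoldEntity(TextSpan(offset + ds, offset + de), dsurf, DRUG),
                    GoldEntity(TextSpan(offset + es, offset + ee), esurf, ADVERSE_EFFECT),
                )
                for dsurf, ds, de, esurf, es, ee in r.relations
            )
            records.append(SentenceRecord(doc_id, idx, r.text, span, relations))
            offset = span.end + 1
        corpus.documents[doc_id] = records
    corpus.validate()
    return corpus


def write_resources(
    lexicon: Lexicon,
    graph: ConceptGraph,
    truth: TruthTable,
    vocab_stream: TextIO,
    group_stream: TextIO,
    relation_stream: TextIO,
) -> None:
    """Emit the lexicon as term/CUI TSV plus a CUI/group table, and the
    graph as a relation TSV, in the formats the loaders read back."""
    for cui in sorted(lexicon.entries):
        entry = lexicon.entries[cui]
        vocab_stream.write(f"{entry.preferred_term}\t{cui}\n")
        group_stream.write(f"{cui}\t{entry.semantic_group}\n")
    for edge in sorted(graph.edges(), key=lambda e: (e.cui_a, e.cui_b, e.relation_type)):
        relation_stream.write(f"{edge.cui_a}\t{edge.cui_b}\t{edge.relation_type}\n")
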