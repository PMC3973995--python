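"""Candidate generation and the knowledge-base relation decision.

A drug-disorder mention pair in one sentence becomes a predicted
adverse-event relation when the shortest-path distance between the two
concepts in the knowledge graph is at most a threshold (default 4), and
-- when a trained relation-type filter is supplied -- at least one
shortest path is free of discarded relation types.  The filter is
trained by labeling distance-accepted training candidates against the
gold standard and counting relation-type occurrences on shortest paths
of true- and false-positive pairs: a type with
(false-positive count + 1) / (true-positive count + 1) strictly greater
than a ratio threshold (default 7) is discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

from adekb.corpus_io import Corpus, SentenceRecord
from adekb.knowledge_graph import INFINITE, ConceptGraph, PathSummary
from adekb.lexicon_concepts import CHEMICALS_AND_DRUGS, DISORDERS, EntityMention, Lexicon
from adekb.nlp_rules import NlpConfig, annotate_document
from adekb.tagging import DEFAULT_TAGGER, Tagger

ANY_PATH_SURVIVES = "any_path_survives"
ALL_PATHS_CLEAN = "all_paths_clean"


@dataclass
class ExtractionConfig:
    distance_threshold: float = 4  # INFINITE gives the co-occurrence baseline
    type_ratio_threshold: float = 7.0
    path_cap: int = 64
    horizon: float | None = None  # defaults to distance_threshold + 1
    filter_mode: str = ANY_PATH_SURVIVES

    def __post_init__(self) -> None:
        if self.horizon is None:
            self.horizon = (
                INFINITE if self.distance_threshold == INFINITE else self.distance_threshold + 1
            )
        if self.horizon < self.distance_threshold:
            raise ValueError("horizon must be >= distance_threshold")
        if self.filter_mode not in (ANY_PATH_SURVIVES, ALL_PATHS_CLEAN):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")


@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    sentence_index: int
    drug: EntityMention
    effect: EntityMention


@dataclass
class ExtractedRelation:
    pair: CandidatePair
    distance: float
    surviving_path_count: int
    decision_trace: str = ""


@dataclass
class RelationTypeFilter:
    """Per-relation-type true/false-positive counts and the derived
    discarded-type set under the (fp+1)/(tp+1) > threshold rule."""

    stats: dict[str, tuple[int, int]] = field(default_factory=dict)  # type -> (tp, fp)
    ratio_threshold: float = 7.0

    def ratio(self, relation_type: str) -> float:
        tp, fp = self.stats.get(relation_type, (0, 0))
        return (fp + 1) / (tp + 1)

    @property
    def discarded(self) -> frozenset[str]:
        return frozenset(t for t in self.stats if self.ratio(t) > self.ratio_threshold)

    def count(self, relation_type: str, true_positive: bool) -> None:
        tp, fp = self.stats.get(relation_type, (0, 0))
        self.stats[relation_type] = (tp + 1, fp) if true_positive else (tp, fp + 1)

    def dump(self, stream: TextIO) -> None:
        json.dump(
            {
                "ratio_threshold": self.ratio_threshold,
                "stats": {t: list(c) for t, c in sorted(self.stats.items())},
                "discarded": sorted(self.discarded),
            },
            stream,
            indent=2,
        )

    @classmethod
    def load(cls, stream: TextIO) -> "RelationTypeFilter":
        data = json.load(stream)
        return cls(
            stats={t: (c[0], c[1]) for t, c in data["stats"].items()},
            ratio_threshold=data["ratio_threshold"],
        )


def generate_candidates(
    doc_id: str, sentence_index: int, mentions: Sequence[EntityMention]
) -> list[CandidatePair]:
    """Cross product of drug-group and disorder-group mentions within
    one sentence; identical-span pairs are excluded; order is by drug
    start then effect start."""
    drugs = [m for m in mentions if m.semantic_group == CHEMICALS_AND_DRUGS]
    effects = [m for m in mentions if m.semantic_group == DISORDERS]
    pairs = [
        CandidatePair(doc_id, sentence_index, d, e)
        for d in drugs
        for e in effects
        if (d.span.start, d.span.end) != (e.span.start, e.span.end)
    ]
    pairs.sort(key=lambda p: (p.drug.span.start, p.drug.span.end, p.effect.span.start, p.effect.span.end))
    return pairs


@dataclass
class _Grounding:
    """Minimum-distance CUI grounding of a candidate pair.

    Mentions sharing a span may carry several CUIs; the pair's distance
    is the minimum over CUI combinations and the minimizing combination
    supplies the paths."""

    distance: float
    summary: PathSummary | None


def _ground(
    pair: CandidatePair,
    co_mentions: Sequence[EntityMention],
    graph: ConceptGraph,
    config: ExtractionConfig,
    need_paths: bool,
) -> _Grounding:
    drug_cuis = sorted(
        {
            m.cui
            for m in co_mentions
            if m.span == pair.drug.span and m.semantic_group == CHEMICALS_AND_DRUGS
        }
        or {pair.drug.cui}
    )
    effect_cuis = sorted(
        {
            m.cui
            for m in co_mentions
            if m.span == pair.effect.span and m.semantic_group == DISORDERS
        }
        or {pair.effect.cui}
    )
    best = INFINITE
    best_pair: tuple[str, str] | None = None
    for dc in drug_cuis:
        for ec in effect_cuis:
            d = graph.distance(dc, ec, config.horizon)
            if d < best:
                best, best_pair = d, (dc, ec)
    summary = None
    if need_paths and best_pair is not None and 0 < best < INFINITE:
        summary = graph.shortest_path_summary(
            best_pair[0], best_pair[1], config.horizon, config.path_cap
        )
    return _Grounding(best, summary)


def _path_clean(path: tuple[frozenset[str], ...], discarded: frozenset[str]) -> bool:
    return all(not (hop & discarded) for hop in path)


def decide_relation(
    pair: CandidatePair,
    graph: ConceptGraph,
    config: ExtractionConfig,
    type_filter: RelationTypeFilter | None = None,
    co_mentions: Sequence[EntityMention] = (),
) -> tuple[bool, ExtractedRelation]:
    """Accept a candidate iff its knowledge-graph distance is at most
    the threshold and (if a filter is given) the shortest paths survive
    relation-type filtering."""
    need_paths = type_filter is not None and bool(type_filter.discarded)
    grounding = _ground(pair, co_mentions or (pair.drug, pair.effect), graph, config, need_paths)
    dist = grounding.distance
    if dist > config.distance_threshold:
        rel = ExtractedRelation(pair, dist, 0, f"reject: distance {dist} > threshold")
        return False, rel
    if not need_paths or grounding.summary is None:
        n_paths = len(grounding.summary.paths) if grounding.summary else 0
        return True, ExtractedRelation(pair, dist, n_paths, "accept: within distance threshold")
    discarded = type_filter.discarded
    surviving = sum(1 for p in grounding.summary.paths if _path_clean(p, discarded))
    trace = f"{surviving}/{len(grounding.summary.paths)} shortest paths pass the type filter"
    if grounding.summary.truncated:
        trace += " (enumeration truncated)"
    if config.filter_mode == ANY_PATH_SURVIVES:
        accept = surviving >= 1
    else:
        accept = surviving == len(grounding.summary.paths) and surviving >= 1
    verdict = "accept" if accept else "reject"
    return accept, ExtractedRelation(pair, dist, surviving, f"{verdict}: {trace}")


def iter_sentence_candidates(
    corpus: Corpus,
    lexicon: Lexicon,
    nlp_config: NlpConfig | None = None,
    tagger: Tagger = DEFAULT_TAGGER,
    use_nlp: bool = True,
) -> Iterator[tuple[SentenceRecord, list[EntityMention], list[CandidatePair]]]:
    """Run concept recognition document by document and yield each
    sentence with its mentions and candidate pairs."""
    for doc_id, records in corpus.documents.items():
        mentions_by_sentence = annotate_document(records, lexicon, nlp_config, tagger, use_nlp)
        for rec in records:
            mentions = mentions_by_sentence.get(rec.sentence_index, [])
            yield rec, mentions, generate_candidates(doc_id, rec.sentence_index, mentions)


def train_relation_type_filter(
    training_corpus: Corpus,
    lexicon: Lexicon,
    graph: ConceptGraph,
    config: ExtractionConfig | None = None,
    nlp_config: NlpConfig | None = None,
    tagger: Tagger = DEFAULT_TAGGER,
    warnings: list[str] | None = None,
) -> RelationTypeFilter:
    """Train the relation-type filter on a gold-annotated corpus.

    Every distance-accepted candidate is labeled true positive when it
    boundary-exactly matches a gold relation, else false positive.  Each
    relation-type occurrence on each hop of each enumerated shortest
    path of the candidate increments that type's TP or FP count.
    """
    config = config or ExtractionConfig()
    type_filter = RelationTypeFilter(ratio_threshold=config.type_ratio_threshold)
    if training_corpus.n_documents == 0 and warnings is not None:
        warnings.append("empty training corpus: relation-type filter discards nothing")
    gold_keys = {
        (r.doc_id, r.drug.span.start, r.drug.span.end, r.effect.span.start, r.effect.span.end)
        for r in training_corpus.gold_relations()
    }
    for rec, mentions, candidates in iter_sentence_candidates(
        training_corpus, lexicon, nlp_config, tagger
    ):
        for pair in candidates:
            grounding = _ground(pair, mentions, graph, config, need_paths=True)
            if grounding.distance > config.distance_threshold or grounding.summary is None:
                continue
            key = (
                pair.doc_id,
                pair.drug.span.start,
                pair.drug.span.end,
                pair.effect.span.start,
                pair.effect.span.end,
            )
            is_tp = key in gold_keys
            for path in grounding.summary.paths:
                for hop in path:
                    for relation_type in hop:
                        type_filter.count(relation_type, is_tp)
    return type_filter


def extract(
    corpus: Corpus,
    lexicon: Lexicon,
    graph: ConceptGraph,
    config: ExtractionConfig | None = None,
    type_filter: RelationTypeFilter | None = None,
    nlp_config: NlpConfig | None = None,
    tagger: Tagger = DEFAULT_TAGGER,
    use_nlp: bool = True,
    manifest: dict | None = None,
) -> list[ExtractedRelation]:
    """Full pipeline: concept recognition, NLP rules, candidate
    generation, and the knowledge-base decision, in corpus order.

    With ``distance_threshold=INFINITE`` and no filter every candidate
    is accepted: the co-occurrence baseline."""
    config = config or ExtractionConfig()
    relations: list[ExtractedRelation] = []
    counts = {"sentences": 0, "mentions": 0, "candidates": 0, "accepted": 0}
    for rec, mentions, candidates in iter_sentence_candidates(
        corpus, lexicon, nlp_config, tagger, use_nlp
    ):
        counts["sentences"] += 1
        counts["mentions"] += len(mentions)
        counts["candidates"] += len(candidates)
        for pair in candidates:
            accepted, rel = decide_relation(pair, graph, config, type_filter, mentions)
            if accepted:
                counts["accepted"] += 1
                relations.append(rel)
    if manifest is not None:
        manifest["config"] = {
            "distance_threshold": config.distance_threshold,
            "type_ratio_threshold": config.type_ratio_threshold,
            "path_cap": config.path_cap,
            "horizon": config.horizon,
            "filter_mode": config.filter_mode,
            "use_nlp": use_nlp,
            "filter_discards": sorted(type_filter.discarded) if type_filter else [],
        }
        manifest["counts"] = counts
    return relations


def write_relations(relations: Iterable[ExtractedRelation], stream: TextIO) -> None:
    """TSV export of extracted relations."""
    header = (
        "doc_id\tsentence_index\tdrug\tdrug_start\tdrug_end\tdrug_cui"
        "\teffect\teffect_start\teffect_end\teffect_cui\tdistance\tsurviving_paths\n"
    )
    stream.write(header)
    for rel in relations:
        p = rel.pair
        dist = "INF" if rel.distance == INFINITE else str(int(rel.distance))
        stream.write(
            "\t".join(
                (
                    p.doc_id,
                    str(p.sentence_index),
                    p.drug.surface,
                    str(p.drug.span.start),
                    str(p.drug.span.end),
                    p.drug.cui,
                    p.effect.surface,
                    str(p.effect.span.start),
                    str(p.effect.span.end),
                    p.effect.cui,
                    dist,
                    str(rel.surviving_path_count),
                )
            )
            + "\n"
        )
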