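"""Boundary-exact scoring, error taxonomy, and comparison-subset
construction.

A predicted relation counts as a true positive only when both its
entity character spans coincide exactly with a gold annotation in the
same document (no partial credit).  Metrics are micro-averaged over the
corpus; duplicate predictions on the same span pair collapse before
scoring, since the gold standard is span-anchored, not concept-anchored.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from adekb.corpus_io import Corpus, GoldRelation
from adekb.knowledge_graph import INFINITE, ConceptGraph
from adekb.lexicon_concepts import Lexicon
from adekb.nlp_rules import NlpConfig
from adekb.relation_extraction import (
    ExtractionConfig,
    ExtractedRelation,
    RelationTypeFilter,
    extract,
    iter_sentence_candidates,
)
from adekb.tagging import DEFAULT_TAGGER, Tagger

# error taxonomy
FP_RELATION_ENTITIES_CORRECT = "FP_RELATION_ENTITIES_CORRECT"
FP_RELATION_ENTITIES_WRONG = "FP_RELATION_ENTITIES_WRONG"
FN_RELATION_FILTERED = "FN_RELATION_FILTERED"
FN_ENTITY_MISSED = "FN_ENTITY_MISSED"

RelationKey = tuple[str, int, int, int, int]  # doc, drug span, effect span


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent scale), rounded to
    one decimal; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return round(2 * precision * recall / (precision + recall), 1)


@dataclass
class Metrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": round(self.precision, 1),
            "recall": round(self.recall, 1),
            "f_score": round(self.f, 1),
        }


def _gold_key(rel: GoldRelation) -> RelationKey:
    return (
        rel.doc_id,
        rel.drug.span.start,
        rel.drug.span.end,
        rel.effect.span.start,
        rel.effect.span.end,
    )


def _pred_key(rel: ExtractedRelation) -> RelationKey:
    p = rel.pair
    return (
        p.doc_id,
        p.drug.span.start,
        p.drug.span.end,
        p.effect.span.start,
        p.effect.span.end,
    )


@dataclass
class MatchResult:
    metrics: Metrics
    true_positives: list[RelationKey]
    false_positives: list[RelationKey]
    false_negatives: list[RelationKey]


def match_exact(
    predicted: Iterable[ExtractedRelation], gold: Iterable[GoldRelation]
) -> MatchResult:
    """One-to-one boundary-exact matching of predictions against gold."""
    pred_keys = sorted(set(map(_pred_key, predicted)))
    gold_keys = set(map(_gold_key, gold))
    tps = [k for k in pred_keys if k in gold_keys]
    fps = [k for k in pred_keys if k not in gold_keys]
    fns = sorted(gold_keys.difference(pred_keys))
    return MatchResult(Metrics(len(tps), len(fps), len(fns)), tps, fps, fns)


@dataclass
class ErrorCase:
    kind: str
    key: RelationKey
    sentence_text: str = ""


def categorize_errors(
    result: MatchResult,
    corpus: Corpus,
    mention_spans: dict[str, set[tuple[int, int]]],
    sample: int | None = None,
    seed: int = 0,
) -> list[ErrorCase]:
    """Four-way error taxonomy over all FP and FN instances.

    A false positive has its entities "correctly identified" when both
    predicted spans boundary-match some gold entity annotation; a false
    negative is an entity miss when either gold entity has no
    boundary-matching system mention, else the relation was rejected by
    the knowledge base or the type filter.

    *mention_spans* maps doc_id to the set of system mention spans.
    Note the corpus only annotates entities participating in relations,
    so "correctly identified" under-counts correct entities.
    """
    gold_entity_spans: dict[str, set[tuple[int, int]]] = {}
    for rec in corpus.sentences():
        for rel in rec.gold_relations:
            spans = gold_entity_spans.setdefault(rec.doc_id, set())
            for ent in (rel.drug, rel.effect):
                spans.add((ent.span.start, ent.span.end))

    def sentence_for(doc_id: str, start: int) -> str:
        for rec in corpus.documents.get(doc_id, []):
            if rec.span.start <= start < rec.span.end:
                return rec.text
        return ""

    cases: list[ErrorCase] = []
    for key in result.false_positives:
        doc_id, ds, de, es, ee = key
        gold_spans = gold_entity_spans.get(doc_id, set())
        kind = (
            FP_RELATION_ENTITIES_CORRECT
            if (ds, de) in gold_spans and (es, ee) in gold_spans
            else FP_RELATION_ENTITIES_WRONG
        )
        cases.append(ErrorCase(kind, key, sentence_for(doc_id, ds)))
    for key in result.false_negatives:
        doc_id, ds, de, es, ee = key
        found = mention_spans.get(doc_id, set())
        kind = (
            FN_RELATION_FILTERED
            if (ds, de) in found and (es, ee) in found
            else FN_ENTITY_MISSED
        )
        cases.append(ErrorCase(kind, key, sentence_for(doc_id, ds)))
    if sample is not None and sample < len(cases):
        cases = random.Random(seed).sample(cases, sample)
    return cases


def error_summary(cases: Sequence[ErrorCase]) -> dict[str, int]:
    summary = {
        FP_RELATION_ENTITIES_CORRECT: 0,
        FP_RELATION_ENTITIES_WRONG: 0,
        FN_RELATION_FILTERED: 0,
        FN_ENTITY_MISSED: 0,
    }
    for c in cases:
        summary[c.kind] += 1
    return summary


# --------------------------------------------------------------------------
# balanced comparison subset (positive sentences only)

@dataclass
class ComparisonSubsetSpec:
    positives_to_negatives_ratio: float = 1.26
    drop_nested: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positives_to_negatives_ratio <= 0:
            raise ValueError("ratio must be positive")


@dataclass
class LabeledPair:
    key: RelationKey
    label: bool  # True relation vs false co-occurrence


def build_comparison_subset(
    corpus: Corpus,
    lexicon: Lexicon,
    spec: ComparisonSubsetSpec,
    nlp_config: NlpConfig | None = None,
    tagger: Tagger = DEFAULT_TAGGER,
    warnings: list[str] | None = None,
) -> list[LabeledPair]:
    """Labeled pair set for comparison against classifier-style systems.

    Uses positive sentences only; optionally drops gold relations with
    nested entity spans; positives are gold relations whose both
    entities the recognizer found boundary-exactly, supplemented by
    seeded-random false co-occurrence pairs until the configured
    positives:negatives ratio is reached.
    """
    gold_keys: set[RelationKey] = set()
    for rel in corpus.gold_relations():
        if spec.drop_nested and rel.nested:
            continue
        gold_keys.add(_gold_key(rel))

    found_positive: set[RelationKey] = set()
    negative_pool: set[RelationKey] = set()
    for rec, mentions, candidates in iter_sentence_candidates(corpus, lexicon, nlp_config, tagger):
        if not rec.is_positive:
            continue
        spans = {(m.span.start, m.span.end) for m in mentions}
        for key in gold_keys:
            doc_id, ds, de, es, ee = key
            if doc_id == rec.doc_id and (ds, de) in spans and (es, ee) in spans:
                found_positive.add(key)
        for pair in candidates:
            key = (
                pair.doc_id,
                pair.drug.span.start,
                pair.drug.span.end,
                pair.effect.span.start,
                pair.effect.span.end,
            )
            if key not in gold_keys:
                negative_pool.add(key)

    n_neg_wanted = round(len(found_positive) / spec.positives_to_negatives_ratio)
    pool = sorted(negative_pool)
    rng = random.Random(spec.seed)
    if n_neg_wanted >= len(pool):
        negatives = pool
        if n_neg_wanted > len(pool) and warnings is not None:
            achieved = len(found_positive) / len(pool) if pool else INFINITE
            warnings.append(
                f"only {len(pool)} negatives available; achieved ratio {achieved:.2f}:1"
            )
    else:
        negatives = rng.sample(pool, n_neg_wanted)
    out = [LabeledPair(k, True) for k in sorted(found_positive)]
    out += [LabeledPair(k, False) for k in sorted(negatives)]
    return out


# --------------------------------------------------------------------------
# stage-wise reporting

STAGES = ("baseline", "nlp", "knowledge_base", "type_filter")


def stage_report(
    corpus: Corpus,
    lexicon: Lexicon,
    graph: ConceptGraph,
    config: ExtractionConfig | None = None,
    type_filter: RelationTypeFilter | None = None,
    nlp_config: NlpConfig | None = None,
    tagger: Tagger = DEFAULT_TAGGER,
) -> dict[str, Metrics]:
    """Evaluate the four nested system configurations: dictionary-only
    co-occurrence; + NLP rules; + distance threshold; + relation-type
    filter."""
    config = config or ExtractionConfig()
    gold = list(corpus.gold_relations())
    cooc = ExtractionConfig(
        distance_threshold=INFINITE,
        type_ratio_threshold=config.type_ratio_threshold,
        path_cap=config.path_cap,
    )
    rows = {
        "baseline": extract(corpus, lexicon, graph, cooc, None, nlp_config, tagger, use_nlp=False),
        "nlp": extract(corpus, lexicon, graph, cooc, None, nlp_config, tagger),
        "knowledge_base": extract(corpus, lexicon, graph, config, None, nlp_config, tagger),
        "type_filter": extract(corpus, lexicon, graph, config, type_filter, nlp_config, tagger),
    }
    return {stage: match_exact(preds, gold).metrics for stage, preds in rows.items()}


def stage_deltas(report: dict[str, Metrics]) -> dict[str, dict[str, float]]:
    """Pairwise differences (percentage points) between consecutive
    stage rows."""
    out = {}
    for prev, cur in zip(STAGES, STAGES[1:]):
        a, b = report[prev], report[cur]
        out[f"{prev}->{cur}"] = {
            "precision": round(b.precision - a.precision, 1),
            "recall": round(b.recall - a.recall, 1),
            "f_score": round(b.f - a.f, 1),
        }
    return out
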