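import random

import pytest

from adekb.corpus_io import (
    ADVERSE_EFFECT,
    DRUG,
    Corpus,
    GoldEntity,
    GoldRelation,
    SentenceRecord,
    TextSpan,
)
from adekb.evaluation import (
    FN_ENTITY_MISSED,
    FN_RELATION_FILTERED,
    FP_RELATION_ENTITIES_CORRECT,
    FP_RELATION_ENTITIES_WRONG,
    ComparisonSubsetSpec,
    Metrics,
    build_comparison_subset,
    categorize_errors,
    error_summary,
    f_score,
    match_exact,
    stage_deltas,
    stage_report,
)
from adekb.lexicon_concepts import CHEMICALS_AND_DRUGS, DISORDERS, EntityMention
from adekb.relation_extraction import CandidatePair, ExtractionConfig, ExtractedRelation
from tests.conftest import make_lexicon


def predicted(doc_id, drug_span, effect_span, distance=1):
    drug = EntityMention(TextSpan(*drug_span), "d", "D1", CHEMICALS_AND_DRUGS)
    effect = EntityMention(TextSpan(*effect_span), "e", "E1", DISORDERS)
    return ExtractedRelation(CandidatePair(doc_id, 0, drug, effect), distance, 1)


def gold(doc_id, drug_span, effect_span, sentence_index=0):
    return GoldRelation(
        doc_id,
        sentence_index,
        GoldEntity(TextSpan(*drug_span), "d", DRUG),
        GoldEntity(TextSpan(*effect_span), "e", ADVERSE_EFFECT),
    )


class TestFScore:
    # precision/recall pairs and the F-scores they should reproduce, as
    # printed in published system evaluations; rounding the inputs to
    # one decimal can move the recomputed F by at most one ulp
    PUBLISHED = [
        (8.9, 78.4, 16.1),
        (21.1, 82.9, 33.6),
        (32.8, 78.1, 46.2),
        (38.1, 74.8, 50.5),
        (43.2, 1.6, 3.1),
        (41.8, 15.2, 22.3),
        (40.6, 64.1, 49.7),
        (37.0, 76.5, 49.9),
        (39.8, 75.2, 52.1),
        (41.1, 75.7, 53.3),
        (42.1, 76.3, 54.3),
        (88.5, 88.6, 88.5),
        (89.1, 88.2, 88.6),
        (91.8, 86.1, 88.8),
    ]

    @pytest.mark.parametrize("p,r,f", PUBLISHED)
    def test_reproduces_published_f_scores(self, p, r, f):
        assert abs(f_score(p, r) - f) <= 0.1 + 1e-9

    def test_edge_values(self):
        assert f_score(100.0, 100.0) == 100.0
        assert f_score(0.0, 50.0) == 0.0
        assert f_score(0.0, 0.0) == 0.0

    @pytest.mark.parametrize("p,r", [(38.1, 74.8), (10.0, 90.0), (55.5, 55.5)])
    def test_symmetry_and_betweenness(self, p, r):
        assert f_score(p, r) == f_score(r, p)
        assert min(p, r) - 0.05 <= f_score(p, r) <= max(p, r) + 0.05


class TestMatchExact:
    def test_off_by_one_is_fp_plus_fn(self):
        result = match_exact([predicted("d1", (0, 4), (10, 15))], [gold("d1", (0, 4), (10, 16))])
        assert (result.metrics.tp, result.metrics.fp, result.metrics.fn) == (0, 1, 1)

    def test_identical_sets(self):
        preds = [predicted("d1", (0, 4), (10, 15)), predicted("d2", (2, 6), (9, 14))]
        golds = [gold("d1", (0, 4), (10, 15)), gold("d2", (2, 6), (9, 14))]
        result = match_exact(preds, golds)
        assert (result.metrics.tp, result.metrics.fp, result.metrics.fn) == (2, 0, 0)

    def test_duplicate_predictions_collapse(self):
        preds = [predicted("d1", (0, 4), (10, 15))] * 3
        result = match_exact(preds, [gold("d1", (0, 4), (10, 15))])
        assert (result.metrics.tp, result.metrics.fp) == (1, 0)

    def test_counts_tie_out_with_set_comparison_oracle(self):
        rng = random.Random(5)
        for _ in range(50):
            gold_keys = {
                ("d", (rng.randint(0, 5), 6), (rng.randint(10, 15), 16))
                for _ in range(rng.randint(0, 8))
            }
            pred_keys = {
                ("d", (rng.randint(0, 5), 6), (rng.randint(10, 15), 16))
                for _ in range(rng.randint(0, 8))
            }
            golds = [gold(d, ds, es) for d, ds, es in gold_keys]
            preds = [predicted(d, ds, es) for d, ds, es in pred_keys]
            result = match_exact(preds, golds)
            assert result.metrics.tp == len(gold_keys & pred_keys)
            assert result.metrics.fp == len(pred_keys - gold_keys)
            assert result.metrics.fn == len(gold_keys - pred_keys)
            # bookkeeping identities
            assert result.metrics.tp + result.metrics.fn == len(gold_keys)
            assert result.metrics.tp + result.metrics.fp == len(pred_keys)


class TestMetrics:
    def test_zero_denominators(self):
        m = Metrics(0, 0, 0)
        assert m.precision == m.recall == m.f == 0.0

    def test_percentages(self):
        m = Metrics(tp=30, fp=10, fn=20)
        assert m.precision == 75.0
        assert m.recall == 60.0
        assert min(60.0, 75.0) <= m.f <= 75.0


def tiny_corpus():
    """One document, two sentences, two gold relations."""
    s1 = "aspirin caused rash."
    s2 = "ibuprofen caused fever."
    corpus = Corpus()
    r1 = GoldRelation(
        "d1", 0,
        GoldEntity(TextSpan(0, 7), "aspirin", DRUG),
        GoldEntity(TextSpan(15, 19), "rash", ADVERSE_EFFECT),
    )
    r2 = GoldRelation(
        "d1", 1,
        GoldEntity(TextSpan(21, 30), "ibuprofen", DRUG),
        GoldEntity(TextSpan(38, 43), "fever", ADVERSE_EFFECT),
    )
    corpus.documents["d1"] = [
        SentenceRecord("d1", 0, s1, TextSpan(0, 20), (r1,)),
        SentenceRecord("d1", 1, s2, TextSpan(21, 44), (r2,)),
    ]
    return corpus


class TestErrorTaxonomy:
    def test_planted_cases_categorized(self):
        corpus = tiny_corpus()
        # FP with both spans matching gold entities (wrong pairing)
        fp_correct = predicted("d1", (0, 7), (38, 43))
        # FP with a span matching nothing in the gold entity inventory
        fp_wrong = predicted("d1", (8, 14), (15, 19))
        preds = [fp_correct, fp_wrong]
        golds = list(corpus.gold_relations())
        result = match_exact(preds, golds)
        # system found the entities of r1 but not of r2
        mention_spans = {"d1": {(0, 7), (15, 19)}}
        cases = categorize_errors(result, corpus, mention_spans)
        summary = error_summary(cases)
        assert summary[FP_RELATION_ENTITIES_CORRECT] == 1
        assert summary[FP_RELATION_ENTITIES_WRONG] == 1
        assert summary[FN_RELATION_FILTERED] == 1  # r1: entities found, no prediction
        assert summary[FN_ENTITY_MISSED] == 1  # r2: entities not found
        # the four categories partition FP ∪ FN
        assert sum(summary.values()) == result.metrics.fp + result.metrics.fn

    def test_sampling_is_seeded(self):
        corpus = tiny_corpus()
        preds = [predicted("d1", (0, 7), (38, 43)), predicted("d1", (8, 14), (15, 19))]
        result = match_exact(preds, list(corpus.gold_relations()))
        a = categorize_errors(result, corpus, {}, sample=2, seed=1)
        b = categorize_errors(result, corpus, {}, sample=2, seed=1)
        assert [c.key for c in a] == [c.key for c in b]


class TestComparisonSubset:
    def corpus_and_lexicon(self):
        corpus = Corpus()
        sentences = []
        offset = 0
        relations_text = [
            # nested: drug inside effect span
            ("acute naproxil intoxication was seen.", "naproxil", "acute naproxil intoxication"),
            ("naproxil caused severe dermatitis here.", "naproxil", "severe dermatitis"),
            ("other drug zelotin caused focal myelitis.", "zelotin", "focal myelitis"),
        ]
        for i, (text, d, e) in enumerate(relations_text):
            ds = text.index(d)
            es = text.index(e)
            rel = GoldRelation(
                "d1", i,
                GoldEntity(TextSpan(offset + ds, offset + ds + len(d)), d, DRUG),
                GoldEntity(TextSpan(offset + es, offset + es + len(e)), e, ADVERSE_EFFECT),
            )
            sentences.append(
                SentenceRecord("d1", i, text, TextSpan(offset, offset + len(text)), (rel,))
            )
            offset += len(text) + 1
        corpus.documents["d1"] = sentences
        lexicon = make_lexicon(
            [
                ("naproxil", "C1", CHEMICALS_AND_DRUGS),
                ("zelotin", "C2", CHEMICALS_AND_DRUGS),
                ("severe dermatitis", "C3", DISORDERS),
                ("focal myelitis", "C4", DISORDERS),
                ("acute naproxil intoxication", "C5", DISORDERS),
            ]
        )
        return corpus, lexicon

    def test_nested_relations_dropped(self):
        corpus, lexicon = self.corpus_and_lexicon()
        pairs = build_comparison_subset(corpus, lexicon, ComparisonSubsetSpec(seed=0))
        positive_keys = {p.key for p in pairs if p.label}
        # only the two non-nested gold relations qualify
        assert len(positive_keys) == 2

    def test_keep_nested_cannot_recover_nested_drug(self):
        # even when nested gold relations are kept, leftmost-longest
        # matching subsumes the inner drug span in the longer disorder
        # match, so the nested relation's entities are never both found
        corpus, lexicon = self.corpus_and_lexicon()
        spec = ComparisonSubsetSpec(drop_nested=False, seed=0)
        pairs = build_comparison_subset(corpus, lexicon, spec)
        assert len({p.key for p in pairs if p.label}) == 2

    def test_ratio_and_determinism(self, bundle):
        spec = ComparisonSubsetSpec(positives_to_negatives_ratio=1.26, seed=9)
        pairs = build_comparison_subset(bundle.split.test, bundle.lexicon, spec)
        n_pos = sum(p.label for p in pairs)
        n_neg = sum(not p.label for p in pairs)
        assert n_pos > 0
        assert n_neg <= round(n_pos / 1.26)
        again = build_comparison_subset(bundle.split.test, bundle.lexicon, spec)
        assert [(p.key, p.label) for p in pairs] == [(q.key, q.label) for q in again]

    def test_insufficient_negatives_warn(self):
        corpus, lexicon = self.corpus_and_lexicon()
        warnings = []
        spec = ComparisonSubsetSpec(positives_to_negatives_ratio=0.01, seed=0)
        build_comparison_subset(corpus, lexicon, spec, warnings=warnings)
        assert warnings

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            ComparisonSubsetSpec(positives_to_negatives_ratio=0)


class TestStageReport:
    def test_predictions_nest_and_f_increases(self, bundle):
        report = stage_report(
            bundle.split.test,
            bundle.lexicon,
            bundle.graph,
            ExtractionConfig(),
            bundle.filter,
        )
        fs = [report[s].f for s in ("baseline", "nlp", "knowledge_base", "type_filter")]
        assert fs == sorted(fs)
        # the knowledge base and filter prune predictions, never add
        assert report["type_filter"].tp + report["type_filter"].fp <= (
            report["knowledge_base"].tp + report["knowledge_base"].fp
        )
        assert report["knowledge_base"].tp + report["knowledge_base"].fp <= (
            report["nlp"].tp + report["nlp"].fp
        )

    def test_deltas_are_row_differences(self, bundle):
        report = stage_report(
            bundle.split.test, bundle.lexicon, bundle.graph, ExtractionConfig(), bundle.filter
        )
        deltas = stage_deltas(report)
        nlp_delta = deltas["baseline->nlp"]
        assert nlp_delta["f_score"] == pytest.approx(
            round(report["nlp"].f - report["baseline"].f, 1)
        )
        assert set(deltas) == {
            "baseline->nlp", "nlp->knowledge_base", "knowledge_base->type_filter"
        }
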