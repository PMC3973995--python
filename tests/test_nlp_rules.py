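import random

from adekb.corpus_io import SentenceRecord, TextSpan
from adekb.lexicon_concepts import (
    ABBREVIATION,
    CHEMICALS_AND_DRUGS,
    COORDINATION,
    DISORDERS,
    EntityMention,
    match_mentions,
)
from adekb.nlp_rules import (
    ConceptFilterList,
    analyze,
    annotate_document,
    apply_nlp_rules,
    correct_boundaries,
    derive_concept_filter_list,
    detect_abbreviations,
    filter_concepts,
    find_long_form,
    resolve_coordination,
    term_variants,
    vary_term,
)
from adekb.relation_extraction import iter_sentence_candidates
from tests.conftest import make_lexicon


def record(text, idx=0, offset=0, doc_id="d1"):
    return SentenceRecord(doc_id, idx, text, TextSpan(offset, offset + len(text)))


def make_document(*texts):
    records, offset = [], 0
    for i, t in enumerate(texts):
        records.append(record(t, idx=i, offset=offset))
        offset += len(t) + 1
    return records


class TestAbbreviationDetection:
    def test_parenthesized_short_form_detected(self):
        sent = analyze(record("The patient developed thrombotic microangiopathy (TMA) early."))
        (pair,) = detect_abbreviations(sent)
        assert pair.short_form == "TMA"
        assert pair.long_form == "thrombotic microangiopathy"
        assert len(pair.short_form) <= len(pair.long_form)

    def test_function_word_in_parentheses_rejected(self):
        sent = analyze(record("Dietary salt (and) fluid were restricted."))
        assert detect_abbreviations(sent) == []

    def test_no_parentheses_no_pairs(self):
        sent = analyze(record("No abbreviations occur here."))
        assert detect_abbreviations(sent) == []

    def test_first_character_must_start_a_word(self):
        # 'XR' cannot anchor on a word-internal character run
        assert find_long_form("XR", "plain words only") is None
        # the long form extends from the anchoring word to the parenthesis
        assert find_long_form("PO", "plain words only") == "plain words only"


def brute_force_valid(short, candidate, max_words):
    """Independent check: some embedding of the short form's characters
    (in order, first char at a word start) exists within the candidate,
    with the implied long form within the word cap."""
    chars = [c.casefold() for c in short if c.isalnum()]
    if not chars:
        return False

    def embeddings(ci, start):
        if ci == len(chars):
            yield ()
            return
        for pos in range(start, len(candidate)):
            if candidate[pos].casefold() != chars[ci]:
                continue
            if ci == 0 and pos > 0 and candidate[pos - 1].isalnum():
                continue
            for rest in embeddings(ci + 1, pos + 1):
                yield (pos,) + rest

    for emb in embeddings(0, 0):
        suffix = candidate[emb[0] :]
        if len(suffix.split()) <= max_words and len(short) <= len(suffix.strip()):
            return True
    return False


def test_long_form_matching_agrees_with_bruteforce():
    rng = random.Random(99)
    words = ["acute", "renal", "failure", "toxic", "anemia", "drug", "skin", "rash"]
    alphabet = "arftdsk"
    for _ in range(400):
        candidate = " ".join(rng.choice(words) for _ in range(rng.randint(1, 5)))
        short = "".join(rng.choice(alphabet) for _ in range(rng.randint(2, 5))).upper()
        max_words = min(len(short) + 5, len(short) * 2)
        got = find_long_form(short, candidate) is not None
        expected = brute_force_valid(short, candidate, max_words)
        assert got == expected, (short, candidate)


class TestAbbreviationPropagation:
    def test_short_form_inherits_long_form_concept(self, toy_lexicon):
        records = make_document(
            "A diagnosis of thrombotic microangiopathy (TMA) was made.",
            "TMA worsened despite treatment.",
        )
        mentions = annotate_document(records, toy_lexicon)
        second = mentions[1]
        assert any(
            m.surface == "TMA" and m.cui == "C203" and m.provenance == ABBREVIATION
            for m in second
        )

    def test_unknown_long_form_blocks_short_form(self):
        # "TMA" is also a drug name in this lexicon; the definition binds
        # it to an unknown long form, so the drug reading is suppressed
        lexicon = make_lexicon(
            [("TMA", "C900", CHEMICALS_AND_DRUGS), ("aspirin", "C901", CHEMICALS_AND_DRUGS)]
        )
        records = make_document(
            "Total mesorectal anomaly (TMA) was discussed.",
            "TMA persisted after aspirin.",
        )
        mentions = annotate_document(records, lexicon)
        assert not any(m.surface == "TMA" for ms in mentions.values() for m in ms)
        assert any(m.surface == "aspirin" for m in mentions[1])

    def test_document_without_parentheses_unchanged(self, toy_lexicon):
        records = make_document("Severe asthma persisted.")
        with_nlp = annotate_document(records, toy_lexicon)
        dict_only = annotate_document(records, toy_lexicon, use_nlp=False)
        assert [m.cui for m in with_nlp[0]] == [m.cui for m in dict_only[0]]


class TestCoordination:
    def test_shared_head_conjuncts_resolved(self, toy_lexicon):
        sent = analyze(record("Renal and hepatic failure occurred during therapy."))
        base = match_mentions(sent.record, toy_lexicon)
        mentions = resolve_coordination(sent, toy_lexicon, base)
        by_cui = {m.cui: m for m in mentions}
        assert by_cui["C207"].surface == "hepatic failure"  # contiguous, dictionary
        assert by_cui["C206"].provenance == COORDINATION
        assert by_cui["C206"].surface == "Renal"  # minimal conjunct anchor

    def test_already_covered_conjuncts_add_nothing(self, toy_lexicon):
        sent = analyze(record("cisplatin and bleomycin were given."))
        base = match_mentions(sent.record, toy_lexicon)
        mentions = resolve_coordination(sent, toy_lexicon, base)
        assert {(m.span.start, m.span.end, m.cui) for m in mentions} == {
            (m.span.start, m.span.end, m.cui) for m in base
        }

    def test_sentence_without_conjunction_is_identity(self, toy_lexicon):
        sent = analyze(record("asthma was treated with methotrexate."))
        base = match_mentions(sent.record, toy_lexicon)
        assert resolve_coordination(sent, toy_lexicon, base) == base

    def test_hyphenated_premodifier_coordination(self, toy_lexicon):
        rec = record("probable cisplatin and bleomycin-induced encephalopathy was seen.")
        mentions = annotate_document([rec], toy_lexicon)[0]
        surfaces = {m.surface for m in mentions}
        assert {"cisplatin", "bleomycin", "encephalopathy"} <= surfaces


class TestTermVariation:
    def test_leading_determiner_dropped(self, toy_lexicon):
        assert vary_term("the acute intoxication", toy_lexicon) == {"C204"}

    def test_of_inversion(self, toy_lexicon):
        assert vary_term("carcinoma of the lung", toy_lexicon) == {"C205"}

    def test_no_variant_found(self, toy_lexicon):
        assert vary_term("completely unrelated phrase", toy_lexicon) == frozenset()

    def test_variant_order(self):
        variants = [v for _, v in term_variants("the acute intoxication of drugs")]
        assert variants[0] == "acute intoxication of drugs"  # determiner drop first
        assert "drugs acute intoxication" in variants  # inversion follows


class TestBoundaryCorrection:
    def test_determiner_trimmed(self, toy_lexicon):
        sent = analyze(record("the asthma was severe."))
        mention = EntityMention(TextSpan(0, 10), "the asthma", "C202", DISORDERS)
        fixed = correct_boundaries(mention, sent)
        assert fixed.surface == "asthma"

    def test_trailing_punctuation_trimmed(self, toy_lexicon):
        sent = analyze(record("He developed asthma, then recovered."))
        mention = EntityMention(TextSpan(13, 20), "asthma,", "C202", DISORDERS)
        fixed = correct_boundaries(mention, sent)
        assert fixed.surface == "asthma"

    def test_clean_mention_unchanged(self, toy_lexicon):
        sent = analyze(record("asthma persisted."))
        mention = EntityMention(TextSpan(0, 6), "asthma", "C202", DISORDERS)
        assert correct_boundaries(mention, sent) is mention

    def test_mention_of_only_trimmable_tokens_dropped(self, toy_lexicon):
        sent = analyze(record("the others recovered."))
        mention = EntityMention(TextSpan(0, 3), "the", "C999", DISORDERS)
        assert correct_boundaries(mention, sent) is None


class TestConceptFiltering:
    def test_mention_outside_noun_phrases_removed(self):
        sent = analyze(record("Patients were walking daily."))
        # "walking" sits in a verb chunk; plant a mention on it
        mention = EntityMention(TextSpan(14, 21), "walking", "C300", DISORDERS)
        assert filter_concepts([mention], sent) == []

    def test_listed_cui_removed_and_partial_overlap_kept(self, toy_lexicon):
        sent = analyze(record("severe asthma attack occurred."))
        mentions = match_mentions(sent.record, toy_lexicon)
        flt = ConceptFilterList(cuis={"C202"})
        assert filter_concepts(mentions, sent, flt) == []
        assert filter_concepts(mentions, sent, ConceptFilterList()) == mentions

    def test_filter_list_parsing(self):
        flt = ConceptFilterList.from_lines(["C123  # a cui", "Drug-Induced  # a term", ""])
        assert flt.cuis == {"C123"}
        assert flt.terms == {"drug induced"}

    def test_derived_filter_list_thresholds_counts(self):
        fp = [EntityMention(TextSpan(0, 4), "drug", "C1", DISORDERS)] * 3
        fp += [EntityMention(TextSpan(0, 4), "rare", "C2", DISORDERS)]
        derived = derive_concept_filter_list(fp, min_count=3)
        assert derived.cuis == {"C1"}


class TestPipeline:
    def test_pipeline_idempotent(self, bundle):
        doc_id = next(iter(bundle.corpus.documents))
        records = bundle.corpus.documents[doc_id]
        sentences = [analyze(r) for r in records]
        base = {r.sentence_index: match_mentions(r, bundle.lexicon) for r in records}
        once = apply_nlp_rules(sentences, base, bundle.lexicon)
        twice = apply_nlp_rules(sentences, once, bundle.lexicon)
        assert twice == once

    def test_gold_annotations_untouched(self, bundle):
        doc_id = next(iter(bundle.corpus.documents))
        records = bundle.corpus.documents[doc_id]
        before = [r.gold_relations for r in records]
        annotate_document(records, bundle.lexicon)
        assert [r.gold_relations for r in records] == before

    def test_survivors_overlap_noun_phrase_or_are_abbreviations(self, bundle):
        for doc_id in list(bundle.corpus.documents)[:30]:
            records = bundle.corpus.documents[doc_id]
            sentences = {r.sentence_index: analyze(r) for r in records}
            mentions = annotate_document(records, bundle.lexicon)
            for idx, ms in mentions.items():
                nps = sentences[idx].noun_phrases
                for m in ms:
                    assert m.provenance == ABBREVIATION or any(
                        m.span.overlaps(np) for np in nps
                    )

    def test_nlp_stage_increases_entity_recall(self, bundle):
        def entity_recall(use_nlp):
            found = total = 0
            for rec, mentions, _ in iter_sentence_candidates(
                bundle.corpus, bundle.lexicon, use_nlp=use_nlp
            ):
                spans = {(m.span.start, m.span.end) for m in mentions}
                for rel in rec.gold_relations:
                    for ent in (rel.drug, rel.effect):
                        total += 1
                        found += (ent.span.start, ent.span.end) in spans
            return found / total

        assert entity_recall(True) > entity_recall(False)
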