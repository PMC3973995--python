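import pytest

from adekb.corpus_io import split_corpus
from adekb.lexicon_concepts import (
    CHEMICALS_AND_DRUGS,
    DISORDERS,
    ConceptEntry,
    Lexicon,
)
from adekb.relation_extraction import train_relation_type_filter
from adekb.synthetic_fixtures import FixtureSpec, generate_corpus, generate_resources


def make_lexicon(entries, suppress=()):
    """entries: iterable of (term, cui, group)."""
    lexicon = Lexicon()
    lexicon.suppress_list = {t for t in suppress}
    for term, cui, group in entries:
        if cui not in lexicon.entries:
            lexicon.entries[cui] = ConceptEntry(cui, term, group)
        lexicon.add_term(term, cui)
    return lexicon


@pytest.fixture
def toy_lexicon():
    """Hand-sized lexicon covering the worked examples."""
    return make_lexicon(
        [
            ("methotrexate", "C100", CHEMICALS_AND_DRUGS),
            ("cisplatin", "C101", CHEMICALS_AND_DRUGS),
            ("bleomycin", "C102", CHEMICALS_AND_DRUGS),
            ("lithium", "C103", CHEMICALS_AND_DRUGS),
            ("alum", "C104", CHEMICALS_AND_DRUGS),
            ("pneumocystis carinii pneumonia", "C200", DISORDERS),
            ("carinii pneumonia", "C201", DISORDERS),
            ("asthma", "C202", DISORDERS),
            ("thrombotic microangiopathy", "C203", DISORDERS),
            ("acute intoxication", "C204", DISORDERS),
            ("lung carcinoma", "C205", DISORDERS),
            ("renal failure", "C206", DISORDERS),
            ("hepatic failure", "C207", DISORDERS),
            ("seizure", "C208", DISORDERS),
            ("encephalopathy", "C209", DISORDERS),
        ]
    )


class SyntheticBundle:
    """Default-condition synthetic study: resources, corpus, 50-document
    training split, and the trained relation-type filter."""

    def __init__(self):
        self.spec = FixtureSpec()
        self.lexicon, self.graph, self.truth = generate_resources(self.spec)
        self.corpus = generate_corpus(self.spec, self.lexicon, self.truth)
        self.split = split_corpus(self.corpus, 50, seed=self.spec.seed)
        self.filter = train_relation_type_filter(self.split.train, self.lexicon, self.graph)


@pytest.fixture(scope="session")
def bundle():
    return SyntheticBundle()
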