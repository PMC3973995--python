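# adekb — knowledge-based extraction of adverse drug events from text

`adekb` extracts drug–adverse-effect relations from biomedical sentences
without training a statistical classifier. It is aimed at
pharmacovigilance and text-mining researchers who have a concept
vocabulary and a typed concept–concept relation table (e.g. derived from
a medical metathesaurus) but little or no annotated training data.

The pipeline has two halves:

1. **Concept recognition.** Sentences are matched against a dictionary of
   drug and disorder terms (normalized, leftmost-longest matching, with
   concept unique identifiers and semantic groups *Chemicals & Drugs* /
   *Disorders*), then refined by five rule submodules driven by
   part-of-speech and chunk tags: coordination resolution, abbreviation
   expansion, term variation, boundary correction, and concept filtering.
2. **Knowledge-base decision.** For every drug–disorder mention pair in a
   sentence, the shortest-path distance *d(c₁, c₂)* between the two
   concepts is computed in a typed, undirected concept graph. A relation
   is asserted iff

   d(c_drug, c_effect) ≤ τ (distance threshold, default τ = 4)

   and, when a trained **relation-type filter** is supplied, at least one
   shortest path contains no discarded relation type. A type *t* is
   discarded when, over distance-accepted training candidates labeled
   against a gold standard,

   (FP(t) + 1) / (TP(t) + 1) > ρ (ratio threshold, default ρ = 7, strict),

   where FP(t)/TP(t) count occurrences of *t* on shortest-path hops of
   false-/true-positive pairs.

Scoring is boundary-exact: a prediction is a true positive only when both
entity character spans coincide with a gold annotation; precision, recall
and F are micro-averaged percentages.

Because the real vocabulary and corpus behind such systems are
license-gated, the package ships a seeded synthetic-fixture generator
(`adekb.synthetic_fixtures`) that emulates the study conditions: true
drug–effect pairs wired into the graph at distance ≤ 3 through clean
relation types, "trap" decoys at distance 2 whose every shortest path
carries a planted noise relation type, far decoys at distance ≥ 5, and a
template-rendered corpus with exact gold offsets, coordination
constructs, and abbreviation definitions.

## Worked example

```python
from adekb import (
    ExtractionConfig, FixtureSpec, generate_corpus, generate_resources,
    split_corpus, stage_report, train_relation_type_filter,
)

spec = FixtureSpec(seed=0)                       # 200 documents, 24 true pairs,
lexicon, graph, truth = generate_resources(spec) # 24 trap + 20 far decoys
corpus = generate_corpus(spec, lexicon, truth)
split = split_corpus(corpus, n_train=50, seed=0)

flt = train_relation_type_filter(split.train, lexicon, graph)
print(sorted(flt.discarded))

report = stage_report(split.test, lexicon, graph, ExtractionConfig(), flt)
for stage, m in report.items():
    print(f"{stage:15s} P={m.precision:5.1f} R={m.recall:5.1f} F={m.f:5.1f}")
```

Output:

```
['co_occurs_with']
baseline        P= 40.2 R= 75.6 F= 52.5
nlp             P= 47.1 R=100.0 F= 64.1
knowledge_base  P= 63.2 R=100.0 F= 77.4
type_filter     P=100.0 R=100.0 F=100.0
```

Reading the rows: the co-occurrence **baseline** pairs every drug with
every disorder in a sentence — high recall, poor precision. The **nlp**
row adds the five rule submodules, recovering coordinated and abbreviated
effect mentions (recall 75.6 → 100.0). The **knowledge_base** row applies
the distance threshold, rejecting the far decoys; the **type_filter** row
additionally rejects the trap decoys, whose shortest paths all carry the
planted `co_occurs_with` type — exactly the type the training step
discarded.

The same flow is available from the shell:

```bash
adekb simulate --out-dir sim --seed 0
adekb build-kb --relations sim/relations.tsv
adekb train-filter --corpus sim/corpus.ade --negatives sim/negatives.txt \
    --vocab sim/lexicon.tsv --groups sim/groups.tsv \
    --relations sim/relations.tsv --out filter.json
adekb extract ... --filter-file filter.json --out predictions.tsv
adekb evaluate --gold sim/corpus.ade --gold-negatives sim/negatives.txt \
    --pred predictions.tsv
```

## Layout

| module | role |
|---|---|
| `adekb.corpus_io` | annotated-corpus data model, pipe-delimited readers/writers, offset-convention detection, seeded splits |
| `adekb.lexicon_concepts` | term normalization, lexicon loading (TSV / RRF-style), leftmost-longest mention matching |
| `adekb.tagging` | deterministic rule POS tagger and IOB noun-phrase chunker (pluggable) |
| `adekb.nlp_rules` | the five post-processing submodules and their orchestration |
| `adekb.knowledge_graph` | typed concept graph, BFS distance, deterministic shortest-path enumeration |
| `adekb.relation_extraction` | candidate generation, distance/filter decision, filter training |
| `adekb.evaluation` | boundary-exact scoring, error taxonomy, comparison-subset builder, stage report |
| `adekb.synthetic_fixtures` | seeded generators for lexicon, graph, and corpus with planted structure |
| `adekb.cli` | `adekb` command-line interface |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
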