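# Methods

## Pipeline model

`adekb` treats adverse-drug-event extraction as two decoupled decisions.

**Concept recognition** assigns concept unique identifiers (CUIs) to
sentence spans. The dictionary stage normalizes both lexicon terms and
sentence n-grams through the same function — case folding, possessive
removal, punctuation-to-space, whitespace collapse, and simple plural
stripping on the final token — so matching is invariant to casing and
hyphen/space alternation by construction. Matching is leftmost-longest
over the token stream (n-grams up to 8 tokens); an ambiguous term emits
one mention per CUI on the same span, and no word-sense disambiguation
is attempted — downstream candidate generation keeps all readings and
grounds a pair at the minimum distance over CUI combinations. Mentions
are then refined by five individually switchable rule submodules:

* *Coordination resolution* — a noun phrase of shape `A and B H` is
  rewritten as `A H` / `B H`, each rewrite is re-matched, and a new
  match is anchored to the minimal original span covering its conjunct
  (a match whose tokens are contiguous in the original keeps its full
  span and deduplicates against the dictionary match). The
  conjunct-anchor convention is this package's choice; how an original
  system would anchor discontinuous matches is genuinely open, and the
  synthetic corpus annotates coordinated gold effects the same way so
  the convention is testable end to end.
* *Abbreviation expansion* — parenthesis-anchored short-form/long-form
  pairing by right-to-left subsequence matching (every short-form
  character in order; the first character must start a long-form word;
  long-form length ≤ min(|SF|+5, 2·|SF|) words). A long form that maps
  to a concept propagates its CUIs to all later occurrences of the
  short form in the document; a short form whose long form is unknown is
  blocked from dictionary matching for the rest of the document.
* *Term variation* — for noun phrases no mention fully covers, an
  ordered variant list (drop leading determiners; invert "H of M" to
  "M H"; strip premodifiers from the left) is looked up, first hit wins.
* *Boundary correction* — leading/trailing determiners, pronouns and
  punctuation are trimmed from mention spans (trim-only; no extension).
* *Concept filtering* — a mention is removed if it overlaps no noun
  phrase (abbreviation-derived mentions are exempt, since short forms
  may fall outside weakly chunked noun phrases) or if its CUI or
  normalized surface is on a configurable filter list. A helper derives
  filter-list candidates from frequent training false positives.

Conflicting span claims are resolved deterministically: the longer span
wins; on ties, dictionary provenance wins. The pipeline touches only
system mentions, never gold annotations, and is idempotent.

POS and chunk tags come from a pluggable callable; the bundled tagger is
a deterministic closed-class-list + suffix-rule tagger with a regular
noun-phrase chunker that joins nominal runs across a single coordinating
conjunction. It is deliberately simple — adequate for the template
corpus and for the rule submodules' needs, not a general-purpose tagger;
any callable `tokens -> [(pos, iob_chunk)]` can replace it.

**The knowledge-base decision** computes the shortest-path distance
between the drug and disorder concepts in a typed concept graph and
asserts a relation iff the distance is at most the threshold τ and, with
a trained filter, at least one shortest path carries no discarded
relation type. Traversal is undirected: concept-relation tables store
each relation together with its inverse, so undirected traversal is the
faithful reading — this choice changes distances and is therefore
recorded prominently. The graph keeps the term and semantic-type tiers
(read-only) but path queries run over the concept tier only.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `distance_threshold` τ | 4 | maximum shortest-path length (hops) for a relation; ∞ gives the co-occurrence baseline |
| `type_ratio_threshold` ρ | 7 | discard type *t* iff (FP(t)+1)/(TP(t)+1) > ρ, strictly |
| `horizon` | τ + 1 | BFS early-termination depth; anything beyond reports as infinite |
| `path_cap` | 64 | maximum shortest paths enumerated per pair; truncation is flagged and the decision is made on the enumerated paths |
| `filter_mode` | `any_path_survives` | a pair survives if ≥ 1 shortest path is clean; `all_paths_clean` rejects a pair if any path is dirty |
| `max_term_tokens` | 8 | dictionary n-gram ceiling |

τ = 4 and ρ = 7 are the operating points reported as empirically optimal
for this class of system; both are exposed, and both add-one smoothing
and the strict inequality of the ratio rule are contracts (a ratio of
exactly 7 retains the type).

Two counting/filtering ambiguities are genuinely open and are resolved
by defaults with the alternative behind a switch: (a) training counts a
relation type once per hop occurrence across all enumerated shortest
paths of a labeled candidate; (b) filtering discards paths, not pairs
(`any_path_survives`), because a dirty parallel path should not void a
clean one.

Shortest-path enumeration visits neighbors in lexicographic CUI order,
so path lists, truncation, and therefore every downstream count are
deterministic. Per-hop relation types are collected as the set of all
parallel edge labels on that hop.

## Evaluation

Matching is boundary-exact on (document, drug span, effect span);
duplicate predictions on one span pair collapse before scoring because
the gold standard is span-anchored, not CUI-anchored. Metrics are
micro-averaged. The error taxonomy partitions false positives into
entities-correct / entities-wrong (both predicted spans boundary-match
some gold entity annotation or not) and false negatives into
relation-filtered / entity-missed (both gold entities had a
boundary-matching system mention or not). Since such corpora only
annotate entities participating in relations, "entities correct"
under-counts genuinely correct entities; reports should be read with
that caveat. The comparison-subset builder (positive sentences only,
nested gold relations dropped, seeded negatives added at a configurable
positives:negatives ratio, default 1.26:1) reproduces the balanced
setting used when comparing against classifier-style systems.

## Synthetic study conditions

The generator is a pure function of its spec (including the seed) and
emulates, at desk scale, the conditions the pipeline is designed for:

* 24 true drug–disorder pairs wired at distance 1–3 through clean
  relation types (`cause_of`, `isa`, `associated_with`,
  `has_finding_site`), each pair in its own chain of fresh background
  nodes;
* 24 trap decoys: drug *i* linked to disorder *i+7 (mod 24)* through a
  private two-hop chain typed entirely with the noise relation
  `co_occurs_with` — short enough to pass the distance threshold,
  rejected only once the trained filter discards the noise type;
* 20 far decoys: drug *i* paired with disorder *i+3 (mod 24)* with no
  dedicated wiring; the shortest route threads several gadgets and the
  generator verifies it stays ≥ 5 hops (an infeasible spec raises
  before emission, as do true chains exceeding their bound and trap
  pairs with a clean shortest path);
* a 200-document corpus (2–4 sentences each, 64% of sentence slots
  negative, echoing the roughly 7560-of-11832 negative-sentence share of
  the real corpus this setting mirrors) rendered from audited templates:
  complication/induced/therapy positives, an extra-disorder variant that
  plants a far-decoy false positive inside a positive sentence,
  coordinated shared-head effects ("renal and hepatic failure"),
  two-sentence abbreviation constructs ("acute nephritis (AN) … AN was
  attributed to …"), and drug-only / disorder-only / trap / far
  negatives. Gold offsets are computed from the rendered strings and
  re-validated on emission.

Two feasibility checks tie the generator to the algorithms it exercises:
abbreviation gadgets are only planted when the short form actually
resolves to the full planted term (initials like "AA" for "acute
anemia" legitimately resolve to just "anemia", so such gadgets are
skipped), and sentence text is unique within a document (duplicate
sentences would merge on round-trip through the per-relation file
format).

What passing on this corpus does **not** show: robustness to real
Medline language (the templates are deliberately simple), real
lexicon noise (term ambiguity across semantic groups is rare here),
hub-dominated graph topology (real metathesauri have highly connected
general concepts; an optional hub-exclusion list exists but is off by
default), or the absolute scores reported on license-gated resources.
The synthetic scores (F ≈ 100 for the full pipeline) reflect the planted
separability, not expected real-world performance; the meaningful
signals are the ordering of the four stage rows, the exact recovery of
the planted noise type, and the ≥ 20-point margin over co-occurrence.

## Numerical and I/O conventions

* Spans are document-level, 0-based, half-open; a document's text is its
  sentences joined by single spaces. ADE-style files carry
  sentence-relative offsets; the reader auto-detects 0/1-based ×
  half-open/closed by surface/slice agreement on the first parsable
  records and applies one correction file-wide, recording the choice in
  the parse report.
* Records sharing (document id, sentence text) merge into one sentence
  record with multiple gold relations.
* Train/test splitting sorts document ids before seeded sampling, so the
  split is independent of storage order.
* Graph loading deduplicates (a, b, type) triples treating (a, b) and
  (b, a) as equal and drops self-loops; loading is row-order
  independent.
* F-scores are reported rounded to one decimal. Recomputing F from
  precision/recall values that were themselves rounded to one decimal
  can move the result by one ulp (0.1), which is the tolerance the test
  suite uses for published triplets.

## Known limitations

* No distinction between adverse-event and treatment relations; both
  look alike to a distance threshold.
* No path-plausibility weighting; all relation types count equally
  outside the discard set.
* The five rule submodules are minimal reconstructions of a rule
  inventory that is not publicly specified; each is switchable so its
  contribution can be audited.
* The bundled tagger is not a general-purpose POS tagger; plug in a
  trained tagger for real text.
* `path_cap` truncation can, in pathological dense graphs, hide a clean
  shortest path and cause a false rejection in `any_path_survives` mode;
  truncation is recorded in the decision trace.
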