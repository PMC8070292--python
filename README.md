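# plantkn

Knowledge networks from plant-science literature, with a time-resolved
proximity analysis that flags candidate gene–trait associations before the
literature states them outright.

## The problem

Evidence linking a gene to a phenotype is often scattered: one paper relates
a gene to a metabolite, another relates that metabolite to the trait, and
only years later does a publication connect the gene and the trait directly.
`plantkn` is for plant scientists and breeders who want to mine a corpus of
abstracts or full texts for such latent associations. The reference use case
is potato (*Solanum tuberosum*) tuber flesh color, a carotenoid-driven trait
whose candidate genes — beta-carotene hydroxylase (BCH) and zeaxanthin
epoxidase (ZEP) — sat in close network proximity to the trait well before
explicit statements appeared.

## The method

1. **Dictionary NER** over a three-class type system (Gene/Protein,
   Metabolite, Trait) with case-insensitive, token-boundary,
   leftmost-longest matching — hyphen/digit-rich names like
   `lutein-5,6-epoxide` are handled as single token sequences.
2. **Within-sentence relation extraction**: every pair of distinct-label
   mentions in a sentence becomes a relation from a closed seven-entry
   registry — the catch-all `RELATED_TO` unless a trigger keyword between
   the mentions upgrades it (`encodes`, `part of`).
3. **Normalization** maps surface variants to canonical labels: Greek
   transliteration and American spelling, apostrophe/`#` cleanup,
   uppercasing, guarded species-prefix stripping (StAN1 → AN1), guarded
   gene-family-digit stripping (BCH1, BCH2 → beta-carotene hydroxylase),
   EC-number expansion, then synonym-table lookup.
4. **Knowledge networks**: relations become knowledge triples (two
   normalized entities + relationship label + provenance, an easily
   parsable CSV); triples aggregate into an undirected graph whose edge
   weight w(u,v) = |{documents relating u and v}| (GREY when w = 1, BLACK
   when w > 1). Only entities with at least one relationship become nodes.
5. **Time analysis**: for each year y, a network is built from all
   documents published up to y, so the series is nested. For a trait node
   set F (the "flesh color nodes") and each eventual direct neighbor v,
   the pipeline tabulates d_y(v, F) = min over f in F of the unweighted
   shortest-path distance in the year-y network, and reports transition
   years: the first y with d_y ≤ k (k = 1 means the association is stated
   directly).

A synthetic-corpus generator plants relations on a known emergence schedule
and computes the expected distance table in closed form with an independent
BFS, so the whole pipeline is testable without downloading anything.

## Worked example

Three toy abstracts over six years; the demonstration lexicon and synonym
table ship with the package:

```python
from plantkn import (Corpus, Document, Normalizer, FleshNodeSet,
                     DEFAULT_FLESH_LABELS, build_series, distance_table,
                     detect_transitions, eventual_direct_neighbors)
from plantkn.data import (load_demo_lexicon, load_reference_synonyms,
                          load_default_triggers)

corpus = Corpus([
    Document("a01", 2004, "In orange cultivars, beta-carotene is associated with flesh color."),
    Document("a02", 2007, "StZEP encodes zeaxanthin epoxidase, which converts zeaxanthin. "
                          "Zeaxanthin correlates with beta-carotene."),
    Document("a03", 2010, "Recent mapping shows ZEP is associated with flesh color."),
])
lexicon = load_demo_lexicon()
normalizer = Normalizer(load_reference_synonyms(), known=lexicon.preferred_labels())
series = build_series(corpus, lexicon, load_default_triggers(), normalizer,
                      [2004, 2007, 2010])
flesh = FleshNodeSet.of(*DEFAULT_FLESH_LABELS)
tracked = sorted(eventual_direct_neighbors(series, flesh))
table = distance_table(series, tracked, flesh)
report = detect_transitions(table, ks=[1, 2])
```

Printing the table rows and transitions gives:

```
BETA-CAROTENE             1  1  1
ZEAXANTHIN EPOXIDASE      x  3  1
BETA-CAROTENE: first seen 2004, within-2 2004, direct 2004
ZEAXANTHIN EPOXIDASE: first seen 2007, within-2 2010, direct 2010
```

Reading: beta-carotene is stated together with flesh color from 2004 on
(distance 1 every year). ZEP enters the network in 2007 — `StZEP` and
`BCH`-style variants all normalize onto canonical labels — at distance 3
(via zeaxanthin and beta-carotene), and transitions to a direct neighbor in
2010, the year a sentence finally relates it to flesh color itself.

The same stages are available from the shell via `plantkn
{annotate,triples,network,timeseries,evaluate,simulate} --config run.yaml`;
outputs include Cytoscape-ready edge/node CSVs and a run manifest.

## Layout

| module | role |
| --- | --- |
| `plantkn.corpus_io` | documents, sentence segmentation, cumulative year slices |
| `plantkn.annotate` | lexicons, dictionary NER, within-sentence relations |
| `plantkn.normalize` | label normalization rules and synonym tables |
| `plantkn.triples_network` | knowledge triples, weighted networks, analytics, exports |
| `plantkn.time_analysis` | yearly series, distance tables, transitions, diffs |
| `plantkn.evaluation` | entity-level precision/recall/F1 and confusion matrices |
| `plantkn.synth_corpus` | planted-schedule corpus generator with answer keys |
| `plantkn.cli` | `plantkn` command-line entry point |
| `plantkn.data` | packaged reference tables, demo lexicon, synonyms, triggers |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
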