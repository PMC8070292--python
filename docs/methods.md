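# Methods

## Model and assumptions

`plantkn` treats a literature corpus as a stream of dated documents and a
knowledge network as an undirected co-occurrence graph over normalized
biological entities. The core modelling commitments:

* **Three entity classes.** Genes and proteins are a single class
  (GENE_PROTEIN): the literature uses the two interchangeably and a merged
  class loses little information while avoiding systematic
  misclassification. METABOLITE and TRAIT complete the closed set.
* **Seven relation classes, mostly generic.** Relation labels carry little
  weight in this model: all-pairs within-sentence co-occurrence with the
  catch-all `RELATED_TO` captures the bulk of the signal, and only trigger
  keywords between two mentions upgrade a pair to `ENCODES` or `PART_OF`.
  The remaining four registry slots (`GENERIC_1..4`) are configurable
  placeholders that never fire unless a trigger table maps keywords onto
  them. Association polarity (positive/negative/inexplicit) is out of
  scope.
* **Sentence-bounded relations.** A relation never crosses a sentence
  boundary. Abbreviation/pronoun co-reference across sentences is not
  attempted; pairs stated across sentences are simply not captured, which
  biases recall downward but keeps precision high.
* **Document-frequency edge weights.** An edge's weight is the number of
  distinct documents relating the pair (GREY = 1, BLACK = >1). Weighting
  by raw mention count is available behind `build_network(...,
  weight_by_mentions=True)` but off by default, and weights never affect
  path lengths.
* **Hop-count proximity.** The time analysis uses unweighted shortest-path
  distances; the tabulated distances are small integers (1–5) and the
  quantity of interest is the *transition year* — the first year a tracked
  node's distance to the trait node set falls to (or below) a threshold —
  not the path weight.

## Pipeline stages and notable choices

**Sentence segmentation** splits on `.!?` followed by whitespace and an
uppercase letter or digit, with a configurable abbreviation stop list
(Fig., et al., e.g., i.e., cv., ...). Offsets are 0-based half-open
throughout; sentence spans never overlap and always slice the document text
exactly.

**Dictionary matching** is case-insensitive and token-boundary aware.
Tokens are maximal alphanumeric runs glued by internal hyphens and
apostrophes, and by commas/periods between digits, so `lutein-5,6-epoxide`
is one token sequence and `carotene` cannot match inside
`beta-carotene-like`. Among overlapping candidates the leftmost-longest
wins; equal-length ties go to the earlier start. A consequence worth
knowing: removing a long dictionary surface can *increase* the mention
count by freeing its nested components — that is intended leftmost-longest
behaviour, and the no-new-matches monotonicity property only holds for
lexicons in which no surface nests inside another (the property test
generates exactly such lexicons).

**Normalization** applies six rules in a fixed order — Greek/spelling
transliteration, apostrophe/`#` removal, uppercasing, species-prefix strip,
gene-family-digit strip, EC-number expansion — followed by synonym-table
lookup. Only the position of the case/spelling conversion (first) is
externally constrained; the rest of the order was chosen so that character
cleanup precedes any dictionary lookup, maximizing hit rate. Both stripping
rules are guarded: they fire only when the stripped remainder resolves in
the synonym table or the active lexicon, which prevents "Or" → "O"-type
damage. Unresolvable labels pass through in processed uppercase form and
are reported on the module logger; normalization is total and idempotent
(property-tested). Allelic/isomer variants ("recessive ZEP") collapse onto
the main label via synonym rows — data, not code. The default species
prefix list is {St, Le, Sl, Ca, At, Nt}.

**Triples and networks.** Relations whose endpoints normalize to the same
label are dropped (self-loop suppression, e.g. a BCH1–BCH2 pair). Multiple
relation types between one label pair collapse onto a single edge carrying
the type set, so edge counts are pair-level-unique. A label occurring with
two different entity types after normalization is a hard error rather than
a silent merge — it invariably signals a lexicon or synonym defect. The
centroid (most distinct neighbors) breaks ties to the lexicographically
smallest label.

**Time analysis.** Year-y networks are built from the cumulative corpus up
to y, so node/edge sets grow monotonically and per-row distances are
non-increasing once numeric. The table cell `x` (ABSENT) covers both "node
not yet in the network" and "no path to any trait node"; the two cases are
not distinguished in the table itself. Tracked labels that are themselves
trait-set members are dropped with a warning. When reading *external*
master tables, monotonicity violations are warnings, not errors. The
`lead_time` helper computes how far network proximity anticipated
experimental evidence, but both anchor years are caller-supplied: the
reference narrative's "two years prior" admits more than one reading (last
year at distance 2 vs. the evidence's publication year), so the package
does not infer anchors.

**Evaluation** is mention-level, micro-averaged (pool TP/FP/FN over
documents, then compute percentages), with greedy left-to-right matching
and each gold span claimable once. `EXACT` span+type matching is the
default; `OVERLAP` is available for robustness studies. F1 is the standard
harmonic mean.

## The synthetic generator

The generator emulates the corpus structure the time analysis assumes:
yearly batches of short documents whose sentences realize planted pairwise
relations on a known emergence schedule, surrounded by distractor
sentences. Defaults: years 2000–2016, 3 documents per year, 2 distractor
sentences per document, noise rate 0 — a desk-scale emulation of a yearly
abstract stream that keeps a full 17-year pipeline run in well under a
second while still exercising every stage. Design points:

* Distractor sentences contain at most one entity, so they can never
  create a relation and the planted graph is exactly controllable.
* Surfaces include normalization stressors — species prefixes (`StZEP`),
  Greek letters (`β-carotene`), family digits (`BCH1`) — that the lexicon
  and synonym table resolve back to canonical labels.
* The expected distance table is computed by a hand-rolled BFS on the
  cumulative planted edge set, sharing no code with the networkx path used
  by the pipeline; it is the independent oracle for end-to-end tests.
* `noise_rate` injects off-schedule random pair sentences. Extra edges can
  only shorten paths, so recovered transition years are never later than
  planted ones; this is asserted on every noisy run.
* All sampling flows from one seeded generator; identical (config,
  schedule) pairs are byte-identical.

What the generator does **not** emulate: linguistically realistic prose,
publication-rate dynamics, cross-sentence references, ambiguous
abbreviations, and entities absent from the dictionary. Passing tests
therefore demonstrate that the pipeline's mechanics are correct under its
stated assumptions — not that dictionary NER achieves any particular
precision/recall on real text, where coverage gaps and co-reference losses
dominate.

## Packaged reference data

Two transcribed reference tables for the potato flesh-color use case ship in
`plantkn/data/`: the neighbor-set comparison (full text vs abstracts) and
the 21 × 17 master distance table. The neighbor-set transcription is
internally set-consistent (|A| = 38, |B| = 17, |A−B| = 21) but its source
narrative gives a different count for the difference column (20); the
fixture preserves the columns as printed and the loader docstring flags the
discrepancy rather than resolving it. The packaged synonym table covers
every entity named in both tables.

## Problem sizes in tests and acceptance

Property suites run on random graphs of at most 50 nodes against
brute-force BFS oracles, and on 100 random planted schedules (1–6 events
over 2000–2006, 1–2 documents per year) for noise-free end-to-end
recovery; the whole suite completes in a few seconds. These sizes were
chosen as the smallest that exercise multi-hop paths, absent years, and
all three relation templates.

## Known limitations

* Dictionary NER only finds what the lexicon contains; there is no
  machine-learned generalization to unseen surface forms.
* Colliding abbreviations (the classic MIC problem) are not disambiguated.
* Section labels come from metadata only; no automatic sectioning of full
  texts is attempted.
* Transition years are descriptive, not inferential: no significance
  testing or forecasting is performed.
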