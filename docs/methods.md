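# Methods

## Model

`combosum` ranks predication patterns by how strongly they express the
point of view implicit in a retrieval query. The inputs are a *foreground*
corpus of subject–PREDICATE–object predications (the query's results) and a
*background* corpus or pre-aggregated predicate count table representing
all points of view on the same seed topic. The core assumption is that a
point-of-view-slanted query skews the foreground's predicate distribution
relative to the background, and that the arguments' semantic types identify
which entity class each predicate binds in that slant.

Three metrics are combined per pattern (a predicate plus the semantic type
of its non-anchor argument slot); all logarithms are base 2:

- KLD term `P(x)·log2(P(x)/Q(x))`: per-predicate foreground enrichment.
  The per-predicate terms, not the summed divergence, are the ranking
  quantity. Only predicates present in both distributions are compared,
  and the relative frequencies are computed over each corpus's full
  predicate set **without renormalizing** after the restriction — the
  restriction is a comparison scope, not a rescaling. Negative terms
  (background-heavier predicates) are kept and rank low naturally.
- RlogF `log2(count)·count/total`: binding strength of a semantic type to
  a predicate. `total` pools all non-anchor semantic-type occurrences for
  the predicate across both argument sides; the pattern key retains the
  side purely for reporting. The log term flattens the probability space,
  rewarding saturated bindings while still crediting frequent
  moderately-bound types.
- PredScal `1/log2(c)`: scales RlogF by the predicate-vocabulary size `c`
  of the dataset under analysis, making binding scores comparable to
  divergence terms. `c` is counted **per stage** (the relevance subset and
  the connectivity subset each have their own `c`).

`Combo = (RlogF × PredScal) × KLD`, computed per pattern; its sign follows
the KLD term.

## Pipeline

Four sequential filters, with Combo as the saliency mechanism:

1. **Novelty** — an explicit concept stoplist (default empty) removes
   assertions about overly general concepts. Deriving generality from an
   ontology hierarchy is deliberately out of scope; a stoplist keeps the
   filter testable and dependency-free.
2. **Relevance** — predications carrying the seed topic as an argument.
   Patterns are Combo-scored against the seed-restricted background; the
   records matching the top `k` patterns (default 4) are salient.
3. **Connectivity** — the *anchor* semantic type is the non-seed type
   occurring in the most top relevance patterns (ties: larger summed
   score, then lexicographic). Seed-free predications carrying the anchor
   type are scored the same way — the anchor type plays the seed's role,
   RlogF binds the *other* argument's type, and both foreground and
   background are restricted to seed-free, anchor-carrying records — and
   records matching the top pattern (default 1) are salient.
4. **Saliency** is the scoring inside stages 2–3.

Comparison arms: `KLD_ONLY` ranks bare predicates by divergence term and
keeps all records with the top-4 predicates (connectivity: top-1 predicate;
its anchor is the most frequent non-seed semantic type among the salient
relevance records, frequency ties broken lexicographically). `RLOGF_ONLY`
ranks side-pooled (predicate, semantic type) pairs by RlogF — it needs no
background — and keeps records matching the top-4 pairs (connectivity:
top-1).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `top_relevance_patterns` | 4 | patterns kept in the relevance stage |
| `top_connectivity_patterns` | 1 | patterns kept in the connectivity stage |
| `novelty_stoplist` | empty | concept names pared away before staging |
| `entity_semtypes` | `{gngm, aapp}` | argument types counted as genetic entities |

The top-k defaults follow the standard practice of carrying four relevance
patterns and one connectivity pattern into curation; no score-threshold
mode is provided because the selection is rank-based by design.

## Numerical and procedural conventions

- **Tie-breaking** of pattern ranks is total and deterministic: score
  descending, support count descending, predicate lexicographic, bound
  semantic type lexicographic, subject side before object side. (The
  semantic-type step is needed for totality: two same-predicate,
  same-count patterns always tie on every other key.)
- **PredScal degenerate inputs**: `c = 2` gives 1.0 analytically; `c = 1`
  would divide by zero and is defined as 1.0 — scaling is meaningless in a
  one- or two-predicate vocabulary.
- **Predicates absent from the background** have no divergence term; their
  patterns are excluded with a logged warning rather than smoothed, since
  smoothing would invent background probability mass.
- **Slot attribution**: every record maps to exactly one pattern. If both
  argument slots qualify as the anchor (seed on both sides, or both slots
  carrying the anchor type), the subject slot is treated as the anchor and
  the object slot is the bound one.
- **Concept matching** is case-insensitive exact string equality on
  argument names; a query of CUI shape (`C` + 7 digits) matches argument
  CUIs instead. Without ontology access, exact names are the reproducible
  proxy for concept identity.
- **Degenerate stages**: an empty connectivity subset, or a connectivity
  background sharing no predicate with it, yields an empty connectivity
  stage with a log note — a legitimate outcome on small corpora — whereas
  a missing seed or an unrestrictable relevance background raises. When
  every pattern scores zero (foreground equals background) the ranking
  falls back to the tie rule and the result log says so.
- **Evaluation truncation policy**: printed percentages and F-scores are
  floor-truncated (61.54% → 61%, F 0.6959 → 0.69), and the truncated F is
  the harmonic mean of the *two-decimal truncated* precision and recall;
  exact untruncated values are always reported alongside. Recall counts
  reference-standard genes only (`reference_tp/(reference_tp+fn)`), while
  precision credits validity-reviewed extra genes (`tp/(tp+fp)`) —
  the two true-positive tallies are deliberately distinct fields.
- Validity labels (TP/FP for asserted genes outside the reference) are
  external inputs standing in for manual curation review; the package
  never computes biological correctness.

## Synthetic corpora

`generate_corpus` draws records by weighted categorical sampling:
predicate, then a (subject, object) semantic-type pair (globally or per
predicate), then names per semantic type, with a configurable seed-topic
inclusion rate and side. This emulates the one statistical property the
metrics consume — a foreground whose predicate/semantic-type distribution
is skewed relative to a flatter background — and nothing else. It does
not emulate extractor linguistics (argument errors, nested predications),
real predicate frequency profiles, citation-level correlation between
records, or synonymy among argument names. Passing tests on synthetic
corpora therefore validate the arithmetic and the pipeline contracts, not
performance on real literature output.

The deterministic fixtures are self-verifying (their declared compositions
are recounted in tests): a 29/100-vs-76/1000 count-table pair realizing
foreground/background relative frequencies 0.290/0.076 with the smallest
exact integer tables; a 261-record relevance corpus with 16 unique
predicates in which `gngm` binds `ASSOCIATED_WITH` 107 times of 171; and a
full-pipeline bundle (675 foreground + 1400 background records) whose
planted pattern order, anchor type, and gene assertions produce an 8-of-13
reference recovery with 60 of 74 assertions surviving validity review.
The bundle's corpus sizes were chosen to keep every stage's counts
hand-checkable while leaving clear score separation between selected and
rejected patterns; randomized property tests use 200 replicates of 5,000
records for pattern-recovery rates and 100 replicates of 300 records for
pipeline invariants.

## Known limitations

- Name-based concept matching conflates homonyms and splits synonyms
  unless CUIs are supplied; the normalization table is the only synonym
  mechanism in the evaluation path.
- The novelty filter is only as good as the supplied stoplist.
- Backgrounds must be restricted per stage (seed-containing; seed-free
  anchor-carrying). Pre-aggregated tables declare the anchor they were
  restricted to, and a mismatch with the discovered anchor is an error
  rather than a silent reuse.
- One semantic type per argument per record; producers whose extractor
  assigns several must emit one record per combination.
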