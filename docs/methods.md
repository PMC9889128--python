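# Methods

This note records the models and procedures implemented in `pathocite`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not show.

## Task model

A *citation* is a MEDLINE-style record: PMID, title, optional abstract, and
a list of MeSH descriptors. The target notion is the *experimentally
studied* pathogen: one the authors actively worked with, as opposed to a
background, comparative or surveillance mention. The pipeline decomposes
this into mention identification (high recall) followed by per-pair
relevance filtering (precision recovery), evaluated at the citation level —
a (PMID, pathogen) pair counts once however many mentions occur — because
the supervision signal (MeSH indexing) is per citation.

The core supervision assumption: **a pathogen whose MeSH descriptor indexes
a citation is a focus entity of that article**. This is deliberately
simplistic (an indexer may assign a descriptor for a non-experimental
focus), but it is cheap, scales to the whole of MEDLINE, and is exactly the
assumption the synthetic fixtures realize, which is what makes end-to-end
closure testable.

## Lexicon construction

Organism terms come from an OBO taxonomy: for each pathogen, the scientific
name and synonyms of its root taxon and every transitive subspecies.
Synonym scopes EXACT, RELATED and NARROW are harvested; BROAD synonyms are
excluded (they name supersets and inflate false positives). Obsolete terms
are skipped.

The normalization cascade, applied in order to organism terms:

1. the token `subtype` is deleted (`H1N1 subtype` → `H1N1`);
2. terms starting (case-insensitively) with `influenza a virus (` or
   `influenza b virus (` are discarded — these are bulk strain entries that
   bloat the dictionary without adding recall;
3. terms whose last whitespace token is `virus` additionally emit the
   variant with that token removed (`influenza A virus` → also
   `influenza A`). Both forms are kept: dropping the full form loses
   nothing (longest match prefers it), while the stripped variant buys
   recall where prose leaves "virus" implicit;
4. single-letter virus names (`B virus`) are discarded — they would fire
   inside `Influenza B virus`, `Hepatitis B virus` etc.;
5. any resulting term of ≤ 3 characters is discarded; abbreviations are too
   ambiguous at this length, and in practice their long forms are present
   as separate dictionary entries.

Deduplication is case-insensitive with first-seen casing kept (matching is
case-insensitive anyway). A "virus term" is defined by its last whitespace
token being `virus`; the cascade's source material gives examples rather
than a predicate, so this is a documented choice. Normalization is
idempotent by construction, which the property suite asserts.

## Mention recognition

**Tokenization**: tokens are maximal runs of letters, digits and hyphens;
everything else separates. Dictionary matches must start and end at token
boundaries, which blocks substring hits inside longer tokens; both the
matcher and the dictionary side tokenize identically.

**Dictionary matching** is case-insensitive, left-to-right, longest-match:
entries are indexed by first token; at each position the longest matching
token sequence wins, the scan resumes after it, and spans never overlap.
When several pathogens share the winning surface the lexicographically
lowest pathogen id is chosen and the alternatives are recorded on the
mention (`ambiguous_with`) — determinism over cleverness.

**Toxin regexes** are built from stems (`aflatox`, `botulinum ?(neuro)?tox`,
`ciguatox`, `conotox`, `enterotox`, `saxitox`, `tetrodotox`) wrapped as
`(?i)[a-z]*STEM[a-z0-9]*`: case-insensitive and intentionally *not*
boundary-constrained, so embedded compounds (`onabotulinumtoxinA`,
`antiaflatoxinB1`) match. The exact production patterns of the original
tooling are not public; these are behaviour-matched to the documented
examples, and the bank is a plain TSV so it can be replaced wholesale.

**Prion detection** is co-occurrence: a mention is emitted for each
occurrence of a host-species term (common name + plural: human, sheep,
cattle, cat, deer, goat, mink) in a field, provided a prion term (`PrPSc`,
`prion(s)`, `scrapie`, ...) occurs anywhere in the citation. No prion term,
or no species term, means no mentions.

**Composition**: the three recognizers run over title and abstract (title
only when the abstract is absent); overlapping spans are resolved longest-
first, with dictionary beating regex beating prion on length ties —
mirroring the longest-match preference across methods.

## Weak labeling and masking

One training example per (citation, pathogen) pair with at least one
mention. The label is `relevant` iff the citation's MeSH descriptors
intersect the pathogen's descriptor set. Masking replaces that pathogen's
mention spans with `@PATHOGEN$` (right-to-left per field so offsets stay
valid; title and abstract joined by one newline); other pathogens' mentions
remain as surface text. Pair granularity — rather than masking all
pathogens jointly — is the only reading consistent with filtering
*individual* pathogens per citation. Pathogens with no MeSH mapping
generate no training examples (the label would be systematically wrong) but
are still recognized at inference.

## Relevance filter

Features: lower-cased tokens minus a fixed, version-pinned stop-word list
(closed-class words only; packaged in `pathocite.stopwords`), binary
presence indicators for unigrams and optionally bigrams. The mask token
survives featurization as a single symbol so the model can condition on the
masked entity position. Feature values are binary, not counts.

Training: SGD on the modified Huber loss, L(m) = max(0, 1−m)² for m ≥ −1
and −4m below, margin m = y·s. The loss is continuous and convex, both
branches give 4 at m = −1, and the linear tail makes it robust to the label
noise inherent in weak supervision. Defaults, serialized with the model:
10 epochs, L2 strength λ = 1e−4, learning rate ηₜ = 1/(λ(t + t₀)) with t₀
set so η₀ = 0.1, per-epoch shuffling with seed 42. Same-seed retraining is
bit-identical by contract. Models serialize to JSON (vocabulary, weights,
bias, config) and reload identically.

Confidence: clip((1 + s)/2, 0, 1) — the standard probability link for this
loss; s = 0 maps to 0.5. Default decision threshold 0.5; raising it can
only shrink the retained set (asserted as a monotonicity property). The
threshold is exposed because the right operating point depends on the
downstream precision/recall trade-off, and the weakly labeled data is too
noisy to fix it universally.

## Evaluation

precision = TP/(FP+TP), recall = TP/Positives, F1 = 2PR/(P+R). Zero
denominators give 0 by convention (never exercised by the published rows).
Micro averaging sums counts before computing metrics; macro averages the
per-pathogen metrics. Reported values are rounded half away from zero at 4
decimals; internal computation keeps full precision; test comparisons use
tolerance 5e−5.

Two published contingency rows are internally inconsistent and excluded
from exact checks: the aflatoxins regex row (printed precision 0.9988 vs
9127/9130 = 0.9997) and the precision cell only of the saxitoxins
dictionary row (printed 0.9279 vs 909/980 = 0.9276, evidently the regex
row's value; its recall and F1 cells are consistent and are checked).

## Dataset builder

The acquisition pipeline is written against a four-capability service
contract (taxon name search scoped to scientific names or all fields, child
listing, MeSH literature search, gene-record links). Resolution takes the
scientific-name hit if unique, falls back to all name fields, and skips
ambiguous (>1 record) names. Subspecies expansion is a BFS closure with
cycle detection. Prion species use the byte-exact template
`"PrPSc Proteins"[MH] AND <species>[MH]`; species without a MeSH heading
(elk, greater kudu, moose, mule, nyala, onyx, ostrich) are flagged
`not_found`. Gene-link PMIDs are collected and reported separately from
MeSH-derived PMIDs but are not used for weak labels. The bundled mock
backend is a directory of TSV tables and is fully deterministic; the live
Entrez client rate-limits and caches every response to disk, and is never
exercised by the test suite.

## Synthetic fixtures

The generator emulates the data shapes, not the language: slot-filled
English-like sentences, synthetic binomial species names (globally unique,
so planted mentions resolve unambiguously), strain-suffixed subspecies, and
two *disjoint* cue vocabularies — experimental (cultured, sequenced,
assayed, ...) vs background (review, surveillance, policy, ...) — that make
relevance a deterministic function of visible words. Defaults: 6 species ×
2 subspecies, 1 synonym per node, 200 citations, 20% without abstract
(matching the published corpus-level rate), 50% relevant pairs, one
pathogen per citation with 1–3 mentions. The standard cue corpus used for
classifier checks is seed 42 with 2000 citations (2000 pairs, 80/20
train/test). An optional `variant_fraction` plants out-of-dictionary forms
(name tokens fused) to exercise recall-loss measurement.

Planted MeSH descriptors include the pathogen's descriptor iff the pair is
relevant, which realizes the weak-labeling assumption *exactly*. Passing
tests therefore demonstrate mechanical correctness — offset fidelity,
longest-match behaviour, label/mask arithmetic, learnability of planted
cues — not performance on natural prose, where term variation,
coordination ("influenza A and B viruses"), abbreviations and indexing
noise all reduce accuracy.

## Problem sizes and numerical choices

The oracle-equivalence suite runs 100 seeded corpora of 12–40 citations
with dictionaries of roughly 30–300 entries, plus one 10,000-entry
dictionary check; brute-force scan oracles are re-implemented independently
in the test helpers. Training checks use the 2000-pair cue corpus. Rounding
is half-away-from-zero at 4 decimals (2 for percentages). Degenerate
inputs: empty dictionaries refuse to compile, single-class training sets
raise naming the missing class, empty corpora refuse abstract statistics,
and overlapping mentions are rejected at masking time (the recognizer
guarantees none).

## Known limitations

- Coordination/ellipsis and abbreviation expansion are out of scope; the
  dictionary path will miss "influenza A and B viruses"-style variants.
- The toxin regex bank is reconstructed from documented examples, not the
  original pattern set.
- MeSH heading strings themselves are not scanned as text; only title and
  abstract are.
- The weak labels inherit every failure mode of MeSH indexing as a proxy
  for experimental study; the filter's confidence threshold should be tuned
  on task-specific annotated data when available.
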