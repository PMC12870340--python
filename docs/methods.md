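# Methods

## The annotation model

`orphindex` treats rare-disease indexing as unsupervised, dictionary-based
named-entity recognition against a taxonomy. The assumptions baked into the
design:

- **Disease names are specific.** Multi-token rare-disease names and
  synonyms rarely occur by accident, so lexical matching attains high
  precision without statistical disambiguation. Ambiguous surfaces (one
  normalized string naming several concepts) are assigned to *all* mapped
  concepts — a pure dictionary matcher has no evidence to pick one.
- **Abstract-level text is the right input.** Only title, abstract and
  keywords are matched; full text mostly adds false positives. The three
  fields are concatenated with a `[SEP]` sentinel and no match may cross a
  field boundary. A literal `[SEP]` inside a field is neutralized to
  `[SEP_]` before concatenation so that exactly two real separators exist.
  Keywords are joined with `"; "`, which normalizes to a token break and is
  therefore boundary-safe.
- **The taxonomy churns.** Concepts are renamed and deprecated monthly, so
  deprecated concepts keep their historical labels in the dictionary but map
  (via `replaced_by` chains) to their active successor, and evaluation
  resolves gold codes the same way.

## Normalization and offsets

One `NormalizationPolicy` governs both dictionary surfaces and document
text: lowercase; strip diacritics (NFKD, drop combining marks); transliterate
Greek letters to Latin names (β → "beta"); replace every non-alphanumeric
character by a space; collapse whitespace. Digits are kept — "type 1"
distinguishes concepts. Normalization is idempotent, and a per-character
origin map is threaded through every step so each token carries its span in
the *original* string (0-based, half-open). A β that expands to four
normalized characters yields a token whose span covers exactly the β.

## Matching

**Exact.** Dictionary surfaces are stored as token sequences in a hash index
keyed by first token; scanning the document's token stream finds every
token-boundary-aligned occurrence ("disease" never matches inside
"diseased"). A match strictly contained in a longer match's span is
suppressed (longest-match-wins); identical spans from ambiguous surfaces are
all kept.

**Fuzzy.** For a k-token term, windows of k−1, k and k+1 consecutive tokens
within one field are scored by normalized Levenshtein similarity
`1 − lev/max(len)` over the normalized strings (distance via edlib, with the
edit budget `⌊(1−threshold)·maxlen⌋` as an early-exit bound and a length
prefilter `|t| ∈ [θ·|w|, |w|/θ]`). The default threshold is 0.8. Distance-0
windows are left to the exact matcher. Surfaces shorter than
`min_term_chars = 4` (mostly acronyms) are never fuzzy-matched
(`short_term_policy = "exact_only"`); fuzzy-matching 2–3-character strings
would destroy precision for a negligible recall gain. The similarity
function is the simplest token-based metric consistent with a fixed
threshold semantics; at threshold 1.0 fuzzy output is empty after exact
precedence, so the combined engine degenerates exactly to the baseline.

**Combination.** Exact and fuzzy mentions are merged with exact precedence:
a fuzzy mention overlapping an exact mention of the same concept is dropped;
an overlapping mention of a different concept is kept and flagged
`overlaps-exact`.

**Propagation.** Direct concepts (resolved through deprecation) are
propagated to ancestors at shortest-path distance 1..`max_dist` in the
parent DAG, with provenance `(ancestor, source, distance)`. The default
`max_dist = 2` reads "ancestors closer than three concepts" literally as
distances {1, 2}; the parameter is exposed for the inclusive reading.
Propagation runs once, from direct matches only — it does not cascade from
its own output.

## Evaluation

Micro-averaging over (document, concept) pairs is the primary convention
(standard for multi-label indexing benchmarks, and it makes Wilson intervals
on pair counts well-defined); per-document (example-based) averaging is
available via `averaging="example"`. Conventions: precision with zero
predictions is 0; gold sets are non-empty by construction, so recall is
always defined; F1 is 0 when P+R = 0. Wilson 95% intervals use pair-level n
for precision (tp+fp) and recall (tp+fn) and document-level n for
CorrectRatio/ExactRatio; no interval is attached to F1 (a closed-form
binomial interval does not apply to a harmonic mean).

## Synthetic data: what it emulates, and what it does not

The generator emulates the features that make this task nontrivial:
multi-token disease-like names (pronounceable CV-syllable words plus
suffixes like "syndrome", "type 3") with synonyms and optional acronyms; a
rooted parent DAG grown level-by-level with 2–4 children per node within
`max_depth = 4`, plus occasional second parents; a fraction
(`deprecated_prob = 0.1`) of deprecated renames whose replacement chains
(sometimes two hops) end in active concepts; and documents of 40–80
distractor tokens with 1–3 injected mentions each, using a synonym with
probability 0.3 and a misspelling of exactly `typo_edits` edits with
probability `typo_prob`.

Two constructions make the recovery guarantees *analytic* rather than
statistical:

- distractor words draw from a consonant inventory disjoint from disease
  names, so no distractor content comes near any dictionary surface;
- generated surfaces are mutually separated: every token window of one
  surface is kept at relative edit distance > 0.3 from every other surface.
  Since a one-edit typo moves a ≥ 12-character mention by at most
  1/12 ≈ 0.083 similarity, no perturbed mention can cross the 0.8 threshold
  toward a *wrong* concept, so combined precision stays exactly 1.0 in the
  typo regimes.

What the generator does **not** emulate — and hence what passing tests do
not show about real literature: real disease names share words massively
("Niemann-Pick disease type A/B" differ by one character), so real fuzzy
matching does confuse sibling subtypes; real text has acronym polysemy,
negation, and mentions of diseases that are not the article's topic; gold
labels derived from another vocabulary are noisy. The synthetic guarantees
validate the machinery (windowing, scoring, thresholds, propagation,
metrics), not corpus-level performance claims.

Everything is a pure function of the `SyntheticSpec` including its seed;
identical specs give byte-identical bundles.

## Numerical and design choices

- Edit distances come from edlib in the engine; all tests cross-check
  against an independent pure-Python dynamic-programming oracle, and the
  matchers are verified set-identical to exhaustive (window × term) scans on
  hundreds of random documents.
- Wilson intervals use `z = Φ⁻¹((1+c)/2)` from scipy; endpoints are clamped
  to exactly 0/1 at k = 0 and k = n.
- Ties in bibliometric `top_n` break lexicographically; only full counting
  is implemented (fractional counting is out of scope).
- Problem sizes in the bundled experiments (100 concepts / 200 documents for
  the noise-free bundle, 60 / 100 for the typo bundle) are chosen so the
  whole verification runs in seconds on one core while leaving every rate
  estimable to two digits.
- Whether deprecation is resolved before or after matching is configurable
  in effect: the dictionary remaps deprecated labels at compile time
  (`include_deprecated_labels=True`), and the engine additionally resolves
  every mention's concept before propagation, so either order yields the
  same final sets.

## Known limitations

- No abbreviation detection (long-form/short-form alignment) or semantic /
  embedding matching; no negation or topicality filtering — "no evidence of
  X" still matches X, as in any pure dictionary NER.
- Fuzzy matching is O(windows × candidate terms) per document with length
  pruning; fine at abstract scale, but corpus-scale ingestion would want a
  candidate index (e.g. q-gram filtering).
- Cross-vocabulary mappings (MeSH → taxonomy codes) are inputs, not
  constructed here; `coverage` assumes the mapping is already applied.
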