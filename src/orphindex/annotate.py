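"""The annotation engine: match article records against the disease dictionary.

An article record (title, abstract, keywords) is concatenated into one
document with ``[SEP]`` sentinels between fields, normalized and tokenized.
Two matchers then run over the token stream:

* exact matching — token-boundary-aligned lookup of dictionary surfaces
  (the high-precision baseline; "disease" never matches inside "diseased");
* fuzzy matching — token windows of width k-1..k+1 around each k-token term
  scored by normalized Levenshtein similarity
  ``1 - dist / max(len(window), len(term))``, kept at score >= 0.8 by
  default, recovering misspellings and slight surface variants.

Matched concepts are resolved through deprecation links and finally
propagated to near ancestors in the hierarchy (shortest-path distance 1..2 by
default), so a paper on a specific subtype also counts toward its parent
disease groups. No mention ever crosses a field boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib

from .dictionary import (
    DEFAULT_POLICY,
    CompiledDictionary,
    NormalizationPolicy,
    Token,
    tokenize,
)
from .taxonomy import Taxonomy, ancestors_with_distance, resolve_concept

__all__ = [
    "ArticleRecord",
    "PreparedDocument",
    "Mention",
    "DocAnnotation",
    "AnnotatorConfig",
    "prepare_document",
    "exact_match",
    "fuzzy_match",
    "combine_mentions",
    "propagate_concepts",
    "annotate_document",
    "annotate_corpus",
]

SEP = "[SEP]"
_SEP_JOIN = " [SEP] "
FIELD_NAMES = ("title", "abstract", "keywords")


@dataclass(frozen=True)
class ArticleRecord:
    """One bibliographic record: identifier, text fields, optional metadata.

    ``metadata`` may carry ``year`` (int), ``countries`` (list of str) and
    ``subject_areas`` (list of str) for downstream bibliometric aggregation.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    keywords: tuple[str, ...] = ()
    metadata: dict | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class PreparedDocument:
    """Concatenated, normalized and tokenized form of an article record."""

    doc_id: str
    full_text: str
    field_boundaries: tuple[tuple[str, int, int], ...]
    tokens: tuple[Token, ...]  # offsets into full_text
    token_fields: tuple[int, ...]  # parallel: index into field_boundaries
    policy: NormalizationPolicy = DEFAULT_POLICY

    def field_token_runs(self) -> list[list[Token]]:
        """Tokens grouped per field, in order."""
        runs: list[list[Token]] = [[] for _ in self.field_boundaries]
        for tok, fi in zip(self.tokens, self.token_fields):
            runs[fi].append(tok)
        return runs


@dataclass(frozen=True)
class Mention:
    """A text span matched to a concept."""

    concept_code: str
    start: int
    end: int
    surface: str
    matched_term: str
    match_type: str  # "exact" | "fuzzy"
    score: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("mention span must be non-empty")
        if self.match_type == "exact" and self.score != 1.0:
            raise ValueError("exact mentions carry score 1.0")


@dataclass(frozen=True)
class AnnotatorConfig:
    """Engine configuration; defaults mirror the best-performing setup
    (exact baseline plus fuzzy at threshold 0.8, propagation to ancestors
    at distance 1-2)."""

    fuzzy: bool = True
    fuzzy_threshold: float = 0.8
    propagate: bool = True
    propagate_max_dist: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.fuzzy_threshold <= 1.0):
            raise ValueError("fuzzy_threshold must be in (0, 1]")
        if self.propagate_max_dist < 1:
            raise ValueError("propagate_max_dist must be >= 1")


@dataclass(frozen=True)
class DocAnnotation:
    """Final annotation of one document: mentions, direct and propagated concepts."""

    doc_id: str
    mentions: tuple[Mention, ...]
    direct_concepts: frozenset[str]
    propagated_concepts: tuple[tuple[str, str, int], ...]  # (code, source, distance)
    final_concepts: frozenset[str]


def _neutralize_sep(text: str) -> str:
    # A literal "[SEP]" inside a field would fake a boundary; break it up.
    return text.replace(SEP, "[SEP_]")


def prepare_document(
    rec: ArticleRecord, policy: NormalizationPolicy = DEFAULT_POLICY
) -> PreparedDocument:
    """Concatenate title/abstract/keywords with ``[SEP]`` and tokenize.

    Keywords are joined by "; " (the ";" normalizes to a token break, so the
    join is boundary-safe). Token offsets refer to the returned ``full_text``;
    no token crosses a field boundary because each field is tokenized
    independently. Raises if all three fields are empty.
    """
    kw_text = "; ".join(rec.keywords)
    fields = [_neutralize_sep(rec.title), _neutralize_sep(rec.abstract), _neutralize_sep(kw_text)]
    if not any(f.strip() for f in fields):
        raise ValueError(f"record {rec.doc_id!r}: title, abstract and keywords all empty")
    boundaries: list[tuple[str, int, int]] = []
    tokens: list[Token] = []
    token_fields: list[int] = []
    pos = 0
    parts: list[str] = []
    for fi, (name, text) in enumerate(zip(FIELD_NAMES, fields)):
        if fi > 0:
            parts.append(_SEP_JOIN)
            pos += len(_SEP_JOIN)
        boundaries.append((name, pos, pos + len(text)))
        for tok in tokenize(text, policy):
            tokens.append(Token(tok.text, tok.start + pos, tok.end + pos))
            token_fields.append(fi)
        parts.append(text)
        pos += len(text)
    return PreparedDocument(
        doc_id=rec.doc_id,
        full_text="".join(parts),
        field_boundaries=tuple(boundaries),
        tokens=tuple(tokens),
        token_fields=tuple(token_fields),
        policy=policy,
    )


def _check_policy(doc: PreparedDocument, dictionary: CompiledDictionary) -> None:
    if doc.policy != dictionary.policy:
        raise ValueError(
            "document was prepared with a different normalization policy "
            "than the dictionary was compiled with"
        )


def _drop_contained(mentions: list[Mention]) -> list[Mention]:
    """Longest-match-wins: drop mentions strictly contained in a longer span.

    Identical spans (ambiguous surfaces) are all kept.
    """
    spans = {(m.start, m.end) for m in mentions}
    kept = []
    for m in mentions:
        contained = any(
            (s <= m.start and m.end <= e) and (s, e) != (m.start, m.end)
            for (s, e) in spans
        )
        if not contained:
            kept.append(m)
    return kept


def _sort_mentions(mentions: Iterable[Mention]) -> list[Mention]:
    return sorted(
        mentions,
        key=lambda m: (m.start, m.end, m.concept_code, m.match_type, m.matched_term),
    )


def exact_match(doc: PreparedDocument, dictionary: CompiledDictionary) -> list[Mention]:
    """Find every dictionary surface occurring as a token-aligned subsequence.

    Ambiguous surfaces yield one mention per mapped concept; a match strictly
    contained in a longer match's span is suppressed (longest-match-wins).
    """
    _check_policy(doc, dictionary)
    found: list[Mention] = []
    for run in doc.field_token_runs():
        texts = [t.text for t in run]
        for i, tok_text in enumerate(texts):
            for seq, entries in dictionary.exact_index.get(tok_text, ()):
                j = i + len(seq)
                if j > len(texts):
                    continue
                if tuple(texts[i:j]) != seq:
                    continue
                start, end = run[i].start, run[j - 1].end
                for e in entries:
                    found.append(
                        Mention(
                            concept_code=e.concept_code,
                            start=start,
                            end=end,
                            surface=doc.full_text[start:end],
                            matched_term=e.surface_normalized,
                            match_type="exact",
                            score=1.0,
                        )
                    )
    return _sort_mentions(_drop_contained(found))


def _similarity(a: str, b: str, max_edits: int) -> float | None:
    """Normalized Levenshtein similarity, or None if below the edit budget."""
    longest = max(len(a), len(b))
    if longest == 0:
        return None
    if abs(len(a) - len(b)) > max_edits:
        return None
    res = edlib.align(a, b, mode="NW", task="distance", k=max_edits)
    d = res["editDistance"]
    if d < 0:
        return None
    return 1.0 - d / longest


def fuzzy_match(
    doc: PreparedDocument,
    dictionary: CompiledDictionary,
    threshold: float = 0.8,
) -> list[Mention]:
    """Score token windows against dictionary terms by edit-distance similarity.

    For a k-token term, candidate windows span k-1..k+1 consecutive tokens
    within a single field; similarity is ``1 - lev(window, term)/max(len)``
    over the normalized strings. Windows at or above ``threshold`` become
    fuzzy mentions. Exact duplicates (distance 0) are left to the exact
    matcher; short exact-only terms are skipped entirely.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    _check_policy(doc, dictionary)
    terms = dictionary.fuzzy_terms()
    if not terms:
        return []
    # group terms by token count, sorted by surface length for window pruning
    by_k: dict[int, list[tuple[int, str, tuple[str, ...]]]] = {}
    for surface, k, codes in terms:
        by_k.setdefault(k, []).append((len(surface), surface, codes))
    for lst in by_k.values():
        lst.sort()
    found: list[Mention] = []
    slack = 1.0 - threshold
    for run in doc.field_token_runs():
        texts = [t.text for t in run]
        n = len(texts)
        for w in range(1, n + 1):
            candidates = [t for k in (w - 1, w, w + 1) for t in by_k.get(k, [])]
            if not candidates:
                continue
            for i in range(n - w + 1):
                window = " ".join(texts[i : i + w])
                lw = len(window)
                # admissible term lengths: |lw - lt| <= slack * max(lw, lt)
                lo = threshold * lw
                hi = lw / threshold
                for lt, surface, codes in candidates:
                    if lt < lo or lt > hi:
                        continue
                    budget = int(slack * max(lw, lt) + 1e-9)
                    if budget < 1:
                        continue  # only exact survives; handled by exact_match
                    score = _similarity(window, surface, budget)
                    if score is None or score >= 1.0:
                        continue
                    if score + 1e-12 < threshold:
                        continue
                    start, end = run[i].start, run[i + w - 1].end
                    for code in codes:
                        found.append(
                            Mention(
                                concept_code=code,
                                start=start,
                                end=end,
                                surface=doc.full_text[start:end],
                                matched_term=surface,
                                match_type="fuzzy",
                                score=score,
                            )
                        )
    return _sort_mentions(found)


def combine_mentions(
    exact: Sequence[Mention], fuzzy: Sequence[Mention]
) -> list[Mention]:
    """Merge exact and fuzzy mention lists with exact precedence.

    A fuzzy mention overlapping an exact mention of the same concept is
    dropped (the exact hit subsumes it); an overlapping fuzzy mention of a
    *different* concept is kept and flagged. Result sorted by span.
    """
    merged: list[Mention] = list(exact)
    for m in fuzzy:
        overlapping = [
            e for e in exact if m.start < e.end and e.start < m.end
        ]
        if any(e.concept_code == m.concept_code for e in overlapping):
            continue
        if overlapping and "overlaps-exact" not in m.flags:
            m = replace(m, flags=m.flags + ("overlaps-exact",))
        merged.append(m)
    return _sort_mentions(merged)


def propagate_concepts(
    direct: set[str], tax: Taxonomy, max_dist: int = 2
) -> set[tuple[str, str, int]]:
    """Assign each directly matched concept's near ancestors with provenance.

    Returns (ancestor code, source code, shortest-path distance) triples for
    distances 1..max_dist; ancestors that are themselves direct matches are
    not re-added.
    """
    out: set[tuple[str, str, int]] = set()
    for code in sorted(direct):
        for anc, d in ancestors_with_distance(tax, code, max_dist).items():
            if anc not in direct:
                out.add((anc, code, d))
    return out


def annotate_document(
    rec: ArticleRecord,
    dictionary: CompiledDictionary,
    tax: Taxonomy,
    config: AnnotatorConfig = AnnotatorConfig(),
) -> DocAnnotation:
    """Run the full pipeline on one record.

    prepare -> exact match -> fuzzy match (optional) -> combine -> resolve
    deprecations -> propagate to ancestors (optional). Pure function of its
    inputs: identical inputs give byte-identical annotations.
    """
    doc = prepare_document(rec, dictionary.policy)
    exact = exact_match(doc, dictionary)
    fuzzy = (
        fuzzy_match(doc, dictionary, config.fuzzy_threshold) if config.fuzzy else []
    )
    mentions = combine_mentions(exact, fuzzy)
    direct = frozenset(resolve_concept(tax, m.concept_code) for m in mentions)
    propagated: set[tuple[str, str, int]] = set()
    if config.propagate:
        propagated = propagate_concepts(set(direct), tax, config.propagate_max_dist)
    final = direct | {code for code, _, _ in propagated}
    return DocAnnotation(
        doc_id=rec.doc_id,
        mentions=tuple(mentions),
        direct_concepts=direct,
        propagated_concepts=tuple(sorted(propagated)),
        final_concepts=frozenset(final),
    )


def annotate_corpus(
    records: Iterable[ArticleRecord],
    dictionary: CompiledDictionary,
    tax: Taxonomy,
    config: AnnotatorConfig = AnnotatorConfig(),
) -> list[DocAnnotation]:
    """Annotate every record in a corpus."""
    return [annotate_document(r, dictionary, tax, config) for r in records]
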