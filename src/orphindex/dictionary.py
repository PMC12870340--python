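"""Term normalization, tokenization, and the compiled disease-name dictionary.

Disease labels and synonyms are normalized (lowercase, diacritics stripped,
Greek letters spelled out, punctuation to whitespace) and indexed as token
sequences for exact multi-pattern lookup. The same normalization is applied to
documents, so "β-Thalassemia" in an abstract and "beta-thalassemia" in the
taxonomy meet at the shared surface "beta thalassemia". Character offsets are
threaded through every transformation so that each token knows its span in the
*original* text (0-based, half-open) — annotations stay usable for
highlighting.

Short surfaces (mostly acronym synonyms) are either dropped or restricted to
exact matching; fuzzy-matching a 2–3-character string would destroy precision.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

from .taxonomy import Taxonomy, UnresolvableConceptError, resolve_concept

__all__ = [
    "NormalizationPolicy",
    "Token",
    "TermEntry",
    "CompiledDictionary",
    "DictionaryError",
    "normalize_text",
    "tokenize",
    "build_dictionary",
    "GREEK_TO_LATIN",
]

logger = logging.getLogger(__name__)

# Lowercase Greek letter -> Latin name. Uppercase forms are lowercased first.
GREEK_TO_LATIN = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
    # common typographic variants
    "ϐ": "beta", "µ": "mu",
}


class DictionaryError(ValueError):
    """Raised for invalid dictionary construction inputs."""


@dataclass(frozen=True)
class NormalizationPolicy:
    """Declarative description of the text normalization pipeline.

    Each step is deterministic and the whole pipeline is idempotent:
    ``norm(norm(s)) == norm(s)``.
    """

    lowercase: bool = True
    strip_diacritics: bool = True
    transliterate_greek: bool = True
    non_alnum_to_space: bool = True
    collapse_whitespace: bool = True


DEFAULT_POLICY = NormalizationPolicy()


class Token(NamedTuple):
    """A normalized token with its character span in the original string."""

    text: str
    start: int
    end: int


def _char_expansion(c: str, idx: int, policy: NormalizationPolicy) -> list[tuple[str, int]]:
    """Expand one original character into normalized characters.

    Returns (normalized char, original index) pairs; a single original
    character may expand to several normalized characters (β -> "beta").
    """
    lower = c.lower()
    if policy.transliterate_greek and lower in GREEK_TO_LATIN:
        out = GREEK_TO_LATIN[lower]
        if not policy.lowercase and c.isupper():
            out = out.capitalize()
        return [(ch, idx) for ch in out]
    if policy.strip_diacritics:
        chars = [d for d in unicodedata.normalize("NFKD", c) if not unicodedata.combining(d)]
    else:
        chars = [c]
    result: list[tuple[str, int]] = []
    for ch in chars:
        if policy.lowercase:
            ch = ch.lower()
        if policy.non_alnum_to_space and not ch.isalnum():
            ch = " "
        result.append((ch, idx))
    return result


def _normalize_with_map(s: str, policy: NormalizationPolicy) -> tuple[str, list[int]]:
    """Normalize ``s`` returning the result and a per-character origin map.

    ``origin[i]`` is the index in ``s`` of the original character that
    produced normalized character ``i``.
    """
    stream: list[tuple[str, int]] = []
    for idx, c in enumerate(s):
        stream.extend(_char_expansion(c, idx, policy))
    if not policy.collapse_whitespace:
        return "".join(ch for ch, _ in stream), [i for _, i in stream]
    out_chars: list[str] = []
    origin: list[int] = []
    pending_space = False
    for ch, idx in stream:
        if ch.isspace():
            if out_chars:
                pending_space = True
            continue
        if pending_space:
            out_chars.append(" ")
            origin.append(idx)  # space attributed to following char's origin
            pending_space = False
        out_chars.append(ch)
        origin.append(idx)
    return "".join(out_chars), origin


def normalize_text(s: str, policy: NormalizationPolicy = DEFAULT_POLICY) -> str:
    """Normalize a string under ``policy``.

    With the default policy: lowercase, strip diacritics, transliterate Greek
    letters to their Latin names, map every non-alphanumeric character to a
    space, collapse whitespace runs and trim. Total on Unicode input; digits
    are retained (disease names such as "type 1" depend on them).
    """
    return _normalize_with_map(s, policy)[0]


def tokenize(s: str, policy: NormalizationPolicy = DEFAULT_POLICY) -> list[Token]:
    """Normalize ``s`` and split it into tokens with original-string offsets.

    Tokens are maximal alphanumeric runs of the normalized text. Each token's
    (start, end) span is 0-based half-open into ``s`` itself, covering the
    original characters that produced it (so a Greek β that expands to "beta"
    yields a token whose span covers just the β).
    """
    norm, origin = _normalize_with_map(s, policy)
    tokens: list[Token] = []
    i = 0
    n = len(norm)
    while i < n:
        if norm[i] == " ":
            i += 1
            continue
        j = i
        while j < n and norm[j] != " ":
            j += 1
        start = origin[i]
        end = origin[j - 1] + 1
        tokens.append(Token(norm[i:j], start, end))
        i = j
    return tokens


@dataclass(frozen=True)
class TermEntry:
    """One dictionary surface mapping to one concept."""

    surface_normalized: str
    token_count: int
    concept_code: str
    source: str  # "preferred_label" | "synonym"
    original_surface: str


@dataclass
class CompiledDictionary:
    """Normalized term surfaces indexed for exact and fuzzy lookup.

    ``exact_index`` maps a first token to the candidate token sequences (and
    their entries) starting with it; scanning a document's token stream
    against it finds exactly the entry surfaces present at token boundaries.
    ``ambiguity_map`` records surfaces shared by several concepts — the engine
    assigns all of them, as a pure dictionary matcher must.
    """

    entries: list[TermEntry]
    policy: NormalizationPolicy
    min_term_chars: int = 4
    short_term_policy: str = "exact_only"  # or "drop"
    exact_index: dict[str, list[tuple[tuple[str, ...], tuple[TermEntry, ...]]]] = field(
        default_factory=dict, repr=False
    )
    ambiguity_map: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exact_index:
            self._build_index()

    def _build_index(self) -> None:
        by_surface: dict[str, list[TermEntry]] = {}
        for e in self.entries:
            by_surface.setdefault(e.surface_normalized, []).append(e)
        index: dict[str, dict[tuple[str, ...], list[TermEntry]]] = {}
        amb: dict[str, frozenset[str]] = {}
        for surface, entries in by_surface.items():
            seq = tuple(surface.split())
            index.setdefault(seq[0], {})[seq] = entries
            codes = frozenset(e.concept_code for e in entries)
            if len(codes) > 1:
                amb[surface] = codes
        self.exact_index = {
            tok: sorted(
                ((seq, tuple(entries)) for seq, entries in seqs.items()),
                key=lambda p: (-len(p[0]), p[0]),
            )
            for tok, seqs in index.items()
        }
        self.ambiguity_map = amb

    def fuzzy_terms(self) -> list[tuple[str, int, tuple[str, ...]]]:
        """Unique surfaces eligible for fuzzy matching.

        Surfaces shorter than ``min_term_chars`` are exact-only (or already
        dropped); returns (surface, token_count, sorted concept codes).
        """
        seen: dict[str, set[str]] = {}
        counts: dict[str, int] = {}
        for e in self.entries:
            if len(e.surface_normalized) < self.min_term_chars:
                continue
            seen.setdefault(e.surface_normalized, set()).add(e.concept_code)
            counts[e.surface_normalized] = e.token_count
        return [
            (s, counts[s], tuple(sorted(codes)))
            for s, codes in sorted(seen.items())
        ]


def build_dictionary(
    tax: Taxonomy,
    policy: NormalizationPolicy = DEFAULT_POLICY,
    min_term_chars: int = 4,
    short_term_policy: str = "exact_only",
    include_deprecated_labels: bool = True,
) -> CompiledDictionary:
    """Compile the taxonomy's labels and synonyms into a matching dictionary.

    Every (concept, label-or-synonym) pair contributes one entry. Labels of
    deprecated concepts are remapped to their active replacement (when
    ``include_deprecated_labels``), mirroring how renamed concepts keep their
    historical surfaces findable. Surfaces shorter than ``min_term_chars``
    are dropped entirely under ``short_term_policy="drop"``, or retained for
    exact matching only under ``"exact_only"``.
    """
    if short_term_policy not in ("drop", "exact_only"):
        raise DictionaryError(f"unknown short_term_policy {short_term_policy!r}")
    if not tax.active_codes():
        raise DictionaryError("taxonomy has no active concepts")
    entries: list[TermEntry] = []
    seen_surfaces: set[tuple[str, str]] = set()  # (target code, normalized surface)
    for code in sorted(tax.concepts):
        concept = tax[code]
        if concept.is_active:
            target = code
        else:
            if not include_deprecated_labels:
                continue
            try:
                target = resolve_concept(tax, code)
            except UnresolvableConceptError:
                logger.debug("skipping terminal-deprecated concept %s", code)
                continue
        for source, surface in (
            ("preferred_label", concept.preferred_label),
            *(("synonym", s) for s in concept.synonyms),
        ):
            norm = normalize_text(surface, policy)
            if not norm:
                continue
            if len(norm) < min_term_chars and short_term_policy == "drop":
                continue
            if (target, norm) in seen_surfaces:
                logger.debug("duplicate surface %r within concept %s", norm, target)
                continue
            seen_surfaces.add((target, norm))
            entries.append(
                TermEntry(
                    surface_normalized=norm,
                    token_count=norm.count(" ") + 1,
                    concept_code=target,
                    source=source,
                    original_surface=surface,
                )
            )
    entries.sort(key=lambda e: (e.concept_code, e.surface_normalized, e.source))
    return CompiledDictionary(
        entries=entries,
        policy=policy,
        min_term_chars=min_term_chars,
        short_term_policy=short_term_policy,
    )
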