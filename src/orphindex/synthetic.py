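"""Synthetic taxonomies, corpora and gold labels for controlled experiments.

Real rare-disease names are multi-token, highly specific strings ("glycogen
storage disease due to acid maltase deficiency") with synonyms and acronyms,
organised in a poly-hierarchy that is continually revised (concepts get
deprecated and renamed). The generator emulates exactly those statistical
features — multi-token pronounceable names with synonyms and acronyms, a
rooted DAG with bounded depth, a controlled fraction of deprecated concepts
with replacement links — and produces article records with known injected
mentions (verbatim, synonym, or misspelled at an exact edit distance) amid
distractor text, so every matching property can be asserted analytically.

Distractor words are built from a consonant inventory disjoint from the one
used for disease names, keeping every distractor far (in edit distance) from
every dictionary surface; spurious matches are then impossible rather than
merely unlikely, which turns precision checks into exact assertions.

Everything is a pure function of the :class:`SyntheticSpec`, including its
seed: the same spec yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import edlib

from .annotate import ArticleRecord
from .dictionary import normalize_text
from .evaluate import GoldSet
from .taxonomy import Concept, Taxonomy, resolve_concept

__all__ = [
    "SyntheticSpec",
    "SyntheticBundle",
    "InjectionRecord",
    "generate_taxonomy",
    "generate_corpus",
    "generate_bundle",
    "perturb_term",
]

# Disease-name words and distractor words draw from disjoint consonant
# inventories; suffix words ("disease", "syndrome", "type N") stay on the
# disease side.
_NAME_CONSONANTS = "bcdfglmnprst"
_DISTRACTOR_CONSONANTS = "hjkqvwxz"
_VOWELS = "aeiou"
_SUFFIX_WORDS = ("disease", "syndrome", "deficiency", "dysplasia")

_COUNTRIES = ("NL", "US", "CN", "DE", "FR", "GB", "IT", "ES", "JP", "BR")
_SUBJECT_AREAS = (
    "Medicine",
    "Biochemistry",
    "Neuroscience",
    "Immunology",
    "Genetics",
    "Pharmacology",
    "Engineering",
    "Computer Science",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the generator; the seed fully determines the output."""

    n_concepts: int = 100
    max_depth: int = 4
    branching: tuple[int, int] = (2, 4)
    synonyms_per_concept: tuple[int, int] = (1, 3)
    acronym_prob: float = 0.2
    deprecated_prob: float = 0.1
    n_docs: int = 200
    mentions_per_doc: tuple[int, int] = (1, 3)
    typo_prob: float = 0.0
    typo_edits: int = 1
    synonym_use_prob: float = 0.3
    distractor_vocab_size: int = 400
    tokens_per_doc: tuple[int, int] = (40, 80)
    min_name_chars: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("acronym_prob", "deprecated_prob", "typo_prob", "synonym_use_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")
        if self.typo_edits < 1:
            raise ValueError("typo_edits must be >= 1")


class InjectionRecord(NamedTuple):
    """Provenance of one injected mention."""

    doc_id: str
    concept_code: str
    surface_used: str
    perturbed: bool
    edit_count: int


@dataclass(frozen=True)
class SyntheticBundle:
    """A matched taxonomy, corpus and gold-label set."""

    taxonomy: Taxonomy
    corpus: tuple[ArticleRecord, ...]
    gold: GoldSet
    injection_log: tuple[InjectionRecord, ...]
    spec: SyntheticSpec


def _word(rng: random.Random, consonants: str, n_syllables: tuple[int, int] = (2, 4)) -> str:
    k = rng.randint(*n_syllables)
    return "".join(rng.choice(consonants) + rng.choice(_VOWELS) for _ in range(k))


def _disease_name(rng: random.Random, min_chars: int) -> str:
    while True:
        n_words = rng.randint(1, 2)
        words = [_word(rng, _NAME_CONSONANTS) for _ in range(n_words)]
        words.append(rng.choice(_SUFFIX_WORDS))
        if rng.random() < 0.3:
            words += ["type", str(rng.randint(1, 9))]
        name = " ".join(words)
        if len(name) >= min_chars:
            return name


def _acronym(name: str) -> str:
    return "".join(w[0] for w in name.split() if w[0].isalpha()).upper()


# Minimum relative edit distance enforced between any window of one surface
# and any other surface. 0.3 leaves the 0.8 similarity threshold unreachable
# even after a one-edit typo on a >=12-char term, so false positives are
# structurally impossible rather than merely improbable.
_MIN_SEPARATION = 0.3


def _windows(norm: str, widths: set[int]) -> list[str]:
    toks = norm.split()
    out = []
    for w in widths:
        if 1 <= w <= len(toks):
            out.extend(" ".join(toks[i : i + w]) for i in range(len(toks) - w + 1))
    return out


def _surfaces_confusable(a: str, b: str) -> bool:
    """True if any token window of one surface sits too close to the other."""
    ka, kb = a.count(" ") + 1, b.count(" ") + 1
    for w, term in (
        *((w, b) for w in _windows(a, {kb - 1, kb, kb + 1})),
        *((w, a) for w in _windows(b, {ka - 1, ka, ka + 1})),
    ):
        longest = max(len(w), len(term))
        budget = int(_MIN_SEPARATION * longest)
        if abs(len(w) - len(term)) > budget:
            continue
        d = edlib.align(w, term, mode="NW", task="distance", k=budget)["editDistance"]
        if 0 <= d <= budget:
            return True
    return False


def generate_taxonomy(spec: SyntheticSpec) -> Taxonomy:
    """Grow a rooted DAG of disease-like concepts per the spec.

    Active concepts form the hierarchy (levels filled with ``branching``
    children per node up to ``max_depth``); a ``deprecated_prob`` fraction of
    concepts are deprecated renames whose ``replaced_by`` chain ends in an
    active concept. All normalized surfaces are unique across concepts.
    Raises if ``n_concepts`` cannot fit within ``max_depth`` at the given
    branching.
    """
    rng = random.Random(spec.seed * 2)
    n_dep = int(round(spec.deprecated_prob * spec.n_concepts))
    n_act = spec.n_concepts - n_dep
    if n_act < 1:
        raise ValueError("spec leaves no active concepts")
    # capacity check: maximal tree size within max_depth
    cap, layer = 1, 1
    for _ in range(spec.max_depth):
        layer *= spec.branching[1]
        cap += layer
    if n_act > cap:
        raise ValueError(
            f"n_concepts={spec.n_concepts} infeasible with branching {spec.branching} "
            f"and max_depth={spec.max_depth}"
        )

    used_surfaces: set[str] = set()
    fuzzy_surfaces: list[str] = []

    def fresh_name() -> str:
        while True:
            name = _disease_name(rng, spec.min_name_chars)
            norm = normalize_text(name)
            if norm in used_surfaces:
                continue
            if any(_surfaces_confusable(norm, s) for s in fuzzy_surfaces):
                continue
            used_surfaces.add(norm)
            fuzzy_surfaces.append(norm)
            return name

    codes = [f"ORPHA:{1000 + i}" for i in range(spec.n_concepts)]
    concepts: dict[str, Concept] = {}
    depth: dict[str, int] = {}

    # --- active hierarchy, level by level -------------------------------
    active = codes[:n_act]
    root = active[0]
    depth[root] = 0
    frontier = [root]
    created = 1
    parents_of: dict[str, list[str]] = {root: []}
    d = 0
    b_lo, b_hi = spec.branching
    while created < n_act:
        if not frontier or d >= spec.max_depth:
            raise ValueError("branching too small to place all concepts within max_depth")
        need = n_act - created
        # capacity of all levels strictly below the one being built, at max branching
        levels_below = spec.max_depth - (d + 1)
        growth = sum(b_hi**i for i in range(1, levels_below + 1))
        if len(frontier) * b_hi * (1 + growth) < need:
            raise ValueError(
                f"n_concepts={spec.n_concepts} infeasible with branching {spec.branching} "
                f"and max_depth={spec.max_depth}"
            )
        counts = [rng.randint(b_lo, b_hi) for _ in frontier]
        # ensure enough children that the remaining levels can absorb the rest
        min_here = -(-need // (1 + growth))  # ceil
        i = 0
        while sum(counts) < min_here:
            counts[i % len(counts)] = min(counts[i % len(counts)] + 1, b_hi)
            i += 1
        next_frontier: list[str] = []
        for parent, n_children in zip(frontier, counts):
            for _ in range(n_children):
                if created >= n_act:
                    break
                child = active[created]
                created += 1
                parents_of[child] = [parent]
                depth[child] = d + 1
                next_frontier.append(child)
        frontier = next_frontier
        d += 1
    # sprinkle second parents to make it a genuine DAG
    for code in active[1:]:
        if depth[code] >= 2 and rng.random() < 0.25:
            shallower = [c for c in active if depth[c] < depth[code] and c not in parents_of[code]]
            if shallower:
                parents_of[code].append(rng.choice(shallower))

    def make_synonyms(name: str) -> list[str]:
        syns = [fresh_name() for _ in range(rng.randint(*spec.synonyms_per_concept))]
        if rng.random() < spec.acronym_prob:
            acro = _acronym(name)
            if len(acro) >= 2 and normalize_text(acro) not in used_surfaces:
                used_surfaces.add(normalize_text(acro))
                syns.append(acro)
        return syns

    for code in active:
        name = fresh_name()
        concepts[code] = Concept(
            code=code,
            preferred_label=name,
            synonyms=tuple(make_synonyms(name)),
            status="active",
            parents=tuple(parents_of[code]),
        )

    # --- deprecated renames ---------------------------------------------
    deprecated_so_far: list[str] = []
    for code in codes[n_act:]:
        if deprecated_so_far and rng.random() < 0.2:
            target = rng.choice(deprecated_so_far)  # chain: deprecated -> deprecated -> active
        else:
            target = rng.choice(active)
        name = fresh_name()
        concepts[code] = Concept(
            code=code,
            preferred_label=name,
            synonyms=tuple(make_synonyms(name)),
            status="deprecated",
            replaced_by=target,
            parents=(),
        )
        deprecated_so_far.append(code)

    return Taxonomy(concepts=concepts, version_tag=f"synthetic-{spec.seed}")


def perturb_term(term: str, n_edits: int, seed: int | random.Random) -> str:
    """Apply exactly ``n_edits`` character edits to ``term``.

    Edits (substitution, insertion, deletion of a letter) never touch token
    boundaries, and the result is resampled until both the raw string and its
    normalized form are at Levenshtein distance exactly ``n_edits`` from the
    input — so injected misspellings have a known, provable similarity.
    """
    if n_edits < 1:
        raise ValueError("n_edits must be >= 1")
    core = term.replace(" ", "")
    if len(core) <= n_edits:
        raise ValueError(f"term {term!r} too short to guarantee edit distance {n_edits}")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    letters = "abcdefghijklmnopqrstuvwxyz"
    norm_term = normalize_text(term)
    for _ in range(200):
        chars = list(term)
        for _ in range(n_edits):
            positions = [i for i, c in enumerate(chars) if c != " "]
            op = rng.choice(("sub", "ins", "del"))
            if op == "sub":
                i = rng.choice(positions)
                chars[i] = rng.choice(letters.replace(chars[i].lower(), "") or letters)
            elif op == "ins":
                i = rng.choice(positions)
                chars.insert(i + 1, rng.choice(letters))
            else:
                # avoid deleting a single-character token (would merge spaces)
                deletable = [
                    i for i in positions
                    if not (
                        (i == 0 or chars[i - 1] == " ")
                        and (i == len(chars) - 1 or chars[i + 1] == " ")
                    )
                ]
                if not deletable:
                    continue
                del chars[rng.choice(deletable)]
        out = "".join(chars)
        if out == term:
            continue
        d_raw = edlib.align(out, term, mode="NW", task="distance")["editDistance"]
        d_norm = edlib.align(normalize_text(out), norm_term, mode="NW", task="distance")[
            "editDistance"
        ]
        if d_raw == n_edits and d_norm == n_edits:
            return out
    raise RuntimeError(f"could not perturb {term!r} to exact distance {n_edits}")


def _distractor_vocab(rng: random.Random, spec: SyntheticSpec, forbidden: set[str]) -> list[str]:
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < spec.distractor_vocab_size:
        w = _word(rng, _DISTRACTOR_CONSONANTS)
        if w in seen or w in forbidden:
            continue
        seen.add(w)
        vocab.append(w)
    return vocab


def generate_corpus(tax: Taxonomy, spec: SyntheticSpec) -> SyntheticBundle:
    """Emit article records with injected mentions and matching gold labels.

    Each document draws its distractor text from the distractor vocabulary,
    then injects 1..k mentions at random non-overlapping token gaps across
    title/abstract/keywords. A mention uses the concept's preferred label or
    a (non-acronym) synonym, misspelled with probability ``typo_prob`` at
    exactly ``typo_edits`` edits. Gold labels are the resolved codes of the
    injected concepts; the injection log reconstructs them exactly.
    """
    rng = random.Random(spec.seed * 2 + 1)
    surface_tokens = {
        t
        for c in tax.concepts.values()
        for s in c.labels()
        for t in normalize_text(s).split()
    }
    vocab = _distractor_vocab(rng, spec, surface_tokens)
    all_codes = sorted(tax.concepts)
    records: list[ArticleRecord] = []
    gold: dict[str, frozenset[str]] = {}
    log: list[InjectionRecord] = []
    lo_m, hi_m = spec.mentions_per_doc

    for di in range(spec.n_docs):
        doc_id = f"DOC{di:05d}"
        total = rng.randint(*spec.tokens_per_doc)
        title_n = max(3, total // 8)
        abstract_n = max(5, total - title_n)
        title_words = [rng.choice(vocab) for _ in range(title_n)]
        abstract_words = [rng.choice(vocab) for _ in range(abstract_n)]
        keywords = [
            " ".join(rng.choice(vocab) for _ in range(rng.randint(1, 3)))
            for _ in range(rng.randint(2, 4))
        ]

        m = rng.randint(lo_m, hi_m)
        if m > len(all_codes):
            raise ValueError("mentions_per_doc exceeds number of concepts")
        chosen = rng.sample(all_codes, m)
        doc_codes: set[str] = set()
        # distinct gap indices per field keep mentions non-overlapping
        free_gaps = {
            "title": list(range(len(title_words) + 1)),
            "abstract": list(range(len(abstract_words) + 1)),
        }
        pending: dict[str, list[tuple[int, str]]] = {"title": [], "abstract": []}
        for code in chosen:
            concept = tax[code]
            plain_syns = [s for s in concept.synonyms if not s.isupper()]
            if plain_syns and rng.random() < spec.synonym_use_prob:
                surface = rng.choice(plain_syns)
            else:
                surface = concept.preferred_label
            perturbed = rng.random() < spec.typo_prob
            edits = 0
            surface_used = surface
            if perturbed:
                surface_used = perturb_term(surface, spec.typo_edits, rng)
                edits = spec.typo_edits
            r = rng.random()
            if r < 0.15 and free_gaps["title"]:
                gap = rng.choice(free_gaps["title"])
                # mentions stay separated by at least one distractor token
                free_gaps["title"] = [g for g in free_gaps["title"] if abs(g - gap) > 1]
                pending["title"].append((gap, surface_used))
            elif r < 0.85 and free_gaps["abstract"]:
                gap = rng.choice(free_gaps["abstract"])
                free_gaps["abstract"] = [g for g in free_gaps["abstract"] if abs(g - gap) > 1]
                pending["abstract"].append((gap, surface_used))
            else:
                keywords.insert(rng.randint(0, len(keywords)), surface_used)
            doc_codes.add(resolve_concept(tax, code))
            log.append(InjectionRecord(doc_id, code, surface_used, perturbed, edits))
        for fname, words in (("title", title_words), ("abstract", abstract_words)):
            for gap, surface_used in sorted(pending[fname], reverse=True):
                words.insert(gap, surface_used)

        metadata = {
            "year": rng.randint(2012, 2022),
            "countries": sorted(rng.sample(_COUNTRIES, rng.randint(1, 3))),
            "subject_areas": sorted(rng.sample(_SUBJECT_AREAS, rng.randint(1, 2))),
        }
        records.append(
            ArticleRecord(
                doc_id=doc_id,
                title=" ".join(title_words),
                abstract=" ".join(abstract_words),
                keywords=tuple(keywords),
                metadata=metadata,
            )
        )
        gold[doc_id] = frozenset(doc_codes)

    return SyntheticBundle(
        taxonomy=tax,
        corpus=tuple(records),
        gold=GoldSet(labels=gold, provenance=f"synthetic seed={spec.seed}"),
        injection_log=tuple(log),
        spec=spec,
    )


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Taxonomy plus corpus plus gold, all from one spec."""
    return generate_corpus(generate_taxonomy(spec), spec)
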