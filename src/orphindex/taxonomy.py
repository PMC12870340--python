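"""Rare-disease taxonomy: loading, validation, and hierarchy queries.

The taxonomy is a set of disease concepts (ORPHAcode-like identifiers with a
preferred label and synonyms) organised as a rooted DAG whose top-level nodes
are generic disease groups and whose leaves are the most specific diseases.
Concepts may be deprecated, in which case they carry a ``replaced_by`` link to
their successor; chains of such links are followed when normalising labels
(e.g. a record annotated with a retired "beta thalassemia major" code resolves
to the current "beta-thalassemia" concept).

The interchange format is a versioned JSON document::

    {"version": "...",
     "concepts": [{"code": str, "preferred_label": str, "synonyms": [str],
                   "status": "active"|"deprecated", "replaced_by": str|null,
                   "parents": [str]}, ...]}
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Concept",
    "Taxonomy",
    "TaxonomyError",
    "TaxonomyParseError",
    "TaxonomyValidationError",
    "UnknownConceptError",
    "UnresolvableConceptError",
    "load_taxonomy",
    "resolve_concept",
    "ancestors_within",
    "ancestors_with_distance",
    "coverage",
]

ACTIVE = "active"
DEPRECATED = "deprecated"

_CONCEPT_KEYS = {"code", "preferred_label", "synonyms", "status", "replaced_by", "parents"}


class TaxonomyError(ValueError):
    """Base class for taxonomy loading/validation failures."""


class TaxonomyParseError(TaxonomyError):
    """The input document does not conform to the taxonomy JSON schema."""


class TaxonomyValidationError(TaxonomyError):
    """The document parsed but violates a structural invariant (cycle, dangling ref)."""


class UnknownConceptError(TaxonomyError):
    """A concept code was requested that does not exist in the taxonomy."""


class UnresolvableConceptError(TaxonomyError):
    """A deprecated concept has no (transitive) active replacement."""

    def __init__(self, code: str):
        super().__init__(f"deprecated concept {code!r} has no active replacement")
        self.code = code


@dataclass(frozen=True)
class Concept:
    """A single disease concept.

    ``parents`` point toward more generic diseases; a deprecated concept may
    name its successor in ``replaced_by``.
    """

    code: str
    preferred_label: str
    synonyms: tuple[str, ...] = ()
    status: str = ACTIVE
    replaced_by: str | None = None
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in (ACTIVE, DEPRECATED):
            raise TaxonomyParseError(
                f"concept {self.code!r}: status must be 'active' or 'deprecated', "
                f"got {self.status!r}"
            )
        if self.code in self.parents:
            raise TaxonomyValidationError(f"concept {self.code!r} lists itself as parent")

    @property
    def is_active(self) -> bool:
        return self.status == ACTIVE

    def labels(self) -> tuple[str, ...]:
        """Preferred label followed by synonyms."""
        return (self.preferred_label, *self.synonyms)


@dataclass
class Taxonomy:
    """A validated concept collection with an acyclic parent graph."""

    concepts: dict[str, Concept]
    version_tag: str = ""
    _children: dict[str, tuple[str, ...]] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.validate()
        kids: dict[str, list[str]] = {c: [] for c in self.concepts}
        for concept in self.concepts.values():
            for p in concept.parents:
                kids[p].append(concept.code)
        self._children = {c: tuple(v) for c, v in kids.items()}

    # -- container protocol ------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def __getitem__(self, code: str) -> Concept:
        try:
            return self.concepts[code]
        except KeyError:
            raise UnknownConceptError(f"unknown concept code {code!r}") from None

    def active_codes(self) -> list[str]:
        return sorted(c.code for c in self.concepts.values() if c.is_active)

    def children(self, code: str) -> tuple[str, ...]:
        self[code]
        return self._children[code]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check referential integrity and acyclicity; raise on violation."""
        for concept in self.concepts.values():
            for p in concept.parents:
                if p not in self.concepts:
                    raise TaxonomyValidationError(
                        f"concept {concept.code!r} references unknown parent {p!r}"
                    )
            rb = concept.replaced_by
            if rb is not None and rb not in self.concepts:
                raise TaxonomyValidationError(
                    f"concept {concept.code!r} references unknown replacement {rb!r}"
                )
        cycle = _find_cycle({c.code: c.parents for c in self.concepts.values()})
        if cycle:
            raise TaxonomyValidationError(
                "cycle in parent graph: " + " -> ".join(cycle)
            )
        redirects = {
            c.code: (c.replaced_by,) if c.replaced_by else ()
            for c in self.concepts.values()
        }
        cycle = _find_cycle(redirects)
        if cycle:
            raise TaxonomyValidationError(
                "cycle in replaced_by chain: " + " -> ".join(cycle)
            )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version_tag,
            "concepts": [
                {
                    "code": c.code,
                    "preferred_label": c.preferred_label,
                    "synonyms": list(c.synonyms),
                    "status": c.status,
                    "replaced_by": c.replaced_by,
                    "parents": list(c.parents),
                }
                for c in sorted(self.concepts.values(), key=lambda c: c.code)
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )


def _find_cycle(edges: Mapping[str, Iterable[str]]) -> list[str] | None:
    """Return one cycle as a node list (closed walk) or None. Iterative DFS."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {n: WHITE for n in edges}
    parent: dict[str, str | None] = {}
    for start in edges:
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(edges[start]))]
        colour[start] = GREY
        parent[start] = None
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == GREY:
                    # unwind the grey path to report the cycle
                    cycle = [nxt, node]
                    cur = parent[node]
                    while cur is not None and cur != nxt:
                        cycle.append(cur)
                        cur = parent[cur]
                    cycle.reverse()
                    return cycle
                if colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    parent[nxt] = node
                    stack.append((nxt, iter(edges[nxt])))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()
    return None


def _parse_concept(obj: dict, strict: bool) -> Concept:
    if not isinstance(obj, dict):
        raise TaxonomyParseError(f"concept entry is not an object: {obj!r}")
    code = obj.get("code")
    if not isinstance(code, str) or not code:
        raise TaxonomyParseError(f"concept with missing or non-string code: {obj!r}")
    if strict:
        extra = set(obj) - _CONCEPT_KEYS
        if extra:
            raise TaxonomyParseError(
                f"concept {code!r}: unknown keys {sorted(extra)} (strict mode)"
            )
    label = obj.get("preferred_label")
    if not isinstance(label, str) or not label:
        raise TaxonomyParseError(f"concept {code!r}: missing preferred_label")
    synonyms = obj.get("synonyms", [])
    parents = obj.get("parents", [])
    if not isinstance(synonyms, list) or not all(isinstance(s, str) for s in synonyms):
        raise TaxonomyParseError(f"concept {code!r}: synonyms must be a list of strings")
    if not isinstance(parents, list) or not all(isinstance(p, str) for p in parents):
        raise TaxonomyParseError(f"concept {code!r}: parents must be a list of strings")
    status = obj.get("status", ACTIVE)
    replaced_by = obj.get("replaced_by")
    if replaced_by is not None and not isinstance(replaced_by, str):
        raise TaxonomyParseError(f"concept {code!r}: replaced_by must be a string or null")
    try:
        return Concept(
            code=code,
            preferred_label=label,
            synonyms=tuple(synonyms),
            status=status,
            replaced_by=replaced_by,
            parents=tuple(parents),
        )
    except TaxonomyError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise TaxonomyParseError(f"concept {code!r}: {exc}") from exc


def load_taxonomy(path: str | Path, format: str = "json", strict: bool = False) -> Taxonomy:
    """Load and validate a taxonomy from its JSON interchange format.

    Parameters
    ----------
    path
        File to read (UTF-8).
    format
        Only ``"json"`` is supported.
    strict
        Reject unknown keys in concept objects.
    """
    if format != "json":
        raise ValueError(f"unsupported taxonomy format: {format!r}")
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise TaxonomyParseError(f"invalid JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict) or "concepts" not in doc:
        raise TaxonomyParseError("top-level object must contain a 'concepts' list")
    raw = doc["concepts"]
    if not isinstance(raw, list):
        raise TaxonomyParseError("'concepts' must be a list")
    concepts: dict[str, Concept] = {}
    for obj in raw:
        concept = _parse_concept(obj, strict)
        if concept.code in concepts:
            raise TaxonomyParseError(f"duplicate concept code {concept.code!r}")
        concepts[concept.code] = concept
    version = doc.get("version", "")
    if not isinstance(version, str):
        raise TaxonomyParseError("'version' must be a string")
    return Taxonomy(concepts=concepts, version_tag=version)


def resolve_concept(tax: Taxonomy, code: str) -> str:
    """Follow ``replaced_by`` links until an active concept is reached.

    Active codes resolve to themselves. A deprecated concept whose replacement
    chain ends in another deprecated concept with no successor raises
    :class:`UnresolvableConceptError` carrying the terminal deprecated code.
    """
    concept = tax[code]
    seen = {code}
    while not concept.is_active:
        if concept.replaced_by is None:
            raise UnresolvableConceptError(concept.code)
        nxt = concept.replaced_by
        if nxt in seen:  # guarded at validation time; defensive here
            raise TaxonomyValidationError(f"replaced_by cycle at {nxt!r}")
        seen.add(nxt)
        concept = tax[nxt]
    return concept.code


def ancestors_with_distance(tax: Taxonomy, code: str, max_dist: int) -> dict[str, int]:
    """Map each ancestor within ``max_dist`` parent edges to its BFS distance."""
    tax[code]
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    dist: dict[str, int] = {}
    queue: deque[tuple[str, int]] = deque([(code, 0)])
    while queue:
        cur, d = queue.popleft()
        if d == max_dist:
            continue
        for p in tax[cur].parents:
            if p not in dist and p != code:
                dist[p] = d + 1
                queue.append((p, d + 1))
    return dist


def ancestors_within(tax: Taxonomy, code: str, max_dist: int) -> set[str]:
    """All codes reachable by 1..max_dist parent edges (shortest-path distance).

    Excludes ``code`` itself; multiple parent paths are deduplicated.
    """
    return set(ancestors_with_distance(tax, code, max_dist))


def coverage(tax: Taxonomy, other_vocabulary: set[str]) -> float:
    """Fraction of active concepts present in another (pre-mapped) vocabulary.

    ``other_vocabulary`` holds identifiers already mapped into this taxonomy's
    code space; constructing such mappings is out of scope here.
    """
    active = tax.active_codes()
    if not active:
        raise TaxonomyError("coverage undefined for a taxonomy with no active concepts")
    hit = sum(1 for c in active if c in other_vocabulary)
    return hit / len(active)
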