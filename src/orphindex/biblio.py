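"""Bibliometric aggregation of annotations with article metadata.

Implements full counting: every (publication, key) incidence contributes one
count, so a paper co-authored from two countries counts once for each, and a
paper assigned three diseases counts once for each disease. The distinction
between the number of unique annotated publications and the total number of
disease matches is tracked explicitly, as the two tell different stories at
corpus scale.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotate import ArticleRecord, DocAnnotation

__all__ = ["CountTable", "aggregate", "top_n"]

logger = logging.getLogger(__name__)

DIMENSIONS = ("concept", "country", "subject_area")
_METADATA_FIELD = {"country": "countries", "subject_area": "subject_areas"}


@dataclass(frozen=True)
class CountTable:
    """Publication counts per key along one dimension, full counting."""

    dimension: str
    rows: tuple[tuple[str, int], ...]  # sorted by count desc, then key
    n_unique_publications: int
    n_total_matches: int
    counting: str = "full"
    include_propagated: bool | None = None

    def as_dict(self) -> dict[str, int]:
        return dict(self.rows)


def _doc_concepts(ann: DocAnnotation, include_propagated: bool) -> frozenset[str]:
    if include_propagated:
        return ann.final_concepts
    return ann.direct_concepts


def aggregate(
    annotations: Iterable[DocAnnotation],
    corpus: Sequence[ArticleRecord],
    dimension: str,
    include_propagated: bool = True,
) -> CountTable:
    """Count annotated publications per concept, country or subject area.

    Documents with no final concepts are excluded. For the metadata
    dimensions, a document lacking the needed metadata field is skipped for
    that dimension (with a warning). ``n_total_matches`` is the summed number
    of (publication, concept) assignments over all counted publications.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    by_id = {rec.doc_id: rec for rec in corpus}
    counts: Counter[str] = Counter()
    n_unique = 0
    n_matches = 0
    for ann in annotations:
        concepts = _doc_concepts(ann, include_propagated)
        if not concepts:
            continue
        rec = by_id.get(ann.doc_id)
        if rec is None:
            raise KeyError(f"annotation for unknown document {ann.doc_id!r}")
        n_unique += 1
        n_matches += len(concepts)
        if dimension == "concept":
            keys: Iterable[str] = concepts
        else:
            meta = rec.metadata or {}
            values = meta.get(_METADATA_FIELD[dimension])
            if not values:
                logger.warning(
                    "document %s lacks metadata %r; skipped for dimension %s",
                    ann.doc_id,
                    _METADATA_FIELD[dimension],
                    dimension,
                )
                continue
            keys = set(values)
        for key in keys:
            counts[key] += 1
    rows = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return CountTable(
        dimension=dimension,
        rows=rows,
        n_unique_publications=n_unique,
        n_total_matches=n_matches,
        include_propagated=include_propagated,
    )


def top_n(table: CountTable, n: int, exclude: set[str] = frozenset()) -> CountTable:
    """Top ``n`` keys by count, descending, ties broken lexicographically.

    Excluded keys (e.g. a dominant catch-all subject area) are removed
    before truncation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows = tuple(
        sorted(
            (kv for kv in table.rows if kv[0] not in exclude),
            key=lambda kv: (-kv[1], kv[0]),
        )[:n]
    )
    return CountTable(
        dimension=table.dimension,
        rows=rows,
        n_unique_publications=table.n_unique_publications,
        n_total_matches=table.n_total_matches,
        counting=table.counting,
        include_propagated=table.include_propagated,
    )
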