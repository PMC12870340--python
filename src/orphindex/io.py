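"""Reading and writing the package's plain-text interchange formats.

Corpora are JSONL (one article record per line, UTF-8); annotations are
JSONL plus an optional flat TSV for downstream counting; gold labels are TSV
(doc_id, code) or JSONL {"doc_id": ..., "codes": [...]}; the compiled
dictionary exports to TSV for auditing and diffing across taxonomy versions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotate import ArticleRecord, DocAnnotation, Mention
from .dictionary import CompiledDictionary, TermEntry
from .evaluate import GoldSet
from .synthetic import InjectionRecord

__all__ = [
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "write_annotations_jsonl",
    "read_annotations_jsonl",
    "write_annotations_tsv",
    "read_predictions",
    "read_gold",
    "write_gold_tsv",
    "write_dictionary_tsv",
    "read_dictionary_tsv",
    "write_injection_log_tsv",
]


# -- corpus ----------------------------------------------------------------

def read_corpus_jsonl(path: str | Path) -> list[ArticleRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{ln}: invalid JSON: {exc}") from exc
            if "id" in obj and "doc_id" not in obj:
                obj["doc_id"] = obj.pop("id")
            records.append(
                ArticleRecord(
                    doc_id=obj["doc_id"],
                    title=obj.get("title", ""),
                    abstract=obj.get("abstract", ""),
                    keywords=tuple(obj.get("keywords", [])),
                    metadata=obj.get("metadata"),
                )
            )
    return records


def write_corpus_jsonl(records: Iterable[ArticleRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "doc_id": rec.doc_id,
                "title": rec.title,
                "abstract": rec.abstract,
                "keywords": list(rec.keywords),
            }
            if rec.metadata is not None:
                obj["metadata"] = rec.metadata
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# -- annotations -----------------------------------------------------------

def _annotation_to_obj(ann: DocAnnotation) -> dict:
    prop_by_code: dict[str, tuple[str, int]] = {}
    for code, source, dist in ann.propagated_concepts:
        prev = prop_by_code.get(code)
        if prev is None or dist < prev[1]:
            prop_by_code[code] = (source, dist)
    final = []
    for code in sorted(ann.final_concepts):
        if code in ann.direct_concepts:
            final.append({"code": code, "origin": "direct", "source": None, "distance": 0})
        else:
            source, dist = prop_by_code[code]
            final.append(
                {"code": code, "origin": "propagated", "source": source, "distance": dist}
            )
    return {
        "doc_id": ann.doc_id,
        "mentions": [
            {
                "code": m.concept_code,
                "start": m.start,
                "end": m.end,
                "surface": m.surface,
                "matched_term": m.matched_term,
                "match_type": m.match_type,
                "score": m.score,
                "flags": list(m.flags),
            }
            for m in ann.mentions
        ],
        "final_concepts": final,
    }


def write_annotations_jsonl(annotations: Iterable[DocAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write(json.dumps(_annotation_to_obj(ann), ensure_ascii=False) + "\n")


def read_annotations_jsonl(path: str | Path) -> list[DocAnnotation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            mentions = tuple(
                Mention(
                    concept_code=m["code"],
                    start=m["start"],
                    end=m["end"],
                    surface=m["surface"],
                    matched_term=m["matched_term"],
                    match_type=m["match_type"],
                    score=m["score"],
                    flags=tuple(m.get("flags", [])),
                )
                for m in obj["mentions"]
            )
            direct = frozenset(
                f["code"] for f in obj["final_concepts"] if f["origin"] == "direct"
            )
            propagated = tuple(
                sorted(
                    (f["code"], f["source"], f["distance"])
                    for f in obj["final_concepts"]
                    if f["origin"] == "propagated"
                )
            )
            out.append(
                DocAnnotation(
                    doc_id=obj["doc_id"],
                    mentions=mentions,
                    direct_concepts=direct,
                    propagated_concepts=propagated,
                    final_concepts=frozenset(f["code"] for f in obj["final_concepts"]),
                )
            )
    return out


def write_annotations_tsv(annotations: Iterable[DocAnnotation], path: str | Path) -> None:
    """Flat (doc_id, code, origin) table for downstream counting."""
    rows = []
    for ann in annotations:
        for code in sorted(ann.final_concepts):
            origin = "direct" if code in ann.direct_concepts else "propagated"
            rows.append((ann.doc_id, code, origin))
    pd.DataFrame(rows, columns=["doc_id", "code", "origin"]).to_csv(
        path, sep="\t", index=False
    )


def read_predictions(path: str | Path) -> dict[str, set[str]]:
    """Read a predictions file (annotations JSONL or flat TSV) as doc -> codes."""
    path = Path(path)
    preds: dict[str, set[str]] = {}
    if path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for doc_id, code in zip(df["doc_id"], df["code"]):
            preds.setdefault(doc_id, set()).add(code)
    else:
        for ann in read_annotations_jsonl(path):
            preds[ann.doc_id] = set(ann.final_concepts)
    return preds


# -- gold ------------------------------------------------------------------

def read_gold(path: str | Path, provenance: str | None = None) -> GoldSet:
    path = Path(path)
    labels: dict[str, set[str]] = {}
    if path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for doc_id, code in zip(df["doc_id"], df["code"]):
            labels.setdefault(doc_id, set()).add(code)
    else:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                labels.setdefault(obj["doc_id"], set()).update(obj["codes"])
    return GoldSet(
        labels={k: frozenset(v) for k, v in labels.items()},
        provenance=provenance or str(path),
    )


def write_gold_tsv(gold: GoldSet, path: str | Path) -> None:
    rows = [
        (doc_id, code)
        for doc_id in sorted(gold.labels)
        for code in sorted(gold.labels[doc_id])
    ]
    pd.DataFrame(rows, columns=["doc_id", "code"]).to_csv(path, sep="\t", index=False)


# -- dictionary ------------------------------------------------------------

def write_dictionary_tsv(dictionary: CompiledDictionary, path: str | Path) -> None:
    pd.DataFrame(
        [
            (e.surface_normalized, e.concept_code, e.source, e.original_surface)
            for e in dictionary.entries
        ],
        columns=["surface_normalized", "concept_code", "source", "original_surface"],
    ).to_csv(path, sep="\t", index=False)


def read_dictionary_tsv(path: str | Path) -> list[TermEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        TermEntry(
            surface_normalized=r.surface_normalized,
            token_count=r.surface_normalized.count(" ") + 1,
            concept_code=r.concept_code,
            source=r.source,
            original_surface=r.original_surface,
        )
        for r in df.itertuples()
    ]


# -- synthetic -------------------------------------------------------------

def write_injection_log_tsv(log: Iterable[InjectionRecord], path: str | Path) -> None:
    pd.DataFrame(
        list(log),
        columns=["doc_id", "concept_code", "surface_used", "perturbed", "edit_count"],
    ).to_csv(path, sep="\t", index=False)
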