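"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain dynamic-programming edit
distance, exhaustive window scans, and BFS via networkx. None of it shares
code with the package's matching path.
"""

from __future__ import annotations

import networkx as nx


def levenshtein(a: str, b: str) -> int:
    """Classic two-row DP edit distance."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def similarity(a: str, b: str) -> float:
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def brute_exact_spans(field_runs, entries):
    """All (start, end, concept, surface) exact hits, longest-span filtered.

    ``field_runs``: per-field lists of (text, start, end) tokens.
    ``entries``: iterable of (normalized surface, concept code).
    """
    hits = set()
    for run in field_runs:
        texts = [t[0] for t in run]
        for surface, code in entries:
            seq = surface.split()
            for i in range(len(texts) - len(seq) + 1):
                if texts[i : i + len(seq)] == seq:
                    hits.add((run[i][1], run[i + len(seq) - 1][2], code, surface))
    spans = {(s, e) for s, e, _, _ in hits}
    return {
        h
        for h in hits
        if not any(
            s <= h[0] and h[1] <= e and (s, e) != (h[0], h[1]) for s, e in spans
        )
    }


def brute_fuzzy_spans(field_runs, terms, threshold):
    """All fuzzy (start, end, concept, surface, score) hits by exhaustive scan.

    ``terms``: iterable of (normalized surface, token_count, codes).
    Windows of width k-1..k+1 per term; distance-0 windows are excluded
    (they belong to the exact matcher).
    """
    hits = set()
    for run in field_runs:
        texts = [t[0] for t in run]
        n = len(texts)
        for surface, k, codes in terms:
            for w in (k - 1, k, k + 1):
                if w < 1 or w > n:
                    continue
                for i in range(n - w + 1):
                    window = " ".join(texts[i : i + w])
                    d = levenshtein(window, surface)
                    if d == 0:
                        continue
                    score = 1.0 - d / max(len(window), len(surface))
                    if score >= threshold:
                        for code in codes:
                            hits.add((run[i][1], run[i + w - 1][2], code, surface, round(score, 12)))
    return hits


def bfs_ancestors(parent_edges: dict[str, tuple[str, ...]], code: str, max_dist: int):
    """Ancestors within max_dist via networkx shortest paths."""
    g = nx.DiGraph()
    g.add_nodes_from(parent_edges)
    for child, parents in parent_edges.items():
        for p in parents:
            g.add_edge(child, p)
    lengths = nx.single_source_shortest_path_length(g, code, cutoff=max_dist)
    return {n for n, d in lengths.items() if 1 <= d <= max_dist}
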