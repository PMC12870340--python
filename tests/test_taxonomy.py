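"""Taxonomy loading, validation, resolution, ancestry and coverage."""

from __future__ import annotations

import random

import pytest

from orphindex import ancestors_within, coverage, load_taxonomy, resolve_concept
from orphindex.taxonomy import (
    Concept,
    Taxonomy,
    TaxonomyParseError,
    TaxonomyValidationError,
    UnknownConceptError,
    UnresolvableConceptError,
)

from _oracles import bfs_ancestors
from conftest import make_taxonomy, write_taxonomy_json


def concept_obj(code, label=None, **kw):
    return {
        "code": code,
        "preferred_label": label or f"{code} disorder",
        "synonyms": kw.pop("synonyms", []),
        "status": kw.pop("status", "active"),
        "replaced_by": kw.pop("replaced_by", None),
        "parents": kw.pop("parents", []),
    }


class TestLoadTaxonomy:
    def test_minimal_wellformed_file(self, tmp_path):
        path = write_taxonomy_json(
            tmp_path / "t.json",
            [
                concept_obj("A"),
                concept_obj("B", parents=["A"]),
                concept_obj("C", status="deprecated", replaced_by="B"),
            ],
        )
        tax = load_taxonomy(path)
        assert len(tax) == 3
        assert tax["B"].parents == ("A",)
        assert tax["C"].replaced_by == "B"
        assert tax.active_codes() == ["A", "B"]

    def test_parent_cycle_rejected(self, tmp_path):
        path = write_taxonomy_json(
            tmp_path / "t.json",
            [concept_obj("A", parents=["B"]), concept_obj("B", parents=["A"])],
        )
        with pytest.raises(TaxonomyValidationError, match="cycle"):
            load_taxonomy(path)

    def test_dangling_replacement_rejected(self, tmp_path):
        path = write_taxonomy_json(
            tmp_path / "t.json",
            [concept_obj("C", status="deprecated", replaced_by="Z")],
        )
        with pytest.raises(TaxonomyValidationError, match="Z"):
            load_taxonomy(path)

    def test_schema_violation_names_concept(self, tmp_path):
        path = write_taxonomy_json(
            tmp_path / "t.json", [{"code": "A", "synonyms": []}]
        )
        with pytest.raises(TaxonomyParseError, match="'A'"):
            load_taxonomy(path)

    def test_strict_mode_rejects_unknown_keys(self, tmp_path):
        obj = concept_obj("A")
        obj["surprise"] = 1
        path = write_taxonomy_json(tmp_path / "t.json", [obj])
        load_taxonomy(path)  # lenient by default
        with pytest.raises(TaxonomyParseError, match="surprise"):
            load_taxonomy(path, strict=True)

    def test_self_parent_rejected(self, tmp_path):
        path = write_taxonomy_json(tmp_path / "t.json", [concept_obj("A", parents=["A"])])
        with pytest.raises(TaxonomyValidationError, match="itself"):
            load_taxonomy(path)

    def test_roundtrip_save_load(self, tmp_path, chain_taxonomy):
        chain_taxonomy.save(tmp_path / "out.json")
        again = load_taxonomy(tmp_path / "out.json", strict=True)
        assert again.to_dict() == chain_taxonomy.to_dict()


class TestResolveConcept:
    def test_active_is_identity(self, chain_taxonomy):
        assert resolve_concept(chain_taxonomy, "L") == "L"

    def test_one_hop_redirect(self, chain_taxonomy):
        assert resolve_concept(chain_taxonomy, "L-old") == "L"

    def test_transitive_chain(self):
        tax = make_taxonomy(
            Concept("B", "current name"),
            Concept("C", "old name", status="deprecated", replaced_by="B"),
            Concept("D", "older name", status="deprecated", replaced_by="C"),
        )
        # oracle: follow the chain by hand -> D -> C -> B
        assert resolve_concept(tax, "D") == "B"

    def test_unknown_code_raises(self, chain_taxonomy):
        with pytest.raises(UnknownConceptError):
            resolve_concept(chain_taxonomy, "nope")

    def test_terminal_deprecated_signals_code(self):
        tax = make_taxonomy(
            Concept("A", "live"),
            Concept("X", "dead end", status="deprecated", replaced_by=None),
        )
        with pytest.raises(UnresolvableConceptError) as err:
            resolve_concept(tax, "X")
        assert err.value.code == "X"

    def test_idempotent(self, chain_taxonomy):
        for code in chain_taxonomy.concepts:
            r = resolve_concept(chain_taxonomy, code)
            assert resolve_concept(chain_taxonomy, r) == r


class TestAncestors:
    def test_linear_chain(self, chain_taxonomy):
        assert ancestors_within(chain_taxonomy, "L", 2) == {"P", "G"}

    def test_root_has_none(self, chain_taxonomy):
        assert ancestors_within(chain_taxonomy, "R", 5) == set()

    def test_diamond_dedup(self, diamond_taxonomy):
        assert ancestors_within(diamond_taxonomy, "L", 2) == {"P1", "P2", "G"}

    def test_unknown_code(self, chain_taxonomy):
        with pytest.raises(UnknownConceptError):
            ancestors_within(chain_taxonomy, "zz", 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle_on_random_dags(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 100)
        codes = [f"N{i}" for i in range(n)]
        concepts = [Concept(codes[0], "root node")]
        for i in range(1, n):
            k = rng.randint(1, min(3, i))
            parents = tuple(rng.sample(codes[:i], k))
            concepts.append(Concept(codes[i], f"node {i}", parents=parents))
        tax = make_taxonomy(*concepts)
        edges = {c.code: c.parents for c in concepts}
        for code in rng.sample(codes, min(20, n)):
            for md in (1, 2, 3):
                assert ancestors_within(tax, code, md) == bfs_ancestors(edges, code, md)

    def test_monotone_in_distance(self, diamond_taxonomy, chain_taxonomy):
        for tax in (diamond_taxonomy, chain_taxonomy):
            for code in tax.concepts:
                for k in (1, 2, 3):
                    assert ancestors_within(tax, code, k) <= ancestors_within(tax, code, k + 1)


class TestCoverage:
    def test_direct_ratio(self):
        tax = make_taxonomy(*(Concept(c, f"{c} disorder") for c in "ABCD"))
        assert coverage(tax, {"A", "C"}) == 0.5

    def test_disjoint_and_superset(self):
        tax = make_taxonomy(*(Concept(c, f"{c} disorder") for c in "AB"))
        assert coverage(tax, {"X"}) == 0.0
        assert coverage(tax, {"A", "B", "X"}) == 1.0

    def test_deprecated_excluded_from_denominator(self):
        tax = make_taxonomy(
            Concept("A", "live"),
            Concept("B", "gone", status="deprecated", replaced_by="A"),
        )
        assert coverage(tax, {"A"}) == 1.0

    def test_monotone_under_inclusion(self):
        tax = make_taxonomy(*(Concept(f"C{i}", f"dis {i}") for i in range(6)))
        vocab: set[str] = set()
        prev = coverage(tax, vocab)
        for i in range(6):
            vocab.add(f"C{i}")
            cur = coverage(tax, vocab)
            assert cur >= prev
            prev = cur

    def test_empty_taxonomy_errors(self):
        tax = make_taxonomy(
            Concept("X", "dead", status="deprecated", replaced_by=None)
        )
        with pytest.raises(Exception):
            coverage(tax, {"X"})
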