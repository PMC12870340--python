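"""Document preparation, exact/fuzzy matching, combination and propagation."""

from __future__ import annotations

import random

import pytest

from orphindex import (
    AnnotatorConfig,
    ArticleRecord,
    annotate_document,
    build_dictionary,
    combine_mentions,
    exact_match,
    fuzzy_match,
    prepare_document,
    propagate_concepts,
)
from orphindex.annotate import Mention
from orphindex.dictionary import NormalizationPolicy
from orphindex.taxonomy import Concept

from _oracles import brute_exact_spans, brute_fuzzy_spans, levenshtein, similarity
from conftest import make_taxonomy

POLICY = NormalizationPolicy()


def runs_of(doc):
    return [
        [(t.text, t.start, t.end) for t in run] for run in doc.field_token_runs()
    ]


class TestPrepareDocument:
    def test_sep_concatenation(self):
        rec = ArticleRecord("d1", title="T", abstract="A", keywords=("k1", "k2"))
        doc = prepare_document(rec)
        assert doc.full_text == "T [SEP] A [SEP] k1; k2"
        assert len(doc.field_boundaries) == 3
        names = [b[0] for b in doc.field_boundaries]
        assert names == ["title", "abstract", "keywords"]

    def test_keywords_only_degenerate_fields(self):
        rec = ArticleRecord("d1", keywords=("k1",))
        doc = prepare_document(rec)
        assert doc.full_text == " [SEP]  [SEP] k1"
        title_span = doc.field_boundaries[0]
        assert title_span[1] == title_span[2] == 0

    def test_literal_sep_in_title_neutralized(self):
        rec = ArticleRecord("d1", title="before [SEP] after", abstract="A")
        doc = prepare_document(rec)
        # exactly two real separators remain
        assert doc.full_text.count(" [SEP] ") == 2

    def test_all_fields_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            prepare_document(ArticleRecord("d1"))

    def test_no_token_crosses_a_field_boundary(self):
        rec = ArticleRecord("d1", title="gaucher", abstract="disease", keywords=("x",))
        doc = prepare_document(rec)
        for tok, fi in zip(doc.tokens, doc.token_fields):
            _, lo, hi = doc.field_boundaries[fi]
            assert lo <= tok.start and tok.end <= hi

    def test_offsets_index_full_text(self):
        rec = ArticleRecord("d1", title="Gaucher disease", abstract="β-thalassemia")
        doc = prepare_document(rec)
        surfaces = [doc.full_text[t.start : t.end] for t in doc.tokens]
        assert surfaces[0] == "Gaucher"
        assert "β" in surfaces[2]


class TestExactMatch:
    def test_single_hit(self, disease_taxonomy, disease_dictionary):
        rec = ArticleRecord("d", abstract="A report on Gaucher disease in adults.")
        doc = prepare_document(rec)
        ms = exact_match(doc, disease_dictionary)
        assert [(m.concept_code, m.match_type, m.score) for m in ms] == [
            ("C-GAUCHER", "exact", 1.0)
        ]
        assert doc.full_text[ms[0].start : ms[0].end] == "Gaucher disease"

    def test_longest_match_wins_and_outside_occurrence_kept(self, disease_dictionary):
        rec = ArticleRecord(
            "d", abstract="hodgkin lymphoma differs from other lymphoma cases"
        )
        ms = exact_match(prepare_document(rec), disease_dictionary)
        codes = [(m.concept_code, m.surface) for m in ms]
        assert ("C-HODG", "hodgkin lymphoma") in codes
        # bare "lymphoma" only matched outside the hodgkin span
        lymph = [m for m in ms if m.concept_code == "C-LYMPH"]
        assert len(lymph) == 1 and lymph[0].surface == "lymphoma"

    def test_word_boundary_anchoring(self, disease_dictionary):
        # "lymphomas" must not match "lymphoma"
        ms = exact_match(
            prepare_document(ArticleRecord("d", abstract="many lymphomas observed")),
            disease_dictionary,
        )
        assert ms == []

    def test_deprecated_surface_maps_to_replacement(self, disease_dictionary):
        ms = exact_match(
            prepare_document(ArticleRecord("d", abstract="β thalassemia major cohort")),
            disease_dictionary,
        )
        assert {m.concept_code for m in ms} == {"C-THAL"}

    def test_empty_document_empty_result(self, disease_dictionary):
        doc = prepare_document(ArticleRecord("d", title="unrelated words only"))
        assert exact_match(doc, disease_dictionary) == []

    def test_ambiguous_surface_yields_all_concepts(self):
        tax = make_taxonomy(
            Concept("C1", "glycogenosis type 2", synonyms=("pompe disease",)),
            Concept("C2", "acid maltase deficiency", synonyms=("pompe disease",)),
        )
        d = build_dictionary(tax)
        ms = exact_match(
            prepare_document(ArticleRecord("x", abstract="pompe disease study")), d
        )
        assert {m.concept_code for m in ms} == {"C1", "C2"}

    def test_policy_mismatch_rejected(self, disease_dictionary):
        doc = prepare_document(
            ArticleRecord("d", abstract="x"), NormalizationPolicy(lowercase=False)
        )
        with pytest.raises(ValueError, match="policy"):
            exact_match(doc, disease_dictionary)


class TestFuzzyMatch:
    def test_single_edit_scores_as_stated(self, disease_dictionary):
        # "gauchers disease" vs "gaucher disease": lev 1, maxlen 16 -> 0.9375
        doc = prepare_document(ArticleRecord("d", abstract="gauchers disease found"))
        ms = fuzzy_match(doc, disease_dictionary, 0.8)
        gaucher = [m for m in ms if m.concept_code == "C-GAUCHER"]
        assert len(gaucher) == 1
        assert gaucher[0].score == pytest.approx(1 - 1 / 16)
        assert levenshtein("gauchers disease", "gaucher disease") == 1

    def test_dissimilar_text_no_match(self, disease_dictionary):
        doc = prepare_document(ArticleRecord("d", abstract="heart failure admission"))
        assert fuzzy_match(doc, disease_dictionary, 0.8) == []

    def test_threshold_one_empty_after_exact_precedence(self, disease_dictionary):
        doc = prepare_document(ArticleRecord("d", abstract="gaucher disease found"))
        assert fuzzy_match(doc, disease_dictionary, 1.0) == []

    def test_invalid_threshold(self, disease_dictionary):
        doc = prepare_document(ArticleRecord("d", abstract="x y"))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                fuzzy_match(doc, disease_dictionary, bad)

    def test_short_terms_never_fuzzy(self):
        tax = make_taxonomy(Concept("C1", "angelman syndrome", synonyms=("ASX",)))
        d = build_dictionary(tax, min_term_chars=4)
        doc = prepare_document(ArticleRecord("d", abstract="asy levels measured"))
        assert all(m.matched_term != "asx" for m in fuzzy_match(doc, d, 0.8))

    def test_mention_never_crosses_sep_boundary(self, disease_dictionary):
        # "gaucher" at the end of the title, "disease" opening the abstract
        rec = ArticleRecord("d", title="studies of gaucher", abstract="disease course")
        doc = prepare_document(rec)
        assert exact_match(doc, disease_dictionary) == []
        for m in fuzzy_match(doc, disease_dictionary, 0.8):
            for _, lo, hi in doc.field_boundaries:
                assert not (m.start < lo < m.end or m.start < hi < m.end)


class TestOracleEquivalence:
    """Exact and fuzzy matchers equal exhaustive brute-force scans."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances(self, seed):
        rng = random.Random(seed)
        vocab = ["".join(rng.choices("abcdefgh", k=rng.randint(3, 8))) for _ in range(30)]
        concepts = []
        for i in range(rng.randint(2, 12)):
            words = rng.choices(vocab, k=rng.randint(1, 3))
            concepts.append(Concept(f"C{i}", " ".join(words)))
        tax = make_taxonomy(*concepts)
        d = build_dictionary(tax, min_term_chars=4)
        text_words = rng.choices(vocab, k=rng.randint(5, 60))
        rec = ArticleRecord(
            "d",
            title=" ".join(text_words[:5]),
            abstract=" ".join(text_words[5:]),
        )
        doc = prepare_document(rec)
        runs = runs_of(doc)

        got_exact = {
            (m.start, m.end, m.concept_code, m.matched_term)
            for m in exact_match(doc, d)
        }
        entries = {(e.surface_normalized, e.concept_code) for e in d.entries}
        assert got_exact == brute_exact_spans(runs, entries)

        got_fuzzy = {
            (m.start, m.end, m.concept_code, m.matched_term, round(m.score, 12))
            for m in fuzzy_match(doc, d, 0.8)
        }
        assert got_fuzzy == brute_fuzzy_spans(runs, d.fuzzy_terms(), 0.8)


class TestCombineMentions:
    def m(self, code, start, end, mtype="exact", score=1.0):
        return Mention(code, start, end, "s", "t", mtype, score)

    def test_exact_only_identity(self):
        m1 = self.m("A", 0, 5)
        assert combine_mentions([m1], []) == [m1]

    def test_same_span_same_concept_exact_wins(self):
        e = self.m("A", 0, 5)
        f = self.m("A", 0, 5, "fuzzy", 0.9)
        assert combine_mentions([e], [f]) == [e]

    def test_disjoint_spans_both_kept(self):
        e = self.m("A", 0, 5)
        f = self.m("B", 10, 15, "fuzzy", 0.85)
        assert combine_mentions([e], [f]) == [e, f]

    def test_overlap_disagreeing_concepts_flagged(self):
        e = self.m("A", 0, 8)
        f = self.m("B", 4, 12, "fuzzy", 0.82)
        out = combine_mentions([e], [f])
        assert len(out) == 2
        kept_fuzzy = [m for m in out if m.match_type == "fuzzy"][0]
        assert "overlaps-exact" in kept_fuzzy.flags


class TestPropagation:
    def test_linear_chain_with_provenance(self, chain_taxonomy):
        assert propagate_concepts({"L"}, chain_taxonomy, 2) == {("P", "L", 1), ("G", "L", 2)}

    def test_direct_codes_not_readded(self, chain_taxonomy):
        out = propagate_concepts({"L", "P"}, chain_taxonomy, 2)
        assert all(code not in {"L", "P"} for code, _, _ in out)
        assert {code for code, _, _ in out} == {"G", "R"}

    def test_root_propagates_nothing(self, chain_taxonomy):
        assert propagate_concepts({"R"}, chain_taxonomy, 2) == set()

    def test_stable_on_recomputation(self, diamond_taxonomy):
        first = propagate_concepts({"L"}, diamond_taxonomy, 2)
        assert propagate_concepts({"L"}, diamond_taxonomy, 2) == first


class TestAnnotateDocument:
    def test_end_to_end_exact_label(self, disease_taxonomy, disease_dictionary):
        rec = ArticleRecord("d", title="Niemann-Pick disease type B in infants")
        cfg = AnnotatorConfig(propagate=False)
        ann = annotate_document(rec, disease_dictionary, disease_taxonomy, cfg)
        assert ann.final_concepts == {"C-NPB"}

    def test_fuzzy_adds_recall_monotonically(self, disease_taxonomy, disease_dictionary):
        rec = ArticleRecord("d", abstract="glucocerebrosidase deficency confirmed")
        off = annotate_document(
            rec, disease_dictionary, disease_taxonomy, AnnotatorConfig(fuzzy=False, propagate=False)
        )
        on = annotate_document(
            rec, disease_dictionary, disease_taxonomy, AnnotatorConfig(fuzzy=True, propagate=False)
        )
        assert off.final_concepts <= on.final_concepts
        assert on.final_concepts == {"C-GAUCHER"}
        assert similarity(
            "glucocerebrosidase deficency", "glucocerebrosidase deficiency"
        ) >= 0.8

    def test_propagation_adds_ancestors(self, disease_taxonomy, disease_dictionary):
        rec = ArticleRecord("d", title="Gaucher disease")
        ann = annotate_document(rec, disease_dictionary, disease_taxonomy)
        assert ann.final_concepts == {"C-GAUCHER", "C-LSD"}
        assert ann.propagated_concepts == (("C-LSD", "C-GAUCHER", 1),)

    def test_deterministic(self, disease_taxonomy, disease_dictionary):
        rec = ArticleRecord("d", abstract="gauchers disease and hodgkin lymphoma")
        a = annotate_document(rec, disease_dictionary, disease_taxonomy)
        b = annotate_document(rec, disease_dictionary, disease_taxonomy)
        assert a == b
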