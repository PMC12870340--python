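from __future__ import annotations

import json

import pytest

from orphindex import (
    Concept,
    SyntheticSpec,
    Taxonomy,
    build_dictionary,
    generate_bundle,
)


def make_taxonomy(*concepts: Concept, version: str = "test") -> Taxonomy:
    return Taxonomy(concepts={c.code: c for c in concepts}, version_tag=version)


@pytest.fixture
def chain_taxonomy() -> Taxonomy:
    """Linear chain L -> P -> G -> R plus a deprecated alias of L."""
    return make_taxonomy(
        Concept("R", "root disorder group"),
        Concept("G", "generic disorder", parents=("R",)),
        Concept("P", "parent disorder", parents=("G",)),
        Concept("L", "leaf disorder", parents=("P",)),
        Concept("L-old", "leaf disorder former name", status="deprecated", replaced_by="L"),
    )


@pytest.fixture
def diamond_taxonomy() -> Taxonomy:
    """Diamond L -> {P1, P2}, P1 -> G, P2 -> G."""
    return make_taxonomy(
        Concept("G", "grandparent disorder"),
        Concept("P1", "first parent disorder", parents=("G",)),
        Concept("P2", "second parent disorder", parents=("G",)),
        Concept("L", "leaf disorder", parents=("P1", "P2")),
    )


@pytest.fixture
def disease_taxonomy() -> Taxonomy:
    """Small realistic taxonomy for matcher tests."""
    return make_taxonomy(
        Concept("C-LSD", "lysosomal storage disease"),
        Concept(
            "C-GAUCHER",
            "Gaucher disease",
            synonyms=("glucocerebrosidase deficiency", "GD"),
            parents=("C-LSD",),
        ),
        Concept(
            "C-NPB",
            "Niemann-Pick disease type B",
            parents=("C-LSD",),
        ),
        Concept("C-LYMPH", "lymphoma"),
        Concept("C-HODG", "hodgkin lymphoma", parents=("C-LYMPH",)),
        Concept(
            "C-THAL-OLD",
            "β thalassemia major",
            status="deprecated",
            replaced_by="C-THAL",
        ),
        Concept("C-THAL", "beta-thalassemia"),
    )


@pytest.fixture
def disease_dictionary(disease_taxonomy):
    return build_dictionary(disease_taxonomy)


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Noise-free study bundle: 100 concepts, 200 docs, no typos."""
    return generate_bundle(
        SyntheticSpec(n_concepts=100, n_docs=200, typo_prob=0.0, seed=11)
    )


def write_taxonomy_json(path, concepts: list[dict], version: str = "t") -> str:
    path.write_text(json.dumps({"version": version, "concepts": concepts}), encoding="utf-8")
    return str(path)
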