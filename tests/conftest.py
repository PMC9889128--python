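from __future__ import annotations

import pytest

from pathocite.fixtures import (
    GeneratorConfig,
    fixture_lexicon,
    generate_corpus,
    write_taxonomy,
)
from pathocite.taxonomy import load_taxonomy

SMALL_OBO = """\
format-version: 1.2
ontology: test-taxon

[Term]
id: TT:0000001
name: Borrelia burgdorferi
synonym: "Lyme disease spirochete" EXACT []

[Term]
id: TT:0000002
name: Borrelia burgdorferi strain N40
synonym: "Bb N40" RELATED []
is_a: TT:0000001

[Term]
id: TT:0000003
name: Borrelia burgdorferi strain B31
synonym: "Bb B31" RELATED []
is_a: TT:0000001
"""


@pytest.fixture
def small_obo_path(tmp_path):
    p = tmp_path / "small.obo"
    p.write_text(SMALL_OBO, encoding="utf-8")
    return p


@pytest.fixture
def small_taxonomy(small_obo_path):
    return load_taxonomy(small_obo_path)


@pytest.fixture(scope="session")
def std_config():
    """Small standard generator configuration shared by unit tests."""
    return GeneratorConfig(seed=7, n_species=4, n_citations=60)


@pytest.fixture(scope="session")
def std_fixture(std_config):
    """(records, dictionary, corpus, gold) for the standard config."""
    records, dictionary = fixture_lexicon(std_config)
    corpus, gold = generate_corpus(std_config, records, dictionary)
    return records, dictionary, corpus, gold


@pytest.fixture(scope="session")
def cue_corpus():
    """The standard cue-word corpus: seed 42, 2000 citations (one
    (citation, pathogen) pair each)."""
    from pathocite.labeling import MeshLink, build_training_set
    from pathocite.recognizer import annotate_corpus, compile as compile_matcher

    config = GeneratorConfig(seed=42, n_species=6, n_citations=2000)
    records, dictionary = fixture_lexicon(config)
    corpus, gold = generate_corpus(config, records, dictionary)
    matcher = compile_matcher(dictionary)
    mentions = annotate_corpus(corpus, matcher)
    link = MeshLink({r.pathogen_id: set(r.mesh_descriptors) for r in records})
    examples = build_training_set(corpus, mentions, link)
    return records, dictionary, corpus, gold, mentions, examples


@pytest.fixture(scope="session")
def cue_examples(cue_corpus):
    return cue_corpus[5]
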