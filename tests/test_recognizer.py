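"""Dictionary, regex and prion recognizers against brute-force oracles."""

from __future__ import annotations

import random

import pytest

from helpers import oracle_dictionary_scan
from pathocite.corpus import Citation
from pathocite.fixtures import GeneratorConfig, fixture_lexicon, generate_corpus
from pathocite.recognizer import (
    CompiledMatcher,
    PrionRule,
    annotate_citation,
    build_toxin_regexes,
    compile as compile_matcher,
    find_dictionary_mentions,
    find_prion_mentions,
    find_toxin_mentions,
)
from pathocite.taxonomy import LexiconEntry, Provenance, TermDictionary


def make_dictionary(surface_to_ids: dict[str, list[str]]) -> TermDictionary:
    return TermDictionary(
        LexiconEntry(surface, pid, Provenance.SYNONYM)
        for surface, ids in surface_to_ids.items()
        for pid in ids
    )


class TestCompile:
    def test_single_entry_found(self):
        matcher = compile_matcher(make_dictionary({"Ebola virus": ["org-1"]}))
        mentions = find_dictionary_mentions(matcher, "the Ebola virus genome")
        assert [m.surface for m in mentions] == ["Ebola virus"]

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            compile_matcher(TermDictionary([]))

    def test_large_dictionary_membership_matches_set_oracle(self):
        rng = random.Random(5)
        words = [f"w{i}" for i in range(400)]
        surfaces = {
            " ".join(rng.sample(words, rng.randrange(1, 4))): ["org-1"]
            for _ in range(10_000)
        }
        matcher = compile_matcher(make_dictionary(surfaces))
        oracle = {s.lower() for s in surfaces}
        probes = list(surfaces)[:500] + [
            " ".join(rng.sample(words, 2)) for _ in range(500)
        ]
        for probe in probes:
            assert (probe in matcher) == (probe.lower() in oracle)

    def test_case_variants_collapse(self):
        matcher = compile_matcher(
            make_dictionary({"EBOLA VIRUS": ["org-1"], "ebola virus": ["org-1"]})
        )
        assert len(matcher._index["ebola"]) == 1


class TestDictionaryMatching:
    def test_longest_match_prefers_subspecies(self):
        matcher = compile_matcher(
            make_dictionary(
                {
                    "Borrelia burgdorferi": ["org-1"],
                    "Borrelia burgdorferi strain N40": ["org-1"],
                }
            )
        )
        text = "Borrelia burgdorferi strain N40 was cultured"
        mentions = find_dictionary_mentions(matcher, text)
        assert len(mentions) == 1
        assert mentions[0].surface == "Borrelia burgdorferi strain N40"

    def test_empty_text(self):
        matcher = compile_matcher(make_dictionary({"abcd": ["org-1"]}))
        assert find_dictionary_mentions(matcher, "") == []

    def test_token_boundary_blocks_substring_hits(self):
        matcher = compile_matcher(make_dictionary({"toxin": ["org-1"]}))
        assert find_dictionary_mentions(matcher, "antiaflatoxinB1 sample") == []

    def test_equal_length_ambiguity_lowest_id_wins(self):
        matcher = compile_matcher(make_dictionary({"shared term": ["org-b", "org-a"]}))
        (m,) = find_dictionary_mentions(matcher, "a shared term here")
        assert m.pathogen_id == "org-a"
        assert m.ambiguous_with == ("org-b",)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_texts_match_bruteforce_oracle(self, seed):
        rng = random.Random(seed)
        vocab = [f"t{i}" for i in range(30)]
        surfaces: dict[str, list[str]] = {}
        for i in range(40):
            s = " ".join(rng.sample(vocab, rng.randrange(1, 4)))
            surfaces.setdefault(s, []).append(f"org-{i%7}")
        matcher = compile_matcher(make_dictionary(surfaces))
        for _ in range(20):
            text = " ".join(rng.choices(vocab + [",", ";"], k=rng.randrange(0, 40)))
            got = [
                (m.start, m.end, m.pathogen_id)
                for m in find_dictionary_mentions(matcher, text)
            ]
            assert got == oracle_dictionary_scan(surfaces, text)

    def test_longer_entry_never_increases_mention_count(self):
        base = {"alpha beta": ["org-1"]}
        extended = {"alpha beta": ["org-1"], "alpha beta gamma": ["org-2"]}
        text = "alpha beta gamma delta"
        n_base = len(
            find_dictionary_mentions(compile_matcher(make_dictionary(base)), text)
        )
        n_ext = len(
            find_dictionary_mentions(compile_matcher(make_dictionary(extended)), text)
        )
        assert n_ext <= n_base


class TestToxinRegexes:
    @pytest.mark.parametrize(
        "text,pathogen_id",
        [
            ("onabotulinumtoxinA", "toxin-botulinum"),
            ("antiaflatoxinB1", "toxin-aflatoxins"),
            ("SAXITOXIN", "toxin-saxitoxins"),
            ("botulinum neurotoxin E", "toxin-botulinum"),
            ("tetrodotoxins", "toxin-tetrodotoxin"),
        ],
    )
    def test_embedded_and_case_insensitive_forms(self, text, pathogen_id):
        bank = build_toxin_regexes()
        mentions = find_toxin_mentions(bank, f"studies of {text} in fish")
        assert pathogen_id in {m.pathogen_id for m in mentions}

    def test_bad_pattern_fails_at_bank_load(self):
        from pathocite.recognizer import RegexBank

        with pytest.raises(ValueError, match="does not compile"):
            RegexBank([("(?i)([unclosed", "toxin-x")])

    def test_mentions_carry_regex_method_and_exact_spans(self):
        bank = build_toxin_regexes()
        text = "Aflatoxin and saxitoxin levels"
        for m in find_toxin_mentions(bank, text):
            assert m.method == "regex"
            assert text[m.start : m.end] == m.surface


class TestPrionRule:
    def test_sheep_title_cooccurrence(self):
        c = Citation(pmid="1", title="PrPSc accumulation in sheep brain")
        mentions = find_prion_mentions(PrionRule(), c)
        assert {m.pathogen_id for m in mentions} == {"prpsc-sheep"}

    def test_species_without_prion_term_is_empty(self):
        c = Citation(pmid="1", title="Grazing behaviour of sheep in winter")
        assert find_prion_mentions(PrionRule(), c) == []

    def test_prion_term_without_species_is_empty(self):
        c = Citation(pmid="1", title="PrPSc misfolding kinetics in vitro")
        assert find_prion_mentions(PrionRule(), c) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_random_corpus_equals_boolean_oracle(self, seed):
        rng = random.Random(seed)
        rule = PrionRule()
        species_words = sorted(
            {w for terms in rule.species_lexicon.values() for w in terms}
        )
        fillers = ["study", "brain", "samples", "protein"]
        for _ in range(40):
            words = rng.choices(
                fillers + species_words + ["PrPSc", "prion"], k=rng.randrange(1, 12)
            )
            c = Citation(pmid="1", title=" ".join(words) or "x")
            got = find_prion_mentions(rule, c)
            prion_present = any(
                w.lower() in ("prpsc", "prion", "prions", "scrapie", "prp-sc")
                for w in words
            )
            expected_count = 0
            if prion_present:
                for terms in rule.species_lexicon.values():
                    expected_count += sum(
                        1 for w in words if w.lower() in {t.lower() for t in terms}
                    )
            assert len(got) == expected_count


class TestAnnotateCitation:
    def test_union_of_methods_across_fields(self):
        matcher = compile_matcher(make_dictionary({"Ebola virus": ["org-1"]}))
        bank = build_toxin_regexes()
        c = Citation(
            pmid="1",
            title="Ebola virus replication",
            abstract="Conotoxin effects were measured.",
        )
        mentions = annotate_citation(c, matcher, bank, PrionRule())
        assert {(m.field, m.method) for m in mentions} == {
            ("title", "dictionary"),
            ("abstract", "regex"),
        }

    def test_no_abstract_scans_title_only(self):
        matcher = compile_matcher(make_dictionary({"Ebola virus": ["org-1"]}))
        c = Citation(pmid="1", title="Ebola virus study")
        mentions = annotate_citation(c, matcher)
        assert all(m.field == "title" for m in mentions)

    def test_dictionary_beats_regex_on_tie_and_longer_wins(self):
        matcher = compile_matcher(make_dictionary({"saxitoxin": ["org-sax"]}))
        bank = build_toxin_regexes()
        c = Citation(pmid="1", title="saxitoxin effects")
        mentions = annotate_citation(c, matcher, bank)
        assert len(mentions) == 1
        assert mentions[0].method == "dictionary"

    def test_offset_fidelity_and_case_invariance_on_fixture(self, std_fixture):
        records, dictionary, corpus, gold = std_fixture
        matcher = compile_matcher(dictionary)
        for citation in corpus:
            mentions = annotate_citation(citation, matcher)
            for m in mentions:
                assert citation.field_text(m.field)[m.start : m.end] == m.surface
            upper = Citation(
                pmid=citation.pmid,
                title=citation.title.upper(),
                abstract=citation.abstract.upper() if citation.abstract else None,
                mesh_descriptors=citation.mesh_descriptors,
            )
            spans = [(m.field, m.start, m.end, m.pathogen_id) for m in mentions]
            upper_spans = [
                (m.field, m.start, m.end, m.pathogen_id)
                for m in annotate_citation(upper, matcher)
            ]
            assert spans == upper_spans
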