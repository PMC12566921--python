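"""Shared fixtures: a small synthetic corpus and lexicons, built once."""
import pytest

from chartlex import (GeneratorConfig, build_lexicon, extract_sentences,
                      generate_cohort, generate_notes, length_filter,
                      match_keywords)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_patients=120, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    patients, outcomes = generate_cohort(small_config)
    notes, truths = generate_notes(patients, small_config, build_lexicon())
    return {"patients": patients, "outcomes": outcomes,
            "notes": notes, "truths": truths}


@pytest.fixture(scope="session")
def seed_lexicon():
    return build_lexicon()


@pytest.fixture(scope="session")
def validated_lexicon():
    lex = build_lexicon()
    lex.validated_terms = ["cooperative", "agitation", "refusal"]
    return lex


@pytest.fixture(scope="session")
def matched_sentences(small_corpus, validated_lexicon):
    sentences = extract_sentences(small_corpus["notes"])
    retained, _, _ = length_filter(sentences)
    for s in retained:
        match_keywords(s, validated_lexicon)
    return retained
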