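"""Sentence filtering, keyword matching and review-set reduction."""
import re

import numpy as np
import pytest

from chartlex import (FilterConfig, Lexicon, Sentence, build_lexicon,
                      dedup_common, filter_keyword_sentences,
                      keyword_fraction_pct, length_filter, match_keywords,
                      nearest_rank_percentile, stepwise_sample)
from chartlex.errors import ConfigurationError


def _sent(i, text, tokens=None):
    from chartlex import tokenize
    return Sentence(sentence_id=f"s{i}", note_id=f"n{i}", position=0, text=text,
                    token_count=tokens if tokens is not None else len(tokenize(text)))


# --------------------------------------------------------------------- length

def test_length_filter_inclusive_boundaries():
    sents = [_sent(i, "x", tokens=t) for i, t in enumerate([2, 3, 27, 28])]
    retained, excluded, _ = length_filter(sents, FilterConfig())
    assert [s.token_count for s in retained] == [3, 27]
    assert len(retained) + len(excluded) == len(sents)


def test_length_filter_percentile_mode_nearest_rank():
    sents = [_sent(i, "x", tokens=t) for i, t in enumerate(range(1, 101))]
    cfg = FilterConfig(max_words_mode="percentile")
    _, _, max_words = length_filter(sents, cfg)
    assert max_words == 95
    assert nearest_rank_percentile(list(range(1, 101)), 95) == 95


def test_length_filter_uniform_corpus_all_retained():
    sents = [_sent(i, "x", tokens=5) for i in range(10)]
    retained, excluded, _ = length_filter(sents)
    assert len(retained) == 10 and not excluded


def test_percentile_mode_empty_corpus_rejected():
    with pytest.raises(ConfigurationError):
        length_filter([], FilterConfig(max_words_mode="percentile"))


def test_fixed_and_percentile_modes_agree_when_p95_is_27():
    # 52 sentences of length 1..26 plus ten of length 27: the nearest-rank
    # 95th percentile (rank 59 of 62) lands on 27
    lengths = list(range(1, 27)) * 2 + [27] * 10
    sents = [_sent(i, "x", tokens=t) for i, t in enumerate(lengths)]
    fixed, _, _ = length_filter(sents, FilterConfig())
    pct, _, cap = length_filter(sents, FilterConfig(max_words_mode="percentile"))
    assert cap == 27
    assert [s.sentence_id for s in fixed] == [s.sentence_id for s in pct]


# ------------------------------------------------------------------- matching

def test_match_seed_keyword():
    s = _sent(0, "Patient was combative overnight")
    hits = match_keywords(s, build_lexicon())
    assert len(hits) == 1
    assert hits[0].token == "combative"
    assert hits[0].term.startswith("combat")
    assert s.text.lower()[hits[0].start:].startswith("combative")


def test_match_empty_lexicon_never_hits():
    empty = Lexicon(seeds=[], roots={})
    for text in ("Patient was combative", "refused meds", "alert and oriented"):
        assert match_keywords(_sent(0, text), empty) == []


def test_cooperative_hit_is_lexicon_dependent(validated_lexicon):
    s = _sent(0, "patient was alert and cooperative")
    assert match_keywords(_sent(1, s.text), build_lexicon()) == []
    hits = match_keywords(s, validated_lexicon)
    assert [h.token for h in hits] == ["cooperative"]


def _regex_oracle(text, lex):
    """Independent brute-force scan with explicit token boundaries."""
    roots, terms = lex.matcher_vocabulary()
    lowered = text.lower()
    spans = set()
    for root in roots:
        pat = rf"(?<![a-z0-9-]){re.escape(root)}[a-z0-9]*(?:-[a-z0-9]+)*"
        for m in re.finditer(pat, lowered):
            spans.add((m.start(), m.group(0)))
    for term in terms:
        pat = rf"(?<![a-z0-9-]){re.escape(term)}(?![a-z0-9-])"
        for m in re.finditer(pat, lowered):
            spans.add((m.start(), m.group(0)))
    return spans


def test_matcher_equals_regex_oracle_on_random_sentences(validated_lexicon):
    """Token-for-token agreement with a brute-force regex scan on 1,000
    random synthetic sentences."""
    rng = np.random.default_rng(42)
    pool = ["patient", "was", "noted", "combative", "agitated", "agitation",
            "aggressive", "refusal", "refused", "cooperative", "cooperatively",
            "non-compliant", "stable", "monitoring", "98", "resistant",
            "preagitated", "anger", "angrily", "unpleasantness", "to", "the"]
    for _ in range(1000):
        n = rng.integers(3, 12)
        words = [pool[i] for i in rng.integers(0, len(pool), n)]
        if rng.random() < 0.3:
            words[0] = words[0].capitalize()
        text = " ".join(words) + "."
        s = _sent(0, text)
        hits = match_keywords(s, validated_lexicon)
        got = {(h.start, h.token) for h in hits}
        assert got == _regex_oracle(text, validated_lexicon), text


# --------------------------------------------------------------------- funnel

def test_keyword_subset_and_percentage():
    sents = [_sent(i, t) for i, t in enumerate(
        ["Patient was combative overnight", "Vitals stable", "Doing well today"])]
    lex = build_lexicon()
    for s in sents:
        match_keywords(s, lex)
    subset, summary = filter_keyword_sentences(sents)
    assert len(subset) == 1
    assert summary["pct"] == 33.3

    empty_subset, empty_summary = filter_keyword_sentences(sents[1:])
    assert empty_subset == [] and empty_summary["pct"] == 0.0


def test_injected_keyword_fraction_recovered():
    """With only negation/out-of-context injection at 6% each the keyword
    sentence fraction lands within 3 binomial s.e. of 12%."""
    from chartlex import (GeneratorConfig, build_lexicon, extract_sentences,
                          generate_cohort, generate_notes)
    cfg = GeneratorConfig(n_patients=150, seed=21, descriptor_base_rate=0.0,
                          negation_rate=0.06, out_of_context_rate=0.06,
                          variant_rate=0.0, template_repeat_rate=0.0)
    patients, _ = generate_cohort(cfg)
    notes, _ = generate_notes(patients, cfg, build_lexicon())
    sents = extract_sentences(notes)
    lex = build_lexicon()
    for s in sents:
        match_keywords(s, lex)
    _, summary = filter_keyword_sentences(sents)
    frac = summary["n_keyword_sentences"] / summary["n_sentences"]
    se = np.sqrt(0.12 * 0.88 / summary["n_sentences"])
    assert abs(frac - 0.12) < 3 * se


def test_printed_counts_render_one_decimal():
    assert keyword_fraction_pct(469_486, 3_916_248) == 12.0


# ---------------------------------------------------------------------- dedup

def test_dedup_collapses_common_sentences():
    sents = [_sent(i, "Patient seen and resisted care today") for i in range(50)]
    review, log = dedup_common(sents, FilterConfig(dedup_min_repeats=10,
                                                   dedup_whitelist=()))
    assert len(review) == 1
    assert sum(r["reason"] == "common" for r in log) == 49


def test_dedup_whitelist_removes_pleasant_template():
    sents = [_sent(0, "A pleasant 26-year-old female patient."),
             _sent(1, "Patient was combative overnight.")]
    review, log = dedup_common(sents, FilterConfig())
    assert [s.sentence_id for s in review] == ["s1"]
    assert log[0]["reason"] == "whitelist"


def test_dedup_all_unique_unchanged():
    sents = [_sent(i, f"Unique sentence number variant {'x' * (i + 1)}")
             for i in range(8)]
    review, log = dedup_common(sents, FilterConfig(dedup_whitelist=()))
    assert len(review) == 8 and not log


# ------------------------------------------------------------------- sampling

def _keyword_pool(counts):
    from chartlex import KeywordHit
    sents = []
    i = 0
    for kw, n in counts.items():
        for _ in range(n):
            s = _sent(i, f"Patient was {kw} today")
            s.keyword_hits = [KeywordHit(token=kw, term=kw, start=12)]
            sents.append(s)
            i += 1
    return sents


def test_stepwise_batches_disjoint_and_truncated():
    pool = _keyword_pool({"combative": 8, "agitated": 7})
    batches = stepwise_sample(pool, [10, 10], seed=3)
    assert [len(b) for b in batches] == [10, 5]
    ids0 = {s.sentence_id for s in batches[0]}
    ids1 = {s.sentence_id for s in batches[1]}
    assert not ids0 & ids1


def test_stepwise_deterministic_under_seed():
    pool = _keyword_pool({"combative": 9, "refused": 9})
    a = stepwise_sample(pool, [6], seed=5)
    b = stepwise_sample(pool, [6], seed=5)
    assert [[s.sentence_id for s in batch] for batch in a] == \
        [[s.sentence_id for s in batch] for batch in b]


def test_stepwise_exact_stratification_on_divisible_case():
    pool = _keyword_pool({k: 4 for k in ("a", "b", "c", "d", "e")})
    (batch,) = stepwise_sample(pool, [10], seed=1)
    from collections import Counter
    counts = Counter(s.keyword_hits[0].term for s in batch)
    assert all(v == 2 for v in counts.values())
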