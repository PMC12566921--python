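"""Sentence extraction, length filtering, keyword matching and review-set
reduction.

The funnel this module implements: note text -> ordered sentences ->
length-filtered sentences (3-27 words inclusive, or a corpus 95th
percentile cap) -> sentences with at least one keyword hit -> a
de-duplicated review set -> stratified annotation batches.
"""
from __future__ import annotations

import logging
import math
import re
from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import FilterConfig
from .errors import ConfigurationError
from .lexicon import Lexicon
from .text import normalize_for_dedup, segment, tokenize
from .types import ClinicalNote, KeywordHit, Sentence

logger = logging.getLogger(__name__)

_TOKEN_SPAN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def extract_sentences(notes: Sequence[ClinicalNote]) -> List[Sentence]:
    """Segment every note into ordered, tokenized sentences."""
    out = []
    for note in notes:
        for pos, text in enumerate(segment(note.text)):
            out.append(Sentence(
                sentence_id=f"{note.note_id}:{pos}",
                note_id=note.note_id,
                position=pos,
                text=text,
                token_count=len(tokenize(text)),
            ))
    return out


def nearest_rank_percentile(values: Sequence[int], q: float) -> int:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    if not values:
        raise ConfigurationError("cannot take a percentile of an empty corpus")
    ordered = sorted(values)
    rank = max(1, math.ceil(q / 100.0 * len(ordered)))
    return ordered[rank - 1]


def length_filter(sentences: Sequence[Sentence],
                  config: Optional[FilterConfig] = None
                  ) -> Tuple[List[Sentence], List[Sentence], int]:
    """Retain sentences with min_words <= token_count <= max_words (inclusive).

    Returns ``(retained, excluded, max_words_used)``.  In percentile mode
    the cap is the nearest-rank percentile of the corpus token counts.
    """
    config = config or FilterConfig()
    config.validate()
    if config.max_words_mode == "percentile":
        max_words = nearest_rank_percentile(
            [s.token_count for s in sentences], config.percentile)
    else:
        max_words = config.max_words
    retained, excluded = [], []
    for s in sentences:
        (retained if config.min_words <= s.token_count <= max_words else excluded).append(s)
    return retained, excluded, max_words


def match_keywords(sentence: Sentence, lex: Lexicon) -> List[KeywordHit]:
    """Keyword hits in one sentence, case-insensitive, with offsets.

    A token is a hit when its lowercase form starts with a lexicon root or
    equals a validated expansion term.  The matched lexicon entry is
    reported alongside the token and its character offset.
    """
    roots, terms = lex.matcher_vocabulary()
    term_set = set(terms)
    hits = []
    lowered = sentence.text.lower()
    for m in _TOKEN_SPAN_RE.finditer(lowered):
        token = m.group(0)
        matched = None
        for root in roots:
            if token.startswith(root):
                matched = root
                break
        if matched is None and token in term_set:
            matched = token
        if matched is not None:
            hits.append(KeywordHit(token=token, term=matched, start=m.start()))
    sentence.keyword_hits = hits
    return hits


def filter_keyword_sentences(sentences: Sequence[Sentence]
                             ) -> Tuple[List[Sentence], Dict]:
    """Subset with >= 1 keyword hit plus a funnel summary."""
    subset = [s for s in sentences if s.keyword_hits]
    total = len(sentences)
    summary = {
        "n_keyword_sentences": len(subset),
        "n_sentences": total,
        "pct": keyword_fraction_pct(len(subset), total),
    }
    return subset, summary


def keyword_fraction_pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, 1)


def dedup_common(sentences: Sequence[Sentence],
                 config: Optional[FilterConfig] = None
                 ) -> Tuple[List[Sentence], List[Dict]]:
    """Reduce the review set: collapse heavily repeated sentences and drop
    whitelisted clearly-non-negative templates.

    Normalization casefolds, strips digits and collapses whitespace so
    age-templated sentences collapse to one key.  A normalized group
    occurring at least ``dedup_min_repeats`` times keeps a single
    representative (reason ``common`` for the rest); whitelist matches are
    removed outright (reason ``whitelist``).  Returns
    ``(review_set, removal_log)``.
    """
    config = config or FilterConfig()
    whitelist = [re.compile(p, re.IGNORECASE) for p in config.dedup_whitelist]
    removal_log: List[Dict] = []

    survivors = []
    for s in sentences:
        if any(p.search(s.text) for p in whitelist):
            removal_log.append({"sentence_id": s.sentence_id, "reason": "whitelist"})
        else:
            survivors.append(s)

    groups: Dict[str, List[Sentence]] = defaultdict(list)
    for s in survivors:
        groups[normalize_for_dedup(s.text)].append(s)

    review = []
    for s in survivors:
        group = groups[normalize_for_dedup(s.text)]
        if len(group) >= config.dedup_min_repeats:
            if s is group[0]:  # one representative per common template
                review.append(s)
            else:
                removal_log.append({"sentence_id": s.sentence_id, "reason": "common"})
        else:
            review.append(s)
    return review, removal_log


def _primary_keyword(sentence: Sentence) -> str:
    return sentence.keyword_hits[0].term if sentence.keyword_hits else ""


def stepwise_sample(review_set: Sequence[Sentence],
                    batch_sizes: Sequence[int],
                    seed: int = 0) -> List[List[Sentence]]:
    """Draw disjoint annotation batches, stratified by matched keyword.

    Each batch allocates slots as evenly as possible across the keyword
    groups still holding sentences (prioritizing diversity of keyword
    context), with any remainder round-robined over a seeded group order.
    A batch larger than the remaining pool is truncated with a warning.
    """
    rng = np.random.default_rng(seed)
    pools: Dict[str, List[Sentence]] = defaultdict(list)
    for s in review_set:
        pools[_primary_keyword(s)].append(s)
    for key in pools:
        pool = pools[key]
        order = rng.permutation(len(pool))
        pools[key] = [pool[i] for i in order]

    batches: List[List[Sentence]] = []
    for size in batch_sizes:
        available = sum(len(p) for p in pools.values())
        if size > available:
            logger.warning("batch of %d truncated to %d remaining sentences",
                           size, available)
            size = available
        batch: List[Sentence] = []
        while len(batch) < size:
            active = sorted(k for k, p in pools.items() if p)
            share = max(1, (size - len(batch)) // len(active))
            start_order = list(rng.permutation(len(active)))
            for gi in start_order:
                key = active[gi]
                take = min(share, len(pools[key]), size - len(batch))
                for _ in range(take):
                    batch.append(pools[key].pop())
                if len(batch) >= size:
                    break
        batches.append(batch)
    return batches
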