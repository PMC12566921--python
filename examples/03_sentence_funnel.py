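"""The sentence funnel: segmentation, length filter, keyword matching,
de-duplication and stratified annotation sampling.

Sentences shorter than 3 or longer than 27 words are excluded (27 being
the reference corpus's 95th-percentile length), keyword hits come from
root-prefix matching, heavily repeated templates collapse to one
representative, and annotation batches are stratified by matched keyword.
"""
from chartlex import (FilterConfig, GeneratorConfig, build_lexicon,
                      dedup_common, extract_sentences,
                      filter_keyword_sentences, generate_cohort,
                      generate_notes, length_filter, match_keywords,
                      stepwise_sample)

config = GeneratorConfig(n_patients=250, seed=3)
patients, _ = generate_cohort(config)
lexicon = build_lexicon()
notes, _ = generate_notes(patients, config, lexicon)

sentences = extract_sentences(notes)
retained, excluded, cap = length_filter(sentences, FilterConfig())
for s in retained:
    match_keywords(s, lexicon)
keyword_sentences, summary = filter_keyword_sentences(retained)
review, removal_log = dedup_common(keyword_sentences, FilterConfig())

print(f"notes -> sentences:          {len(notes)} -> {len(sentences)}")
print(f"length filter [3, {cap}]:     kept {len(retained)}, dropped {len(excluded)}")
print(f"keyword sentences:           {summary['n_keyword_sentences']} "
      f"({summary['pct']}% of filtered)")
print(f"review set after dedup:      {len(review)} "
      f"({sum(r['reason'] == 'common' for r in removal_log)} repeats collapsed, "
      f"{sum(r['reason'] == 'whitelist' for r in removal_log)} whitelisted)")

batches = stepwise_sample(review, [30], seed=3)
from collections import Counter
by_kw = Counter(s.keyword_hits[0].term for s in batches[0])
print(f"\nannotation batch of {len(batches[0])}, stratified across "
      f"{len(by_kw)} matched keywords:")
print(" ", dict(by_kw))
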