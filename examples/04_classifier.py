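"""Train the elastic-net sentence classifier on annotated keyword sentences
and evaluate the full metric panel with bootstrap intervals.

Labels come from a simulated dual-reviewer pass over generator truth;
sentences where the reviewers disagree on descriptor presence are
conservatively excluded.  The model separates "contains a negative
descriptor" from negated / out-of-context / benign keyword uses.
"""
import numpy as np

from chartlex import (FeatureSpec, GeneratorConfig, ModelSpec, SplitSpec,
                      build_lexicon, evaluate, extract_sentences, featurize,
                      filter_keyword_sentences, generate_cohort, generate_notes,
                      kappa_binary_presence, length_filter, match_keywords,
                      resolve_all, simulate_annotation, split_data, train_model,
                      LABEL_NEGATIVE)

config = GeneratorConfig(n_patients=250, seed=12)
patients, _ = generate_cohort(config)
lexicon = build_lexicon()
notes, truths = generate_notes(patients, config, lexicon)
truth_map = {t.sentence_id: t.label for t in truths}

retained, _, _ = length_filter(extract_sentences(notes))
for s in retained:
    match_keywords(s, lexicon)
keyword_sentences, _ = filter_keyword_sentences(retained)

records = simulate_annotation(keyword_sentences, truth_map,
                              disagreement_rate=0.006, seed=12)
records, summary = resolve_all(records)
print(f"annotated {summary['n_records']} sentences; "
      f"{summary['n_disagreements']} disagreements "
      f"({summary['n_excluded']} excluded); "
      f"kappa on presence = {kappa_binary_presence(records):.3f}")

split = split_data(records, SplitSpec(seed=12))
by_id = {s.sentence_id: s for s in keyword_sentences}
labels = {r.sentence_id: r.final_label for r in records
          if not r.excluded_from_modeling}
train_s = [by_id[i] for i in split["train_ids"]]
test_s = [by_id[i] for i in split["test_ids"]]
y_train = np.array([labels[s.sentence_id] == LABEL_NEGATIVE for s in train_s], int)
y_test = np.array([labels[s.sentence_id] == LABEL_NEGATIVE for s in test_s], int)

X_train, vocab, fz = featurize(train_s, FeatureSpec())
model = train_model(X_train, y_train, ModelSpec(seed=12))
print(f"\nelastic net: {len(vocab)} n-gram features, "
      f"best params {model.best_params}, CV AUROC {model.cv_score:.3f}")

rep = evaluate(y_test, model.scores(fz.transform(test_s)), seed=12)
print(f"\ntest panel (n={rep.n}, prevalence {rep.prevalence:.3f}):")
for name, v in rep.metrics.items():
    point, lo, hi = v
    print(f"  {name:>12}: {point:.3f}  [{lo:.3f}, {hi:.3f}]")
print("\nIntervals are 95% percentile bootstrap over test sentences.")
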