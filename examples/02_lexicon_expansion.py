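"""Build the negative-keyword lexicon: roots, corpus frequency replacement,
Word2Vec expansion and dual-reviewer validation.

The 15 seed keywords are reduced to root prefixes so grammatical variants
match; the most corpus-frequent token sharing each root becomes the
representative; two Word2Vec models propose semantically similar
candidates; and only candidates both reviewers accept enter the final
matcher vocabulary.
"""
from chartlex import (EmbeddingConfig, apply_validation, build_lexicon,
                      expand_keywords, frequency_replacement, generate_cohort,
                      generate_notes, GeneratorConfig, tokenize,
                      train_embeddings, segment)

config = GeneratorConfig(n_patients=150, seed=7)
patients, _ = generate_cohort(config)
notes, _ = generate_notes(patients, config, build_lexicon())

lex = build_lexicon()
print("seed keywords:", ", ".join(lex.seeds))
print("example roots:", {k: lex.roots[k] for k in ("aggressive", "refuse", "agitated")})

lex = frequency_replacement((t for n in notes for t in tokenize(n.text)), lex)
changed = {k: v for k, v in lex.representatives.items() if k != v}
print("\nfrequency replacement (root family member more frequent than the seed):")
print(" ", changed or "none on this corpus")

sentences = [s for n in notes for s in segment(n.text)]
models = {algo: train_embeddings(sentences, EmbeddingConfig(
    algorithm=algo, vector_dim=50, epochs=3, seed=7))
    for algo in ("skip-gram", "cbow")}
candidates = expand_keywords(models, lex, top_k=10)
print(f"\n{len(candidates)} expansion candidates; top 5 by cosine similarity:")
for c in candidates[:5]:
    print(f"  {c.term:<18} (from {c.source_keyword}, {c.algorithm}, "
          f"sim {c.similarity:.3f})")

# simulated dual review: accept candidates from known descriptor families
family = {"agitation", "aggression", "refusal", "resisting", "noncompliance",
          "confrontational", "cooperative"}
decisions = {c.term: ("accept", "accept") if c.term in family
             else ("reject", "reject") for c in candidates}
lex, summary = apply_validation(lex, decisions)
print(f"\nvalidation: {summary['n_validated']}/{summary['n_candidates']} "
      f"dual-accepted ({summary['acceptance_pct']}%) -> "
      f"final matcher = 15 roots + {len(lex.validated_terms)} validated terms")
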