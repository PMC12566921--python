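"""Generate a synthetic maternal-care note corpus with known ground truth.

The generator draws a demographically mixed cohort, assigns each patient a
true descriptor flag from a logistic model with configurable odds ratios,
and assembles typed clinical notes from templates, recording a truth label
for every sentence.
"""
from chartlex import (GeneratorConfig, build_lexicon, generate_cohort,
                      generate_notes, truth_summary)

config = GeneratorConfig(n_patients=2000, seed=42)
patients, outcomes = generate_cohort(config)
notes, truths = generate_notes(patients, config, build_lexicon())

print(f"cohort: {len(patients)} patients, {len(notes)} notes, "
      f"{len(truths)} sentences with truth labels")

summary = truth_summary(truths, patients)
print(f"\noverall true descriptor prevalence: "
      f"{summary['overall']['prevalence']:.3f} "
      f"({summary['overall']['n_with_descriptor']} patients)")
print("\nper-race prevalence (the generator's configured odds ratios make")
print("descriptors more likely for Black patients than the White reference):")
for race, row in summary["race"].items():
    print(f"  {race:>6}: {row['prevalence']:.3f}  "
          f"({row['n_with_descriptor']}/{row['n_patients']})")
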