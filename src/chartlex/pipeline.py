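"""End-to-end pipeline: generation (or loading), lexicon building, sentence
extraction, annotation, classification, and patient-level analysis.

Stages run in a fixed order — lexicon -> sentence extraction ->
annotation/training -> corpus classification -> patient-level analysis —
and every artifact bundle is stamped with a hash of the configuration that
produced it.  A fixed global seed fans out to per-stage seeds, so rerunning
the same config reproduces identical outputs byte for byte.

In demo mode the synthetic generator supplies the corpus and simulated
reviewer decisions stand in for expert validation and annotation, with
ground truth retained so every stage's output can be audited.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as clio
from .annotation import kappa_binary_presence, resolve_all, split_data
from .classifier import (SentenceFeaturizer, classify_corpus, compare_families,
                         error_audit, evaluate, featurize, train_model)
from .cohort import (assign_case_control, odds_ratios, or_results_frame,
                     prevalence_table, rollup)
from .config import (CaseControlRule, EmbeddingConfig, FeatureSpec,
                     FilterConfig, GeneratorConfig, ModelSpec, SplitSpec,
                     config_hash, stage_seed)
from .errors import StageError
from .lexicon import (apply_validation, build_lexicon, expand_keywords,
                      frequency_replacement)
from .sentences import (dedup_common, extract_sentences,
                        filter_keyword_sentences, keyword_fraction_pct,
                        length_filter, match_keywords, stepwise_sample)
from .synthetic import (DESCRIPTOR_FORMS, VARIANT_FORMS, generate_cohort,
                        generate_notes)
from .embeddings import train_embeddings
from .text import tokenize
from .types import (AnnotationRecord, LABEL_NEGATIVE, LABEL_NOT_NEGATIVE,
                    LABEL_OUT_OF_CONTEXT, SENTENCE_LABELS)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, demo-mode by default.

    In non-demo mode ``paths`` must provide patients / notes / outcomes
    (CSV, JSONL, CSV) and annotations, and the generator is unused.
    """

    seed: int = 0
    output_dir: Optional[str] = None
    demo: bool = True
    paths: Dict[str, str] = field(default_factory=dict)
    generator: Optional[GeneratorConfig] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    embedding: EmbeddingConfig = field(default_factory=lambda: EmbeddingConfig(
        vector_dim=50, epochs=3))
    feature: FeatureSpec = field(default_factory=FeatureSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    case_rule: CaseControlRule = field(default_factory=CaseControlRule)
    top_k: int = 15
    embed_max_sentences: int = 1500
    annotation_batch_size: int = 600
    disagreement_rate: float = 0.006
    threshold: float = 0.5
    n_bootstrap: int = 200
    compare_baselines: bool = False

    def resolved_generator(self) -> GeneratorConfig:
        gen = self.generator or GeneratorConfig(n_patients=500)
        gen.seed = stage_seed(self.seed, "generate")
        return gen


def _demo_decisions(candidates) -> Dict[str, tuple]:
    """Simulated dual-reviewer validation: both reviewers accept candidates
    that belong to a known descriptor family, reject everything else."""
    family = set(DESCRIPTOR_FORMS) | set(VARIANT_FORMS) | {"cooperative"}
    roots = build_lexicon().root_list()
    decisions = {}
    for c in candidates:
        ok = c.term in family or any(c.term.startswith(r) for r in roots)
        decisions[c.term] = ("accept", "accept") if ok else ("reject", "reject")
    return decisions


def simulate_annotation(batch, truth_by_sentence: Dict[str, str],
                        disagreement_rate: float, seed: int) -> List[AnnotationRecord]:
    """Reviewer labels derived from generator truth.

    Reviewer A reads off the truth; reviewer B flips descriptor presence
    with the configured probability, producing the occasional
    presence-level disagreement the conservative resolution rule handles.
    """
    rng = np.random.default_rng(seed)
    records = []
    for s in batch:
        true = truth_by_sentence.get(s.sentence_id, LABEL_NOT_NEGATIVE)
        if true not in SENTENCE_LABELS:
            true = LABEL_NOT_NEGATIVE
        label_b = true
        if rng.random() < disagreement_rate:
            label_b = LABEL_NOT_NEGATIVE if true == LABEL_NEGATIVE else LABEL_NEGATIVE
        records.append(AnnotationRecord(sentence_id=s.sentence_id,
                                        label_a=true, label_b=label_b))
    return records


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run every stage and return the artifact bundle.

    The bundle carries the funnel counts, lexicon, metrics, predictions,
    stratified tables, odds ratios and the config stamp.  Stage failures
    raise :class:`StageError` naming the stage; artifacts produced before
    the failure stay in the partially filled bundle attached to the error.
    """
    bundle: Dict = {"config_hash": config_hash(
        config.filter, config.embedding, config.feature, config.model,
        config.split, config.case_rule, config.resolved_generator()),
        "seed": config.seed}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                err = StageError(name, str(exc))
                err.bundle = bundle
                raise err from exc
        return wrap

    # --- inputs -----------------------------------------------------------
    def load_inputs():
        if config.demo:
            gen = config.resolved_generator()
            patients, outcomes = generate_cohort(gen)
            lex0 = build_lexicon()
            notes, truths = generate_notes(patients, gen, lex0)
            return patients, outcomes, notes, truths
        patients = clio.read_patients(config.paths["patients"])
        outcomes = clio.read_outcomes(config.paths["outcomes"])
        notes = clio.read_notes(config.paths["notes"])
        truths = (clio.read_truth(config.paths["truth"])
                  if "truth" in config.paths else [])
        return patients, outcomes, notes, truths

    patients, outcomes, notes, truths = stage("inputs")(load_inputs)
    truth_by_sentence = {t.sentence_id: t.label for t in truths}
    bundle["n_patients"] = len(patients)
    bundle["n_notes"] = len(notes)

    # --- lexicon ----------------------------------------------------------
    def build_lex():
        lex = build_lexicon()
        corpus_tokens = [t for n in notes for t in tokenize(n.text)]
        lex = frequency_replacement(corpus_tokens, lex)
        emb_seed = stage_seed(config.seed, "embeddings")
        from .text import segment
        sent_texts = [s for n in notes for s in segment(n.text)]
        rng = np.random.default_rng(emb_seed)
        if len(sent_texts) > config.embed_max_sentences:
            idx = rng.choice(len(sent_texts), config.embed_max_sentences, replace=False)
            sent_texts = [sent_texts[i] for i in sorted(idx)]
        models = {}
        for algo in ("skip-gram", "cbow"):
            cfg = EmbeddingConfig(**{**config.embedding.__dict__,
                                     "algorithm": algo, "seed": emb_seed})
            models[algo] = train_embeddings(sent_texts, cfg)
        candidates = expand_keywords(models, lex, top_k=config.top_k)
        if config.demo:
            decisions = _demo_decisions(candidates)
        else:
            from .lexicon import read_decisions
            decisions = read_decisions(config.paths["decisions"])
        lex, summary = apply_validation(lex, decisions)
        bundle["lexicon_summary"] = summary
        return lex

    lexicon = stage("lexicon")(build_lex)
    bundle["lexicon"] = lexicon

    # --- sentence extraction ----------------------------------------------
    def extract():
        sentences = extract_sentences(notes)
        retained, excluded, max_words = length_filter(sentences, config.filter)
        for s in retained:
            match_keywords(s, lexicon)
        keyword_sentences, kw_summary = filter_keyword_sentences(retained)
        review_set, removal_log = dedup_common(keyword_sentences, config.filter)
        bundle["funnel"] = {
            "n_sentences_raw": len(sentences),
            "n_sentences_filtered": len(retained),
            "max_words_used": max_words,
            **kw_summary,
            "n_review_set": len(review_set),
            "n_removed_common": sum(r["reason"] == "common" for r in removal_log),
            "n_removed_whitelist": sum(r["reason"] == "whitelist" for r in removal_log),
        }
        return sentences, retained, keyword_sentences, review_set

    sentences, retained, keyword_sentences, review_set = stage("extract")(extract)

    # --- annotation -------------------------------------------------------
    def annotate():
        batches = stepwise_sample(
            review_set, [min(config.annotation_batch_size, len(review_set))],
            seed=stage_seed(config.seed, "sample"))
        batch = batches[0]
        if config.demo:
            records = simulate_annotation(batch, truth_by_sentence,
                                          config.disagreement_rate,
                                          stage_seed(config.seed, "annotate"))
        else:
            records = clio.read_annotations(config.paths["annotations"])
        records, summary = resolve_all(records)
        summary["kappa_presence"] = round(kappa_binary_presence(records), 3)
        bundle["annotation_summary"] = summary
        split_spec = SplitSpec(**{**config.split.__dict__,
                                  "seed": stage_seed(config.seed, "split")})
        split = split_data(records, split_spec)
        return batch, records, split

    batch, records, split = stage("annotate")(annotate)

    # --- training ---------------------------------------------------------
    def train():
        by_id = {s.sentence_id: s for s in keyword_sentences}
        label_by_id = {r.sentence_id: r.final_label for r in records
                       if not r.excluded_from_modeling}
        train_s = [by_id[i] for i in split["train_ids"] if i in by_id]
        test_s = [by_id[i] for i in split["test_ids"] if i in by_id]
        y_train = np.array([label_by_id[s.sentence_id] == LABEL_NEGATIVE
                            for s in train_s], dtype=int)
        y_test = np.array([label_by_id[s.sentence_id] == LABEL_NEGATIVE
                           for s in test_s], dtype=int)
        X_train, vocab, fz = featurize(train_s, config.feature)
        X_test = fz.transform(test_s)
        spec = ModelSpec(**{**config.model.__dict__,
                            "seed": stage_seed(config.seed, "train")})
        model = train_model(X_train, y_train, spec)
        eval_seed = stage_seed(config.seed, "evaluate")
        metrics = {
            "elastic_net": {
                "best_params": model.best_params,
                "train": evaluate(y_train, model.scores(X_train), config.threshold,
                                  config.n_bootstrap, eval_seed).as_dict(),
                "test": evaluate(y_test, model.scores(X_test), config.threshold,
                                 config.n_bootstrap, eval_seed).as_dict(),
            }
        }
        if config.compare_baselines:
            metrics = compare_families(X_train, y_train, X_test, y_test,
                                       seed=spec.seed,
                                       n_bootstrap=config.n_bootstrap)
        bundle["metrics"] = metrics
        return model, fz, train_s, test_s, label_by_id

    model, featurizer, train_s, test_s, label_by_id = stage("train")(train)

    # --- corpus classification --------------------------------------------
    def classify():
        annotated_ids = set(label_by_id)
        unlabeled = [s for s in keyword_sentences if s.sentence_id not in annotated_ids]
        preds = classify_corpus(model, featurizer, unlabeled, config.threshold)
        bundle["n_classified"] = len(preds)
        labels = dict(label_by_id)
        labels.update({p["sentence_id"]: p["label"] for p in preds})
        if truth_by_sentence:
            truth_kw = {s.sentence_id: truth_by_sentence.get(s.sentence_id,
                                                             LABEL_NOT_NEGATIVE)
                        for s in keyword_sentences}
            pred_all = {s.sentence_id: labels[s.sentence_id] for s in keyword_sentences}
            agree = np.mean([
                (pred_all[i] == LABEL_NEGATIVE) == (truth_kw[i] == LABEL_NEGATIVE)
                for i in pred_all])
            bundle["corpus_accuracy_vs_truth"] = float(agree)
            bundle["error_audit"] = error_audit(pred_all, truth_kw, keyword_sentences)
        bundle["predictions"] = preds
        return labels

    sentence_labels = stage("classify")(classify)

    # --- patient-level analysis -------------------------------------------
    def analyze():
        groups = assign_case_control(outcomes, config.case_rule)
        eligible = {pid for pid, g in groups.items() if g != "excluded"}
        cohort = [p for p in patients if p.patient_id in eligible]
        cohort_notes = [n for n in notes if n.patient_id in eligible]
        cohort_sentences = [s for s in retained
                            if s.note_id in {n.note_id for n in cohort_notes}]
        rollups = rollup(cohort, cohort_notes, cohort_sentences, sentence_labels)
        keyword_rollups = [r for r in rollups if r.n_keyword_notes >= 1]
        table = prevalence_table(keyword_rollups)
        ors = odds_ratios(rollups)
        bundle["case_control"] = {
            "n_case": sum(g == "case" for g in groups.values()),
            "n_control": sum(g == "control" for g in groups.values()),
            "n_excluded": sum(g == "excluded" for g in groups.values()),
        }
        bundle["n_keyword_patients"] = len(keyword_rollups)
        bundle["n_descriptor_patients"] = sum(r.has_descriptor for r in rollups)
        bundle["prevalence_table"] = table
        bundle["odds_ratios"] = ors
        return rollups

    bundle["rollups"] = stage("analyze")(analyze)

    if config.output_dir:
        write_bundle(bundle, patients, notes, truths, config.output_dir)
    return bundle


def write_bundle(bundle: Dict, patients, notes, truths, output_dir) -> None:
    out = clio.ensure_dir(output_dir)
    clio.write_patients(patients, out / "patients.csv")
    clio.write_notes(notes, out / "notes.jsonl")
    if truths:
        clio.write_truth(truths, out / "truth.csv")
    bundle["lexicon"].to_yaml(out / "lexicon.yaml")
    with open(out / "metrics.json", "w") as fh:
        json.dump(bundle["metrics"], fh, indent=2, sort_keys=True)
    clio.write_predictions(bundle["predictions"], out / "predictions.csv")
    bundle["prevalence_table"].table.to_csv(out / "prevalence_table.csv", index=False)
    or_results_frame(bundle["odds_ratios"]).to_csv(out / "odds_ratios.csv", index=False)
    summary = {k: bundle[k] for k in
               ("config_hash", "seed", "n_patients", "n_notes", "funnel",
                "lexicon_summary", "annotation_summary", "case_control",
                "n_keyword_patients", "n_descriptor_patients")
               if k in bundle}
    summary["corpus_accuracy_vs_truth"] = bundle.get("corpus_accuracy_vs_truth")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def report(bundle: Dict) -> str:
    """Human-readable funnel, metric, table and odds-ratio summary."""
    lines = [f"chartlex pipeline report  (config {bundle['config_hash']}, "
             f"seed {bundle['seed']})", ""]
    f = bundle["funnel"]
    funnel = [
        ("notes", bundle["n_notes"]),
        ("sentences", f["n_sentences_raw"]),
        ("length-filtered", f["n_sentences_filtered"]),
        ("keyword sentences", f["n_keyword_sentences"]),
        ("review set", f["n_review_set"]),
    ]
    lines.append("Funnel:")
    prev = None
    for name, count in funnel:
        pct = "" if prev in (None, 0) else f"  ({keyword_fraction_pct(count, prev)}%)"
        lines.append(f"  {name:>18}: {count}{pct}")
        prev = count
    ann = bundle.get("annotation_summary", {})
    lines += ["", f"Annotation: {ann.get('n_records', 0)} sentences, "
                  f"{ann.get('n_disagreements', 0)} disagreements, "
                  f"kappa(presence) = {ann.get('kappa_presence')}"]
    for family, m in bundle.get("metrics", {}).items():
        test = m["test"]["metrics"]
        fmt = {k: (f"{v['point']:.3f}" if v else "n/a") for k, v in test.items()}
        lines.append(f"Model [{family}] test: AUROC {fmt['auroc']}, F1 {fmt['f1']}, "
                     f"sens {fmt['sensitivity']}, spec {fmt['specificity']}")
    cc = bundle.get("case_control", {})
    lines += ["", f"Cohort: {bundle['n_patients']} patients "
                  f"({cc.get('n_case')} case / {cc.get('n_control')} control / "
                  f"{cc.get('n_excluded')} excluded); "
                  f"{bundle.get('n_keyword_patients')} with keyword notes; "
                  f"{bundle.get('n_descriptor_patients')} with a negative descriptor"]
    table = bundle.get("prevalence_table")
    if table is not None:
        lines.append("")
        lines.append(f"Stratified table (without n={table.n_without}, "
                     f"with n={table.n_with}):")
        for _, row in table.table.iterrows():
            lines.append(f"  {row['axis']:>13} {row['stratum']:>18}: "
                         f"{row['count_without']:>4} ({row['pct_without']:>5.1f}%)  "
                         f"{row['count_with']:>4} ({row['pct_with']:>5.1f}%)")
        for axis, p in table.p_values.items():
            lines.append(f"  chi-square p [{axis}]: {p:.4g}")
    ors = bundle.get("odds_ratios")
    if ors:
        lines.append("")
        lines.append("Odds ratios (unadjusted / adjusted):")
        for r in ors:
            if r.estimable:
                lines.append(f"  {r.axis}={r.level} (ref {r.reference}): "
                             f"{r.or_unadjusted:.2f} / {r.or_adjusted:.2f} "
                             f"{r.band_adjusted}")
            else:
                lines.append(f"  {r.axis}={r.level}: non-estimable (separation)")
    return "\n".join(lines)
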