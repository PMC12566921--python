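"""The negative-keyword lexicon and its expansion workflow.

The lexicon starts from 15 seed keywords previously reported to flag
potentially negative patient descriptors.  It grows in four steps:

1. each keyword is reduced to a *root* — the shortest prefix covering its
   grammatical variants (``aggress`` for aggressive/aggression) — so
   matching catches alternative forms;
2. a corpus-frequency rule replaces a keyword by the most frequent corpus
   token sharing its root, when that token is not the keyword itself;
3. Word2Vec models (skip-gram and CBOW) propose semantically similar
   candidate terms;
4. a dual-reviewer validation ledger retains only candidates both
   reviewers accept.

The final matcher vocabulary is the set of roots plus the validated terms.
"""
from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from os import PathLike
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import yaml

from .errors import InputError, IntegrityError

logger = logging.getLogger(__name__)

#: The 15 seed keywords, lowercase, in their canonical order.
SEED_KEYWORDS = (
    "nonadherent", "aggressive", "agitated", "angry", "challenging",
    "combative", "noncompliant", "confront", "uncooperative", "defensive",
    "exaggerate", "hysterical", "unpleasant", "refuse", "resist",
)

#: Grammatical-variant families used to derive the default roots.  Each
#: root is the longest prefix shared by the keyword and its variants.
DEFAULT_VARIANTS: Dict[str, tuple] = {
    "nonadherent": ("nonadherence", "nonadhering"),
    "aggressive": ("aggression", "aggressor", "aggressively"),
    "agitated": ("agitation", "agitate", "agitating"),
    "angry": ("angrily", "angrier"),
    "challenging": ("challenged", "challenges", "challenge"),
    "combative": ("combativeness", "combatively"),
    "noncompliant": ("noncompliance",),
    "confront": ("confronted", "confrontation", "confrontational"),
    "uncooperative": ("uncooperatively",),
    "defensive": ("defensiveness", "defensively"),
    "exaggerate": ("exaggerated", "exaggerating", "exaggeration"),
    "hysterical": ("hysterically", "hysteria"),
    "unpleasant": ("unpleasantly", "unpleasantness"),
    "refuse": ("refused", "refusal", "refusing", "refuses"),
    "resist": ("resisted", "resistant", "resisting", "resistance"),
}

PROVENANCE_SEED = "seed"
PROVENANCE_FREQ = "frequency_replacement"
PROVENANCE_EMBEDDING = "embedding"
PROVENANCE_VALIDATED = "validated"


@dataclass(frozen=True)
class Candidate:
    term: str
    source_keyword: str
    similarity: float
    algorithm: str  # "skip-gram" or "cbow"


@dataclass
class Lexicon:
    seeds: List[str] = field(default_factory=lambda: list(SEED_KEYWORDS))
    roots: Dict[str, str] = field(default_factory=dict)  # keyword -> root
    representatives: Dict[str, str] = field(default_factory=dict)  # keyword -> corpus representative
    candidates: List[Candidate] = field(default_factory=list)
    validated_terms: List[str] = field(default_factory=list)
    provenance: Dict[str, str] = field(default_factory=dict)

    def root_list(self) -> List[str]:
        return [self.roots[k] for k in self.seeds if k in self.roots]

    def matcher_vocabulary(self):
        """(root prefixes, exact terms) the sentence matcher scans for."""
        return self.root_list(), list(self.validated_terms)

    def to_yaml(self, path: Union[str, PathLike]) -> None:
        payload = {
            "seeds": self.seeds,
            "roots": self.roots,
            "representatives": self.representatives,
            "candidates": [
                {"term": c.term, "source": c.source_keyword,
                 "sim": round(c.similarity, 6), "algo": c.algorithm}
                for c in self.candidates
            ],
            "validated": self.validated_terms,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, PathLike]) -> "Lexicon":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            seeds=list(payload.get("seeds", [])),
            roots=dict(payload.get("roots", {})),
            representatives=dict(payload.get("representatives", {})),
            candidates=[
                Candidate(c["term"], c["source"], float(c["sim"]), c["algo"])
                for c in payload.get("candidates", [])
            ],
            validated_terms=list(payload.get("validated", [])),
            provenance=dict(payload.get("provenance", {})),
        )


def seed_keywords() -> List[str]:
    """The 15 seed keywords, lowercase, in fixed order."""
    return list(SEED_KEYWORDS)


def _longest_common_prefix(words: Sequence[str]) -> str:
    shortest = min(words, key=len)
    for i, ch in enumerate(shortest):
        if any(w[i] != ch for w in words):
            return shortest[:i]
    return shortest


def derive_roots(keywords: Sequence[str],
                 variants: Optional[Mapping[str, Sequence[str]]] = None) -> Dict[str, str]:
    """Root per keyword: the longest prefix shared with its variant family.

    A keyword with no known variants keeps itself as root.  Roots are
    always a prefix of their keyword.
    """
    if not keywords:
        raise InputError("keywords must be non-empty")
    variants = DEFAULT_VARIANTS if variants is None else variants
    roots = {}
    for kw in keywords:
        if not kw:
            raise InputError("empty keyword")
        kw = kw.lower()
        family = [kw] + [v.lower() for v in variants.get(kw, ())]
        roots[kw] = _longest_common_prefix(family)
    return roots


def build_lexicon(keywords: Optional[Sequence[str]] = None,
                  variants: Optional[Mapping[str, Sequence[str]]] = None) -> Lexicon:
    """Seed lexicon with derived roots and seed provenance."""
    seeds = list(keywords) if keywords is not None else seed_keywords()
    lex = Lexicon(seeds=seeds, roots=derive_roots(seeds, variants))
    lex.representatives = {k: k for k in seeds}
    lex.provenance = {k: PROVENANCE_SEED for k in seeds}
    return lex


def frequency_replacement(corpus_tokens: Iterable[str], lex: Lexicon) -> Lexicon:
    """Replace each keyword by the most corpus-frequent token sharing its root.

    Ties break toward the original seed keyword; a root matching no corpus
    token keeps its keyword (logged).  Idempotent for a fixed corpus.
    """
    counts = Counter(t.lower() for t in corpus_tokens)
    for kw in lex.seeds:
        root = lex.roots.get(kw, kw)
        matching = {tok: c for tok, c in counts.items() if tok.startswith(root)}
        if not matching:
            logger.info("root %r matched no corpus token; keeping %r", root, kw)
            lex.representatives[kw] = lex.representatives.get(kw, kw)
            continue
        # ties break toward the seed keyword itself, then lexicographically
        best = max(matching, key=lambda t: (matching[t], t == kw, [-ord(c) for c in t]))
        lex.representatives[kw] = best
        if best != kw:
            lex.provenance[best] = PROVENANCE_FREQ
    return lex


def expand_keywords(models, lex: Lexicon, top_k: int = 15) -> List[Candidate]:
    """Embedding-nearest-neighbour expansion candidates for every keyword.

    ``models`` is a mapping algorithm-name -> trained model (or a single
    model).  For each keyword the corpus representative is queried (falling
    back to the keyword itself); out-of-vocabulary keywords contribute no
    candidates.  The union over algorithms is deduplicated keeping the
    maximum similarity, and sorted by descending similarity.
    """
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    if not isinstance(models, Mapping):
        models = {getattr(models.config, "algorithm", "model"): models}
    known = set(lex.seeds) | set(lex.representatives.values())
    best: Dict[str, Candidate] = {}
    for algo, model in models.items():
        for kw in lex.seeds:
            query = lex.representatives.get(kw, kw)
            query = query if query in model else kw
            for term, sim in model.most_similar(query, topn=top_k):
                if term in known:
                    continue
                prev = best.get(term)
                if prev is None or sim > prev.similarity:
                    best[term] = Candidate(term, kw, sim, algo)
    ranked = sorted(best.values(), key=lambda c: (-c.similarity, c.term))
    lex.candidates = ranked
    for c in ranked:
        lex.provenance.setdefault(c.term, PROVENANCE_EMBEDDING)
    return ranked


def read_decisions(path: Union[str, PathLike]) -> Dict[str, tuple]:
    """Read the dual-reviewer CSV ledger (term,reviewer_a,reviewer_b)."""
    decisions = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            decisions[row["term"]] = (row["reviewer_a"].strip().lower(),
                                      row["reviewer_b"].strip().lower())
    return decisions


def apply_validation(lex: Lexicon, decisions: Mapping[str, tuple]):
    """Retain only candidates both reviewers accepted.

    Returns ``(lexicon, summary)`` where summary reports the candidate
    count, accepted count and acceptance percentage (one decimal).
    Decisions naming unknown terms raise :class:`IntegrityError`.
    """
    candidate_terms = {c.term for c in lex.candidates}
    unknown = set(decisions) - candidate_terms
    if unknown:
        raise IntegrityError(f"decisions reference unknown terms: {sorted(unknown)[:5]}")
    validated = [c.term for c in lex.candidates
                 if decisions.get(c.term, ("reject", "reject")) == ("accept", "accept")]
    lex.validated_terms = validated
    for term in validated:
        lex.provenance[term] = PROVENANCE_VALIDATED
    n_cand = len(lex.candidates)
    summary = {
        "n_candidates": n_cand,
        "n_validated": len(validated),
        "acceptance_pct": round(100.0 * len(validated) / n_cand, 1) if n_cand else 0.0,
    }
    return lex, summary
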