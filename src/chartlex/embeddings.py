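"""Compact Word2Vec trainer (skip-gram and CBOW with negative sampling).

Deterministic by construction: a single numpy generator drives
initialization, shuffling and negative sampling, and training is
single-threaded vectorized minibatch SGD.  Intended for the moderate
corpora this pipeline trains on, where reproducibility matters more than
throughput.

Model sketch: each vocabulary word w has an input vector v_w and an output
vector u_w.  Skip-gram with negative sampling maximizes
``log s(v_c . u_o) + sum_neg log s(-v_c . u_n)`` over observed
(center c, context o) pairs within a symmetric window; CBOW predicts the
center word from the mean of the context input vectors.  Negatives are
drawn from the unigram distribution raised to 3/4.
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .config import EmbeddingConfig
from .errors import InputError
from .text import tokenize

_BATCH = 512
_NEG_TABLE_SIZE = 100_000


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class Word2VecModel:
    """Trained embedding table with cosine-similarity queries."""

    def __init__(self, vocab: Sequence[str], vectors: np.ndarray, config: EmbeddingConfig):
        self.vocab = list(vocab)
        self.vectors = vectors
        self.config = config
        self.index = {w: i for i, w in enumerate(self.vocab)}
        norms = np.linalg.norm(vectors, axis=1)
        norms[norms == 0] = 1.0
        self._unit = vectors / norms[:, None]

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def vector(self, word: str) -> np.ndarray:
        if word not in self.index:
            raise KeyError(word)
        return self.vectors[self.index[word]]

    def similarity(self, w1: str, w2: str) -> float:
        return float(self._unit[self.index[w1]] @ self._unit[self.index[w2]])

    def most_similar(self, word: str, topn: int = 10) -> list:
        """Nearest neighbours by cosine similarity, excluding the word itself.

        Returns an empty list when the word is out of vocabulary.
        """
        if word not in self.index:
            return []
        i = self.index[word]
        sims = self._unit @ self._unit[i]
        sims[i] = -np.inf
        order = np.argsort(-sims, kind="stable")[:topn]
        return [(self.vocab[j], float(sims[j])) for j in order]


def _build_vocab(token_sentences: list, min_count: int):
    counts = Counter(t for sent in token_sentences for t in sent)
    # frequency-descending, token ascending: stable, reproducible ordering
    vocab = sorted((w for w, c in counts.items() if c >= min_count),
                   key=lambda w: (-counts[w], w))
    return vocab, counts


def _negative_table(vocab, counts) -> np.ndarray:
    freq = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    freq /= freq.sum()
    cum = np.cumsum(freq)
    positions = (np.arange(_NEG_TABLE_SIZE) + 0.5) / _NEG_TABLE_SIZE
    return np.searchsorted(cum, positions).astype(np.int64)


def _lr_schedule(base: float, step: int, total: int) -> float:
    return base * max(1e-4, 1.0 - step / total)


def _train_sgns(pairs, W, Wp, neg_table, config, rng):
    n = len(pairs)
    total_steps = config.epochs * ((n + _BATCH - 1) // _BATCH)
    step = 0
    d = W.shape[1]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, _BATCH):
            lr = _lr_schedule(config.learning_rate, step, total_steps)
            step += 1
            batch = pairs[order[start:start + _BATCH]]
            centers, contexts = batch[:, 0], batch[:, 1]
            negs = neg_table[rng.integers(0, _NEG_TABLE_SIZE,
                                          size=(len(batch), config.negative))]
            v = W[centers]
            u_pos = Wp[contexts]
            u_neg = Wp[negs]
            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - 1.0
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))
            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(W, centers, -lr * grad_v)
            np.add.at(Wp, contexts, -lr * g_pos[:, None] * v)
            np.add.at(Wp, negs.reshape(-1),
                      (-lr * (g_neg[:, :, None] * v[:, None, :])).reshape(-1, d))


def _train_cbow(examples, ctx_matrix, ctx_mask, W, Wp, neg_table, config, rng):
    # examples: center ids; ctx_matrix: padded context ids; ctx_mask: 1 where valid
    n = len(examples)
    total_steps = config.epochs * ((n + _BATCH - 1) // _BATCH)
    step = 0
    d = W.shape[1]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, _BATCH):
            lr = _lr_schedule(config.learning_rate, step, total_steps)
            step += 1
            sel = order[start:start + _BATCH]
            centers = examples[sel]
            ctx = ctx_matrix[sel]
            mask = ctx_mask[sel]
            counts = mask.sum(axis=1)
            negs = neg_table[rng.integers(0, _NEG_TABLE_SIZE,
                                          size=(len(sel), config.negative))]
            h = (W[ctx] * mask[:, :, None]).sum(axis=1) / counts[:, None]
            u_pos = Wp[centers]
            u_neg = Wp[negs]
            g_pos = _sigmoid(np.einsum("bd,bd->b", h, u_pos)) - 1.0
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", h, u_neg))
            grad_h = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            # gradient w.r.t. each context vector is grad_h / |context|
            per_ctx = (grad_h / counts[:, None])[:, None, :] * mask[:, :, None]
            np.add.at(W, ctx.reshape(-1), (-lr * per_ctx).reshape(-1, d))
            np.add.at(Wp, centers, -lr * g_pos[:, None] * h)
            np.add.at(Wp, negs.reshape(-1),
                      (-lr * (g_neg[:, :, None] * h[:, None, :])).reshape(-1, d))


def train_embeddings(sentences: Iterable, config: EmbeddingConfig | None = None) -> Word2VecModel:
    """Train one Word2Vec model on tokenized (or raw-string) sentences.

    With ``min_count=1`` (the default) the vocabulary is exactly the set of
    unique tokens.  Identical sentences + config (including seed) yield
    identical vectors.
    """
    config = config or EmbeddingConfig()
    config.validate()
    token_sentences = [tokenize(s) if isinstance(s, str) else list(s) for s in sentences]
    token_sentences = [s for s in token_sentences if s]
    if not token_sentences:
        raise InputError("cannot train embeddings on an empty corpus")

    vocab, counts = _build_vocab(token_sentences, config.min_count)
    if not vocab:
        raise InputError("no token meets min_count")
    index = {w: i for i, w in enumerate(vocab)}
    rng = np.random.default_rng(config.seed)
    W = (rng.random((len(vocab), config.vector_dim)) - 0.5) / config.vector_dim
    Wp = np.zeros_like(W)
    neg_table = _negative_table(vocab, counts)

    id_sentences = [[index[t] for t in s if t in index] for s in token_sentences]
    id_sentences = [s for s in id_sentences if len(s) >= 2]
    if not id_sentences:  # nothing to predict; vectors stay at initialization
        return Word2VecModel(vocab, W, config)

    if config.algorithm == "skip-gram":
        pairs = []
        for ids in id_sentences:
            n = len(ids)
            for i in range(n):
                lo, hi = max(0, i - config.window), min(n, i + config.window + 1)
                pairs.extend((ids[i], ids[j]) for j in range(lo, hi) if j != i)
        _train_sgns(np.asarray(pairs, dtype=np.int64), W, Wp, neg_table, config, rng)
    else:
        centers, contexts = [], []
        width = 2 * config.window
        for ids in id_sentences:
            n = len(ids)
            for i in range(n):
                lo, hi = max(0, i - config.window), min(n, i + config.window + 1)
                ctx = [ids[j] for j in range(lo, hi) if j != i]
                centers.append(ids[i])
                contexts.append(ctx + [0] * (width - len(ctx)))
        true_lens = []
        for ids in id_sentences:
            n = len(ids)
            for i in range(n):
                lo, hi = max(0, i - config.window), min(n, i + config.window + 1)
                true_lens.append(hi - lo - 1)
        centers = np.asarray(centers, dtype=np.int64)
        ctx_matrix = np.asarray(contexts, dtype=np.int64)
        # padded slots sit after the true context entries; mask them out
        ctx_mask = (np.arange(width)[None, :] < np.asarray(true_lens)[:, None]).astype(float)
        _train_cbow(centers, ctx_matrix, ctx_mask, W, Wp, neg_table, config, rng)

    return Word2VecModel(vocab, W, config)
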