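"""Pretrained per-token atom embeddings (word2vec-style, trained on SMILES tokens).

Token sequences from SMILES strings are treated as sentences and embedded
with skip-gram + negative sampling so that tokens appearing in similar
chemical contexts get nearby vectors.  The trainer is deterministic under a
fixed seed.  Out-of-vocabulary tokens receive a small random vector hashed
from (token, oov_seed), so the fallback is stable across calls and
processes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np


@dataclass
class EmbeddingTable:
    """token -> d1-dim vector mapping with a seeded OOV fallback."""

    vocab: Dict[str, int]
    vectors: np.ndarray                 # |vocab| x d1, float32
    oov_seed: int = 0
    _oov_cache: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def d1(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, token: str) -> np.ndarray:
        idx = self.vocab.get(token)
        if idx is not None:
            return self.vectors[idx]
        vec = self._oov_cache.get(token)
        if vec is None:
            seed = zlib.crc32(f"{token}|{self.oov_seed}".encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(seed)
            vec = rng.uniform(-0.05, 0.05, self.d1).astype(np.float32)
            self._oov_cache[token] = vec
        return vec

    # -- serialization ----------------------------------------------------
    def save(self, vocab_path, vectors_path) -> None:
        with open(vocab_path, "w") as fh:
            for tok, _ in sorted(self.vocab.items(), key=lambda kv: kv[1]):
                fh.write(tok + "\n")
        np.save(vectors_path, self.vectors.astype(np.float32))

    @classmethod
    def load(cls, vocab_path, vectors_path, oov_seed: int = 0) -> "EmbeddingTable":
        with open(vocab_path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        vectors = np.load(vectors_path).astype(np.float32)
        return cls({t: i for i, t in enumerate(tokens)}, vectors, oov_seed)

    @classmethod
    def load_word2vec_text(cls, path, oov_seed: int = 0) -> "EmbeddingTable":
        """Load the standard word2vec text format (header line: count dim)."""
        vocab, rows = {}, []
        with open(path) as fh:
            header = fh.readline().split()
            dim = int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    continue
                vocab[parts[0]] = len(rows)
                rows.append(np.array(parts[1:], dtype=np.float32))
        return cls(vocab, np.stack(rows), oov_seed)


def embed_sequence(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """m x d1 matrix whose row t is the embedding of token t."""
    if len(tokens) < 1:
        raise ValueError("empty token sequence")
    return np.stack([table.lookup(t) for t in tokens])


def _scatter_mean_update(W: np.ndarray, rows: np.ndarray, deltas: np.ndarray) -> None:
    """W[rows] += deltas, averaging deltas that target the same row.

    Uses a one-hot matmul for the scatter: SMILES vocabularies are tiny, so
    the (batch x vocab) indicator is small and BLAS does the grouping.
    """
    uniq, inv, counts = np.unique(rows, return_inverse=True, return_counts=True)
    onehot = (inv[:, None] == np.arange(len(uniq))[None, :]).astype(deltas.dtype)
    acc = onehot.T @ deltas
    W[uniq] += (acc / counts[:, None]).astype(W.dtype)


def train_atom_embeddings(corpus: Sequence[Sequence[str]], d1: int = 100,
                          window: int = 5, epochs: int = 10, seed: int = 0,
                          negatives: int = 5, lr: float = 0.025,
                          min_lr: float = 1e-4) -> EmbeddingTable:
    """Train skip-gram-with-negative-sampling embeddings on token sentences.

    The vocabulary covers every token in the corpus (no frequency cutoff:
    SMILES token vocabularies are tiny).  Negative samples are drawn from
    the unigram distribution raised to 3/4, as in word2vec.  The learning
    rate decays linearly from ``lr`` to ``min_lr`` over all updates.
    """
    sentences = [list(s) for s in corpus if len(s) >= 1]
    if not sentences:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(seed)

    # vocabulary ordered by (-count, token) for determinism
    counts: Dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab_tokens = sorted(counts, key=lambda t: (-counts[t], t))
    vocab = {t: i for i, t in enumerate(vocab_tokens)}
    V = len(vocab)

    W_in = ((rng.random((V, d1)) - 0.5) / d1).astype(np.float32)
    W_out = np.zeros((V, d1), dtype=np.float32)

    freq = np.array([counts[t] for t in vocab_tokens], dtype=np.float64) ** 0.75
    noise_p = freq / freq.sum()

    encoded = [np.array([vocab[t] for t in sent], dtype=np.int64) for sent in sentences]

    # pre-count total pairs for the lr schedule (dynamic windows resampled per epoch)
    def epoch_pairs():
        centers, contexts = [], []
        for sent in encoded:
            L = len(sent)
            if L < 2:
                continue
            spans = rng.integers(1, window + 1, size=L)
            for pos in range(L):
                w = spans[pos]
                lo, hi = max(0, pos - w), min(L, pos + w + 1)
                for j in range(lo, hi):
                    if j != pos:
                        centers.append(sent[pos])
                        contexts.append(sent[j])
        return np.array(centers, dtype=np.int64), np.array(contexts, dtype=np.int64)

    all_epochs = [epoch_pairs() for _ in range(epochs)]
    total = sum(len(c) for c, _ in all_epochs)
    done = 0
    batch = 128  # SMILES vocabularies are tiny; small batches keep the
    # per-row mean-gradient close to sequential SGD
    for centers, contexts in all_epochs:
        order = rng.permutation(len(centers))
        centers, contexts = centers[order], contexts[order]
        negs = rng.choice(V, size=(len(centers), negatives), p=noise_p)
        for start in range(0, len(centers), batch):
            c = centers[start:start + batch]
            o = contexts[start:start + batch]
            B = len(c)
            cur_lr = max(min_lr, lr * (1.0 - done / max(total, 1)))
            done += B
            neg = negs[start:start + batch]
            vin = W_in[c]                                    # B x d
            upos = W_out[o]                                  # B x d
            uneg = W_out[neg]                                # B x k x d
            # dot products clipped: the logistic is saturated beyond +/-30 anyway
            dpos = np.clip(np.einsum("bd,bd->b", vin, upos), -30.0, 30.0)
            dneg = np.clip(np.einsum("bd,bkd->bk", vin, uneg), -30.0, 30.0)
            spos = 1.0 / (1.0 + np.exp(-dpos))
            sneg = 1.0 / (1.0 + np.exp(-dneg))
            gpos = (spos - 1.0)[:, None]                     # dL/d(score)
            gneg = sneg[:, :, None]
            grad_in = gpos * upos + np.einsum("bk,bkd->bd", sneg, uneg)
            # rows hit multiple times in a batch take the MEAN update, so a
            # tiny vocabulary cannot accumulate an unbounded step
            _scatter_mean_update(W_in, c, (-cur_lr * grad_in))
            _scatter_mean_update(W_out, o, (-cur_lr * gpos * vin))
            _scatter_mean_update(W_out, neg.ravel(),
                                 (-cur_lr * gneg * vin[:, None, :]).reshape(-1, vin.shape[1]))
    return EmbeddingTable(vocab, W_in, oov_seed=seed)
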