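"""k-mer word embeddings for DNA sequences.

Sequences are tokenized into overlapping k-mers ("words", stride 1) and a
skip-gram model with negative sampling learns a dense vector per word, the
word2vec construction adapted to DNA.  The trainer is a compact vectorized
numpy implementation: deterministic under a fixed seed, single worker.
Out-of-vocabulary words (unseen k-mers, or k-mers containing N) map to the
zero vector.  A final adaptive average pooling step makes every sequence's
embedded matrix the same height regardless of its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_WORD_BASES = frozenset("ACGT")


def tokenize_kmers(seq: str, k: int) -> list[str]:
    """Overlapping k-mer words of ``seq`` in order; ``L - k + 1`` of them.

    A sequence shorter than ``k`` yields an empty list (not an error): such
    elements simply contribute no words.
    """
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    seq = seq.upper()
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


def adaptive_pool(matrix: np.ndarray, pooled_length: int) -> np.ndarray:
    """Adaptive average pooling along axis 0 to exactly ``pooled_length`` rows.

    Bucket ``i`` averages input rows ``floor(i*n/P) .. ceil((i+1)*n/P)-1``;
    when ``n < P`` rows are repeated by the same rule.  An empty input pools
    to all zeros.
    """
    if pooled_length <= 0:
        raise ValidationError("pooled_length must be positive")
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    n = matrix.shape[0]
    if n == 0:
        return np.zeros((pooled_length, matrix.shape[1]))
    idx = np.arange(pooled_length)
    starts = (idx * n) // pooled_length
    ends = -((-(idx + 1) * n) // pooled_length)          # ceil division
    csum = np.vstack([np.zeros((1, matrix.shape[1])), np.cumsum(matrix, axis=0)])
    return (csum[ends] - csum[starts]) / (ends - starts)[:, None]


@dataclass
class KmerEmbeddingModel:
    """Fitted k-mer -> vector lookup with a fixed pooled output height."""

    k: int
    dim: int
    vocabulary: dict[str, int]
    vectors: np.ndarray                      # (V, dim)
    pooled_length: int = 1000

    def lookup(self, words: list[str]) -> np.ndarray:
        """Embed ``words`` row-wise; OOV words become zero rows."""
        out = np.zeros((len(words), self.dim))
        for i, w in enumerate(words):
            j = self.vocabulary.get(w)
            if j is not None:
                out[i] = self.vectors[j]
        return out


def _collect_pairs(sentences: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for arr in sentences:
        for off in range(1, window + 1):
            if arr.size <= off:
                continue
            centers.append(arr[:-off]); contexts.append(arr[off:])
            centers.append(arr[off:]);  contexts.append(arr[:-off])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def train_kmer_embedding(corpus, k: int, dim: int = 8, *, window: int = 5,
                         epochs: int = 2, negatives: int = 5,
                         max_pairs: int = 200_000, lr: float = 0.025,
                         pooled_length: int = 1000,
                         seed: int = 0) -> KmerEmbeddingModel:
    """Train skip-gram-with-negative-sampling vectors on tokenized sequences.

    ``corpus`` is a collection of word lists (see :func:`tokenize_kmers`).
    Words containing N are excluded from the vocabulary.  Training is
    deterministic for a fixed ``seed``.
    """
    sentences_words = [[w for w in sent if set(w) <= _WORD_BASES] for sent in corpus]
    all_words = sorted({w for sent in sentences_words for w in sent})
    if not all_words:
        raise ValidationError("empty corpus: no valid k-mer words to train on")
    vocab = {w: i for i, w in enumerate(all_words)}
    rng = np.random.default_rng(seed)

    sentences = [np.array([vocab[w] for w in sent], dtype=np.int64)
                 for sent in sentences_words if sent]
    centers, contexts = _collect_pairs(sentences, window)
    if centers.size > max_pairs:
        keep = rng.choice(centers.size, size=max_pairs, replace=False)
        centers, contexts = centers[keep], contexts[keep]

    counts = np.zeros(len(vocab))
    for sent in sentences:
        counts += np.bincount(sent, minlength=len(vocab))
    noise = counts ** 0.75
    noise /= noise.sum()

    v = len(vocab)
    w_in = (rng.random((v, dim)) - 0.5) / dim
    w_out = np.zeros((v, dim))

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))

    batch = 4096
    for _ in range(epochs):
        order = rng.permutation(centers.size)
        for lo in range(0, centers.size, batch):
            sel = order[lo:lo + batch]
            c, o = centers[sel], contexts[sel]
            negs = rng.choice(v, size=(sel.size, negatives), p=noise)
            vin = w_in[c]
            # positive context: gradient of -log sigma(u.v)
            pos = w_out[o]
            gpos = (sigmoid(np.einsum("bd,bd->b", vin, pos)) - 1.0) * lr
            # negative samples: gradient of -log sigma(-u.v)
            neg = w_out[negs]
            gneg = sigmoid(np.einsum("bd,bkd->bk", vin, neg)) * lr
            gin = gpos[:, None] * pos + np.einsum("bk,bkd->bd", gneg, neg)
            np.add.at(w_out, o, -gpos[:, None] * vin)
            np.add.at(w_out, negs.reshape(-1),
                      -(gneg[..., None] * vin[:, None, :]).reshape(-1, dim))
            np.add.at(w_in, c, -gin)

    return KmerEmbeddingModel(k=k, dim=dim, vocabulary=vocab, vectors=w_in,
                              pooled_length=pooled_length)


def encode_dna2vec(seq: str, model: KmerEmbeddingModel,
                   pooled_length: int | None = None) -> np.ndarray:
    """Embed ``seq`` word-by-word and pool to ``pooled_length x dim``."""
    words = tokenize_kmers(seq, model.k)
    embedded = model.lookup(words)
    target = pooled_length if pooled_length is not None else model.pooled_length
    if embedded.shape[0] == 0:
        return np.zeros((target, model.dim))
    return adaptive_pool(embedded, target)
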