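"""Skip-gram with negative sampling (SGNS), vectorized over mini-batches.

Word2vec-style training specialised for k-mer sentences: dynamic context
windows (the effective window size is drawn uniformly from 1..window per
center token), a unigram^0.75 noise distribution, a linearly decaying learning
rate, and mini-batch SGD where gradients of colliding rows within a batch are
summed.  Entirely deterministic for a fixed seed (single worker, no hogwild).
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from scipy import sparse

_NOISE_EXPONENT = 0.75


def build_vocab(
    sentences: Sequence[Sequence[str]], min_count: int = 1
) -> Tuple[List[str], dict, np.ndarray]:
    """Count tokens and keep those with frequency ≥ min_count.

    Returns (tokens, token→index map, counts), ordered by descending count
    with ties broken lexicographically so indices are reproducible.
    """
    counts: dict = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    index = {t: i for i, t in enumerate(kept)}
    freq = np.array([counts[t] for t in kept], dtype=np.int64)
    return kept, index, freq


def encode_sentences(
    sentences: Sequence[Sequence[str]], index: dict
) -> List[np.ndarray]:
    """Map sentences to int32 index arrays, dropping out-of-vocabulary tokens."""
    return [
        np.array([index[t] for t in sent if t in index], dtype=np.int32)
        for sent in sentences
    ]


def _epoch_pairs(
    encoded: List[np.ndarray], window: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """(center, context) index pairs for one epoch, shuffled.

    Each center i gets a dynamic radius b_i ~ U{1..window}; contexts are the
    tokens within that radius.
    """
    centers, contexts = [], []
    for sent in encoded:
        n = len(sent)
        if n < 2:
            continue
        radius = rng.integers(1, window + 1, size=n)
        for d in range(1, window + 1):
            left = np.arange(n - d)  # pair (i, i+d)
            m = radius[left] >= d
            centers.append(sent[left[m]])
            contexts.append(sent[left[m] + d])
            m2 = radius[left + d] >= d  # pair (i+d, i)
            centers.append(sent[left[m2] + d])
            contexts.append(sent[left[m2]])
    if not centers:
        raise ValueError("corpus yields no skip-gram pairs (sentences too short?)")
    c = np.concatenate(centers)
    o = np.concatenate(contexts)
    perm = rng.permutation(len(c))
    return c[perm], o[perm]


def _scatter_sub(M: np.ndarray, rows: np.ndarray, grads: np.ndarray) -> None:
    """``M[rows] -= grads`` with duplicate rows summed (order-independent).

    Equivalent to ``np.subtract.at`` but much faster: duplicate rows are
    summed by a sparse one-hot product, then one subtraction per unique row.
    Touches only the referenced rows, so cost is independent of vocab size.
    """
    uniq, inverse = np.unique(rows, return_inverse=True)
    n = len(rows)
    onehot = sparse.csr_matrix(
        (np.ones(n, dtype=grads.dtype), inverse, np.arange(n + 1, dtype=np.int64)),
        shape=(n, len(uniq)),
    )
    M[uniq] -= onehot.T @ grads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.clip(x, -30.0, 30.0, out=out)
    np.negative(out, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def train_sgns(
    sentences: Sequence[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    min_count: int = 1,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    seed: int = 0,
    batch_size: int = 4096,
) -> Tuple[List[str], np.ndarray]:
    """Train SGNS embeddings; returns (vocabulary tokens, V×dim float32 matrix).

    Input vectors (the center/"word" matrix) are returned as the embeddings,
    following word2vec convention.
    """
    if not sentences:
        raise ValueError("empty corpus")
    tokens, index, freq = build_vocab(sentences, min_count=min_count)
    if not tokens:
        raise ValueError("vocabulary is empty after min_count filtering")
    encoded = encode_sentences(sentences, index)
    vocab_size = len(tokens)

    rng = np.random.default_rng(seed)
    W = ((rng.random((vocab_size, dim)) - 0.5) / dim).astype(np.float32)
    C = np.zeros((vocab_size, dim), dtype=np.float32)

    noise = freq.astype(np.float64) ** _NOISE_EXPONENT
    noise_cdf = np.cumsum(noise / noise.sum())

    # Expected pair count for the LR schedule: E[b] = (window+1)/2 per side.
    n_tokens = sum(len(s) for s in encoded if len(s) >= 2)
    total_expected = max(1, int(epochs * n_tokens * (window + 1)))
    processed = 0

    for _epoch in range(epochs):
        centers, contexts = _epoch_pairs(encoded, window, rng)
        n_pairs = len(centers)
        neg_draws = np.searchsorted(
            noise_cdf, rng.random((n_pairs, negative))
        ).astype(np.int32)
        for start in range(0, n_pairs, batch_size):
            stop = min(start + batch_size, n_pairs)
            lr = max(min_alpha, alpha * (1.0 - processed / total_expected))
            c = centers[start:stop]
            o = contexts[start:stop]
            negs = neg_draws[start:stop]

            Wc = W[c]                      # (B, dim)
            Co = C[o]                      # (B, dim)
            Cn = C[negs]                   # (B, K, dim)

            g_pos = (_sigmoid(np.einsum("bd,bd->b", Wc, Co)) - 1.0) * lr
            g_neg = _sigmoid(np.einsum("bkd,bd->bk", Cn, Wc)) * lr

            grad_w = g_pos[:, None] * Co + np.einsum("bk,bkd->bd", g_neg, Cn)
            _scatter_sub(W, c, grad_w)
            grad_c = np.concatenate(
                [
                    g_pos[:, None] * Wc,
                    (g_neg[:, :, None] * Wc[:, None, :]).reshape(-1, dim),
                ]
            )
            _scatter_sub(C, np.concatenate([o, negs.ravel()]), grad_c)
            processed += stop - start

    return tokens, W
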