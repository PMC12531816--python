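"""Sequence feature representations: bidirectional k-mers, skip-gram
embeddings with average pooling, and the k-mer frequency-vector baseline.

A sequence is tokenized into k-mers with a sliding window of length ``k`` and
stride ``L`` in two orientations: as given (forward) and reverse-complemented.
Each orientation is a "sentence" for skip-gram training.  A trained model maps
each k-mer to an N-dimensional vector; a sequence is pooled to the
concatenation of the forward-token mean and the reverse-token mean (2N values,
200 at the default N=100).

The k-mer frequency vector (KFV) — the 4^k count vector classical
alignment-free classifiers use — is provided as the high-dimensional baseline
the embedding is compared against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _skipgram
from .seqio import Dataset, load_word2vec, save_word2vec

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(sequence: str) -> str:
    """Reverse complement over the strict DNA alphabet; an involution."""
    if not set(sequence) <= _BASE_CODE.keys():
        bad = sorted(set(sequence) - _BASE_CODE.keys())
        raise ValueError(f"non-ACGT character(s) in sequence: {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class TokenizedSeq:
    """K-mer tokens of one sequence in both orientations."""

    k: int
    stride: int
    forward_tokens: List[str]
    reverse_tokens: List[str]


def n_windows(length: int, k: int, stride: int) -> int:
    """Number of sliding windows: floor((len − k)/stride) + 1."""
    return (length - k) // stride + 1


def _windows(sequence: str, k: int, stride: int) -> List[str]:
    return [sequence[i : i + k] for i in range(0, len(sequence) - k + 1, stride)]


def tokenize_bikmer(
    sequence: str,
    k: int,
    stride: int = 1,
    reverse_mode: str = "revcomp",
    record_id: str = "?",
) -> TokenizedSeq:
    """Tokenize one sequence into forward and reverse k-mer lists.

    ``reverse_mode`` is "revcomp" (biological convention, default) or
    "reverse" (plain string reversal).
    """
    if k < 1 or stride < 1:
        raise ValueError("k and stride must be ≥ 1")
    if len(sequence) < k:
        raise ValueError(
            f"record {record_id!r}: sequence length {len(sequence)} < k={k}"
        )
    if reverse_mode == "revcomp":
        other = revcomp(sequence)
    elif reverse_mode == "reverse":
        other = sequence[::-1]
    else:
        raise ValueError(f"unknown reverse_mode {reverse_mode!r}")
    return TokenizedSeq(
        k=k,
        stride=stride,
        forward_tokens=_windows(sequence, k, stride),
        reverse_tokens=_windows(other, k, stride),
    )


def build_corpus(
    dataset: Union[Dataset, Sequence[str]],
    k: int,
    stride: int = 1,
    reverse_mode: str = "revcomp",
) -> List[List[str]]:
    """Two sentences per record (forward then reverse), in dataset order."""
    sentences: List[List[str]] = []
    for rec in dataset:
        seq = rec if isinstance(rec, str) else rec.sequence
        rid = "?" if isinstance(rec, str) else rec.id
        tok = tokenize_bikmer(seq, k, stride, reverse_mode, record_id=rid)
        sentences.append(tok.forward_tokens)
        sentences.append(tok.reverse_tokens)
    return sentences


@dataclass
class EmbeddingModel:
    """A k-mer → N-dim vector table trained by skip-gram."""

    k: int
    dim: int
    tokens: List[str]
    vectors: np.ndarray  # (vocab, dim) float32
    train_params: dict = field(default_factory=dict)
    index: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.tokens)}

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def save(self, path) -> None:
        save_word2vec(path, self.tokens, self.vectors)

    @classmethod
    def load(cls, path, k: int, train_params: Optional[dict] = None) -> "EmbeddingModel":
        tokens, vectors = load_word2vec(path)
        return cls(k=k, dim=vectors.shape[1], tokens=tokens, vectors=vectors,
                   train_params=train_params or {})


def train_embedding(
    corpus: Sequence[Sequence[str]],
    k: int,
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    min_count: int = 1,
    seed: int = 0,
) -> EmbeddingModel:
    """Train skip-gram-with-negative-sampling embeddings on a k-mer corpus.

    Deterministic for a fixed seed (single-worker SGD).
    """
    tokens, vectors = _skipgram.train_sgns(
        corpus,
        dim=dim,
        window=window,
        epochs=epochs,
        negative=negative,
        min_count=min_count,
        seed=seed,
    )
    params = dict(window=window, epochs=epochs, negative=negative,
                  min_count=min_count, seed=seed)
    return EmbeddingModel(k=k, dim=dim, tokens=tokens, vectors=vectors,
                          train_params=params)


@dataclass
class SequenceVector:
    """2N pooled values plus out-of-vocabulary token counts per direction."""

    values: np.ndarray
    k: int
    n_oov_forward: int = 0
    n_oov_reverse: int = 0


def _pool(tokens: Sequence[str], model: EmbeddingModel) -> Tuple[np.ndarray, int]:
    rows = [model.index[t] for t in tokens if t in model.index]
    n_oov = len(tokens) - len(rows)
    if not rows:
        return np.zeros(model.dim, dtype=np.float32), n_oov
    return model.vectors[rows].mean(axis=0), n_oov


def embed_sequence(tokenized: TokenizedSeq, model: EmbeddingModel) -> SequenceVector:
    """Mean-pool each direction's in-vocabulary tokens and concatenate.

    A direction whose tokens are all out-of-vocabulary contributes an all-zero
    half (logged at debug level); OOV tokens are dropped and counted.
    """
    if tokenized.k != model.k:
        raise ValueError(f"tokenized k={tokenized.k} != model k={model.k}")
    fwd, oov_f = _pool(tokenized.forward_tokens, model)
    rev, oov_r = _pool(tokenized.reverse_tokens, model)
    if oov_f == len(tokenized.forward_tokens) or oov_r == len(tokenized.reverse_tokens):
        logger.debug("a direction is fully out-of-vocabulary; zero half-vector used")
    return SequenceVector(
        values=np.concatenate([fwd, rev]),
        k=model.k,
        n_oov_forward=oov_f,
        n_oov_reverse=oov_r,
    )


def embed_multi_k(
    sequence: str,
    models: Sequence[EmbeddingModel],
    stride: int = 1,
    reverse_mode: str = "revcomp",
) -> np.ndarray:
    """Concatenate per-k sequence vectors in ascending-k order (hybrid k)."""
    ks = [m.k for m in models]
    if len(set(ks)) != len(ks):
        raise ValueError(f"duplicate k among models: {sorted(ks)}")
    parts = []
    for model in sorted(models, key=lambda m: m.k):
        tok = tokenize_bikmer(sequence, model.k, stride, reverse_mode)
        parts.append(embed_sequence(tok, model).values)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# KFV baseline


@dataclass
class KFV:
    """4^k k-mer counts (lexicographic order over A<C<G<T), optionally
    normalized to frequencies."""

    k: int
    counts: np.ndarray
    normalized: bool


def kfv(sequence: str, k: int, normalize: bool = False, stride: int = 1) -> KFV:
    """Forward-orientation k-mer frequency vector of length 4^k."""
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    codes = np.array([_BASE_CODE[b] for b in sequence], dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    starts = np.arange(0, len(sequence) - k + 1, stride)
    window_codes = (codes[starts[:, None] + np.arange(k)] * weights).sum(axis=1)
    counts = np.bincount(window_codes, minlength=4**k).astype(np.float64)
    if normalize:
        counts = counts / counts.sum()
    return KFV(k=k, counts=counts, normalized=normalize)


# ---------------------------------------------------------------------------
# sklearn-style transformers


class BiKmerWord2Vec(BaseEstimator, TransformerMixin):
    """Transformer: raw sequences → 2N-dim bidirectional skip-gram vectors.

    fit(X) trains the embedding on X's Bi-kmer corpus; transform(X) pools each
    sequence into a ``(len(X), 2*n_dims)`` array.  X is a sequence of ACGT
    strings (or objects with a ``.sequence`` attribute).
    """

    def __init__(self, k=7, n_dims=100, window=5, epochs=5, negative=5,
                 min_count=1, stride=1, reverse_mode="revcomp", seed=0):
        self.k = k
        self.n_dims = n_dims
        self.window = window
        self.epochs = epochs
        self.negative = negative
        self.min_count = min_count
        self.stride = stride
        self.reverse_mode = reverse_mode
        self.seed = seed

    def fit(self, X, y=None):
        corpus = build_corpus(X, self.k, self.stride, self.reverse_mode)
        self.model_ = train_embedding(
            corpus, k=self.k, dim=self.n_dims, window=self.window,
            epochs=self.epochs, negative=self.negative,
            min_count=self.min_count, seed=self.seed,
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("BiKmerWord2Vec is not fitted")
        out = np.empty((len(X), 2 * self.n_dims), dtype=np.float32)
        for i, rec in enumerate(X):
            seq = rec if isinstance(rec, str) else rec.sequence
            tok = tokenize_bikmer(seq, self.k, self.stride, self.reverse_mode)
            out[i] = embed_sequence(tok, self.model_).values
        return out


class KmerFrequencyVectorizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: sequences → 4^k KFV matrix (the baseline)."""

    def __init__(self, k=7, normalize=True, stride=1):
        self.k = k
        self.normalize = normalize
        self.stride = stride

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for rec in X:
            seq = rec if isinstance(rec, str) else rec.sequence
            rows.append(kfv(seq, self.k, self.normalize, self.stride).counts)
        return np.asarray(rows)
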