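"""Skip-gram with negative sampling over a walk corpus.

A compact, vectorized word2vec-style trainer: input/output vector tables,
unigram^0.75 negative-sampling distribution, linearly decaying learning
rate, minibatch SGD with exact scatter-adds. Single-threaded and fully
deterministic under a fixed seed, which the reproducibility contract of the
pipeline relies on.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def build_vocab(walks: Sequence[Sequence[str]]) -> Tuple[list, dict, np.ndarray]:
    """Sorted vocabulary, token->index map, and token counts."""
    counts: dict = {}
    for walk in walks:
        for tok in walk:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(counts)
    index = {tok: i for i, tok in enumerate(vocab)}
    freq = np.array([counts[tok] for tok in vocab], dtype=np.float64)
    return vocab, index, freq


def _skipgram_pairs(walks, index, window: int) -> Tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks:
        idx = np.fromiter((index[t] for t in walk), dtype=np.int32, count=len(walk))
        n = len(idx)
        for d in range(1, min(window, n - 1) + 1):
            centers.append(idx[:-d]); contexts.append(idx[d:])
            centers.append(idx[d:]); contexts.append(idx[:-d])
    if not centers:
        return np.empty(0, np.int32), np.empty(0, np.int32)
    return np.concatenate(centers), np.concatenate(contexts)


def train_sgns(
    walks: Sequence[Sequence[str]],
    dims: int = 128,
    window: int = 10,
    epochs: int = 1,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    batch: int = 4096,
    seed: int = 0,
) -> Tuple[list, np.ndarray]:
    """Train embeddings; returns (vocabulary, input-vector matrix).

    If ``dims`` >= vocabulary size a warning is emitted (the embedding is
    then not a compression), but training proceeds.
    """
    vocab, index, freq = build_vocab(walks)
    n = len(vocab)
    if n == 0:
        raise ValueError("empty walk corpus")
    if dims >= n:
        import warnings

        warnings.warn(f"dims={dims} >= vocabulary size {n}")
    rng = np.random.default_rng(seed)
    W_in = (rng.random((n, dims)) - 0.5) / dims
    W_out = np.zeros((n, dims))

    noise = freq ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    centers, contexts = _skipgram_pairs(walks, index, window)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("no training pairs (walks too short)")
    total = n_pairs * epochs
    done = 0
    labels = np.zeros((1, negative + 1))
    labels[0, 0] = 1.0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            sel = order[lo : lo + batch]
            c = centers[sel]
            B = len(c)
            # column 0: true context; rest: unigram^0.75 negatives
            T = np.empty((B, negative + 1), dtype=np.int64)
            T[:, 0] = contexts[sel]
            T[:, 1:] = np.searchsorted(noise_cdf, rng.random((B, negative)))
            lr = alpha + (min_alpha - alpha) * (done / total)
            Vc = W_in[c]
            U = W_out[T]
            g = (_sigmoid(np.einsum("bd,bkd->bk", Vc, U)) - labels) * lr
            dV = np.einsum("bk,bkd->bd", g, U)
            dU = g[:, :, None] * Vc[:, None, :]
            np.add.at(W_in, c, -dV)
            np.add.at(W_out, T.reshape(-1), -dU.reshape(-1, dims))
            done += B
    return vocab, W_in
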