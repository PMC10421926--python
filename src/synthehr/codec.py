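"""Categorical feature codec: one-hot blocks <-> compact embeddings.

Each categorical feature gets one indicator slot per category plus an
explicit "missing" slot, so unobserved entries have a well-defined
encoding.  A shared MLP encoder maps the concatenated one-hot blocks to a
``d_c``-dimensional embedding (tanh-bounded so downstream reconstruction
losses are on a common scale), and one linear-softmax head per feature
maps the embedding back to a probability vector over its categories plus
the missing slot.  Encoder and heads are trained jointly on the summed
per-head softmax cross entropy.  Separate codecs are used for static and
temporal scopes; the temporal codec is applied per step with shared
weights.

An :class:`IdentityCodec` passes the raw one-hot block straight through —
the "no categorical embedding" ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import MLP, Adam, Linear, Module, Tensor, concat, grad, logsumexp, matmul, tsum

MISSING = -1


def one_hot(codes: np.ndarray, n_categories: int) -> np.ndarray:
    """Indicator block with an extra missing slot; one slot set per entry.

    ``codes`` holds vocabulary indices with -1 for missing.  Output width is
    ``n_categories + 1``; the final slot marks missing.
    """
    codes = np.asarray(codes)
    if np.any(codes >= n_categories):
        bad = np.unique(codes[codes >= n_categories])
        raise ValueError(f"codes out of vocabulary (size {n_categories}): {bad}")
    out = np.zeros(codes.shape + (n_categories + 1,))
    idx = np.where(codes >= 0, codes, n_categories)
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return out


def one_hot_block(codes: np.ndarray, vocab_sizes: list[int]) -> np.ndarray:
    """Concatenate per-feature one-hot blocks along the last axis."""
    if not vocab_sizes:
        return np.zeros(codes.shape[:-1] + (0,))
    blocks = [one_hot(codes[..., k], V) for k, V in enumerate(vocab_sizes)]
    return np.concatenate(blocks, axis=-1)


@dataclass
class CodecTrainingConfig:
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 1e-2
    seed: int = 0


class CategoricalCodec(Module):
    """Trained encoder + multi-head decoder for one categorical scope."""

    def __init__(self, scope: str, vocab_sizes: list[int], d_c: int,
                 rng: np.random.Generator, hidden: int | None = None):
        if not vocab_sizes:
            raise ValueError("codec needs at least one categorical feature")
        if d_c < 1:
            raise ValueError("embedding dimension must be >= 1")
        self.scope = scope
        self.vocab_sizes = list(vocab_sizes)
        self.d_c = d_c
        self.input_width = sum(V + 1 for V in vocab_sizes)
        hidden = hidden if hidden is not None else 2 * d_c
        self.encoder = MLP([self.input_width, hidden, d_c], rng, output_activation="tanh")
        self.heads = [Linear(d_c, V + 1, rng) for V in vocab_sizes]

    @property
    def out_dim(self) -> int:
        return self.d_c

    def encode(self, onehot: np.ndarray) -> np.ndarray:
        """One-hot block (n, input_width) -> embeddings (n, d_c)."""
        if onehot.shape[-1] != self.input_width:
            raise ValueError(
                f"{self.scope} codec expects one-hot width {self.input_width}, "
                f"got {onehot.shape[-1]} (scope mismatch?)"
            )
        flat = onehot.reshape(-1, onehot.shape[-1])
        emb = self.encoder(Tensor(flat)).data
        return emb.reshape(onehot.shape[:-1] + (self.d_c,))

    def head_probs(self, embeddings: np.ndarray) -> list[np.ndarray]:
        """Per-feature probability vectors over V_k + 1 slots (softmax)."""
        flat = Tensor(embeddings.reshape(-1, self.d_c))
        probs = []
        for head in self.heads:
            logits = head(flat).data
            z = logits - logits.max(axis=-1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=-1, keepdims=True)
            probs.append(p.reshape(embeddings.shape[:-1] + (p.shape[-1],)))
        return probs

    def decode(self, embeddings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Embeddings -> (codes with -1 for missing, missing-flag mask).

        Per head, argmax over the V_k+1 slots; ties break to the lower
        index, and the missing slot (last) yields code -1 / mask 0.
        """
        K = len(self.vocab_sizes)
        shape = embeddings.shape[:-1]
        codes = np.zeros(shape + (K,), dtype=np.int64)
        observed = np.zeros(shape + (K,), dtype=np.uint8)
        for k, p in enumerate(self.head_probs(embeddings)):
            top = np.argmax(p, axis=-1)
            is_missing = top == self.vocab_sizes[k]
            codes[..., k] = np.where(is_missing, MISSING, top)
            observed[..., k] = (~is_missing).astype(np.uint8)
        return codes, observed

    def decode_forced(self, embeddings: np.ndarray) -> np.ndarray:
        """Argmax over category slots only (missing slot excluded)."""
        K = len(self.vocab_sizes)
        codes = np.zeros(embeddings.shape[:-1] + (K,), dtype=np.int64)
        for k, p in enumerate(self.head_probs(embeddings)):
            codes[..., k] = np.argmax(p[..., : self.vocab_sizes[k]], axis=-1)
        return codes

    # training ------------------------------------------------------
    def _loss(self, onehot: np.ndarray) -> Tensor:
        """Sum over heads of softmax cross entropy, averaged over the batch."""
        x = Tensor(onehot)
        emb = self.encoder(x)
        total = Tensor(0.0)
        offset = 0
        n = onehot.shape[0]
        for k, (head, V) in enumerate(zip(self.heads, self.vocab_sizes)):
            target = Tensor(onehot[:, offset: offset + V + 1])
            logits = head(emb)
            ce = logsumexp(logits, axis=-1) - tsum(logits * target, axis=-1)
            total = total + tsum(ce) * Tensor(1.0 / n)
            offset += V + 1
        return total


def train_codec(
    onehot: np.ndarray,
    vocab_sizes: list[int],
    d_c: int | None = None,
    config: CodecTrainingConfig | None = None,
    scope: str = "static",
) -> tuple[CategoricalCodec, list[float]]:
    """Fit a codec on stacked one-hot blocks; returns (codec, loss history)."""
    config = config or CodecTrainingConfig()
    if d_c is None:
        d_c = min(16, max(1, int(np.ceil(sum(vocab_sizes) / 2))))
    input_width = sum(V + 1 for V in vocab_sizes)
    if d_c >= input_width:
        import warnings

        warnings.warn(f"embedding dim {d_c} >= one-hot width {input_width}: no compression")
    rng = np.random.default_rng(config.seed)
    onehot = onehot.reshape(-1, onehot.shape[-1])
    codec = CategoricalCodec(scope, vocab_sizes, d_c, rng)
    opt = Adam(codec.parameters(), lr=config.learning_rate)
    history: list[float] = []
    n = onehot.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = onehot[order[start: start + config.batch_size]]
            loss = codec._loss(batch)
            grads = grad(loss, codec.parameters())
            opt.step([g.data for g in grads])
            epoch_loss += float(loss.data) * batch.shape[0]
        history.append(epoch_loss / n)
    return codec, history


class IdentityCodec:
    """Pass-through codec: the embedding IS the one-hot block."""

    def __init__(self, scope: str, vocab_sizes: list[int]):
        self.scope = scope
        self.vocab_sizes = list(vocab_sizes)
        self.d_c = sum(V + 1 for V in vocab_sizes)
        self.input_width = self.d_c

    @property
    def out_dim(self) -> int:
        return self.d_c

    def encode(self, onehot: np.ndarray) -> np.ndarray:
        return np.array(onehot, dtype=np.float64)

    def head_probs(self, embeddings: np.ndarray) -> list[np.ndarray]:
        probs = []
        offset = 0
        for V in self.vocab_sizes:
            block = embeddings[..., offset: offset + V + 1]
            block = np.clip(block, 0.0, None)
            denom = block.sum(axis=-1, keepdims=True)
            denom[denom == 0] = 1.0
            probs.append(block / denom)
            offset += V + 1
        return probs

    def decode(self, embeddings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        K = len(self.vocab_sizes)
        shape = embeddings.shape[:-1]
        codes = np.zeros(shape + (K,), dtype=np.int64)
        observed = np.zeros(shape + (K,), dtype=np.uint8)
        for k, p in enumerate(self.head_probs(embeddings)):
            top = np.argmax(p, axis=-1)
            is_missing = top == self.vocab_sizes[k]
            codes[..., k] = np.where(is_missing, MISSING, top)
            observed[..., k] = (~is_missing).astype(np.uint8)
        return codes, observed

    def decode_forced(self, embeddings: np.ndarray) -> np.ndarray:
        K = len(self.vocab_sizes)
        codes = np.zeros(embeddings.shape[:-1] + (K,), dtype=np.int64)
        for k, p in enumerate(self.head_probs(embeddings)):
            codes[..., k] = np.argmax(p[..., : self.vocab_sizes[k]], axis=-1)
        return codes
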