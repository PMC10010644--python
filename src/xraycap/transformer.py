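"""Decoder-only transformer language model over BPE subwords.

A GPT-style stack: learned token + positional embeddings, pre-norm
blocks of masked (causal) multi-head self-attention and a GELU
feed-forward network, and a linear head producing next-token logits.
The causal mask guarantees position t depends only on positions <= t.

The model is fine-tuned self-supervised on report text (next-token
cross-entropy over fixed-length blocks, gradient-norm clipping) and
continues a seed report: a start-of-continuation marker is appended to
the seed, K-beam search runs until the end-of-text token, and the
continuation returned is the second-best completed hypothesis (falling
back to the best when k = 1 or only one hypothesis completes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, log_softmax, no_grad, softmax
from .bpe import BpeModel, bpe_decode, bpe_encode
from .search import beam_search


@dataclass
class TransformerConfig:
    vocab_size: int
    layers: int = 2
    heads: int = 2
    model_dim: int = 128
    ff_dim: int = 512
    block_size: int = 1024      # scaled down to 256 in the desk profile
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.model_dim % self.heads != 0:
            raise ValueError("model_dim must be divisible by heads")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")


class CausalSelfAttention(nn.Module):
    def __init__(self, cfg: TransformerConfig, rng):
        super().__init__()
        d = cfg.model_dim
        self.qkv = nn.Linear(d, 3 * d, rng)
        self.proj = nn.Linear(d, d, rng)
        self.heads = cfg.heads
        self.head_dim = d // cfg.heads

    def forward(self, x: Tensor) -> Tensor:
        B, T, d = x.shape
        H, hd = self.heads, self.head_dim
        qkv = self.qkv(x)                                # (B, T, 3d)
        q = qkv[:, :, 0 * d:1 * d].reshape((B, T, H, hd)).transpose((0, 2, 1, 3))
        k = qkv[:, :, 1 * d:2 * d].reshape((B, T, H, hd)).transpose((0, 2, 1, 3))
        v = qkv[:, :, 2 * d:3 * d].reshape((B, T, H, hd)).transpose((0, 2, 1, 3))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(hd))
        mask = np.triu(np.full((T, T), -1e30), k=1)      # forbid future positions
        scores = scores + Tensor(mask)
        att = softmax(scores, axis=-1)                   # rows renormalise under mask
        out = att @ v                                    # (B, H, T, hd)
        out = out.transpose((0, 2, 1, 3)).reshape((B, T, d))
        return self.proj(out)


class Block(nn.Module):
    """One pre-norm causal block: masked self-attention + feed-forward."""

    def __init__(self, cfg: TransformerConfig, rng):
        super().__init__()
        self.ln1 = nn.LayerNorm(cfg.model_dim)
        self.attn = CausalSelfAttention(cfg, rng)
        self.ln2 = nn.LayerNorm(cfg.model_dim)
        self.fc1 = nn.Linear(cfg.model_dim, cfg.ff_dim, rng)
        self.fc2 = nn.Linear(cfg.ff_dim, cfg.model_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).gelu())


class GptLm(nn.Module):
    def __init__(self, cfg: TransformerConfig, rng=None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.tok_emb = nn.Embedding(cfg.vocab_size, cfg.model_dim, rng)
        self.pos_emb = nn.parameter(
            rng.normal(0.0, 0.02, size=(cfg.block_size, cfg.model_dim)))
        self.blocks = [Block(cfg, rng) for _ in range(cfg.layers)]
        self.ln_f = nn.LayerNorm(cfg.model_dim)
        self.head = nn.Linear(cfg.model_dim, cfg.vocab_size, rng, bias=False)

    def embed(self, ids) -> Tensor:
        """Token embedding plus learned positional encoding, (B, T, d)."""
        ids = np.asarray(ids, dtype=np.int64)
        if ids.ndim == 1:
            ids = ids[None]
        T = ids.shape[1]
        if T > self.cfg.block_size:
            raise ValueError(f"sequence length {T} exceeds block size "
                             f"{self.cfg.block_size}")
        return self.tok_emb(ids) + self.pos_emb[np.arange(T)]

    def forward(self, ids) -> Tensor:
        """(B, T) ids -> (B, T, vocab) next-token logits."""
        x = self.embed(ids)
        for block in self.blocks:
            x = block(x)
        return self.head(self.ln_f(x))

    def next_log_probs(self, prefix_ids) -> np.ndarray:
        """Log-probabilities of the next token after ``prefix_ids``."""
        prefix = list(prefix_ids)[-self.cfg.block_size:]
        with no_grad():
            logits = self.forward(np.asarray(prefix, dtype=np.int64))
            return log_softmax(logits[:, -1, :], axis=-1).data[0]


def _blockify(ids: np.ndarray, block_size: int) -> np.ndarray:
    """Chop a flat id stream into (num_blocks, <=block_size+1) windows."""
    span = block_size + 1        # inputs + shifted targets
    if len(ids) <= span:
        return np.asarray(ids, dtype=np.int64)[None, :]
    n = (len(ids) - 1) // block_size
    rows = [ids[i * block_size: i * block_size + span] for i in range(n)]
    rows = [r for r in rows if len(r) >= 2]
    width = max(len(r) for r in rows)
    rows = [r for r in rows if len(r) == width]
    return np.asarray(rows, dtype=np.int64)


def lm_loss(model: GptLm, batch: np.ndarray) -> Tensor:
    """Mean next-token cross-entropy over a (B, T+1) id batch."""
    inputs, targets = batch[:, :-1], batch[:, 1:]
    logits = model.forward(inputs)                       # (B, T, V)
    B, T, V = logits.shape
    logp = log_softmax(logits, axis=-1)
    flat = logp.reshape((B * T, V))
    picked = flat[np.arange(B * T), targets.reshape(-1)]
    return -picked.mean()


def lm_finetune(model: GptLm, corpus_ids, epochs: int, lr: float = 5e-5,
                grad_clip: float = 1.0, batch_size: int = 4, seed: int = 0,
                adam_eps: float = 1e-8, log_every: int = 0) -> list:
    """Self-supervised LM fine-tuning on a BPE-encoded corpus.

    Gradients with global norm above ``grad_clip`` are rescaled to the
    threshold (a threshold of 0 freezes the model).  Returns the
    per-epoch mean training loss.
    """
    corpus_ids = np.asarray(list(corpus_ids), dtype=np.int64)
    if corpus_ids.size < 2:
        raise ValueError("corpus too small to form a single prediction")
    blocks = _blockify(corpus_ids, model.cfg.block_size)
    rng = np.random.default_rng(seed)
    opt = nn.Adam([p for p in model.parameters() if p.requires_grad],
                  lr=lr, eps=adam_eps)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(blocks))
        losses = []
        for lo in range(0, len(blocks), batch_size):
            batch = blocks[order[lo:lo + batch_size]]
            loss = lm_loss(model, batch)
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(model.parameters(), grad_clip)
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if log_every and (epoch + 1) % log_every == 0:
            print(f"[train-lm] epoch {epoch + 1}/{epochs} loss {history[-1]:.4f}")
    return history


def continuation_corpus(texts, bpe_model: BpeModel, splits=(2, 3)) -> list:
    """BPE id stream teaching the start-of-continuation marker.

    Each document contributes a plain copy plus copies with the marker
    inserted at word-boundary split points (halves, thirds, ...), all
    terminated by end-of-text, so the LM learns that the marker simply
    precedes the rest of the report — the hand-off convention used when
    the captioner's seed is continued.
    """
    ids = []
    for text in texts:
        words = text.split()
        # marker-split copies first: with learned positional embeddings the
        # split context then occupies the same positions it will occupy at
        # inference time (a fresh block starting at the seed)
        for parts in splits:
            for j in range(1, parts):
                k = max(1, (j * len(words)) // parts)
                if k >= len(words):
                    continue
                ids += bpe_encode(" ".join(words[:k]), bpe_model)
                ids += [bpe_model.start_id]
                ids += bpe_encode(" ".join(words[k:]), bpe_model)
                ids += [bpe_model.end_of_text_id]
        ids += bpe_encode(text, bpe_model) + [bpe_model.end_of_text_id]
    return ids


def perplexity(model: GptLm, corpus_ids) -> float:
    """exp(mean next-token NLL) over a held-out id stream."""
    blocks = _blockify(np.asarray(list(corpus_ids), dtype=np.int64),
                       model.cfg.block_size)
    with no_grad():
        nll = lm_loss(model, blocks).item()
    return float(np.exp(nll))


def continue_report(model: GptLm, bpe_model: BpeModel, seed_text: str,
                    k: int = 3, second_best: bool = True) -> dict:
    """Continue a seed report with the LM.

    The start-of-continuation marker is appended to the BPE-encoded
    seed; K-beam search runs until the end-of-text token or the block
    bound.  The returned continuation is the second-best completed beam
    hypothesis (the best one when ``k`` is 1, only one hypothesis
    completes, or ``second_best`` is disabled).
    """
    if not seed_text.strip():
        raise ValueError("seed text must be non-empty")
    seed_ids = bpe_encode(seed_text, bpe_model)
    # condition on at most half a block of seed context (sliding window);
    # the full seed text is still preserved verbatim in the output
    window = model.cfg.block_size // 2
    prefix = seed_ids[-window:] + [bpe_model.start_id]
    budget = model.cfg.block_size - len(prefix) - 1

    def step(state, token_id):
        # state holds the generated tokens consumed so far; the start
        # marker fed on the first call is already the tail of ``prefix``
        new_state = () if state is None else state + (int(token_id),)
        logp = model.next_log_probs(prefix + list(new_state))
        return new_state, logp

    hyps = beam_search(step, None, bpe_model.start_id,
                       bpe_model.end_of_text_id, k, budget)
    pick = hyps[1] if (second_best and len(hyps) > 1) else hyps[0]
    continuation = bpe_decode(pick.ids, bpe_model)
    sep = " " if continuation else ""
    return {"report": seed_text + sep + continuation,
            "seed": seed_text, "continuation": continuation,
            "beam_scores": [h.score for h in hyps]}
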