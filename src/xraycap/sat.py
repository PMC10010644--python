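"""Show-Attend-Tell captioner: soft attention + LSTM decoder.

At every step the decoder scores each of the N spatial locations of the
encoder grid with a small MLP conditioned on the previous hidden state,
softmaxes the scores into attention weights alpha_t (which always sum
to 1), and feeds the resulting context vector — the attention-weighted
sum of location features — into an LSTM cell together with the previous
word embedding.  The next-word distribution comes from a deep output
layer that looks jointly at the hidden state, the context vector and
the previous word embedding.  Hidden and cell states are initialised by
two separate MLPs from the mean location feature.

Training is teacher-forced cross-entropy over non-pad positions only
(batches sorted by decreasing length, per-step effective batch size);
the doubly-stochastic attention regulariser is deliberately absent —
chest anatomy is spatially stable, so attention need not be spread.
Decoding is greedy or K-beam (inference only), and per-step attention
weights are kept for 2-D localization heatmaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .autodiff import Tensor, concat, log_softmax, no_grad
from .encoder import ImageEncoder, SmallCNN
from .report_prep import Vocabulary
from .search import beam_search, greedy_search


@dataclass
class SatConfig:
    vocab_size: int
    embed_dim: int = 100        # m
    hidden_dim: int = 512       # n (LSTM dimension)
    attn_dim: int = 512         # width of the attention MLP
    feat_channels: int = 64     # C, set by the encoder backbone
    side: int = 7               # D; attention runs over N = D*D locations
    dropout: float = 0.1
    max_len: int = 100
    seed: int = 0

    def __post_init__(self):
        for f in ("vocab_size", "embed_dim", "hidden_dim", "attn_dim",
                  "feat_channels", "side", "max_len"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


class SatDecoder(nn.Module):
    def __init__(self, cfg: SatConfig, rng):
        super().__init__()
        W, m, n, A, C = (cfg.vocab_size, cfg.embed_dim, cfg.hidden_dim,
                         cfg.attn_dim, cfg.feat_channels)
        self.cfg = cfg
        self.embed = nn.Embedding(W, m, rng)
        # f_att: two linear maps summed, ReLU, then linear -> 1
        self.feat_att = nn.Linear(C, A, rng, bias=False)
        self.hid_att = nn.Linear(n, A, rng)
        self.att_score = nn.Linear(A, 1, rng, bias=False)
        # two separate init MLPs (init-h, init-c) on the mean feature
        self.init_h = nn.Linear(C, n, rng)
        self.init_c = nn.Linear(C, n, rng)
        # single affine map T_{C+m+n, 4n} producing all four gates
        self.lstm = nn.Linear(C + m + n, 4 * n, rng)
        # deep output layer
        self.out_h = nn.Linear(n, m, rng, bias=False)
        self.out_ctx = nn.Linear(C, m, rng, bias=False)
        self.out_proj = nn.Linear(m, W, rng)
        self.drop = nn.Dropout(cfg.dropout, rng)

    # ---- pieces ------------------------------------------------------
    def init_state(self, feats: Tensor):
        """h0, c0 from the mean location feature, via separate MLPs."""
        mean_feat = feats.mean(axis=1)          # (B, C)
        return self.init_h(mean_feat).tanh(), self.init_c(mean_feat).tanh()

    def project_features(self, feats: Tensor) -> Tensor:
        """Precompute the feature half of the attention MLP, (B, N, A)."""
        return self.feat_att(feats)

    def attend(self, feats: Tensor, proj_feats: Tensor, h_prev: Tensor):
        """Attention weights over the N locations and the context vector."""
        B, n = h_prev.shape
        hidden_part = self.hid_att(h_prev).reshape((B, 1, -1))
        scores = self.att_score((proj_feats + hidden_part).relu())  # (B, N, 1)
        scores = scores.reshape((B, proj_feats.shape[1]))
        shifted = scores - Tensor(scores.data.max(axis=1, keepdims=True))
        e = shifted.exp()
        alpha = e / e.sum(axis=1, keepdims=True)                    # (B, N)
        context = (alpha.reshape((B, -1, 1)) * feats).sum(axis=1)   # (B, C)
        return alpha, context

    def lstm_step(self, emb: Tensor, h_prev: Tensor, c_prev: Tensor,
                  context: Tensor):
        """One LSTM cell update on [E z_{t-1}; h_{t-1}; a_hat_t]."""
        n = self.cfg.hidden_dim
        z = self.lstm(concat([emb, h_prev, context], axis=1))  # (B, 4n)
        i = z[:, 0 * n:1 * n].sigmoid()
        f = z[:, 1 * n:2 * n].sigmoid()
        o = z[:, 2 * n:3 * n].sigmoid()
        g = z[:, 3 * n:4 * n].tanh()
        c = f * c_prev + i * g
        h = o * c.tanh()
        return h, c

    def output_logits(self, h: Tensor, context: Tensor, emb: Tensor) -> Tensor:
        """Deep output layer: L_o(L_h h + L_a a_hat + E z_{t-1})."""
        d = self.out_h(h) + self.out_ctx(context) + emb
        return self.out_proj(self.drop(d))


class SatModel(nn.Module):
    """Encoder + attention decoder, with training and decoding loops."""

    def __init__(self, cfg: SatConfig, rng=None, encoder: ImageEncoder = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        if encoder is None:
            encoder = ImageEncoder(rng=rng, backbone=SmallCNN(rng), side=cfg.side)
        if encoder.channels is not None and encoder.channels != cfg.feat_channels:
            raise ValueError("feat_channels must match the encoder backbone")
        self.cfg = cfg
        self.encoder = encoder
        self.decoder = SatDecoder(cfg, rng)

    # ---- training ----------------------------------------------------
    def teacher_forcing_loss(self, feats: Tensor, captions: np.ndarray,
                             lengths: np.ndarray, return_stats: bool = False):
        """Mean cross-entropy per predicted (non-pad) token.

        ``captions`` is a (B, T) id matrix sorted by decreasing true
        length; the ground-truth previous word is always fed.
        """
        lengths = np.asarray(lengths)
        if np.any(np.diff(lengths) > 0):
            raise ValueError("batch must be sorted by decreasing length")
        dec = self.decoder
        h, c = dec.init_state(feats)
        proj = dec.project_features(feats)
        total = None
        n_tokens = 0
        n_correct = 0
        T = captions.shape[1]
        for t in range(T - 1):
            bs = int(np.sum(lengths >= t + 2))
            if bs == 0:
                break
            h, c = h[:bs], c[:bs]
            feats_b, proj_b = feats[:bs], proj[:bs]
            alpha, ctx = dec.attend(feats_b, proj_b, h)
            emb = dec.embed(captions[:bs, t])
            h, c = dec.lstm_step(emb, h, c, ctx)
            logits = dec.output_logits(h, ctx, emb)
            targets = captions[:bs, t + 1]
            logp = log_softmax(logits, axis=-1)
            picked = logp[np.arange(bs), targets]
            step_loss = -picked.sum()
            total = step_loss if total is None else total + step_loss
            n_tokens += bs
            n_correct += int(np.sum(np.argmax(logits.data, axis=1) == targets))
        loss = total * (1.0 / n_tokens)
        if return_stats:
            return loss, {"tokens": n_tokens, "accuracy": n_correct / n_tokens}
        return loss

    def encode_batch(self, images: np.ndarray) -> Tensor:
        """(B, 1, H, W) float array -> (B, N, C) feature grids."""
        return self.encoder(Tensor(np.asarray(images, dtype=np.float64)))

    # ---- decoding ----------------------------------------------------
    def _step_fn(self, feats: Tensor):
        dec = self.decoder
        proj = dec.project_features(feats)

        def step(state, token_id):
            if state is None:
                h, c = dec.init_state(feats)
                alphas = ()
            else:
                h, c, alphas = state
            alpha, ctx = dec.attend(feats, proj, h)
            emb = dec.embed(np.array([token_id]))
            h, c = dec.lstm_step(emb, h, c, ctx)
            logits = dec.output_logits(h, ctx, emb)
            logp = log_softmax(logits, axis=-1).data[0]
            return (h, c, alphas + (alpha.data[0].copy(),)), logp

        return step

    def _feats_for(self, image: np.ndarray) -> Tensor:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim == 2:
            image = image[None]
        with no_grad():
            return self.encoder(Tensor(image[None]))

    def greedy_decode(self, image: np.ndarray, max_len: int = None):
        """Argmax decoding; returns (ids, per-step attention weights)."""
        max_len = max_len or self.cfg.max_len
        was_training = self.training
        self.eval()
        with no_grad():
            feats = self._feats_for(image)
            hyp = greedy_search(self._step_fn(feats), None,
                                Vocabulary.START_ID, Vocabulary.END_ID, max_len)
        self.train(was_training)
        h, c, alphas = hyp.state
        return list(hyp.ids), [a for a in alphas]

    def beam_decode(self, image: np.ndarray, k: int, max_len: int = None):
        """Top-k caption hypotheses; each returns (ids, score, alphas)."""
        if k < 1:
            raise ValueError("beam width k must be >= 1")
        max_len = max_len or self.cfg.max_len
        was_training = self.training
        self.eval()
        with no_grad():
            feats = self._feats_for(image)
            hyps = beam_search(self._step_fn(feats), None, Vocabulary.START_ID,
                               Vocabulary.END_ID, k, max_len)
        self.train(was_training)
        out = []
        for h in hyps:
            _, _, alphas = h.state
            out.append((list(h.ids), h.score, [a for a in alphas[: len(h.ids) + 1]]))
        return out


# ---- training loop ---------------------------------------------------
def train_sat(model: SatModel, images: np.ndarray, sequences, epochs: int,
              lr: float = 1e-3, batch_size: int = 16, seed: int = 0,
              encoder_lr: float = None, log_every: int = 0):
    """Teacher-forced training; returns per-epoch loss/accuracy history.

    When the encoder is frozen (finetune off) feature grids are computed
    once and cached, which makes decoder-only training much faster.
    """
    from .report_prep import pad_and_sort

    rng = np.random.default_rng(seed)
    finetune = getattr(model.encoder, "finetune", True)
    params = model.parameters()
    opt = nn.Adam([p for p in params if p.requires_grad], lr=lr)
    cached = None
    if not finetune:
        with no_grad():
            cached = model.encode_batch(images).data
    history = []
    M = len(sequences)
    for epoch in range(epochs):
        order = rng.permutation(M)
        ep_loss, ep_tokens, ep_correct = 0.0, 0, 0
        for lo in range(0, M, batch_size):
            idx = order[lo:lo + batch_size]
            mat, lengths, perm = pad_and_sort([sequences[i] for i in idx])
            img_idx = idx[perm]
            if cached is None:
                feats = model.encode_batch(images[img_idx])
            else:
                feats = Tensor(cached[img_idx])
            loss, stats = model.teacher_forcing_loss(
                feats, mat, lengths, return_stats=True)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() * stats["tokens"]
            ep_tokens += stats["tokens"]
            ep_correct += stats["accuracy"] * stats["tokens"]
        history.append({"epoch": epoch, "loss": ep_loss / ep_tokens,
                        "accuracy": ep_correct / ep_tokens})
        if log_every and (epoch + 1) % log_every == 0:
            h = history[-1]
            print(f"[train-sat] epoch {epoch + 1}/{epochs} "
                  f"loss {h['loss']:.4f} acc {h['accuracy']:.3f}")
    return history


def teacher_forced_alphas(model: SatModel, image: np.ndarray,
                          caption_ids) -> list:
    """Per-step attention weights while force-feeding a reference caption.

    Entry t is the attention used when predicting ``caption_ids[t + 1]``.
    """
    dec = model.decoder
    with no_grad():
        feats = model._feats_for(image)
        proj = dec.project_features(feats)
        h, c = dec.init_state(feats)
        alphas = []
        for t in range(len(caption_ids) - 1):
            alpha, ctx = dec.attend(feats, proj, h)
            emb = dec.embed(np.array([caption_ids[t]]))
            h, c = dec.lstm_step(emb, h, c, ctx)
            alphas.append(alpha.data[0].copy())
    return alphas


# ---- heatmaps --------------------------------------------------------
def _interp_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Mass-preserving bilinear upsampling matrix (out_size, in_size).

    Output pixel centres are bilinearly interpolated between input cell
    centres; columns are then rescaled so every input cell distributes
    exactly out_size/in_size units of mass, making the total attention
    mass invariant under upsampling.
    """
    M = np.zeros((out_size, in_size))
    scale = in_size / out_size
    for i in range(out_size):
        p = (i + 0.5) * scale - 0.5
        lo = int(np.floor(p))
        w = p - lo
        lo_c = min(max(lo, 0), in_size - 1)
        hi_c = min(max(lo + 1, 0), in_size - 1)
        M[i, lo_c] += 1.0 - w
        M[i, hi_c] += w
    M /= M.sum(axis=0, keepdims=True)   # each input cell distributes mass 1
    return M


def upsample_attention(alpha: np.ndarray, side: int, image_size: int) -> np.ndarray:
    """(N,) attention -> (image_size, image_size) map with total mass 1."""
    grid = np.asarray(alpha, dtype=np.float64).reshape(side, side)
    B = _interp_matrix(image_size, side)
    return B @ grid @ B.T


def attention_heatmap(alphas, side: int, image_size: int) -> list:
    """Per-word heatmaps, each bilinearly upsampled and rescaled to [0, 1]."""
    maps = []
    for alpha in alphas:
        up = upsample_attention(alpha, side, image_size)
        lo, hi = up.min(), up.max()
        maps.append((up - lo) / (hi - lo) if hi > lo else np.zeros_like(up))
    return maps


def save_heatmap_overlay(image: np.ndarray, heatmap: np.ndarray, path,
                         word: str = ""):
    """PNG overlay of one attention map on the source image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(image, cmap="gray", vmin=0, vmax=1)
    ax.imshow(heatmap, cmap="jet", alpha=0.4)
    if word:
        ax.set_title(word)
    ax.axis("off")
    fig.savefig(path, dpi=80, bbox_inches="tight")
    plt.close(fig)


def attention_mass_in_mask(alpha: np.ndarray, mask: np.ndarray, side: int):
    """Attention mass falling in a lesion mask, and the uniform baseline.

    The mask is averaged over the same adaptive D x D cells the encoder
    pools to, so a uniform attention scores exactly the mask's area
    fraction.
    """
    mask = np.asarray(mask, dtype=np.float64)
    R = nn._pool_bins(mask.shape[0], side)
    C = nn._pool_bins(mask.shape[1], side)
    frac = R @ mask @ C.T                    # (D, D) mask fraction per cell
    mass = float(np.sum(np.asarray(alpha).reshape(side, side) * frac))
    return mass, float(mask.mean())


# ---- checkpoints -----------------------------------------------------
def save_checkpoint(path, model: SatModel, vocab: Vocabulary):
    state = model.state_dict()
    meta = {"config": asdict(model.cfg), "vocab": json.loads(vocab.to_json())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = SatConfig(**meta["config"])
    vocab = Vocabulary(meta["vocab"]["words"])
    model = SatModel(cfg)
    model.load_state_dict(state)
    return model, vocab
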