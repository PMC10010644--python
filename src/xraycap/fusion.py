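"""Combining the two language models.

Approach 1 learns a joint next-word distribution: at each step the
captioner and the transformer LM each produce a score (log-probability)
for every word of the captioner's vocabulary; the two score vectors are
concatenated and pushed through a small feed-forward head whose softmax
gives the fused next-word distribution.  Because the LM lives on a BPE
subword vocabulary, its continuous distribution is first discretised
onto the word vocabulary: a word's score is the log-probability of its
greedy BPE segmentation, accumulated subword by subword by the chain
rule (words whose first subword has no support get a floor score).

Approach 2 simply stacks the models: the captioner decodes a seed
report from the image, and the LM continues it from the
start-of-continuation marker.  The seed is always preserved verbatim as
the prefix of the returned report.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, log_softmax, no_grad, softmax
from .bpe import BpeModel, segment_word
from .report_prep import Vocabulary
from .sat import SatModel
from .transformer import GptLm, continue_report

FLOOR_SCORE = -1e9

# scores entering the learned head are clipped here so the impossible-word
# floor does not blow up the hidden layer
HEAD_CLIP = -50.0


def _word_segmentations(vocab: Vocabulary, bpe_model: BpeModel) -> list:
    """BPE id segmentation for every word of the captioner vocabulary."""
    segs = []
    for idx in range(len(vocab)):
        word = vocab.decode_id(idx)
        if word in Vocabulary.SPECIALS:
            segs.append(None if word != Vocabulary.END else "END")
        else:
            segs.append([bpe_model.vocab[s] for s in segment_word(word, bpe_model)])
    return segs


def align_vocabulary(lm_model: GptLm, bpe_model: BpeModel, context_ids,
                     vocab: Vocabulary, segmentations=None) -> np.ndarray:
    """LM next-step scores for every word of the captioner vocabulary.

    The score of word w is log P(subwords of w | context), computed by
    running the LM one extra step per additional subword.  The end-of-
    caption word maps to the end-of-text token; other special tokens
    get the floor score.  The output is a score vector over W, not a
    renormalised distribution.
    """
    if segmentations is None:
        segmentations = _word_segmentations(vocab, bpe_model)
    context_ids = list(context_ids)
    base_logp = lm_model.next_log_probs(context_ids)
    scores = np.full(len(vocab), FLOOR_SCORE)
    cache = {}
    for widx, seg in enumerate(segmentations):
        if seg is None:
            continue
        if seg == "END":
            scores[widx] = base_logp[bpe_model.end_of_text_id]
            continue
        total = base_logp[seg[0]]
        prefix = (seg[0],)
        for sub in seg[1:]:
            if prefix not in cache:
                cache[prefix] = lm_model.next_log_probs(context_ids + list(prefix))
            total += cache[prefix][sub]
            prefix = prefix + (sub,)
        scores[widx] = total
    return scores


class FusionHead(nn.Module):
    """Feed-forward net C: concat(2W scores) -> hidden W -> W logits."""

    def __init__(self, vocab_size: int, rng):
        super().__init__()
        self.fc1 = nn.Linear(2 * vocab_size, vocab_size, rng)
        self.fc2 = nn.Linear(vocab_size, vocab_size, rng)

    def forward(self, scores: Tensor) -> Tensor:
        return self.fc2(self.fc1(scores).relu())


def identity_fusion_head(vocab_size: int, shift: float = 1000.0) -> FusionHead:
    """A head that passes the captioner scores through and zeroes the LM branch.

    The hidden ReLU is bypassed by shifting scores up by ``shift`` and
    subtracting it again at the output, so softmax(head(x)) equals
    softmax of the captioner scores for any scores above ``-shift``.
    """
    head = FusionHead(vocab_size, np.random.default_rng(0))
    W = vocab_size
    w1 = np.zeros((2 * W, W))
    w1[:W, :] = np.eye(W)
    head.fc1.weight.data = w1
    head.fc1.bias.data = np.full(W, shift)
    head.fc2.weight.data = np.eye(W)
    head.fc2.bias.data = np.full(W, -shift)
    return head


def fuse_next_word(sat_scores, lm_scores, head: FusionHead) -> Tensor:
    """Fused next-word probability vector over the captioner vocabulary."""
    sat_scores = np.asarray(sat_scores, dtype=np.float64)
    lm_scores = np.asarray(lm_scores, dtype=np.float64)
    if sat_scores.shape != lm_scores.shape:
        raise ValueError("score vectors must have identical length")
    x = Tensor(np.concatenate([np.maximum(sat_scores, HEAD_CLIP),
                               np.maximum(lm_scores, HEAD_CLIP)])[None, :])
    logits = head(x)
    return softmax(logits, axis=-1).reshape((-1,))


def generate_approach1(image, sat_model: SatModel, lm_model: GptLm,
                       bpe_model: BpeModel, vocab: Vocabulary,
                       head: FusionHead, max_len: int = None,
                       advance_lm: bool = True) -> dict:
    """Joint stepwise decoding through the fusion head.

    Both models advance with each chosen word: the captioner consumes
    its embedding, the LM appends the word's BPE ids to its context
    (disable with ``advance_lm=False``).  Emitted words necessarily
    belong to the captioner vocabulary — the discretisation limitation
    of score alignment.
    """
    max_len = max_len or sat_model.cfg.max_len
    segs = _word_segmentations(vocab, bpe_model)
    with no_grad():
        feats = sat_model._feats_for(np.asarray(image))
        sat_step = sat_model._step_fn(feats)
        state = None
        lm_ctx = [bpe_model.end_of_text_id]     # document-start convention
        prev = Vocabulary.START_ID
        words = []
        for _ in range(max_len):
            state, sat_logp = sat_step(state, prev)
            lm_scores = align_vocabulary(lm_model, bpe_model, lm_ctx, vocab,
                                         segmentations=segs)
            probs = fuse_next_word(sat_logp, lm_scores, head).data
            tok = int(np.argmax(probs))
            if tok == Vocabulary.END_ID:
                break
            words.append(vocab.decode_id(tok))
            if advance_lm and segs[tok] not in (None, "END"):
                lm_ctx.extend(segs[tok])
            prev = tok
    report = " ".join(words)
    return {"report": report, "tokens": words}


def generate_approach2(image, sat_model: SatModel, lm_model: GptLm,
                       bpe_model: BpeModel, vocab: Vocabulary,
                       beam_k_sat: int = 1, beam_k_lm: int = 3) -> dict:
    """Stacked pipeline: captioner seed, then LM continuation."""
    if beam_k_sat <= 1:
        ids, _ = sat_model.greedy_decode(np.asarray(image))
    else:
        ids = sat_model.beam_decode(np.asarray(image), beam_k_sat)[0][0]
    seed = " ".join(vocab.decode_ids(ids))
    if not seed:
        seed = vocab.decode_id(Vocabulary.UNK_ID)
    out = continue_report(lm_model, bpe_model, seed, k=beam_k_lm)
    return {"report": out["report"], "sat_seed": seed,
            "lm_continuation": out["continuation"]}


def train_fusion_head(sat_model: SatModel, lm_model: GptLm,
                      bpe_model: BpeModel, vocab: Vocabulary,
                      images, sequences, epochs: int, lr: float = 1e-3,
                      seed: int = 0, log_every: int = 0):
    """Train the head by teacher-forced cross-entropy, backbones frozen.

    Both backbones are treated as fixed feature extractors: their
    per-step score vectors over the caption corpus are precomputed once
    and the head is fitted on top.
    """
    head = FusionHead(len(vocab), np.random.default_rng(seed))
    if epochs == 0:
        return head, []
    pairs = _fusion_training_pairs(sat_model, lm_model, bpe_model, vocab,
                                   images, sequences)
    inputs = np.stack([p[0] for p in pairs])
    targets = np.array([p[1] for p in pairs], dtype=np.int64)
    opt = nn.Adam(head.parameters(), lr=lr)
    history = []
    for epoch in range(epochs):
        logits = head(Tensor(inputs))
        logp = log_softmax(logits, axis=-1)
        picked = logp[np.arange(len(targets)), targets]
        loss = -picked.mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(loss.item())
        if log_every and (epoch + 1) % log_every == 0:
            print(f"[train-fusion] epoch {epoch + 1}/{epochs} "
                  f"loss {history[-1]:.4f}")
    return head, history


def _fusion_training_pairs(sat_model, lm_model, bpe_model, vocab,
                           images, sequences):
    segs = _word_segmentations(vocab, bpe_model)
    pairs = []
    with no_grad():
        for image, seq in zip(images, sequences):
            feats = sat_model._feats_for(np.asarray(image))
            step = sat_model._step_fn(feats)
            state = None
            lm_ctx = [bpe_model.end_of_text_id]
            for t in range(seq.length - 1):
                prev, target = seq.ids[t], seq.ids[t + 1]
                state, sat_logp = step(state, prev)
                lm_scores = align_vocabulary(lm_model, bpe_model, lm_ctx,
                                             vocab, segmentations=segs)
                pairs.append((np.concatenate(
                    [np.maximum(sat_logp, HEAD_CLIP),
                     np.maximum(lm_scores, HEAD_CLIP)]), target))
                if segs[target] not in (None, "END"):
                    lm_ctx.extend(segs[target])
    return pairs
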