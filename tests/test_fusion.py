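"""Model combination: score alignment, fusion head, both generation modes."""

import numpy as np
import pytest

import xraycap as xc
from xraycap.bpe import segment_word
from xraycap.fusion import FLOOR_SCORE, _word_segmentations
from xraycap.transformer import GptLm, TransformerConfig


@pytest.fixture(scope="module")
def lm_setup(phantom_sentences):
    corpus = " ".join(phantom_sentences)
    model_bpe = xc.train_bpe(corpus, 120)
    cfg = TransformerConfig(vocab_size=len(model_bpe), layers=2, heads=2,
                            model_dim=32, ff_dim=64, block_size=128, seed=0)
    lm = GptLm(cfg)
    xc.lm_finetune(lm, xc.bpe_encode(corpus, model_bpe), epochs=5, lr=3e-3,
                   seed=0)
    return lm, model_bpe


def test_single_subword_score_equals_token_logprob(lm_setup, phantom_corpus):
    lm, model_bpe = lm_setup
    _, vocab, _ = phantom_corpus
    ctx = [model_bpe.end_of_text_id]
    base = lm.next_log_probs(ctx)
    scores = xc.align_vocabulary(lm, model_bpe, ctx, vocab)
    for idx in range(4, len(vocab)):
        word = vocab.decode_id(idx)
        seg = [model_bpe.vocab[s] for s in segment_word(word, model_bpe)]
        if len(seg) == 1:
            assert scores[idx] == pytest.approx(base[seg[0]], abs=1e-12)


def test_multi_subword_score_is_chain_rule(lm_setup, phantom_corpus):
    lm, model_bpe = lm_setup
    _, vocab, _ = phantom_corpus
    ctx = [model_bpe.end_of_text_id]
    scores = xc.align_vocabulary(lm, model_bpe, ctx, vocab)
    multi = [i for i in range(4, len(vocab))
             if len(segment_word(vocab.decode_id(i), model_bpe)) == 2]
    assert multi, "need at least one two-subword word in the vocabulary"
    for idx in multi[:5]:
        seg = [model_bpe.vocab[s]
               for s in segment_word(vocab.decode_id(idx), model_bpe)]
        manual = (lm.next_log_probs(ctx)[seg[0]]
                  + lm.next_log_probs(ctx + [seg[0]])[seg[1]])
        assert scores[idx] == pytest.approx(manual, abs=1e-9)


def test_uniform_lm_gives_equal_single_token_scores(phantom_corpus):
    _, vocab, _ = phantom_corpus

    model_bpe = xc.train_bpe(" ".join(vocab.decode_id(i)
                                      for i in range(4, len(vocab))), 300)
    V = len(model_bpe)

    class UniformLm:
        def next_log_probs(self, ctx):
            return np.full(V, -np.log(float(V)))
    scores = xc.align_vocabulary(UniformLm(), model_bpe,
                                 [model_bpe.end_of_text_id], vocab)
    single = [scores[i] for i in range(4, len(vocab))
              if len(segment_word(vocab.decode_id(i), model_bpe)) == 1]
    assert len(set(np.round(single, 12))) == 1


def test_special_tokens_get_floor_or_end_mapping(lm_setup, phantom_corpus):
    lm, model_bpe = lm_setup
    _, vocab, _ = phantom_corpus
    scores = xc.align_vocabulary(lm, model_bpe, [model_bpe.end_of_text_id],
                                 vocab)
    assert scores[xc.Vocabulary.START_ID] == FLOOR_SCORE
    assert scores[xc.Vocabulary.PAD_ID] == FLOOR_SCORE
    base = lm.next_log_probs([model_bpe.end_of_text_id])
    assert scores[xc.Vocabulary.END_ID] == \
        pytest.approx(base[model_bpe.end_of_text_id], abs=1e-12)


def test_fuse_output_is_distribution():
    rng = np.random.default_rng(0)
    head = xc.FusionHead(7, rng)
    p = xc.fuse_next_word(rng.normal(size=7), rng.normal(size=7), head).data
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(p >= 0)


def test_identity_head_reproduces_sat_softmax():
    rng = np.random.default_rng(1)
    sat_scores = rng.normal(size=9) - 3.0
    head = xc.identity_fusion_head(9)
    p = xc.fuse_next_word(sat_scores, rng.normal(size=9), head).data
    ref = np.exp(sat_scores) / np.exp(sat_scores).sum()
    assert np.allclose(p, ref, atol=1e-6)


def test_fuse_is_permutation_equivariant():
    rng = np.random.default_rng(2)
    W = 6
    head = xc.FusionHead(W, rng)
    sat, lm = rng.normal(size=W), rng.normal(size=W)
    p = xc.fuse_next_word(sat, lm, head).data
    perm = rng.permutation(W)
    head_p = xc.FusionHead(W, np.random.default_rng(2))
    # permute the head weights consistently with the vocabulary
    head_p.fc1.weight.data = head.fc1.weight.data[
        np.concatenate([perm, W + perm])][:, perm]
    head_p.fc1.bias.data = head.fc1.bias.data[perm]
    head_p.fc2.weight.data = head.fc2.weight.data[perm][:, perm]
    head_p.fc2.bias.data = head.fc2.bias.data[perm]
    p2 = xc.fuse_next_word(sat[perm], lm[perm], head_p).data
    assert np.allclose(p2, p[perm], atol=1e-9)


def test_fuse_rejects_length_mismatch():
    head = xc.FusionHead(4, np.random.default_rng(0))
    with pytest.raises(ValueError):
        xc.fuse_next_word(np.zeros(4), np.zeros(5), head)


def test_approach1_zero_lm_branch_equals_greedy(lm_setup, tiny_sat,
                                                phantom_corpus,
                                                phantom_batch):
    lm, model_bpe = lm_setup
    _, vocab, _ = phantom_corpus
    head = xc.identity_fusion_head(len(vocab))
    for s in phantom_batch[:3]:
        out = xc.generate_approach1(s.image.astype(float), tiny_sat, lm,
                                    model_bpe, vocab, head, max_len=10)
        ids, _ = tiny_sat.greedy_decode(s.image.astype(float), max_len=10)
        assert out["tokens"] == vocab.decode_ids(ids, strip_special=False)


def test_approach1_words_in_sat_vocab(lm_setup, tiny_sat, phantom_corpus,
                                      phantom_batch):
    lm, model_bpe = lm_setup
    _, vocab, _ = phantom_corpus
    head = xc.FusionHead(len(vocab), np.random.default_rng(0))
    out = xc.generate_approach1(phantom_batch[0].image.astype(float),
                                tiny_sat, lm, model_bpe, vocab, head,
                                max_len=6)
    assert all(w in vocab for w in out["tokens"])


def test_approach2_prefix_is_sat_caption(lm_setup, tiny_sat, phantom_corpus,
                                         phantom_batch):
    lm, model_bpe = lm_setup
    _, vocab, _ = phantom_corpus
    for s in phantom_batch[:3]:
        out = xc.generate_approach2(s.image.astype(float), tiny_sat, lm,
                                    model_bpe, vocab)
        assert out["report"].startswith(out["sat_seed"])
        assert len(out["report"]) >= len(out["sat_seed"])


def test_approach2_degenerate_lm_returns_caption(tiny_sat, phantom_corpus,
                                                 phantom_batch):
    _, vocab, _ = phantom_corpus
    model_bpe = xc.train_bpe("a b", 0)

    class EndsImmediately:
        class cfg:
            block_size = 4096

        def next_log_probs(self, ctx):
            lp = np.full(len(model_bpe), -50.0)
            lp[model_bpe.end_of_text_id] = 0.0
            return lp

    out = xc.generate_approach2(phantom_batch[0].image.astype(float),
                                tiny_sat, EndsImmediately(), model_bpe, vocab)
    assert out["report"] == out["sat_seed"]
    assert out["lm_continuation"] == ""


def test_fusion_head_training_reduces_loss(lm_setup, phantom_batch,
                                           phantom_corpus):
    lm, model_bpe = lm_setup
    _, vocab, seqs = phantom_corpus
    cfg = xc.SatConfig(vocab_size=len(vocab), embed_dim=16, hidden_dim=24,
                       attn_dim=24, dropout=0.0, max_len=40, seed=5)
    sat = xc.SatModel(cfg, rng=np.random.default_rng(5))
    imgs = [s.image.astype(float) for s in phantom_batch[:3]]
    head, hist = xc.train_fusion_head(sat, lm, model_bpe, vocab, imgs,
                                      seqs[:3], epochs=40, lr=1e-2, seed=0)
    assert hist[-1] < hist[0]


def test_fusion_head_zero_epochs_untouched(lm_setup, phantom_batch,
                                           phantom_corpus, tiny_sat):
    lm, model_bpe = lm_setup
    _, vocab, seqs = phantom_corpus
    head, hist = xc.train_fusion_head(tiny_sat, lm, model_bpe, vocab, [],
                                      [], epochs=0, seed=0)
    ref = xc.FusionHead(len(vocab), np.random.default_rng(0))
    assert hist == []
    assert np.array_equal(head.fc1.weight.data, ref.fc1.weight.data)
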