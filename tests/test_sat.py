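"""Attention-LSTM captioner: equations, losses, decoding, heatmaps."""

import numpy as np
import pytest

import xraycap as xc
from xraycap.autodiff import Tensor, no_grad
from xraycap.sat import SatDecoder, upsample_attention
from oracles import attend_scalar, deep_output_scalar, lstm_step_scalar


def small_decoder(W=5, m=3, n=4, A=4, C=3, seed=0):
    cfg = xc.SatConfig(vocab_size=W, embed_dim=m, hidden_dim=n, attn_dim=A,
                       feat_channels=C, side=2, dropout=0.0, max_len=10,
                       seed=seed)
    return cfg, SatDecoder(cfg, np.random.default_rng(seed))


# ---- init MLPs -------------------------------------------------------
def test_init_state_uses_mean_feature():
    cfg, dec = small_decoder()
    v = np.array([0.3, -0.2, 0.7])
    feats = Tensor(np.tile(v, (1, 4, 1)))          # identical locations
    h0, c0 = dec.init_state(feats)
    manual_h = np.tanh(v @ dec.init_h.weight.data + dec.init_h.bias.data)
    assert np.allclose(h0.data[0], manual_h, atol=1e-12)


def test_init_state_permutation_invariant():
    cfg, dec = small_decoder()
    rng = np.random.default_rng(1)
    feats = rng.normal(size=(1, 4, 3))
    h1, c1 = dec.init_state(Tensor(feats))
    h2, c2 = dec.init_state(Tensor(feats[:, [2, 0, 3, 1], :]))
    assert np.allclose(h1.data, h2.data)
    assert np.allclose(c1.data, c2.data)


def test_init_state_zero_features_zero_bias():
    cfg, dec = small_decoder()
    dec.init_h.bias.data[:] = 0.0
    h0, _ = dec.init_state(Tensor(np.zeros((1, 4, 3))))
    assert np.allclose(h0.data, 0.0)


# ---- attention -------------------------------------------------------
def test_attend_uniform_when_scores_equal():
    cfg, dec = small_decoder()
    v = np.array([0.5, 0.1, -0.3])
    feats = Tensor(np.tile(v, (1, 4, 1)))          # identical features
    proj = dec.project_features(feats)
    alpha, ctx = dec.attend(feats, proj, Tensor(np.zeros((1, 4))))
    assert np.allclose(alpha.data, 0.25, atol=1e-12)
    assert np.allclose(ctx.data[0], v, atol=1e-12)


def test_attend_one_hot_with_large_score_gap():
    cfg, dec = small_decoder()
    rng = np.random.default_rng(2)
    feats_data = rng.normal(size=(1, 4, 3))
    # force a >= 20 score gap onto location 2 by rigging the score layer
    dec.att_score.weight.data[:] = 0.0
    dec.feat_att.weight.data[:] = 0.0
    dec.hid_att.weight.data[:] = 0.0
    dec.hid_att.bias.data[:] = 1.0
    dec.feat_att.weight.data[0, 0] = 40.0
    dec.att_score.weight.data[0, 0] = 1.0
    feats_data[0, :, 0] = [0.0, 0.0, 1.0, 0.0]
    feats = Tensor(feats_data)
    alpha, ctx = dec.attend(feats, dec.project_features(feats),
                            Tensor(np.zeros((1, 4))))
    assert alpha.data[0, 2] > 1 - 1e-4
    assert np.allclose(ctx.data[0], feats_data[0, 2], atol=1e-4)


def test_attend_matches_scalar_oracle():
    cfg, dec = small_decoder(seed=7)
    rng = np.random.default_rng(7)
    feats = rng.normal(size=(1, 4, 3))
    h = rng.normal(size=(1, 4))
    alpha, ctx = dec.attend(Tensor(feats), dec.project_features(Tensor(feats)),
                            Tensor(h))
    o_alpha, o_ctx = attend_scalar(
        dec.feat_att.weight.data, dec.hid_att.weight.data,
        dec.hid_att.bias.data, dec.att_score.weight.data[:, 0],
        feats[0], h[0])
    assert np.allclose(alpha.data[0], o_alpha, atol=1e-6)
    assert np.allclose(ctx.data[0], o_ctx, atol=1e-6)
    assert alpha.data.sum() == pytest.approx(1.0, abs=1e-6)


def test_context_is_convex_combination():
    cfg, dec = small_decoder(seed=9)
    rng = np.random.default_rng(9)
    feats = rng.normal(size=(1, 6, 3))
    cfg2 = xc.SatConfig(vocab_size=5, embed_dim=3, hidden_dim=4, attn_dim=4,
                        feat_channels=3, side=2, dropout=0.0, max_len=10)
    _, ctx = dec.attend(Tensor(feats[:, :4]),
                        dec.project_features(Tensor(feats[:, :4])),
                        Tensor(rng.normal(size=(1, 4))))
    lo = feats[0, :4].min(axis=0) - 1e-12
    hi = feats[0, :4].max(axis=0) + 1e-12
    assert np.all(ctx.data[0] >= lo) and np.all(ctx.data[0] <= hi)


# ---- LSTM cell -------------------------------------------------------
def test_lstm_zero_weights_closed_form():
    cfg, dec = small_decoder()
    dec.lstm.weight.data[:] = 0.0
    dec.lstm.bias.data[:] = 0.0
    c_prev = np.array([[0.4, -0.6, 0.2, 1.0]])
    h, c = dec.lstm_step(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 4))),
                         Tensor(c_prev), Tensor(np.zeros((1, 3))))
    assert np.allclose(c.data, 0.5 * c_prev, atol=1e-12)
    assert np.allclose(h.data, 0.5 * np.tanh(0.5 * c_prev), atol=1e-12)
    # and with c_prev = 0 everything is 0
    h0, c0 = dec.lstm_step(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 4))),
                           Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 3))))
    assert np.allclose(c0.data, 0.0) and np.allclose(h0.data, 0.0)


def test_lstm_step_matches_scalar_oracle():
    cfg, dec = small_decoder(seed=11)
    rng = np.random.default_rng(11)
    emb = rng.normal(size=4)[:3]
    h_prev = rng.normal(size=4)
    c_prev = rng.normal(size=4)
    ctx = rng.normal(size=3)
    h, c = dec.lstm_step(Tensor(emb[None]), Tensor(h_prev[None]),
                         Tensor(c_prev[None]), Tensor(ctx[None]))
    oh, oc = lstm_step_scalar(dec.lstm.weight.data.T, dec.lstm.bias.data,
                              emb, h_prev, c_prev, ctx)
    assert np.allclose(h.data[0], oh, atol=1e-6)
    assert np.allclose(c.data[0], oc, atol=1e-6)


# ---- deep output layer ----------------------------------------------
def test_output_distribution_is_normalised():
    cfg, dec = small_decoder(seed=13)
    rng = np.random.default_rng(13)
    logits = dec.output_logits(Tensor(rng.normal(size=(1, 4))),
                               Tensor(rng.normal(size=(1, 3))),
                               Tensor(rng.normal(size=(1, 3))))
    p = np.exp(logits.data[0] - logits.data[0].max())
    p /= p.sum()
    assert p.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.all(p >= 0)


def test_output_uniform_at_zero_inputs():
    cfg, dec = small_decoder()
    dec.out_proj.bias.data[:] = 0.0
    logits = dec.output_logits(Tensor(np.zeros((1, 4))),
                               Tensor(np.zeros((1, 3))),
                               Tensor(np.zeros((1, 3))))
    assert np.allclose(logits.data, 0.0, atol=1e-12)  # softmax -> uniform 1/W


def test_output_matches_matrix_oracle():
    cfg, dec = small_decoder(seed=17, W=3)
    rng = np.random.default_rng(17)
    h, ctx, emb = rng.normal(size=4), rng.normal(size=3), rng.normal(size=3)
    logits = dec.output_logits(Tensor(h[None]), Tensor(ctx[None]),
                               Tensor(emb[None]))
    probs = np.exp(logits.data[0] - logits.data[0].max())
    probs /= probs.sum()
    oracle = deep_output_scalar(dec.out_h.weight.data, dec.out_ctx.weight.data,
                                dec.out_proj.weight.data,
                                dec.out_proj.bias.data, emb, h, ctx)
    assert np.allclose(probs, oracle, atol=1e-6)


# ---- teacher forcing -------------------------------------------------
def _loss_setup(tiny_sat, phantom_batch, phantom_corpus, k=4):
    _, vocab, seqs = phantom_corpus
    imgs = np.stack([s.image for s in phantom_batch[:k]])[:, None].astype(float)
    mat, lengths, perm = xc.pad_and_sort(seqs[:k])
    feats = tiny_sat.encode_batch(imgs[perm])
    return feats, mat, lengths


def test_uniform_predictions_give_log_W(tiny_sat, phantom_batch,
                                        phantom_corpus):
    _, vocab, _ = phantom_corpus
    cfg = xc.SatConfig(vocab_size=len(vocab), embed_dim=16, hidden_dim=24,
                       attn_dim=24, dropout=0.0, max_len=40, seed=3)
    model = xc.SatModel(cfg, rng=np.random.default_rng(3))
    # zero the output layer -> exactly uniform next-word distributions
    model.decoder.out_h.weight.data[:] = 0.0
    model.decoder.out_ctx.weight.data[:] = 0.0
    model.decoder.out_proj.weight.data[:] = 0.0
    model.decoder.out_proj.bias.data[:] = 0.0
    model.decoder.embed.weight.data[:] = 0.0
    feats, mat, lengths = _loss_setup(model, phantom_batch, phantom_corpus)
    loss = model.teacher_forcing_loss(feats, mat, lengths)
    assert loss.item() == pytest.approx(np.log(len(vocab)), abs=1e-9)


def test_pad_positions_do_not_contribute(tiny_sat, phantom_batch,
                                         phantom_corpus):
    feats, mat, lengths = _loss_setup(tiny_sat, phantom_batch, phantom_corpus)
    loss1 = tiny_sat.teacher_forcing_loss(feats, mat, lengths).item()
    pad = np.full((mat.shape[0], 5), xc.Vocabulary.PAD_ID, dtype=mat.dtype)
    loss2 = tiny_sat.teacher_forcing_loss(
        feats, np.concatenate([mat, pad], axis=1), lengths).item()
    assert loss1 == pytest.approx(loss2, abs=1e-12)


def test_unsorted_batch_rejected(tiny_sat, phantom_batch, phantom_corpus):
    feats, mat, lengths = _loss_setup(tiny_sat, phantom_batch, phantom_corpus)
    bad = lengths.copy()
    if bad[0] == bad[-1]:
        bad[-1] += 1
    else:
        bad = bad[::-1].copy()
    with pytest.raises(ValueError):
        tiny_sat.teacher_forcing_loss(feats, mat, bad)


# ---- decoding --------------------------------------------------------
def test_greedy_decode_deterministic(tiny_sat, phantom_batch):
    img = phantom_batch[0].image.astype(float)
    ids1, al1 = tiny_sat.greedy_decode(img)
    ids2, al2 = tiny_sat.greedy_decode(img)
    assert ids1 == ids2
    assert all(np.array_equal(a, b) for a, b in zip(al1, al2))


def test_alphas_sum_to_one_during_decode(tiny_sat, phantom_batch):
    _, alphas = tiny_sat.greedy_decode(phantom_batch[2].image.astype(float))
    for a in alphas:
        assert a.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(a >= 0)


def test_beam_k1_equals_greedy_on_phantoms(tiny_sat, phantom_batch):
    for s in phantom_batch[:5]:
        ids_g, _ = tiny_sat.greedy_decode(s.image.astype(float))
        hyps = tiny_sat.beam_decode(s.image.astype(float), k=1)
        assert hyps[0][0] == ids_g


# ---- heatmaps --------------------------------------------------------
def test_uniform_alpha_gives_constant_map():
    maps = xc.attention_heatmap([np.full(49, 1 / 49)], side=7, image_size=224)
    assert np.allclose(maps[0], 0.0)  # rescaled constant map is flat


def test_upsampled_mass_is_preserved():
    rng = np.random.default_rng(0)
    for _ in range(20):
        alpha = rng.dirichlet(np.ones(49))
        up = upsample_attention(alpha, side=7, image_size=224)
        assert up.sum() == pytest.approx(1.0, abs=1e-3)


def test_heatmap_values_in_unit_interval():
    rng = np.random.default_rng(1)
    maps = xc.attention_heatmap([rng.dirichlet(np.ones(49))], 7, 224)
    assert maps[0].min() >= 0.0 and maps[0].max() <= 1.0


def test_attention_mass_uniform_equals_area_fraction(phantom_batch):
    lesion = next(s for s in phantom_batch if s.masks)
    mask = next(iter(lesion.masks.values()))
    mass, frac = xc.attention_mass_in_mask(np.full(49, 1 / 49), mask, 7)
    assert mass == pytest.approx(frac, abs=1e-9)


# ---- checkpoints -----------------------------------------------------
def test_checkpoint_roundtrip(tmp_path, tiny_sat, phantom_corpus,
                              phantom_batch):
    _, vocab, _ = phantom_corpus
    path = tmp_path / "sat.npz"
    xc.save_checkpoint(path, tiny_sat, vocab)
    model, vocab2 = xc.load_checkpoint(path)
    assert vocab2.word_to_id == vocab.word_to_id
    img = phantom_batch[0].image.astype(float)
    assert model.greedy_decode(img)[0] == tiny_sat.greedy_decode(img)[0]
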