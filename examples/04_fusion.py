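"""The two ways to combine the captioner with the transformer LM.

Approach 1 fuses per-step next-word scores from both models through a
small feed-forward head (the LM's subword distribution is discretised
onto the word vocabulary first).  Approach 2 stacks them: the captioner
decodes a seed which the LM then continues.
"""

import numpy as np

import xraycap as xc
from xraycap.transformer import continuation_corpus

spec = xc.PhantomSpec(seed=8)
samples = [xc.generate_phantom(spec, i) for i in range(40)]
images = np.stack([s.image for s in samples])[:, None].astype(np.float64)
token_lists = [xc.normalize_text(s.report) for s in samples]
vocab = xc.build_vocab(token_lists)
seqs = [xc.encode_caption(t, vocab, 40) for t in token_lists]

cfg = xc.SatConfig(vocab_size=len(vocab), embed_dim=32, hidden_dim=64,
                   attn_dim=64, dropout=0.0, max_len=40, seed=8)
sat = xc.SatModel(cfg, rng=np.random.default_rng(8))
xc.set_finetune(sat.encoder, False)
xc.train_sat(sat, images, seqs, epochs=80, lr=1e-3, batch_size=8, seed=8)

reports = [" ".join(t) for t in token_lists]
bpe = xc.train_bpe(" ".join(reports), 120)
lm_cfg = xc.TransformerConfig(vocab_size=len(bpe), layers=2, heads=2,
                              model_dim=64, ff_dim=256, block_size=256, seed=8)
lm = xc.GptLm(lm_cfg)
xc.lm_finetune(lm, continuation_corpus(reports, bpe, splits=(2,)),
               epochs=12, lr=3e-3, seed=8)

head, hist = xc.train_fusion_head(sat, lm, bpe, vocab, images[:6, 0],
                                  seqs[:6], epochs=100, lr=1e-2, seed=8)
print(f"fusion head loss {hist[0]:.3f} -> {hist[-1]:.3f}")

test = xc.generate_phantom(spec, 200)
img = test.image.astype(np.float64)
a1 = xc.generate_approach1(img, sat, lm, bpe, vocab, head, max_len=40)
a2 = xc.generate_approach2(img, sat, lm, bpe, vocab)
print("truth      :", " ".join(xc.normalize_text(test.report)))
print("approach 1 :", a1["report"])
print("approach 2 :", a2["report"])
print("  seed     :", a2["sat_seed"])
print("  continued:", a2["lm_continuation"])
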