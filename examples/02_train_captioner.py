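"""Train the soft-attention captioner on phantoms and decode with a beam.

A small CNN encodes the image into a 7x7 grid of feature vectors; at
each step the LSTM decoder softmax-attends over the 49 locations, and
the attention weights double as localization heatmaps.
"""

import numpy as np

import xraycap as xc

spec = xc.PhantomSpec(seed=3)
samples = [xc.generate_phantom(spec, i) for i in range(10)]
images = np.stack([s.image for s in samples])[:, None].astype(np.float64)
token_lists = [xc.normalize_text(s.report) for s in samples]
vocab = xc.build_vocab(token_lists)
seqs = [xc.encode_caption(t, vocab, 40) for t in token_lists]

cfg = xc.SatConfig(vocab_size=len(vocab), embed_dim=32, hidden_dim=64,
                   attn_dim=64, dropout=0.0, max_len=40, seed=3)
model = xc.SatModel(cfg, rng=np.random.default_rng(3))
# encoder fine-tuning is on by default: the CNN learns lesion detectors
history = xc.train_sat(model, images, seqs, epochs=150, lr=2e-3,
                       batch_size=2, seed=3)
print(f"loss {history[0]['loss']:.3f} -> {history[-1]['loss']:.3f}, "
      f"teacher-forcing accuracy {history[-1]['accuracy']:.3f}")

model.eval()
# decode a memorised training image (held-out generalisation needs the
# larger schedules in xraycap.studies)
sample = samples[7]
ids, alphas = model.greedy_decode(sample.image.astype(np.float64))
print("truth  :", " ".join(xc.normalize_text(sample.report)))
print("greedy :", " ".join(vocab.decode_ids(ids)))
for ids_k, score, _ in model.beam_decode(sample.image.astype(np.float64), k=3):
    print(f"beam   : {score:7.2f}  {' '.join(vocab.decode_ids(ids_k))}")

# attention heatmaps: one [0,1] map per generated word
maps = xc.attention_heatmap(alphas, side=cfg.side, image_size=224)
print(f"{len(maps)} heatmaps of shape {maps[0].shape}; "
      "each step's weights sum to", round(float(alphas[0].sum()), 6))
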