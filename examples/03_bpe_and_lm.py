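"""Byte-pair encoding and the decoder-only transformer LM.

BPE merges the most frequent adjacent symbol pairs of the report corpus
so any text can be encoded without an unknown token; the GPT-style LM
is fine-tuned self-supervised and continues a seed report from the
start-of-continuation marker, taking the second-best beam hypothesis.
"""

import xraycap as xc
from xraycap.transformer import continuation_corpus

spec = xc.PhantomSpec(seed=5)
reports = [" ".join(xc.normalize_text(xc.generate_phantom(spec, i).report))
           for i in range(80)]
corpus = " ".join(reports)

bpe = xc.train_bpe(corpus, num_merges=150)
sample = reports[0]
ids = xc.bpe_encode(sample, bpe)
print(f"'{sample[:50]}...' -> {len(ids)} subwords "
      f"({len(sample.split())} words); round-trip exact:",
      xc.bpe_decode(ids, bpe) == sample)

cfg = xc.TransformerConfig(vocab_size=len(bpe), layers=2, heads=2,
                           model_dim=64, ff_dim=256, block_size=256, seed=5)
lm = xc.GptLm(cfg)
stream = continuation_corpus(reports, bpe, splits=(2,))
history = xc.lm_finetune(lm, stream, epochs=8, lr=3e-3, seed=5)
print(f"LM loss {history[0]:.3f} -> {history[-1]:.3f} over {len(history)} epochs")

seed_text = "opacityleft . left lung opacity"
out = xc.continue_report(lm, bpe, seed_text, k=3)
print("seed        :", out["seed"])
print("continuation:", out["continuation"])
# The continuation is the 2nd-best beam hypothesis (the paper's rule);
# scores of all completed hypotheses:
print("beam scores :", [round(s, 2) for s in out["beam_scores"]])
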