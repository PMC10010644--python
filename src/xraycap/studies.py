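"""Canonical desk-scale experiments on the phantom corpus.

Each function defines one study — its data, model size and training
schedule — as a pure function of a seed, so tests and reproduction
scripts measure exactly the same conditions.  Problem sizes are chosen
for a single CPU: the captioner memorisation study uses 10 phantoms and
a tiny model; the localization study trains a small captioner on 500
phantoms with the encoder frozen (feature grids are cached once, which
makes the schedule fast) and evaluates attention placement on 50
held-out lesioned phantoms; the evaluation study trains briefly on a
few hundred phantoms and scores generated reports.
"""

from __future__ import annotations

import numpy as np

from . import bpe as bpe_mod
from . import metrics as metrics_mod
from .encoder import set_finetune
from .phantom import PhantomSpec, generate_phantom, label_token
from .report_prep import build_vocab, encode_caption, normalize_text
from .sat import (SatConfig, SatModel, attention_mass_in_mask,
                  teacher_forced_alphas, train_sat)
from .transformer import GptLm, TransformerConfig, lm_finetune, lm_loss


def _corpus(seed: int, n: int, offset: int = 0):
    spec = PhantomSpec(seed=seed)
    samples = [generate_phantom(spec, offset + i) for i in range(n)]
    images = np.stack([s.image for s in samples])[:, None].astype(np.float64)
    token_lists = [normalize_text(s.report) for s in samples]
    return spec, samples, images, token_lists


def overfit_study(seed: int = 0, n_samples: int = 10, epochs: int = 200):
    """Memorise a handful of phantoms with a tiny captioner.

    Returns the training history; the last entry's ``accuracy`` is the
    teacher-forcing next-token accuracy on the memorised set.  Training
    stops early once accuracy reaches 99.5%.
    """
    _, _, images, token_lists = _corpus(seed, n_samples)
    vocab = build_vocab(token_lists)
    seqs = [encode_caption(t, vocab, 40) for t in token_lists]
    cfg = SatConfig(vocab_size=len(vocab), embed_dim=32, hidden_dim=64,
                    attn_dim=64, dropout=0.0, max_len=40, seed=seed)
    model = SatModel(cfg, rng=np.random.default_rng(seed))
    history = []
    for chunk in range(epochs // 10):
        history += train_sat(model, images, seqs, epochs=10, lr=2e-3,
                             batch_size=2, seed=seed * 1000 + chunk)
        if history[-1]["accuracy"] >= 0.995:
            break
    return {"model": model, "vocab": vocab, "history": history,
            "accuracy": history[-1]["accuracy"],
            "epochs_run": len(history)}


def lm_memorization_study(seed: int = 0, epochs: int = 400):
    """Memorise a one-sentence corpus with a tiny transformer LM.

    Returns the final per-token training loss (early-stopped once it
    falls below 0.01, at which point the sentence is reproduced
    verbatim from any prefix).
    """
    from .transformer import continuation_corpus

    sentence = ("the cardiac silhouette is enlarged and there is a focal "
                "opacity in the left lung")
    model_bpe = bpe_mod.train_bpe(sentence, 40)
    # one plain copy and one marker-split copy, inside a single block so
    # no training window ever cuts a word in half
    ids = continuation_corpus([sentence], model_bpe, splits=(2,))
    cfg = TransformerConfig(vocab_size=len(model_bpe), layers=2, heads=2,
                            model_dim=64, ff_dim=256, block_size=256,
                            seed=seed)
    model = GptLm(cfg)
    history = []
    for chunk in range(epochs // 20):
        history += lm_finetune(model, ids, epochs=20, lr=3e-3,
                               seed=seed * 1000 + chunk)
        if history[-1] < 0.01:
            break
    return {"model": model, "bpe": model_bpe, "sentence": sentence,
            "history": history, "final_loss": history[-1]}


def localization_study(seed: int = 0, n_train: int = 500, n_heldout: int = 50,
                       epochs: int = 20):
    """Does attention land on the lesion when the lesion word is emitted?

    A small captioner (frozen random-feature encoder) is trained on
    ``n_train`` phantoms; on held-out lesioned phantoms the attention
    weights at the step that predicts each pathology's label token are
    scored against the lesion mask.  The comparison baseline is uniform
    attention, which scores exactly the mask's area fraction.
    """
    spec, train_samples, images, token_lists = _corpus(seed, n_train)
    held = []
    idx = n_train
    while len(held) < n_heldout:
        s = generate_phantom(spec, idx)
        idx += 1
        if s.masks:
            held.append(s)
    vocab = build_vocab(token_lists)
    seqs = [encode_caption(t, vocab, 40) for t in token_lists]
    cfg = SatConfig(vocab_size=len(vocab), embed_dim=48, hidden_dim=128,
                    attn_dim=128, dropout=0.1, max_len=40, seed=seed)
    model = SatModel(cfg, rng=np.random.default_rng(seed))
    set_finetune(model.encoder, False)
    history = train_sat(model, images, seqs, epochs=epochs, lr=1e-3,
                        batch_size=16, seed=seed)
    model.eval()
    masses, fracs = [], []
    for s in held:
        seq = encode_caption(normalize_text(s.report), vocab, 40)
        alphas = teacher_forced_alphas(model, s.image.astype(np.float64),
                                       seq.ids)
        for kind, mask in s.masks.items():
            pos = seq.ids.index(vocab.encode_token(label_token(kind)))
            mass, frac = attention_mass_in_mask(alphas[pos - 1], mask,
                                                cfg.side)
            masses.append(mass)
            fracs.append(frac)
    return {"model": model, "vocab": vocab, "history": history,
            "mean_mass": float(np.mean(masses)),
            "mean_area_fraction": float(np.mean(fracs)),
            "ratio": float(np.mean(masses) / np.mean(fracs)),
            "n_lesions": len(masses), "n_heldout": len(held)}


def evaluation_study(seed: int = 0, n_train: int = 300, n_eval: int = 30,
                     frozen_epochs: int = 10, joint_epochs: int = 15):
    """Train briefly, decode held-out phantoms greedily, score the output.

    The schedule warms up with the encoder frozen (cached features make
    the language side cheap to fit) and then fine-tunes jointly so the
    encoder learns lesion detectors that generalise to unseen phantoms.
    Returns the full metric report (BLEU-1..4, ROUGE-L, CIDEr, geometric
    mean BLEU, clinical-efficacy metrics over the pathology terms).
    """
    spec, train_samples, images, token_lists = _corpus(seed, n_train)
    eval_samples = [generate_phantom(spec, n_train + i) for i in range(n_eval)]
    vocab = build_vocab(token_lists)
    seqs = [encode_caption(t, vocab, 40) for t in token_lists]
    cfg = SatConfig(vocab_size=len(vocab), embed_dim=48, hidden_dim=128,
                    attn_dim=128, dropout=0.1, max_len=40, seed=seed)
    model = SatModel(cfg, rng=np.random.default_rng(seed))
    set_finetune(model.encoder, False)
    history = train_sat(model, images, seqs, epochs=frozen_epochs, lr=1e-3,
                        batch_size=16, seed=seed)
    set_finetune(model.encoder, True)
    history += train_sat(model, images, seqs, epochs=joint_epochs, lr=1e-3,
                         batch_size=16, seed=seed + 1)
    model.eval()
    cands, refs = [], []
    for s in eval_samples:
        ids, _ = model.greedy_decode(s.image.astype(np.float64))
        cands.append(" ".join(vocab.decode_ids(ids)))
        refs.append([" ".join(normalize_text(s.report))])
    labels = [label_token(k) for k in spec.catalogue if k != "none"]
    report = metrics_mod.evaluate_all(cands, refs, labels)
    return {"model": model, "vocab": vocab, "history": history,
            "candidates": cands, "references": refs, "report": report}
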