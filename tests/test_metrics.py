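"""Caption metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest

import xraycap as xc
from oracles import bleu_oracle, cider_oracle, rouge_l_oracle


def random_pairs(phantom_sentences, n=100, seed=0):
    """Candidate/reference pairs with controlled corruption."""
    rng = np.random.default_rng(seed)
    cands, refs = [], []
    for i in range(n):
        ref = phantom_sentences[i % len(phantom_sentences)].split()
        cand = list(ref)
        for _ in range(int(rng.integers(0, 4))):
            j = int(rng.integers(0, len(cand)))
            op = rng.integers(0, 3)
            if op == 0 and len(cand) > 2:
                cand.pop(j)
            elif op == 1:
                cand.insert(j, cand[int(rng.integers(0, len(cand)))])
            else:
                cand[j] = phantom_sentences[
                    int(rng.integers(0, len(phantom_sentences)))].split()[0]
        extra = phantom_sentences[int(rng.integers(0, len(phantom_sentences)))]
        refs.append([" ".join(ref)] + ([extra] if rng.random() < 0.3 else []))
        cands.append(" ".join(cand))
    return cands, refs


# ---- hand-worked examples -------------------------------------------
def test_bleu_identity_is_one():
    scores = xc.bleu(["the lungs are clear"], [["the lungs are clear"]])
    assert all(s == pytest.approx(1.0) for s in scores)


def test_bleu_clipped_unigram_precision():
    # candidate "the the the the" vs reference "the cat": clipped count 1,
    # total 4 -> p1 = 1/4; brevity penalty exp(1 - 2/4) applies
    scores = xc.bleu(["the the the the"], [["the cat"]])
    assert scores[0] == pytest.approx(0.25, abs=1e-12)


def test_rouge_l_hand_example():
    # "a b c" vs "a c": LCS 2, R = 1, P = 2/3, beta = 1.2
    beta2 = 1.2 ** 2
    expected = (1 + beta2) * 1.0 * (2 / 3) / (1.0 + beta2 * (2 / 3))
    assert xc.rouge_l(["a b c"], [["a c"]]) == pytest.approx(expected, abs=1e-6)


def test_rouge_l_identity_and_disjoint():
    assert xc.rouge_l(["x y z"], [["x y z"]]) == pytest.approx(1.0)
    assert xc.rouge_l(["x y"], [["p q"]]) == 0.0


def test_cider_identity_scores_ten(phantom_sentences):
    cands = list(dict.fromkeys(phantom_sentences))[:8]
    per = xc.cider_per_sample(cands, [[c] for c in cands])
    for s, cand in zip(per, cands):
        if len(cand.split()) >= 4:
            assert s == pytest.approx(10.0, abs=1e-6)


def test_cider_disjoint_is_zero(phantom_sentences):
    cands = ["zzz qqq www rrr"] * 3
    refs = [[s] for s in phantom_sentences[:3]]
    assert xc.cider(cands, refs) == pytest.approx(0.0, abs=1e-12)


def test_gm_bleu():
    assert xc.gm_bleu([1, 1, 1, 1]) == 1.0
    assert xc.gm_bleu([0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)
    assert xc.gm_bleu([0.9, 0.0, 0.5, 0.5]) == 0.0
    with pytest.raises(ValueError):
        xc.gm_bleu([-0.1, 1, 1, 1])


# ---- oracle equivalence ---------------------------------------------
def test_bleu_matches_oracle(phantom_sentences):
    cands, refs = random_pairs(phantom_sentences, 100)
    mine = xc.bleu(cands, refs)
    oracle = bleu_oracle([c.split() for c in cands],
                         [[r.split() for r in rl] for rl in refs])
    assert np.allclose(mine, oracle, atol=1e-4)


def test_rouge_matches_oracle(phantom_sentences):
    cands, refs = random_pairs(phantom_sentences, 100, seed=1)
    mine = xc.rouge_l(cands, refs)
    oracle = rouge_l_oracle([c.split() for c in cands],
                            [[r.split() for r in rl] for rl in refs])
    assert mine == pytest.approx(oracle, abs=1e-6)


def test_cider_matches_oracle(phantom_sentences):
    cands, refs = random_pairs(phantom_sentences, 100, seed=2)
    mine = xc.cider(cands, refs)
    oracle = cider_oracle([c.split() for c in cands],
                          [[r.split() for r in rl] for rl in refs])
    assert mine == pytest.approx(oracle, abs=1e-3)


# ---- properties ------------------------------------------------------
def test_metrics_permutation_invariant(phantom_sentences):
    cands, refs = random_pairs(phantom_sentences, 20, seed=3)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(cands))
    c2 = [cands[i] for i in perm]
    r2 = [refs[i] for i in perm]
    assert np.allclose(xc.bleu(cands, refs), xc.bleu(c2, r2), atol=1e-12)
    assert xc.rouge_l(cands, refs) == pytest.approx(xc.rouge_l(c2, r2))
    assert xc.cider(cands, refs) == pytest.approx(xc.cider(c2, r2))


def test_corrupting_matched_token_never_raises_bleu1(phantom_sentences):
    rng = np.random.default_rng(4)
    for i in range(10):
        ref = phantom_sentences[i]
        cand = ref.split()
        base = xc.bleu([" ".join(cand)], [[ref]])[0]
        j = int(rng.integers(0, len(cand)))
        cand[j] = "zzzz"
        corrupted = xc.bleu([" ".join(cand)], [[ref]])[0]
        assert corrupted <= base + 1e-12


def test_bleu_rejects_empty():
    with pytest.raises(ValueError):
        xc.bleu([], [])


# ---- clinical efficacy ----------------------------------------------
def test_ce_perfect_match_is_all_ones(phantom_batch):
    labels = [xc.phantom.label_token(k)
              for k in xc.phantom.PATHOLOGY_KINDS if k != "none"]
    reports = [s.report for s in phantom_batch]
    ce = xc.ce_metrics(reports, reports, labels)
    tp_present = ce["tp"] > 0
    assert tp_present
    assert ce["accuracy"] == 1.0 and ce["precision"] == 1.0
    assert ce["recall"] == 1.0 and ce["f1"] == 1.0


def test_ce_hand_pooled_contingency():
    # 2 samples x 2 labels pooled to TP=1 FP=1 FN=1 TN=1
    labels = ["la", "lb"]
    generated = ["la here", "lb wrongly"]
    reference = ["la and lb", "clean"]
    ce = xc.ce_metrics(generated, reference, labels)
    assert (ce["tp"], ce["fp"], ce["fn"], ce["tn"]) == (1, 1, 1, 1)
    assert ce["accuracy"] == 0.5
    assert ce["precision"] == 0.5
    assert ce["recall"] == 0.5
    assert ce["f1"] == 0.5


def test_ce_degenerate_no_mentions():
    ce = xc.ce_metrics(["all clear"], ["nothing here"], ["opacity"])
    assert ce["accuracy"] == 1.0
    assert ce["precision"] == 0.0 and ce["recall"] == 0.0 and ce["f1"] == 0.0


def test_ce_rejects_empty_vocabulary():
    with pytest.raises(ValueError):
        xc.ce_metrics(["a"], ["a"], [])


def test_extract_labels_normalises():
    v = xc.extract_labels("Opacity_Left present", ["opacityleft", "other"])
    assert list(v) == [True, False]


def test_evaluate_all_schema(phantom_sentences):
    cands, refs = random_pairs(phantom_sentences, 10, seed=5)
    rep = xc.evaluate_all(cands, refs, ["left", "right"])
    d = rep.as_dict()
    assert len(d["bleu"]) == 4
    assert 0 <= d["rouge_l"] <= 1 and 0 <= d["cider"] <= 10
    assert d["gm_bleu"] == pytest.approx(xc.gm_bleu(d["bleu"]))
    assert {"accuracy", "precision", "recall", "f1"} <= set(d["ce"])
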