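"""Caption evaluation: BLEU-1..4, ROUGE-L, CIDEr, and clinical efficacy.

All metrics tokenize through the same :func:`normalize_text` used for
training, so scores are consistent with what the models saw.

* BLEU-n: corpus-level modified (clipped) n-gram precision with the
  brevity penalty; BLEU-n uses n-grams up to order n (geometric mean of
  p_1..p_n).
* ROUGE-L: longest-common-subsequence F-measure with the captioning
  convention beta = 1.2, max over references, averaged over samples.
* CIDEr: TF-IDF weighted n-gram cosine consensus (n = 1..4) with count
  clipping and a Gaussian length penalty (sigma = 6), averaged over n
  and references, scaled by 10.
* Clinical efficacy (CE): a binary presence vector over a closed label
  vocabulary is extracted from each text by exact term matching;
  TP/FP/FN/TN are pooled over all (sample, label) pairs
  (micro-averaging) into accuracy, precision, recall and F1.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .report_prep import normalize_text


@dataclass
class MetricReport:
    bleu: list                  # BLEU-1..4
    rouge_l: float
    cider: float
    gm_bleu: float
    ce: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"bleu": list(self.bleu), "rouge_l": self.rouge_l,
                "cider": self.cider, "gm_bleu": self.gm_bleu,
                "ce": dict(self.ce)}


def _ngrams(tokens, n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def _tokenize_pairs(candidates, reference_lists):
    cands = [normalize_text(c) if isinstance(c, str) else list(c)
             for c in candidates]
    refs = [[normalize_text(r) if isinstance(r, str) else list(r)
             for r in rl] for rl in reference_lists]
    return cands, refs


def bleu(candidates, reference_lists, max_n: int = 4) -> list:
    """Corpus-level BLEU-1..max_n (each using n-grams up to that order)."""
    if not candidates:
        raise ValueError("empty candidate set")
    if len(candidates) != len(reference_lists):
        raise ValueError("one reference list per candidate required")
    cands, refs = _tokenize_pairs(candidates, reference_lists)
    clipped = np.zeros(max_n)
    total = np.zeros(max_n)
    cand_len, ref_len = 0, 0
    for cand, rl in zip(cands, refs):
        cand_len += len(cand)
        # closest reference length (ties toward the shorter reference)
        ref_len += min((abs(len(r) - len(cand)), len(r)) for r in rl)[1]
        for n in range(1, max_n + 1):
            cg = _ngrams(cand, n)
            if not cg:
                continue
            max_ref = Counter()
            for r in rl:
                for g, c in _ngrams(r, n).items():
                    max_ref[g] = max(max_ref[g], c)
            clipped[n - 1] += sum(min(c, max_ref[g]) for g, c in cg.items())
            total[n - 1] += sum(cg.values())
    bp = 1.0 if cand_len > ref_len else float(np.exp(1.0 - ref_len / max(cand_len, 1)))
    precisions = [clipped[i] / total[i] if total[i] else 0.0 for i in range(max_n)]
    scores = []
    for n in range(1, max_n + 1):
        ps = precisions[:n]
        if min(ps) == 0.0:
            scores.append(0.0)
        else:
            scores.append(bp * float(np.exp(np.mean(np.log(ps)))))
    return scores


def _lcs_len(a, b) -> int:
    if not a or not b:
        return 0
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=np.int64)
    for i, x in enumerate(a, 1):
        for j, y in enumerate(b, 1):
            dp[i, j] = dp[i - 1, j - 1] + 1 if x == y else max(dp[i - 1, j],
                                                               dp[i, j - 1])
    return int(dp[len(a), len(b)])


def rouge_l_single(cand, ref, beta: float = 1.2) -> float:
    lcs = _lcs_len(cand, ref)
    if lcs == 0:
        return 0.0
    rec = lcs / len(ref)
    prec = lcs / len(cand)
    return ((1 + beta ** 2) * rec * prec) / (rec + beta ** 2 * prec)


def rouge_l(candidates, reference_lists, beta: float = 1.2) -> float:
    """Mean over samples of the max-over-references LCS F-measure."""
    cands, refs = _tokenize_pairs(candidates, reference_lists)
    scores = [max(rouge_l_single(c, r, beta) for r in rl)
              for c, rl in zip(cands, refs)]
    return float(np.mean(scores))


def cider(candidates, reference_lists, max_n: int = 4,
          sigma: float = 6.0) -> float:
    """Consensus metric: clipped TF-IDF n-gram cosine, scaled to [0, 10]."""
    return float(np.mean(cider_per_sample(candidates, reference_lists,
                                          max_n=max_n, sigma=sigma)))


def cider_per_sample(candidates, reference_lists, max_n: int = 4,
                     sigma: float = 6.0) -> list:
    """Per-sample CIDEr scores (IDF taken over the whole reference corpus)."""
    cands, refs = _tokenize_pairs(candidates, reference_lists)
    if len(cands) < 2:
        warnings.warn("CIDEr IDF is degenerate on a single-sample corpus")
    # document frequency over reference sets
    doc_freq = [Counter() for _ in range(max_n)]
    for rl in refs:
        for n in range(1, max_n + 1):
            seen = set()
            for r in rl:
                seen.update(_ngrams(r, n))
            for g in seen:
                doc_freq[n - 1][g] += 1
    n_images = len(refs)

    def tfidf(counts: Counter, n: int) -> dict:
        return {g: c * np.log(max(n_images, 1.0e-9) / max(doc_freq[n - 1][g], 1))
                if doc_freq[n - 1][g] > 0 else 0.0
                for g, c in counts.items()}

    sample_scores = []
    for cand, rl in zip(cands, refs):
        per_n = np.zeros(max_n)
        for n in range(1, max_n + 1):
            cg = _ngrams(cand, n)
            cvec = tfidf(cg, n)
            cnorm = float(np.sqrt(sum(v * v for v in cvec.values())))
            acc = 0.0
            for r in rl:
                rg = _ngrams(r, n)
                rvec = tfidf(rg, n)
                rnorm = float(np.sqrt(sum(v * v for v in rvec.values())))
                if cnorm == 0 or rnorm == 0:
                    continue
                # clip candidate counts by the reference counts
                num = sum(min(cvec[g], rvec.get(g, 0.0)) * rvec.get(g, 0.0)
                          for g in cvec)
                delta = len(cand) - len(r)
                penalty = float(np.exp(-(delta ** 2) / (2 * sigma ** 2)))
                acc += penalty * num / (cnorm * rnorm)
            per_n[n - 1] = acc / len(rl)
        sample_scores.append(10.0 * float(per_n.mean()))
    return sample_scores


def gm_bleu(bleu_scores) -> float:
    """Geometric mean of the four BLEU scores (0 if any component is 0)."""
    b = np.asarray(bleu_scores, dtype=np.float64)
    if np.any(b < 0):
        raise ValueError("BLEU components must be >= 0")
    if np.any(b == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(b))))


def _contains_term(tokens, term_tokens) -> bool:
    k = len(term_tokens)
    return any(tokens[i:i + k] == term_tokens for i in range(len(tokens) - k + 1))


def extract_labels(text, label_vocabulary) -> np.ndarray:
    """Binary presence vector over the closed label-term vocabulary."""
    tokens = normalize_text(text) if isinstance(text, str) else list(text)
    out = np.zeros(len(label_vocabulary), dtype=bool)
    for j, term in enumerate(label_vocabulary):
        term_tokens = normalize_text(term) if isinstance(term, str) else list(term)
        out[j] = _contains_term(tokens, term_tokens)
    return out


def ce_metrics(generated, references, label_vocabulary) -> dict:
    """Micro-averaged clinical-efficacy metrics over (sample, label) pairs."""
    if not list(label_vocabulary):
        raise ValueError("empty label vocabulary")
    tp = fp = fn = tn = 0
    for gen, ref in zip(generated, references):
        g = extract_labels(gen, label_vocabulary)
        r = extract_labels(ref, label_vocabulary)
        tp += int(np.sum(g & r))
        fp += int(np.sum(g & ~r))
        fn += int(np.sum(~g & r))
        tn += int(np.sum(~g & ~r))
    total = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"accuracy": (tp + tn) / total if total else 0.0,
            "precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def evaluate_all(candidates, reference_lists, label_vocabulary=None,
                 reference_texts=None) -> MetricReport:
    """Full metric report for a generated corpus."""
    b = bleu(candidates, reference_lists)
    report = MetricReport(
        bleu=b,
        rouge_l=rouge_l(candidates, reference_lists),
        cider=cider(candidates, reference_lists),
        gm_bleu=gm_bleu(b),
    )
    if label_vocabulary is not None:
        refs = (reference_texts if reference_texts is not None
                else [rl[0] for rl in reference_lists])
        report.ce = ce_metrics(candidates, refs, label_vocabulary)
    return report
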