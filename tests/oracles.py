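"""Independent brute-force oracles used by the test suite.

Everything here is written from the mathematical definitions with
deliberately different structure from the package implementations
(scalar loops instead of vectorised code, dict-of-loops n-gram
counting), so agreement between the two routes is evidence of
correctness rather than a tautology.
"""

import math
from itertools import product

import numpy as np


# ---- scalar re-implementations of the captioner equations -----------
def lstm_step_scalar(W, b, emb, h_prev, c_prev, ctx):
    """One LSTM step on concat([emb, h_prev, ctx]), gate order i,f,o,g."""
    x = list(emb) + list(h_prev) + list(ctx)
    n = len(h_prev)
    z = [sum(W[r][k] * x[k] for k in range(len(x))) + b[r]
         for r in range(4 * n)]
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    i = [sig(z[r]) for r in range(0, n)]
    f = [sig(z[r]) for r in range(n, 2 * n)]
    o = [sig(z[r]) for r in range(2 * n, 3 * n)]
    g = [math.tanh(z[r]) for r in range(3 * n, 4 * n)]
    c = [f[j] * c_prev[j] + i[j] * g[j] for j in range(n)]
    h = [o[j] * math.tanh(c[j]) for j in range(n)]
    return h, c


def attend_scalar(Wf, Wh, bh, v, feats, h_prev):
    """Additive attention: e_i = v . relu(Wf a_i + Wh h + bh)."""
    N = len(feats)
    scores = []
    for i in range(N):
        pre = [sum(Wf[k][a] * feats[i][k] for k in range(len(feats[i])))
               + sum(Wh[k][a] * h_prev[k] for k in range(len(h_prev))) + bh[a]
               for a in range(len(bh))]
        act = [max(0.0, p) for p in pre]
        scores.append(sum(v[a] * act[a] for a in range(len(act))))
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    Z = sum(exps)
    alpha = [e / Z for e in exps]
    ctx = [sum(alpha[i] * feats[i][k] for i in range(N))
           for k in range(len(feats[0]))]
    return alpha, ctx


def deep_output_scalar(Lh, La, Lo, bo, emb, h, ctx):
    """softmax(Lo (Lh h + La ctx + emb) + bo) by scalar arithmetic."""
    m = len(emb)
    d = [sum(Lh[k][j] * h[k] for k in range(len(h)))
         + sum(La[k][j] * ctx[k] for k in range(len(ctx))) + emb[j]
         for j in range(m)]
    logits = [sum(Lo[j][w] * d[j] for j in range(m)) + bo[w]
              for w in range(len(bo))]
    mx = max(logits)
    exps = [math.exp(x - mx) for x in logits]
    Z = sum(exps)
    return [e / Z for e in exps]


# ---- exhaustive sequence enumeration for beam-search checks ---------
def enumerate_sequences(step_table, start_id, end_id, vocab_size, max_len):
    """Score every token sequence of length <= max_len by brute force.

    ``step_table(prev_tokens) -> log-prob vector`` mirrors the model
    interface but is called on explicit prefixes.  Returns a list of
    (ids_tuple, total_log_prob) for every complete (ended or cut-off)
    sequence, sorted by decreasing score then lexicographic ids.
    """
    results = []

    def rec(prefix, score):
        if len(prefix) == max_len:
            results.append((prefix, score))
            return
        logp = step_table(prefix)
        for tok in range(vocab_size):
            s = score + logp[tok]
            if tok == end_id:
                results.append((prefix, s))
            else:
                rec(prefix + (tok,), s)

    rec((), 0.0)
    results.sort(key=lambda r: (-r[1], r[0]))
    return results


# ---- greedy BPE segmentation oracle ---------------------------------
def bpe_segment_oracle(word, merges):
    """Apply merges in learned order; plain-list scan per merge."""
    symbols = list(word) + ["</w>"]
    for left, right in merges:
        out = []
        i = 0
        while i < len(symbols):
            if (i < len(symbols) - 1 and symbols[i] == left
                    and symbols[i + 1] == right):
                out.append(left + right)
                i += 2
            else:
                out.append(symbols[i])
                i += 1
        symbols = out
    return symbols


# ---- metric oracles -------------------------------------------------
def _count_ngrams(tokens, n):
    counts = {}
    for i in range(len(tokens) - n + 1):
        g = tuple(tokens[i:i + n])
        counts[g] = counts.get(g, 0) + 1
    return counts


def bleu_oracle(cands, refs_lists, max_n=4):
    """Corpus BLEU-1..4 from the definition: clipped precision + BP."""
    num = [0] * max_n
    den = [0] * max_n
    c_len = 0
    r_len = 0
    for cand, refs in zip(cands, refs_lists):
        c_len += len(cand)
        best = None
        for r in refs:
            key = (abs(len(r) - len(cand)), len(r))
            if best is None or key < best:
                best = key
        r_len += best[1]
        for n in range(1, max_n + 1):
            cg = _count_ngrams(cand, n)
            for g, c in cg.items():
                mx = 0
                for r in refs:
                    rc = _count_ngrams(r, n).get(g, 0)
                    mx = max(mx, rc)
                num[n - 1] += min(c, mx)
                den[n - 1] += c
    bp = 1.0 if c_len > r_len else math.exp(1 - r_len / max(c_len, 1))
    out = []
    for n in range(1, max_n + 1):
        ps = []
        ok = True
        for k in range(n):
            if den[k] == 0 or num[k] == 0:
                ok = False
                break
            ps.append(num[k] / den[k])
        out.append(bp * math.exp(sum(math.log(p) for p in ps) / n) if ok else 0.0)
    return out


def lcs_oracle(a, b):
    """Recursive LCS with memoisation — independent of the DP-table route."""
    memo = {}

    def rec(i, j):
        if i == len(a) or j == len(b):
            return 0
        if (i, j) not in memo:
            if a[i] == b[j]:
                memo[(i, j)] = 1 + rec(i + 1, j + 1)
            else:
                memo[(i, j)] = max(rec(i + 1, j), rec(i, j + 1))
        return memo[(i, j)]

    return rec(0, 0)


def rouge_l_oracle(cands, refs_lists, beta=1.2):
    scores = []
    for cand, refs in zip(cands, refs_lists):
        best = 0.0
        for r in refs:
            l = lcs_oracle(cand, r)
            if l == 0:
                continue
            rec = l / len(r)
            prec = l / len(cand)
            f = (1 + beta * beta) * rec * prec / (rec + beta * beta * prec)
            best = max(best, f)
        scores.append(best)
    return sum(scores) / len(scores)


def cider_oracle(cands, refs_lists, max_n=4, sigma=6.0):
    n_images = len(refs_lists)
    scores = []
    df = [{} for _ in range(max_n)]
    for refs in refs_lists:
        for n in range(1, max_n + 1):
            seen = set()
            for r in refs:
                seen |= set(_count_ngrams(r, n))
            for g in seen:
                df[n - 1][g] = df[n - 1].get(g, 0) + 1

    def vec(tokens, n):
        counts = _count_ngrams(tokens, n)
        out = {}
        for g, c in counts.items():
            d = df[n - 1].get(g, 0)
            out[g] = c * math.log(n_images / d) if d > 0 else 0.0
        return out

    for cand, refs in zip(cands, refs_lists):
        total = 0.0
        for n in range(1, max_n + 1):
            cvec = vec(cand, n)
            cnorm = math.sqrt(sum(v * v for v in cvec.values()))
            acc = 0.0
            for r in refs:
                rvec = vec(r, n)
                rnorm = math.sqrt(sum(v * v for v in rvec.values()))
                if cnorm == 0 or rnorm == 0:
                    continue
                s = 0.0
                for g, cv in cvec.items():
                    s += min(cv, rvec.get(g, 0.0)) * rvec.get(g, 0.0)
                pen = math.exp(-((len(cand) - len(r)) ** 2) / (2 * sigma * sigma))
                acc += pen * s / (cnorm * rnorm)
            total += acc / len(refs)
        scores.append(10.0 * total / max_n)
    return sum(scores) / len(scores)
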