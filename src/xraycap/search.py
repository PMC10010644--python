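"""Length-synchronous K-beam search over a generic stepping model.

Both language models in the package decode through this one routine,
so search behaviour (scoring, tie-breaking, retirement of completed
hypotheses) is identical everywhere and can be checked once against
exhaustive enumeration on toy models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Hypothesis:
    ids: tuple          # emitted token ids (without the start token)
    score: float        # total log-probability
    state: object


def beam_search(step_fn, init_state, start_id: int, end_id: int,
                k: int, max_len: int):
    """Top-``k`` sequences by summed log-probability.

    ``step_fn(state, token_id) -> (new_state, log_probs)`` advances the
    model by one token and returns the log-probability vector for the
    next token.  Hypotheses are retired when they emit ``end_id`` (the
    end token is not included in ``ids``); all hypotheses are cut off at
    ``max_len`` emitted tokens.  Ties are broken toward the lowest token
    id, so decoding is fully deterministic.

    Returns a list of at most ``k`` ``Hypothesis`` objects sorted by
    decreasing score (ties: lexicographically smaller id sequence first).
    """
    if k < 1:
        raise ValueError("beam width k must be >= 1")
    state0, logp0 = step_fn(init_state, start_id)
    live = _expand([(0.0, (), state0, logp0)], k, end_id)
    live, completed = _partition(live, end_id)
    steps = 1
    while live and steps < max_len:
        frontier = []
        for h in live:
            new_state, logp = step_fn(h.state, h.ids[-1])
            frontier.append((h.score, h.ids, new_state, logp))
        live = _expand(frontier, k, end_id)
        live, done = _partition(live, end_id)
        completed.extend(done)
        steps += 1
        if len(completed) >= k and live and \
                max(h.score for h in live) < min(sorted(
                    (c.score for c in completed), reverse=True)[:k]):
            break
    # force-complete anything still live at the length bound
    completed.extend(live)
    completed.sort(key=lambda h: (-h.score, h.ids))
    return completed[:k]


def _expand(frontier, k, end_id):
    """Grow every hypothesis by one token, keep the best k extensions."""
    candidates = []
    for score, ids, state, logp in frontier:
        logp = np.asarray(logp, dtype=np.float64)
        # k + 1 extensions per hypothesis: up to one may retire at the
        # end token while still leaving k live continuations
        order = np.argsort(-logp, kind="stable")[: k + 1]
        for tok in order:
            candidates.append(Hypothesis(ids=ids + (int(tok),),
                                         score=score + float(logp[tok]),
                                         state=state))
    candidates.sort(key=lambda h: (-h.score, h.ids))
    return candidates[:k]


def _partition(hyps, end_id):
    live, done = [], []
    for h in hyps:
        if h.ids[-1] == end_id:
            done.append(Hypothesis(ids=h.ids[:-1], score=h.score, state=h.state))
        else:
            live.append(h)
    return live, done


def greedy_search(step_fn, init_state, start_id: int, end_id: int, max_len: int):
    """Argmax decoding; ties go to the lowest token id (np.argmax rule)."""
    state, ids, score = init_state, [], 0.0
    prev = start_id
    for _ in range(max_len):
        state, logp = step_fn(state, prev)
        tok = int(np.argmax(logp))
        score += float(logp[tok])
        if tok == end_id:
            break
        ids.append(tok)
        prev = tok
    return Hypothesis(ids=tuple(ids), score=score, state=state)
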