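"""Byte-pair-encoding subword tokenizer for the transformer LM.

Merges are learned greedily: at each step the most frequent adjacent
symbol pair over the training corpus is merged (ties broken by taking
the lexicographically smallest pair); learning stops early once no pair
occurs at least twice.  Each whitespace word is terminated by an
explicit end-of-word symbol before merging, so word boundaries survive
the round trip.  Characters never seen in training fall back to byte
tokens (``<0xNN>``), so encoding never needs an unknown token: any text
can be encoded and decoded exactly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

EOW = "</w>"
START_TOKEN = "<start>"          # start-of-continuation marker
END_OF_TEXT = "<|endoftext|>"
_BYTE_TOKENS = tuple(f"<0x{b:02X}>" for b in range(256))


@dataclass
class BpeModel:
    merges: list                      # list of (left, right) pairs, in learned order
    vocab: dict                       # symbol -> id
    inv_vocab: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.inv_vocab:
            self.inv_vocab = {i: s for s, i in self.vocab.items()}
        self._ranks = {tuple(p): r for r, p in enumerate(self.merges)}

    @property
    def start_id(self) -> int:
        return self.vocab[START_TOKEN]

    @property
    def end_of_text_id(self) -> int:
        return self.vocab[END_OF_TEXT]

    def __len__(self):
        return len(self.vocab)

    def to_json(self) -> str:
        return json.dumps({"merges": [list(p) for p in self.merges],
                           "vocab": self.vocab})

    @classmethod
    def from_json(cls, text: str) -> "BpeModel":
        obj = json.loads(text)
        return cls(merges=[tuple(p) for p in obj["merges"]], vocab=obj["vocab"])


def _word_symbols(word: str, charset=None) -> list:
    """Split a word into initial symbols, byte-falling-back unseen chars."""
    symbols = []
    for ch in word:
        if charset is not None and ch not in charset:
            symbols.extend(_BYTE_TOKENS[b] for b in ch.encode("utf-8"))
        else:
            symbols.append(ch)
    symbols.append(EOW)
    return symbols


def _pair_counts(words: dict) -> Counter:
    counts = Counter()
    for symbols, freq in words.values():
        for pair in zip(symbols, symbols[1:]):
            counts[pair] += freq
    return counts


def _merge_word(symbols: list, pair: tuple) -> list:
    merged = pair[0] + pair[1]
    out, i = [], 0
    while i < len(symbols):
        if i + 1 < len(symbols) and symbols[i] == pair[0] and symbols[i + 1] == pair[1]:
            out.append(merged)
            i += 2
        else:
            out.append(symbols[i])
            i += 1
    return out


def train_bpe(corpus: str, num_merges: int) -> BpeModel:
    """Learn ``num_merges`` greedy merges from whitespace-tokenized text."""
    if not corpus.strip():
        raise ValueError("empty corpus")
    if num_merges < 0:
        raise ValueError("num_merges must be >= 0")
    word_freq = Counter(corpus.split())
    words = {w: (_word_symbols(w), f) for w, f in word_freq.items()}
    charset = {ch for w in word_freq for ch in w}

    merges = []
    symbols_seen = set(charset) | {EOW}
    for _ in range(num_merges):
        counts = _pair_counts(words)
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break
        pair = min(p for p, c in counts.items() if c == best_count)
        merges.append(pair)
        symbols_seen.add(pair[0] + pair[1])
        words = {w: (_merge_word(s, pair), f) for w, (s, f) in words.items()}

    ordered = [START_TOKEN, END_OF_TEXT, *_BYTE_TOKENS]
    ordered += sorted(symbols_seen)
    vocab = {s: i for i, s in enumerate(ordered)}
    return BpeModel(merges=merges, vocab=vocab)


def segment_word(word: str, model: BpeModel) -> list:
    """Apply learned merges, in order, to one whitespace word."""
    charset = {s for s in model.vocab if len(s) == 1}
    symbols = _word_symbols(word, charset=charset)
    for pair in model.merges:
        if len(symbols) < 2:
            break
        symbols = _merge_word(symbols, pair)
    return symbols


def bpe_encode(text: str, model: BpeModel) -> list:
    """Encode whitespace-normalized text to subword ids (no unk ever)."""
    ids = []
    for word in text.split():
        for sym in segment_word(word, model):
            ids.append(model.vocab[sym])
    return ids


def bpe_decode(ids, model: BpeModel) -> str:
    """Invert :func:`bpe_encode`; words are re-joined with single spaces."""
    words, current, byte_buf = [], [], []

    def flush_bytes():
        if byte_buf:
            # model-generated byte sequences need not be valid UTF-8
            current.append(bytes(byte_buf).decode("utf-8", errors="replace"))
            byte_buf.clear()

    for idx in ids:
        sym = model.inv_vocab[int(idx)]
        if sym in (START_TOKEN, END_OF_TEXT):
            continue
        if sym.startswith("<0x") and sym.endswith(">") and len(sym) == 6:
            byte_buf.append(int(sym[3:5], 16))
            continue
        flush_bytes()
        if sym.endswith(EOW):
            stem = sym[: -len(EOW)]
            if stem:
                current.append(stem)
            words.append("".join(current))
            current = []
        else:
            current.append(sym)
    flush_bytes()
    if current:
        words.append("".join(current))
    return " ".join(w for w in words if w)
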