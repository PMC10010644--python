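"""Radiology-report preprocessing for the word-level captioner.

The target caption for an image is the concatenation of the report's
impression and findings sections (a report with both sections empty is
excluded).  Text is lower-cased, whitespace-tokenized, and stripped of
non-alphanumeric characters; abbreviations can be expanded from a
user-supplied dictionary; pathology label tokens are prepended to the
report so the captioner sees a summary "sentence" first.  A closed
word vocabulary with four fixed special tokens maps captions to id
sequences, and batches are padded and sorted by decreasing length so a
per-step effective batch size can skip pad positions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from collections import Counter

import numpy as np


class Excluded:
    """Sentinel for reports whose impression and findings are both empty."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "EXCLUDED"


EXCLUDED = Excluded()


class ConfigurationError(ValueError):
    pass


def assemble_report(impression: str, findings: str):
    """Join the two report sections; EXCLUDED if both are empty."""
    parts = [p.strip() for p in (impression, findings)]
    parts = [p for p in parts if p]
    if not parts:
        return EXCLUDED
    return " ".join(parts)


_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_text(text: str) -> list:
    """Lowercase, whitespace-tokenize, strip non-alphanumeric characters."""
    tokens = []
    for raw in text.lower().split():
        tok = _NON_ALNUM.sub("", raw)
        if tok:
            tokens.append(tok)
    return tokens


def expand_abbreviations(tokens, abbrev_map: dict) -> list:
    """Single-pass replacement of abbreviation tokens by their expansions."""
    out = []
    for tok in tokens:
        expansion = abbrev_map.get(tok)
        if expansion is None:
            out.append(tok)
        else:
            out.extend(expansion)
    return out


def load_abbreviations(path) -> dict:
    """Load a two-column TSV (token -> space-separated expansion).

    Keys and expansions are normalized.  A cyclic map (a key whose
    expansion leads back to itself through other keys) is rejected.
    """
    mapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ConfigurationError(f"{path}:{lineno}: expected 2 columns")
            key = _NON_ALNUM.sub("", cols[0].lower())
            expansion = normalize_text(cols[1])
            if not key or not expansion:
                raise ConfigurationError(f"{path}:{lineno}: empty key or expansion")
            mapping[key] = expansion
    _check_acyclic(mapping, path)
    return mapping


def _check_acyclic(mapping: dict, origin):
    for start in mapping:
        seen = {start}
        frontier = [t for t in mapping[start] if t in mapping]
        while frontier:
            tok = frontier.pop()
            if tok in seen:
                raise ConfigurationError(
                    f"cyclic abbreviation map in {origin}: involves '{tok}'")
            seen.add(tok)
            frontier.extend(t for t in mapping[tok] if t in mapping)


def prepend_labels(labels, report_text: str) -> str:
    """Prefix the report with its label tokens, terminated by a period."""
    labels = list(labels)
    if not labels:
        return report_text
    return " ".join(labels) + " . " + report_text


@dataclass
class TokenSequence:
    ids: list
    length: int  # count excluding pad, including start/end framing


class Vocabulary:
    """Closed word vocabulary with fixed special ids 0..3."""

    START, END, PAD, UNK = "<start>", "<end>", "<pad>", "<unk>"
    SPECIALS = (START, END, PAD, UNK)
    START_ID, END_ID, PAD_ID, UNK_ID = 0, 1, 2, 3

    def __init__(self, words):
        self.word_to_id = {w: i for i, w in enumerate(self.SPECIALS)}
        for w in words:
            if w in self.word_to_id:
                raise ValueError(f"duplicate or reserved word: {w}")
            self.word_to_id[w] = len(self.word_to_id)
        self.id_to_word = {i: w for w, i in self.word_to_id.items()}

    def __len__(self):
        return len(self.word_to_id)

    def __contains__(self, word):
        return word in self.word_to_id

    def encode_token(self, word: str) -> int:
        return self.word_to_id.get(word, self.UNK_ID)

    def decode_id(self, idx: int) -> str:
        return self.id_to_word[int(idx)]

    def decode_ids(self, ids, strip_special: bool = True) -> list:
        words = [self.id_to_word[int(i)] for i in ids]
        if strip_special:
            words = [w for w in words if w not in self.SPECIALS]
        return words

    def to_json(self) -> str:
        non_special = [self.id_to_word[i] for i in range(4, len(self.word_to_id))]
        return json.dumps({"words": non_special})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls(json.loads(text)["words"])


def build_vocab(corpus, min_freq: int = 1) -> Vocabulary:
    """Vocabulary over token lists, ordered by frequency desc then lexicographic.

    ``min_freq`` defaults to 1 (closed vocabulary on phantom corpora);
    rarer tokens map to the unk id at encode time.
    """
    counts = Counter()
    n_docs = 0
    for tokens in corpus:
        n_docs += 1
        counts.update(tokens)
    if n_docs == 0 or not counts:
        raise ValueError("empty corpus")
    kept = sorted((w for w, c in counts.items() if c >= min_freq),
                  key=lambda w: (-counts[w], w))
    return Vocabulary(kept)


def encode_caption(tokens, vocab: Vocabulary, max_len: int = 100) -> TokenSequence:
    """Frame with start/end, map through the vocabulary, truncate to max_len."""
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    body = [vocab.encode_token(t) for t in tokens[: max_len - 2]]
    ids = [vocab.START_ID] + body + [vocab.END_ID]
    return TokenSequence(ids=ids, length=len(ids))


def pad_and_sort(sequences):
    """Pad to a matrix and sort rows by decreasing true length (stable).

    Returns ``(matrix, lengths, permutation)`` where ``matrix[i]`` is the
    sequence originally at position ``permutation[i]``; lengths are in
    decreasing order.
    """
    lengths = np.array([s.length for s in sequences], dtype=np.int64)
    perm = np.argsort(-lengths, kind="stable")
    max_len = int(lengths.max())
    mat = np.full((len(sequences), max_len), Vocabulary.PAD_ID, dtype=np.int64)
    for row, src in enumerate(perm):
        seq = sequences[src]
        mat[row, : seq.length] = seq.ids
    return mat, lengths[perm], perm


def effective_batch_sizes(sorted_lengths) -> list:
    """Number of sequences still active at each time step (1-indexed steps)."""
    lengths = np.asarray(sorted_lengths)
    if np.any(np.diff(lengths) > 0):
        raise ValueError("lengths must be sorted in decreasing order")
    return [int(np.sum(lengths >= t)) for t in range(1, int(lengths.max()) + 1)]
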