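"""Byte-pair-encoding sub-word vocabulary over protein sequences.

BPE iteratively replaces the most frequent adjacent symbol pair in the
training corpus with a new merged token, building a vocabulary of reused
oligomers.  At full scale such vocabularies reach tens of thousands of tokens
averaging about four residues each; here any vocabulary size down to the bare
character alphabet is supported, with the full-scale size available as a
configuration preset.

Layout decisions (the classic GPT-2 recipe leaves these open for proteins):
each sequence is one BPE "word" — merges never cross sequence boundaries;
specials are ``<eos>`` (id 0) and ``<unk>`` (id 1) and are never produced by
merges; pair-count ties break lexicographically by pair; characters outside
the base alphabet encode to ``<unk>`` and are counted rather than erroring.
"""

from __future__ import annotations

import json
from collections import Counter
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence

from .io_seq import SequenceRecord

__all__ = ["TokenizerModel", "bpe_train", "encode", "decode", "mean_token_length", "PAPER_SCALE_VOCAB"]

EOS = "<eos>"
UNK = "<unk>"

#: Full-scale vocabulary-size preset (GPT-2-style training on a large natural
#: corpus); descriptive only — desk-scale tests never instantiate it.
PAPER_SCALE_VOCAB = 50_256


class TokenizerModel:
    """An ordered list of merge rules plus a dense token↔id vocabulary."""

    def __init__(self, alphabet: Sequence[str], merges: list[tuple[str, str]]):
        self.specials = (EOS, UNK)
        self.alphabet = tuple(sorted(alphabet))
        self.merges = list(merges)
        tokens = list(self.specials) + list(self.alphabet)
        for a, b in self.merges:
            tokens.append(a + b)
        self.id_to_token: list[str] = tokens
        self.token_to_id: dict[str, int] = {t: i for i, t in enumerate(tokens)}
        if len(self.token_to_id) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self._ranks = {pair: r for r, pair in enumerate(self.merges)}
        #: running tally of out-of-alphabet characters seen by encode
        self.unk_counts: Counter[str] = Counter()

    # -- basic properties -------------------------------------------------
    @property
    def vocab_size(self) -> int:
        return len(self.id_to_token)

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def vocab_tokens(self) -> list[str]:
        return list(self.id_to_token)

    def is_character_level(self) -> bool:
        return not self.merges

    # -- encode / decode --------------------------------------------------
    def encode(self, sequence: str) -> list[int]:
        """Tokenize a residue string by applying merges in training order.

        Equivalent to replaying merges in rank order: at every step the
        lowest-rank (earliest-trained) applicable merge is applied first.
        """
        if not sequence:
            return []
        symbols: list[str] = []
        for ch in sequence:
            if ch in self.token_to_id and ch not in self.specials and len(ch) == 1 and ch in self.alphabet:
                symbols.append(ch)
            else:
                self.unk_counts[ch] += 1
                symbols.append(UNK)
        while len(symbols) > 1:
            best_rank = None
            best_pos = -1
            for i in range(len(symbols) - 1):
                r = self._ranks.get((symbols[i], symbols[i + 1]))
                if r is not None and (best_rank is None or r < best_rank):
                    best_rank, best_pos = r, i
            if best_rank is None:
                break
            a, b = self.merges[best_rank]
            merged: list[str] = []
            i = 0
            while i < len(symbols):
                if i < len(symbols) - 1 and symbols[i] == a and symbols[i + 1] == b:
                    merged.append(a + b)
                    i += 2
                else:
                    merged.append(symbols[i])
                    i += 1
            symbols = merged
        return [self.token_to_id[s] for s in symbols]

    def decode(self, ids: Iterable[int]) -> str:
        """Concatenate token strings, stripping specials."""
        out = []
        for i in ids:
            i = int(i)
            if not (0 <= i < self.vocab_size):
                raise KeyError(f"token id {i} outside vocabulary of size {self.vocab_size}")
            tok = self.id_to_token[i]
            if tok in self.specials:
                continue
            out.append(tok)
        return "".join(out)

    # -- serialization ----------------------------------------------------
    def save(self, directory: str | PathLike) -> None:
        """Write a plain-text merges file and a JSON vocab map."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "merges.txt", "w") as fh:
            for a, b in self.merges:
                fh.write(f"{a} {b}\n")
        with open(d / "vocab.json", "w") as fh:
            json.dump({"alphabet": list(self.alphabet), "vocab": self.token_to_id}, fh, indent=0)

    @classmethod
    def load(cls, directory: str | PathLike) -> "TokenizerModel":
        d = Path(directory)
        merges = []
        with open(d / "merges.txt") as fh:
            for line in fh:
                if line.strip():
                    a, b = line.rstrip("\n").split(" ")
                    merges.append((a, b))
        with open(d / "vocab.json") as fh:
            meta = json.load(fh)
        model = cls(meta["alphabet"], merges)
        if model.token_to_id != {k: int(v) for k, v in meta["vocab"].items()}:
            raise ValueError("merges and vocab map are inconsistent")
        return model


def bpe_train(corpus: Sequence[SequenceRecord | str], vocab_size: int) -> TokenizerModel:
    """Learn a BPE vocabulary of at most ``vocab_size`` tokens from a corpus.

    Merging stops when the vocabulary is full or when no adjacent pair occurs
    at least twice.  Given the same corpus and size, training is fully
    deterministic: pair-count ties break on the lexicographically smallest
    pair.
    """
    seqs = [r.sequence if isinstance(r, SequenceRecord) else r for r in corpus]
    if not seqs:
        raise ValueError("corpus must be non-empty")
    alphabet = sorted({ch for s in seqs for ch in s})
    n_base = len(alphabet) + 2  # specials
    if vocab_size < n_base:
        raise ValueError(
            f"vocab_size {vocab_size} below base alphabet + specials ({n_base})"
        )

    # collapse duplicate sequences: pair counts weight by occurrence
    word_freq = Counter(seqs)
    words: list[tuple[list[str], int]] = [(list(w), f) for w, f in sorted(word_freq.items())]

    merges: list[tuple[str, str]] = []
    while n_base + len(merges) < vocab_size:
        pair_counts: Counter[tuple[str, str]] = Counter()
        for symbols, freq in words:
            for i in range(len(symbols) - 1):
                pair_counts[(symbols[i], symbols[i + 1])] += freq
        if not pair_counts:
            break
        best_pair, best_count = min(
            pair_counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
        if best_count < 2:
            break
        merges.append(best_pair)
        a, b = best_pair
        for w, (symbols, freq) in enumerate(words):
            merged: list[str] = []
            i = 0
            while i < len(symbols):
                if i < len(symbols) - 1 and symbols[i] == a and symbols[i + 1] == b:
                    merged.append(a + b)
                    i += 2
                else:
                    merged.append(symbols[i])
                    i += 1
            words[w] = (merged, freq)
    return TokenizerModel(alphabet, merges)


def encode(model: TokenizerModel, sequence: str) -> list[int]:
    return model.encode(sequence)


def decode(model: TokenizerModel, ids: Iterable[int]) -> str:
    return model.decode(ids)


def mean_token_length(model: TokenizerModel, corpus: Sequence[SequenceRecord | str]) -> float:
    """Average residues per token over a corpus: total residues / total tokens."""
    seqs = [r.sequence if isinstance(r, SequenceRecord) else r for r in corpus]
    if not seqs or all(not s for s in seqs):
        raise ValueError("corpus must contain residues")
    total_res = sum(len(s) for s in seqs)
    total_tok = sum(len(model.encode(s)) for s in seqs)
    return total_res / total_tok
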