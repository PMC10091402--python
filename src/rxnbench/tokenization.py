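"""Atom-level and pair-encoding tokenizers over SMILES or SELFIES.

Atom-level tokenization follows the molecular-transformer convention: each
token is an atom (including bracket expressions and two-letter elements), a
bond symbol, a ring-closure digit (including ``%nn``), a parenthesis, or
the "." molecule separator. Pair encoding (the SMILES-pair-encoding flavour
of BPE) iteratively merges the most frequent adjacent token pair, never
across molecule boundaries, stopping once no pair reaches the configured
corpus frequency threshold.

Both schemes are lossless: concatenating the tokens reproduces the input
string byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import ConfigurationError, TokenizationError

Dialect = Literal["smiles", "selfies"]
Scheme = Literal["atom", "bpe"]

PAD, UNK, BOS, EOS = "<pad>", "<unk>", "<bos>", "<eos>"
SPECIALS = (PAD, UNK, BOS, EOS, "?", ".")

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|@@|[BCNOSPFIbcnosp]|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)
_SELFIES_TOKEN_RE = re.compile(r"(\[[^\[\]]*\]|\.|\?)")


def atom_tokenize(s: str, dialect: Dialect = "smiles") -> list[str]:
    """Tokenize a (possibly "."-joined, possibly empty) molecule string.

    Raises :class:`TokenizationError` if any character is left over (e.g. a
    dangling "[").
    """
    if s == "":
        return []
    pattern = _SMILES_TOKEN_RE if dialect == "smiles" else _SELFIES_TOKEN_RE
    tokens = pattern.findall(s)
    if "".join(tokens) != s:
        raise TokenizationError(f"cannot tokenize {s!r} as {dialect}")
    return tokens


@dataclass
class Vocabulary:
    """Ordered token set with corpus counts; specials always lead."""

    tokens: list[str]
    counts: dict[str, int]
    specials: tuple[str, ...] = SPECIALS

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ConfigurationError("duplicate tokens in vocabulary")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_corpus(cls, corpus: Iterable[Sequence[str]],
                    specials: tuple[str, ...] = SPECIALS) -> "Vocabulary":
        counts: dict[str, int] = {}
        for seq in corpus:
            for tok in seq:
                counts[tok] = counts.get(tok, 0) + 1
        learned = sorted(t for t in counts if t not in specials)
        tokens = list(specials) + learned
        full_counts = {t: counts.get(t, 0) for t in tokens}
        return cls(tokens=tokens, counts=full_counts, specials=specials)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def id_of(self, token: str) -> int:
        return self._index.get(token, self._index[UNK])

    def token_of(self, idx: int) -> str:
        return self.tokens[idx]

    @property
    def pad_id(self) -> int:
        return self._index[PAD]

    @property
    def bos_id(self) -> int:
        return self._index[BOS]

    @property
    def eos_id(self) -> int:
        return self._index[EOS]

    @property
    def unk_id(self) -> int:
        return self._index[UNK]

    def save(self, path: str | Path) -> None:
        """One ``token<TAB>count`` per line, specials first."""
        with open(path, "w") as fh:
            for t in self.tokens:
                fh.write(f"{t}\t{self.counts.get(t, 0)}\n")

    @classmethod
    def load(cls, path: str | Path,
             specials: tuple[str, ...] = SPECIALS) -> "Vocabulary":
        tokens, counts = [], {}
        with open(path) as fh:
            for line in fh:
                tok, cnt = line.rstrip("\n").split("\t")
                tokens.append(tok)
                counts[tok] = int(cnt)
        return cls(tokens=tokens, counts=counts, specials=specials)


@dataclass
class TokenizerSpec:
    scheme: Scheme = "atom"
    dialect: Dialect = "smiles"
    min_substring_freq: int = 2000

    def __post_init__(self) -> None:
        if self.min_substring_freq < 1:
            raise ConfigurationError("min_substring_freq must be >= 1")


def _pair_counts(corpus: list[list[str]],
                 barrier: set[str]) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for seq in corpus:
        for a, b in zip(seq, seq[1:]):
            if a in barrier or b in barrier:
                continue
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def _apply_merge(seq: list[str], pair: tuple[str, str]) -> list[str]:
    out: list[str] = []
    i = 0
    merged = pair[0] + pair[1]
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == pair[0] and seq[i + 1] == pair[1]:
            out.append(merged)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def train_bpe(corpus: Sequence[Sequence[str]], spec: TokenizerSpec,
              ) -> tuple[Vocabulary, list[tuple[str, str]]]:
    """Learn pair-encoding merges over an atom-tokenized corpus.

    Merging is greedy on corpus pair frequency (ties broken
    lexicographically), never crosses the "." separator or special tokens,
    and stops when no adjacent pair occurs at least
    ``spec.min_substring_freq`` times. The returned vocabulary contains all
    base atom tokens plus the merged substrings, with counts taken from the
    fully merged corpus (base tokens keep their pre-merge counts so none is
    dropped).
    """
    corpus = [list(seq) for seq in corpus]
    if not corpus:
        raise ConfigurationError("empty corpus")
    base_counts: dict[str, int] = {}
    for seq in corpus:
        for tok in seq:
            base_counts[tok] = base_counts.get(tok, 0) + 1
    barrier = set(SPECIALS)
    merges: list[tuple[str, str]] = []
    while True:
        counts = _pair_counts(corpus, barrier)
        if not counts:
            break
        best = min(counts, key=lambda p: (-counts[p], p))
        if counts[best] < spec.min_substring_freq:
            break
        merges.append(best)
        corpus = [_apply_merge(seq, best) for seq in corpus]

    merged_counts: dict[str, int] = {}
    for seq in corpus:
        for tok in seq:
            merged_counts[tok] = merged_counts.get(tok, 0) + 1
    # base atom tokens always stay in the vocabulary, as does every merge
    # product (even when a later merge absorbs all its occurrences)
    all_counts = dict(merged_counts)
    for tok, cnt in base_counts.items():
        all_counts.setdefault(tok, cnt)
    for a, b in merges:
        all_counts.setdefault(a + b, 0)
    learned = sorted(t for t in all_counts if t not in SPECIALS)
    vocab = Vocabulary(tokens=list(SPECIALS) + learned,
                       counts={t: all_counts.get(t, 0) for t in
                               list(SPECIALS) + learned})
    return vocab, merges


@dataclass
class Tokenizer:
    """A trained tokenizer: atom grammar plus an optional merge table."""

    spec: TokenizerSpec
    vocab: Vocabulary
    merges: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def train(cls, strings: Sequence[str], spec: TokenizerSpec) -> "Tokenizer":
        corpus = [atom_tokenize(s, spec.dialect) for s in strings]
        if spec.scheme == "atom":
            vocab = Vocabulary.from_corpus(corpus)
            return cls(spec=spec, vocab=vocab)
        vocab, merges = train_bpe(corpus, spec)
        return cls(spec=spec, vocab=vocab, merges=merges)

    def tokenize(self, s: str) -> list[str]:
        tokens = atom_tokenize(s, self.spec.dialect)
        if not self.merges:
            return tokens
        # merges apply within molecules only: segment on "." and rejoin
        out: list[str] = []
        segment: list[str] = []
        for tok in tokens + ["."]:
            if tok == ".":
                for merge in self.merges:
                    segment = _apply_merge(segment, merge)
                out.extend(segment)
                out.append(".")
                segment = []
            else:
                segment.append(tok)
        return out[:-1]

    def encode(self, s: str) -> list[int]:
        return [self.vocab.id_of(t) for t in self.tokenize(s)]

    def decode(self, ids: Sequence[int]) -> str:
        return "".join(self.vocab.token_of(i) for i in ids)

    def encode_corpus(self, strings: Sequence[str],
                      ) -> tuple[list[list[int]], dict[str, int]]:
        """Encode many strings; stats report out-of-vocabulary token hits."""
        ids = []
        n_unk = n_tok = 0
        for s in strings:
            enc = self.encode(s)
            n_unk += sum(1 for i in enc if i == self.vocab.unk_id)
            n_tok += len(enc)
            ids.append(enc)
        return ids, {"n_tokens": n_tok, "n_unk": n_unk}


def save_merges(merges: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in merges:
            fh.write(f"{a}\t{b}\n")


def load_merges(path: str | Path) -> list[tuple[str, str]]:
    merges = []
    with open(path) as fh:
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            merges.append((a, b))
    return merges


def write_tokenized(sequences: Iterable[Sequence[str]], path: str | Path) -> None:
    """Space-separated tokens, one sample per line (parallel-text convention)."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(" ".join(seq) + "\n")


def read_tokenized(path: str | Path) -> list[list[str]]:
    with open(path) as fh:
        return [line.split() for line in fh.read().splitlines()]
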