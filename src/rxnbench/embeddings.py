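"""Static token embeddings pre-trained on single-molecule corpora.

For the frozen-input-embedding condition, token vectors are learned with
the word2vec objective — skip-gram with negative sampling — over a corpus
in which every individual molecule (each reactant, reagent and product
separately) is one token sequence, so the "." separator never occurs and
co-occurrence statistics are purely intramolecular.

Skip-gram is used (the common choice for small corpora); specials get zero
vectors because they never occur in single-molecule text. Training is
plain numpy, minibatched, and deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, CoverageError
from . import selfies_codec
from .synthetic import ReactionRecord
from .tokenization import SPECIALS, Tokenizer, Vocabulary


@dataclass
class EmbeddingTable:
    vectors: dict[str, np.ndarray]
    dim: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tok, v in self.vectors.items():
            if v.shape != (self.dim,) or not np.all(np.isfinite(v)):
                raise ConfigurationError(f"bad vector for token {tok!r}")

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def matrix(self, vocab: Vocabulary) -> np.ndarray:
        """Vectors stacked in vocabulary order; every token must be covered."""
        missing = [t for t in vocab.tokens if t not in self.vectors]
        if missing:
            raise CoverageError(f"embedding table missing tokens: {missing[:5]}"
                                f"{'...' if len(missing) > 5 else ''}")
        return np.stack([self.vectors[t] for t in vocab.tokens])

    def save(self, path: str | Path) -> None:
        """Standard word-vector text format: ``n dim`` header, then rows."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for tok, vec in self.vectors.items():
                fh.write(tok + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        with open(path) as fh:
            n, dim = map(int, fh.readline().split())
            vectors = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(vectors) != n:
            raise ConfigurationError("embedding file header/body mismatch")
        return cls(vectors=vectors, dim=dim)


def build_molecule_corpus(records: Sequence[ReactionRecord],
                          tokenizer: Tokenizer) -> list[list[str]]:
    """One tokenized sequence per individual molecule in the records.

    Reactants, reagents and products each contribute separately, so no
    sequence contains the "." separator. For the SELFIES dialect, each
    molecule is encoded first (unencodable molecules become the single
    "?" token).
    """
    if not records:
        raise ConfigurationError("no records to build a corpus from")
    corpus: list[list[str]] = []
    for rec in records:
        for mol in list(rec.reactants) + list(rec.reagents) + list(rec.products):
            if tokenizer.spec.dialect == "selfies":
                mol = selfies_codec.encode(mol)
            corpus.append(tokenizer.tokenize(mol))
    return corpus


def train_embeddings(corpus: Sequence[Sequence[str]], dim: int = 256,
                     window: int = 5, seed: int = 0, epochs: int = 5,
                     negative: int = 5, lr: float = 0.025,
                     specials: tuple[str, ...] = SPECIALS,
                     extra_tokens: Sequence[str] = ()) -> EmbeddingTable:
    """Skip-gram with negative sampling over a token corpus.

    Covers every corpus token plus ``specials`` and ``extra_tokens`` (zero
    vectors — word2vec cannot learn tokens it never sees; pair-encoding
    vocabularies may contain merge intermediates absorbed by later merges,
    which never occur in tokenized text). The window is sampled per center
    token in 1..window as in the reference word2vec.
    """
    corpus = [list(seq) for seq in corpus if seq]
    if not corpus:
        raise ConfigurationError("empty corpus")
    tokens = sorted({t for seq in corpus for t in seq})
    index = {t: i for i, t in enumerate(tokens)}
    v = len(tokens)
    rng = np.random.default_rng(seed)

    counts = np.zeros(v)
    for seq in corpus:
        for t in seq:
            counts[index[t]] += 1
    noise = counts ** 0.75
    noise /= noise.sum()

    w_in = (rng.random((v, dim)) - 0.5) / dim
    w_out = np.zeros((v, dim))

    seqs = [np.array([index[t] for t in seq]) for seq in corpus]
    # linear learning-rate decay over the whole run, as in reference word2vec
    n_pairs_estimate = sum(len(s) for s in seqs) * window * epochs
    pairs_done = 0
    for _ in range(epochs):
        centers, contexts = [], []
        for seq in seqs:
            n = len(seq)
            spans = rng.integers(1, window + 1, size=n)
            for i in range(n):
                lo, hi = max(0, i - spans[i]), min(n, i + spans[i] + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(seq[i])
                        contexts.append(seq[j])
        centers = np.array(centers)
        contexts = np.array(contexts)
        order = rng.permutation(len(centers))
        centers, contexts = centers[order], contexts[order]
        for start in range(0, len(centers), 512):
            c = centers[start:start + 512]
            o = contexts[start:start + 512]
            b = len(c)
            neg = rng.choice(v, size=(b, negative), p=noise)
            vc = w_in[c]                                   # (b, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (b, 1+K)
            vt = w_out[targets]                            # (b, 1+K, d)
            score = np.einsum("bd,bkd->bk", vc, vt)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            frac = min(pairs_done / max(n_pairs_estimate, 1), 1.0)
            step_lr = lr * max(1.0 - frac, 1e-4)
            pairs_done += b
            g = (label - sig) * step_lr                    # (b, 1+K)
            grad_c = np.einsum("bk,bkd->bd", g, vt)
            grad_t = g[..., None] * vc[:, None, :]
            # accumulate per-row, then cap each token's movement: reference
            # word2vec updates pair-by-pair, where sigmoid saturation limits
            # drift; batched accumulation needs an explicit cap or frequent
            # tokens (hundreds of hits per batch on small vocabularies)
            # receive runaway same-direction updates
            upd_in = np.zeros_like(w_in)
            upd_out = np.zeros_like(w_out)
            np.add.at(upd_in, c, grad_c)
            np.add.at(upd_out, targets.ravel(), grad_t.reshape(-1, dim))
            for upd, w in ((upd_in, w_in), (upd_out, w_out)):
                norms = np.linalg.norm(upd, axis=1, keepdims=True)
                np.multiply(upd, np.minimum(1.0, 0.5 / np.maximum(norms, 1e-12)),
                            out=upd)
                w += upd

    vectors = {t: w_in[index[t]].copy() for t in tokens}
    for s in (*specials, *extra_tokens):
        vectors.setdefault(s, np.zeros(dim))
    meta = {"architecture": "skip-gram negative sampling", "window": window,
            "epochs": epochs, "negative": negative, "lr": lr, "seed": seed}
    return EmbeddingTable(vectors=vectors, dim=dim, metadata=meta)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))
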