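"""Sequence-to-sequence translation harness for tokenized reaction strings.

An encoder–decoder transformer (pre-norm, sinusoidal positions, scaled
dot-product attention) trained with token-batched Adam and early stopping
on validation token accuracy and perplexity, with beam-search n-best
inference. The reference preset mirrors the molecular-transformer
configuration (4 layers, embedding 256, feedforward 2048, 8 heads, 4096
token batches, beam 10, patience 10); the desk preset is small enough to
train a toy task on one CPU in minutes.

The input (source-side) embedding layer can be replaced by a static
pre-trained table and frozen, which is the pre-trained-embedding condition
of the scenario grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import (Adam, Tensor, cross_entropy_logits, dropout,
                       embedding, layer_norm, relu, softmax)
from .embeddings import EmbeddingTable
from .errors import ConfigurationError
from .tokenization import Vocabulary

NEG_INF = -1e9


@dataclass
class ModelConfig:
    n_layers: int = 4
    emb_dim: int = 256
    ff_dim: int = 2048
    n_heads: int = 8
    batch_tokens: int = 4096
    beam_size: int = 10
    patience: int = 10
    augmentation_factor: int = 1
    validate_every: int | None = None  # default: 10_000 x augmentation factor
    freeze_input_embeddings: bool = False
    seed: int = 0
    lr: float = 1.5e-3
    warmup_steps: int = 200
    max_steps: int = 100_000
    max_decode_len: int = 80
    length_normalize: bool = True  # rank beams by mean (not sum) log-prob
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.beam_size < 1 or self.patience < 1:
            raise ConfigurationError("beam_size and patience must be >= 1")
        if self.emb_dim % self.n_heads:
            raise ConfigurationError("emb_dim must be divisible by n_heads")

    @property
    def validation_interval(self) -> int:
        if self.validate_every is not None:
            return self.validate_every
        return 10_000 * self.augmentation_factor

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Small CPU preset: 2 layers, emb 64, ff 256, 4 heads."""
        base = dict(n_layers=2, emb_dim=64, ff_dim=256, n_heads=4,
                    batch_tokens=2048, validate_every=200, patience=10)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainingLog:
    """Per-validation metrics plus the stopping decision."""

    validations: list[dict] = field(default_factory=list)
    stopping_step: int = 0
    stopping_reason: str = ""


def _positional_encoding(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(np.float32)


class Seq2SeqTranslator:
    """Trainable encoder–decoder over token-id sequences."""

    def __init__(self, src_vocab: Vocabulary, tgt_vocab: Vocabulary,
                 config: ModelConfig,
                 input_embeddings: EmbeddingTable | None = None):
        if config.freeze_input_embeddings and input_embeddings is None:
            raise ConfigurationError(
                "freeze_input_embeddings requires an embedding table")
        self.src_vocab = src_vocab
        self.tgt_vocab = tgt_vocab
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        self._build(input_embeddings)
        self._pe = _positional_encoding(2048, config.emb_dim)
        self._training = False
        self._drop_rng = np.random.default_rng(config.seed + 7)

    # -- parameters ----------------------------------------------------------

    def _param(self, name: str, shape: tuple[int, ...],
               scale: float | None = None) -> Tensor:
        if scale is None:
            scale = (2.0 / sum(shape)) ** 0.5
        t = Tensor(self.rng.standard_normal(shape) * scale, requires_grad=True)
        self.params[name] = t
        return t

    def _build(self, table: EmbeddingTable | None) -> None:
        c = self.config
        d = c.emb_dim
        self._param("src_emb", (len(self.src_vocab), d), scale=d ** -0.5)
        if table is not None:
            emb = table.matrix(self.src_vocab).astype(np.float32)
            if emb.shape[1] != d:
                raise ConfigurationError(
                    f"embedding dim {emb.shape[1]} != model dim {d}")
            self.params["src_emb"].data = emb.copy()
        self._param("tgt_emb", (len(self.tgt_vocab), d), scale=d ** -0.5)
        for side, n in (("enc", c.n_layers), ("dec", c.n_layers)):
            for l in range(n):
                p = f"{side}{l}"
                attns = ["self"] if side == "enc" else ["self", "cross"]
                for a in attns:
                    for w in ("q", "k", "v", "o"):
                        self._param(f"{p}.{a}.{w}", (d, d))
                    self._param(f"{p}.{a}.ln_g", (d,), scale=0.0).data[:] = 1.0
                    self._param(f"{p}.{a}.ln_b", (d,), scale=0.0)
                self._param(f"{p}.ff.w1", (d, c.ff_dim))
                self._param(f"{p}.ff.b1", (c.ff_dim,), scale=0.0)
                self._param(f"{p}.ff.w2", (c.ff_dim, d))
                self._param(f"{p}.ff.b2", (d,), scale=0.0)
                self._param(f"{p}.ff.ln_g", (d,), scale=0.0).data[:] = 1.0
                self._param(f"{p}.ff.ln_b", (d,), scale=0.0)
        for side in ("enc", "dec"):
            self._param(f"{side}.ln_g", (d,), scale=0.0).data[:] = 1.0
            self._param(f"{side}.ln_b", (d,), scale=0.0)
        self._param("out.w", (d, len(self.tgt_vocab)))
        self._param("out.b", (len(self.tgt_vocab),), scale=0.0)

    def trainable_params(self) -> list[Tensor]:
        return [t for name, t in self.params.items()
                if not (self.config.freeze_input_embeddings and name == "src_emb")]

    # -- forward -------------------------------------------------------------

    def _attention(self, prefix: str, x: Tensor, kv: Tensor,
                   mask: np.ndarray | None) -> Tensor:
        c = self.config
        h, d = c.n_heads, c.emb_dim
        dk = d // h
        p = self.params
        b, tq = x.shape[0], x.shape[1]
        tk = kv.shape[1]
        q = (x @ p[f"{prefix}.q"]).reshape(b, tq, h, dk).transpose(0, 2, 1, 3)
        k = (kv @ p[f"{prefix}.k"]).reshape(b, tk, h, dk).transpose(0, 2, 1, 3)
        v = (kv @ p[f"{prefix}.v"]).reshape(b, tk, h, dk).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dk ** -0.5)
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = softmax(scores)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, tq, d)
        return self._drop(ctx @ p[f"{prefix}.o"])

    def _sublayer_attn(self, prefix: str, x: Tensor, kv: Tensor | None,
                       mask: np.ndarray | None) -> Tensor:
        p = self.params
        normed = layer_norm(x, p[f"{prefix}.ln_g"], p[f"{prefix}.ln_b"])
        source = normed if kv is None else kv
        return x + self._attention(prefix, normed, source, mask)

    def _sublayer_ff(self, prefix: str, x: Tensor) -> Tensor:
        p = self.params
        normed = layer_norm(x, p[f"{prefix}.ln_g"], p[f"{prefix}.ln_b"])
        hidden = relu(normed @ p[f"{prefix}.w1"] + p[f"{prefix}.b1"])
        return x + self._drop(hidden @ p[f"{prefix}.w2"] + p[f"{prefix}.b2"])

    def _drop(self, t: Tensor) -> Tensor:
        if not self._training:
            return t
        return dropout(t, self.config.dropout, self._drop_rng)

    def encode(self, src_ids: np.ndarray) -> tuple[Tensor, np.ndarray]:
        c = self.config
        pad_mask = np.where(src_ids == self.src_vocab.pad_id, NEG_INF, 0.0
                            ).astype(np.float32)[:, None, None, :]
        x = embedding(self.params["src_emb"], src_ids) * (c.emb_dim ** 0.5)
        x = self._drop(x + Tensor(self._pe[:src_ids.shape[1]]))
        for l in range(c.n_layers):
            x = self._sublayer_attn(f"enc{l}.self", x, None, pad_mask)
            x = self._sublayer_ff(f"enc{l}.ff", x)
        x = layer_norm(x, self.params["enc.ln_g"], self.params["enc.ln_b"])
        return x, pad_mask

    def decode(self, memory: Tensor, src_pad_mask: np.ndarray,
               tgt_ids: np.ndarray) -> Tensor:
        c = self.config
        t = tgt_ids.shape[1]
        causal = np.triu(np.full((t, t), NEG_INF, dtype=np.float32), k=1)
        causal = causal[None, None]
        x = embedding(self.params["tgt_emb"], tgt_ids) * (c.emb_dim ** 0.5)
        x = self._drop(x + Tensor(self._pe[:t]))
        for l in range(c.n_layers):
            x = self._sublayer_attn(f"dec{l}.self", x, None, causal)
            x = self._sublayer_attn(f"dec{l}.cross", x, memory, src_pad_mask)
            x = self._sublayer_ff(f"dec{l}.ff", x)
        x = layer_norm(x, self.params["dec.ln_g"], self.params["dec.ln_b"])
        return x @ self.params["out.w"] + self.params["out.b"]

    # -- data plumbing -------------------------------------------------------

    def _ids(self, tokens: Sequence[str], vocab: Vocabulary) -> list[int]:
        return [vocab.id_of(t) for t in tokens]

    def _make_batches(self, pairs, rng) -> list[tuple[np.ndarray, np.ndarray]]:
        c = self.config
        encoded = [(self._ids(s, self.src_vocab), self._ids(t, self.tgt_vocab))
                   for s, t in pairs]
        encoded.sort(key=lambda p: (len(p[0]), len(p[1])))
        batches = []
        i = 0
        while i < len(encoded):
            j = i
            max_s = max_t = 0
            while j < len(encoded):
                ms = max(max_s, len(encoded[j][0]))
                mt = max(max_t, len(encoded[j][1]) + 2)
                if (j - i + 1) * (ms + mt) > c.batch_tokens and j > i:
                    break
                max_s, max_t = ms, mt
                j += 1
            chunk = encoded[i:j]
            src = np.full((len(chunk), max_s), self.src_vocab.pad_id, dtype=np.int64)
            tgt = np.full((len(chunk), max_t), self.tgt_vocab.pad_id, dtype=np.int64)
            for r, (s, t) in enumerate(chunk):
                src[r, :len(s)] = s
                tgt[r, :len(t) + 2] = [self.tgt_vocab.bos_id] + t + [self.tgt_vocab.eos_id]
            batches.append((src, tgt))
            i = j
        return batches

    # -- training ------------------------------------------------------------

    def _loss_on_batch(self, src: np.ndarray, tgt: np.ndarray):
        memory, pad_mask = self.encode(src)
        logits = self.decode(memory, pad_mask, tgt[:, :-1])
        b, t, v = logits.shape
        flat = logits.reshape(b * t, v)
        targets = tgt[:, 1:].reshape(-1)
        mask = (targets != self.tgt_vocab.pad_id).astype(np.float32)
        return cross_entropy_logits(flat, targets, mask), mask.sum()

    def evaluate(self, pairs) -> tuple[float, float]:
        """Teacher-forced token accuracy and perplexity on (src, tgt) pairs."""
        rng = np.random.default_rng(0)
        total_ll = total_tok = 0.0
        correct = 0.0
        was_training, self._training = self._training, False
        for src, tgt in self._make_batches(pairs, rng):
            (loss, acc, ll), n_tok = self._loss_on_batch(src, tgt)
            total_ll += ll
            total_tok += n_tok
            correct += acc * n_tok
        self._training = was_training
        ppl = float(np.exp(-total_ll / max(total_tok, 1.0)))
        return correct / max(total_tok, 1.0), ppl

    def fit(self, train_pairs, valid_pairs) -> TrainingLog:
        """Train with early stopping.

        Training stops when neither validation token accuracy nor
        perplexity has improved for ``patience`` consecutive validations
        (or at ``max_steps``). The parameters of the best-accuracy
        validation are restored at the end.
        """
        if not train_pairs:
            raise ConfigurationError("empty training set")
        c = self.config
        frozen_before = self.params["src_emb"].data.copy() \
            if c.freeze_input_embeddings else None
        opt = Adam(self.trainable_params(), lr=c.lr)
        rng = np.random.default_rng(c.seed + 1)
        batches = self._make_batches(train_pairs, rng)
        log = TrainingLog()
        best_acc, best_ppl = -1.0, np.inf
        best_params = None
        stale = 0
        step = 0
        done = False
        self._training = True
        while not done:
            for bi in rng.permutation(len(batches)):
                src, tgt = batches[bi]
                (loss, _, _), _ = self._loss_on_batch(src, tgt)
                opt.zero_grad()
                loss.backward()
                # linear warmup then inverse-sqrt decay
                w = c.warmup_steps
                opt.lr = c.lr * min((step + 1) / w, (w / (step + 1)) ** 0.5)
                opt.step()
                step += 1
                if step % c.validation_interval == 0:
                    acc, ppl = self.evaluate(valid_pairs) if valid_pairs \
                        else self.evaluate(train_pairs[:256])
                    log.validations.append(
                        {"step": step, "token_accuracy": acc, "perplexity": ppl})
                    improved = False
                    if acc > best_acc:
                        best_acc = acc
                        best_params = {k: v.data.copy()
                                       for k, v in self.params.items()}
                        improved = True
                    if ppl < best_ppl:
                        best_ppl = ppl
                        improved = True
                    stale = 0 if improved else stale + 1
                    if stale >= c.patience:
                        log.stopping_step = step
                        log.stopping_reason = (
                            f"no improvement in accuracy or perplexity for "
                            f"{c.patience} validations")
                        done = True
                        break
                if step >= c.max_steps:
                    log.stopping_step = step
                    log.stopping_reason = "reached max_steps"
                    done = True
                    break
        self._training = False
        if best_params is not None:
            for k, v in self.params.items():
                v.data = best_params[k]
        if frozen_before is not None:
            # frozen embeddings are excluded from the optimizer; restore-from-
            # best must not have altered them either
            self.params["src_emb"].data = frozen_before
        return log

    # -- inference -----------------------------------------------------------

    def predict(self, sources: Sequence[Sequence[str]], k: int,
                batch_size: int = 16) -> list[list[tuple[list[str], float]]]:
        """Beam-search n-best decoding.

        Returns, per source, up to ``k`` (token list, log-probability)
        candidates with non-increasing scores. ``k`` may not exceed the
        configured beam size.
        """
        c = self.config
        if not 1 <= k <= c.beam_size:
            raise ConfigurationError(
                f"k must be in 1..beam_size({c.beam_size}), got {k}")
        results = []
        for i in range(0, len(sources), batch_size):
            chunk = sources[i:i + batch_size]
            results.extend(self._beam_chunk(chunk, k))
        return results

    def _beam_chunk(self, sources, k: int):
        c = self.config
        K = c.beam_size
        pad, bos, eos = (self.tgt_vocab.pad_id, self.tgt_vocab.bos_id,
                         self.tgt_vocab.eos_id)
        b = len(sources)
        max_s = max(max(len(s) for s in sources), 1)
        src = np.full((b, max_s), self.src_vocab.pad_id, dtype=np.int64)
        for r, s in enumerate(sources):
            src[r, :len(s)] = self._ids(s, self.src_vocab)
        memory, pad_mask = self.encode(src)
        mem = Tensor(np.repeat(memory.data, K, axis=0))
        mask = np.repeat(pad_mask, K, axis=0)

        seqs = np.full((b * K, 1), bos, dtype=np.int64)
        scores = np.full((b, K), NEG_INF, dtype=np.float64)
        scores[:, 0] = 0.0
        finished = np.zeros((b, K), dtype=bool)
        vsize = len(self.tgt_vocab)
        for _ in range(c.max_decode_len):
            logits = self.decode(mem, mask, seqs).data[:, -1, :]
            z = logits - logits.max(axis=-1, keepdims=True)
            logp = (z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
                    ).reshape(b, K, vsize).astype(np.float64)
            # finished beams may only extend with pad, at no cost
            fin = finished[:, :, None]
            pad_only = np.full_like(logp, NEG_INF)
            pad_only[:, :, pad] = 0.0
            logp = np.where(fin, pad_only, logp)
            cand = scores[:, :, None] + logp
            flat = cand.reshape(b, K * vsize)
            top = np.argsort(-flat, axis=1, kind="stable")[:, :K]
            scores = np.take_along_axis(flat, top, axis=1)
            beam_idx, tok_idx = top // vsize, top % vsize
            new_seqs = np.empty((b * K, seqs.shape[1] + 1), dtype=np.int64)
            new_fin = np.zeros((b, K), dtype=bool)
            for r in range(b):
                for j in range(K):
                    parent = r * K + beam_idx[r, j]
                    new_seqs[r * K + j, :-1] = seqs[parent]
                    new_seqs[r * K + j, -1] = tok_idx[r, j]
                    new_fin[r, j] = (finished[r, beam_idx[r, j]]
                                     or tok_idx[r, j] == eos)
            seqs, finished = new_seqs, new_fin
            if finished.all():
                break
        out = []
        for r in range(b):
            ranked = []
            for j in range(K):
                ids = [int(t) for t in seqs[r * K + j, 1:]
                       if t not in (pad, bos, eos)]
                score = float(scores[r, j])
                if c.length_normalize:
                    score /= max(len(ids) + 1, 1)  # +1 for the eos step
                ranked.append(([self.tgt_vocab.token_of(t) for t in ids],
                               score))
            ranked.sort(key=lambda x: -x[1])
            out.append(ranked[:k])
        return out

    def predict_strings(self, sources: Sequence[Sequence[str]], k: int,
                        batch_size: int = 16) -> list[list[tuple[str, float]]]:
        """Like :meth:`predict` but with candidates joined back to strings."""
        return [[("".join(toks), score) for toks, score in ranked]
                for ranked in self.predict(sources, k, batch_size)]

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{k: v.data for k, v in self.params.items()})
        manifest = {"config": asdict(self.config),
                    "src_vocab": self.src_vocab.tokens,
                    "tgt_vocab": self.tgt_vocab.tokens}
        path.with_suffix(".json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, path: str | Path) -> "Seq2SeqTranslator":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        src_vocab = Vocabulary(tokens=manifest["src_vocab"],
                               counts={t: 0 for t in manifest["src_vocab"]})
        tgt_vocab = Vocabulary(tokens=manifest["tgt_vocab"],
                               counts={t: 0 for t in manifest["tgt_vocab"]})
        model = cls(src_vocab, tgt_vocab, ModelConfig(**manifest["config"]))
        data = np.load(path.with_suffix(".npz"))
        for key in model.params:
            model.params[key].data = data[key].astype(np.float32)
        return model


def write_nbest(predictions: Sequence[Sequence[tuple[list[str], float]]],
                path: str | Path) -> None:
    """n-best text format: k consecutive ``rank<TAB>score<TAB>tokens`` lines
    per source, tokens space-separated."""
    with open(path, "w") as fh:
        for ranked in predictions:
            for rank, (tokens, score) in enumerate(ranked, start=1):
                fh.write(f"{rank}\t{score:.6f}\t{' '.join(tokens)}\n")


def read_nbest(path: str | Path) -> list[list[tuple[list[str], float]]]:
    out: list[list[tuple[list[str], float]]] = []
    with open(path) as fh:
        for line in fh:
            rank_s, score_s, tok_s = line.rstrip("\n").split("\t")
            if int(rank_s) == 1:
                out.append([])
            out[-1].append((tok_s.split(" ") if tok_s else [], float(score_s)))
    return out


def train(train_samples, valid_samples, vocabularies, config: ModelConfig,
          embeddings: EmbeddingTable | None = None,
          ) -> tuple[Seq2SeqTranslator, TrainingLog]:
    """Train a translator on (source tokens, target tokens) pairs.

    ``vocabularies`` is a (source, target) :class:`Vocabulary` pair. When
    ``config.freeze_input_embeddings`` is set, ``embeddings`` must cover the
    source vocabulary and the input embedding matrix stays bit-identical
    through training.
    """
    src_vocab, tgt_vocab = vocabularies
    model = Seq2SeqTranslator(src_vocab, tgt_vocab, config, embeddings)
    log = model.fit(train_samples, valid_samples)
    return model, log


def predict(model: Seq2SeqTranslator, sources, k: int):
    """Ranked n-best candidates for each tokenized source."""
    return model.predict(sources, k)
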