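import numpy as np
import pytest

from rxnbench.embeddings import train_embeddings
from rxnbench.errors import ConfigurationError, CoverageError
from rxnbench.tokenization import SPECIALS, Vocabulary
from rxnbench.transformer import (ModelConfig, Seq2SeqTranslator, read_nbest,
                                  train, write_nbest)

TOKENS = list("ABCDE")


def vocab():
    toks = list(SPECIALS) + TOKENS
    return Vocabulary(tokens=toks, counts={t: 1 for t in toks})


def tiny_config(**kw):
    base = dict(n_layers=1, emb_dim=16, ff_dim=32, n_heads=2,
                batch_tokens=256, beam_size=3, validate_every=50,
                patience=3, max_steps=600, seed=0, dropout=0.0)
    base.update(kw)
    return ModelConfig(**base)


def copy_pairs(n=60, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        seq = [TOKENS[i] for i in rng.integers(0, len(TOKENS),
                                               rng.integers(2, 5))]
        pairs.append((seq, seq))
    return pairs


@pytest.fixture(scope="module")
def trained():
    v = vocab()
    model, log = train(copy_pairs(120), copy_pairs(12, seed=1),
                       (v, v), tiny_config())
    return model, log


class TestConfig:
    def test_bad_beam_or_patience(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(beam_size=0)
        with pytest.raises(ConfigurationError):
            ModelConfig(patience=0)

    def test_heads_divide_dim(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(emb_dim=10, n_heads=4)

    def test_validation_interval_scales_with_augmentation(self):
        assert ModelConfig(augmentation_factor=5).validation_interval == 50_000
        assert ModelConfig.desk().validation_interval == 200

    def test_desk_preset_shape(self):
        c = ModelConfig.desk()
        assert (c.n_layers, c.emb_dim, c.ff_dim, c.n_heads) == (2, 64, 256, 4)


class TestTrain:
    def test_empty_training_set_rejected(self):
        v = vocab()
        with pytest.raises(ConfigurationError):
            train([], [], (v, v), tiny_config())

    def test_frozen_flag_without_table_rejected(self):
        v = vocab()
        with pytest.raises(ConfigurationError):
            Seq2SeqTranslator(v, v, tiny_config(freeze_input_embeddings=True))

    def test_table_missing_token_rejected(self):
        v = vocab()
        table = train_embeddings([["A", "B"]] * 5, dim=16, seed=0, epochs=1)
        with pytest.raises(CoverageError):
            Seq2SeqTranslator(v, v, tiny_config(freeze_input_embeddings=True),
                              input_embeddings=table)

    def test_frozen_embeddings_bit_identical(self):
        v = vocab()
        table = train_embeddings([TOKENS] * 5, dim=16, seed=0, epochs=1)
        model = Seq2SeqTranslator(v, v,
                                  tiny_config(freeze_input_embeddings=True,
                                              max_steps=60),
                                  input_embeddings=table)
        before = model.params["src_emb"].data.copy()
        model.fit(copy_pairs(20), copy_pairs(5, seed=2))
        assert np.abs(model.params["src_emb"].data - before).max() == 0.0

    def test_early_stopping_invariant(self, trained):
        _, log = trained
        assert log.stopping_step > 0
        assert log.validations
        if "no improvement" in log.stopping_reason:
            # the last `patience` validations improved neither metric
            tail = log.validations[-3:]
            best_acc = max(v["token_accuracy"] for v in log.validations[:-3])
            best_ppl = min(v["perplexity"] for v in log.validations[:-3])
            for v in tail:
                assert v["token_accuracy"] <= best_acc
                assert v["perplexity"] >= best_ppl


class TestPredict:
    def test_k_exceeding_beam_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ConfigurationError):
            model.predict([list("AB")], k=4)

    def test_k1_single_candidate(self, trained):
        model, _ = trained
        preds = model.predict([list("AB"), list("BC")], k=1)
        assert all(len(p) == 1 for p in preds)

    def test_scores_non_increasing(self, trained):
        model, _ = trained
        preds = model.predict([list("ABC")], k=3)
        scores = [s for _, s in preds[0]]
        assert scores == sorted(scores, reverse=True)

    def test_inference_deterministic(self, trained):
        model, _ = trained
        srcs = [list("ABDE"), list("CC")]
        assert model.predict(srcs, k=3) == model.predict(srcs, k=3)

    def test_copy_task_learned(self, trained):
        model, _ = trained
        held_out = copy_pairs(20, seed=9)
        preds = model.predict([s for s, _ in held_out], k=1)
        acc = np.mean([preds[i][0][0] == held_out[i][1]
                       for i in range(len(held_out))])
        assert acc >= 0.8  # tiny model, tiny budget; full bar tested end-to-end


class TestPersistence:
    def test_save_load_same_predictions(self, trained, tmp_path):
        model, _ = trained
        model.save(tmp_path / "ckpt")
        back = Seq2SeqTranslator.load(tmp_path / "ckpt")
        srcs = [list("ABC"), list("DE")]
        assert back.predict(srcs, k=2) == model.predict(srcs, k=2)

    def test_nbest_file_round_trip(self, tmp_path):
        preds = [[(list("AB"), -0.1), (list("A"), -2.0)],
                 [([], -0.5)]]
        write_nbest(preds, tmp_path / "nbest.txt")
        assert read_nbest(tmp_path / "nbest.txt") == preds
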