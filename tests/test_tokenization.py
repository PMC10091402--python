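import pytest

from rxnbench import selfies_codec
from rxnbench.errors import ConfigurationError, TokenizationError
from rxnbench.tokenization import (SPECIALS, Tokenizer, TokenizerSpec,
                                   Vocabulary, atom_tokenize, load_merges,
                                   read_tokenized, save_merges, train_bpe,
                                   write_tokenized)


class TestAtomTokenize:
    @pytest.mark.parametrize("s,expected", [
        ("CC(=O)O", ["C", "C", "(", "=", "O", ")", "O"]),
        ("[nH]", ["[nH]"]),
        ("Cl", ["Cl"]),
        ("CCO.CC", ["C", "C", "O", ".", "C", "C"]),
        ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
        ("", []),
        ("?", ["?"]),
    ])
    def test_smiles_examples(self, s, expected):
        assert atom_tokenize(s, "smiles") == expected

    def test_selfies_groups(self):
        assert atom_tokenize("[C][=C].[O]?", "selfies") == \
            ["[C]", "[=C]", ".", "[O]", "?"]

    @pytest.mark.parametrize("bad,dialect", [
        ("C[", "smiles"), ("[C", "selfies"), ("x[C]", "selfies")])
    def test_dangling_bracket(self, bad, dialect):
        with pytest.raises(TokenizationError):
            atom_tokenize(bad, dialect)

    def test_lossless_on_library(self, molecule_library):
        for m in molecule_library:
            assert "".join(atom_tokenize(m, "smiles")) == m
            enc = selfies_codec.encode(m)
            assert "".join(atom_tokenize(enc, "selfies")) == enc


class TestBpe:
    def corpus(self, pair_count):
        return [["C", "C", "O"]] * pair_count

    def test_frequent_pair_merged(self):
        # ("C","C") occurs 5000 times, over the 2000 threshold
        vocab, merges = train_bpe(self.corpus(5000),
                                  TokenizerSpec("bpe", "smiles", 2000))
        assert ("C", "C") in merges
        assert "CC" in vocab.tokens

    def test_threshold_above_all_pairs_no_merges(self):
        vocab, merges = train_bpe(self.corpus(10),
                                  TokenizerSpec("bpe", "smiles", 2000))
        assert merges == []
        assert set(vocab.tokens) == set(SPECIALS) | {"C", "O"}

    def test_formation_frequency_respects_threshold(self):
        corpus = [["C", "C", "O"]] * 70 + [["N", "N"]] * 30
        vocab, merges = train_bpe(corpus, TokenizerSpec("bpe", "smiles", 50))
        # ("C","C") at 70 and ("CC","O") at 70 qualify; ("N","N") at 30 does not
        assert ("N", "N") not in merges
        for a, b in merges:
            assert a + b in vocab.tokens

    def test_tie_break_lexicographic(self):
        corpus = [["B", "B"]] * 5 + [["A", "A"]] * 5
        _, merges = train_bpe(corpus, TokenizerSpec("bpe", "smiles", 5))
        assert merges[0] == ("A", "A")

    def test_no_merge_across_separator(self):
        corpus = [["C", ".", "C"]] * 100
        _, merges = train_bpe(corpus, TokenizerSpec("bpe", "smiles", 2))
        assert all("." not in a + b for a, b in merges)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ConfigurationError):
            train_bpe([], TokenizerSpec("bpe", "smiles", 10))

    def test_base_tokens_kept(self):
        vocab, _ = train_bpe(self.corpus(100),
                             TokenizerSpec("bpe", "smiles", 10))
        assert {"C", "O"} <= set(vocab.tokens)

    def test_merge_table_round_trip(self, tmp_path):
        _, merges = train_bpe(self.corpus(100),
                              TokenizerSpec("bpe", "smiles", 10))
        save_merges(merges, tmp_path / "merges.txt")
        assert load_merges(tmp_path / "merges.txt") == merges


@pytest.mark.parametrize("scheme", ["atom", "bpe"])
@pytest.mark.parametrize("dialect", ["smiles", "selfies"])
class TestRoundTrip:
    def test_lossless(self, scheme, dialect, molecule_library):
        strings = molecule_library
        if dialect == "selfies":
            strings = [selfies_codec.encode(m) for m in strings]
        tok = Tokenizer.train(strings, TokenizerSpec(scheme, dialect, 5))
        for s in strings:
            tokens = tok.tokenize(s)
            assert "".join(tokens) == s
            assert tok.decode(tok.encode(s)) == s


@pytest.mark.parametrize("dialect", ["smiles", "selfies"])
def test_bpe_never_longer_than_atom(dialect, molecule_library):
    strings = molecule_library
    if dialect == "selfies":
        strings = [selfies_codec.encode(m) for m in strings]
    bpe = Tokenizer.train(strings, TokenizerSpec("bpe", dialect, 5))
    for s in strings:
        assert len(bpe.tokenize(s)) <= len(atom_tokenize(s, dialect))


class TestVocabulary:
    def test_specials_first_and_separator_present(self, molecule_library):
        tok = Tokenizer.train(molecule_library, TokenizerSpec("atom", "smiles"))
        assert tuple(tok.vocab.tokens[:len(SPECIALS)]) == SPECIALS
        assert "." in tok.vocab

    def test_unknown_maps_to_unk_and_is_counted(self, molecule_library):
        tok = Tokenizer.train(molecule_library, TokenizerSpec("atom", "smiles"))
        ids, stats = tok.encode_corpus(["I"])  # iodine never generated
        assert ids[0] == [tok.vocab.unk_id]
        assert stats["n_unk"] == 1

    def test_duplicate_tokens_rejected(self):
        with pytest.raises(ConfigurationError):
            Vocabulary(tokens=["a", "a"], counts={"a": 1})

    def test_file_round_trip(self, tmp_path, molecule_library):
        tok = Tokenizer.train(molecule_library, TokenizerSpec("atom", "smiles"))
        tok.vocab.save(tmp_path / "vocab.tsv")
        back = Vocabulary.load(tmp_path / "vocab.tsv")
        assert back.tokens == tok.vocab.tokens
        assert back.counts == tok.vocab.counts

    def test_tokenized_corpus_file_round_trip(self, tmp_path,
                                              molecule_library):
        tok = Tokenizer.train(molecule_library, TokenizerSpec("atom", "smiles"))
        corpus = [tok.tokenize(m) for m in molecule_library[:20]]
        write_tokenized(corpus, tmp_path / "corpus.txt")
        assert read_tokenized(tmp_path / "corpus.txt") == corpus
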