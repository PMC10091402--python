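import random

import numpy as np
import pytest

from rxnbench.errors import (ConfigurationError, UndefinedMetricError)
from rxnbench.metrics import (PredictionRecord, bin_and_pool, evaluate,
                              invalid_candidate_rate, lenient_hit, prf_at_k,
                              roundtrip_accuracy, strict_hit, topk_accuracy)
from rxnbench.molformat import canonicalize, join_molecules, split_molecules


def record(target, candidates, **kw):
    return PredictionRecord(source=kw.pop("source", "CCO"), target=target,
                            candidates=[(c, -float(i)) for i, c in
                                        enumerate(candidates)], **kw)


class TestHits:
    def test_strict_order_invariant(self):
        assert strict_hit("CCO.CC", "CC.CCO")

    def test_strict_canonical_forms(self):
        # both spellings of ethanol
        assert strict_hit("C(O)C", "OCC")

    def test_strict_missing_molecule(self):
        assert not strict_hit("CCO", "CCO.CC")

    def test_strict_extra_molecule(self):
        assert not strict_hit("CCO.CC", "CCO")

    def test_strict_unparseable_is_miss(self):
        assert not strict_hit("C1CC", "CCO")
        assert not strict_hit("CCO.C1CC", "CCO")

    def test_lenient_shared_molecule(self):
        assert lenient_hit("CCO.CCC", "CCO.N")

    def test_lenient_disjoint(self):
        assert not lenient_hit("CCC", "CCO.N")

    def test_lenient_ignores_unparseable_individually(self):
        assert lenient_hit("C1CC.CCO", "CCO.N")

    def test_strict_implies_lenient(self, molecule_library):
        rng = random.Random(3)
        for _ in range(200):
            cand = join_molecules(rng.sample(molecule_library, rng.randint(1, 3)))
            tgt = join_molecules(rng.sample(molecule_library, rng.randint(1, 3)))
            if strict_hit(cand, tgt):
                assert lenient_hit(cand, tgt)


class TestTopK:
    def test_hand_count(self):
        recs = [record("CCO", ["CC", "CCO"]),   # hit at rank 2
                record("CCO", ["CC", "CCC"])]   # no hit
        assert topk_accuracy(recs, 1) == 0.0
        assert topk_accuracy(recs, 2) == 0.5

    def test_perfect_rank1(self):
        recs = [record("CCO", ["CCO", "N"]), record("CC", ["CC", "O"])]
        for k in (1, 2):
            assert topk_accuracy(recs, k) == 1.0

    def test_below_rank_shuffling_irrelevant(self):
        a = record("CCO", ["CCO", "CC", "N"])
        b = record("CCO", ["CCO", "N", "CC"])
        assert topk_accuracy([a], 1) == topk_accuracy([b], 1)

    def test_empty_records_undefined(self):
        with pytest.raises(UndefinedMetricError):
            topk_accuracy([], 1)

    def test_dedup_switch_collapses_identical_candidates(self):
        # "C(C)C" repeats "CCC" canonically; dedup frees one rank so the
        # true hit enters the top-3 window
        rec = PredictionRecord(source="C", target="CCO",
                               candidates=[("CC", -0.1), ("C(C)C", -0.2),
                                           ("CCC", -0.3), ("CCO", -0.4)])
        assert topk_accuracy([rec], 2, "strict") == 0.0
        # "C(C)C" and "CCC" are the same molecule; dedup removes one rank
        assert topk_accuracy([rec], 3, "strict", dedup=True) == 1.0
        assert topk_accuracy([rec], 3, "strict") == 0.0


class TestRoundTrip:
    def records(self):
        return [PredictionRecord(source="CCOCC", target="CCO.CC",
                                 candidates=[("CCO.CC", 0.0)],
                                 task="reactant", record_id=str(i))
                for i in range(4)]

    def test_oracle_forward_model_gives_one(self):
        recs = self.records()
        oracle = lambda sources, records: [join_molecules(r.products())
                                           for r in records]
        assert roundtrip_accuracy(recs, oracle) == 1.0

    def test_adversarial_stub_gives_zero(self):
        recs = self.records()
        stub = lambda sources, records: ["N" for _ in records]
        assert roundtrip_accuracy(recs, stub) == 0.0

    def test_half_correct_stub(self):
        # forward stub rebuilds the product by grafting the predicted
        # reactants; the reactant predictions are right for half the records
        recs = []
        for i in range(4):
            cand = "CCO.CC" if i % 2 == 0 else "N.N"
            recs.append(PredictionRecord(
                source="CCOCC", target="CCO.CC", candidates=[(cand, 0.0)],
                task="reactant", record_id=str(i)))

        def graft(sources, records):
            out = []
            for s in sources:
                try:
                    out.append(canonicalize("".join(split_molecules(s))))
                except Exception:
                    out.append(None)
            return out

        assert roundtrip_accuracy(recs, graft) == 0.5

    def test_reagent_setting_requires_true_reagents(self):
        rec = PredictionRecord(source="CCOCC.O", target="CCO.CC",
                               candidates=[("CCO.CC", 0.0)], task="reactant",
                               include_reagents=True)
        with pytest.raises(ConfigurationError):
            roundtrip_accuracy([rec], lambda s, r: ["CCOCC"] * len(r))

    def test_reagents_appended_to_forward_input(self):
        rec = PredictionRecord(source="CCOCC.O", target="CCO.CC",
                               candidates=[("CCO.CC", 0.0)], task="reactant",
                               include_reagents=True, true_reagents=["O"])
        seen = {}

        def spy(sources, records):
            seen["src"] = sources[0]
            return ["CCOCC"]

        assert roundtrip_accuracy([rec], spy) == 1.0
        assert seen["src"] == "CCO.CC.O"


class TestPrf:
    def test_hand_example(self):
        # prediction set {A,B}, target set {A,C,D}
        rec = record("CCO.CC.N", ["CCO.CCC"])
        p, r, f = prf_at_k(rec, 1)
        assert p == pytest.approx(0.5)
        assert r == pytest.approx(1 / 3)
        assert f == pytest.approx(0.4)

    def test_perfect(self):
        rec = record("CCO.CC", ["CC.CCO"])
        assert prf_at_k(rec, 1) == (1.0, 1.0, 1.0)

    def test_disjoint_zero_convention(self):
        rec = record("CCO", ["CC"])
        assert prf_at_k(rec, 1) == (0.0, 0.0, 0.0)

    def test_pooling_across_ranks_unique(self):
        rec = record("CCO.CC", ["CCO", "CCO.CC", "N"])
        p, r, f = prf_at_k(rec, 3)
        assert p == pytest.approx(2 / 3)   # pooled set {CCO, CC, N}
        assert r == pytest.approx(1.0)

    def test_unparseable_dropped_from_n(self):
        rec = record("CCO", ["CCO.C1CC"])
        p, r, f = prf_at_k(rec, 1)
        assert p == 1.0 and r == 1.0


class TestBinning:
    def rec_with_reagents(self, n_reagents, prediction_right):
        reagents = ["O", "CO", "CCO", "CC", "CCC", "N", "CN", "CCN", "ClCCl",
                    "COC", "CCOCC", "NCCN", "CNC"][:n_reagents]
        target = join_molecules(reagents)
        cand = target if prediction_right else "c1ccccc1"
        return PredictionRecord(source="CCO.CC", target=target,
                                candidates=[(cand, 0.0)], task="reagent")

    def test_weighted_pooling(self):
        recs = [self.rec_with_reagents(1, True)] * 3 + \
               [self.rec_with_reagents(2, False)]
        bins, pooled = bin_and_pool(recs, k=1, min_bin_n=1)
        assert bins[1]["precision"] == 1.0 and bins[2]["precision"] == 0.0
        assert pooled["precision"] == pytest.approx(0.75)

    def test_single_bin_pooled_equals_bin(self):
        recs = [self.rec_with_reagents(2, True)] * 5
        bins, pooled = bin_and_pool(recs, k=1, min_bin_n=1)
        assert pooled["f1"] == bins[2]["f1"]

    def test_bin_beyond_twelve_reagents_discarded(self):
        recs = [self.rec_with_reagents(1, True)] * 2 + \
               [self.rec_with_reagents(13, True)] * 50
        bins, pooled = bin_and_pool(recs, k=1, min_bin_n=1)
        assert 13 not in bins
        assert pooled["n"] == 2

    def test_sparse_bin_discarded(self):
        recs = [self.rec_with_reagents(1, True)] * 30 + \
               [self.rec_with_reagents(2, False)] * 3
        bins, _ = bin_and_pool(recs, k=1, min_bin_n=10)
        assert 2 not in bins

    def test_no_bins_undefined(self):
        with pytest.raises(UndefinedMetricError):
            bin_and_pool([self.rec_with_reagents(13, True)], k=1, min_bin_n=1)

    def test_pooling_conservation(self):
        """Size-weighted pooling of per-bin means equals the direct mean
        over all retained records."""
        rng = random.Random(0)
        recs = [self.rec_with_reagents(rng.randint(1, 4), rng.random() < 0.5)
                for _ in range(60)]
        bins, pooled = bin_and_pool(recs, k=1, min_bin_n=1)
        direct = np.mean([prf_at_k(r, 1)[0] for r in recs])
        assert pooled["precision"] == pytest.approx(direct)


class TestBruteForceOracle:
    """Every metric must agree exactly with a brute-force recomputation
    based on explicit set comparisons, on small randomized fixtures."""

    def make_fixture(self, seed, molecule_library):
        rng = random.Random(seed)
        recs = []
        for _ in range(50):
            target = join_molecules(rng.sample(molecule_library,
                                               rng.randint(1, 3)))
            cands = []
            for rank in range(rng.randint(1, 5)):
                mols = rng.sample(molecule_library, rng.randint(1, 3))
                if rng.random() < 0.3:
                    mols[0] = target.split(".")[0]
                if rng.random() < 0.1:
                    mols.append("C1CC")  # unparseable
                cands.append((join_molecules(mols), -float(rank)))
            recs.append(PredictionRecord(source="CCO", target=target,
                                         candidates=cands))
        return recs

    @staticmethod
    def canonical_set(line):
        out = set()
        for m in split_molecules(line):
            try:
                out.add(canonicalize(m))
            except Exception:
                pass
        return out

    @staticmethod
    def has_invalid(line):
        for m in split_molecules(line):
            try:
                canonicalize(m)
            except Exception:
                return True
        return False

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_topk_matches_brute_force(self, seed, molecule_library):
        recs = self.make_fixture(seed, molecule_library)
        for k in (1, 2, 5):
            brute_strict = np.mean([
                any(not self.has_invalid(c)
                    and self.canonical_set(c) == self.canonical_set(r.target)
                    for c, _ in r.candidates[:k])
                for r in recs])
            brute_lenient = np.mean([
                any(self.canonical_set(c) & self.canonical_set(r.target)
                    for c, _ in r.candidates[:k])
                for r in recs])
            assert topk_accuracy(recs, k, "strict") == brute_strict
            assert topk_accuracy(recs, k, "lenient") == brute_lenient

    @pytest.mark.parametrize("seed", [4, 5])
    def test_prf_matches_brute_force(self, seed, molecule_library):
        recs = self.make_fixture(seed, molecule_library)
        for r in recs:
            for k in (1, 3):
                pooled = set()
                for c, _ in r.candidates[:k]:
                    pooled |= self.canonical_set(c)
                tset = self.canonical_set(r.target)
                t = len(pooled & tset)
                p_exp = t / len(pooled) if pooled else 0.0
                r_exp = t / len(tset)
                f_exp = (2 * p_exp * r_exp / (p_exp + r_exp)
                         if p_exp + r_exp else 0.0)
                assert prf_at_k(r, k) == (pytest.approx(p_exp),
                                          pytest.approx(r_exp),
                                          pytest.approx(f_exp))


class TestReportInvariants:
    def random_records(self, seed, molecule_library, n=20):
        rng = random.Random(seed)
        recs = []
        for _ in range(n):
            target = join_molecules(rng.sample(molecule_library,
                                               rng.randint(1, 2)))
            cands = []
            score = 0.0
            for _ in range(rng.randint(1, 6)):
                score -= rng.random()
                mols = rng.sample(molecule_library, rng.randint(1, 2))
                if rng.random() < 0.4:
                    mols = split_molecules(target)[:1] + mols[:1]
                cands.append((join_molecules(mols), score))
            recs.append(PredictionRecord(source="CCO", target=target,
                                         candidates=cands))
        return recs

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_and_lenient_dominates(self, seed, molecule_library):
        recs = self.random_records(seed, molecule_library)
        prev_s = prev_l = 0.0
        for k in range(1, 7):
            s = topk_accuracy(recs, k, "strict")
            l = topk_accuracy(recs, k, "lenient")
            assert s >= prev_s and l >= prev_l
            assert l >= s
            prev_s, prev_l = s, l

    def test_evaluate_report_fields(self, molecule_library):
        recs = self.random_records(0, molecule_library)
        report = evaluate(recs, k_values=range(1, 4))
        assert report.n_records == len(recs)
        assert set(report.topk_strict) == {1, 2, 3}
        assert 0.0 <= report.invalid_candidate_rate <= 1.0
        for k in (1, 2, 3):
            assert report.topk_lenient[k] >= report.topk_strict[k]


def test_invalid_candidate_rate_counts_molecules():
    recs = [record("CCO", ["CCO.C1CC"]), record("CCO", ["CCO"])]
    assert invalid_candidate_rate(recs) == pytest.approx(1 / 3)
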