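"""Evaluation suite for reaction-prediction models.

Implements molecule-set scoring of ranked candidate lists:

* **strict** top-k accuracy — the canonical molecule set of some top-k
  candidate equals the target's set exactly;
* **lenient** top-k accuracy — at least one predicted molecule matches a
  target molecule;
* **round-trip accuracy** — the rank-1 predicted reactants (plus the true
  reagents, when the models were trained with reagent information) are fed
  to the matched forward model, and the prediction counts as a success iff
  the forward model's rank-1 product strict-matches the original product;
* **precision / recall / f1 at rank k** — molecule-level scores over the
  set of unique molecules pooled from the top-k candidates, for tasks
  (reagent prediction) where target cardinality varies widely;
* **binned evaluation** — per-reagent-count bins with size-weighted
  pooling, discarding bins beyond 12 reagents or with too few samples.

Molecule comparison is set-based over canonical strings. An unparseable
molecule makes a strict candidate a miss; in lenient and P/R/F scoring the
unparseable molecule is dropped individually and counted in the
invalid-candidate rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Optional, Sequence

import rdkit

from .errors import ConfigurationError, InvalidMoleculeError, UndefinedMetricError
from .molformat import (canonical_molecule_set, join_molecules,
                        partition_valid, split_molecules)

Mode = Literal["strict", "lenient"]


@dataclass
class PredictionRecord:
    """A scored test sample: source, target, and ranked candidates."""

    source: str
    target: str
    candidates: list[tuple[str, float]]
    task: str = "product"
    include_reagents: bool = False
    augmentation_factor: int = 1
    true_reagents: Optional[list[str]] = None
    true_products: Optional[list[str]] = None
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.target:
            raise ConfigurationError("prediction record with empty target")
        scores = [s for _, s in self.candidates]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ConfigurationError("candidates must be ranked by score")

    def products(self) -> list[str]:
        """The true product molecules of the underlying reaction.

        For reactant-prediction records these sit in the source (minus the
        appended reagents when the reagent setting is on), unless
        ``true_products`` was given explicitly.
        """
        if self.true_products is not None:
            return list(self.true_products)
        if self.task == "product":
            return split_molecules(self.target)
        mols = split_molecules(self.source)
        if self.include_reagents:
            if self.true_reagents is None:
                raise ConfigurationError(
                    "cannot recover products: reagents in source but "
                    "true_reagents missing")
            rest = list(mols)
            for r in self.true_reagents:
                if r in rest:
                    rest.remove(r)
            return rest
        return mols


# ---------------------------------------------------------------------------
# hit predicates
# ---------------------------------------------------------------------------


def strict_hit(candidate: str, target: str) -> bool:
    """Exact canonical molecule-set equality; any unparseable molecule in
    the candidate makes it a miss."""
    try:
        cand_set = canonical_molecule_set(candidate)
    except InvalidMoleculeError:
        return False
    return cand_set == canonical_molecule_set(target)


def lenient_hit(candidate: str, target: str) -> bool:
    """At least one shared canonical molecule; unparseable candidate
    molecules are ignored individually."""
    valid, _ = partition_valid(split_molecules(candidate))
    return bool(set(valid) & canonical_molecule_set(target))


_HIT = {"strict": strict_hit, "lenient": lenient_hit}


def _dedup_candidates(candidates: Sequence[tuple[str, float]],
                      ) -> list[tuple[str, float]]:
    """Drop candidates whose canonical molecule set repeats an earlier rank
    (unparseable candidates are kept: they are distinct misses)."""
    seen: set[frozenset[str]] = set()
    out = []
    for cand, score in candidates:
        try:
            key = canonical_molecule_set(cand)
        except InvalidMoleculeError:
            out.append((cand, score))
            continue
        if key in seen:
            continue
        seen.add(key)
        out.append((cand, score))
    return out


def topk_accuracy(records: Sequence[PredictionRecord], k: int,
                  mode: Mode = "strict", dedup: bool = False) -> float:
    """Fraction of records with >=1 hit among the first k candidates.

    ``dedup=True`` collapses canonically identical beam candidates before
    applying k; the default scores the raw n-best ranks.
    """
    if not records:
        raise UndefinedMetricError("top-k accuracy of an empty record list")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    hit = _HIT[mode]
    n_hit = 0
    for rec in records:
        cands = _dedup_candidates(rec.candidates) if dedup else rec.candidates
        n_hit += any(hit(cand, rec.target) for cand, _ in cands[:k])
    return n_hit / len(records)


def invalid_candidate_rate(records: Sequence[PredictionRecord],
                           k: int | None = None) -> float:
    """Fraction of candidate molecules (within top-k) that fail to parse."""
    n_mol = n_bad = 0
    for rec in records:
        for cand, _ in (rec.candidates if k is None else rec.candidates[:k]):
            valid, invalid = partition_valid(split_molecules(cand))
            n_mol += len(valid) + len(invalid)
            n_bad += len(invalid)
    return n_bad / n_mol if n_mol else 0.0


# ---------------------------------------------------------------------------
# round trip
# ---------------------------------------------------------------------------

#: Takes the "."-joined forward-model inputs and the records they came
#: from; returns one top-1 product candidate string (or None) per input.
ForwardModel = Callable[[Sequence[str], Sequence[PredictionRecord]],
                        Sequence[Optional[str]]]


def roundtrip_successes(records: Sequence[PredictionRecord],
                        forward_model: ForwardModel) -> list[bool]:
    """Per-record round-trip outcome for reactant-prediction records.

    The rank-1 candidate (predicted reactants) — concatenated with the true
    reagents when the reagent setting is on — is fed to the matched forward
    model; success means its rank-1 product strict-matches the true product.
    """
    sources = []
    for rec in records:
        if not rec.candidates:
            sources.append("")
            continue
        mols = split_molecules(rec.candidates[0][0])
        if rec.include_reagents:
            if rec.true_reagents is None:
                raise ConfigurationError(
                    "round trip with reagent setting needs true_reagents")
            mols = mols + list(rec.true_reagents)
        sources.append(join_molecules(mols))
    predictions = forward_model(sources, records)
    out = []
    for rec, pred in zip(records, predictions):
        target_products = join_molecules(rec.products())
        out.append(pred is not None and strict_hit(pred, target_products))
    return out


def roundtrip_accuracy(records: Sequence[PredictionRecord],
                       forward_model: ForwardModel) -> float:
    if not records:
        raise UndefinedMetricError("round-trip accuracy of an empty list")
    successes = roundtrip_successes(records, forward_model)
    return sum(successes) / len(records)


# ---------------------------------------------------------------------------
# molecule-level P/R/F
# ---------------------------------------------------------------------------


def prf_at_k(record: PredictionRecord, k: int) -> tuple[float, float, float]:
    """Precision, recall and f1 over the unique molecules pooled from the
    top-k candidates: P = T/N, R = T/M, F = 2PR/(P+R).

    Unparseable predicted molecules are excluded from the prediction set;
    P = 0 when the set is empty, F = 0 when P + R = 0.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    target_set = canonical_molecule_set(record.target)
    m = len(target_set)
    if m == 0:
        raise UndefinedMetricError("P/R/F with an empty target set")
    pooled: set[str] = set()
    for cand, _ in record.candidates[:k]:
        valid, _ = partition_valid(split_molecules(cand))
        pooled.update(valid)
    n = len(pooled)
    t = len(pooled & target_set)
    precision = t / n if n else 0.0
    recall = t / m
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def bin_and_pool(records: Sequence[PredictionRecord], k: int,
                 max_bin: int = 12, min_bin_n: int = 20,
                 ) -> tuple[dict[int, dict[str, float]], dict[str, float]]:
    """Mean P/R/F per reagent-count bin, plus the size-weighted pooled value.

    The bin key is the number of target reagent molecules. Bins with more
    than ``max_bin`` reagents (too few reactions at that complexity) or
    fewer than ``min_bin_n`` records are discarded before pooling.
    """
    by_bin: dict[int, list[tuple[float, float, float]]] = {}
    for rec in records:
        key = len(split_molecules(rec.target))
        by_bin.setdefault(key, []).append(prf_at_k(rec, k))
    bins: dict[int, dict[str, float]] = {}
    for key in sorted(by_bin):
        vals = by_bin[key]
        if key > max_bin or len(vals) < min_bin_n:
            continue
        n = len(vals)
        bins[key] = {
            "n": n,
            "precision": sum(v[0] for v in vals) / n,
            "recall": sum(v[1] for v in vals) / n,
            "f1": sum(v[2] for v in vals) / n,
        }
    if not bins:
        raise UndefinedMetricError("no bins retained for pooling")
    total = sum(b["n"] for b in bins.values())
    pooled = {metric: sum(b[metric] * b["n"] for b in bins.values()) / total
              for metric in ("precision", "recall", "f1")}
    pooled["n"] = total
    return bins, pooled


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-k accuracies and optional round-trip / binned P/R/F values."""

    n_records: int
    topk_strict: dict[int, float]
    topk_lenient: dict[int, float]
    invalid_candidate_rate: float
    roundtrip_accuracy: Optional[float] = None
    bins: Optional[dict[int, dict[str, float]]] = None
    pooled_prf: Optional[dict[str, float]] = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(records: Sequence[PredictionRecord],
             k_values: Sequence[int] = tuple(range(1, 11)),
             forward_model: ForwardModel | None = None,
             prf_k: int | None = None,
             max_bin: int = 12, min_bin_n: int = 20,
             metadata: dict | None = None) -> EvaluationReport:
    """Run the full metric suite on scored records."""
    if not records:
        raise UndefinedMetricError("evaluation of an empty record list")
    max_rank = max(len(r.candidates) for r in records)
    ks = [k for k in k_values if k <= max_rank]
    meta = {"canonicalization": f"rdkit-{rdkit.__version__}"}
    meta.update(metadata or {})
    report = EvaluationReport(
        n_records=len(records),
        topk_strict={k: topk_accuracy(records, k, "strict") for k in ks},
        topk_lenient={k: topk_accuracy(records, k, "lenient") for k in ks},
        invalid_candidate_rate=invalid_candidate_rate(records),
        metadata=meta)
    if forward_model is not None:
        report.roundtrip_accuracy = roundtrip_accuracy(records, forward_model)
    if prf_k is not None:
        report.bins, report.pooled_prf = bin_and_pool(
            records, prf_k, max_bin=max_bin, min_bin_n=min_bin_n)
    return report
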