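"""Expert-label agreement tabulation.

Reactant predictions that fail strict top-1 matching but pass the
round-trip test are candidate *alternative pathways*: whether they are
chemically sensible is a judgment call, so each is labelled independently
by two expert groups as wrong, semi-correct, or correct. This module
selects those candidates and tabulates the two-group labels: "not wrong"
means semi-correct or correct, and a pair of labels is *contradictory*
when exactly one group says wrong.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import ConfigurationError, UndefinedMetricError
from .metrics import (ForwardModel, PredictionRecord, roundtrip_successes,
                      strict_hit)

LABELS = ("wrong", "semi", "correct")
NOT_WRONG = ("semi", "correct")


@dataclass(frozen=True)
class ExpertLabelSet:
    """One reaction's labels: exactly one per expert group."""

    reaction_id: str
    label_group_a: str
    label_group_b: str

    def __post_init__(self) -> None:
        for lab in (self.label_group_a, self.label_group_b):
            if lab not in LABELS:
                raise ConfigurationError(f"unknown expert label {lab!r}")


def select_candidates(records: Sequence[PredictionRecord],
                      forward_model: ForwardModel) -> list[str]:
    """Ids of records that miss strict top-1 but succeed in the round trip."""
    successes = roundtrip_successes(records, forward_model)
    out = []
    for i, (rec, rt) in enumerate(zip(records, successes)):
        top1_hit = bool(rec.candidates) and strict_hit(rec.candidates[0][0],
                                                       rec.target)
        if rt and not top1_hit:
            out.append(rec.record_id if rec.record_id is not None else str(i))
    return out


def tabulate(labels: Sequence[ExpertLabelSet]) -> dict:
    """Two-group agreement summary.

    Returns counts and fractions for: both groups not wrong, both wrong,
    and contradictory (one wrong, one not). Counts partition the total;
    percentages are also reported rounded to integer percent, the form in
    which such tabulations are usually quoted.
    """
    if not labels:
        raise UndefinedMetricError("tabulate on an empty label list")
    total = len(labels)
    both_not_wrong = both_wrong = contradictory = 0
    not_wrong_a = not_wrong_b = 0
    for lab in labels:
        a_ok = lab.label_group_a in NOT_WRONG
        b_ok = lab.label_group_b in NOT_WRONG
        not_wrong_a += a_ok
        not_wrong_b += b_ok
        if a_ok and b_ok:
            both_not_wrong += 1
        elif not a_ok and not b_ok:
            both_wrong += 1
        else:
            contradictory += 1
    def pack(count: int) -> dict:
        return {"count": count, "fraction": count / total,
                "percent": round(100 * count / total)}
    return {
        "total": total,
        "both_not_wrong": pack(both_not_wrong),
        "both_wrong": pack(both_wrong),
        "contradictory": pack(contradictory),
        "group_a_not_wrong": pack(not_wrong_a),
        "group_b_not_wrong": pack(not_wrong_b),
    }


def read_labels(path: str | Path) -> list[ExpertLabelSet]:
    """CSV with header ``reaction_id,group_a,group_b``."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(ExpertLabelSet(row["reaction_id"],
                                      row["group_a"], row["group_b"]))
    return out


def write_labels(labels: Sequence[ExpertLabelSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["reaction_id", "group_a", "group_b"])
        for lab in labels:
            writer.writerow([lab.reaction_id, lab.label_group_a,
                             lab.label_group_b])
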