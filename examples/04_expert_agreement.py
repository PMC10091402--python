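"""Tabulate two-group expert labels over round-trip-positive predictions.

Reactant predictions that fail strict top-1 but pass the round trip are
the interesting disagreement cases: a reference tabulation of 447 such
reactions labelled by two expert groups (362 judged not-wrong by both, 18
wrong by both, 67 contradictory) illustrates the summary this module
computes.
"""

from rxnbench.agreement import ExpertLabelSet, tabulate

labels = []
labels += [ExpertLabelSet(f"r{i}", "correct", "semi") for i in range(362)]
labels += [ExpertLabelSet(f"w{i}", "wrong", "wrong") for i in range(18)]
labels += [ExpertLabelSet(f"c{i}", "correct", "wrong") for i in range(67)]

summary = tabulate(labels)
print(f"total labelled reactions: {summary['total']}")
for key in ("both_not_wrong", "both_wrong", "contradictory"):
    cell = summary[key]
    print(f"  {key:15s}: n={cell['count']:3d}  {cell['percent']}%")
# "not wrong" = semi-correct or correct; a large both-not-wrong share means
# round-trip-positive predictions are mostly chemically plausible even when
# they differ from the reference precursors
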