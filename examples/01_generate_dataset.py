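"""Generate a synthetic reaction dataset and inspect its shape.

Builds 2000 template-derived reactions, checks that the reactant/reagent
count statistics match the patent-corpus profile they emulate (reactants:
1-5, median 2; reagents: 0-21, median 3), and writes the three splits as
reaction-SMILES text files.
"""

import numpy as np

from rxnbench import SyntheticConfig, generate_reactions, split_dataset
from rxnbench.synthetic import write_reactions

config = SyntheticConfig(n_reactions=2000, seed=42)
records = generate_reactions(config)

reactant_counts = np.array([len(r.reactants) for r in records])
reagent_counts = np.array([len(r.reagents) for r in records])
print(f"reactions: {len(records)}")
print(f"reactants per reaction: median {np.median(reactant_counts):.0f}, "
      f"mean {reactant_counts.mean():.2f} (target ~1.78)")
print(f"reagents  per reaction: median {np.median(reagent_counts):.0f}, "
      f"mean {reagent_counts.mean():.2f} (target ~3.03), "
      f"range {reagent_counts.min()}-{reagent_counts.max()}")

train, valid, test = split_dataset(records, config.split_fractions, seed=1)
for name, part in (("train", train), ("valid", valid), ("test", test)):
    write_reactions(part, f"{name}.txt")
    print(f"{name}.txt: {len(part)} reactions")

example = records[0]
print("\nexample reaction (reactants>reagents>products):")
print(f"  {'.'.join(example.reactants)}>{'.'.join(example.reagents)}>"
      f"{'.'.join(example.products)}")
print("the product is derived from the reactants by the record's template,"
      f" {example.template_id}")
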