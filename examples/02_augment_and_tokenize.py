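"""Source-only augmentation and the four tokenization variants.

Takes product-prediction samples, augments them 5-fold (randomized SMILES +
molecule permutation on the source side only), then tokenizes one sample
under every format x scheme combination to show how sequence length and
vocabulary change.
"""

from rxnbench import (AugmentationSpec, SyntheticConfig, Tokenizer,
                      TokenizerSpec, augment_dataset, build_task_samples,
                      generate_reactions, to_selfies)
from rxnbench.molformat import canonicalize, split_molecules

records = generate_reactions(SyntheticConfig(n_reactions=500, seed=7))
samples = build_task_samples(records, "product", include_reagents=True)

augmented = augment_dataset(samples, AugmentationSpec(factor=5, seed=0))
print(f"{len(samples)} samples -> {len(augmented)} after 5-fold augmentation")
original, variant = augmented[0], augmented[1]
print("original source:", original.source)
print("variant  source:", variant.source)
print("same molecules? ",
      sorted(map(canonicalize, split_molecules(original.source)))
      == sorted(map(canonicalize, split_molecules(variant.source))))
print("target untouched:", variant.target == original.target)

smiles_line = samples[0].source
selfies_line = ".".join(to_selfies(m) for m in split_molecules(smiles_line))
train_smiles = [s.source for s in samples] + [s.target for s in samples]
train_selfies = [".".join(to_selfies(m) for m in split_molecules(line))
                 for line in train_smiles]

for dialect, line, corpus in (("smiles", smiles_line, train_smiles),
                              ("selfies", selfies_line, train_selfies)):
    for scheme in ("atom", "bpe"):
        tok = Tokenizer.train(corpus, TokenizerSpec(scheme, dialect,
                                                    min_substring_freq=50))
        tokens = tok.tokenize(line)
        print(f"{dialect:7s} {scheme:4s}: {len(tokens):3d} tokens, "
              f"vocab {len(tok.vocab)}, merges {len(tok.merges)}")
# pair encoding shortens sequences by merging frequent substructures;
# SELFIES strings are longer than SMILES at the atom level
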