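"""Source-only dataset augmentation.

Training sets are enlarged k-fold by re-serializing the *source* molecules
of each sample as random non-canonical SMILES and randomly permuting their
order. Targets are never touched (byte equality is a tested contract), so
the model still learns to emit canonical, consistently ordered outputs.

The original sample is always the first copy at every factor, so factor 1
reproduces the unaugmented dataset exactly. Variants are drawn with
replacement from the randomized-string space; small molecules with few
enumerations may yield duplicate variants, which is accepted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigurationError, InvalidMoleculeError
from .molformat import join_molecules, randomize_smiles, split_molecules
from .synthetic import TaskSample


@dataclass
class AugmentationSpec:
    """Settings for k-fold source-side augmentation.

    ``permute_molecules=False`` keeps the source molecule order fixed (the
    order-preserving variant that can matter for tasks whose source mixes
    roles, e.g. reactants+product in reagent prediction).
    """

    factor: int = 1
    permute_molecules: bool = True
    randomize_strings: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ConfigurationError("augmentation factor must be >= 1")


def _variant_source(molecules: Sequence[str], spec: AugmentationSpec,
                    rng: random.Random, sample_index: int) -> str:
    mols = list(molecules)
    if spec.randomize_strings:
        try:
            mols = [randomize_smiles(m, rng) for m in mols]
        except InvalidMoleculeError as exc:
            raise InvalidMoleculeError(
                f"sample {sample_index}: {exc}") from exc
    if spec.permute_molecules:
        rng.shuffle(mols)
    return join_molecules(mols)


def augment_dataset(samples: Sequence[TaskSample],
                    spec: AugmentationSpec) -> list[TaskSample]:
    """Return ``spec.factor`` copies of each sample, variants randomized.

    Output is grouped by input sample: the untouched original first, then
    ``factor - 1`` variants whose source strings are independently
    randomized/permuted but whose canonical molecule multiset is unchanged.
    Targets are byte-identical to the originals. Deterministic per seed.
    """
    rng = random.Random(spec.seed)
    out: list[TaskSample] = []
    for i, sample in enumerate(samples):
        out.append(sample)
        if spec.factor == 1:
            continue
        molecules = split_molecules(sample.source)
        for _ in range(spec.factor - 1):
            out.append(TaskSample(
                source=_variant_source(molecules, spec, rng, i),
                target=sample.target,
                task=sample.task,
                include_reagents=sample.include_reagents,
                record_index=sample.record_index))
    return out


def write_parallel(samples: Sequence[TaskSample], src_path, tgt_path) -> None:
    """Order-aligned source/target text files, one sample per line."""
    with open(src_path, "w") as fs, open(tgt_path, "w") as ft:
        for s in samples:
            fs.write(s.source + "\n")
            ft.write(s.target + "\n")


def read_parallel(src_path, tgt_path, task="product",
                  include_reagents=False) -> list[TaskSample]:
    with open(src_path) as fs, open(tgt_path) as ft:
        sources = fs.read().splitlines()
        targets = ft.read().splitlines()
    if len(sources) != len(targets):
        raise ConfigurationError("source/target files are not aligned")
    return [TaskSample(source=s, target=t, task=task,
                       include_reagents=include_reagents, record_index=i)
            for i, (s, t) in enumerate(zip(sources, targets))]
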