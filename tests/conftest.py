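import numpy as np
import pytest

from rxnbench.synthetic import (SyntheticConfig, default_templates,
                                generate_reactions)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def small_reactions():
    """200 synthetic reactions shared by read-only tests."""
    return generate_reactions(SyntheticConfig(n_reactions=200, seed=11))


@pytest.fixture(scope="session")
def molecule_library(small_reactions):
    """Distinct molecules (reactants, reagents, products) of the small set."""
    mols = sorted({m for r in small_reactions
                   for m in (*r.reactants, *r.reagents, *r.products)})
    return mols


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
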