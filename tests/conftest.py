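import numpy as np
import pandas as pd
import pytest

import nichebalance as nb


@pytest.fixture
def rng():
    return np.random.default_rng(20170117)


@pytest.fixture
def two_tip_tree():
    return nb.read_newick("(A,B);")


@pytest.fixture
def three_tip_tree():
    # caterpillar ((A,B),C) with the cherry as the first child
    return nb.read_newick("((A,B),C);")


@pytest.fixture
def five_species_tree():
    """Five-species tree whose root splits a singleton against the rest,
    like a tree whose top balance contrasts one species with the
    geometric mean of the other four."""
    return nb.read_newick("(Yellow,((Red,Green),(Blue,Purple)));")


def random_composition(rng, n_samples, d, alpha=1.0):
    """Strictly positive random compositions (Dirichlet rows)."""
    x = rng.dirichlet(np.full(d, alpha), size=n_samples)
    return np.clip(x, 1e-12, None)


@pytest.fixture
def random_composition_factory():
    return random_composition
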