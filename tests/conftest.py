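import numpy as np
import pytest

from polynj import simulate, treeio
from polynj.reconcile import SpeciesIndex


@pytest.fixture
def species_abc():
    """The worked-example species frame: ((a,b),c)."""
    return treeio.parse_newick("((a,b),c);", kind="species")


@pytest.fixture
def strip_digits_map():
    def bind(tree, species_tree):
        return treeio.bind_species(tree, species_tree, rule="strip-digits")
    return bind


@pytest.fixture
def random_polytomy_factory():
    """Random (species subtree root, child images, multiplicity) instances."""

    def make(rng, max_species=4, max_children=6, min_children=3):
        n_sp = int(rng.integers(2, max_species + 1))
        S = simulate.simulate_species_tree(n_sp, int(rng.integers(1 << 30)))
        idx = SpeciesIndex(S)
        n_child = int(rng.integers(min_children, max_children + 1))
        images = [idx.nodes[rng.integers(len(idx.nodes))] for _ in range(n_child)]
        root = images[0]
        for im in images[1:]:
            root = idx.lca(root, im)
        mult = {}
        for im in images:
            mult[im] = mult.get(im, 0) + 1
        return S, root, images, mult

    return make


@pytest.fixture
def family_factory():
    """Simulated gene families over a shared 8-species tree."""
    S = simulate.simulate_species_tree(8, seed=20240901)

    def make(seed, rate_dup=0.15, rate_loss=0.1):
        return S, simulate.simulate_gene_family(S, rate_dup, rate_loss, seed=seed)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
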