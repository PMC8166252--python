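import numpy as np
import pytest

from primsel import SiteClassMixture, SimulationConfig, build_default_tree, simulate_codon_alignment
from primsel.trees import PhyloTree


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def dirichlet_pi():
    return np.random.default_rng(0).dirichlet(np.ones(61) * 8)


@pytest.fixture(scope="session")
def toy3_tree():
    """Three taxa, foreground on the A terminal branch; one non-root internal node."""
    return PhyloTree.from_newick("((A:0.3,B:0.2):0.1,C:0.4);", "A")


@pytest.fixture(scope="session")
def toy4_tree():
    """Four taxa with a trifurcating root (root + one internal node)."""
    return PhyloTree.from_newick("((A:0.3,B:0.2):0.1,C:0.4,D:0.25);", "A")


@pytest.fixture(scope="session")
def primate_tree():
    return build_default_tree(0.05, "Hominina")


@pytest.fixture(scope="session")
def selected_alignment(primate_tree, uniform_pi):
    """One alignment simulated with strong foreground selection, with labels."""
    mix = SiteClassMixture(0.5, 0.35, 0.2, 8.0, 2.0, uniform_pi)
    aln, classes = simulate_codon_alignment(SimulationConfig(primate_tree, 300, mix, seed=2024))
    return aln, classes, mix
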