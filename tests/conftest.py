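import numpy as np
import pytest

from gnathomech import LandmarkConfiguration, Phylogeny


@pytest.fixture
def triangle():
    """A scalene reference triangle (2D)."""
    return LandmarkConfiguration(
        "tri", ["a", "b", "c"], np.array([[0.0, 0.0], [3.0, 0.0], [1.0, 2.0]]),
        side="left")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def balanced4_tree():
    """Four-taxon balanced tree with unit branch lengths."""
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star3_tree():
    return Phylogeny.from_newick("(A:1,B:1,C:1);")


def random_configuration(rng, k=6, d=2, specimen_id="spec"):
    """A random, non-degenerate landmark configuration."""
    coords = rng.normal(0.0, 1.0, size=(k, d))
    labels = [f"p{i}" for i in range(k)]
    return LandmarkConfiguration(specimen_id, labels, coords)


def random_rotation(rng, d):
    """A uniformly random proper rotation matrix."""
    if d == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        return np.array([[np.cos(theta), -np.sin(theta)],
                         [np.sin(theta), np.cos(theta)]])
    from scipy.stats import special_ortho_group
    return special_ortho_group.rvs(d, random_state=rng)
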