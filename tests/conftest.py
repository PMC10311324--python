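import numpy as np
import pytest

from l2unifrac import ProfileVector, parse_newick
from l2unifrac.synthetic import SyntheticSpec, random_tree


@pytest.fixture
def t0():
    """Two-leaf worked tree: l(A)=1, l(B)=4, post-order [A, B, R]."""
    return parse_newick("((A:1.0,B:4.0)R:0.0);")


@pytest.fixture
def t0_profiles(t0):
    return {
        "eA": ProfileVector("eA", [1.0, 0.0, 0.0]),
        "eB": ProfileVector("eB", [0.0, 1.0, 0.0]),
        "eR": ProfileVector("eR", [0.0, 0.0, 1.0]),
    }


def make_tree(n_leaves, seed, bl_mean=1.0):
    return random_tree(SyntheticSpec(n_leaves=n_leaves, bl_mean=bl_mean, seed=seed))


def random_profile(tree, rng, leaves_only=False, sample_id="s"):
    v = np.zeros(tree.n_nodes)
    if leaves_only:
        idx = tree.leaf_indices()
        v[idx] = rng.dirichlet(np.ones(idx.size))
    else:
        v = rng.dirichlet(np.ones(tree.n_nodes))
    return ProfileVector(sample_id, v)


@pytest.fixture
def tree_factory():
    return make_tree


@pytest.fixture
def profile_factory():
    return random_profile
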