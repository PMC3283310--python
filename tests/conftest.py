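import random

import pytest

import coalphylo as cp


@pytest.fixture
def rng():
    return random.Random(20240917)


def random_gene_tree_set(seed, n_trees=5, labels="ABCDEFGH", unrooted=True):
    """A list of random binary trees on a common leaf set."""
    r = random.Random(seed)
    out = []
    for _ in range(n_trees):
        t = cp.random_binary_tree(list(labels), r, rooted=not unrooted)
        out.append(t)
    return out
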