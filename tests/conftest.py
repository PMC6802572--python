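import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from treelike import (
    Alignment,
    RateCategories,
    build_model,
    compress_patterns,
    discretize_gamma,
    read_newick,
)

NUC = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_gtr(rng):
    """A random reversible nucleotide model."""
    ex = rng.uniform(0.5, 2.0, size=6)
    pi = rng.dirichlet(np.full(4, 10.0))
    return build_model("GTR", pi, exchangeabilities=ex)


def random_rates(rng, max_categories=3):
    c = int(rng.integers(1, max_categories + 1))
    if c == 1:
        return RateCategories(np.ones(1), np.ones(1))
    return discretize_gamma(float(rng.uniform(0.2, 2.0)), c)


def random_alignment(rng, n_taxa, n_sites, ambiguity=0.0):
    chars = np.array(list(NUC))
    mat = chars[rng.integers(0, 4, size=(n_taxa, n_sites))]
    if ambiguity > 0:
        mask = rng.random((n_taxa, n_sites)) < ambiguity
        mat[mask] = "N"
    names = tuple(f"t{i}" for i in range(n_taxa))
    return Alignment(names, tuple("".join(row) for row in mat))


def balanced_tree(k: int, branch: float = 0.1):
    """A balanced rooted tree with 2^k tips."""

    def clade(depth, offset):
        if depth == 0:
            return f"t{offset}:{branch}"
        half = 2 ** (depth - 1)
        return (
            f"({clade(depth - 1, offset)},{clade(depth - 1, offset + half)}):{branch}"
        )

    text = (
        f"({clade(k - 1, 0)},{clade(k - 1, 2 ** (k - 1))});"
    )
    return read_newick(text)


def caterpillar_tree(n: int, branch: float = 0.1):
    """A fully unbalanced (ladder) tree rooted at one end."""
    text = f"t0:{branch}"
    for i in range(1, n):
        text = f"({text},t{i}:{branch}):{branch}"
    return read_newick(text[: text.rfind(":")] + ";")


def patterns_for(aln, subset_map=None):
    return compress_patterns(aln, subset_map)
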