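"""Independent reference implementations used only to check the engine.

Everything here is deliberately written against a *different* route
than the library: transition probabilities come from scipy's matrix
exponential (never the eigen path), the tree likelihood is an explicit
sum over all ancestral state assignments (never the pruning recursion),
and the partials oracle is a scalar double loop.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm

# local copy of the IUPAC nucleotide compatibility sets
AMBIG = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3), "-": (0, 1, 2, 3), "?": (0, 1, 2, 3),
}


def char_vector(ch: str, s: int = 4) -> np.ndarray:
    v = np.zeros(s)
    v[list(AMBIG[ch.upper()])] = 1.0
    return v


def transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    return expm(q * t)


def brute_force_loglik(tree, q, pi, rates, weights, pattern_chars, pattern_weights):
    """Total lnL by exhaustive marginalization over ancestral states.

    ``pattern_chars`` is a sequence of strings, one per pattern, giving
    each taxon's character (taxon order = tip id order).  Sums over all
    S^(n_internal) ancestral assignments per pattern per category.
    """
    s = q.shape[0]
    n = tree.tip_count
    internals = list(range(n, tree.node_count))
    root = tree.root
    total = 0.0
    for chars, pw in zip(pattern_chars, pattern_weights):
        site_l = 0.0
        for rate, w in zip(rates, weights):
            pmats = {
                v: transition_matrix(q, rate * float(tree.lengths[v]))
                for v in range(tree.node_count)
                if v != root
            }
            acc = 0.0
            for assign in itertools.product(range(s), repeat=len(internals)):
                state_of = dict(zip(internals, assign))
                term = pi[state_of[root]]
                for v in range(tree.node_count):
                    if v == root:
                        continue
                    sp = state_of[int(tree.parent[v])]
                    if v < n:
                        vec = char_vector(chars[v], s)
                        term *= float(pmats[v][sp] @ vec)
                    else:
                        term *= pmats[v][sp, state_of[v]]
                acc += term
            site_l += w * acc
        total += pw * math.log(site_l)
    return total


def scalar_partials(p1, p2, child1, child2):
    """dest[p,c,i] via explicit scalar loops (the kernel's definition)."""
    n_pat, n_cat, s = child1.shape
    out = np.zeros((n_pat, n_cat, s))
    for p in range(n_pat):
        for c in range(n_cat):
            for i in range(s):
                a = sum(p1[c, i, j] * child1[p, c, j] for j in range(s))
                b = sum(p2[c, i, k] * child2[p, c, k] for k in range(s))
                out[p, c, i] = a * b
    return out


def internal_height(tree, node=None):
    """Longest path to a descendant tip, counting internal nodes."""
    if node is None:
        node = tree.root
    if tree.is_tip(int(node)):
        return 0
    c1, c2 = tree.children[int(node)]
    return 1 + max(internal_height(tree, c1), internal_height(tree, c2))


def jc_match_probability(t_total: float) -> float:
    """P(same state at both tips) for JC over total path length t."""
    return 0.25 + 0.75 * math.exp(-4.0 * t_total / 3.0)
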