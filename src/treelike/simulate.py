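"""Synthetic data: random trees, simulated alignments, benchmark inputs.

Everything downstream of this module is testable without external data:
the simulator draws a tree, evolves sequences along it under the same
substitution models the engine evaluates, and can emit ready-made
benchmark problems (a base instance plus parameter variations) for the
scaling harness.

Topologies are uniform over labeled unrooted topologies, generated by
sequential random edge addition (each new taxon attaches to a uniformly
chosen edge of the current tree), then rooted on a uniformly chosen
edge.  Branch lengths are i.i.d. exponential.  Every stochastic
operation takes an explicit seed (or an existing numpy Generator) and
is byte-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Alignment, PatternSet
from .errors import ValidationError
from .model import (
    NUCLEOTIDES,
    RateCategories,
    SubstitutionModel,
    compute_transition_matrices,
    eigendecompose,
)
from .tree import Tree, root_on_edge, unrooted_edges

__all__ = [
    "SimConfig",
    "random_tree",
    "simulate_alignment",
    "nni_perturb",
    "synthetic_benchmark_inputs",
    "BenchmarkScenario",
]


@dataclass(frozen=True)
class SimConfig:
    """Declarative description of one simulation."""

    otu_count: int
    site_count: int
    seed: int
    branch_mean: float = 0.1
    alpha: float | None = None
    category_count: int = 1


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_tree(otu_count: int, branch_mean: float = 0.1, seed=None) -> Tree:
    """Draw a random rooted binary tree.

    The topology is uniform over the (2n-5)!! labeled unrooted
    topologies: taxa are added one at a time to a uniformly chosen edge
    of the growing unrooted tree.  The root is then placed at the
    midpoint of a uniformly chosen edge, and branch lengths are i.i.d.
    exponential with mean ``branch_mean``.
    """
    if otu_count < 2:
        raise ValidationError("a tree needs at least two OTUs")
    rng = _rng(seed)
    n = otu_count
    # adjacency over node ids: tips 0..n-1, internal attachment points n..2n-3
    edges: list[tuple[int, int]] = [(0, 1)]
    next_internal = n
    for tip in range(2, n):
        pick = rng.integers(len(edges))
        u, v = edges.pop(int(pick))
        mid = next_internal
        next_internal += 1
        edges.extend([(u, mid), (mid, v), (mid, tip)])
    lengths = rng.exponential(branch_mean, size=2 * n - 2)

    if n == 2:
        names = tuple(f"t{i}" for i in range(n))
        parent = np.array([2, 2, -1])
        children = np.array([[-1, -1], [-1, -1], [0, 1]])
        lens = np.array([lengths[0] / 2, lengths[0] / 2, 0.0])
        return Tree(names, parent, children, lens)

    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in zip(edges, lengths):
        adj.setdefault(u, []).append((v, float(w)))
        adj.setdefault(v, []).append((u, float(w)))
    root_edge = edges[int(rng.integers(len(edges)))]

    # materialize a rooted Tree by DFS from the midpoint of root_edge
    names = [f"t{i}" for i in range(n)]
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    lens = np.zeros(2 * n - 1)
    next_id = [n]

    def build(node: int, came_from: int) -> int:
        kids = sorted((nbr, w) for nbr, w in adj[node] if nbr != came_from)
        if not kids:
            return node
        vid_children = [(build(nbr, node), w) for nbr, w in kids]
        vid = next_id[0]
        next_id[0] += 1
        for slot, (cid, w) in enumerate(vid_children):
            parent[cid] = vid
            children[vid, slot] = cid
            lens[cid] = w
        return vid

    u, v = root_edge
    half = next(w for nbr, w in adj[u] if nbr == v) / 2.0
    left = build(u, v)
    right = build(v, u)
    root = 2 * n - 2
    for side, cid in enumerate((left, right)):
        parent[cid] = root
        children[root, side] = cid
    lens[left], lens[right] = half, half
    tree = Tree(tuple(names), parent, children, lens)
    tree.validate()
    return tree


def simulate_alignment(
    tree: Tree,
    model: SubstitutionModel,
    rates: RateCategories | None,
    site_count: int,
    seed=None,
) -> Alignment:
    """Evolve sequences along the tree.

    Per site: draw a rate category by its weight, draw the root state
    from the equilibrium frequencies, then propagate root-to-tips by
    sampling each child state from the parent's row of P(t * r_c).
    """
    if site_count < 1:
        raise ValidationError("site_count must be >= 1")
    if tree.tip_count < 2:
        raise ValidationError("simulation needs at least two tips")
    rng = _rng(seed)
    rates = rates if rates is not None else RateCategories(np.ones(1), np.ones(1))
    s = model.state_count
    eigen = eigendecompose(model)
    tset = compute_transition_matrices(eigen, rates, tree.lengths)
    pmats = tset.probabilities()  # (node, category, S, S)
    # normalize each row exactly for sampling
    pmats = pmats / pmats.sum(axis=3, keepdims=True)

    cats = rng.choice(len(rates.rates), size=site_count, p=rates.weights)
    states = np.empty((tree.node_count, site_count), dtype=np.int64)
    root = tree.root
    states[root] = rng.choice(s, size=site_count, p=model.frequencies)
    # preorder traversal: parents before children
    preorder: list[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        preorder.append(v)
        if not tree.is_tip(v):
            c1, c2 = tree.children[v]
            stack.extend([int(c2), int(c1)])
    for v in preorder:
        if v == root:
            continue
        par = int(tree.parent[v])
        # cumulative row lookup per (category, parent state)
        cum = np.cumsum(pmats[v], axis=2)  # (C, S, S)
        u = rng.random(site_count)
        rows = cum[cats, states[par]]  # (sites, S)
        states[v] = (u[:, None] > rows).sum(axis=1)

    alphabet = np.array(list(NUCLEOTIDES if s == 4 else [str(i) for i in range(s)]))
    seqs = tuple("".join(alphabet[states[i]]) for i in range(tree.tip_count))
    return Alignment(tree.taxon_names, seqs)


def nni_perturb(tree: Tree, seed=None) -> Tree:
    """One random nearest-neighbor interchange on an internal edge.

    Picks a random internal edge of the unrooted tree and swaps one
    subtree across it, changing exactly one bipartition.
    """
    rng = _rng(seed)
    n = tree.tip_count
    if n < 4:
        raise ValidationError("NNI needs at least four tips")
    adj, edges = unrooted_edges(tree)
    internal_edges = [
        (u, v, w) for u, v, w in edges
        if len(adj[u]) == 3 and len(adj[v]) == 3
    ]
    u, v, w = internal_edges[int(rng.integers(len(internal_edges)))]
    u_nbrs = sorted(nbr for nbr, _ in adj[u] if nbr != v)
    v_nbrs = sorted(nbr for nbr, _ in adj[v] if nbr != u)
    a = u_nbrs[int(rng.integers(2))]
    b = v_nbrs[int(rng.integers(2))]

    def wt(x, y):
        return next(wgt for nbr, wgt in adj[x] if nbr == y)

    new_adj = {k: [t for t in vs] for k, vs in adj.items()}

    def replace_nbr(node, old, new, wgt):
        new_adj[node] = [(nbr, wg) for nbr, wg in new_adj[node] if nbr != old]
        new_adj[node].append((new, wgt))

    wa, wb = wt(u, a), wt(v, b)
    replace_nbr(u, a, b, wb)
    replace_nbr(v, b, a, wa)
    replace_nbr(a, u, v, wa)
    replace_nbr(b, v, u, wb)

    # rebuild a Tree by DFS over new_adj, rooting on the swapped edge (u, v)
    names = tree.taxon_names
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    lens = np.zeros(2 * n - 1)
    next_id = [n]

    def build(node: int, came_from: int) -> int:
        kids = sorted((nbr, wg) for nbr, wg in new_adj[node] if nbr != came_from)
        if node < n:
            return node
        vids = [(build(nbr, node), wg) for nbr, wg in kids]
        vid = next_id[0]
        next_id[0] += 1
        for slot, (cid, wg) in enumerate(vids):
            parent[cid] = vid
            children[vid, slot] = cid
            lens[cid] = wg
        return vid

    left = build(u, v)
    right = build(v, u)
    root = 2 * n - 2
    for side, cid in enumerate((left, right)):
        parent[cid] = root
        children[root, side] = cid
    lens[left] = w / 2.0
    lens[right] = w / 2.0
    out = Tree(names, parent, children, lens)
    out.validate()
    return out


@dataclass
class BenchmarkScenario:
    """One benchmark problem: a base configuration plus variations.

    Each variation perturbs topology (one random NNI), branch lengths
    (multiplicative jitter), category rates and weights (jitter then
    renormalize), and pattern weights (re-drawn), mirroring a test
    harness that exercises the engine across the parameters a sampler
    would vary.
    """

    pattern_count: int
    tree: Tree
    patterns: PatternSet
    model: SubstitutionModel
    rates: RateCategories
    variations: list[dict] = field(default_factory=list)


def synthetic_benchmark_inputs(
    pattern_counts,
    otu_count: int = 128,
    seed: int = 0,
    *,
    variation_count: int = 10,
    alpha: float = 0.5,
    category_count: int = 4,
    kappa: float = 2.0,
    branch_mean: float = 0.1,
) -> list[BenchmarkScenario]:
    """Build the scaling-harness inputs: per size, a base plus variations.

    For each requested pattern count a tree is drawn, sequences are
    simulated, and the raw columns become weighted patterns (for many
    OTUs nearly every simulated column is already unique).  Each of the
    ``variation_count`` variations jitters topology, branch lengths,
    category rates/weights (renormalized to valid simplexes and unit
    mean rate), and pattern weights.
    """
    from .data import compress_patterns
    from .model import build_model, discretize_gamma

    rng = _rng(seed)
    scenarios = []
    for count in pattern_counts:
        if count < 1:
            raise ValidationError("pattern counts must be positive")
        freqs = rng.dirichlet(np.full(4, 20.0))
        model = build_model("HKY", freqs, kappa=kappa)
        rates = discretize_gamma(alpha, category_count)
        tree = random_tree(otu_count, branch_mean, rng)
        aln = simulate_alignment(tree, model, rates, count, rng)
        patterns = compress_patterns(aln)
        variations = []
        for _ in range(variation_count):
            var_tree = nni_perturb(tree, rng)
            jitter = rng.uniform(0.8, 1.25, size=var_tree.lengths.shape)
            var_tree = Tree(
                var_tree.taxon_names,
                var_tree.parent,
                var_tree.children,
                var_tree.lengths * jitter,
            )
            r = rates.rates * rng.uniform(0.8, 1.25, size=category_count)
            w = rates.weights * rng.uniform(0.8, 1.25, size=category_count)
            w = w / w.sum()
            r = np.sort(r / (w @ r))
            var_rates = RateCategories(r, w, shape=None)
            pattern_weights = rng.integers(
                1, 5, size=patterns.pattern_count
            ).astype(float)
            variations.append(
                {
                    "tree": var_tree,
                    "rates": var_rates,
                    "pattern_weights": pattern_weights,
                }
            )
        scenarios.append(
            BenchmarkScenario(
                pattern_count=int(count),
                tree=tree,
                patterns=patterns,
                model=model,
                rates=rates,
                variations=variations,
            )
        )
    return scenarios
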