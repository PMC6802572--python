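"""Turning trees into ordered partial-likelihood operation plans.

The pruning recursion imposes only a partial order (children before
parents), which leaves room for batching: grouping internal nodes by
their height above the tips — the reverse level-order — yields *waves*
of mutually independent operations whose inputs are all ready when the
wave starts.  Wave count equals the internal-node height of the tree,
so rerooting a tree on a more central edge (legitimate under reversible
models, where root placement does not change the likelihood) can cut
the number of sequential waves roughly in half for unbalanced trees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .tree import Tree, root_on_edge, unrooted_edges

__all__ = [
    "PartialOperation",
    "WavePlan",
    "plan_postorder",
    "plan_wavefront",
    "plan_partitioned",
    "reroot_for_concurrency",
    "node_heights",
]

ALL_SUBSETS = -1


@dataclass(frozen=True)
class PartialOperation:
    """One partials update: combine two children into a destination buffer.

    Buffer and matrix slots are integer indices into the engine
    instance.  ``subset_index`` restricts the update to one partition's
    pattern range (ALL_SUBSETS = whole pattern axis); ``dest_scale`` is
    the scale buffer receiving this node's log rescaling factors, or
    None when rescaling is off.
    """

    dest_partials: int
    child1_buffer: int
    child2_buffer: int
    child1_matrix: int
    child2_matrix: int
    dest_scale: int | None = None
    subset_index: int = ALL_SUBSETS


@dataclass(frozen=True)
class WavePlan:
    """Ordered waves of independent operations.

    Flattening the waves in order is a valid children-before-parents
    sequence; operations within a wave touch disjoint destinations and
    read only buffers written in earlier waves (or tips).
    """

    waves: tuple[tuple[PartialOperation, ...], ...]

    @property
    def wave_count(self) -> int:
        return len(self.waves)

    def flatten(self) -> list[PartialOperation]:
        return [op for wave in self.waves for op in wave]

    def operation_count(self) -> int:
        return sum(len(w) for w in self.waves)


def _node_op(tree: Tree, node: int, subset: int = ALL_SUBSETS,
             matrix_offset: int = 0) -> PartialOperation:
    c1, c2 = (int(c) for c in tree.children[node])
    return PartialOperation(
        dest_partials=node,
        child1_buffer=c1,
        child2_buffer=c2,
        child1_matrix=matrix_offset + c1,
        child2_matrix=matrix_offset + c2,
        dest_scale=node - tree.tip_count,
        subset_index=subset,
    )


def plan_postorder(tree: Tree) -> list[PartialOperation]:
    """Classic postorder schedule: one op per internal node, left first."""
    return [_node_op(tree, v) for v in tree.postorder_internal()]


def node_heights(tree: Tree) -> np.ndarray:
    """Height above the tips: 0 for tips, 1 + max(children) for internals."""
    h = np.zeros(tree.node_count, dtype=np.int64)
    for v in tree.postorder_internal():
        c1, c2 = tree.children[v]
        h[v] = 1 + max(h[c1], h[c2])
    return h


def plan_wavefront(tree: Tree) -> WavePlan:
    """Reverse level-order schedule grouped by height above the tips.

    Wave ``k`` holds exactly the internal nodes of height ``k+1``; all
    their children lie in earlier waves or are tips, so each wave is a
    batch of independent operations.  Within a wave, nodes are ordered
    by id for reproducibility.
    """
    h = node_heights(tree)
    waves = []
    for k in range(1, int(h.max()) + 1):
        nodes = [v for v in range(tree.tip_count, tree.node_count) if h[v] == k]
        waves.append(tuple(_node_op(tree, v) for v in sorted(nodes)))
    return WavePlan(tuple(waves))


def plan_partitioned(tree: Tree, subset_count: int,
                     matrices_per_subset: int | None = None) -> WavePlan:
    """Wavefront plan with all subsets' same-level operations merged.

    Each wave holds (subset, node) operations in subset-major order, so
    independent partitions are evaluated concurrently within a wave
    rather than in sequence.  Per-subset transition matrices live in
    distinct buffer blocks of size ``matrices_per_subset`` (default: one
    per node).
    """
    if subset_count < 1:
        raise ValueError("subset_count must be >= 1")
    stride = matrices_per_subset if matrices_per_subset is not None else tree.node_count
    base = plan_wavefront(tree)
    waves = []
    for wave in base.waves:
        merged = []
        for s in range(subset_count):
            for op in wave:
                merged.append(
                    replace(
                        op,
                        subset_index=s if subset_count > 1 else ALL_SUBSETS,
                        child1_matrix=s * stride + op.child1_buffer,
                        child2_matrix=s * stride + op.child2_buffer,
                    )
                )
        waves.append(tuple(merged))
    return WavePlan(tuple(waves))


def reroot_for_concurrency(tree: Tree) -> Tree:
    """Re-root on the edge minimizing the wavefront wave count.

    Tries every edge of the unrooted tree (root at the edge midpoint,
    preserving all path lengths), computes the internal-node height of
    each candidate rooting in O(n), and returns the minimum-height
    rooting; ties break toward the lowest edge index.  Valid whenever
    the model is reversible, since the likelihood is root-invariant.
    """
    adj, edges = unrooted_edges(tree)

    def side_height(node: int, came_from: int, memo: dict) -> int:
        key = (node, came_from)
        if key in memo:
            return memo[key]
        kids = [nbr for nbr, _ in adj[node] if nbr != came_from]
        h = 0 if not kids else 1 + max(side_height(k, node, memo) for k in kids)
        memo[key] = h
        return h

    memo: dict = {}
    best_idx, best_height = None, None
    for idx, (u, v, _w) in enumerate(edges):
        height = 1 + max(side_height(u, v, memo), side_height(v, u, memo))
        if best_height is None or height < best_height:
            best_idx, best_height = idx, height
    u, v, _ = edges[best_idx]
    return root_on_edge(tree, (u, v))
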