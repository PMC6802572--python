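"""The likelihood engine: buffer store and pruning kernels.

An :class:`Instance` owns every array the pruning recursion touches —
tip encodings, internal partial-likelihood buffers, eigensystems,
transition-matrix buffers, per-subset rate categories and frequencies,
and per-pattern log scale accumulators — all addressed by integer
indices, so a driver describes a likelihood evaluation as data flow
between numbered slots rather than as tree recursion.

The partials update for an internal node combines its two children
through their branch transition matrices::

    dest[p, c, i] = (sum_j P1[c, i, j] child1[p, c, j])
                  * (sum_k P2[c, i, k] child2[p, c, k])

Three interchangeable implementations exist: ``serial`` (a per-pattern
reference loop), ``vectorized`` (whole pattern axis in one einsum), and
``threaded`` (contiguous pattern blocks on a thread pool).  All three
share the same reduction kernel, whose floating-point result is
invariant to how the pattern axis is blocked, so they are required —
and tested — to agree bitwise.

Rescaling divides each pattern's partials by their maximum across
states and categories and accumulates the log factors per pattern;
the factors re-enter additively in log space at the root, making the
procedure exact up to round-off while keeping intermediate values in
the representable range on large trees.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING_STATE, PatternSet, encode_tip, has_partial_ambiguity
from .errors import StateError, ValidationError
from .model import (
    EigenSystem,
    RateCategories,
    SubstitutionModel,
    compute_transition_matrices,
    eigendecompose,
)
from .scheduler import (
    ALL_SUBSETS,
    PartialOperation,
    WavePlan,
    plan_partitioned,
    plan_postorder,
    plan_wavefront,
)
from .tree import Tree

__all__ = [
    "InstanceConfig",
    "Instance",
    "LikelihoodResult",
    "create_instance",
    "set_instance_data",
    "update_transition_matrices",
    "update_partials",
    "calculate_root_log_likelihood",
    "calculate_edge_log_likelihood",
    "accumulate_scale_factors",
    "TreeLikelihood",
    "IMPLEMENTATIONS",
]

IMPLEMENTATIONS = ("serial", "vectorized", "threaded")

#: pattern-block size used to pick the automatic worker count
_AUTO_BLOCK = 512


@dataclass
class InstanceConfig:
    """Dimensions and execution policy of an engine instance."""

    tip_count: int
    pattern_count: int
    partials_buffer_count: int
    state_count: int = 4
    compact_buffer_count: int = 0
    eigen_buffer_count: int = 1
    matrix_buffer_count: int = 1
    category_count: int = 1
    scale_buffer_count: int = 0
    subset_count: int = 1
    precision: str = "double"
    implementation: str = "vectorized"
    max_workers: int | str = "auto"

    def validate(self) -> None:
        if self.tip_count < 2:
            raise ValidationError("tip_count must be >= 2")
        if self.pattern_count < 1:
            raise ValidationError("pattern_count must be >= 1")
        if self.state_count < 2:
            raise ValidationError("state_count must be >= 2")
        if self.partials_buffer_count < self.tip_count + 1:
            raise ValidationError(
                "partials_buffer_count must cover all tips plus one internal node"
            )
        for name in ("eigen_buffer_count", "matrix_buffer_count",
                     "category_count", "subset_count"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.scale_buffer_count < 0:
            raise ValidationError("scale_buffer_count must be >= 0")
        if self.precision not in ("double", "single"):
            raise ValidationError("precision must be 'double' or 'single'")
        if self.implementation not in IMPLEMENTATIONS + ("auto",):
            raise ValidationError(f"unknown implementation {self.implementation!r}")


@dataclass
class LikelihoodResult:
    """Log-likelihood (nats) and optional per-pattern / derivative extras."""

    total_log_likelihood: float
    per_subset_log_likelihood: np.ndarray
    per_pattern_site_log_likelihood: np.ndarray | None = None
    d1: float | None = None
    d2: float | None = None
    underflow_patterns: tuple[int, ...] = ()


class Instance:
    """Buffer store; create via :func:`create_instance`."""

    def __init__(self, config: InstanceConfig):
        config.validate()
        self.config = config
        self.dtype = np.float64 if config.precision == "double" else np.float32
        n_buf, p, c, s = (
            config.partials_buffer_count,
            config.pattern_count,
            config.category_count,
            config.state_count,
        )
        self.partials = np.zeros((n_buf, p, c, s), dtype=self.dtype)
        self.buffer_written = np.zeros(n_buf, dtype=bool)
        self.tip_states: dict[int, np.ndarray] = {}
        self.eigens: list[EigenSystem | None] = [None] * config.eigen_buffer_count
        self.category_rates = np.ones((config.subset_count, c), dtype=self.dtype)
        self.category_weights = np.full(
            (config.subset_count, c), 1.0 / c, dtype=self.dtype
        )
        self.frequencies = np.full((config.subset_count, s), 1.0 / s, dtype=self.dtype)
        self.pattern_weights = np.ones(p, dtype=self.dtype)
        self.subset_ranges: list[tuple[int, int]] = [(0, p)]
        self.matrices = np.zeros((config.matrix_buffer_count, c, s, s), dtype=self.dtype)
        self.matrices_d1: np.ndarray | None = None
        self.matrices_d2: np.ndarray | None = None
        self.matrix_written = np.zeros(config.matrix_buffer_count, dtype=bool)
        self.scales = np.zeros((config.scale_buffer_count, p), dtype=self.dtype)
        self._impl: str | None = (
            None if config.implementation == "auto" else config.implementation
        )
        self._pool: ThreadPoolExecutor | None = None

    # -- execution policy ------------------------------------------------

    @property
    def implementation(self) -> str:
        if self._impl is None:
            from .bench import auto_select  # deferred: bench builds instances

            self._impl = auto_select(self.config)
        return self._impl

    def worker_count(self, n_patterns: int) -> int:
        limit = self.config.max_workers
        cores = os.cpu_count() or 1
        auto = max(1, min(-(-n_patterns // _AUTO_BLOCK), cores))
        if limit == "auto":
            return auto
        return max(1, min(int(limit), auto if limit == "auto" else int(limit)))

    def _executor(self, workers: int) -> ThreadPoolExecutor:
        if self._pool is None or self._pool._max_workers < workers:
            if self._pool is not None:
                self._pool.shutdown(wait=True)
            self._pool = ThreadPoolExecutor(max_workers=workers)
        return self._pool

    # -- buffer population ----------------------------------------------

    def set_tip_states(self, index: int, codes: np.ndarray) -> None:
        codes = np.asarray(codes)
        if codes.shape != (self.config.pattern_count,):
            raise ValidationError(
                f"tip states for buffer {index}: expected "
                f"({self.config.pattern_count},), got {codes.shape}"
            )
        if self.buffer_written[index]:
            raise StateError(f"tip buffer {index} is immutable once set")
        self.tip_states[index] = codes.astype(np.int64)
        self.buffer_written[index] = True

    def set_tip_partials(self, index: int, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=self.dtype)
        p, c, s = (
            self.config.pattern_count,
            self.config.category_count,
            self.config.state_count,
        )
        if values.shape == (p, s):  # replicate across categories
            values = np.repeat(values[:, None, :], c, axis=1)
        if values.shape != (p, c, s):
            raise ValidationError(
                f"tip partials for buffer {index}: expected ({p}, {c}, {s})"
            )
        if self.buffer_written[index] and index in self.tip_states:
            raise StateError(f"tip buffer {index} is immutable once set")
        self.partials[index] = values
        self.buffer_written[index] = True

    def set_eigen(self, index: int, eigen: EigenSystem) -> None:
        self.eigens[index] = eigen
        self.matrix_written[:] = False  # dependent matrices now stale

    def set_category_rates(self, subset: int, rates: np.ndarray) -> None:
        rates = np.asarray(rates, dtype=self.dtype)
        if rates.shape != (self.config.category_count,):
            raise ValidationError(f"category rates for subset {subset}: wrong shape")
        self.category_rates[subset] = rates
        self.matrix_written[:] = False

    def set_category_weights(self, subset: int, weights: np.ndarray) -> None:
        weights = np.asarray(weights, dtype=self.dtype)
        if weights.shape != (self.config.category_count,):
            raise ValidationError(f"category weights for subset {subset}: wrong shape")
        self.category_weights[subset] = weights

    def set_frequencies(self, subset: int, freqs: np.ndarray) -> None:
        freqs = np.asarray(freqs, dtype=self.dtype)
        if freqs.shape != (self.config.state_count,):
            raise ValidationError(f"frequencies for subset {subset}: wrong shape")
        self.frequencies[subset] = freqs

    def set_pattern_weights(self, weights: np.ndarray) -> None:
        weights = np.asarray(weights, dtype=self.dtype)
        if weights.shape != (self.config.pattern_count,):
            raise ValidationError(
                f"pattern_weights: expected ({self.config.pattern_count},), "
                f"got {weights.shape}"
            )
        self.pattern_weights = weights

    def set_subset_ranges(self, ranges) -> None:
        ranges = [tuple(r) for r in ranges]
        if len(ranges) != self.config.subset_count:
            raise ValidationError(
                f"expected {self.config.subset_count} subset ranges, got {len(ranges)}"
            )
        pos = 0
        for start, end in ranges:
            if start != pos or end <= start:
                raise ValidationError("subset ranges must be contiguous and nonempty")
            pos = end
        if pos != self.config.pattern_count:
            raise ValidationError("subset ranges must cover the pattern axis")
        self.subset_ranges = ranges

    # -- internals -------------------------------------------------------

    def _range(self, subset_index: int) -> tuple[int, int]:
        if subset_index == ALL_SUBSETS:
            return 0, self.config.pattern_count
        try:
            return self.subset_ranges[subset_index]
        except IndexError:
            raise ValidationError(f"no subset {subset_index}") from None

    def full_partials(self, buffer: int, start: int, end: int) -> np.ndarray:
        """Buffer contents as dense (patterns, categories, states)."""
        if not self.buffer_written[buffer]:
            raise StateError(f"partials buffer {buffer} was never written")
        if buffer in self.tip_states:
            codes = self.tip_states[buffer][start:end]
            s = self.config.state_count
            dense = np.zeros((end - start, s), dtype=self.dtype)
            known = codes < s
            dense[np.where(known)[0], codes[known]] = 1.0
            dense[~known] = 1.0  # missing sentinel: factor one for every state
            return np.repeat(dense[:, None, :], self.config.category_count, axis=1)
        return self.partials[buffer, start:end]


def create_instance(config: InstanceConfig) -> Instance:
    """Allocate an instance with all buffers zeroed."""
    return Instance(config)


def set_instance_data(
    instance: Instance,
    *,
    tips: dict[int, np.ndarray] | None = None,
    eigen=None,
    rates=None,
    frequencies=None,
    pattern_weights=None,
    subset_ranges=None,
) -> Instance:
    """Populate instance slots in one call.

    ``tips`` maps buffer index to either an int code vector (compact) or
    a (patterns, states) / (patterns, categories, states) float array
    (tip partials).  ``eigen``, ``rates`` and ``frequencies`` may each
    be a single object (broadcast to every subset) or a per-subset list.
    Re-setting eigensystems or category rates invalidates any cached
    transition matrices.
    """
    k = instance.config.subset_count

    def per_subset(value, n):
        if value is None:
            return [None] * n
        if isinstance(value, (list, tuple)):
            if len(value) != n:
                raise ValidationError(f"expected {n} per-subset values, got {len(value)}")
            return list(value)
        return [value] * n

    if subset_ranges is not None:
        instance.set_subset_ranges(subset_ranges)
    if tips:
        for idx, payload in tips.items():
            arr = np.asarray(payload)
            if arr.dtype.kind in "iu" and arr.ndim == 1:
                instance.set_tip_states(idx, arr)
            else:
                instance.set_tip_partials(idx, arr)
    for slot, eig in enumerate(per_subset(eigen, min(k, len(instance.eigens)))):
        if eig is not None:
            instance.set_eigen(slot, eig)
    for slot, rc in enumerate(per_subset(rates, k)):
        if rc is not None:
            instance.set_category_rates(slot, rc.rates)
            instance.set_category_weights(slot, rc.weights)
    for slot, freqs in enumerate(per_subset(frequencies, k)):
        if freqs is not None:
            instance.set_frequencies(slot, freqs)
    if pattern_weights is not None:
        instance.set_pattern_weights(pattern_weights)
    return instance


def update_transition_matrices(
    instance: Instance,
    subset_index: int,
    edge_lengths,
    matrix_indices,
    *,
    want_derivatives: bool = False,
) -> Instance:
    """Fill matrix buffers with P (and optionally dP/dt, d2P/dt2).

    Matrices come from the subset's eigensystem and category rates via
    :func:`treelike.model.compute_transition_matrices`.
    """
    slot = 0 if subset_index == ALL_SUBSETS else subset_index
    eigen_slot = min(slot, len(instance.eigens) - 1)
    eigen = instance.eigens[eigen_slot]
    if eigen is None:
        raise StateError(f"eigen buffer {eigen_slot} was never set")
    t = np.atleast_1d(np.asarray(edge_lengths, dtype=float))
    idx = np.atleast_1d(np.asarray(matrix_indices, dtype=int))
    if t.shape != idx.shape:
        raise ValidationError("edge_lengths and matrix_indices must align")
    if np.any(idx < 0) or np.any(idx >= instance.config.matrix_buffer_count):
        raise ValidationError("matrix index out of range")
    rates = RateCategories(
        np.asarray(instance.category_rates[slot], dtype=float),
        np.asarray(instance.category_weights[slot], dtype=float),
    )
    tset = compute_transition_matrices(eigen, rates, t, want_derivatives=want_derivatives)
    instance.matrices[idx] = np.maximum(tset.matrices, 0.0)
    if want_derivatives:
        if instance.matrices_d1 is None:
            instance.matrices_d1 = np.zeros_like(instance.matrices)
            instance.matrices_d2 = np.zeros_like(instance.matrices)
        instance.matrices_d1[idx] = tset.d1
        instance.matrices_d2[idx] = tset.d2
    instance.matrix_written[idx] = True
    return instance


# -- the pruning kernel ----------------------------------------------------


def _child_factor(
    instance: Instance, buffer: int, matrix: np.ndarray, start: int, end: int
) -> np.ndarray:
    """sum_j P[c,i,j] * child[p,c,j] as (patterns, categories, states).

    Compact tips replace the reduction with a column lookup: a known
    state selects one matrix column, the missing sentinel contributes a
    factor of one.  The einsum reduction (optimize disabled) is
    elementwise-invariant to pattern blocking, which underwrites the
    bitwise-determinism contract across implementations.
    """
    if buffer in instance.tip_states:
        codes = instance.tip_states[buffer][start:end]
        c, s = matrix.shape[0], matrix.shape[1]
        padded = np.concatenate(
            [matrix, np.ones((c, s, 1), dtype=matrix.dtype)], axis=2
        )
        return np.ascontiguousarray(np.moveaxis(padded[:, :, codes], 2, 0))
    if not instance.buffer_written[buffer]:
        raise StateError(f"partials buffer {buffer} was never written")
    child = instance.partials[buffer, start:end]
    return np.einsum("cij,pcj->pci", matrix, child, optimize=False)


def _apply_operation(
    instance: Instance, op: PartialOperation, start: int, end: int, rescale: bool
) -> None:
    m1 = instance.matrices[op.child1_matrix]
    m2 = instance.matrices[op.child2_matrix]
    if not (instance.matrix_written[op.child1_matrix]
            and instance.matrix_written[op.child2_matrix]):
        raise StateError(
            f"operation for buffer {op.dest_partials} reads an unset matrix"
        )
    dest = _child_factor(instance, op.child1_buffer, m1, start, end) * _child_factor(
        instance, op.child2_buffer, m2, start, end
    )
    if rescale:
        if op.dest_scale is None:
            raise StateError("rescaling requested but operation has no scale buffer")
        peak = dest.max(axis=(1, 2))
        positive = peak > 0
        scaled = np.where(positive, peak, 1.0)
        dest /= scaled[:, None, None]
        with np.errstate(divide="ignore"):
            logs = np.where(positive, np.log(scaled), 0.0)
        instance.scales[op.dest_scale, start:end] = logs
    instance.partials[op.dest_partials, start:end] = dest
    instance.buffer_written[op.dest_partials] = True


def update_partials(instance: Instance, plan, rescale: str = "none") -> Instance:
    """Execute a WavePlan or operation list.

    ``rescale`` is ``"none"`` or ``"always"``; with ``"always"``, each
    destination pattern is divided by its maximum across states and
    categories and the log factor lands in the operation's scale buffer.
    Whatever the implementation (serial / vectorized / threaded), the
    double-precision results are bitwise identical.
    """
    if rescale not in ("none", "always"):
        raise ValidationError("rescale must be 'none' or 'always'")
    ops = plan.flatten() if isinstance(plan, WavePlan) else list(plan)
    impl = instance.implementation
    do_rescale = rescale == "always"
    for op in ops:
        start, end = instance._range(op.subset_index)
        n = end - start
        if impl == "serial":
            for p in range(start, end):
                _apply_operation(instance, op, p, p + 1, do_rescale)
        elif impl == "vectorized" or n == 1:
            _apply_operation(instance, op, start, end, do_rescale)
        elif impl == "threaded":
            workers = instance.worker_count(n)
            if workers == 1:
                _apply_operation(instance, op, start, end, do_rescale)
            else:
                bounds = np.linspace(start, end, workers + 1).astype(int)
                pool = instance._executor(workers)
                futures = [
                    pool.submit(_apply_operation, instance, op, int(a), int(b), do_rescale)
                    for a, b in zip(bounds[:-1], bounds[1:])
                    if b > a
                ]
                for fut in futures:
                    fut.result()
        else:  # pragma: no cover - guarded by config validation
            raise ValidationError(f"unknown implementation {impl!r}")
    return instance


# -- likelihood reductions -------------------------------------------------


def _as_scale_list(scale_buffers, n_subsets):
    if scale_buffers is None:
        return [None] * n_subsets
    if isinstance(scale_buffers, (list, tuple)):
        return list(scale_buffers)
    return [scale_buffers] * n_subsets


def calculate_root_log_likelihood(
    instance: Instance,
    root_buffers,
    scale_buffers=None,
    *,
    want_site_lnl: bool = False,
) -> LikelihoodResult:
    """Reduce root partials to the total and per-subset log-likelihood.

    Per pattern ``L_p = sum_i pi_i sum_c w_c root[p,c,i]`` and
    ``lnL_p = ln L_p + accumulated_scale[p]``; subset log-likelihoods
    are pattern-weight-weighted sums over each subset's range, and the
    total is their sum.  A zero site likelihood yields -inf with the
    offending patterns reported rather than an exception.
    """
    k = len(instance.subset_ranges)
    roots = root_buffers if isinstance(root_buffers, (list, tuple)) else [root_buffers] * k
    if len(roots) != k:
        raise ValidationError(f"expected {k} root buffers, got {len(roots)}")
    scales = _as_scale_list(scale_buffers, k)

    per_subset = np.zeros(k)
    site_lnl = np.full(instance.config.pattern_count, np.nan) if want_site_lnl else None
    underflow: list[int] = []
    for s_idx, ((start, end), buf, scl) in enumerate(
        zip(instance.subset_ranges, roots, scales)
    ):
        root = instance.full_partials(buf, start, end)
        site_l = np.einsum(
            "pci,c,i->p",
            root,
            instance.category_weights[s_idx],
            instance.frequencies[s_idx],
            optimize=False,
        )
        with np.errstate(divide="ignore"):
            lnl = np.log(site_l)
        if scl is not None:
            lnl = lnl + instance.scales[scl, start:end]
        zero = site_l <= 0.0
        if np.any(zero):
            underflow.extend((start + np.where(zero)[0]).tolist())
            lnl = np.where(zero, -np.inf, lnl)
        if site_lnl is not None:
            site_lnl[start:end] = lnl
        per_subset[s_idx] = float(lnl @ instance.pattern_weights[start:end])
    return LikelihoodResult(
        total_log_likelihood=float(per_subset.sum()),
        per_subset_log_likelihood=per_subset,
        per_pattern_site_log_likelihood=site_lnl,
        underflow_patterns=tuple(underflow),
    )


def calculate_edge_log_likelihood(
    instance: Instance,
    parent_buffer: int,
    child_buffer: int,
    matrix_index: int,
    subset_index: int = ALL_SUBSETS,
    *,
    want_derivatives: bool = False,
    scale_buffer: int | None = None,
) -> LikelihoodResult:
    """Likelihood factorized across one edge, with branch derivatives.

    ``parent_buffer`` holds the outside ("pre-order") partials — the
    tree minus the child subtree, computed by the caller toward this
    edge — and ``child_buffer`` the child subtree partials.  Per pattern

        L_p  = sum_c w_c sum_i pi_i parent[p,c,i] sum_j P[c,i,j] child[p,c,j]

    and the derivative sums replace P with dP/dt and d2P/dt2:
    ``d1 = sum_p w_p L'_p / L_p`` and
    ``d2 = sum_p w_p (L''_p / L_p - (L'_p / L_p)^2)``.
    """
    slot = 0 if subset_index == ALL_SUBSETS else subset_index
    start, end = instance._range(subset_index)
    if not instance.matrix_written[matrix_index]:
        raise StateError(f"matrix buffer {matrix_index} was never set")
    parent = instance.full_partials(parent_buffer, start, end)
    child = instance.full_partials(child_buffer, start, end)
    w = instance.category_weights[slot]
    pi = instance.frequencies[slot]

    def bilinear(mat):
        inner = np.einsum("cij,pcj->pci", mat, child, optimize=False)
        return np.einsum("pci,pci,c,i->p", parent, inner, w, pi, optimize=False)

    site_l = bilinear(instance.matrices[matrix_index])
    with np.errstate(divide="ignore"):
        site_lnl = np.log(site_l)
    if scale_buffer is not None:
        site_lnl = site_lnl + instance.scales[scale_buffer, start:end]
    zero = site_l <= 0.0
    underflow = tuple((start + np.where(zero)[0]).tolist())
    site_lnl = np.where(zero, -np.inf, site_lnl)
    pw = instance.pattern_weights[start:end]
    total = float(site_lnl @ pw)

    d1 = d2 = None
    if want_derivatives:
        if instance.matrices_d1 is None or not instance.matrix_written[matrix_index]:
            raise StateError("derivative matrices missing; recompute with derivatives")
        l1 = bilinear(instance.matrices_d1[matrix_index])
        l2 = bilinear(instance.matrices_d2[matrix_index])
        ratio1 = l1 / site_l
        ratio2 = l2 / site_l
        d1 = float(ratio1 @ pw)
        d2 = float((ratio2 - ratio1**2) @ pw)

    per_subset = np.array([total])
    return LikelihoodResult(
        total_log_likelihood=total,
        per_subset_log_likelihood=per_subset,
        per_pattern_site_log_likelihood=site_lnl,
        d1=d1,
        d2=d2,
        underflow_patterns=underflow,
    )


def accumulate_scale_factors(instance: Instance, scale_indices, destination: int) -> Instance:
    """destination[p] = sum over listed scale buffers of their log factors."""
    idx = list(scale_indices)
    n = instance.config.scale_buffer_count
    for i in idx + [destination]:
        if not 0 <= i < n:
            raise ValidationError(f"scale buffer {i} out of range [0, {n})")
    if idx:
        instance.scales[destination] = instance.scales[idx].sum(axis=0)
    else:
        instance.scales[destination] = 0.0
    return instance


# -- high-level driver -----------------------------------------------------


class TreeLikelihood:
    """Convenience driver wiring patterns, tree, and models to an instance.

    Buffer conventions: partials buffer ``v`` belongs to tree node ``v``
    (tips 0..n-1, internals n..2n-2); one extra scratch buffer holds
    outside partials for edge-derivative queries.  Matrix buffer
    ``k * (2n-1) + v`` holds subset ``k``'s matrices for the edge above
    node ``v``.  Scale buffer ``v - n`` belongs to internal node ``v``,
    with one extra cumulative buffer at index ``n-1``.

    Parameters
    ----------
    patterns : PatternSet
    tree : Tree
        Taxon names must match the pattern set's.
    models, rates : per-subset lists (or single objects, broadcast)
    subset_rates : optional per-subset relative rate multipliers applied
        to branch lengths, as in partitioned analyses where each gene
        evolves at its own relative rate.
    rescale : "none" or "always"
    plan : "wavefront" (default) or "postorder"
    """

    def __init__(
        self,
        patterns: PatternSet,
        tree: Tree,
        models,
        rates,
        *,
        subset_rates=None,
        rescale: str = "none",
        implementation: str = "vectorized",
        max_workers: int | str = "auto",
        plan: str = "wavefront",
        prefer_tip_states: bool = True,
    ):
        if tuple(tree.taxon_names) != tuple(patterns.taxon_names):
            raise ValidationError("tree and pattern set disagree on taxa")
        k = patterns.subset_count
        self.patterns = patterns
        self.tree = tree
        self.models = list(models) if isinstance(models, (list, tuple)) else [models] * k
        self.rates = list(rates) if isinstance(rates, (list, tuple)) else [rates] * k
        if len(self.models) != k or len(self.rates) != k:
            raise ValidationError("need one model and one rate set per subset")
        self.subset_rates = (
            np.ones(k) if subset_rates is None else np.asarray(subset_rates, dtype=float)
        )
        self.rescale = rescale
        n = tree.tip_count
        nodes = tree.node_count
        cats = self.rates[0].category_count
        if any(r.category_count != cats for r in self.rates):
            raise ValidationError("all subsets must share the category count")
        config = InstanceConfig(
            tip_count=n,
            pattern_count=patterns.pattern_count,
            partials_buffer_count=nodes + 1,  # +1 scratch for outside partials
            state_count=self.models[0].state_count,
            eigen_buffer_count=k,
            matrix_buffer_count=k * nodes,
            category_count=cats,
            scale_buffer_count=n,  # per-internal-node + 1 cumulative
            subset_count=k,
            implementation=implementation,
            max_workers=max_workers,
        )
        self.instance = create_instance(config)
        self._scratch = nodes
        self._cumulative_scale = n - 1

        tips = {}
        for i in range(n):
            column = patterns.taxon_column(i)
            if prefer_tip_states and not has_partial_ambiguity(column):
                tips[i] = encode_tip(column, "compact")
            else:
                tips[i] = encode_tip(column, "partial")
        eigens = [eigendecompose(m) for m in self.models]
        set_instance_data(
            self.instance,
            tips=tips,
            eigen=eigens,
            rates=self.rates,
            frequencies=[m.frequencies for m in self.models],
            pattern_weights=patterns.weights.astype(float),
            subset_ranges=patterns.subset_ranges,
        )
        self._update_all_matrices()
        if plan == "wavefront":
            self.plan = plan_partitioned(tree, k, matrices_per_subset=nodes)
        elif plan == "postorder":
            base = plan_postorder(tree)
            ops = []
            for op in base:
                for s in range(k):
                    from dataclasses import replace

                    ops.append(
                        replace(
                            op,
                            subset_index=s if k > 1 else ALL_SUBSETS,
                            child1_matrix=s * nodes + op.child1_buffer,
                            child2_matrix=s * nodes + op.child2_buffer,
                        )
                    )
            self.plan = ops
        else:
            raise ValidationError(f"unknown plan {plan!r}")

    def _update_all_matrices(self, want_derivatives: bool = False) -> None:
        nodes = self.tree.node_count
        edge_nodes = np.arange(nodes - 1)  # every node but the root has an edge
        lengths = self.tree.lengths[edge_nodes]
        for s_idx in range(self.patterns.subset_count):
            update_transition_matrices(
                self.instance,
                s_idx,
                lengths * self.subset_rates[s_idx],
                s_idx * nodes + edge_nodes,
                want_derivatives=want_derivatives,
            )

    def compute(self, *, want_site_lnl: bool = False) -> LikelihoodResult:
        """Run the traversal and return the log-likelihood."""
        update_partials(self.instance, self.plan, rescale=self.rescale)
        scale = None
        if self.rescale == "always":
            n = self.tree.tip_count
            accumulate_scale_factors(
                self.instance, list(range(n - 1)), self._cumulative_scale
            )
            scale = self._cumulative_scale
        return calculate_root_log_likelihood(
            self.instance,
            self.tree.root,
            scale,
            want_site_lnl=want_site_lnl,
        )

    def edge_derivatives(self, node: int | None = None) -> LikelihoodResult:
        """Total lnL with d1/d2 w.r.t. the branch length above ``node``.

        ``node`` must be a child of the root (the default picks the
        first); for other edges, re-root the tree on the edge of
        interest first.  The outside partials are the sibling subtree
        propagated through its own branch.
        """
        tree = self.tree
        c1, c2 = (int(c) for c in tree.children[tree.root])
        if node is None:
            node = c1
        if node not in (c1, c2):
            raise ValidationError("edge derivatives need a child of the root")
        sibling = c2 if node == c1 else c1
        update_partials(self.instance, self.plan, rescale=self.rescale)
        self._update_all_matrices(want_derivatives=True)

        nodes = tree.node_count
        k = self.patterns.subset_count
        inst = self.instance
        total = 0.0
        d1 = 0.0
        d2 = 0.0
        per_subset = np.zeros(k)
        scale = None
        if self.rescale == "always":
            # every internal node's factor except the root's own
            internals = [v - tree.tip_count for v in range(tree.tip_count, nodes - 1)]
            accumulate_scale_factors(inst, internals, self._cumulative_scale)
            scale = self._cumulative_scale
        for s_idx in range(k):
            start, end = inst.subset_ranges[s_idx] if k > 1 else inst._range(ALL_SUBSETS)
            sib_vals = inst.full_partials(sibling, start, end)
            sib_mat = inst.matrices[s_idx * nodes + sibling]
            outside = np.einsum("cij,pcj->pci", sib_mat, sib_vals, optimize=False)
            inst.partials[self._scratch, start:end] = outside
            inst.buffer_written[self._scratch] = True
            res = calculate_edge_log_likelihood(
                inst,
                self._scratch,
                node,
                s_idx * nodes + node,
                subset_index=s_idx if k > 1 else ALL_SUBSETS,
                want_derivatives=True,
                scale_buffer=scale,
            )
            per_subset[s_idx] = res.total_log_likelihood
            total += res.total_log_likelihood
            rho = self.subset_rates[s_idx]  # chain rule for relative rates
            d1 += rho * res.d1
            d2 += rho * rho * res.d2
        return LikelihoodResult(
            total_log_likelihood=total,
            per_subset_log_likelihood=per_subset,
            d1=d1,
            d2=d2,
        )

    def set_branch_lengths(self, lengths) -> None:
        """Replace branch lengths and refresh the transition matrices."""
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != self.tree.lengths.shape:
            raise ValidationError("branch length vector has wrong shape")
        object.__setattr__(self.tree, "lengths", lengths)
        self._update_all_matrices()
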