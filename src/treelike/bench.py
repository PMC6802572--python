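"""Automatic implementation selection and the scaling harness.

The engine ships several interchangeable kernels (serial reference,
vectorized, threaded).  Which is fastest depends on the problem's
dimensions, so rather than asking the user to guess, the benchmark runs
the identical traversal-plus-root-likelihood workload on a synthetic
problem of the *exact* dimensions of the target analysis and ranks the
candidates by median wall time.  Correctness precedes speed: candidates
must agree bitwise on the log-likelihood before any ranking is
returned.

``run_synthetictest`` is the scaling harness: it simulates data for a
tree, evaluates the likelihood for a set of parameter variations
(topology, branch lengths, category rates and weights, pattern
weights) across replicates and pattern counts, and reports timing and
cross-implementation agreement as a DataFrame.
"""

from __future__ import annotations

import logging
import statistics
import time
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .engine import IMPLEMENTATIONS, InstanceConfig, TreeLikelihood
from .errors import StateError, ValidationError
from .model import build_model, discretize_gamma
from .simulate import synthetic_benchmark_inputs

__all__ = [
    "ResourceRanking",
    "benchmark_implementations",
    "auto_select",
    "run_synthetictest",
]

log = logging.getLogger(__name__)

#: problem sizes (patterns * tips) above which the pure-Python reference
#: path is not auto-benchmarked (it is never competitive there)
_SERIAL_AUTO_LIMIT = 5000

_auto_cache: dict[tuple, str] = {}


@dataclass(frozen=True)
class ResourceRanking:
    """Implementations ordered by median measured evaluation time."""

    entries: tuple[tuple[str, float, int], ...]  # (impl, median seconds, reps)
    chosen: str


def _synthetic_problem(patterns, tips, categories, subsets, seed):
    """A likelihood problem of exactly the requested dimensions."""
    scenario = synthetic_benchmark_inputs(
        [patterns], otu_count=tips, seed=seed, variation_count=0,
        category_count=categories,
    )[0]
    pset = scenario.patterns
    if subsets > 1:
        n = pset.pattern_count
        bounds = np.linspace(0, n, subsets + 1).astype(int)
        ranges = tuple(
            (int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
        )
        if len(ranges) != subsets:
            raise ValidationError("more subsets than patterns")
        sub = np.zeros(n, dtype=int)
        for k, (a, b) in enumerate(ranges):
            sub[a:b] = k
        pset = _dc_replace(pset, subset_ranges=ranges, subset_of_site=sub)
    models = [scenario.model] * subsets
    rates = [scenario.rates] * subsets
    return pset, scenario.tree, models, rates


def benchmark_implementations(
    *,
    patterns: int,
    tips: int,
    categories: int = 4,
    subsets: int = 1,
    states: int = 4,
    candidates=IMPLEMENTATIONS,
    reps: int = 5,
    seed: int = 0,
    timer=time.perf_counter,
) -> ResourceRanking:
    """Time each candidate on the target dimensions and rank them.

    Each candidate runs one discarded warm-up evaluation plus ``reps``
    (at least 3) timed full-traversal + root-likelihood evaluations on
    the same internally generated synthetic problem; the median wall
    time is recorded.  All candidates must produce bitwise-identical
    log-likelihoods, otherwise a :class:`StateError` is raised.
    Candidates that fail to run are excluded with a logged notice.
    """
    if not candidates:
        raise ValidationError("no candidate implementations")
    if states != 4:
        raise ValidationError("benchmark generation supports nucleotide models (4 states)")
    reps = max(3, int(reps))
    pset, tree, models, rates = _synthetic_problem(
        patterns, tips, categories, subsets, seed
    )
    entries = []
    lnls: dict[str, float] = {}
    for cand in candidates:
        try:
            tl = TreeLikelihood(
                pset, tree, models, rates, implementation=cand
            )
            tl.compute()  # warm-up, discarded
            times = []
            for _ in range(reps):
                t0 = timer()
                res = tl.compute()
                times.append(timer() - t0)
            lnls[cand] = res.total_log_likelihood
            entries.append((cand, float(statistics.median(times)), reps))
        except ValidationError:
            raise
        except Exception as exc:  # unavailable candidate: exclude, keep going
            log.warning("excluding implementation %r: %s", cand, exc)
    if not entries:
        raise StateError("no candidate implementation could be benchmarked")
    values = set(lnls.values())
    if len(values) != 1:
        raise StateError(
            f"implementations disagree on the log-likelihood: {lnls}"
        )
    entries.sort(key=lambda e: e[1])
    return ResourceRanking(entries=tuple(entries), chosen=entries[0][0])


def auto_select(config: InstanceConfig) -> str:
    """Pick the implementation for a config, benchmarking on first use.

    Explicit implementations bypass benchmarking.  For ``auto``, the
    result is cached per problem dimensions for the process lifetime;
    if benchmarking fails for any reason the serial reference path is
    chosen.
    """
    if config.implementation != "auto":
        return config.implementation
    key = (
        config.tip_count,
        config.pattern_count,
        config.state_count,
        config.category_count,
        config.subset_count,
    )
    if key in _auto_cache:
        return _auto_cache[key]
    candidates = list(IMPLEMENTATIONS)
    if config.pattern_count * config.tip_count > _SERIAL_AUTO_LIMIT:
        candidates.remove("serial")
    try:
        ranking = benchmark_implementations(
            patterns=config.pattern_count,
            tips=config.tip_count,
            categories=config.category_count,
            subsets=config.subset_count,
            candidates=candidates,
            reps=5,
            seed=0,
        )
        chosen = ranking.chosen
    except Exception as exc:
        log.warning("auto-selection failed (%s); falling back to serial", exc)
        chosen = "serial"
    _auto_cache[key] = chosen
    return chosen


def run_synthetictest(
    pattern_counts=(100, 1000, 10000),
    otu_count: int = 128,
    *,
    variation_count: int = 10,
    replicate_count: int = 3,
    implementations=("vectorized", "threaded"),
    category_count: int = 4,
    alpha: float = 0.5,
    kappa: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate data and evaluate the likelihood across parameter variations.

    For every (pattern count, replicate): simulate an alignment on a
    random tree, then evaluate the base problem plus ``variation_count``
    variations (one NNI, jittered branch lengths, jittered renormalized
    category rates/weights, re-drawn pattern weights) under each
    implementation, timing each full evaluation.

    Returns a tidy DataFrame with columns pattern_count, replicate,
    variation (-1 = base), implementation, lnl, seconds, throughput
    (internal-node updates x patterns x states x categories per second
    — this harness's own metric).  Raises if implementations disagree
    bitwise on any log-likelihood.
    """
    rows = []
    for rep in range(replicate_count):
        scenarios = synthetic_benchmark_inputs(
            list(pattern_counts),
            otu_count=otu_count,
            seed=seed + 1000 * rep,
            variation_count=variation_count,
            alpha=alpha,
            category_count=category_count,
            kappa=kappa,
        )
        for scen in scenarios:
            cases = [
                {"tree": scen.tree, "rates": scen.rates, "pattern_weights": None}
            ] + scen.variations
            for var_idx, case in enumerate(cases, start=-1):
                pset = scen.patterns
                if case["pattern_weights"] is not None:
                    pset = _dc_replace(pset, weights=case["pattern_weights"].astype(np.int64))
                lnl_by_impl = {}
                for impl in implementations:
                    tl = TreeLikelihood(
                        pset,
                        case["tree"],
                        scen.model,
                        case["rates"],
                        implementation=impl,
                    )
                    t0 = time.perf_counter()
                    res = tl.compute()
                    seconds = time.perf_counter() - t0
                    lnl_by_impl[impl] = res.total_log_likelihood
                    n_updates = (otu_count - 1) * pset.pattern_count
                    throughput = (
                        n_updates * 4 * category_count / seconds if seconds > 0 else np.nan
                    )
                    rows.append(
                        {
                            "pattern_count": scen.pattern_count,
                            "replicate": rep,
                            "variation": var_idx,
                            "implementation": impl,
                            "lnl": res.total_log_likelihood,
                            "seconds": seconds,
                            "throughput": throughput,
                        }
                    )
                if len(set(lnl_by_impl.values())) > 1:
                    raise StateError(
                        f"implementations disagree at patterns={scen.pattern_count} "
                        f"rep={rep} variation={var_idx}: {lnl_by_impl}"
                    )
    return pd.DataFrame(rows)
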