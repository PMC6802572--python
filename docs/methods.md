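# Methods

This note records the models implemented, the numerical and design
choices made where the design was genuinely open, what the synthetic
data does and does not emulate, and the known limitations.

## Substitution models and transition probabilities

All named models (JC, HKY, GTR) are time-reversible generators
assembled as Q_ij = s_ij π_j (i ≠ j) from symmetric exchangeabilities
`s` and equilibrium frequencies π, with the diagonal closing each row
to zero. Arbitrary square rate matrices of any state count (e.g. 61
codon states) are accepted as-is provided rows sum to zero; detailed
balance is then *checked*, not assumed. Every generator is rescaled so
that −Σ_i π_i Q_ii = 1, i.e. one expected substitution per site per
unit branch length. This normalization is always applied: it makes
branch lengths comparable across models and subsets, and a per-subset
relative-rate multiplier (as used in partitioned analyses) is the
supported way to express rate differences.

Transition probabilities P(t) = exp(Qt) use the real eigendecomposition
of Q obtained from the symmetric similarity transform
B = diag(√π) Q diag(1/√π): for reversible Q, B is symmetric, eigh is
stable, and the eigensystem is exact up to round-off. Non-reversible
arbitrary matrices have no real decomposition in general; they carry a
flagged ("unavailable") eigensystem and all downstream code falls back
to scipy's scaling-and-squaring matrix exponential, with derivative
matrices formed as (rQ)P and (rQ)²P. Entries of P that round off
slightly negative (observed at the 1e−16 … 1e−12 scale) are clamped to
zero when read; this is harmless at that magnitude and prevents
log-domain failures downstream.

## Discretized gamma rate heterogeneity

Rate categories follow the discretized gamma model: C equal-weight
categories over the equal-probability intervals of a gamma density with
shape α and mean one. Category rates are the conditional **means** over
each interval, computed from the regularized incomplete gamma function
(for X ~ gamma(α, rate α), E[X; a<X<b] = I(α+1, bα) − I(α+1, aα)), then
renormalized so Σ w_c r_c = 1 holds exactly in floating point. Means
are the default because they preserve the unit mean rate exactly and
are the convention of the major client programs; interval medians are
available behind a flag (`use_median=True`) for comparison with
median-discretizing software.

## Pattern compression and tip encoding

Identical alignment columns within a partition subset are collapsed to
one weighted pattern, ordered by first occurrence (a deterministic
order that tests can rely on); subsets occupy contiguous, disjoint
ranges of the pattern axis, which makes per-subset evaluation a range
slice. Partition files use 1-based inclusive site ranges (the
user-facing convention) and are converted to 0-based half-open ranges
internally. The partition-config YAML syntax is this package's own
invention — client programs in this field each define their own.

Tips enter the engine as compact integer state codes when the sequence
contains only unambiguous characters or fully-missing symbols
(gap, `?`, `N` map to a sentinel contributing factor one); any sequence
with informative IUPAC ambiguity (R, Y, …) is automatically upgraded to
tip partials (0/1 indicator vectors), trading the fast lookup path for
exact ambiguity handling.

## The engine and its determinism contract

An instance owns all buffers (tip encodings, internal partials laid out
as pattern × category × state, eigensystems, transition matrices,
per-subset category rates/weights and frequencies, per-pattern log
scale factors) addressed by integer indices. The partials update is

    dest[p,c,i] = (Σ_j P1[c,i,j] child1[p,c,j]) (Σ_k P2[c,i,k] child2[p,c,k])

Three implementations exist: `serial` executes the reduction pattern by
pattern; `vectorized` processes the whole pattern range in one einsum;
`threaded` splits the range into contiguous blocks on a thread pool.
All three call the same einsum reduction (with optimization disabled),
whose per-element floating-point result is invariant to how the pattern
axis is blocked; consequently the three implementations — and any
thread count — produce bitwise-identical double-precision results, and
this is enforced by test. The automatic worker count is
min(⌈patterns/512⌉, cores), honoring a user limit.

Single precision is supported through the instance config, but all
stated tolerances are for double precision, the default.

## Scheduling: postorder, waves, re-rooting

A postorder operation list (children before parents, left subtree
first) is always valid. The wavefront plan groups internal nodes by
height above the tips — the unique grouping in which every operation's
inputs are complete when its wave starts — so wave k holds exactly the
nodes of height k+1 and the wave count equals the tree's internal
height. For partitioned instances, the same-level operations of all
subsets merge into one wave in subset-major order, with per-subset
transition-matrix blocks.

Because the likelihood of a reversible model is invariant to root
placement, the engine may re-root to reduce the wave count. The search
is exhaustive over the O(n) edges of the unrooted tree (each candidate
height evaluated in O(n) with memoized directed-edge heights), rooting
at the midpoint of the winning edge and breaking ties toward the lowest
edge index. Exhaustive search was chosen over a heuristic because n is
small at library scale and optimality is directly testable (a balanced
2^k-tip tree stays at k waves; an 8-tip ladder drops from 7 to the
provable minimum of 4).

## Rescaling

Only two policies exist: `none` and `always`. With `always`, after each
update the destination partials of every pattern are divided by their
maximum across states and categories (when positive) and the log factor
accumulates in the operation's per-pattern scale buffer; the root
reduction adds the accumulated log factors back, so the procedure is
exact up to round-off. An all-zero partial column is left in place and
surfaces at the root as a −infinity total with the offending patterns
reported, rather than as an exception. Dynamic/on-demand rescaling
policies found in some engines are deliberately not implemented: the
simple pair is verifiable (neutrality on shallow trees to 1e−8, rescue
of ≥500-tip long-branch trees from underflow) and the cost is paid only
when requested.

## Branch-length derivatives

The edge factorization L_p = Σ_c w_c Σ_i π_i parent[p,c,i]
(Σ_j P[c,i,j] child[p,c,j]) uses *outside* partials for the parent side
(the tree minus the child subtree, built by propagating the sibling
subtree through its own branch), and replaces P by dP/dt and d²P/dt²
for the derivative sums, combined per pattern as d1 = Σ w_p L′/L and
d2 = Σ w_p (L″/L − (L′/L)²). The driver exposes derivatives for
root-adjacent edges; any edge can be queried by first re-rooting on it,
which is exact under reversibility. Per-subset relative rates enter by
the chain rule (ρ for d1, ρ² for d2). This factorization was chosen for
direct testability against central finite differences; first
derivatives are verified against differences of the log-likelihood and
second derivatives against differences of the analytic first derivative
(differencing the smooth analytic d1 avoids the precision floor that
second differences of the log-likelihood itself hit at step h ≈ 1e−6).

## Synthetic data

The simulator draws topologies uniformly over labeled unrooted
topologies by sequential random edge addition, then roots on a
uniformly chosen edge; branch lengths are i.i.d. exponential
(default mean 0.1 substitutions/site). Sequences evolve site by site:
category by weight, root state from π, then child states sampled from
the parent's row of P(t r_c) down the tree. Every stochastic function
takes an explicit seed and is byte-reproducible.

The scaling harness (`synthetictest`) simulates data for a 128-OTU tree
under HKY with 4-category gamma rates, and evaluates the base problem
plus 10 parameter variations — one random NNI, multiplicative branch
jitter U(0.8, 1.25), jittered-then-renormalized category rates and
weights, re-drawn integer pattern weights — across replicates and
pattern counts (default 10², 10³, 10⁴), timing each evaluation and
requiring bitwise cross-implementation agreement. Pattern counts of
10² … 10⁴ with three replicates keep a full run around a minute on one
core while spanning two orders of magnitude of problem size; the
reported throughput (internal-node updates × patterns × states ×
categories per second) is this package's own metric for comparing
kernels, not an externally defined one.

What the simulator does *not* emulate: indels and alignment error
(sequences are generated pre-aligned), among-site model heterogeneity
beyond the gamma mixture, non-stationarity, and selection-driven site
dependence. Passing tests therefore demonstrate correctness of the
likelihood machinery under its own model assumptions, not robustness of
inference on real data.

## Automatic implementation selection

`benchmark_implementations` builds a synthetic problem of exactly the
requested dimensions, runs one discarded warm-up evaluation per
candidate plus at least three timed repetitions of the identical
traversal + root-likelihood workload, and ranks candidates by median
wall time. Candidates must agree bitwise on the log-likelihood before a
ranking is returned (correctness precedes speed); candidates that fail
to run are excluded with a logged notice. `auto` selection caches the
choice per problem dimensions for the process lifetime and falls back
to the serial reference if benchmarking fails. The pure-Python serial
path is excluded from *automatic* benchmarking above 5000
patterns × tips — it is never competitive there — but remains available
explicitly everywhere. The benchmarking protocol (median, ≥3 reps, one
warm-up, problem-specific workload) is this package's own.

## Numerical choices and degenerate inputs

- Zero-length branches produce exact identity matrices; t = 0 partials
  updates are exact lookups.
- Zero site likelihood → −infinity with per-pattern underflow report.
- Frequencies must be a simplex to 1e−8 and are renormalized exactly;
  zero frequencies are rejected at eigendecomposition (the symmetric
  transform divides by √π).
- Unrooted (trifurcating) Newick input is rooted deterministically on
  the first-listed child edge at its midpoint; missing branch lengths
  default to zero with a warning.
- Ties in within-wave operation order break by node id, then subset,
  making any parallel execution's output reproducible.

## Known limitations

- CPU only; the wave abstraction is the portable stand-in for
  device-stream scheduling, and multi-device evaluation is emulated
  only as multiple instances driven from one process.
- No branch-length optimization, proposal mechanisms, or MCMC — the
  engine computes likelihoods and derivatives; optimization belongs to
  the caller.
- Nucleotide alphabet for I/O (arbitrary state counts are supported at
  the engine/model level, but the alignment parser is IUPAC-nucleotide).
- No NEXUS input, no codon-position partition shorthand, no empirical
  amino-acid matrices shipped as data.
- The serial kernel is a reference implementation and is orders of
  magnitude slower than the vectorized path at large pattern counts.
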