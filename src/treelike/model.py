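"""Reversible substitution models and transition probabilities.

A substitution model is a continuous-time Markov chain on the character
states with instantaneous rate matrix ``Q``.  For the reversible models
built here, ``Q_ij = s_ij * pi_j`` for ``i != j`` where ``s`` is a
symmetric matrix of exchangeabilities and ``pi`` the equilibrium (state)
frequencies.  ``Q`` is always rescaled so that the expected number of
substitutions per unit time at equilibrium is one,
``-sum_i pi_i Q_ii = 1``, which makes branch lengths comparable across
models (expected substitutions per site).

Transition probabilities over a branch of length ``t`` are
``P(t) = exp(Q t)``, computed through the eigendecomposition of ``Q``
(real for reversible models via a symmetric similarity transform), or by
scipy's matrix exponential for non-reversible arbitrary matrices.

Among-site rate heterogeneity uses the discretized gamma model: ``C``
equal-weight categories whose relative rates are the means of a
mean-one gamma density over its equal-probability intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .errors import ValidationError

__all__ = [
    "SubstitutionModel",
    "EigenSystem",
    "RateCategories",
    "TransitionMatrixSet",
    "build_model",
    "eigendecompose",
    "discretize_gamma",
    "compute_transition_matrices",
    "NUCLEOTIDES",
]

NUCLEOTIDES = "ACGT"

# index pairs of the six GTR exchangeabilities, in conventional order
_GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class SubstitutionModel:
    """A normalized reversible (or arbitrary) rate matrix with its frequencies.

    Attributes
    ----------
    state_count : int
        Number of character states S (4 for nucleotides, 61 for codons, ...).
    frequencies : ndarray, shape (S,)
        Equilibrium state frequencies pi; nonnegative, summing to one.
    rate_matrix : ndarray, shape (S, S)
        Normalized generator Q: rows sum to zero, -sum(pi * diag(Q)) == 1.
    name : str
        Model family ("JC", "HKY", "GTR", "ARBITRARY").
    reversible : bool
        Whether Q satisfies detailed balance w.r.t. ``frequencies``.
    """

    state_count: int
    frequencies: np.ndarray
    rate_matrix: np.ndarray
    name: str = "ARBITRARY"
    reversible: bool = True


@dataclass(frozen=True)
class EigenSystem:
    """Eigendecomposition Q = E diag(values) E^-1 of a rate matrix.

    For non-reversible matrices no real decomposition is guaranteed; such
    systems carry ``available=False`` plus the raw Q, and downstream code
    falls back to the matrix exponential.
    """

    values: np.ndarray
    vectors: np.ndarray
    inverse_vectors: np.ndarray
    available: bool = True
    rate_matrix: np.ndarray | None = None

    @property
    def state_count(self) -> int:
        return self.rate_matrix.shape[0] if self.rate_matrix is not None else len(self.values)


@dataclass(frozen=True)
class RateCategories:
    """Discrete relative-rate categories with weights summing to one.

    The mean rate ``sum(weights * rates)`` is one, so category rates act as
    multipliers on the branch length without changing its expectation.
    """

    rates: np.ndarray
    weights: np.ndarray
    shape: float | None = None

    @property
    def category_count(self) -> int:
        return len(self.rates)


@dataclass
class TransitionMatrixSet:
    """Per-(edge, category) transition probability matrices.

    ``matrices[e, c]`` is the row-stochastic ``P(t_e * r_c)``.  When
    derivatives were requested, ``d1`` and ``d2`` hold dP/dt and d2P/dt2
    (with respect to the *edge length* t, so the category rate enters as
    the chain-rule factor r_c).
    """

    matrices: np.ndarray
    d1: np.ndarray | None = None
    d2: np.ndarray | None = None
    edge_lengths: np.ndarray = field(default_factory=lambda: np.empty(0))

    def probabilities(self) -> np.ndarray:
        """Matrices with tiny negative round-off clamped to zero."""
        return np.maximum(self.matrices, 0.0)


def _validate_frequencies(freqs, state_count: int) -> np.ndarray:
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (state_count,):
        raise ValidationError(
            f"expected {state_count} frequencies, got shape {pi.shape}"
        )
    if np.any(pi < 0):
        raise ValidationError("negative equilibrium frequency")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValidationError(f"frequencies sum to {pi.sum():.10f}, not 1")
    return pi / pi.sum()


def _assemble_reversible(s: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Q_ij = s_ij pi_j off-diagonal; diagonal closes rows; normalized."""
    q = s * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return _normalize(q, pi)


def _normalize(q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    mu = -float(pi @ np.diag(q))
    if mu <= 0:
        raise ValidationError("rate matrix has nonpositive total rate")
    return q / mu


def build_model(
    name: str,
    frequencies,
    *,
    kappa: float | None = None,
    exchangeabilities=None,
    rate_matrix=None,
) -> SubstitutionModel:
    """Construct a normalized substitution model.

    Parameters
    ----------
    name : {"JC", "HKY", "GTR", "ARBITRARY"}
        Model family (case-insensitive).  HKY takes ``kappa`` (the
        transition/transversion rate ratio), GTR takes six
        ``exchangeabilities`` in order (AC, AG, AT, CG, CT, GT),
        ARBITRARY takes a full S x S ``rate_matrix`` whose rows sum to
        zero (any S, e.g. 61 for codon models).
    frequencies : array-like
        Equilibrium frequencies; a valid probability simplex.

    Returns
    -------
    SubstitutionModel
        With Q normalized to one expected substitution per unit time.
    """
    key = name.upper()
    if key == "ARBITRARY":
        q = np.array(rate_matrix, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValidationError("rate_matrix must be square")
        s = q.shape[0]
        pi = _validate_frequencies(frequencies, s)
        if np.any(np.abs(q.sum(axis=1)) > 1e-8):
            raise ValidationError("rate_matrix rows must sum to zero")
        if np.any(q - np.diag(np.diag(q)) < 0):
            raise ValidationError("off-diagonal rates must be nonnegative")
        q = _normalize(q, pi)
        flux = pi[:, None] * q
        reversible = bool(np.allclose(flux, flux.T, atol=1e-10))
        return SubstitutionModel(s, pi, q, name="ARBITRARY", reversible=reversible)

    # named nucleotide models
    pi = _validate_frequencies(frequencies, 4)
    s = np.zeros((4, 4))
    if key == "JC":
        s[:] = 1.0
    elif key == "HKY":
        if kappa is None:
            raise ValidationError("HKY requires kappa")
        if kappa < 0:
            raise ValidationError("kappa must be nonnegative")
        s[:] = 1.0
        s[0, 2] = s[2, 0] = kappa  # A<->G
        s[1, 3] = s[3, 1] = kappa  # C<->T
    elif key == "GTR":
        if exchangeabilities is None:
            raise ValidationError("GTR requires six exchangeabilities")
        ex = np.asarray(exchangeabilities, dtype=float)
        if ex.shape != (6,):
            raise ValidationError("GTR takes exactly 6 exchangeabilities")
        if np.any(ex < 0):
            raise ValidationError("negative exchangeability")
        for (i, j), v in zip(_GTR_PAIRS, ex):
            s[i, j] = s[j, i] = v
    else:
        raise ValidationError(f"unknown model name {name!r}")
    np.fill_diagonal(s, 0.0)
    q = _assemble_reversible(s, pi)
    return SubstitutionModel(4, pi, q, name=key, reversible=True)


def eigendecompose(model: SubstitutionModel) -> EigenSystem:
    """Real eigendecomposition of a reversible Q.

    Uses the symmetric similarity transform
    ``B = diag(sqrt(pi)) Q diag(1/sqrt(pi))``: for reversible Q, B is
    symmetric, so its eigensystem is real and the eigenvectors of Q are
    recovered as ``E = diag(1/sqrt(pi)) V``, ``E^-1 = V^T diag(sqrt(pi))``.

    Non-reversible models cannot use this route; they return a flagged
    system (``available=False``) that triggers the matrix-exponential
    fallback in :func:`compute_transition_matrices`.
    """
    pi = model.frequencies
    if np.any(pi <= 0):
        raise ValidationError("eigendecomposition requires strictly positive frequencies")
    if not model.reversible:
        return EigenSystem(
            values=np.empty(0),
            vectors=np.empty((0, 0)),
            inverse_vectors=np.empty((0, 0)),
            available=False,
            rate_matrix=model.rate_matrix,
        )
    sqrt_pi = np.sqrt(pi)
    b = (sqrt_pi[:, None] * model.rate_matrix) / sqrt_pi[None, :]
    b = 0.5 * (b + b.T)  # symmetrize round-off
    lam, v = np.linalg.eigh(b)
    vectors = v / sqrt_pi[:, None]
    inverse = v.T * sqrt_pi[None, :]
    return EigenSystem(lam, vectors, inverse, available=True, rate_matrix=model.rate_matrix)


def discretize_gamma(
    alpha: float, category_count: int, *, use_median: bool = False
) -> RateCategories:
    """Discretize a mean-one gamma distribution into equal-weight categories.

    Category ``c`` covers the gamma(alpha, rate=alpha) probability interval
    ``(c/C, (c+1)/C)``; its rate is the conditional mean of the density over
    that interval (computed from the regularized incomplete gamma function),
    or the interval median when ``use_median`` is set.  Rates are then
    renormalized so the weighted mean is exactly one.
    """
    if alpha <= 0:
        raise ValidationError("gamma shape alpha must be positive")
    if category_count < 1:
        raise ValidationError("need at least one rate category")
    c = int(category_count)
    if c == 1:
        return RateCategories(np.ones(1), np.ones(1), shape=float(alpha))
    probs = np.arange(1, c) / c
    cuts = _gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    if use_median:
        mid = (np.arange(c) + 0.5) / c
        rates = _gamma_dist.ppf(mid, a=alpha, scale=1.0 / alpha)
    else:
        # E[X | a < X < b] * P(a < X < b) = I(alpha+1, b*alpha) - I(alpha+1, a*alpha)
        # for X ~ gamma(alpha, rate alpha) with mean one.
        upper = np.concatenate([cuts * alpha, [np.inf]])
        lower = np.concatenate([[0.0], cuts * alpha])
        mass = gammainc(alpha + 1.0, upper) - gammainc(alpha + 1.0, lower)
        rates = mass * c
    weights = np.full(c, 1.0 / c)
    rates = rates / (weights @ rates)
    return RateCategories(rates, weights, shape=float(alpha))


def compute_transition_matrices(
    eigen: EigenSystem,
    rates: RateCategories,
    edge_lengths,
    *,
    want_derivatives: bool = False,
) -> TransitionMatrixSet:
    """P(t, c) = exp(Q * r_c * t) for every edge and rate category.

    On the eigen path, ``P = E diag(exp(lambda r_c t)) E^-1`` and the
    branch-length derivatives come from multiplying the exponentials by
    ``lambda r_c`` (d1) and ``(lambda r_c)^2`` (d2).  Flagged
    (non-reversible) eigensystems use scipy's scaling-and-squaring
    matrix exponential, with derivatives ``Q r P`` and ``Q^2 r^2 P``.

    Returns matrices of shape ``(n_edges, n_categories, S, S)``.
    """
    t = np.atleast_1d(np.asarray(edge_lengths, dtype=float))
    if np.any(t < 0):
        raise ValidationError("negative branch length")
    r = rates.rates
    n_edges, n_cat = len(t), len(r)

    if not eigen.available:
        q = eigen.rate_matrix
        s = q.shape[0]
        p = np.empty((n_edges, n_cat, s, s))
        d1 = np.empty_like(p) if want_derivatives else None
        d2 = np.empty_like(p) if want_derivatives else None
        for e in range(n_edges):
            for c in range(n_cat):
                p[e, c] = expm(q * (r[c] * t[e]))
                if want_derivatives:
                    qr = q * r[c]
                    d1[e, c] = qr @ p[e, c]
                    d2[e, c] = qr @ qr @ p[e, c]
        return TransitionMatrixSet(p, d1, d2, edge_lengths=t)

    lam, ev, iv = eigen.values, eigen.vectors, eigen.inverse_vectors
    # exponent array (edge, cat, state)
    x = lam[None, None, :] * (t[:, None, None] * r[None, :, None])
    ex = np.exp(x)
    p = np.einsum("ik,eck,kj->ecij", ev, ex, iv, optimize=True)
    d1 = d2 = None
    if want_derivatives:
        lr = lam[None, None, :] * r[None, :, None]  # broadcast (1, cat, state)
        d1 = np.einsum("ik,eck,kj->ecij", ev, lr * ex, iv, optimize=True)
        d2 = np.einsum("ik,eck,kj->ecij", ev, lr * lr * ex, iv, optimize=True)
    return TransitionMatrixSet(p, d1, d2, edge_lengths=t)
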