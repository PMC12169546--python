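"""Exact-enumeration checks of the variational theory behind the sampler.

On shells small enough to enumerate, the ideal sampling target — the
Boltzmann distribution ``p(x) = exp(f(x)/T) / Z`` over the k-mutation
shell — can be computed exactly, along with the product distribution
``q*(x) = prod_{m in x} q*_m`` that best approximates it in KL
divergence,

    ``q*_m = (1 / (k Z)) * sum_{x in N_m} exp(f(x)/T)``,

where ``N_m`` is the set of shell variants containing mutation ``m``
(equivalently ``q*_m = P_p(m in x) / k``), and the cheaper mean-field
product ``q~_m proportional to exp(f_m/T)`` with ``f_m`` the plain average
score over ``N_m``.  This module verifies, by brute force:

* that ``q*`` minimizes KL(p || q) over product distributions;
* the entropy bound ``k H(q*) >= H(p)`` (with equality at k = 1);
* the closed forms for the beta-derivatives of both KL divergences
  against central finite differences, and their negative low-temperature
  limit ``beta (1 - k) sigma_f^2`` for the optimal product.

Conventions.  KL(p || q) is evaluated with the product form
``q(x) = prod_{m in x} q_m`` taken as-is over the site-constrained shell
(its total mass is <= 1/k!, not 1); this is the convention in which the
optimality of q*, the entropy bound — which equals KL(p || q*) — and the
derivative identities are exact.  ``induced_probabilities`` renormalizes
when a genuine distribution over the shell is needed.  All entropies and
divergences use natural logarithms.

Enumeration respects the distinct-site constraint, so the per-mutation
neighborhood count reported in :func:`mean_field_product` is the actual
``C(L-1, k-1) * 19**(k-1)`` rather than the nominal ``C(M-1, k-1)`` that
ignores site exclusivity; both are returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .ablations import DEFAULT_ENUMERATION_CAP
from .oracles import FitnessOracle
from .sequence_space import (
    ReferenceSequence,
    VariantSpec,
    enumerate_shell,
    shell_index_matrix,
    shell_size,
)

__all__ = [
    "ExactShellDistribution",
    "ProductDistribution",
    "exact_boltzmann",
    "exact_optimal_product",
    "mean_field_product",
    "kl_divergence",
    "induced_probabilities",
    "check_entropy_bound",
    "kl_beta_derivative_check",
    "low_temperature_limit",
    "random_product_distribution",
]


@dataclass
class ExactShellDistribution:
    """The Boltzmann distribution over an enumerated exact-k shell."""

    ref: ReferenceSequence
    k: int
    T: float
    variants: list[VariantSpec] | None   # None when enumerated index-only
    scores: np.ndarray          # (n,)
    index_matrix: np.ndarray    # (n, k) flat mutation indices per variant
    log_p: np.ndarray           # (n,)
    log_Z: float

    @property
    def p(self) -> np.ndarray:
        return np.exp(self.log_p)

    @property
    def n(self) -> int:
        return self.index_matrix.shape[0]

    def variant_at(self, i: int) -> VariantSpec:
        if self.variants is not None:
            return self.variants[i]
        return VariantSpec.from_indices(self.ref, self.index_matrix[i])

    def entropy(self) -> float:
        return float(-(self.p * self.log_p).sum())

    def mean_score(self) -> float:
        return float((self.p * self.scores).sum())

    def score_variance(self) -> float:
        mu = self.mean_score()
        return float((self.p * (self.scores - mu) ** 2).sum())


@dataclass
class ProductDistribution:
    """A distribution q_m over mutations, inducing q(x) = prod_{m in x} q_m."""

    q: np.ndarray
    k: int

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if np.any(q < 0):
            raise ValueError("q_m must be >= 0")
        total = q.sum()
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"q_m must sum to 1; got {total}")
        self.q = q

    def entropy(self) -> float:
        q = self.q[self.q > 0]
        return float(-(q * np.log(q)).sum())

    def log_product(self, index_matrix: np.ndarray) -> np.ndarray:
        """log prod_{m in x} q_m for each row of mutation indices."""
        with np.errstate(divide="ignore"):
            logq = np.log(self.q)
        return logq[index_matrix].sum(axis=1)


def _enumerate_scored_shell(
    oracle: FitnessOracle, ref: ReferenceSequence, k: int, cap: int
) -> tuple[list[VariantSpec] | None, np.ndarray, np.ndarray]:
    size = shell_size(ref.L, k)
    if size > cap:
        raise ValueError(
            f"shell S_{k} for L={ref.L} holds {size} variants, above the cap of {cap}"
        )
    if hasattr(oracle, "score_indices"):
        # fast path for synthetic landscapes: no VariantSpec materialization
        index_matrix = shell_index_matrix(ref, k)
        scores = np.asarray(oracle.score_indices(index_matrix), dtype=float)
        return None, scores, index_matrix
    variants = list(enumerate_shell(ref, k))
    scores = np.asarray(oracle.score_batch(variants), dtype=float)
    index_matrix = np.array([v.indices(ref) for v in variants], dtype=np.intp)
    return variants, scores, index_matrix


def exact_boltzmann(
    oracle: FitnessOracle,
    ref: ReferenceSequence,
    k: int,
    T: float,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> ExactShellDistribution:
    """Enumerate S_k and compute p(x) = exp(f(x)/T)/Z exactly."""
    if T <= 0:
        raise ValueError("T must be > 0")
    variants, scores, index_matrix = _enumerate_scored_shell(oracle, ref, k, cap)
    return _boltzmann_from_scores(ref, k, T, variants, scores, index_matrix)


def _boltzmann_from_scores(ref, k, T, variants, scores, index_matrix) -> ExactShellDistribution:
    logits = scores / T
    m = logits.max()
    log_Z = m + np.log(np.exp(logits - m).sum())
    return ExactShellDistribution(
        ref=ref,
        k=k,
        T=T,
        variants=variants,
        scores=scores,
        index_matrix=index_matrix,
        log_p=logits - log_Z,
        log_Z=float(log_Z),
    )


def exact_optimal_product(p: ExactShellDistribution) -> ProductDistribution:
    """The KL-optimal product distribution q* by exact summation over N_m.

    Because sum_{x in N_m} exp(f(x)/T) / Z = P_p(mutation m in x), the
    closed form reduces to q*_m = P_p(m in x) / k, which sums to one since
    every shell variant contains exactly k mutations.
    """
    M = p.ref.n_mutations
    w = np.zeros(M)
    np.add.at(w, p.index_matrix, p.p[:, None])
    return ProductDistribution(q=w / p.k, k=p.k)


class MeanFieldResult(NamedTuple):
    product: ProductDistribution
    f_m: np.ndarray
    n_k_enumerated: int      # actual |N_m| under the distinct-site shell
    n_k_nominal: int         # C(M-1, k-1), ignoring site exclusivity


def mean_field_product(
    oracle: FitnessOracle,
    ref: ReferenceSequence,
    k: int,
    T: float,
    cap: int = DEFAULT_ENUMERATION_CAP,
    _shell: ExactShellDistribution | None = None,
) -> MeanFieldResult:
    """The mean-field product q~_m = exp(f_m/T)/Q~ with f_m averaged over N_m."""
    if _shell is not None:
        scores, index_matrix = _shell.scores, _shell.index_matrix
    else:
        _, scores, index_matrix = _enumerate_scored_shell(oracle, ref, k, cap)
    M = ref.n_mutations
    sums = np.zeros(M)
    counts = np.zeros(M)
    np.add.at(sums, index_matrix, scores[:, None])
    np.add.at(counts, index_matrix, 1.0)
    f_m = sums / counts
    z = f_m / T
    q = np.exp(z - z.max())
    q /= q.sum()
    return MeanFieldResult(
        product=ProductDistribution(q=q, k=k),
        f_m=f_m,
        n_k_enumerated=int(counts[0]),
        n_k_nominal=math.comb(M - 1, k - 1),
    )


def kl_divergence(p: ExactShellDistribution, q: ProductDistribution) -> float:
    """KL(p || q) with q in the product convention (see module docstring).

    Non-negative for any product distribution, since the product form's
    total mass over the shell never exceeds one; zero iff q(x) reproduces
    p(x) exactly.
    """
    used = np.unique(p.index_matrix)
    if np.any(q.q[used] <= 0):
        bad = used[q.q[used] <= 0][0]
        raise ValueError(
            f"support violation: q_m = 0 for mutation index {int(bad)} "
            "which appears in the shell"
        )
    return float((p.p * (p.log_p - q.log_product(p.index_matrix))).sum())


def induced_probabilities(p: ExactShellDistribution, q: ProductDistribution) -> np.ndarray:
    """The product form renormalized into a genuine distribution over the shell."""
    logq = q.log_product(p.index_matrix)
    m = logq.max()
    w = np.exp(logq - m)
    return w / w.sum()


class EntropyBoundResult(NamedTuple):
    k_H_qstar: float
    H_p: float
    holds: bool


def check_entropy_bound(
    p: ExactShellDistribution, q_star: ProductDistribution, tol: float = 1e-9
) -> EntropyBoundResult:
    """The bound k H(q*) >= H(p); equals KL(p || q*) >= 0 in the product
    convention, hence equality exactly at k = 1."""
    k_H = p.k * q_star.entropy()
    H_p = p.entropy()
    return EntropyBoundResult(k_H_qstar=k_H, H_p=H_p, holds=bool(k_H >= H_p - tol))


def low_temperature_limit(beta: float, sigma_f2: float, k: int) -> float:
    """Low-T limit of the beta-derivative of KL(p || q*): beta (1 - k) sigma_f^2."""
    return beta * (1 - k) * sigma_f2


class DerivativeCheck(NamedTuple):
    numeric: float
    closed_form: float
    relative_error: float


def _conditional_means(p: ExactShellDistribution) -> tuple[np.ndarray, np.ndarray]:
    """(q*_m, E_p[f | m in x]) by exact summation."""
    M = p.ref.n_mutations
    den = np.zeros(M)
    num = np.zeros(M)
    np.add.at(den, p.index_matrix, p.p[:, None])
    np.add.at(num, p.index_matrix, (p.p * p.scores)[:, None])
    qs = den / p.k
    with np.errstate(invalid="ignore"):
        cond = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return qs, cond


def _cov(weights: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ma = float((weights * a).sum())
    mb = float((weights * b).sum())
    return float((weights * (a - ma) * (b - mb)).sum())


def kl_beta_derivative_check(
    oracle: FitnessOracle,
    ref: ReferenceSequence,
    k: int,
    T: float,
    which: Literal["q_star", "mean_field"] = "q_star",
    h_rel: float = 1e-4,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> DerivativeCheck:
    """Compare the closed-form beta-derivative of the exact KL with a
    central finite difference (step h = h_rel * beta).

    For the optimal product:
        d/d(beta) KL(p || q*) = beta sigma_f^2 - k Cov_{q*}(E[f|m], log q*_m)
    For the mean field:
        d/d(beta) KL(p || q~) = beta (sigma_f^2 - k Cov_{q*}(E[f|m], f_m))
                                 - k (<f_m>_{q*} - <f_m>_{q~})
    """
    if which not in ("q_star", "mean_field"):
        raise ValueError(f"which must be 'q_star' or 'mean_field'; got {which!r}")
    variants, scores, index_matrix = _enumerate_scored_shell(oracle, ref, k, cap)
    beta = 1.0 / T

    def kl_at(b: float) -> float:
        shell = _boltzmann_from_scores(ref, k, 1.0 / b, variants, scores, index_matrix)
        if which == "q_star":
            q = exact_optimal_product(shell)
        else:
            q = mean_field_product(oracle, ref, k, 1.0 / b, _shell=shell).product
        return kl_divergence(shell, q)

    h = h_rel * beta
    numeric = (kl_at(beta + h) - kl_at(beta - h)) / (2 * h)

    shell = _boltzmann_from_scores(ref, k, T, variants, scores, index_matrix)
    sigma_f2 = shell.score_variance()
    qs, cond_mean = _conditional_means(shell)
    if which == "q_star":
        with np.errstate(divide="ignore"):
            log_qs = np.where(qs > 0, np.log(np.maximum(qs, 1e-300)), 0.0)
        closed = beta * sigma_f2 - k * _cov(qs, cond_mean, log_qs)
    else:
        mf = mean_field_product(oracle, ref, k, T, _shell=shell)
        f_m = mf.f_m
        mean_qstar = float((qs * f_m).sum())
        mean_qtilde = float((mf.product.q * f_m).sum())
        closed = beta * (sigma_f2 - k * _cov(qs, cond_mean, f_m)) - k * (
            mean_qstar - mean_qtilde
        )
    for name, val in (("numeric", numeric), ("closed_form", closed)):
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite {name} term in derivative check")
    rel = abs(numeric - closed) / max(abs(closed), abs(numeric), 1e-12)
    return DerivativeCheck(numeric=float(numeric), closed_form=float(closed), relative_error=float(rel))


def random_product_distribution(rng: np.random.Generator, M: int, k: int) -> ProductDistribution:
    """A random product distribution (flat Dirichlet over mutations)."""
    return ProductDistribution(q=rng.dirichlet(np.ones(M)), k=k)
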