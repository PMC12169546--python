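"""Fitness oracles: the batch scoring contract and seeded synthetic landscapes.

An oracle maps a batch of variants to real-valued fitness scores.  The
contract is batch-first (list in, array out, order-aligned) to mirror how
GPU-batched sequence models are called; external models (protein language
models, supervised fitness predictors) plug in by implementing
:class:`FitnessOracle`.

Two synthetic landscape families with known structure make every
downstream component testable without external models:

* :class:`AdditiveLandscape` — ``f(x) = f(ref) + sum_m a_m`` with i.i.d.
  normal per-mutation effects.  Its global optimum over the k-mutation
  shell has a closed form (:func:`argmax_additive`).
* :class:`EpistaticLandscape` — adds sparse symmetric pairwise couplings
  ``J[m, m']`` so multi-mutant fitness deviates from the sum of single
  effects, emulating the ruggedness real fitness models exhibit.

Couplings are realized by counter-based hashing of the (seed, pair) key,
so scoring is O(k^2) per variant with exact reproducibility and no M x M
storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.special import ndtri

from .sequence_space import ReferenceSequence, VariantSpec

__all__ = [
    "FitnessOracle",
    "AdditiveLandscape",
    "EpistaticLandscape",
    "CachedOracle",
    "make_additive_landscape",
    "make_epistatic_landscape",
    "argmax_additive",
    "landscape_to_json",
    "landscape_from_json",
]


@runtime_checkable
class FitnessOracle(Protocol):
    """Batch scoring contract: ``score_batch`` returns one score per variant,
    order-aligned with its input.  ``deterministic`` oracles return identical
    scores for identical variants across calls."""

    name: str
    deterministic: bool

    def score_batch(self, variants: Sequence[VariantSpec]) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# counter-based hashing for reproducible sparse couplings
# ---------------------------------------------------------------------------

_U64 = np.uint64


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: a high-quality 64-bit mix, vectorized.

    Wrapping uint64 arithmetic is intentional."""
    with np.errstate(over="ignore"):
        x = (x + _U64(0x9E3779B97F4A7C15)).astype(_U64)
        x = ((x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)).astype(_U64)
        x = ((x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)).astype(_U64)
        return x ^ (x >> _U64(31))


def _hash_u01(key: np.ndarray, stream: int) -> np.ndarray:
    """Deterministic uniforms in (0, 1) from integer keys, one per stream."""
    h = _splitmix64(key.astype(_U64) ^ _splitmix64(np.asarray(stream, dtype=_U64)))
    # 53-bit mantissa; +0.5 keeps the value strictly inside (0, 1)
    return ((h >> _U64(11)).astype(np.float64) + 0.5) * 2.0**-53


@dataclass
class AdditiveLandscape:
    """Additive fitness: ``f(x) = ref_score + sum of per-mutation effects``."""

    ref: ReferenceSequence
    effects: np.ndarray  # shape (M,)
    ref_score: float = 0.0
    seed: int = 0
    name: str = "additive"
    deterministic: bool = True
    params: dict = field(default_factory=dict)

    def score_batch(self, variants: Sequence[VariantSpec]) -> np.ndarray:
        out = np.empty(len(variants), dtype=np.float64)
        for i, v in enumerate(variants):
            idx = np.fromiter(v.indices(self.ref), dtype=np.intp, count=v.k)
            out[i] = self.ref_score + self.effects[idx].sum()
        return out

    def score_indices(self, index_matrix: np.ndarray) -> np.ndarray:
        """Vectorized scoring of an (n, k) matrix of flat mutation indices."""
        return self.ref_score + self.effects[index_matrix].sum(axis=1)


@dataclass
class EpistaticLandscape(AdditiveLandscape):
    """Additive effects plus sparse symmetric pairwise couplings.

    A pair (m, m') carries a nonzero coupling with probability ``density``;
    nonzero values are N(0, coupling_sd^2).  Both the presence indicator and
    the value are pure functions of (seed, m, m'), so the coupling matrix is
    never materialized.
    """

    coupling_sd: float = 0.5
    density: float = 0.02
    name: str = "epistatic"

    def coupling(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """J[i, j] for arrays of mutation indices; symmetric, zero diagonal."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        M = self.ref.n_mutations
        key = (lo.astype(_U64) * _U64(M) + hi.astype(_U64)) ^ _splitmix64(
            np.asarray(self.seed, dtype=_U64)
        )
        present = _hash_u01(key, stream=1) < self.density
        values = ndtri(_hash_u01(key, stream=2)) * self.coupling_sd
        return np.where((lo != hi) & present, values, 0.0)

    def score_batch(self, variants: Sequence[VariantSpec]) -> np.ndarray:
        out = np.empty(len(variants), dtype=np.float64)
        for i, v in enumerate(variants):
            idx = np.fromiter(v.indices(self.ref), dtype=np.intp, count=v.k)
            score = self.ref_score + self.effects[idx].sum()
            if v.k >= 2:
                a, b = np.triu_indices(v.k, 1)
                score += self.coupling(idx[a], idx[b]).sum()
            out[i] = score
        return out

    def score_indices(self, index_matrix: np.ndarray) -> np.ndarray:
        out = super().score_indices(index_matrix)
        k = index_matrix.shape[1]
        if k >= 2:
            a, b = np.triu_indices(k, 1)
            for i, j in zip(a, b):
                out += self.coupling(index_matrix[:, i], index_matrix[:, j])
        return out


def make_additive_landscape(
    ref: ReferenceSequence,
    seed: int,
    effect_mean: float = -0.5,
    effect_sd: float = 1.0,
    ref_score: float = 0.0,
) -> AdditiveLandscape:
    """Seeded additive landscape with i.i.d. normal per-mutation effects.

    Defaults emulate deep-mutational-scanning statistics: most substitutions
    are deleterious (negative mean), a minority beneficial.
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    rng = np.random.default_rng(seed)
    effects = rng.normal(effect_mean, effect_sd, size=ref.n_mutations)
    return AdditiveLandscape(
        ref=ref,
        effects=effects,
        ref_score=ref_score,
        seed=seed,
        params={"effect_mean": effect_mean, "effect_sd": effect_sd},
    )


def make_epistatic_landscape(
    ref: ReferenceSequence,
    seed: int,
    effect_mean: float = -0.5,
    effect_sd: float = 1.0,
    coupling_sd: float = 0.5,
    density: float = 0.02,
    ref_score: float = 0.0,
) -> EpistaticLandscape:
    """Seeded epistatic landscape: additive effects + sparse pairwise couplings."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    if effect_sd < 0 or coupling_sd < 0:
        raise ValueError("scales must be >= 0")
    rng = np.random.default_rng(seed)
    effects = rng.normal(effect_mean, effect_sd, size=ref.n_mutations)
    return EpistaticLandscape(
        ref=ref,
        effects=effects,
        ref_score=ref_score,
        seed=seed,
        coupling_sd=coupling_sd,
        density=density,
        params={
            "effect_mean": effect_mean,
            "effect_sd": effect_sd,
            "coupling_sd": coupling_sd,
            "density": density,
        },
    )


def argmax_additive(landscape: AdditiveLandscape, k: int) -> VariantSpec:
    """Closed-form global optimum of an additive landscape over the exact-k shell.

    Take the best substitution at each site, then the top-k sites by that
    best effect; no search is involved, so this serves as an independent
    ground truth for the optimizer.
    """
    ref = landscape.ref
    if k < 1 or k > ref.L:
        raise ValueError(f"k must satisfy 1 <= k <= L; got k={k}, L={ref.L}")
    per_site = landscape.effects.reshape(ref.L, 19)
    best_rank = per_site.argmax(axis=1)
    best_effect = per_site[np.arange(ref.L), best_rank]
    # deterministic tie-break: stable sort on (-effect, site)
    top_sites = np.argsort(-best_effect, kind="stable")[:k]
    indices = [int(s) * 19 + int(best_rank[s]) for s in sorted(top_sites)]
    return VariantSpec.from_indices(ref, indices)


class CachedOracle:
    """Memoizing wrapper: each unique variant hits the wrapped oracle once.

    Keys are canonical mutation strings, so the cache is order-independent.
    ``n_unique_evaluations`` counts first-seen variants only.
    """

    def __init__(self, oracle: FitnessOracle, ref: ReferenceSequence):
        self.oracle = oracle
        self.ref = ref
        self.cache: dict[str, float] = {}
        self.n_unique_evaluations = 0

    @property
    def name(self) -> str:
        return f"cached({self.oracle.name})"

    @property
    def deterministic(self) -> bool:
        return True

    def score_batch(self, variants: Sequence[VariantSpec]) -> np.ndarray:
        keys = [v.canonical_key(self.ref) for v in variants]
        fresh: dict[str, VariantSpec] = {}
        for key, v in zip(keys, variants):
            if key not in self.cache and key not in fresh:
                fresh[key] = v
        if fresh:
            try:
                scores = np.asarray(self.oracle.score_batch(list(fresh.values())), dtype=float)
            except Exception as exc:
                raise RuntimeError(
                    f"oracle {self.oracle.name!r} failed on batch containing "
                    f"{next(iter(fresh))!r}: {exc}"
                ) from exc
            for key, s in zip(fresh, scores):
                if not np.isfinite(s):
                    raise ValueError(f"oracle returned non-finite score for variant {key!r}")
                self.cache[key] = float(s)
            self.n_unique_evaluations += len(fresh)
        return np.array([self.cache[key] for key in keys], dtype=np.float64)


# ---------------------------------------------------------------------------
# serialization: self-describing JSON so runs replay bit-exactly
# ---------------------------------------------------------------------------

_MAX_TRIPLET_PAIRS = 1_000_000


def landscape_to_json(landscape: AdditiveLandscape) -> dict:
    """A self-describing dict: seed, parameters, effect vector and, for
    epistatic landscapes of tractable size, the nonzero coupling triplets."""
    doc = {
        "kind": landscape.name,
        "reference": {"id": landscape.ref.id, "residues": landscape.ref.residues},
        "seed": landscape.seed,
        "ref_score": landscape.ref_score,
        "params": landscape.params,
        "effects": [float(a) for a in landscape.effects],
    }
    if isinstance(landscape, EpistaticLandscape):
        M = landscape.ref.n_mutations
        if M * (M - 1) // 2 <= _MAX_TRIPLET_PAIRS:
            i, j = np.triu_indices(M, 1)
            J = landscape.coupling(i, j)
            nz = np.nonzero(J)[0]
            doc["coupling_triplets"] = [
                [int(i[t]), int(j[t]), float(J[t])] for t in nz
            ]
        else:
            doc["coupling_triplets"] = None  # recomputed from the seed on load
    return doc


def landscape_from_json(doc: dict) -> AdditiveLandscape:
    ref = ReferenceSequence(residues=doc["reference"]["residues"], id=doc["reference"]["id"])
    effects = np.asarray(doc["effects"], dtype=np.float64)
    common = dict(ref=ref, effects=effects, ref_score=doc["ref_score"], seed=doc["seed"])
    if doc["kind"] == "additive":
        return AdditiveLandscape(params=doc["params"], **common)
    if doc["kind"] == "epistatic":
        return EpistaticLandscape(
            coupling_sd=doc["params"]["coupling_sd"],
            density=doc["params"]["density"],
            params=doc["params"],
            **common,
        )
    raise ValueError(f"unknown landscape kind {doc['kind']!r}")


def save_landscape(landscape: AdditiveLandscape, path) -> None:
    with open(path, "w") as fh:
        json.dump(landscape_to_json(landscape), fh, indent=1)


def load_landscape(path) -> AdditiveLandscape:
    with open(path) as fh:
        return landscape_from_json(json.load(fh))
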