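"""The biphasic-annealing sequence optimizer.

The optimizer maintains a product distribution over single substitutions:
each mutation ``m`` carries a probability ``q_m`` derived from a softmax
of per-mutation energies at the current temperature ``T``.  Batches of
k-mutant variants are drawn from the product distribution (k mutations at
distinct sites), scored by the fitness oracle, and the energies are
re-estimated from the running per-mutation score statistics.

Temperature control is *biphasic* rather than monotone: the system cools
while the batch-mean score climbs, overshoots the high set point
``mu_high`` for ``patience`` iterations (*active phase transition*), then
reheats (*phase transition reversal*) until the mean falls below
``mu_low``, at which point accelerated cooling resumes.  The heating
phases collect less biased samples that refine the energy estimates; the
cooling phases exploit them.

Normalized energies.  With single-mutant scores ``f(x_m)`` scored at
initialization, the starting energies are ``e_m = (f_o - f(x_m)) / (1 + tau)``
and ``q_m = exp(-e_m / T_0) / Q``.  After each iteration the energies
become ``e~_m = -mean_m - gamma * std_m`` from the running statistics of
all scored sequences containing ``m``, renormalized the same way.  By
default ``f_o`` is the 80th percentile and ``tau`` the standard deviation
of the single-mutant scores.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .oracles import CachedOracle, FitnessOracle
from .sequence_space import ReferenceSequence, VariantSpec, enumerate_single_mutations

__all__ = [
    "BadassConfig",
    "OptimizerPhase",
    "MutationStats",
    "SamplerState",
    "IterationRecord",
    "ScoredSequence",
    "RunResult",
    "initialize",
    "sample_batch",
    "compute_batch_stats",
    "update_phase",
    "update_temperature",
    "update_mutation_stats",
    "update_sampler",
    "run",
]

_Q_FLOOR = 1e-300  # keeps q strictly positive despite exp underflow at low T


class OptimizerPhase(enum.Enum):
    INITIAL_TRANSIENT = "initial_transient"
    COOLING = "cooling_phase"
    ACTIVE_PHASE_TRANSITION = "active_phase_transition"
    PHASE_TRANSITION_REVERSAL = "phase_transition_reversal"


def _default_k_mixture() -> dict[int, float]:
    # an even mix of 2 to 6 mutations
    return {k: 0.2 for k in range(2, 7)}


@dataclass(frozen=True)
class BadassConfig:
    """Run configuration.  ``None`` fields are resolved at initialization
    from the single-mutant score distribution (see :func:`initialize`)."""

    T0: float = 1.5
    alpha: float = 0.90          # base cooling rate
    alpha_heat: float = 1.5      # reheating rate, > 1
    alpha_cool: float | None = None   # accelerated cooling; default alpha**3
    mu_high: float | None = None      # default: 90th pct of single-mutant scores
    mu_low: float | None = None       # default: median of single-mutant scores
    patience: int = 5
    gamma: float = 1.0           # weight of the per-mutation score std bonus
    f_o: float | None = None     # default: 80th pct of single-mutant scores
    tau: float | None = None     # default: std of single-mutant scores
    batch_size: int = 500
    n_iterations: int = 200
    max_evaluations: int | None = None  # unique oracle calls, incl. initialization
    k_mixture: dict[int, float] = field(default_factory=_default_k_mixture)
    moving_average_window: int = 5
    T_min: float = 1e-4
    T_max: float = 1e2
    seed: int = 0

    def validate(self) -> None:
        if self.T0 <= 0 or self.T_min <= 0 or self.T_max < self.T_min:
            raise ValueError("temperatures must satisfy 0 < T_min <= T_max and T0 > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.alpha_heat <= 1:
            raise ValueError("alpha_heat must exceed 1")
        a_cool = self.alpha_cool if self.alpha_cool is not None else self.alpha**3
        if not 0 < a_cool < self.alpha:
            raise ValueError("alpha_cool must lie in (0, alpha)")
        if self.mu_high is not None and self.mu_low is not None and self.mu_low >= self.mu_high:
            raise ValueError("mu_low must be < mu_high")
        if self.patience < 1 or self.moving_average_window < 1:
            raise ValueError("patience and moving_average_window must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.batch_size < 1 or self.n_iterations < 0:
            raise ValueError("batch_size must be >= 1 and n_iterations >= 0")
        props = np.array(list(self.k_mixture.values()), dtype=float)
        if len(props) == 0 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("k_mixture proportions must be >= 0 and sum to 1")
        if any(k < 1 for k in self.k_mixture):
            raise ValueError("k_mixture keys must be >= 1")


@dataclass
class MutationStats:
    """Running count / sum / sum-of-squares of scores per mutation.

    Mutation ``m``'s statistics aggregate over every scored sequence that
    contains ``m`` (each sequence is counted once, at first scoring)."""

    count: np.ndarray
    score_sum: np.ndarray
    score_sumsq: np.ndarray

    @classmethod
    def empty(cls, n_mutations: int) -> "MutationStats":
        z = np.zeros(n_mutations, dtype=np.float64)
        return cls(count=z.copy(), score_sum=z.copy(), score_sumsq=z.copy())

    def mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.count > 0, self.score_sum / np.maximum(self.count, 1), 0.0)

    def variance(self) -> np.ndarray:
        # population form; clamped against negative float error
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = self.score_sumsq / np.maximum(self.count, 1) - self.mean() ** 2
        return np.maximum(np.where(self.count > 0, raw, 0.0), 0.0)

    def std(self) -> np.ndarray:
        return np.sqrt(self.variance())


@dataclass
class SamplerState:
    q: np.ndarray
    T: float
    phase: OptimizerPhase
    patience_counter: int = 0
    mu_buffer: deque = field(default_factory=lambda: deque(maxlen=5))


@dataclass(frozen=True)
class IterationRecord:
    t: int
    mu: float
    sigma: float
    T: float                 # temperature that generated this iteration's batch
    phase: OptimizerPhase    # controller state after this iteration's update
    n_new: int               # newly scored (first-seen) sequences
    unique_total: int


@dataclass(frozen=True)
class ScoredSequence:
    key: str
    variant: VariantSpec
    score: float
    first_iteration: int     # 0 = initialization single mutants


@dataclass
class RunResult:
    ref: ReferenceSequence
    config: BadassConfig
    sequences: dict[str, ScoredSequence]
    records: list[IterationRecord]
    final_state: SamplerState
    n_unique_evaluations: int


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def _softmax_q(neg_energy_over_T: np.ndarray) -> np.ndarray:
    z = neg_energy_over_T - neg_energy_over_T.max()
    q = np.exp(z)
    q /= q.sum()
    q = np.maximum(q, _Q_FLOOR)
    return q / q.sum()


def initialize(
    oracle: FitnessOracle,
    ref: ReferenceSequence,
    config: BadassConfig,
) -> tuple[SamplerState, MutationStats, CachedOracle, BadassConfig]:
    """Score all M single mutants and build the initial sampler.

    Returns the state, per-mutation statistics seeded with the single-mutant
    scores, the caching oracle wrapper, and the *resolved* configuration
    (percentile defaults filled in from the single-mutant scores).
    """
    config.validate()
    singles = enumerate_single_mutations(ref)
    if any(k > ref.L for k in config.k_mixture):
        raise ValueError(f"k_mixture contains k > L = {ref.L}")
    cache = CachedOracle(oracle, ref)
    scores = cache.score_batch([VariantSpec((m,)) for m in singles])

    resolved = replace(
        config,
        f_o=config.f_o if config.f_o is not None else float(np.percentile(scores, 80)),
        tau=config.tau if config.tau is not None else float(np.std(scores)),
        mu_high=config.mu_high
        if config.mu_high is not None
        else float(np.percentile(scores, 90)),
        mu_low=config.mu_low if config.mu_low is not None else float(np.percentile(scores, 50)),
        alpha_cool=config.alpha_cool if config.alpha_cool is not None else config.alpha**3,
    )
    resolved.validate()

    energies = (resolved.f_o - scores) / (1.0 + resolved.tau)
    q = _softmax_q(-energies / resolved.T0)

    stats = MutationStats.empty(ref.n_mutations)
    stats.count += 1.0
    stats.score_sum += scores
    stats.score_sumsq += scores**2

    state = SamplerState(
        q=q,
        T=resolved.T0,
        phase=OptimizerPhase.INITIAL_TRANSIENT,
        mu_buffer=deque(maxlen=resolved.moving_average_window),
    )
    return state, stats, cache, resolved


def sample_batch(
    state: SamplerState,
    ref: ReferenceSequence,
    config: BadassConfig,
    rng: np.random.Generator,
    n: int | None = None,
) -> list[VariantSpec]:
    """Draw N k-mutant variants from the product distribution over mutations.

    Each variant's k is drawn from the configured mixture; its k mutations
    are drawn sequentially from q restricted to sites not yet used within
    that variant (renormalized after each draw).  The draw is realized with
    Gumbel-perturbed log-probabilities and a first-per-site scan, which is
    distributionally identical to the sequential renormalized scheme and
    vectorizes over the batch.

    RNG order is fixed (k values first, then one Gumbel matrix) for
    bit-exact replay.
    """
    n = config.batch_size if n is None else n
    k_values = sorted(config.k_mixture)
    if any(k > ref.L for k in k_values):
        raise ValueError(f"cannot place {max(k_values)} mutations on {ref.L} distinct sites")
    props = np.array([config.k_mixture[k] for k in k_values], dtype=float)
    ks = rng.choice(np.array(k_values), size=n, p=props / props.sum())

    keys = np.log(state.q)[None, :] + rng.gumbel(size=(n, state.q.size))
    order = np.argsort(-keys, axis=1)

    out: list[VariantSpec] = []
    for row, k in zip(order, ks):
        sites_used: set[int] = set()
        chosen: list[int] = []
        for m in row:
            s = int(m) // 19
            if s not in sites_used:
                sites_used.add(s)
                chosen.append(int(m))
                if len(chosen) == k:
                    break
        out.append(VariantSpec.from_indices(ref, chosen))
    return out


def compute_batch_stats(scores: Sequence[float]) -> tuple[float, float]:
    """Batch mean and *population* variance of the sampled multiset
    (duplicates counted with multiplicity); variance clamped at 0."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot compute statistics of an empty batch")
    mu = float(scores.mean())
    var = max(float((scores**2).mean() - mu**2), 0.0)
    return mu, var


def update_phase(
    state: SamplerState, mu_t: float, sigma_t: float, config: BadassConfig
) -> OptimizerPhase:
    """Advance the biphasic controller by one iteration.

    A simple moving average of the batch mean crossing above ``mu_high``
    triggers the active phase transition, which persists for ``patience``
    iterations (or until the moving average drops below ``mu_high`` minus
    one batch standard deviation) before reversing into heating; heating
    continues until the batch mean falls below ``mu_low``.
    """
    state.mu_buffer.append(mu_t)
    moving_avg = float(np.mean(state.mu_buffer))

    if state.phase is OptimizerPhase.ACTIVE_PHASE_TRANSITION:
        state.patience_counter += 1
        rapid_decline = moving_avg < config.mu_high - sigma_t
        if state.patience_counter >= config.patience or rapid_decline:
            state.phase = OptimizerPhase.PHASE_TRANSITION_REVERSAL
            state.patience_counter = 0
    elif state.phase is not OptimizerPhase.PHASE_TRANSITION_REVERSAL and moving_avg > config.mu_high:
        state.phase = OptimizerPhase.ACTIVE_PHASE_TRANSITION
        state.patience_counter = 0
    elif mu_t < config.mu_low:
        state.phase = OptimizerPhase.COOLING
    return state.phase


def update_temperature(phase: OptimizerPhase, T: float, config: BadassConfig) -> float:
    """One multiplicative temperature step, clipped to [T_min, T_max]."""
    rate = {
        OptimizerPhase.INITIAL_TRANSIENT: config.alpha,
        OptimizerPhase.ACTIVE_PHASE_TRANSITION: config.alpha,  # cooling continues
        OptimizerPhase.PHASE_TRANSITION_REVERSAL: config.alpha_heat,
        OptimizerPhase.COOLING: config.alpha_cool,
    }[phase]
    return float(np.clip(rate * T, config.T_min, config.T_max))


def update_mutation_stats(
    stats: MutationStats,
    ref: ReferenceSequence,
    new_variants: Sequence[VariantSpec],
    new_scores: Sequence[float],
) -> MutationStats:
    """Fold newly scored sequences into the per-mutation running sums.

    Only first-time-scored sequences belong here; resampled (cached)
    sequences must not inflate the statistics again.
    """
    if len(new_variants) == 0:
        return stats
    idx = np.concatenate([np.asarray(v.indices(ref), dtype=np.intp) for v in new_variants])
    rep = np.repeat(np.asarray(new_scores, dtype=float), [v.k for v in new_variants])
    np.add.at(stats.count, idx, 1.0)
    np.add.at(stats.score_sum, idx, rep)
    np.add.at(stats.score_sumsq, idx, rep**2)
    return stats


def update_sampler(
    stats: MutationStats,
    T_next: float,
    config: BadassConfig,
    ref: ReferenceSequence | None = None,
) -> np.ndarray:
    """Recompute q from the running per-mutation statistics.

    Raw energies reward both a high mean score and (with weight gamma) a
    high score spread: ``e~_m = -mean_m - gamma * std_m``.  Energies are
    renormalized by ``(e~_m + f_o) / (1 + tau)`` and passed through a
    numerically stable softmax at temperature ``T_next``.
    """
    raw = -stats.mean() - config.gamma * stats.std()
    energies = (raw + config.f_o) / (1.0 + config.tau)
    bad = np.nonzero(~np.isfinite(energies))[0]
    if bad.size:
        m = int(bad[0])
        label = str(ref.index_to_mutation(m)) if ref is not None else f"index {m}"
        raise ValueError(f"non-finite mutation energy for {label}")
    return _softmax_q(-energies / T_next)


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def run(
    oracle: FitnessOracle,
    ref: ReferenceSequence,
    config: BadassConfig,
    *,
    update_energies: bool = True,
    biphasic: bool = True,
) -> RunResult:
    """Execute the full optimization loop.

    ``update_energies=False`` freezes q at its post-initialization value;
    ``biphasic=False`` replaces the controller with monotone cooling at the
    base rate.  Both flags exist for the ablation studies and leave every
    other line of the loop untouched.
    """
    M = ref.n_mutations
    if config.max_evaluations is not None and config.max_evaluations < M:
        raise ValueError(
            f"evaluation budget {config.max_evaluations} is below the {M} "
            "single-mutant scores initialization requires"
        )
    state, stats, cache, cfg = initialize(oracle, ref, config)
    rng = np.random.default_rng(cfg.seed)

    singles = enumerate_single_mutations(ref)
    sequences: dict[str, ScoredSequence] = {}
    for mut in singles:
        v = VariantSpec((mut,))
        key = v.canonical_key(ref)
        sequences[key] = ScoredSequence(key, v, cache.cache[key], 0)

    records: list[IterationRecord] = []
    for t in range(1, cfg.n_iterations + 1):
        batch = sample_batch(state, ref, cfg, rng)
        T_sample = state.T

        # budget accounting on unique new sequences; truncate the final batch
        if cfg.max_evaluations is not None:
            remaining = cfg.max_evaluations - cache.n_unique_evaluations
            if remaining <= 0:
                break
            kept, n_new_planned, seen = [], 0, set()
            for v in batch:
                key = v.canonical_key(ref)
                is_new = key not in cache.cache and key not in seen
                if is_new and n_new_planned == remaining:
                    break
                kept.append(v)
                if is_new:
                    seen.add(key)
                    n_new_planned += 1
            batch = kept
            if not batch:
                break

        keys = [v.canonical_key(ref) for v in batch]
        new_mask = [key not in cache.cache for key in keys]
        scores = cache.score_batch(batch)

        new_seen: set[str] = set()
        new_variants: list[VariantSpec] = []
        new_scores: list[float] = []
        for v, key, s, was_new in zip(batch, keys, scores, new_mask):
            if was_new and key not in new_seen:
                new_seen.add(key)
                new_variants.append(v)
                new_scores.append(float(s))
                sequences[key] = ScoredSequence(key, v, float(s), t)
        update_mutation_stats(stats, ref, new_variants, new_scores)

        mu_t, var_t = compute_batch_stats(scores)
        sigma_t = float(np.sqrt(var_t))

        if biphasic:
            update_phase(state, mu_t, sigma_t, cfg)
            state.T = update_temperature(state.phase, state.T, cfg)
        else:
            state.T = float(np.clip(cfg.alpha * state.T, cfg.T_min, cfg.T_max))

        if update_energies:
            state.q = update_sampler(stats, state.T, cfg, ref)

        records.append(
            IterationRecord(
                t=t,
                mu=mu_t,
                sigma=sigma_t,
                T=T_sample,
                phase=state.phase,
                n_new=len(new_variants),
                unique_total=cache.n_unique_evaluations,
            )
        )

    return RunResult(
        ref=ref,
        config=cfg,
        sequences=sequences,
        records=records,
        final_state=state,
        n_unique_evaluations=cache.n_unique_evaluations,
    )
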