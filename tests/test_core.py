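"""Optimizer core: energies, sampling, phase machine, full-loop contracts."""

from collections import deque

import numpy as np
import pytest

from badass import (
    BadassConfig,
    MutationStats,
    OptimizerPhase,
    ReferenceSequence,
    SamplerState,
    VariantSpec,
    compute_batch_stats,
    initialize,
    make_additive_landscape,
    make_epistatic_landscape,
    run,
    sample_batch,
    update_mutation_stats,
    update_phase,
    update_sampler,
    update_temperature,
)


def stats_from(counts, sums, sumsqs):
    return MutationStats(
        count=np.asarray(counts, dtype=float),
        score_sum=np.asarray(sums, dtype=float),
        score_sumsq=np.asarray(sumsqs, dtype=float),
    )


def cfg(**kw):
    base = dict(f_o=0.0, tau=0.0, mu_high=1.0, mu_low=-1.0)
    base.update(kw)
    return BadassConfig(**base)


class TestEnergyArithmetic:
    def test_initial_energies_softmax_of_shifted_scores(self):
        # single-mutant scores [2, 1, 0] with f_o=1, tau=0, T0=1:
        # e = (f_o - f) = [-1, 0, 1], q = softmax([1, 0, -1])
        stats = stats_from([1, 1, 1], [2, 1, 0], [4, 1, 0])
        q = update_sampler(stats, T_next=1.0, config=cfg(f_o=1.0, gamma=0.0))
        expected = np.exp([1.0, 0.0, -1.0])
        expected /= expected.sum()
        assert np.allclose(q, expected, atol=1e-12)
        assert np.allclose(q, [0.66524096, 0.24472847, 0.09003057], atol=1e-8)

    def test_update_with_std_bonus(self):
        # m1 scores {2,4}: mean 3, std 1; m2 scores {3,3}: mean 3, std 0.
        # gamma=1 -> raw energies [-4, -3] -> q = softmax([4, 3])
        stats = stats_from([2, 2], [6, 6], [20, 18])
        q = update_sampler(stats, T_next=1.0, config=cfg(gamma=1.0))
        assert np.allclose(q, [1 / (1 + np.exp(-1)), 1 / (1 + np.exp(1))], atol=1e-9)
        assert np.allclose(q, [0.73105858, 0.26894142], atol=1e-8)

    def test_gamma_zero_equal_means_gives_uniform(self):
        stats = stats_from([2, 2, 2], [6, 6, 6], [20, 18, 26])
        q = update_sampler(stats, T_next=0.7, config=cfg(gamma=0.0))
        assert np.allclose(q, 1 / 3, atol=1e-12)

    def test_reference_shift_invariance(self):
        stats = stats_from([2, 3], [5, 9], [13, 29])
        q0 = update_sampler(stats, T_next=0.9, config=cfg(f_o=0.0))
        for shift in (-1e3, 1e3):
            q = update_sampler(stats, T_next=0.9, config=cfg(f_o=shift))
            assert np.max(np.abs(q - q0)) <= 1e-12

    def test_q_is_normalized_and_positive(self):
        stats = stats_from([1, 1, 1], [50, 0, -50], [2500, 0, 2500])
        q = update_sampler(stats, T_next=0.05, config=cfg(gamma=0.0))
        assert abs(q.sum() - 1.0) < 1e-12
        assert np.all(q > 0)


class TestInitialize:
    def test_percentile_defaults_and_softmax(self, ref5, additive5):
        config = BadassConfig(k_mixture={2: 1.0})
        state, stats, cache, resolved = initialize(additive5, ref5, config)
        scores = additive5.score_batch(
            [VariantSpec((m,)) for m in __import__("badass").enumerate_single_mutations(ref5)]
        )
        assert resolved.f_o == pytest.approx(np.percentile(scores, 80))
        assert resolved.tau == pytest.approx(np.std(scores))
        assert resolved.mu_high == pytest.approx(np.percentile(scores, 90))
        assert resolved.mu_low == pytest.approx(np.percentile(scores, 50))
        e = (resolved.f_o - scores) / (1 + resolved.tau)
        expected = np.exp(-e / resolved.T0)
        expected /= expected.sum()
        assert np.allclose(state.q, expected, atol=1e-12)
        assert state.phase is OptimizerPhase.INITIAL_TRANSIENT
        assert cache.n_unique_evaluations == ref5.n_mutations
        assert np.all(stats.count == 1)

    def test_equal_scores_give_uniform_q(self, ref5):
        flat = make_additive_landscape(ref5, seed=0, effect_sd=0.0)
        config = BadassConfig(tau=0.0, mu_high=1.0, mu_low=-1.0, k_mixture={1: 1.0})
        state, *_ = initialize(flat, ref5, config)
        assert np.allclose(state.q, 1 / ref5.n_mutations, atol=1e-12)

    def test_high_temperature_flattens_q(self, ref5, additive5):
        config = BadassConfig(T0=1e6, tau=0.0, k_mixture={1: 1.0})
        state, *_ = initialize(additive5, ref5, config)
        assert np.allclose(state.q, 1 / ref5.n_mutations, rtol=1e-3)


class TestBatchStats:
    def test_population_variance(self):
        mu, var = compute_batch_stats([1, 2, 3])
        assert mu == pytest.approx(2.0)
        assert var == pytest.approx(2 / 3)

    @pytest.mark.parametrize("scores,mu", [([4.0] * 6, 4.0), ([2.5], 2.5)])
    def test_degenerate_batches_have_zero_variance(self, scores, mu):
        got_mu, got_var = compute_batch_stats(scores)
        assert got_mu == pytest.approx(mu)
        assert got_var == 0.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            compute_batch_stats([])


class TestPhaseMachine:
    def make_state(self, phase, window=3):
        return SamplerState(
            q=np.full(4, 0.25), T=1.0, phase=phase, mu_buffer=deque(maxlen=window)
        )

    def test_crossing_mu_high_triggers_active_transition(self):
        state = self.make_state(OptimizerPhase.COOLING)
        phase = update_phase(state, mu_t=2.0, sigma_t=0.1, config=cfg(patience=3))
        assert phase is OptimizerPhase.ACTIVE_PHASE_TRANSITION

    def test_patience_exhaustion_reverses(self):
        config = cfg(patience=2)
        state = self.make_state(OptimizerPhase.COOLING)
        update_phase(state, 2.0, 0.1, config)
        assert state.phase is OptimizerPhase.ACTIVE_PHASE_TRANSITION
        update_phase(state, 2.0, 0.1, config)
        assert state.phase is OptimizerPhase.ACTIVE_PHASE_TRANSITION
        update_phase(state, 2.0, 0.1, config)
        assert state.phase is OptimizerPhase.PHASE_TRANSITION_REVERSAL

    def test_rapid_decline_exits_active_early(self):
        config = cfg(patience=50, moving_average_window=1)
        state = self.make_state(OptimizerPhase.ACTIVE_PHASE_TRANSITION, window=1)
        # moving average 0.0 < mu_high(1.0) - sigma(0.5)
        update_phase(state, 0.0, 0.5, config)
        assert state.phase is OptimizerPhase.PHASE_TRANSITION_REVERSAL

    def test_reversal_exits_to_cooling_below_mu_low(self):
        state = self.make_state(OptimizerPhase.PHASE_TRANSITION_REVERSAL)
        update_phase(state, -2.0, 0.1, cfg())
        assert state.phase is OptimizerPhase.COOLING

    def test_reversal_ignores_mu_high(self):
        state = self.make_state(OptimizerPhase.PHASE_TRANSITION_REVERSAL)
        update_phase(state, 5.0, 0.1, cfg())
        assert state.phase is OptimizerPhase.PHASE_TRANSITION_REVERSAL


class TestTemperatureUpdate:
    @pytest.mark.parametrize(
        "phase,T,expected",
        [
            (OptimizerPhase.COOLING, 1.0, 0.8),
            (OptimizerPhase.PHASE_TRANSITION_REVERSAL, 1.0, 1.5),
            (OptimizerPhase.INITIAL_TRANSIENT, 2.0, 1.8),
            (OptimizerPhase.ACTIVE_PHASE_TRANSITION, 2.0, 1.8),
        ],
    )
    def test_phase_rates(self, phase, T, expected):
        config = cfg(alpha=0.9, alpha_heat=1.5, alpha_cool=0.8)
        assert update_temperature(phase, T, config) == pytest.approx(expected)

    def test_bounds_clip(self):
        config = cfg(alpha=0.9, alpha_heat=1.5, alpha_cool=0.5, T_min=0.9, T_max=1.2)
        assert update_temperature(OptimizerPhase.COOLING, 1.0, config) == 0.9
        assert update_temperature(OptimizerPhase.PHASE_TRANSITION_REVERSAL, 1.0, config) == 1.2


class TestMutationStatsUpdate:
    def test_one_new_three_mutant_touches_three_entries(self, ref5):
        from badass import Mutation

        stats = MutationStats.empty(ref5.n_mutations)
        variant = VariantSpec((Mutation(1, "W"), Mutation(3, "G"), Mutation(5, "C")))
        update_mutation_stats(stats, ref5, [variant], [2.0])
        assert int((stats.count > 0).sum()) == 3
        assert stats.score_sum.sum() == pytest.approx(6.0)

    def test_no_new_sequences_is_a_noop(self, ref5):
        stats = MutationStats.empty(ref5.n_mutations)
        before = stats.count.copy()
        update_mutation_stats(stats, ref5, [], [])
        assert np.array_equal(stats.count, before)

    def test_mean_and_std_from_running_sums(self, ref5):
        from badass import Mutation

        stats = MutationStats.empty(ref5.n_mutations)
        v = VariantSpec((Mutation(1, "W"),))
        w = VariantSpec((Mutation(1, "W"), Mutation(2, "Y")))
        update_mutation_stats(stats, ref5, [v, w], [2.0, 4.0])
        m = ref5.mutation_to_index(Mutation(1, "W"))
        assert stats.mean()[m] == pytest.approx(3.0)
        assert stats.std()[m] == pytest.approx(1.0)


class TestSampleBatch:
    def test_concentrated_q_yields_deterministic_pair(self, ref5):
        M = ref5.n_mutations
        q = np.full(M, 1e-15)
        q[0] = q[20] = 0.5  # sites 1 and 2
        q /= q.sum()
        state = SamplerState(q=q, T=1.0, phase=OptimizerPhase.INITIAL_TRANSIENT)
        config = cfg(k_mixture={2: 1.0}, batch_size=64)
        batch = sample_batch(state, ref5, config, np.random.default_rng(0))
        keys = {v.canonical_key(ref5) for v in batch}
        assert len(keys) == 1
        assert sorted(batch[0].indices(ref5)) == [0, 20]

    def test_k1_frequencies_follow_q(self, ref5):
        M = ref5.n_mutations
        q = np.random.default_rng(3).dirichlet(np.ones(M))
        state = SamplerState(q=q, T=1.0, phase=OptimizerPhase.INITIAL_TRANSIENT)
        config = cfg(k_mixture={1: 1.0})
        n = 20_000
        batch = sample_batch(state, ref5, config, np.random.default_rng(1), n=n)
        counts = np.zeros(M)
        for v in batch:
            counts[v.indices(ref5)[0]] += 1
        from scipy.stats import chisquare

        assert chisquare(counts, q * n).pvalue > 1e-3

    def test_k2_pair_frequencies_match_sequential_renormalization(self):
        # Two sites, q supported on two substitutions per site: the exact
        # distribution over site-spanning pairs follows from enumerating both
        # draw orders with renormalization over the unused site.
        ref = ReferenceSequence("AC", id="tiny")
        q = np.full(ref.n_mutations, 1e-15)
        support = {0: 0.4, 5: 0.2, 19: 0.3, 24: 0.1}
        for m, p in support.items():
            q[m] = p
        q /= q.sum()
        site0 = {0, 5}
        exact = {}
        for a in site0:
            for b in support.keys() - site0:
                pa, pb = support[a], support[b]
                mass0 = sum(support[m] for m in site0)
                exact[frozenset((a, b))] = pa * pb / (1 - mass0) + pb * pa / mass0
        assert sum(exact.values()) == pytest.approx(1.0)

        state = SamplerState(q=q, T=1.0, phase=OptimizerPhase.INITIAL_TRANSIENT)
        n = 20_000
        batch = sample_batch(
            state, ref, cfg(k_mixture={2: 1.0}), np.random.default_rng(7), n=n
        )
        counts: dict[frozenset, int] = {}
        for v in batch:
            counts[frozenset(v.indices(ref))] = counts.get(frozenset(v.indices(ref)), 0) + 1
        for pair, p in exact.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(pair, 0) / n - p) < 4 * se

    def test_k_exceeding_sites_rejected(self, ref5):
        state = SamplerState(
            q=np.full(ref5.n_mutations, 1 / ref5.n_mutations),
            T=1.0,
            phase=OptimizerPhase.INITIAL_TRANSIENT,
        )
        with pytest.raises(ValueError, match="distinct sites"):
            sample_batch(state, ref5, cfg(k_mixture={6: 1.0}), np.random.default_rng(0))


class TestRunLoop:
    def small_config(self, **kw):
        base = dict(batch_size=40, n_iterations=15, k_mixture={2: 0.5, 3: 0.5}, seed=11)
        base.update(kw)
        return BadassConfig(**base)

    def test_same_seed_reproduces_everything(self, ref5, epistatic5):
        a = run(epistatic5, ref5, self.small_config())
        b = run(epistatic5, ref5, self.small_config())
        assert list(a.sequences) == list(b.sequences)
        assert all(
            a.sequences[k].score == b.sequences[k].score for k in a.sequences
        )
        assert a.records == b.records
        assert np.array_equal(a.final_state.q, b.final_state.q)

    def test_budget_below_initialization_rejected(self, ref5, epistatic5):
        with pytest.raises(ValueError, match="single-mutant"):
            run(epistatic5, ref5, self.small_config(max_evaluations=10))

    def test_budget_exhausted_mid_iteration(self, ref5, epistatic5):
        budget = ref5.n_mutations + 60
        res = run(epistatic5, ref5, self.small_config(max_evaluations=budget))
        assert res.n_unique_evaluations <= budget
        assert res.n_unique_evaluations == len(res.sequences)
        assert res.records[-1].unique_total == res.n_unique_evaluations
        assert ref5.n_mutations + sum(r.n_new for r in res.records) == res.n_unique_evaluations

    def test_q_normalized_positive_after_run(self, ref5, epistatic5):
        res = run(epistatic5, ref5, self.small_config())
        assert abs(res.final_state.q.sum() - 1.0) < 1e-12
        assert np.all(res.final_state.q > 0)

    def test_cache_soundness(self, ref5, epistatic5):
        res = run(epistatic5, ref5, self.small_config())
        assert res.n_unique_evaluations == len(res.sequences)

    def test_effective_temperature_equivalence(self, ref30):
        # q depends on tau and T only through (1 + tau) * T, so rescaling the
        # whole temperature schedule compensates a change of tau exactly.
        landscape = make_epistatic_landscape(ref30, seed=2)
        tau_a, tau_b = 0.5, 2.0
        scale = (1 + tau_a) / (1 + tau_b)
        common = dict(
            batch_size=50, n_iterations=20, k_mixture={2: 1.0}, seed=4,
            f_o=0.0, mu_high=1.0, mu_low=-1.0,
        )
        cfg_a = BadassConfig(tau=tau_a, T0=1.5, T_min=1e-4, T_max=1e2, **common)
        cfg_b = BadassConfig(
            tau=tau_b, T0=1.5 * scale, T_min=1e-4 * scale, T_max=1e2 * scale, **common
        )
        a = run(landscape, ref30, cfg_a)
        b = run(landscape, ref30, cfg_b)
        assert np.max(np.abs(a.final_state.q - b.final_state.q)) < 1e-12
        assert list(a.sequences) == list(b.sequences)
        assert [r.mu for r in a.records] == [r.mu for r in b.records]
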