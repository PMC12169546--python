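# Methods

## The optimization problem

Given a fixed reference protein of length `L` and a batch fitness oracle
`f(x)`, the optimizer searches the shell `S_k` of variants carrying exactly
`k` substitutions at distinct sites (or a blend of shells, `M_k`).  There
are `M = 19 L` possible single substitutions, indexed `m`; a variant is a
set of them.  `S_k` holds `C(L, k)·19^k` sequences, so enumeration is
practical only for `k = 1` (or tiny `L`, which the theory checks exploit).

The ideal sampler at temperature `T` is the Boltzmann distribution
`p(x) = exp(f(x)/T)/Z`, the maximizer of `⟨f⟩ + T·H` — but `Z` is
intractable.  The optimizer instead samples from the tractable product
family `q(x) = ∏_{m∈x} q_m`, adapting both `q_m` and `T` as it scores
batches.

## The sampler

**Energies.**  After scoring all `M` single mutants, each mutation gets a
normalized energy `e_m = (f_o − f(x_m))/(1 + τ)` and probability
`q_m = exp(−e_m/T_0)/Q`.  Thereafter `e~_m = −mean_m − γ·std_m`, where
mean/std are running statistics of *every scored sequence containing m*
(each sequence counted once, at first scoring; resampled cached sequences
do not re-enter).  The same normalization `(e~_m + f_o)/(1 + τ)` and
softmax at the current temperature produce the next `q`.  The std bonus
(`γ`, default 1) favors mutations whose context-dependence is still
uncertain, which keeps exploration alive in epistatic regions.

`f_o` and `τ` only set the scale: the softmax is invariant to shifting
`f_o`, and `q` depends on `(τ, T)` only through `(1+τ)·T` (both properties
are asserted in tests).  Defaults: `f_o` = 80th percentile, `τ` = standard
deviation of the single-mutant scores.

**Sampling without replacement over sites.**  A product distribution can
propose two mutations at one site; variants are therefore drawn
sequentially from `q` restricted to unused sites, renormalizing after each
draw.  The implementation uses Gumbel-perturbed log-probabilities with a
first-per-site greedy scan, which is distributionally identical
(Plackett–Luce orders restricted to a subset are Plackett–Luce on that
subset) and vectorizes over the batch.  A test checks the resulting pair
frequencies against hand-enumerated sequential-renormalization
probabilities on a two-site reference.

**Temperature control.**  Four controller states: *initial transient*
(cool at base rate `α`), *cooling phase* (accelerated, `α_cool`), *active
phase transition* (keep cooling at `α`), *phase transition reversal* (heat
at `α_heat`).  A moving average (window 5) of the batch mean crossing
above `μ_high` triggers the active transition, which persists `patience`
iterations — or ends early if the moving average falls below
`μ_high − σ_t`, a scale-aware operationalization of a rapid decline — then
reverses into heating; heating ends when the batch mean drops below
`μ_low`.  Defaults: `α = 0.90` (useful range roughly 0.87–0.94),
`α_heat = 1.5` (1.3–1.8), `α_cool = α³`, `patience = 5`, `T_0 = 1.5` on
the normalized-energy scale (near-uniform initial `q`), batch size 500,
200 iterations, `μ_high`/`μ_low` at the 90th/50th percentile of
single-mutant scores.  Set points are interpreted on the raw oracle score
scale.  The mixture over mutation counts defaults to an even blend of
2–6.

**Numerical choices.**  Temperatures are clipped to `[1e−4, 1e2]`
(configurable); softmaxes are computed with max-subtraction; after each
update `q` is floored at `1e−300` and renormalized, because at very low
temperature strict positivity is otherwise impossible in float64 (the
perturbation is ~1e−300 per component, far below sampling resolution).
Batch mean/variance use the population form over the sampled multiset
(duplicates counted with multiplicity), with variance clamped at zero.
One seeded generator drives k-choices then mutation draws, in that fixed
order, so runs replay bit-exactly; the moving-average buffer does not
reset on phase changes (config-exposed window).

## Synthetic landscapes

The additive landscape draws i.i.d. per-mutation effects
`a_m ~ N(−0.5, 1)` — most substitutions deleterious, a minority
beneficial, the gross shape of deep-mutational-scanning data — with
`f(ref) = 0` and `f(x) = f(ref) + Σ a_m`.  Its global optimum over `S_k`
is closed-form (top-k sites by site-best effect), giving an exact oracle
for optimizer recovery tests.  The epistatic landscape adds sparse
symmetric pairwise couplings (presence probability `density`, default
0.02; scale `coupling_sd`, default 0.5) realized by counter-based hashing
(SplitMix64) of the (seed, pair) key: scoring is O(k²) per variant with
no `M×M` storage, and serialization (seed + parameters + effect vector +
nonzero triplets) replays bit-exactly.

What these fixtures do *not* emulate: bounded/saturating scores (real
assay readouts and classifier-based fitness models saturate at both
ends), higher-order epistasis, and measurement noise.  Consequences are
discussed under the variance peak below; optimizer tests passing on these
landscapes demonstrate correct mechanics and search behavior, not
performance on any real protein task.

## Biphasic signatures

On default settings the controller settles into regular cooling/heating
oscillations (typically ~14 cycles in 200 iterations on the default
epistatic landscape).  The second signature — batch score variance
peaking at an intermediate temperature — depends on the score surface:
for an *unbounded* linear-epistatic landscape the hot-side variance
saturates at the random-sampling plateau rather than dropping, so the
dome only emerges when elite mutation combinations tower far enough above
the bulk that intermediate-temperature batches are elite/bulk mixtures
with variance exceeding that plateau.  The variance-peak check therefore
runs in the coupling-dominated regime (`density = 0.1`,
`coupling_sd = 2.0`, fixed `k = 4`) with `patience = 15` so cooling
overshoots deep enough to trace the cold side of the dome; set points
stay at their percentile defaults.  Fixed `k` is used because blending
mutation counts adds a between-k score spread that floors the cold-side
variance.

## Variational theory, verified exactly

On enumerable shells the package computes `p`, the KL-optimal product
`q*_m = (1/(kZ)) Σ_{x∈N_m} exp(f(x)/T)` (equivalently `P_p(m ∈ x)/k`,
which makes `Σ_m q*_m = 1` immediate), and the mean-field product
`q~_m ∝ exp(f_m/T)` with `f_m` the plain average over `N_m`.

**Conventions.**  KL divergences against product distributions use the
product form `q(x) = ∏ q_m` as-is over the site-constrained shell.  Its
total mass is ≤ 1/k!, so `KL(p‖q) ≥ 0` still holds for every product
distribution, `q*` is the exact minimizer, and the entropy bound
`k·H(q*) ≥ H(p)` *is* `KL(p‖q*) ≥ 0` — non-trivial precisely because the
product form is unnormalized (with equality at `k = 1`).  A separate
helper renormalizes the induced distribution when a genuine probability
over the shell is needed.  All logarithms are natural.  The neighborhood
`N_m` is enumerated inside the distinct-site shell, so its size is
`C(L−1, k−1)·19^(k−1)` rather than the nominal `C(M−1, k−1)` that ignores
site exclusivity; both counts are reported.

**Derivative identities.**  With `β = 1/T`:

    ∂β KL(p‖q*) = β σ_f² − k·Cov_{q*}(⟨f|m⟩_p, log q*_m)
    ∂β KL(p‖q~) = β (σ_f² − k·Cov_{q*}(⟨f|m⟩_p, f_m)) − k(⟨f_m⟩_{q*} − ⟨f_m⟩_{q~})

are checked against central finite differences of the exact KL in `β`
(relative step 1e−4); observed agreement is ~1e−8, against a test
tolerance of 1e−3.

**Low-temperature limit.**  The limit `∂β KL(p‖q*) → β(1−k)σ_f²`
(negative for `k > 1`) holds only when the runner-up sequence shares no
mutations with the optimum: a two-level expansion shows an overlapping
runner-up cancels the leading order exactly, leaving an indeterminate
sign, while a disjoint runner-up yields the stated limit (confirmed
numerically to ratio 1.000).  On short references with additive-dominated
landscapes the top variants typically share their best single mutation,
so the sign check is run on coupling-dominated instances
(`effect_sd = 0.3`, `density = 0.3`, `coupling_sd = 3.0`), where
near-optima are idiosyncratic combinations and the limit is robust.  For
long proteins disjoint near-optima are generic, so this is the regime the
asymptotics speak to.

## Ablations

Both ablations reuse the identical main loop with one strategy flag:
`pure_cooling` replaces the controller with monotone `T_{t+1} = αT_t`
(the simulated-annealing special case) and `static_energies` freezes `q`
at its post-initialization value.  On the default epistatic landscape
(L=30, k=3, 100 iterations, batch 200) frozen energies lose decisively
(top-100 mean ≈ 4.6 vs 6.6); pure cooling — which still updates energies —
trails by a small but consistent margin (≈0.01–0.04), winning occasional
(landscape, seed) pairs.  The directional claim (full ≥ each ablation in
≥4/5 seeds on a fixed landscape) held on every landscape seed probed.

## Problem sizes

Tests and the acceptance script use desk-scale instances chosen so every
ground truth is exact: L=30 references (M=570) for optimizer runs with
batches of 200 and 100–200 iterations; L=5–6 references for enumerated
shells (95–137,180 variants).  Shell enumeration and scoring are
vectorized over flat mutation-index matrices (~40 ms for the 68,590
variants of L=5, k=3).

## Known limitations

* The external-model oracle is a contract plus a cache; no protein
  language model or trained fitness predictor ships with the package, so
  claims about real design tasks are out of reach of the test suite by
  construction.
* Substitutions only — no insertions, deletions, or non-canonical
  residues.
* The low-temperature asymptotics and the variance-peak signature hold in
  regimes stated above, not universally; both validity conditions are
  documented rather than patched over.
* `μ_high`/`μ_low` percentile defaults collide on degenerate (constant
  score) landscapes; set them explicitly there.
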