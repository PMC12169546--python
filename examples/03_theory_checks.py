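"""Verify the variational theory behind the sampler by exact enumeration.

On a 6-residue reference the 2-mutation shell (5,415 sequences) can be
enumerated, so the Boltzmann distribution p, the KL-optimal product
distribution q*, and the mean-field product q~ are all exact.  This
checks, with no sampling anywhere: q* beats q~ and random product
distributions in KL divergence; k·H(q*) bounds H(p) from above; and the
closed-form beta-derivatives of both KL divergences match central finite
differences.
"""

import numpy as np

from badass import (
    ReferenceSequence,
    check_entropy_bound,
    exact_boltzmann,
    exact_optimal_product,
    kl_beta_derivative_check,
    kl_divergence,
    make_epistatic_landscape,
    mean_field_product,
    random_product_distribution,
)

ref = ReferenceSequence("ACDEFG", id="demo-theory")
landscape = make_epistatic_landscape(ref, seed=1)
rng = np.random.default_rng(0)

for T in (0.25, 1.0, 4.0):
    p = exact_boltzmann(landscape, ref, k=2, T=T)
    q_star = exact_optimal_product(p)
    q_mf = mean_field_product(landscape, ref, k=2, T=T, _shell=p).product
    kl_star = kl_divergence(p, q_star)
    kl_mf = kl_divergence(p, q_mf)
    kl_rand = min(
        kl_divergence(p, random_product_distribution(rng, ref.n_mutations, 2))
        for _ in range(50)
    )
    bound = check_entropy_bound(p, q_star)
    d8 = kl_beta_derivative_check(landscape, ref, 2, T, "q_star")
    d9 = kl_beta_derivative_check(landscape, ref, 2, T, "mean_field")
    print(f"T={T:5.2f}  KL(p||q*)={kl_star:.4f} <= KL(p||q~)={kl_mf:.4f} "
          f"<= best random {kl_rand:.4f}")
    print(f"         kH(q*)={bound.k_H_qstar:.4f} >= H(p)={bound.H_p:.4f}  "
          f"derivative rel. errors: q* {d8.relative_error:.1e}, "
          f"mean-field {d9.relative_error:.1e}")
# The KL ordering shows q* is the best product approximation of the
# Boltzmann target; the entropy bound equals KL(p||q*) >= 0 under the
# product convention; derivative errors near 1e-8 confirm the closed
# forms are exact, not approximations.
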