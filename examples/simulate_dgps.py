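"""Generate each synthetic process and summarize what it produces.

Run:  python examples/simulate_dgps.py
"""

import numpy as np

from shaplogit import (
    gen_epistasis_dgp,
    gen_interaction_dgp,
    gen_linear_dgp,
    gen_nonlinear_dgp,
)

n = 20_000

linear = gen_linear_dgp(n, seed=1)
print("linear logit       : P(Y=1) = %.3f  (X1 and the logistic noise are "
      "symmetric about 0, so prevalence sits at 1/2)" % linear.y.mean())

interval = gen_nonlinear_dgp(n, seed=1)
print("interval membership: P(Y=1) = %.3f  (interval lengths 3.5+1.5 over a "
      "support of 20 give 1/4)" % interval.y.mean())

inter = gen_interaction_dgp(n, beta=10.0, seed=1)
agree = (inter.y == (inter.X.sum(1) + 10.0 * inter.X[:, 2] * inter.X[:, 3] > 0)).mean()
print("product interaction: P(Y=1) = %.3f, labels match the closed-form rule "
      "1{sum X_i + beta*X3*X4 > 0} on %.0f%% of rows (deterministic given X)"
      % (inter.y.mean(), 100 * agree))

epi = gen_epistasis_dgp(n, n_noise_loci=18, heritability_noise=0.1, seed=1)
carrier = (epi.X[:, :2] >= 1).mean(axis=0)
print("two-locus epistasis: P(Y=1) = %.3f, causal carrier frequencies %.3f/%.3f"
      % (epi.y.mean(), carrier[0], carrier[1]))
for g in range(3):
    m = epi.y[epi.X[:, 0] == g].mean()
    print("    P(trait | causal_a = %d) = %.3f  (marginally flat: the signal "
          "lives only in the pair)" % (g, m))
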