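"""Accuracy of each model family as the interaction strengthens.

Sweeps the product-interaction coefficient beta over 0..10 on the
four-predictor process, averages held-out accuracy over replicate seeds,
and prints the smoothed curves: logistic regression decays with beta
while the forest stays flat. Run:  python examples/interaction_sweep.py
(about a minute on one CPU; shrink n or the seed count to go faster).
"""

import numpy as np

from shaplogit import interaction_sweep, smooth_curve

betas = np.arange(0.0, 10.5, 1.0)
result = interaction_sweep(betas, n_train=2000, n_test=2000, n_seeds=3,
                           base_seed=0)

print("beta   LR acc   DT acc   RF acc   (Savitzky-Golay smoothed, window 5)")
curves = {m: smooth_curve(result.mean_curve(m)[1], 5, 2) for m in ("lr", "dt", "rf")}
for i, beta in enumerate(betas):
    print(f"{beta:4.0f}   {curves['lr'][i]:.3f}    {curves['dt'][i]:.3f}    "
          f"{curves['rf'][i]:.3f}")
lr = curves["lr"]
print(f"\nLR accuracy falls by {lr[0] - lr[-1]:.3f} from beta=0 to beta=10; "
      "the tree families barely move — a missing product term hurts only "
      "the linear model.")
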