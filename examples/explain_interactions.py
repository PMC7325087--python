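"""Shapley interaction values of a forest, fast path vs brute force.

Fits a random forest to the four-predictor process with a strong X3*X4
product term, computes the per-sample interaction tensor with the
tree-path explainer, verifies a subsample against exhaustive coalition
enumeration, and prints the global ranking.
Run:  python examples/explain_interactions.py
"""

import numpy as np

from shaplogit import (
    BackgroundSet,
    exact_interactions,
    fit_random_forest,
    gen_interaction_dgp,
    rank_interactions,
    tree_interactions,
)

data = gen_interaction_dgp(4000, beta=10.0, seed=3)
forest = fit_random_forest(data, max_depth=5, min_samples_leaf=10, seed=0)
background = BackgroundSet.subsample(data.X, max_rows=64, seed=0)

tensor = tree_interactions(forest, data.X[:256], background)
ranking = rank_interactions(tensor, data.names)
print("global interaction ranking (sum of |per-sample attributions|):")
for a, b, score in ranking.entries:
    print(f"  {data.names[a]} x {data.names[b]:3s}  score = {score:7.3f}")
print("the X3 x X4 score dominates: that pair carries the simulated "
      "interaction\n")

oracle = exact_interactions(forest, data.X[:4], background)
fast = tree_interactions(forest, data.X[:4], background)
err = np.abs(oracle.values - fast.values).max()
print(f"tree-path explainer vs exhaustive enumeration on 4 rows: "
      f"max |difference| = {err:.2e} (identical up to float round-off)")
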