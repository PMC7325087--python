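"""When does logistic regression beat trees, and vice versa?

Fits L2 logistic regression, a decision tree and a random forest to the
linear-logit and interval-membership processes and prints held-out
accuracy. Run:  python examples/compare_model_families.py
"""

from shaplogit import (
    fit_decision_tree,
    fit_logistic,
    fit_random_forest,
    gen_linear_dgp,
    gen_nonlinear_dgp,
)

n = 10_000
for name, gen, note in (
    ("linear logit", gen_linear_dgp,
     "log-odds are linear in X1, so LR is the true model"),
    ("interval membership", gen_nonlinear_dgp,
     "discontinuous decision regions favour recursive partitioning"),
):
    train, test = gen(n, seed=10), gen(n, seed=11)
    lr, _ = fit_logistic(train)
    dt = fit_decision_tree(train, seed=0)
    rf = fit_random_forest(train, seed=0)
    accs = {
        label: 100 * (m.predict_label(test.X) == test.y).mean()
        for label, m in (("LR", lr), ("DT", dt), ("RF", rf))
    }
    print(f"{name:20s} LR {accs['LR']:5.1f}%  DT {accs['DT']:5.1f}%  "
          f"RF {accs['RF']:5.1f}%   <- {note}")
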