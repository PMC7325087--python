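"""Ranking, selection, design augmentation and the hybrid pipeline."""

import numpy as np
import pytest

from shaplogit.data import LabeledDataset
from shaplogit.exceptions import IntegrityError, InvalidArgumentError, SchemaError
from shaplogit.models import fit_logistic
from shaplogit.shapley import InteractionTensor
from shaplogit.simulate import gen_interaction_dgp
from shaplogit.transformer import (
    HybridConfig,
    InteractionRanking,
    augment_design,
    fit_hybrid,
    rank_interactions,
    select_pairs,
)

FAST = HybridConfig(n_trees=40, explain_rows=128, background_rows=32)


def _tensor(p, entries, n=2):
    """Symmetric n x p x p tensor from {(sample, a, b): value} entries."""
    V = np.zeros((n, p, p))
    for (i, a, b), val in entries.items():
        V[i, a, b] = V[i, b, a] = val
    return InteractionTensor(V)


def test_rank_interactions_hand_summed_scores():
    # |0.5| + |-0.5| doubled across the symmetric entries -> 2.0, and
    # 2 * (0.2 + 0.2) = 0.8
    t = _tensor(
        3,
        {(0, 0, 1): 0.5, (1, 0, 1): -0.5, (0, 0, 2): 0.2, (1, 0, 2): 0.2},
    )
    ranking = rank_interactions(t)
    assert ranking.entries == (
        (0, 1, pytest.approx(2.0)),
        (0, 2, pytest.approx(0.8)),
        (1, 2, pytest.approx(0.0)),
    )


def test_rank_interactions_zero_tensor_is_lexicographic():
    ranking = rank_interactions(_tensor(3, {}))
    assert ranking.pairs() == [(0, 1), (0, 2), (1, 2)]
    assert (ranking.scores() == 0).all()


def test_rank_interactions_is_homogeneous():
    t = _tensor(3, {(0, 0, 1): 0.5, (0, 1, 2): 0.1, (1, 0, 2): -0.3})
    base = rank_interactions(t)
    scaled = rank_interactions(InteractionTensor(3.0 * t.values))
    assert scaled.pairs() == base.pairs()
    np.testing.assert_allclose(scaled.scores(), 3.0 * base.scores())


def test_rank_interactions_rejects_asymmetry():
    V = np.zeros((1, 2, 2))
    V[0, 0, 1] = 1.0  # transpose entry left at 0
    with pytest.raises(IntegrityError):
        rank_interactions(InteractionTensor(V))


def _ranking(scores):
    entries = tuple((0, i + 1, s) for i, s in enumerate(scores))
    return InteractionRanking(entries)


def test_select_pairs_top_k_prefix_and_clamp():
    r = _ranking([2.0, 0.8, 0.1])
    assert select_pairs(r, k=1) == [(0, 1)]
    assert select_pairs(r, k=0) == []
    with pytest.warns(UserWarning):
        assert select_pairs(r, k=10) == r.pairs()


def test_select_pairs_elbow_finds_largest_ratio_gap():
    assert len(select_pairs(_ranking([10.0, 9.5, 0.4, 0.3]), strategy="elbow")) == 2
    assert select_pairs(_ranking([0.0, 0.0]), strategy="elbow") == []
    assert len(select_pairs(_ranking([1.0]), strategy="elbow")) == 1


def test_select_pairs_invalid_strategy():
    with pytest.raises(InvalidArgumentError):
        select_pairs(_ranking([1.0]), strategy="best")


def _toy(names=("a", "b", "c")):
    X = np.array([[2.0, 3.0, 1.0], [1.0, -1.0, 0.5], [0.0, 1.0, 2.0], [1.0, 1.0, 1.0]])
    return LabeledDataset(X, np.array([1, 0, 1, 0]), names)


def test_augment_design_appends_products_in_order():
    aug = augment_design(_toy(), [(0, 1), (0, 2)])
    assert aug.data.names == ("a", "b", "c", "a_x_b", "a_x_c")
    np.testing.assert_array_equal(aug.data.X[0], [2.0, 3.0, 1.0, 6.0, 2.0])
    np.testing.assert_array_equal(aug.data.X[:, :3], _toy().X)


def test_augment_design_empty_pairs_is_identity():
    data = _toy()
    aug = augment_design(data, [])
    assert aug.data is data


def test_augment_design_name_collision():
    with pytest.raises(SchemaError):
        augment_design(_toy(("a", "b", "a_x_b")), [(0, 1)])


def test_augment_design_rejects_bad_indices():
    with pytest.raises(InvalidArgumentError):
        augment_design(_toy(), [(0, 5)])


# ---------------------------------------------------------------------------
# Hybrid pipeline.

def test_hybrid_with_zero_pairs_equals_plain_logistic():
    train = gen_interaction_dgp(800, 5.0, 1)
    test = gen_interaction_dgp(800, 5.0, 2)
    res = fit_hybrid(train, test, config=FAST, k=0, seed=3)
    model, _ = fit_logistic(train, standardize=True)
    from shaplogit.evaluate import auroc

    assert res.test_auroc == auroc(test.y, model.predict_probability(test.X))


def test_hybrid_selects_true_pair_under_strong_interaction():
    train = gen_interaction_dgp(3000, 10.0, 11)
    test = gen_interaction_dgp(3000, 10.0, 12)
    res = fit_hybrid(train, test, config=FAST, k=1, seed=5)
    assert res.selected_pairs == ((2, 3),)
    assert res.selected_names == ("X3_x_X4",)
    assert (res.coefficients.odds_ratio > 0).all()


def test_hybrid_does_not_touch_test_rows():
    """No leakage: the test design is only extended by train-selected
    product columns; its original columns and outcome are untouched."""
    train = gen_interaction_dgp(1500, 8.0, 21)
    test = gen_interaction_dgp(700, 8.0, 22)
    X_before, y_before = test.X.copy(), test.y.copy()
    res = fit_hybrid(train, test, config=FAST, k=2, seed=1)
    np.testing.assert_array_equal(test.X, X_before)
    np.testing.assert_array_equal(test.y, y_before)
    assert len(res.augmented_names) == train.p + 2


def test_hybrid_is_equivariant_to_column_permutation():
    train = gen_interaction_dgp(2500, 10.0, 31)
    test = gen_interaction_dgp(2500, 10.0, 32)
    perm = np.array([3, 1, 0, 2])
    names_p = tuple(train.names[j] for j in perm)
    train_p = LabeledDataset(train.X[:, perm], train.y, names_p)
    test_p = LabeledDataset(test.X[:, perm], test.y, names_p)
    res = fit_hybrid(train, test, config=FAST, k=1, seed=9)
    res_p = fit_hybrid(train_p, test_p, config=FAST, k=1, seed=9)
    original = {tuple(sorted((train.names[a], train.names[b])))
                for a, b in res.selected_pairs}
    permuted = {tuple(sorted((names_p[a], names_p[b])))
                for a, b in res_p.selected_pairs}
    assert original == permuted == {("X3", "X4")}


def test_hybrid_uplift_grows_with_interaction_strength():
    """Mean (hybrid - plain LR) held-out accuracy is positive under a
    strong interaction and larger at beta=10 than at beta=2."""
    uplifts = {}
    for beta in (2.0, 6.0, 10.0):
        diffs = []
        for rep in range(6):
            train = gen_interaction_dgp(1500, beta, 500 + 2 * rep)
            test = gen_interaction_dgp(1500, beta, 501 + 2 * rep)
            res = fit_hybrid(train, test, config=FAST, k=1, seed=rep)
            lr, _ = fit_logistic(train, standardize=True)
            lr_acc = (lr.predict_label(test.X) == test.y).mean()
            diffs.append(res.test_accuracy - lr_acc)
        uplifts[beta] = float(np.mean(diffs))
    assert uplifts[6.0] > 0 and uplifts[10.0] > 0
    assert uplifts[10.0] > uplifts[2.0]


def test_top_pair_is_insensitive_to_explain_row_cap():
    """The subsample cap on the rows the tensor is computed from does not
    change which pair ranks first."""
    train = gen_interaction_dgp(3000, 10.0, 41)
    test = gen_interaction_dgp(3000, 10.0, 42)
    tops = set()
    for rows, bg in ((64, 16), (128, 32), (512, 64)):
        cfg = HybridConfig(n_trees=40, explain_rows=rows, background_rows=bg)
        res = fit_hybrid(train, test, config=cfg, k=1, seed=2)
        tops.add(res.selected_pairs[0])
    assert tops == {(2, 3)}


def test_hybrid_schema_mismatch():
    train = gen_interaction_dgp(100, 1.0, 1)
    bad = LabeledDataset(train.X, train.y, ("a", "b", "c", "d"))
    with pytest.raises(SchemaError):
        fit_hybrid(train, bad, config=FAST, k=1)
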