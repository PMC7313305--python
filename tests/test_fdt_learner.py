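import itertools
import math

import numpy as np
import pandas as pd
import pytest

from vitalwatch import (PlantedEmergency, TreeParams, extract_paths,
                        generate_training_fixture, learn_tree, predict, prune)
from vitalwatch.errors import ConfigError
from vitalwatch.prep import LabelledInstanceTable
from vitalwatch.tree import (DecisionTree, TreeNode, predict_frame,
                             training_error, tree_from_json, tree_to_json,
                             tree_to_text)

UNPRUNED = TreeParams(min_leaf=1, prune_fraction=0.0)


def table_of(data: dict, labels: list[str]) -> LabelledInstanceTable:
    frame = pd.DataFrame({**data, "label": labels})
    return LabelledInstanceTable(frame=frame,
                                 feature_columns=list(data.keys()))


# -- independent oracles ----------------------------------------------------

def entropy(labels) -> float:
    n = len(labels)
    out = 0.0
    for lab in set(labels):
        p = sum(1 for l in labels if l == lab) / n
        out -= p * math.log2(p)
    return out


def exhaustive_best_gain(columns, rows, labels) -> float:
    """Maximum information gain over every attribute and threshold."""
    best = 0.0
    h = entropy(labels)
    n = len(labels)
    for col in columns:
        vals = sorted({r[col] for r in rows})
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2
            left = [l for r, l in zip(rows, labels) if r[col] < thr]
            right = [l for r, l in zip(rows, labels) if r[col] >= thr]
            gain = h - (len(left) / n) * entropy(left) \
                - (len(right) / n) * entropy(right)
            best = max(best, gain)
    return best


def trace(node: TreeNode, row) -> str:
    """Independent recursive tracer for prediction cross-checks."""
    if node.kind == "leaf":
        return node.label
    v = row.get(node.attribute)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        supports = [c.support for c in node.children]
        return trace(node.children[supports.index(max(supports))], row)
    if node.kind == "real":
        return trace(node.children[0] if v < node.threshold
                     else node.children[1], row)
    if str(v) in node.values:
        return trace(node.children[node.values.index(str(v))], row)
    supports = [c.support for c in node.children]
    return trace(node.children[supports.index(max(supports))], row)


# -- growing ----------------------------------------------------------------

def test_uniform_labels_give_a_single_leaf():
    t = table_of({"x": list(range(10))}, ["NORMAL"] * 10)
    tree = learn_tree(t, UNPRUNED)
    assert tree.root.is_leaf
    assert tree.root.label == "NORMAL" and tree.root.support == 10


def test_one_dimensional_split_lands_between_the_classes():
    t = table_of({"x": [1.0, 1.5, 3.0, 4.0]}, ["A", "A", "B", "B"])
    tree = learn_tree(t, UNPRUNED)
    assert tree.root.kind == "real"
    assert 1.5 < tree.root.threshold < 3.0
    assert all(c.is_leaf and c.counts[c.label] == c.support
               for c in tree.root.children)


def test_zero_features_is_an_error():
    with pytest.raises(ConfigError):
        learn_tree(LabelledInstanceTable(
            frame=pd.DataFrame({"label": ["A"]}), feature_columns=[]))


def test_planted_two_condition_rule_is_learned_without_training_errors():
    em = PlantedEmergency("EMERGENCY",
                          (("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0)),
                          margin=0.2)
    t = generate_training_fixture(em, n_per_class=1000, seed=11)
    tree = learn_tree(t, UNPRUNED)
    assert training_error(tree, t) == 0


def test_root_split_gain_matches_exhaustive_search_on_small_tables():
    rng = np.random.default_rng(31)
    for _ in range(25):
        n = int(rng.integers(4, 13))
        cols = [f"f{j}" for j in range(int(rng.integers(1, 4)))]
        data = {c: list(np.round(rng.uniform(0, 10, size=n), 2))
                for c in cols}
        labels = [str(l) for l in rng.choice(["A", "B"], size=n)]
        if len(set(labels)) < 2:
            labels[0] = "A" if labels[0] == "B" else "B"
        t = table_of(data, labels)
        tree = learn_tree(t, UNPRUNED)
        rows = [dict(zip(cols, vals)) for vals in zip(*data.values())]
        best = exhaustive_best_gain(cols, rows, labels)
        if tree.root.is_leaf:
            assert best <= 1e-9
            continue
        col, thr = tree.root.attribute, tree.root.threshold
        left = [l for r, l in zip(rows, labels) if r[col] < thr]
        right = [l for r, l in zip(rows, labels) if r[col] >= thr]
        got = entropy(labels) - (len(left) / n) * entropy(left) \
            - (len(right) / n) * entropy(right)
        assert got == pytest.approx(best, abs=1e-9)


def test_learning_is_deterministic():
    em = PlantedEmergency("E", (("Perf", "<", 0.5),), margin=0.2)
    t = generate_training_fixture(em, n_per_class=300, noise_label_rate=0.05,
                                  seed=4)
    j1 = tree_to_json(learn_tree(t, TreeParams(seed=9)))
    j2 = tree_to_json(learn_tree(t, TreeParams(seed=9)))
    assert j1 == j2


def test_threshold_recovery_within_margin_band_over_twenty_seeds():
    """Planted thresholds are recovered inside the empty margin interval."""
    em = PlantedEmergency("EMERGENCY",
                          (("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0)),
                          margin=0.2)
    planted = {"Perf": 0.5, "NBP_Sys": 105.0}
    for seed in range(20):
        t = generate_training_fixture(em, n_per_class=1000, seed=seed)
        tree = learn_tree(t, TreeParams(min_leaf=1, prune_fraction=0.0,
                                        seed=seed))
        assert training_error(tree, t) == 0
        for path in extract_paths(tree, {"EMERGENCY"}):
            for attr, _op, c in path.conditions:
                assert attr in planted
                assert abs(c - planted[attr]) <= em.margin


# -- pruning ----------------------------------------------------------------

def test_single_leaf_tree_is_unchanged_by_pruning():
    t = table_of({"x": [1.0, 2.0]}, ["A", "A"])
    tree = learn_tree(t, UNPRUNED)
    pruned = prune(tree, t)
    assert tree_to_json(pruned) == tree_to_json(tree)


def test_subtree_overfit_to_noise_point_is_collapsed():
    # five A's and one stray B force an overfit split; a pruning set without
    # the stray point makes the collapsed majority leaf at least as good
    train = table_of({"x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
                     ["A", "A", "A", "A", "A", "B"])
    tree = learn_tree(train, UNPRUNED)
    assert not tree.root.is_leaf
    pruning = table_of({"x": [1.5, 2.5, 5.5, 6.5]}, ["A", "A", "A", "A"])
    pruned = prune(tree, pruning)
    assert pruned.root.is_leaf and pruned.root.label == "A"


def test_pruning_never_increases_pruning_set_error():
    rng = np.random.default_rng(77)
    for _ in range(10):
        n = int(rng.integers(20, 60))
        data = {"a": list(rng.uniform(0, 10, n)),
                "b": list(rng.uniform(0, 10, n))}
        labels = [str(l) for l in rng.choice(["X", "Y"], size=n)]
        t = table_of(data, labels)
        tree = learn_tree(t, UNPRUNED)
        m = int(rng.integers(5, 20))
        pdata = {"a": list(rng.uniform(0, 10, m)),
                 "b": list(rng.uniform(0, 10, m))}
        plabels = [str(l) for l in rng.choice(["X", "Y"], size=m)]
        pset = table_of(pdata, plabels)
        pruned = prune(tree, pset)
        assert training_error(pruned, pset) <= training_error(tree, pset)


def test_empty_pruning_set_returns_tree_unchanged():
    t = table_of({"x": [1.0, 2.0, 3.0, 4.0]}, ["A", "A", "B", "B"])
    tree = learn_tree(t, UNPRUNED)
    empty = LabelledInstanceTable(
        frame=pd.DataFrame({"x": pd.Series(dtype=float),
                            "label": pd.Series(dtype=object)}),
        feature_columns=["x"])
    assert tree_to_json(prune(tree, empty)) == tree_to_json(tree)


# -- prediction -------------------------------------------------------------

def test_single_leaf_predicts_its_label_for_anything():
    t = table_of({"x": [0.0]}, ["A"])
    tree = learn_tree(t, UNPRUNED)
    assert predict(tree, {"x": 123.0}) == "A"
    assert predict(tree, {"x": float("nan")}) == "A"


def test_boundary_value_routes_to_the_geq_branch():
    t = table_of({"x": [1.0, 1.5, 3.0, 4.0]}, ["A", "A", "B", "B"])
    tree = learn_tree(t, UNPRUNED)
    assert predict(tree, {"x": tree.root.threshold}) == "B"


def test_missing_value_routes_to_larger_support_child():
    t = table_of({"x": [1.0, 1.5, 2.0, 3.0, 4.0]}, ["A", "A", "A", "B", "B"])
    tree = learn_tree(t, UNPRUNED)
    assert predict(tree, {"x": float("nan")}) == "A"


def test_prediction_agrees_with_independent_tracer():
    em = PlantedEmergency("E", (("Perf", "<", 0.5), ("Temp", ">", 38.5)),
                          margin=0.2)
    t = generate_training_fixture(em, n_per_class=200, noise_label_rate=0.1,
                                  seed=3)
    tree = learn_tree(t, TreeParams(min_leaf=2, prune_fraction=0.25, seed=3))
    rng = np.random.default_rng(8)
    for _ in range(100):
        row = {c: (float("nan") if rng.random() < 0.15
                   else float(rng.uniform(-5, 130)))
               for c in t.feature_columns}
        assert predict(tree, row) == trace(tree.root, row)


# -- path extraction --------------------------------------------------------

def _manual_tree():
    leaf_e = TreeNode("leaf", {"E": 30}, 30, label="E")
    leaf_n1 = TreeNode("leaf", {"N": 10}, 10, label="N")
    inner = TreeNode("real", {"E": 30, "N": 10}, 40, attribute="x",
                     threshold=3.0, children=[leaf_e, leaf_n1])
    leaf_n2 = TreeNode("leaf", {"N": 60}, 60, label="N")
    root = TreeNode("real", {"E": 30, "N": 70}, 100, attribute="x",
                    threshold=5.0, children=[inner, leaf_n2])
    return DecisionTree(root=root, feature_columns=["x"],
                        feature_kinds={"x": "real"}, params=TreeParams(),
                        labels=["E", "N"])


def test_repeated_bounds_on_one_attribute_are_simplified():
    paths = extract_paths(_manual_tree(), {"E"})
    assert len(paths) == 1
    # x < 5 then x < 3 collapses to the tighter x < 3
    assert paths[0].conditions == [("x", "<", 3.0)]
    assert paths[0].support == 30 and paths[0].purity == 1.0


def test_min_support_larger_than_n_gives_empty_list():
    assert extract_paths(_manual_tree(), {"E"}, min_support=1000) == []


def test_planted_rule_path_implies_the_planted_region():
    em = PlantedEmergency("EMERGENCY",
                          (("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0)),
                          margin=0.2)
    t = generate_training_fixture(em, n_per_class=1000, seed=11)
    tree = learn_tree(t, UNPRUNED)
    paths = extract_paths(tree, {"EMERGENCY"})
    assert len(paths) == 1
    conds = {a: (op, c) for a, op, c in paths[0].conditions}
    # every labelled point satisfies the planted predicate by construction;
    # the extracted conditions must carve a region inside the margin band
    for sign, planted_c in (("Perf", 0.5), ("NBP_Sys", 105.0)):
        op, c = conds[sign]
        assert op == "<"
        assert planted_c - em.margin <= c <= planted_c + em.margin


def test_paths_are_sorted_by_support_descending():
    paths = extract_paths(_manual_tree())
    assert [p.support for p in paths] == sorted(
        (p.support for p in paths), reverse=True)


# -- serialization ----------------------------------------------------------

def test_tree_json_round_trip_is_lossless():
    em = PlantedEmergency("E", (("Perf", "<", 0.5),), margin=0.2)
    t = generate_training_fixture(em, n_per_class=100, seed=2)
    tree = learn_tree(t, TreeParams(seed=2))
    back = tree_from_json(tree_to_json(tree))
    assert tree_to_json(back) == tree_to_json(tree)
    assert predict_frame(back, t.frame) == predict_frame(tree, t.frame)


def test_text_rendering_mentions_split_and_leaves():
    t = table_of({"x": [1.0, 1.5, 3.0, 4.0]}, ["A", "A", "B", "B"])
    text = tree_to_text(learn_tree(t, UNPRUNED))
    assert "x <" in text and ": A" in text and ": B" in text


# -- reference-library cross-check ------------------------------------------

def test_separable_fixture_agrees_with_reference_entropy_tree():
    sklearn = pytest.importorskip("sklearn.tree")
    em = PlantedEmergency("EMERGENCY",
                          (("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0)),
                          margin=0.2)
    t = generate_training_fixture(em, n_per_class=500, seed=13)
    ours = learn_tree(t, UNPRUNED)
    assert training_error(ours, t) == 0
    X = t.features.to_numpy()
    y = t.labels.to_numpy()
    ref = sklearn.DecisionTreeClassifier(criterion="entropy", random_state=0)
    ref.fit(X, y)
    assert (ref.predict(X) == y).all()
    # identical training predictions on the separable fixture
    assert (np.array(predict_frame(ours, t.frame)) == ref.predict(X)).all()
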