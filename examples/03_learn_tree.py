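"""Learn a decision tree from a planted-rule fixture and extract its rule.

The fixture is separable with a margin of 0.2 around each planted
threshold, so the tree reaches zero training errors and the recovered
thresholds land inside the margin bands (0.3..0.7 for Perf, 104.8..105.2
for NBP_Sys).
"""

from vitalwatch import (PlantedEmergency, TreeParams, extract_paths,
                        generate_training_fixture, learn_tree)
from vitalwatch.tree import training_error, tree_to_text

planted = PlantedEmergency(
    label="EMERGENCY",
    predicate=(("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0)), margin=0.2)
table = generate_training_fixture(planted, n_per_class=1000, seed=11)

tree = learn_tree(table, TreeParams(min_leaf=1, prune_fraction=0.0))
print(tree_to_text(tree))
print("\ntraining errors:", training_error(tree, table))
for path in extract_paths(tree, {"EMERGENCY"}, min_support=30,
                          min_purity=0.95):
    conds = " and ".join(f"{a} {op} {c:g}" for a, op, c in path.conditions)
    print(f"extracted path: {conds}  "
          f"(support={path.support}, purity={path.purity:.2f})")
# The printed conjunction is the candidate alarm rule; each condition also
# defines a per-sign abnormal-range axiom (e.g. PerfAN = real < threshold).
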