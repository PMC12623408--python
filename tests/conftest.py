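import numpy as np
import pandas as pd
import pytest

from cellpair.expr_io import ExpressionMatrix
from cellpair.pair_rules import evaluate_rules, generate_rules
from cellpair.rule_forest import train_forest
from cellpair.simulate import SimulationConfig, simulate_bulk


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 3-class, 2-study cohort for unit tests."""
    cfg = SimulationConfig(
        seed=7,
        n_classes=3,
        n_genes=120,
        n_markers_per_class=6,
        n_samples_per_class=(12, 20, 10),
        n_studies=2,
    )
    expr, ann, profiles = simulate_bulk(cfg)
    return cfg, expr, ann, profiles


@pytest.fixture(scope="session")
def separable_rule_matrix():
    """A linearly separable binary rule matrix over three classes.

    Each class has two indicator rules that are 1 exactly on its samples,
    plus a handful of noise rules.
    """
    rng = np.random.default_rng(0)
    n_per = 12
    labels = ["a"] * n_per + ["b"] * n_per + ["c"] * n_per
    n = len(labels)
    cols = []
    rules = []
    for ci, cls in enumerate(("a", "b", "c")):
        ind = np.array([1 if l == cls else 0 for l in labels], dtype=np.uint8)
        for j in range(2):
            cols.append(ind)
            rules.append((f"{cls.upper()}{j}x", f"{cls.upper()}{j}y"))
    for j in range(4):
        cols.append(rng.integers(0, 2, n).astype(np.uint8))
        rules.append((f"N{j}x", f"N{j}y"))
    X = np.column_stack(cols)
    sids = [f"s{i}" for i in range(n)]
    ann = pd.DataFrame({"sample_id": sids, "class_label": labels, "study_id": "x"})
    from cellpair.pair_rules import RuleMatrix

    return RuleMatrix(X, rules, sids), ann


@pytest.fixture(scope="session")
def tiny_model(small_cohort):
    """A small trained forest plus its training rule matrix and annotation."""
    cfg, expr, ann, profiles = small_cohort
    marker_genes = sorted({g for p in profiles.values() for g in p.marker_genes})
    rules = generate_rules(marker_genes[:16])
    rm = evaluate_rules(expr, rules)
    model = train_forest(rm, ann, n_trees=200, seed=3)
    return model, rm, ann, expr
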