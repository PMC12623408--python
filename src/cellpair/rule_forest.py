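"""Boruta pruning, the rule forest itself, prediction and proximity.

The classifier is a bagging ensemble of CART trees over binary gene-pair
rule features.  Class scores are tree-vote fractions (the fraction of trees
whose leaf majority is each class), so every score row sums to exactly 1.
Per-tree bootstrap (in-bag) membership is retained for out-of-bag
self-assessment and the proximity matrix, and the whole model serializes to
a single JSON document whose round-trip reproduces predictions bit-exactly.

Prediction tolerates missing genes: a rule whose genes are absent from the
query matrix is imputed from the training rule matrix (stored in the model),
up to a configurable missing fraction.  The default imputation takes the
majority value among the k training samples nearest to the query in Hamming
distance over the rules that *are* evaluable; a plain training-majority fill
is available but is biased toward the largest training class when most rules
are missing, because the all-majority rule vector is essentially that class's
archetype.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .expr_io import ExpressionMatrix
from .pair_rules import Rule, RuleMatrix, RuleRanking, select_rules

__all__ = [
    "BorutaResult",
    "TrainedRuleForest",
    "PredictionScores",
    "boruta_prune",
    "train_forest",
    "predict_scores",
    "predict_on_rule_matrix",
    "proximity_matrix",
    "optimize_parameters",
    "oob_scores",
]

MODEL_FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# Boruta-style shadow-feature pruning
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BorutaResult:
    kept_rules: list[Rule]
    verdicts: dict[str, str]  # "A<B" -> confirmed | tentative | rejected


def boruta_prune(
    rm: RuleMatrix,
    ann: pd.DataFrame,
    max_iterations: int = 25,
    alpha: float = 0.01,
    n_trees: int = 300,
    seed: int = 0,
) -> BorutaResult:
    """Reject rules whose importance never beats their own shuffled shadow.

    Each iteration appends a column-shuffled copy of every undecided feature,
    fits an importance forest, and scores a "hit" for features exceeding the
    maximum shadow importance.  Hit counts are tested against Binomial(k, ½)
    two-sidedly at ``alpha`` with Bonferroni correction: significantly many
    hits confirms a feature, significantly few rejects it.  Features still
    undecided after ``max_iterations`` are tentative and kept.
    """
    from .pair_rules import _check_classes

    y = _check_classes(ann, rm.sample_ids).to_numpy()
    names = [f"{a}<{b}" for a, b in rm.rules]
    n_feat = len(names)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    active = np.ones(n_feat, dtype=bool)
    hits = np.zeros(n_feat, dtype=int)
    verdict = np.array(["tentative"] * n_feat, dtype=object)
    X_full = rm.X.astype(np.float32)
    for it in range(1, max_iterations + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        X = X_full[:, idx]
        shadow = X.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        X_aug = np.hstack([X, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(X_aug, y)
        imp = rf.feature_importances_
        real, sh = imp[: idx.size], imp[idx.size :]
        thresh = sh.max() if sh.size else 0.0
        hits[idx] += (real > thresh).astype(int)
        # two-sided binomial test with Bonferroni over the active features
        bound = alpha / max(n_feat, 1)
        k = hits[idx]
        p_hi = scipy.stats.binom.sf(k - 1, it, 0.5)  # P(X >= k)
        p_lo = scipy.stats.binom.cdf(k, it, 0.5)  # P(X <= k)
        confirmed = p_hi < bound
        rejected = p_lo < bound
        verdict[idx[confirmed]] = "confirmed"
        verdict[idx[rejected]] = "rejected"
        active[idx[confirmed | rejected]] = False
    kept = [r for r, v in zip(rm.rules, verdict) if v != "rejected"]
    if not kept:
        raise ValueError(
            "Boruta rejected every rule; the rule set carries no class signal"
        )
    return BorutaResult(kept, dict(zip(names, verdict)))


# ---------------------------------------------------------------------------
# The bagged rule forest
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PredictionScores:
    """Per-sample class score rows (tree-vote fractions summing to 1)."""

    scores: pd.DataFrame  # samples x classes
    imputed_rule_counts: pd.Series  # per sample

    def __post_init__(self) -> None:
        rs = self.scores.to_numpy().sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("score rows must sum to 1")


@dataclasses.dataclass
class _Tree:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray  # -2 at leaves (sklearn convention)
    leaf_class: np.ndarray  # class index at leaves, -1 internally

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node index per row, for binary features (split at 0.5)."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feat = self.feature[node]
            internal = feat >= 0
            if not internal.any():
                return node
            rows = np.flatnonzero(internal)
            cur = node[rows]
            go_left = X[rows, feat[rows]] <= 0.5
            node[rows] = np.where(
                go_left, self.children_left[cur], self.children_right[cur]
            )

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        return self.leaf_class[self.apply(X)]


def _tree_from_sklearn(dt: DecisionTreeClassifier, classes: np.ndarray, all_classes: list[str]) -> _Tree:
    t = dt.tree_
    leaf_class = np.full(t.node_count, -1, dtype=np.int64)
    leaves = t.children_left == -1
    # map the tree's local class order back to the model's global class list
    local = np.asarray(dt.classes_)
    votes = t.value[leaves, 0, :]
    local_best = votes.argmax(axis=1)
    global_idx = np.array([all_classes.index(str(c)) for c in local])
    leaf_class[leaves] = global_idx[local_best]
    return _Tree(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        leaf_class=leaf_class,
    )


@dataclasses.dataclass
class TrainedRuleForest:
    """A serializable bagged forest over binary gene-pair rules."""

    rules: list[Rule]
    classes: list[str]
    trees: list[_Tree]
    inbag_counts: np.ndarray  # n_trees x n_train, bootstrap multiplicities
    train_majority: np.ndarray  # per-rule majority value over training samples
    train_X: np.ndarray  # training rule matrix (n_train x n_rules), for kNN imputation
    train_sample_ids: list[str]
    metadata: dict
    version: str = MODEL_FORMAT_VERSION

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def rule_genes(self) -> set[str]:
        return {g for r in self.rules for g in r}

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format_version": self.version,
            "classes": self.classes,
            "rules": [list(r) for r in self.rules],
            "train_majority": self.train_majority.astype(int).tolist(),
            "train_X": self.train_X.astype(int).tolist(),
            "train_sample_ids": self.train_sample_ids,
            "inbag_counts": self.inbag_counts.astype(int).tolist(),
            "metadata": self.metadata,
            "trees": [
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "leaf_class": t.leaf_class.tolist(),
                }
                for t in self.trees
            ],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "TrainedRuleForest":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or (len(str(source)) < 4096 and Path(str(source)).exists())
            else str(source)
        )
        doc = json.loads(text)
        trees = [
            _Tree(
                children_left=np.array(d["children_left"], dtype=np.int64),
                children_right=np.array(d["children_right"], dtype=np.int64),
                feature=np.array(d["feature"], dtype=np.int64),
                leaf_class=np.array(d["leaf_class"], dtype=np.int64),
            )
            for d in doc["trees"]
        ]
        return TrainedRuleForest(
            rules=[tuple(r) for r in doc["rules"]],
            classes=list(doc["classes"]),
            trees=trees,
            inbag_counts=np.array(doc["inbag_counts"], dtype=np.int64),
            train_majority=np.array(doc["train_majority"], dtype=np.uint8),
            train_X=np.array(doc["train_X"], dtype=np.uint8),
            train_sample_ids=list(doc["train_sample_ids"]),
            metadata=doc.get("metadata", {}),
            version=doc.get("format_version", MODEL_FORMAT_VERSION),
        )


def train_forest(
    rm: RuleMatrix,
    ann: pd.DataFrame,
    n_trees: int = 1000,
    class_weights: str = "inverse_frequency",
    probability: bool = True,
    seed: int = 0,
) -> TrainedRuleForest:
    """Train the bagged rule forest.

    Each tree is fit on a bootstrap of the training samples (multiplicities
    retained for out-of-bag bookkeeping) with ``sqrt`` feature subsampling;
    ``inverse_frequency`` reweights samples by 1/(class size).  Deterministic
    for a fixed seed.
    """
    from .pair_rules import _check_classes

    if class_weights not in ("none", "inverse_frequency"):
        raise ValueError(f"unknown class_weights {class_weights!r}")
    y = _check_classes(ann, rm.sample_ids)
    classes = sorted(y.unique())
    yarr = y.to_numpy()
    n = len(yarr)
    if class_weights == "inverse_frequency":
        freq = y.value_counts()
        base_w = np.array([1.0 / freq[c] for c in yarr])
    else:
        base_w = np.ones(n)
    X = rm.X.astype(np.float32)
    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.generate_state(2 * n_trees) % (2**31)
    trees: list[_Tree] = []
    inbag = np.zeros((n_trees, n), dtype=np.int64)
    for t in range(n_trees):
        rng = np.random.default_rng(int(tree_seeds[2 * t]))
        idx = rng.integers(0, n, n)
        counts = np.bincount(idx, minlength=n)
        inbag[t] = counts
        sw = counts * base_w
        dt = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(tree_seeds[2 * t + 1])
        )
        dt.fit(X, yarr, sample_weight=sw)
        trees.append(_tree_from_sklearn(dt, np.array(classes), classes))
    majority = (rm.X.mean(axis=0) >= 0.5).astype(np.uint8)
    meta = {
        "seed": int(seed),
        "n_trees": int(n_trees),
        "class_weights": class_weights,
        "probability": bool(probability),
        "n_train_samples": int(n),
        "class_counts": {c: int((yarr == c).sum()) for c in classes},
    }
    return TrainedRuleForest(
        rules=list(rm.rules),
        classes=classes,
        trees=trees,
        inbag_counts=inbag,
        train_majority=majority,
        train_X=rm.X.astype(np.uint8),
        train_sample_ids=list(rm.sample_ids),
        metadata=meta,
    )


def _vote_scores(model: TrainedRuleForest, X: np.ndarray) -> np.ndarray:
    votes = np.zeros((X.shape[0], len(model.classes)), dtype=np.int64)
    for tree in model.trees:
        pred = tree.predict_class(X)
        votes[np.arange(X.shape[0]), pred] += 1
    return votes / model.n_trees


def predict_on_rule_matrix(model: TrainedRuleForest, rm: RuleMatrix) -> PredictionScores:
    """Score samples whose rule matrix is already evaluated (no imputation)."""
    rm = rm.subset(model.rules)
    scores = _vote_scores(model, rm.X.astype(np.float32))
    return PredictionScores(
        pd.DataFrame(scores, index=rm.sample_ids, columns=model.classes),
        pd.Series(0, index=rm.sample_ids, name="imputed_rule_count"),
    )


def predict_scores(
    model: TrainedRuleForest,
    m: ExpressionMatrix,
    missing_policy: str = "impute_knn",
    max_missing_fraction: float = 0.75,
    n_neighbors: int = 5,
) -> PredictionScores:
    """Score new samples, imputing rules whose genes are absent.

    A rule is evaluable when both its genes are present in ``m``.  Missing
    rules are imputed per sample under ``impute_knn`` (majority value among
    the ``n_neighbors`` training samples nearest in Hamming distance over the
    evaluable rules — neutral to class imbalance) or ``impute_majority``
    (global training-majority fill).  Prediction is refused when more than
    ``max_missing_fraction`` of rules are missing.
    """
    if missing_policy not in ("impute_knn", "impute_majority", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    present = set(m.gene_ids)
    evaluable = np.array([a in present and b in present for a, b in model.rules])
    miss_frac = 1.0 - evaluable.mean()
    if miss_frac > 0 and missing_policy == "error":
        absent = sorted({g for r in model.rules for g in r if g not in present})
        raise ValueError(f"missing rule genes and missing_policy='error': {absent[:10]}")
    if miss_frac > max_missing_fraction:
        raise ValueError(
            f"{miss_frac:.1%} of rules are missing, above the "
            f"{max_missing_fraction:.0%} cap"
        )
    n_samp = m.n_samples
    X = np.tile(model.train_majority.astype(np.float32), (n_samp, 1))
    ev = np.flatnonzero(evaluable)
    if evaluable.any():
        index = {g: i for i, g in enumerate(m.gene_ids)}
        vals = m.values.to_numpy()
        ia = np.array([index[model.rules[j][0]] for j in ev])
        ib = np.array([index[model.rules[j][1]] for j in ev])
        X[:, ev] = (vals[ia, :] < vals[ib, :]).T.astype(np.float32)
    mi = np.flatnonzero(~evaluable)
    if mi.size and missing_policy == "impute_knn" and ev.size:
        train_ev = model.train_X[:, ev].astype(np.float32)
        train_mi = model.train_X[:, mi].astype(np.float32)
        k = min(n_neighbors, train_ev.shape[0])
        for s in range(n_samp):
            dist = np.abs(train_ev - X[s, ev]).sum(axis=1)
            nn = np.argsort(dist, kind="stable")[:k]
            filled = train_mi[nn].mean(axis=0)
            # neighbour ties at 0.5 fall back to the global training majority
            X[s, mi] = np.where(
                filled == 0.5, model.train_majority[mi], (filled > 0.5).astype(float)
            )
    scores = _vote_scores(model, X)
    n_imputed = int((~evaluable).sum())
    return PredictionScores(
        pd.DataFrame(scores, index=m.sample_ids, columns=model.classes),
        pd.Series(n_imputed, index=m.sample_ids, name="imputed_rule_count"),
    )


def oob_scores(model: TrainedRuleForest, rm: RuleMatrix) -> pd.DataFrame:
    """Out-of-bag vote fractions for the training samples.

    For each sample only the trees whose bootstrap excluded it vote; samples
    that are in-bag for every tree get a zero row (flagged by NaN-free zeros).
    """
    rm = rm.subset(model.rules)
    if rm.sample_ids != model.train_sample_ids:
        raise ValueError("rule matrix does not match the training samples")
    X = rm.X.astype(np.float32)
    n = X.shape[0]
    votes = np.zeros((n, len(model.classes)), dtype=float)
    n_oob = np.zeros(n, dtype=int)
    for t, tree in enumerate(model.trees):
        oob = model.inbag_counts[t] == 0
        if not oob.any():
            continue
        pred = tree.predict_class(X[oob])
        votes[np.flatnonzero(oob), pred] += 1
        n_oob[oob] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_oob[:, None] > 0, votes / np.maximum(n_oob, 1)[:, None], 0.0)
    return pd.DataFrame(frac, index=rm.sample_ids, columns=model.classes)


def oob_balanced_accuracy(model: TrainedRuleForest, rm: RuleMatrix, ann: pd.DataFrame) -> float:
    """Macro-averaged out-of-bag recall over classes."""
    from .pair_rules import _check_classes

    y = _check_classes(ann, rm.sample_ids)
    frac = oob_scores(model, rm)
    pred = frac.idxmax(axis=1)
    recalls = []
    for cls in model.classes:
        mask = y == cls
        if mask.any():
            recalls.append((pred[mask.to_numpy()] == cls).mean())
    return float(np.mean(recalls))


def proximity_matrix(
    model: TrainedRuleForest, rm: RuleMatrix, mode: str = "oob"
) -> pd.DataFrame:
    """Random-Forest proximity: fraction of trees co-locating two samples.

    ``oob`` counts a tree for a pair only when both samples are out-of-bag in
    it (requires ``rm`` to be the training matrix); ``all`` uses every tree.
    The diagonal is 1 by definition.
    """
    if mode not in ("oob", "all"):
        raise ValueError(f"unknown proximity mode {mode!r}")
    rm = rm.subset(model.rules)
    X = rm.X.astype(np.float32)
    n = X.shape[0]
    same = np.zeros((n, n), dtype=float)
    denom = np.zeros((n, n), dtype=float)
    use_oob = mode == "oob"
    if use_oob and rm.sample_ids != model.train_sample_ids:
        raise ValueError("oob proximity requires the training rule matrix")
    for t, tree in enumerate(model.trees):
        leaves = tree.apply(X)
        co = leaves[:, None] == leaves[None, :]
        if use_oob:
            oob = model.inbag_counts[t] == 0
            both = oob[:, None] & oob[None, :]
            same += co & both
            denom += both
        else:
            same += co
            denom += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prox = np.where(denom > 0, same / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(prox, 1.0)
    prox = (prox + prox.T) / 2
    return pd.DataFrame(prox, index=rm.sample_ids, columns=rm.sample_ids)


# ---------------------------------------------------------------------------
# Parameter optimization
# ---------------------------------------------------------------------------


def optimize_parameters(
    ranking: RuleRanking,
    rm_full: RuleMatrix,
    ann: pd.DataFrame,
    grid: Mapping[str, Sequence],
    seed: int = 0,
    boruta_kwargs: dict | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search scored by out-of-bag balanced accuracy.

    Grid keys: ``gene_repetition_cap``, ``n_rules_altogether``,
    ``n_rules_per_class``, ``boruta`` (bool), ``n_trees``.  Ties break toward
    fewer selected rules, then fewer trees.
    """
    defaults = {
        "gene_repetition_cap": [1],
        "n_rules_altogether": [100],
        "n_rules_per_class": [100],
        "boruta": [True],
        "n_trees": [1000],
    }
    unknown = set(grid) - set(defaults)
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    full = {**defaults, **{k: list(v) for k, v in grid.items()}}
    if any(len(v) == 0 for v in full.values()):
        raise ValueError("grid values must be non-empty")
    keys = list(full)
    rows = []
    best = None
    for combo in itertools.product(*(full[k] for k in keys)):
        params = dict(zip(keys, combo))
        sel = select_rules(
            ranking,
            n_altogether=params["n_rules_altogether"],
            n_per_class=params["n_rules_per_class"],
            gene_repetition_cap=params["gene_repetition_cap"],
        )
        rm = rm_full.subset(sel.rules)
        if params["boruta"]:
            kept = boruta_prune(rm, ann, seed=seed, **(boruta_kwargs or {}))
            rm = rm.subset(kept.kept_rules)
        model = train_forest(rm, ann, n_trees=params["n_trees"], seed=seed)
        score = oob_balanced_accuracy(model, rm, ann)
        rows.append({**params, "n_final_rules": len(rm.rules), "oob_balanced_accuracy": score})
        key = (-score, len(rm.rules), params["n_trees"])
        if best is None or key < best[0]:
            best = (key, params)
    table = pd.DataFrame(rows)
    return dict(best[1]), table
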