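"""Gene ranking, gene-pair rule generation, evaluation and selection.

A rule is the binary within-sample statement "expression(gene_a) <
expression(gene_b)".  Because it only compares values inside one sample, a
rule's value is invariant to any strictly increasing transform applied to
that sample — the property that lets matrices from different platforms be
merged without normalization.

Ranking uses an impurity-importance Random Forest on within-sample gene
ranks, under two schemes: "altogether" (all classes jointly) and
"one-vs-rest" (one binary model per class).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier

from .expr_io import ExpressionMatrix

__all__ = [
    "GeneRanking",
    "RuleMatrix",
    "RuleRanking",
    "RuleSelection",
    "rank_genes",
    "select_top_genes",
    "generate_rules",
    "evaluate_rules",
    "rank_rules",
    "select_rules",
]

Rule = tuple[str, str]

SCHEMES = ("altogether", "one_vs_rest", "both")


@dataclasses.dataclass
class GeneRanking:
    """Importance-ranked genes under one or both ranking schemes."""

    altogether: pd.Series | None = None  # gene -> importance, sorted desc
    per_class: dict[str, pd.Series] | None = None


@dataclasses.dataclass
class RuleMatrix:
    """Binary samples x rules matrix of evaluated gene-pair rules."""

    X: np.ndarray  # uint8, samples x rules
    rules: list[Rule]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.sample_ids), len(self.rules)):
            raise ValueError("rule matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X,
            index=self.sample_ids,
            columns=[f"{a}<{b}" for a, b in self.rules],
        )

    def subset(self, rules: Sequence[Rule]) -> "RuleMatrix":
        pos = {r: i for i, r in enumerate(self.rules)}
        missing = [r for r in rules if r not in pos]
        if missing:
            raise KeyError(f"rules absent from matrix: {missing[:5]}")
        idx = [pos[r] for r in rules]
        return RuleMatrix(self.X[:, idx], list(rules), self.sample_ids)


@dataclasses.dataclass
class RuleRanking:
    altogether: pd.Series | None = None  # index "A<B" -> importance
    per_class: dict[str, pd.Series] | None = None


@dataclasses.dataclass
class RuleSelection:
    """Chosen rules with provenance and the gene-repetition cap applied."""

    rules: list[Rule]
    provenance: pd.DataFrame  # columns: gene_a, gene_b, scheme, class, rank, importance
    gene_repetition_cap: float

    def __post_init__(self) -> None:
        # the diversity cap holds within each ranked list (scheme, class);
        # distinct lists may legitimately reuse a gene
        for (_, _), grp in self.provenance.groupby(["scheme", "class"], dropna=False):
            counts: dict[str, int] = {}
            for a, b in zip(grp["gene_a"], grp["gene_b"]):
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            over = {g: c for g, c in counts.items() if c > self.gene_repetition_cap}
            if over:
                raise ValueError(f"gene repetition cap violated: {over}")

    def to_tsv(self, path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path) -> "RuleSelection":
        df = pd.read_csv(path, sep="\t")
        rules = list(zip(df["gene_a"], df["gene_b"]))
        cap = float(df["gene_repetition_cap"].iloc[0]) if "gene_repetition_cap" in df else np.inf
        return RuleSelection(rules, df, cap)


def _check_classes(ann: pd.DataFrame, sample_ids: Sequence[str]) -> pd.Series:
    lab = ann.set_index("sample_id")["class_label"]
    missing = [s for s in sample_ids if s not in lab.index]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    y = lab.loc[list(sample_ids)]
    small = y.value_counts()
    tiny = small[small < 2]
    if len(tiny):
        raise ValueError(f"classes with < 2 samples: {sorted(tiny.index)}")
    if y.nunique() < 2:
        raise ValueError("need at least two classes")
    return y


def _importances(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    seed: int,
    sample_weight: np.ndarray | None,
) -> np.ndarray:
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed % (2**31),
        n_jobs=1,
    )
    rf.fit(X, y, sample_weight=sample_weight)
    return rf.feature_importances_


def rank_genes(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    scheme: str = "both",
    n_trees: int = 2000,
    use_within_sample_ranks: bool = True,
    seed: int = 0,
) -> GeneRanking:
    """Rank genes by Random-Forest impurity importance.

    With ``use_within_sample_ranks`` (the default) the features are each
    sample's within-column gene ranks (average ranks for ties), making the
    ranking invariant to strictly monotone per-sample transforms.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    y = _check_classes(ann, m.sample_ids)
    vals = m.values.to_numpy(dtype=float)
    if use_within_sample_ranks:
        feats = scipy.stats.rankdata(vals, axis=0)  # rank genes within sample
    else:
        feats = vals
    X = feats.T  # samples x genes
    genes = np.array(m.gene_ids)
    out = GeneRanking()
    if scheme in ("altogether", "both"):
        imp = _importances(X, y.to_numpy(), n_trees, seed, None)
        s = pd.Series(imp, index=genes).sort_values(ascending=False, kind="stable")
        out.altogether = s
    if scheme in ("one_vs_rest", "both"):
        out.per_class = {}
        for ci, cls in enumerate(sorted(y.unique())):
            yb = (y.to_numpy() == cls).astype(int)
            imp = _importances(X, yb, n_trees, seed + 1 + ci, None)
            out.per_class[cls] = pd.Series(imp, index=genes).sort_values(
                ascending=False, kind="stable"
            )
    return out


def select_top_genes(
    ranking: GeneRanking,
    n_altogether: int = 85,
    n_per_class: int = 100,
) -> tuple[list[str], pd.DataFrame]:
    """Union (deduplicated, order-preserving) of the top-n ranked gene lists."""
    chosen: list[str] = []
    prov = []
    lists: list[tuple[str, str, pd.Series]] = []
    if n_altogether > 0:
        if ranking.altogether is None:
            raise ValueError("altogether ranking not available")
        if n_altogether > len(ranking.altogether):
            raise ValueError("n_altogether exceeds number of ranked genes")
        lists.append(("altogether", "", ranking.altogether))
    if n_per_class > 0:
        if ranking.per_class is None:
            raise ValueError("one-vs-rest ranking not available")
        for cls in sorted(ranking.per_class):
            if n_per_class > len(ranking.per_class[cls]):
                raise ValueError("n_per_class exceeds number of ranked genes")
            lists.append(("one_vs_rest", cls, ranking.per_class[cls]))
    seen: set[str] = set()
    for scheme, cls, series in lists:
        depth = n_altogether if scheme == "altogether" else n_per_class
        for rank, (gene, imp) in enumerate(series.iloc[:depth].items(), start=1):
            prov.append((gene, scheme, cls, rank, imp))
            if gene not in seen:
                seen.add(gene)
                chosen.append(gene)
    prov_df = pd.DataFrame(
        prov, columns=["gene", "scheme", "class", "rank", "importance"]
    )
    return chosen, prov_df


def generate_rules(genes: Sequence[str]) -> list[Rule]:
    """All unordered gene pairs in canonical (lexicographic) orientation."""
    uniq = sorted(set(genes))
    if len(uniq) < 2:
        raise ValueError("need at least two genes to form rules")
    return list(itertools.combinations(uniq, 2))


def evaluate_rules(m: ExpressionMatrix, rules: Sequence[Rule]) -> RuleMatrix:
    """Evaluate rules within each sample: 1 iff value(a) < value(b), ties 0."""
    index = {g: i for i, g in enumerate(m.gene_ids)}
    absent = sorted({g for r in rules for g in r if g not in index})
    if absent:
        raise KeyError(f"rule genes absent from matrix: {absent[:10]}")
    vals = m.values.to_numpy()
    ia = np.array([index[a] for a, _ in rules])
    ib = np.array([index[b] for _, b in rules])
    X = (vals[ia, :] < vals[ib, :]).T.astype(np.uint8)
    return RuleMatrix(X, list(rules), m.sample_ids)


def rank_rules(
    rm: RuleMatrix,
    ann: pd.DataFrame,
    scheme: str = "both",
    class_weights: str = "inverse_frequency",
    n_trees: int = 500,
    seed: int = 0,
) -> RuleRanking:
    """Rank binary rule features by discriminative power (RF importance).

    ``inverse_frequency`` weights each sample by 1/(class size) so that
    imbalanced cohorts do not dominate the ranking; constant rule columns
    receive zero importance by construction (no split gain).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if class_weights not in ("none", "inverse_frequency"):
        raise ValueError(f"unknown class_weights {class_weights!r}")
    y = _check_classes(ann, rm.sample_ids)
    yarr = y.to_numpy()
    if class_weights == "inverse_frequency":
        freq = y.value_counts()
        sw = np.array([1.0 / freq[c] for c in yarr])
    else:
        sw = None
    names = pd.Index([f"{a}<{b}" for a, b in rm.rules])
    X = rm.X.astype(np.float32)
    out = RuleRanking()
    if scheme in ("altogether", "both"):
        imp = _importances(X, yarr, n_trees, seed, sw)
        out.altogether = pd.Series(imp, index=names).sort_values(
            ascending=False, kind="stable"
        )
    if scheme in ("one_vs_rest", "both"):
        out.per_class = {}
        for ci, cls in enumerate(sorted(y.unique())):
            yb = (yarr == cls).astype(int)
            if sw is not None:
                fb = pd.Series(yb).value_counts()
                swb = np.array([1.0 / fb[v] for v in yb])
            else:
                swb = None
            imp = _importances(X, yb, n_trees, seed + 1 + ci, swb)
            out.per_class[cls] = pd.Series(imp, index=names).sort_values(
                ascending=False, kind="stable"
            )
    return out


def _parse_rule_name(name: str) -> Rule:
    a, b = name.split("<")
    return (a, b)


def select_rules(
    ranking: RuleRanking,
    n_altogether: int = 100,
    n_per_class: int = 100,
    gene_repetition_cap: float = 1,
) -> RuleSelection:
    """Greedy capped selection down each ranked list, deduplicated.

    Lists are traversed in a fixed order (altogether first, then classes in
    sorted order).  Within each list a rule is skipped when taking it would
    push either of its genes past ``gene_repetition_cap`` *in that list* —
    the cap enforces gene diversity per ranked list, so distinct class lists
    may reuse a gene.  Rules already chosen by an earlier list are not
    duplicated but still count toward the later list's quota.
    """
    if gene_repetition_cap < 1:
        raise ValueError("gene_repetition_cap must be >= 1")
    lists: list[tuple[str, str, pd.Series, int]] = []
    if n_altogether > 0 and ranking.altogether is not None:
        lists.append(("altogether", "", ranking.altogether, n_altogether))
    if n_per_class > 0 and ranking.per_class is not None:
        for cls in sorted(ranking.per_class):
            lists.append(("one_vs_rest", cls, ranking.per_class[cls], n_per_class))
    if not lists:
        raise ValueError("no ranked rule lists supplied")
    chosen: list[Rule] = []
    chosen_set: set[Rule] = set()
    prov = []
    for scheme, cls, series, depth in lists:
        taken = 0
        gene_use: dict[str, int] = {}  # per-list diversity cap
        for rank, (name, imp) in enumerate(series.items(), start=1):
            if taken >= depth:
                break
            rule = _parse_rule_name(str(name))
            a, b = rule
            if (
                gene_use.get(a, 0) + 1 > gene_repetition_cap
                or gene_use.get(b, 0) + 1 > gene_repetition_cap
            ):
                continue
            gene_use[a] = gene_use.get(a, 0) + 1
            gene_use[b] = gene_use.get(b, 0) + 1
            taken += 1
            if rule in chosen_set:
                continue  # already contributed by an earlier list
            chosen.append(rule)
            chosen_set.add(rule)
            prov.append((a, b, scheme, cls, rank, imp))
        if taken == 0:
            warnings.warn(
                f"rule list {scheme}/{cls or 'all'} contributed zero rules "
                f"under gene_repetition_cap={gene_repetition_cap}",
                stacklevel=2,
            )
    prov_df = pd.DataFrame(
        prov, columns=["gene_a", "gene_b", "scheme", "class", "rank", "importance"]
    )
    prov_df["gene_repetition_cap"] = gene_repetition_cap
    return RuleSelection(chosen, prov_df, gene_repetition_cap)
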