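import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from cellpair.expr_io import ExpressionMatrix
from cellpair.pair_rules import (
    GeneRanking,
    RuleMatrix,
    RuleRanking,
    evaluate_rules,
    generate_rules,
    rank_genes,
    rank_rules,
    select_rules,
    select_top_genes,
)


def _em(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _ann(samples, labels):
    return pd.DataFrame({"sample_id": samples, "class_label": labels, "study_id": "x"})


class TestRankGenes:
    def _toy(self):
        # one gene separates the classes perfectly, the rest are noise
        rng = np.random.default_rng(0)
        n = 24
        labels = ["pos"] * 12 + ["neg"] * 12
        vals = rng.uniform(10, 20, (8, n))
        sep = np.where(np.array(labels) == "pos", 100.0, 1.0)
        vals = np.vstack([vals, sep])
        genes = [f"g{i}" for i in range(8)] + ["SEP"]
        samples = [f"s{i}" for i in range(n)]
        return _em(vals, genes, samples), _ann(samples, labels)

    def test_perfect_separator_ranks_first_in_both_schemes(self):
        m, ann = self._toy()
        r = rank_genes(m, ann, scheme="both", n_trees=300, seed=1)
        assert r.altogether.index[0] == "SEP"
        for cls, series in r.per_class.items():
            assert series.index[0] == "SEP"

    def test_rank_features_invariant_to_monotone_transform(self):
        m, ann = self._toy()
        r1 = rank_genes(m, ann, scheme="altogether", n_trees=200, seed=5)
        m_exp = ExpressionMatrix(np.exp(m.values / 10.0))
        r2 = rank_genes(m_exp, ann, scheme="altogether", n_trees=200, seed=5)
        pd.testing.assert_series_equal(r1.altogether, r2.altogether)

    def test_permuted_labels_give_no_standout_gene(self):
        # with labels shuffled, the top importance should not dominate the
        # median importance the way a real marker would
        m, ann = self._toy()
        ratios = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            shuffled = ann.assign(class_label=rng.permutation(ann["class_label"]))
            r = rank_genes(m, shuffled, scheme="altogether", n_trees=100, seed=rep)
            imp = r.altogether
            ratios.append(imp.iloc[0] / max(imp.median(), 1e-12))
        real = rank_genes(m, ann, scheme="altogether", n_trees=100, seed=0).altogether
        real_ratio = real.iloc[0] / max(real.median(), 1e-12)
        assert real_ratio > np.percentile(ratios, 95)

    def test_tiny_class_rejected(self):
        m, _ = self._toy()
        bad = _ann(m.sample_ids, ["a"] + ["b"] * (m.n_samples - 1))
        with pytest.raises(ValueError, match="< 2 samples"):
            rank_genes(m, bad, n_trees=10)


class TestSelectTopGenes:
    def _ranking(self, seed=0, n_genes=20, classes=("a", "b", "c")):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        mk = lambda: pd.Series(
            rng.random(n_genes), index=genes
        ).sort_values(ascending=False, kind="stable")
        return GeneRanking(altogether=mk(), per_class={c: mk() for c in classes})

    def test_degenerate_altogether_only(self):
        r = self._ranking()
        genes, _ = select_top_genes(r, n_altogether=2, n_per_class=0)
        assert genes == list(r.altogether.index[:2])

    def test_union_deduplicates(self):
        r = self._ranking(n_genes=6)
        genes, prov = select_top_genes(r, n_altogether=5, n_per_class=5)
        assert len(genes) < len(prov)
        assert len(genes) == len(set(genes))

    def test_matches_set_union_oracle(self):
        for seed in range(10):
            r = self._ranking(seed=seed)
            genes, _ = select_top_genes(r, n_altogether=5, n_per_class=5)
            expected = set(r.altogether.index[:5])
            for c in r.per_class:
                expected |= set(r.per_class[c].index[:5])
            assert set(genes) == expected

    def test_depth_beyond_available_rejected(self):
        r = self._ranking(n_genes=4)
        with pytest.raises(ValueError):
            select_top_genes(r, n_altogether=10, n_per_class=0)


class TestGenerateRules:
    @pytest.mark.parametrize("n,expected", [(3, 3), (10, 45)])
    def test_counts(self, n, expected):
        rules = generate_rules([f"g{i}" for i in range(n)])
        assert len(rules) == expected

    @given(st.integers(min_value=2, max_value=12))
    @settings(max_examples=20, deadline=None)
    def test_matches_enumeration_oracle(self, n):
        genes = [f"g{i:02d}" for i in range(n)]
        rules = generate_rules(genes)
        brute = {
            tuple(sorted(p)) for p in itertools.permutations(genes, 2)
        }
        assert set(rules) == brute
        assert len(rules) == n * (n - 1) // 2
        assert all(a < b for a, b in rules)


class TestEvaluateRules:
    def test_definition_and_tie_policy(self):
        m = _em([[1.0], [2.0], [2.0]], ["A", "B", "C"], ["s"])
        rm = evaluate_rules(m, [("A", "B"), ("B", "C")])
        assert rm.X[0, 0] == 1  # 1 < 2
        assert rm.X[0, 1] == 0  # tie -> 0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 5, (20, 10)).astype(float)
        genes = [f"g{i}" for i in range(20)]
        m = _em(vals, genes, [f"s{i}" for i in range(10)])
        rules = generate_rules(genes[:6])[:15]
        rm = evaluate_rules(m, rules)
        for si in range(10):
            for ri, (a, b) in enumerate(rules):
                expected = int(vals[genes.index(a), si] < vals[genes.index(b), si])
                assert rm.X[si, ri] == expected

    def test_absent_gene_listed(self):
        m = _em([[1.0]], ["A"], ["s"])
        with pytest.raises(KeyError, match="ZZZ"):
            evaluate_rules(m, [("A", "ZZZ")])

    @pytest.mark.parametrize(
        "transform",
        [np.exp, lambda v: 3.1 * v + 7.0, lambda v: scipy.stats.rankdata(v, axis=0)],
        ids=["exp", "affine", "rank"],
    )
    def test_invariant_under_monotone_per_sample_transform(self, transform):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 50, (12, 8))
        genes = [f"g{i}" for i in range(12)]
        m = _em(vals, genes, [f"s{i}" for i in range(8)])
        rules = generate_rules(genes)[:30]
        base = evaluate_rules(m, rules)
        t = _em(np.asarray(transform(vals / vals.max())), genes, m.sample_ids)
        assert np.array_equal(base.X, evaluate_rules(t, rules).X)


class TestRankRules:
    def test_class_indicator_rule_tops_its_one_vs_rest_list(self, separable_rule_matrix):
        rm, ann = separable_rule_matrix
        ranking = rank_rules(rm, ann, scheme="one_vs_rest", n_trees=300, seed=2)
        for cls in ("a", "b", "c"):
            top = ranking.per_class[cls].index[0]
            assert top.startswith(cls.upper())

    def test_constant_rule_importance_zero(self):
        labels = ["a"] * 6 + ["b"] * 6
        sids = [f"s{i}" for i in range(12)]
        ind = np.array([1] * 6 + [0] * 6, dtype=np.uint8)
        const = np.ones(12, dtype=np.uint8)
        rm = RuleMatrix(np.column_stack([ind, const]), [("A", "B"), ("C", "D")], sids)
        ranking = rank_rules(rm, _ann(sids, labels), scheme="altogether", n_trees=100, seed=0)
        assert ranking.altogether["C<D"] == 0.0

    def test_inverse_frequency_stabilizes_against_majority_duplication(self, separable_rule_matrix):
        rm, ann = separable_rule_matrix
        r1 = rank_rules(rm, ann, scheme="one_vs_rest", n_trees=400, seed=6)
        # double the majority class 'a' samples
        dup_idx = [i for i, l in enumerate(ann["class_label"]) if l == "a"]
        X2 = np.vstack([rm.X, rm.X[dup_idx]])
        sids2 = rm.sample_ids + [f"dup{i}" for i in range(len(dup_idx))]
        ann2 = pd.concat(
            [ann, ann.iloc[dup_idx].assign(sample_id=[f"dup{i}" for i in range(len(dup_idx))])],
            ignore_index=True,
        )
        rm2 = RuleMatrix(X2, rm.rules, sids2)
        r2 = rank_rules(rm2, ann2, scheme="one_vs_rest", n_trees=400, seed=6)
        # the indicator rules still dominate every per-class list
        for cls in ("a", "b", "c"):
            assert r2.per_class[cls].index[0].startswith(cls.upper())
            assert r1.per_class[cls].index[0].startswith(cls.upper())


class TestSelectRules:
    def _ranking_from(self, named):
        s = pd.Series(
            np.linspace(1, 0.1, len(named)), index=[f"{a}<{b}" for a, b in named]
        )
        return RuleRanking(altogether=s, per_class=None)

    def test_cap_forces_skip(self):
        r = self._ranking_from([("A", "B"), ("A", "C"), ("D", "E")])
        sel = select_rules(r, n_altogether=3, n_per_class=0, gene_repetition_cap=1)
        assert sel.rules == [("A", "B"), ("D", "E")]

    def test_infinite_cap_keeps_topn(self):
        named = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")]
        r = self._ranking_from(named)
        sel = select_rules(r, n_altogether=4, n_per_class=0, gene_repetition_cap=np.inf)
        assert sel.rules == named

    def test_matches_greedy_oracle(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(12)]
        for rep in range(20):
            all_rules = generate_rules(genes)
            order = rng.permutation(len(all_rules))
            ranked = [all_rules[i] for i in order]
            r = self._ranking_from(ranked)
            cap, depth = 2, 10
            sel = select_rules(r, n_altogether=depth, n_per_class=0, gene_repetition_cap=cap)
            # independent greedy reimplementation
            use, expected, taken = {}, [], 0
            for a, b in ranked:
                if taken >= depth:
                    break
                if use.get(a, 0) + 1 > cap or use.get(b, 0) + 1 > cap:
                    continue
                use[a] = use.get(a, 0) + 1
                use[b] = use.get(b, 0) + 1
                expected.append((a, b))
                taken += 1
            assert sel.rules == expected

    def test_cap_warning_when_list_contributes_nothing(self):
        r = RuleRanking(
            altogether=pd.Series({"A<B": 1.0}),
            per_class={"c1": pd.Series({"A<B": 0.9})},
        )
        sel = select_rules(r, n_altogether=1, n_per_class=0, gene_repetition_cap=1)
        assert sel.rules == [("A", "B")]

    def test_per_list_cap_enforced_in_provenance(self, separable_rule_matrix):
        rm, ann = separable_rule_matrix
        ranking = rank_rules(rm, ann, scheme="both", n_trees=200, seed=1)
        sel = select_rules(ranking, n_altogether=5, n_per_class=5, gene_repetition_cap=1)
        for _, grp in sel.provenance.groupby(["scheme", "class"]):
            genes = list(grp["gene_a"]) + list(grp["gene_b"])
            assert len(genes) == len(set(genes))
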