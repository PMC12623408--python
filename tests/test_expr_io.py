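import numpy as np
import pandas as pd
import pytest

from cellpair.expr_io import (
    ExpressionMatrix,
    counts_to_tpm,
    filter_genes_by_prevalence,
    harmonize_gene_ids,
    merge_studies,
    read_expression,
)


def _em(values, genes, samples, unit="counts"):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit=unit)


class TestReadExpression:
    def test_tsv_round_trip_preserves_names_and_values(self, tmp_path):
        m = _em([[1, 2], [3, 4], [5, 6]], ["TP53", "GFAP", "AIF1"], ["s1", "s2"])
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = read_expression(p)
        assert back.gene_ids == m.gene_ids
        assert back.sample_ids == m.sample_ids
        assert np.array_equal(back.values.to_numpy(), m.values.to_numpy())

    def test_duplicate_gene_row_raises_naming_gene(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene\ts1\ts2\nGFAP\t1\t2\nGFAP\t3\t4\n")
        with pytest.raises(ValueError, match="GFAP"):
            read_expression(p)

    def test_mtx_triplet_densifies_exactly(self, tmp_path):
        # 5 nonzeros over 4x3 -> dense with 7 zeros; oracle is direct
        # placement of the triplet list into a zero matrix
        triplets = [(1, 1, 5.0), (2, 3, 1.0), (3, 2, 2.0), (4, 1, 7.0), (4, 3, 3.0)]
        mtx = tmp_path / "m.mtx"
        lines = ["%%MatrixMarket matrix coordinate real general", "4 3 5"]
        lines += [f"{i} {j} {v}" for i, j, v in triplets]
        mtx.write_text("\n".join(lines) + "\n")
        (tmp_path / "m.genes.txt").write_text("g1\ng2\ng3\ng4\n")
        (tmp_path / "m.samples.txt").write_text("s1\ns2\ns3\n")
        m = read_expression(mtx, format="mtx_triplet")
        expected = np.zeros((4, 3))
        for i, j, v in triplets:
            expected[i - 1, j - 1] = v
        assert np.array_equal(m.values.to_numpy(), expected)
        assert (m.values.to_numpy() == 0).sum() == 7

    def test_nan_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            _em([[1.0, np.nan]], ["g"], ["s1", "s2"])


class TestHarmonize:
    def test_direct_mapping_drops_unmapped(self):
        m = _em([[1, 2], [3, 4]], ["ENSG1", "ENSG2"], ["s1", "s2"])
        out, rec = harmonize_gene_ids(m, {"ENSG1": "TP53"})
        assert out.gene_ids == ["TP53"]
        assert rec.n_unmapped_dropped == 1

    def test_collision_sum_adds_rows(self):
        m = _em([[1, 2], [3, 4]], ["E1", "E2"], ["s1", "s2"])
        out, rec = harmonize_gene_ids(m, {"E1": "TP53", "E2": "TP53"}, "sum")
        assert out.gene_ids == ["TP53"]
        assert out.values.loc["TP53"].tolist() == [4, 6]
        assert rec.collisions == {"TP53": ["E1", "E2"]}

    def test_identity_map_is_noop(self):
        m = _em([[1, 2], [3, 4]], ["A", "B"], ["s1", "s2"])
        out, _ = harmonize_gene_ids(m, {"A": "A", "B": "B"})
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_collision_error_policy_lists_symbols(self):
        m = _em([[1, 2], [3, 4]], ["E1", "E2"], ["s1", "s2"])
        with pytest.raises(ValueError, match="TP53"):
            harmonize_gene_ids(m, {"E1": "TP53", "E2": "TP53"}, "error")


class TestPrevalenceFilter:
    def test_inclusive_threshold_boundary(self):
        vals = np.ones((2, 5))
        vals[0, 0] = 0  # 4/5 nonzero -> kept at 0.8
        vals[1, :2] = 0  # 3/5 nonzero -> dropped
        m = _em(vals, ["keep", "drop"], [f"s{i}" for i in range(5)])
        out = filter_genes_by_prevalence(m, 0.8)
        assert out.gene_ids == ["keep"]

    def test_all_positive_matrix_unchanged(self):
        m = _em(np.ones((3, 4)), list("abc"), list("wxyz"))
        out = filter_genes_by_prevalence(m, 0.8)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_random_mask_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(3.0, (50, 20)) * (rng.random((50, 20)) < 0.9)
        genes = [f"g{i}" for i in range(50)]
        m = _em(vals, genes, [f"s{i}" for i in range(20)])
        out = filter_genes_by_prevalence(m, 0.8)
        # brute-force per-gene count oracle, exact rational threshold
        from fractions import Fraction

        expected = [
            g
            for i, g in enumerate(genes)
            if Fraction(int((vals[i] > 0).sum()), 20) >= Fraction(4, 5)
        ]
        assert out.gene_ids == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        vals = rng.poisson(1.0, (30, 10))
        vals[vals < 0] = 0
        m = _em(vals + 0.0, [f"g{i}" for i in range(30)], [f"s{i}" for i in range(10)])
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8, 1.0):
            try:
                kept = set(filter_genes_by_prevalence(m, t).gene_ids)
            except ValueError:
                kept = set()
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestMergeStudies:
    def _ann(self, samples, study):
        return pd.DataFrame(
            {"sample_id": samples, "class_label": "x", "study_id": study}
        )

    def test_gene_intersection(self):
        m1 = _em(np.ones((3, 2)), ["A", "B", "C"], ["s1", "s2"])
        m2 = _em(np.ones((3, 2)), ["B", "C", "D"], ["t1", "t2"])
        merged, _ = merge_studies(
            [m1, m2], [self._ann(["s1", "s2"], "u"), self._ann(["t1", "t2"], "v")]
        )
        assert merged.gene_ids == ["B", "C"]

    def test_values_copied_verbatim(self):
        rng = np.random.default_rng(11)
        mats, anns = [], []
        for i in range(3):
            vals = rng.poisson(10.0, (6, 4)).astype(float)
            samples = [f"st{i}_s{j}" for j in range(4)]
            mats.append(_em(vals, [f"g{k}" for k in range(6)], samples))
            anns.append(self._ann(samples, f"st{i}"))
        merged, ann = merge_studies(mats, anns)
        for m in mats:
            for s in m.sample_ids:
                assert np.array_equal(
                    merged.values[s].to_numpy(), m.values[s].to_numpy()
                )
        assert len(ann) == 12

    def test_duplicate_sample_id_rejected(self):
        m1 = _em(np.ones((2, 1)), ["A", "B"], ["s1"])
        m2 = _em(np.ones((2, 1)), ["A", "B"], ["s1"])
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_studies([m1, m2], [self._ann(["s1"], "u"), self._ann(["s1"], "v")])

    def test_empty_intersection_rejected(self):
        m1 = _em(np.ones((1, 1)), ["A"], ["s1"])
        m2 = _em(np.ones((1, 1)), ["B"], ["t1"])
        with pytest.raises(ValueError, match="intersection"):
            merge_studies([m1, m2], [self._ann(["s1"], "u"), self._ann(["t1"], "v")])


class TestCountsToTpm:
    def test_single_gene_is_forced_to_one_million(self):
        m = _em([[123.0, 7.0]], ["g"], ["s1", "s2"])
        out = counts_to_tpm(m, {"g": 2.0})
        assert np.allclose(out.values.to_numpy(), 1e6)

    def test_length_normalization_ratio(self):
        # equal counts, lengths 1 and 2 kb -> TPM ratio 2:1
        m = _em([[10.0], [10.0]], ["short", "long"], ["s"])
        out = counts_to_tpm(m, {"short": 1.0, "long": 2.0})
        assert out.values.at["short", "s"] == pytest.approx(
            2 * out.values.at["long", "s"]
        )

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        m = _em(
            rng.poisson(50.0, (20, 6)).astype(float) + 1,
            [f"g{i}" for i in range(20)],
            [f"s{i}" for i in range(6)],
        )
        lengths = {f"g{i}": float(rng.uniform(0.5, 5)) for i in range(20)}
        out = counts_to_tpm(m, lengths)
        assert np.allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_column_total_names_sample(self):
        m = _em([[0.0, 1.0]], ["g"], ["empty", "ok"])
        with pytest.raises(ValueError, match="empty"):
            counts_to_tpm(m, {"g": 1.0})
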