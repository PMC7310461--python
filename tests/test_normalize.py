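"""Quantile normalization, platform merging, ComBat and QC summaries."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pathbn.normalize import (
    ExpressionDataset,
    MergedPlatformDataset,
    combat_adjust,
    collapse_probes,
    merge_platform,
    qc_summary,
    quantile_normalize,
    quantile_normalize_frame,
)

DATA = Path(__file__).parent / "data"


def _brute_force_qn(df):
    """Independent oracle: sort each column, average across columns, map
    back by rank with tie groups averaged."""
    vals = df.to_numpy(float)
    n, k = vals.shape
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        col = vals[:, j]
        for i in range(n):
            tied = np.flatnonzero(col == col[i])
            ranks = np.searchsorted(np.sort(col), col[i]) + np.arange(len(tied))
            out[i, j] = ref[ranks].mean()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


class TestQuantileNormalize:
    def test_matches_bruteforce_oracle(self):
        df = pd.DataFrame(
            [[5.0, 2.0, 3.0], [1.0, 4.0, 4.0], [4.0, 4.0, 6.0], [2.0, 8.0, 5.0]],
            index=list("abcd"),
            columns=["s1", "s2", "s3"],
        )
        got = quantile_normalize_frame(df)
        expected = _brute_force_qn(df)
        pd.testing.assert_frame_equal(got, expected)

    def test_permuted_columns_share_distribution(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        df = pd.DataFrame(
            {f"s{j}": rng.permutation(base) for j in range(4)},
            index=[f"g{i}" for i in range(20)],
        )
        out = quantile_normalize_frame(df)
        for j in range(4):
            assert np.allclose(np.sort(out.iloc[:, j]), np.sort(out.iloc[:, 0]))

    def test_single_column_unchanged(self):
        df = pd.DataFrame({"s1": [3.0, 1.0, 2.0]}, index=list("abc"))
        pd.testing.assert_frame_equal(quantile_normalize_frame(df), df)

    def test_non_finite_cells_reported(self):
        df = pd.DataFrame({"s1": [1.0, np.nan], "s2": [0.0, 1.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="g2"):
            quantile_normalize_frame(df)

    @given(st.integers(0, 2**31 - 1))
    def test_ranks_preserved_within_columns(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(12, 3)))
        out = quantile_normalize_frame(df)
        for j in range(3):
            rho = stats.spearmanr(df.iloc[:, j], out.iloc[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_dataset_wrapper_keeps_labels(self, dataset_factory):
        d = dataset_factory()
        out = quantile_normalize(d)
        assert list(out.matrix.index) == list(d.matrix.index)
        assert list(out.matrix.columns) == list(d.matrix.columns)
        assert out.dataset_id == d.dataset_id


class TestMergePlatform:
    def test_identical_gene_sets_lose_nothing(self, dataset_factory):
        d1 = dataset_factory("DS1", seed=1)
        d2 = dataset_factory("DS2", seed=2)
        m = merge_platform([d1, d2])
        assert (m.lost_gene_report["lost_fraction"] == 0.0).all()
        assert m.matrix.shape[1] == d1.n_samples + d2.n_samples

    def test_partial_overlap_set_arithmetic(self, dataset_factory):
        d1 = dataset_factory("DS1", genes=("A", "B", "C"), seed=1)
        d2 = dataset_factory("DS2", genes=("B", "C", "D"), seed=2)
        m = merge_platform([d1, d2])
        assert list(m.matrix.index) == ["B", "C"]
        assert m.lost_gene_report.loc["DS1", "lost_fraction"] == pytest.approx(1 / 3)
        assert m.lost_gene_report.loc["DS2", "lost_fraction"] == pytest.approx(1 / 3)

    def test_single_dataset_identity(self, dataset_factory):
        d = dataset_factory()
        m = merge_platform([d])
        pd.testing.assert_frame_equal(m.matrix, d.matrix.sort_index())
        assert m.lost_gene_report.loc["DS1", "lost_fraction"] == 0.0

    def test_mixed_platforms_rejected(self, dataset_factory):
        with pytest.raises(ValueError, match="mixed platform"):
            merge_platform(
                [dataset_factory("DS1", "P1"), dataset_factory("DS2", "P2")]
            )

    def test_empty_intersection_rejected(self, dataset_factory):
        with pytest.raises(ValueError, match="empty gene intersection"):
            merge_platform(
                [
                    dataset_factory("DS1", genes=("A", "B")),
                    dataset_factory("DS2", genes=("C", "D")),
                ]
            )

    def test_order_invariant_up_to_column_order(self, dataset_factory):
        d1 = dataset_factory("DS1", genes=("A", "B", "C"), seed=1)
        d2 = dataset_factory("DS2", genes=("B", "C", "D"), seed=2)
        m12 = merge_platform([d1, d2])
        m21 = merge_platform([d2, d1])
        assert list(m12.matrix.index) == list(m21.matrix.index)
        pd.testing.assert_frame_equal(
            m12.matrix, m21.matrix[m12.matrix.columns]
        )


class TestCollapseProbes:
    def test_highest_mean_probe_wins(self):
        mat = pd.DataFrame(
            {"s1": [1.0, 5.0, 2.0], "s2": [2.0, 6.0, 2.0]},
            index=["p1", "p2", "p3"],
        )
        out = collapse_probes(mat, {"p1": "G1", "p2": "G1", "p3": "G2"})
        assert list(out.index) == ["G1", "G2"]
        assert out.loc["G1", "s1"] == 5.0  # p2 has the higher mean


class TestCombat:
    def _merged_two_batch(self, shift=2.0, n=200, n_genes=30, seed=3):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(5, 9, n_genes)
        genes = [f"g{i}" for i in range(n_genes)]

        def block(ds, offset):
            cols = [f"{ds}.s{i}" for i in range(n)]
            mat = pd.DataFrame(
                mu[:, None] + offset + rng.standard_normal((n_genes, n)),
                index=genes,
                columns=cols,
            )
            meta = pd.DataFrame(
                {"group": ["case"] * (n // 2) + ["control"] * (n // 2)}, index=cols
            )
            return ExpressionDataset(ds, "P", mat, meta)

        return merge_platform([block("B1", 0.0), block("B2", shift)])

    def test_matches_sva_reference(self):
        """Output agrees with reference values computed once with the
        Bioconductor sva implementation on this fixture."""
        rng = np.random.default_rng(42)
        G, n1, n2 = 6, 10, 8
        mu = rng.uniform(5, 9, G)
        X1 = mu[:, None] + rng.standard_normal((G, n1)) * rng.uniform(0.6, 1.4, G)[:, None] + 1.0
        X2 = mu[:, None] + rng.standard_normal((G, n2)) * rng.uniform(0.6, 1.4, G)[:, None] - 0.5
        cols = [f"s{i + 1}" for i in range(n1 + n2)]
        mat = pd.DataFrame(
            np.hstack([X1, X2]), index=[f"g{i + 1}" for i in range(G)], columns=cols
        )
        meta = pd.DataFrame(
            {
                "dataset_id": ["B1"] * n1 + ["B2"] * n2,
                "group": ["case"] * 5 + ["control"] * 5 + ["case"] * 4 + ["control"] * 4,
            },
            index=cols,
        )
        m = MergedPlatformDataset("P", mat, meta)
        got = combat_adjust(m, preserve_group=True).matrix
        ref = pd.read_csv(DATA / "combat_sva_reference.tsv", sep="\t", index_col=0)
        assert np.abs(got.to_numpy() - ref.to_numpy()).max() < 1e-4

    def test_removes_additive_batch_shift(self):
        """A shared shift of 2 between batches is removed down to the
        sampling noise of batch means (empirical-Bayes shrinkage keeps a
        residual of order sqrt(2/n) per gene, as the reference
        implementation does)."""
        m = self._merged_two_batch(shift=2.0)
        b1 = (m.sample_meta["dataset_id"] == "B1").to_numpy()

        def gap(mm):
            return (
                mm.matrix.loc[:, b1].mean(axis=1)
                - mm.matrix.loc[:, ~b1].mean(axis=1)
            ).abs()

        adj = combat_adjust(m)
        assert gap(adj).mean() < 0.1
        assert gap(adj).mean() < 0.1 * gap(m).mean()  # >=90% shrinkage

    def test_single_batch_bypass_is_identity(self, dataset_factory):
        d = dataset_factory(n_case=5, n_control=5)
        m = merge_platform([d])
        out = combat_adjust(m, allow_single_batch=True)
        assert np.allclose(out.matrix.to_numpy(), m.matrix.to_numpy(), atol=1e-8)
        with pytest.raises(ValueError, match=">=2 batches"):
            combat_adjust(m)

    def test_single_sample_batch_rejected(self, dataset_factory):
        d1 = dataset_factory("DS1", n_case=3, n_control=3, seed=1)
        d2 = dataset_factory("DS2", n_case=3, n_control=3, seed=2)
        m = merge_platform([d1, d2])
        m.sample_meta.loc[m.sample_meta.index[-5:], "dataset_id"] = "DS3"
        m.sample_meta.loc[m.sample_meta.index[-6], "dataset_id"] = "DS4"
        with pytest.raises(ValueError, match="single sample"):
            combat_adjust(m)

    def test_zero_variance_gene_passes_through(self, dataset_factory):
        d1 = dataset_factory("DS1", seed=1)
        d2 = dataset_factory("DS2", seed=2)
        m = merge_platform([d1, d2])
        m.matrix.loc["A"] = 3.14
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = combat_adjust(m)
        assert (adj.matrix.loc["A"] == 3.14).all()
        assert not np.allclose(
            adj.matrix.loc["B"].to_numpy(), m.matrix.loc["B"].to_numpy()
        )


class TestQcSummary:
    def test_batch_free_data_has_low_pc1_batch_r2(self, dataset_factory):
        d1 = dataset_factory("DS1", n_case=25, n_control=25, genes=[f"g{i}" for i in range(40)], seed=1)
        d2 = dataset_factory("DS2", n_case=25, n_control=25, genes=[f"g{i}" for i in range(40)], seed=2)
        qc = qc_summary(merge_platform([d1, d2]))
        assert qc.pc1_batch_r2 < 0.1

    def test_batch_shift_r2_high_then_drops_after_combat(self):
        m = TestCombat()._merged_two_batch(shift=3.0, n=50, n_genes=40)
        before = qc_summary(m)
        after = qc_summary(combat_adjust(m))
        assert before.pc1_batch_r2 > 0.9
        assert after.pc1_batch_r2 < before.pc1_batch_r2
        assert after.pc1_batch_r2 < 0.1

    def test_constant_matrix_flagged_degenerate(self, dataset_factory):
        d = dataset_factory()
        m = merge_platform([d])
        m.matrix.loc[:, :] = 1.0
        qc = qc_summary(m)
        assert qc.degenerate
        assert (qc.sample_quartiles["q25"] == qc.sample_quartiles["q75"]).all()
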