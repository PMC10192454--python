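"""Standardized PCA, Ward clustering with auto-k, v-tests, correlations."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

import kolacross as kc
from kolacross import multivariate as mv


def _table(arr, prefix="t"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"c{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_one_component(self):
        x = np.arange(10, dtype=float)
        pca = mv.pca_standardized(_table(np.c_[x, 2 * x + 1]))
        assert pca.explained_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_independent_traits_spread_variance(self):
        rng = np.random.default_rng(0)
        pca = mv.pca_standardized(_table(rng.normal(size=(600, 4))))
        assert pca.explained_pct == pytest.approx([25.0] * 4, abs=10.0)

    def test_scores_preserve_euclidean_distances(self):
        rng = np.random.default_rng(1)
        table = _table(rng.normal(size=(12, 5)))
        pca = mv.pca_standardized(table)
        X = (table - table.mean()) / table.std(ddof=1)
        assert pdist(pca.scores.to_numpy()) == pytest.approx(
            pdist(X.to_numpy()), abs=1e-8
        )

    def test_explained_sums_to_hundred_and_is_sorted(self):
        rng = np.random.default_rng(2)
        pca = mv.pca_standardized(_table(rng.normal(size=(20, 6))))
        assert pca.explained_pct.sum() == pytest.approx(100.0)
        assert (np.diff(pca.explained_pct) <= 1e-9).all()

    def test_zero_variance_trait_dropped(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(10, 3))
        arr[:, 1] = 5.0
        pca = mv.pca_standardized(_table(arr))
        assert pca.dropped_traits == ["t1"]

    def test_missing_cells_mean_imputed(self, caplog):
        rng = np.random.default_rng(4)
        table = _table(rng.normal(size=(10, 3)))
        table.iloc[0, 0] = np.nan
        with caplog.at_level(logging.WARNING):
            pca = mv.pca_standardized(table)
        assert pca.imputed_cells == 1

    def test_too_few_crosses_rejected(self):
        with pytest.raises(ValueError):
            mv.pca_standardized(_table(np.eye(2)))

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        table = _table(rng.normal(size=(15, 4)))
        p1, p2 = mv.pca_standardized(table), mv.pca_standardized(table)
        for j in range(p1.loadings.shape[1]):
            col = p1.loadings.iloc[:, j]
            assert col.iloc[np.argmax(np.abs(col.values))] > 0
        pd.testing.assert_frame_equal(p1.scores, p2.scores)


class TestClustering:
    def _blobs(self, n=20, sep=10.0, seed=6):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=(n, 3))
        b = rng.normal(sep, 1.0, size=(n, 3))
        return _table(np.vstack([a, b]))

    def test_two_separated_blobs_recovered(self):
        table = self._blobs()
        pca = mv.pca_standardized(table)
        rep = mv.hcpc_cluster(pca, k="auto", k_range=(2, 6))
        assert rep.k == 2
        labels = [rep.assignments[f"c{i}"] for i in range(len(table))]
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_singleton_clusters_have_zero_inertia(self):
        rng = np.random.default_rng(7)
        table = _table(rng.normal(size=(8, 3)))
        pca = mv.pca_standardized(table)
        rep = mv.hcpc_cluster(pca, k=8, retain_pct=100.0)
        assert sorted(rep.assignments.values()) == list(range(1, 9))
        assert rep.within_inertia[8] == pytest.approx(0.0, abs=1e-10)

    def test_k_larger_than_n_rejected(self):
        table = self._blobs(n=3)
        with pytest.raises(ValueError):
            mv.hcpc_cluster(mv.pca_standardized(table), k=10)

    def test_row_permutation_invariance(self):
        table = self._blobs(n=10, seed=8)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(table))
        shuffled = table.iloc[perm]
        r1 = mv.hcpc_cluster(mv.pca_standardized(table), k=3)
        r2 = mv.hcpc_cluster(mv.pca_standardized(shuffled), k=3)
        assert np.sort(r1.merge_heights) == pytest.approx(
            np.sort(r2.merge_heights)
        )
        # same partition (cluster ids may be renumbered)
        part1 = {}
        for lab, c in r1.assignments.items():
            part1.setdefault(c, set()).add(lab)
        part2 = {}
        for lab, c in r2.assignments.items():
            part2.setdefault(c, set()).add(lab)
        assert set(map(frozenset, part1.values())) == set(
            map(frozenset, part2.values())
        )

    def test_gx1_fixture_auto_k_soft_target(self, gx1):
        """The trial reported three clusters for this table; the selection
        rule is unprinted, so k is asserted within the searched range and a
        deviation from 3 is only logged."""
        pca = mv.pca_standardized(mv.feature_table(gx1))
        rep = mv.hcpc_cluster(pca, k="auto")
        assert 3 <= rep.k <= 6
        if rep.k != 3:
            logging.getLogger(__name__).warning(
                "GX1 auto-k selected %d (reported solution was 3)", rep.k
            )


class TestDescribeClusters:
    def _toy(self):
        table = _table(
            [
                [1.0, 10.0], [2.0, 11.0], [1.5, 10.5],
                [5.0, 10.0], [6.0, 11.0],
                [9.0, 30.0], [10.0, 31.0], [11.0, 29.0],
            ]
        )
        assignments = {f"c{i}": c for i, c in enumerate([1, 1, 1, 2, 2, 3, 3, 3])}
        return table, assignments

    def test_v_statistic_matches_brute_force_oracle(self):
        table, assignments = self._toy()
        stats_df = mv.describe_clusters(assignments, table)
        labels = pd.Series(assignments)
        for _, row in stats_df.iterrows():
            col = table[row["trait"]]
            sub = col[labels == row["cluster"]]
            N, n_c = len(col), len(sub)
            s2 = float(np.var(col))  # population variance
            expected_v = (sub.mean() - col.mean()) / math.sqrt(
                (s2 / n_c) * (N - n_c) / (N - 1)
            )
            assert row["v_statistic"] == pytest.approx(expected_v, rel=1e-12)
            assert row["p_value"] == pytest.approx(
                2 * stats.norm.sf(abs(expected_v)), rel=1e-12
            )

    def test_conservation_of_weighted_category_means(self):
        table, assignments = self._toy()
        stats_df = mv.describe_clusters(assignments, table)
        for trait in table.columns:
            sub = stats_df[stats_df["trait"] == trait]
            total = (sub["n"] * sub["category_mean"]).sum()
            assert total == pytest.approx(len(table) * table[trait].mean())

    def test_cluster_at_overall_mean_has_zero_v(self):
        table = _table([[0.0], [2.0], [1.0], [1.0], [5.0], [-3.0]])
        assignments = {"c2": 1, "c3": 1, "c0": 2, "c1": 2, "c4": 2, "c5": 2}
        stats_df = mv.describe_clusters(assignments, table)
        row = stats_df[(stats_df["cluster"] == 1)].iloc[0]
        assert row["v_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_v_sign_tracks_mean_difference(self, gx1):
        table = mv.feature_table(gx1)
        pca = mv.pca_standardized(table)
        rep = mv.hcpc_cluster(pca, k=3)
        stats_df = mv.describe_clusters(rep.assignments, table)
        for _, row in stats_df.dropna(subset=["v_statistic"]).iterrows():
            diff = row["category_mean"] - row["overall_mean"]
            if diff != 0:
                assert np.sign(row["v_statistic"]) == np.sign(diff)

    def test_single_cluster_rejected(self):
        table, _ = self._toy()
        with pytest.raises(ValueError):
            mv.describe_clusters({lab: 1 for lab in table.index}, table)


class TestCorrelations:
    def test_self_and_anti_correlation(self):
        x = np.arange(8, dtype=float)
        table = _table(np.c_[x, x, -x])
        rep = mv.correlation_matrix(table)
        assert rep.matrix.at["t0", "t1"] == pytest.approx(1.0)
        assert rep.matrix.at["t0", "t2"] == pytest.approx(-1.0)
        assert (np.diag(rep.matrix) == 1.0).all()

    def test_hand_computed_five_points(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        # hand/oracle computation of Pearson r
        r_oracle = float(
            ((a - a.mean()) * (b - b.mean())).sum()
            / math.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        rep = mv.correlation_matrix(_table(np.c_[a, b]))
        assert rep.matrix.at["t0", "t1"] == pytest.approx(r_oracle, rel=1e-12)
        t = r_oracle * math.sqrt(3 / (1 - r_oracle**2))
        assert rep.p_values.at["t0", "t1"] == pytest.approx(
            2 * stats.t.sf(abs(t), 3), rel=1e-9
        )

    def test_pairwise_complete_and_min_pairs(self):
        table = _table(np.c_[np.arange(5.0), np.arange(5.0)])
        table.iloc[2:, 1] = np.nan
        rep = mv.correlation_matrix(table)
        assert math.isnan(rep.matrix.at["t0", "t1"])  # only 2 complete pairs
        assert rep.n_pairs.at["t0", "t1"] == 2

    def test_matrix_symmetric_and_psd(self, gx1):
        rep = mv.correlation_matrix(mv.feature_table(gx1))
        m = rep.matrix.to_numpy()
        assert np.allclose(m, m.T)
        assert np.linalg.eigvalsh(m).min() > -1e-8
        assert ((m >= -1 - 1e-12) & (m <= 1 + 1e-12)).all()

    def test_stars_rendering(self):
        x = np.arange(30, dtype=float)
        rng = np.random.default_rng(11)
        rep = mv.correlation_matrix(
            _table(np.c_[x, x + rng.normal(0, 1, 30)])
        )
        assert rep.stars().at["t0", "t1"] == "***"
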