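import numpy as np
import pandas as pd
import pytest
import skbio
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import neutralcore as nc
from neutralcore.multivariate import (
    _block_permutations,
    alpha_mixed_model_contrasts,
    kruskal_wallis_by_group,
    nested_permanova,
    nmds,
    permdisp,
    spearman_assoc,
    stress1,
)


def euclid_dm(x: np.ndarray, ids=None) -> skbio.DistanceMatrix:
    ids = ids or [f"s{i}" for i in range(len(x))]
    return skbio.DistanceMatrix(squareform(pdist(np.atleast_2d(x.T).T)), ids=ids)


def meta_from(frame: pd.DataFrame) -> nc.SampleMetadata:
    return nc.SampleMetadata(frame)


class TestNestedPermanova:
    def small_design(self, rng, n_per_cell=3):
        rows = []
        for year in (2019, 2022):
            for loc in ("a", "b"):
                for cond in ("uninvaded", "invaded"):
                    for r in range(n_per_cell):
                        rows.append((year, f"{year}{loc}", cond, f"p{r}"))
        frame = pd.DataFrame(
            rows, columns=["year", "location", "condition", "plot"],
            index=[f"s{i}" for i in range(len(rows))],
        )
        x = rng.standard_normal((len(frame), 4))
        return euclid_dm(x, list(frame.index)), meta_from(frame)

    def test_nested_degrees_of_freedom(self):
        dm, meta = self.small_design(np.random.default_rng(0))
        res = nested_permanova(dm, meta, n_perm=19, seed=0)
        # 2 years; 2 locations per year; 2 conditions per location-year
        assert res.df == [1, 2, 4]
        assert res.residual_df == 24 - 8

    def test_ss_partition_conserved(self):
        dm, meta = self.small_design(np.random.default_rng(1))
        res = nested_permanova(dm, meta, n_perm=19, seed=1)
        assert sum(res.ss) + res.residual_ss == pytest.approx(res.total_ss)
        assert sum(res.r_squared) + res.residual_ss / res.total_ss == pytest.approx(1.0)

    def test_matches_classical_anova_on_univariate_euclidean(self):
        # one-way PERMANOVA on Euclidean distances of scalars reproduces the
        # classical ANOVA between/within sums of squares exactly
        rng = np.random.default_rng(2)
        y = rng.standard_normal(15)
        groups = np.repeat(["g1", "g2", "g3"], 5)
        frame = pd.DataFrame(
            {"year": 2019, "location": "L", "condition": "invaded", "group": groups},
            index=[f"s{i}" for i in range(15)],
        )
        dm = euclid_dm(y[:, None], list(frame.index))
        res = nested_permanova(
            dm, meta_from(frame), terms=("group",), blocks=None, n_perm=19, seed=0
        )
        grand = y.mean()
        between = sum(5 * (y[groups == g].mean() - grand) ** 2 for g in set(groups))
        within = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
                     for g in set(groups))
        assert res.ss[0] == pytest.approx(between, abs=1e-9)
        assert res.residual_ss == pytest.approx(within, abs=1e-9)

    def test_block_permutations_never_cross_blocks(self):
        blocks = np.array(["A", "A", "B", "B", "B", "C", "C"])
        perms = _block_permutations(blocks, 50, np.random.default_rng(0))
        for row in perms:
            assert (blocks[row] == blocks).all()

    def test_permutation_p_in_valid_range(self):
        dm, meta = self.small_design(np.random.default_rng(3))
        res = nested_permanova(dm, meta, n_perm=99, seed=3)
        for p in res.p_values:
            assert 1 / 100 <= p <= 1.0

    def test_empty_cell_rejected(self):
        frame = pd.DataFrame(
            {
                "year": [2019, 2019, 2019],
                "location": ["a", "a", "b"],
                "condition": ["invaded"] * 3,
            },
            index=["s0", "s1", "s2"],
        )
        dm = euclid_dm(np.random.default_rng(0).standard_normal((3, 2)),
                       ["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="<2 samples"):
            nested_permanova(dm, meta_from(frame), n_perm=9)


class TestPermdisp:
    def two_groups(self, rng, n=20, contract=1.0):
        a = rng.standard_normal((n, 3))
        b = rng.standard_normal((n, 3)) * contract
        x = np.vstack([a, b])
        ids = [f"s{i}" for i in range(2 * n)]
        groups = pd.Series(["a"] * n + ["b"] * n, index=ids)
        return euclid_dm(x, ids), groups

    def test_df_arithmetic(self):
        dm, groups = self.two_groups(np.random.default_rng(0))
        res = permdisp(dm, groups, n_perm=49, seed=0)
        assert (res.df_between, res.df_within) == (1, 38)

    def test_three_group_df(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 3))
        ids = [f"s{i}" for i in range(30)]
        groups = pd.Series(np.repeat(["a", "b", "c"], 10), index=ids)
        res = permdisp(euclid_dm(x, ids), groups, n_perm=49, seed=1)
        assert (res.df_between, res.df_within) == (2, 27)

    def test_contracted_group_detected(self):
        dm, groups = self.two_groups(np.random.default_rng(2), n=40, contract=0.5)
        res = permdisp(dm, groups, n_perm=199, seed=2)
        assert res.group_means["b"] < res.group_means["a"]
        assert res.p_value <= 0.05

    def test_centroid_center_runs(self):
        dm, groups = self.two_groups(np.random.default_rng(3))
        res = permdisp(dm, groups, center="centroid", n_perm=49, seed=3)
        assert (res.distances >= 0).all()

    def test_singleton_group_rejected(self):
        dm, groups = self.two_groups(np.random.default_rng(4), n=2)
        groups.iloc[0] = "c"
        with pytest.raises(ValueError, match="singleton|<2|at least"):
            permdisp(dm, groups, n_perm=9)

    def test_negative_eigenvalue_correction(self):
        # Bray-Curtis matrices are non-Euclidean: distances must stay real
        prof = nc.simulate_metacommunity(100, seed=5)
        table = nc.simulate_neutral_local_communities(prof, 24, 500, 0.1, seed=5)
        dm = nc.bray_curtis(table)
        groups = pd.Series(
            np.repeat(["a", "b"], 12), index=list(dm.ids)
        )
        res = permdisp(dm, groups, n_perm=49, seed=5)
        assert np.isfinite(res.distances).all() and (res.distances >= 0).all()


class TestNmds:
    def test_collinear_points_embed_with_zero_stress(self):
        x = np.linspace(0, 1, 9)[:, None]
        res = nmds(euclid_dm(x), k=2, n_restarts=16, max_iter=2000, tol=1e-9, seed=0)
        assert res.stress < 1e-3

    def test_duplicated_sample_stays_coincident(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 3))
        x[9] = x[0]
        res = nmds(euclid_dm(x), k=2, n_restarts=8, seed=1)
        coords = res.coordinates.to_numpy()
        dup = np.linalg.norm(coords[0] - coords[9])
        scale = np.mean(pdist(coords))
        assert dup < 0.1 * scale

    def test_stress_self_consistent(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 6))
        dm = euclid_dm(x)
        res = nmds(dm, k=3, n_restarts=6, seed=2)
        recomputed = stress1(dm.data, res.coordinates.to_numpy())
        assert recomputed == pytest.approx(res.stress, rel=0.10, abs=0.01)

    def test_k_bound(self):
        with pytest.raises(ValueError):
            nmds(euclid_dm(np.arange(3.0)[:, None]), k=3)


class TestKruskalWallis:
    def test_hand_computed_no_ties(self):
        h, df, p = kruskal_wallis_by_group([1, 2, 3, 4, 5, 6],
                                           ["a", "a", "a", "b", "b", "b"])
        assert h == pytest.approx(3.857, abs=5e-4)
        assert df == 1

    def test_identical_groups(self):
        h, df, p = kruskal_wallis_by_group([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_monotone_invariance(self):
        x = np.array([1.0, 3.0, 2.0, 8.0, 5.0, 9.0])
        g = ["a", "a", "a", "b", "b", "b"]
        h1, _, _ = kruskal_wallis_by_group(x, g)
        h2, _, _ = kruskal_wallis_by_group(x**3, g)
        assert h1 == pytest.approx(h2)


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_assoc([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman_assoc([1, 2, 3, 4], [9, 7, 5, 3])[0] == pytest.approx(-1.0)

    def test_ties_match_pearson_on_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
        rho, _ = spearman_assoc(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_zero_variance_undefined(self):
        rho, p = spearman_assoc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)


class TestAlphaMixedModel:
    def make_meta(self, conditions, locations, reps, year=2019):
        rows, ids = [], []
        i = 0
        for loc in locations:
            for cond in conditions:
                for _ in range(reps):
                    ids.append(f"s{i}")
                    rows.append({"year": year, "location": loc, "condition": cond})
                    i += 1
        return nc.SampleMetadata(pd.DataFrame(rows, index=ids))

    def test_single_location_reduces_to_t_test(self):
        rng = np.random.default_rng(0)
        meta = self.make_meta(["uninvaded", "invaded"], ["L1"], 12)
        y = rng.standard_normal(24)
        y[meta.frame["condition"] == "invaded"] += 0.8
        alpha = pd.Series(y, index=meta.sample_ids)
        with pytest.warns(UserWarning, match="single location"):
            res = alpha_mixed_model_contrasts(alpha, meta, 2019)
        t_p = stats.ttest_ind(
            y[(meta.frame["condition"] == "invaded").to_numpy()],
            y[(meta.frame["condition"] == "uninvaded").to_numpy()],
        ).pvalue
        assert res.model == "ols"
        assert res.contrasts["p_tukey"].iloc[0] == pytest.approx(t_p, abs=0.01)

    def test_large_effect_detected(self):
        rng = np.random.default_rng(1)
        meta = self.make_meta(["uninvaded", "invaded", "rhizosphere"],
                              ["L1", "L2", "L3", "L4"], 6)
        y = rng.standard_normal(len(meta.sample_ids))
        y[(meta.frame["condition"] == "rhizosphere").to_numpy()] += 5.0
        res = alpha_mixed_model_contrasts(pd.Series(y, index=meta.sample_ids),
                                          meta, 2019)
        big = res.contrasts.filter(like="rhizosphere", axis=0)
        assert (big["p_tukey"] < 0.001).all()
        assert res.model == "mixed"

    def test_null_calibration(self):
        # identical conditions: all pairwise contrasts non-significant in
        # at least 90% of replicates
        meta = self.make_meta(["uninvaded", "invaded", "rhizosphere"],
                              ["L1", "L2", "L3", "L4"], 5)
        ok = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            loc_eff = dict(zip(["L1", "L2", "L3", "L4"], rng.standard_normal(4)))
            y = rng.standard_normal(len(meta.sample_ids))
            y += meta.frame["location"].map(loc_eff).to_numpy()
            res = alpha_mixed_model_contrasts(
                pd.Series(y, index=meta.sample_ids), meta, 2019
            )
            if (res.contrasts["p_tukey"] > 0.05).all():
                ok += 1
        assert ok >= 0.90 * n_rep
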