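import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest

import fluvimyco as fm
from fluvimyco import beta
from fluvimyco.containers import DistanceMatrix, ValidationError

from _oracles import classical_anova_f, naive_gunifrac
from conftest import random_tree_table


def euclid_dm(points, ids=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    ids = ids or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestGunifrac:
    def test_identical_samples_zero(self, three_tip_tree):
        t = fm.OtuTable(pd.DataFrame([[2, 1, 1], [2, 1, 1]],
                                     index=["a", "b"], columns=list("ABC")))
        d = beta.gunifrac(t, three_tip_tree)
        assert d["a", "b"] == pytest.approx(0.0)

    def test_star_tree_disjoint_alpha1(self):
        star = fm.PhyloTree.from_newick("(A:1,B:1,C:1);")
        t = fm.OtuTable(pd.DataFrame([[1, 0, 0], [0, 1, 0]],
                                     index=["a", "b"], columns=list("ABC")))
        d = beta.gunifrac(t, star, alpha=1.0)
        assert d["a", "b"] == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_matches_naive_oracle(self, alpha):
        for seed in range(20):
            tree, table = random_tree_table(8, 4, seed=seed)
            got = beta.gunifrac(table, tree, alpha=alpha)
            rel = table.relative_abundance()
            rel_dict = {s: rel.loc[s].to_dict() for s in table.sample_ids}
            want = naive_gunifrac(tree, rel_dict, alpha)
            for (a, b), v in want.items():
                assert got[a, b] == pytest.approx(v, abs=1e-10)

    def test_bounded_and_symmetric(self):
        tree, table = random_tree_table(12, 6, seed=99)
        d = beta.gunifrac(table, tree).data
        assert np.allclose(d, d.T)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


class TestBrayCurtis:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 1, 0], [0, 0, 2], 1.0),
        ([1, 1, 0], [0, 1, 1], 0.5),
    ])
    def test_known_pairs(self, x, y, expected):
        d = beta.bray_curtis(np.array([x, y], dtype=float))
        assert d.data[0, 1] == pytest.approx(expected)


class TestPcoa:
    def test_equilateral_triangle_eigenvalues(self):
        d = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc"))
        res = beta.pcoa(d)
        assert np.allclose(sorted(res.eigenvalues, reverse=True),
                           [0.5, 0.5, 0.0], atol=1e-10)
        assert res.prop_explained.sum() == pytest.approx(1.0)

    def test_euclidean_embedding_recovered(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 2))
        res = beta.pcoa(euclid_dm(pts))
        # eigenvalues 3..n vanish, coordinates reproduce the distances
        assert np.all(np.abs(res.eigenvalues[2:]) < 1e-8)
        rec = squareform(pdist(res.coordinates.to_numpy()[:, :2]))
        assert np.allclose(rec, squareform(pdist(pts)), atol=1e-8)

    def test_duplicated_point_preserved(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1]])
        res = beta.pcoa(euclid_dm(pts))
        c = res.coordinates.to_numpy()
        assert np.linalg.norm(c[1] - c[2]) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            beta.pcoa(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


class TestPermanova:
    def test_two_cluster_closed_form(self):
        d = euclid_dm([0.0, 1.0, 10.0, 11.0])
        res = beta.permanova(d, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(200.0, abs=1e-8)
        assert res.r_squared == pytest.approx(100.0 / 101.0, abs=1e-10)

    def test_equals_classical_anova_f(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            values = rng.normal(size=12)
            groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
            res = beta.permanova(euclid_dm(values), groups, n_perm=9, seed=1)
            assert res.pseudo_f == pytest.approx(
                classical_anova_f(values, groups), abs=1e-8)

    def test_no_structure_high_p(self):
        d = euclid_dm([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        res = beta.permanova(d, ["a", "a", "a", "b", "b", "b"],
                             n_perm=99, seed=2)
        assert res.p_value > 0.5

    def test_p_floor_and_determinism(self):
        rng = np.random.default_rng(7)
        d = euclid_dm(rng.normal(size=(10, 2)))
        g = ["a"] * 5 + ["b"] * 5
        r1 = beta.permanova(d, g, n_perm=99, seed=5)
        r2 = beta.permanova(d, g, n_perm=99, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1.0 / 100.0

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for i in range(300):
            d = euclid_dm(rng.normal(size=(12, 2)))
            g = rng.permutation(["a"] * 6 + ["b"] * 6)
            pvals.append(beta.permanova(d, g, n_perm=99, seed=i).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPairwisePermanova:
    def test_separated_clusters_all_significant(self):
        rng = np.random.default_rng(1)
        pts = np.concatenate([rng.normal(0, 0.1, (5, 2)),
                              rng.normal(5, 0.1, (5, 2)),
                              rng.normal(10, 0.1, (5, 2))])
        g = pd.Series(np.repeat(["a", "b", "c"], 5),
                      index=[f"p{i}" for i in range(15)])
        out = beta.pairwise_permanova(euclid_dm(pts), g, n_perm=199, seed=0)
        assert len(out) == 3
        assert (out["p_adj"] <= 0.05).all()

    def test_bh_identity_single_pair(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 2))
        g = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"p{i}" for i in range(8)])
        out = beta.pairwise_permanova(euclid_dm(pts), g, n_perm=99, seed=0)
        assert out["p_adj"].iloc[0] == out["p"].iloc[0]

    def test_identical_groups_rarely_flagged(self):
        rng = np.random.default_rng(3)
        flags = 0
        n_rep = 50
        for i in range(n_rep):
            pts = rng.normal(size=(12, 2))
            g = pd.Series(np.repeat(["a", "b", "c"], 4),
                          index=[f"p{i}" for i in range(12)])
            out = beta.pairwise_permanova(euclid_dm(pts), g, n_perm=99, seed=i)
            flags += (out["p_adj"] <= 0.05).any()
        assert flags <= 0.2 * n_rep


class TestEnvfit:
    def _ordination(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        return beta.pcoa(euclid_dm(pts)), rng

    def test_variable_equal_to_axis_flagged(self):
        ordn, _ = self._ordination()
        env = fm.EnvTable(
            pd.DataFrame({"v": ordn.coordinates.iloc[:, 0].to_numpy(),
                          "noise": np.linspace(0, 1, 24) ** 2},
                         index=ordn.coordinates.index),
            pd.Series(np.arange(24.0), index=ordn.coordinates.index))
        out = beta.envfit_axes(ordn, env)
        row = out.loc["v"]
        assert row["r_axis1"] == pytest.approx(1.0)
        assert bool(row["flag_axis1"])

    def test_sign_flip_keeps_flag(self):
        ordn, _ = self._ordination(seed=5)
        x = ordn.coordinates.iloc[:, 0].to_numpy()
        env = fm.EnvTable(pd.DataFrame({"v": x, "w": -x},
                                       index=ordn.coordinates.index),
                          pd.Series(np.arange(24.0),
                                    index=ordn.coordinates.index))
        out = beta.envfit_axes(ordn, env)
        assert out.loc["v", "r_axis1"] == pytest.approx(-out.loc["w", "r_axis1"])
        assert bool(out.loc["v", "flag_axis1"]) == bool(out.loc["w", "flag_axis1"])

    def test_noise_rarely_flagged(self):
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            ordn, rng = self._ordination(seed=100 + i)
            env = fm.EnvTable(
                pd.DataFrame({"noise": rng.normal(size=24)},
                             index=ordn.coordinates.index),
                pd.Series(np.arange(24.0), index=ordn.coordinates.index))
            out = beta.envfit_axes(ordn, env)
            hits += bool(out[["flag_axis1", "flag_axis2"]].any().any())
        assert hits <= 0.01 * n_rep + 2


class TestCollinearityScreen:
    def test_perfect_monotone_flagged(self):
        x = np.linspace(0, 1, 24)
        env = fm.EnvTable(pd.DataFrame({"x": x, "y": 2 * x,
                                        "z": np.random.default_rng(0).normal(size=24)}),
                          pd.Series(np.arange(24.0)))
        out = beta.collinearity_screen(env)
        row = out[(out.var_a == "x") & (out.var_b == "y")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert bool(row["flagged"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=24)
        y = rng.normal(size=24)
        e1 = fm.EnvTable(pd.DataFrame({"x": x, "y": y}), pd.Series(np.arange(24.0)))
        e2 = fm.EnvTable(pd.DataFrame({"x": np.exp(x), "y": y}),
                         pd.Series(np.arange(24.0)))
        r1 = beta.collinearity_screen(e1)["rho"].iloc[0]
        r2 = beta.collinearity_screen(e2)["rho"].iloc[0]
        assert r1 == pytest.approx(r2)

    def test_independent_noise_rarely_flagged(self):
        rng = np.random.default_rng(2)
        flags = 0
        n_rep = 200
        for _ in range(n_rep):
            env = fm.EnvTable(pd.DataFrame(rng.uniform(size=(24, 2)),
                                           columns=["a", "b"]),
                              pd.Series(np.arange(24.0)))
            flags += bool(beta.collinearity_screen(env)["flagged"].any())
        assert flags < 0.1 * n_rep


class TestSimprof:
    def _blob_env(self, delta, seed=0, n_per=6):
        rng = np.random.default_rng(seed)
        pts = np.concatenate([rng.normal(0, 1, (n_per, 3)),
                              rng.normal(delta, 1, (n_per, 3))])
        return fm.EnvTable(pd.DataFrame(pts, columns=["a", "b", "c"]),
                           pd.Series(np.arange(float(2 * n_per))))

    def test_two_blobs_found(self):
        env = self._blob_env(delta=10.0)
        res = beta.simprof_cluster(env, n_perm=99, seed=0)
        assert res.k == 2
        assert res.p_value <= 0.05

    def test_noise_usually_insignificant(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 40
        for i in range(n_rep):
            env = fm.EnvTable(pd.DataFrame(rng.normal(size=(12, 3)),
                                           columns=["a", "b", "c"]),
                              pd.Series(np.arange(12.0)))
            res = beta.simprof_cluster(env, n_perm=99, seed=i)
            hits += bool(res.significant)
        assert hits <= 0.25 * n_rep

    def test_duplicating_samples_keeps_k(self):
        env = self._blob_env(delta=10.0, n_per=6)
        doubled = fm.EnvTable(
            pd.concat([env.data, env.data.set_axis(
                [f"d{i}" for i in range(len(env.data))])]),
            pd.concat([env.channel_km, env.channel_km.set_axis(
                [f"d{i}" for i in range(len(env.data))])]))
        r1 = beta.simprof_cluster(env, n_perm=99, seed=1)
        r2 = beta.simprof_cluster(doubled, n_perm=99, seed=1)
        assert r1.k == r2.k


class TestDistanceDecay:
    def test_exact_linear_relation(self):
        km = pd.Series(np.arange(6.0), index=[f"s{i}" for i in range(6)])
        from fluvimyco.spatial import geographic_distance
        geo = geographic_distance(km)
        comm = DistanceMatrix(2.0 * geo.data, ids=list(geo.ids))
        res = beta.distance_decay(comm, geo)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_pair_count(self):
        n = 22
        km = pd.Series(np.arange(float(n)), index=[f"s{i}" for i in range(n)])
        from fluvimyco.spatial import geographic_distance
        geo = geographic_distance(km)
        res = beta.distance_decay(geo, geo)
        assert res.n_pairs == 231  # n(n-1)/2 for 22 samples

    def test_slope_recovery_with_noise(self):
        from fluvimyco.spatial import geographic_distance
        n = 15
        km = pd.Series(np.linspace(0, 1, n), index=[f"s{i}" for i in range(n)])
        geo = geographic_distance(km)
        rng = np.random.default_rng(0)
        inside = 0
        n_rep = 200
        for _ in range(n_rep):
            noise = rng.normal(0, 0.1, size=(n, n))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            comm = DistanceMatrix(1.0 + 0.5 * geo.data + noise
                                  - np.eye(n), ids=list(geo.ids))
            res = beta.distance_decay(comm, geo)
            iu = np.triu_indices(n, 1)
            x = geo.data[iu]
            se = np.sqrt(np.sum((comm.data[iu] - res.intercept
                                 - res.slope * x) ** 2)
                         / (len(x) - 2) / np.sum((x - x.mean()) ** 2))
            inside += abs(res.slope - 0.5) <= 1.96 * se
        assert inside >= 0.88 * n_rep
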