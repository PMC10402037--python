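"""Clustering, MDS, time courses and the connectome density test."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from sklearn.metrics import adjusted_rand_score

import pairbondmap as pbm


def brute_force_ward_cophenetic(D):
    """O(n^3) ward.D2 oracle via the Lance-Williams update.

    Maintains squared inter-cluster distances and returns the
    cophenetic distance matrix (merge height for every leaf pair),
    which is invariant to the bookkeeping order scipy uses.
    """
    n = D.shape[0]
    d2 = {(i, j): D[i, j] ** 2 for i in range(n) for j in range(n) if i < j}
    clusters = {i: [i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    coph = np.zeros((n, n))
    nxt = n

    def key(a, b):
        return (a, b) if a < b else (b, a)

    while len(clusters) > 1:
        (i, j), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        h = np.sqrt(best)
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = h
        ni, nj = sizes[i], sizes[j]
        merged = clusters[i] + clusters[j]
        for k in clusters:
            if k in (i, j):
                continue
            nk = sizes[k]
            val = (
                (ni + nk) * d2[key(i, k)]
                + (nj + nk) * d2[key(j, k)]
                - nk * d2[key(i, j)]
            ) / (ni + nj + nk)
            d2[key(nxt, k)] = val
        for k in list(d2):
            if i in k or j in k:
                del d2[k]
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[nxt] = merged
        sizes[nxt] = ni + nj
        nxt += 1
    return coph


class TestScaling:
    def test_columns_standardized(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 6)), columns=list("abcdef"))
        scaled = pbm.zscore_units(df)
        assert np.abs(scaled.mean()).max() < 1e-10
        assert np.abs(scaled.std(ddof=1) - 1).max() < 1e-10

    def test_round_trip(self, rng):
        df = pd.DataFrame(rng.poisson(20, size=(30, 4)).astype(float), columns=list("wxyz"))
        scaled = pbm.zscore_units(df)
        back = scaled * scaled.attrs["scale"] + scaled.attrs["center"]
        assert np.abs(back - df).max().max() < 1e-10

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": 3.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled = pbm.zscore_units(df)
        assert list(scaled.columns) == ["a"]


class TestDistance:
    def test_three_four_five(self):
        df = pd.DataFrame({"u": [0.0, 0.0], "v": [3.0, 4.0]})
        d = pbm.unit_distance(df)
        assert d.loc["u", "v"] == pytest.approx(5.0)
        assert d.loc["u", "u"] == 0.0

    def test_matches_naive_double_loop(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 8)))
        d = pbm.unit_distance(df).to_numpy()
        X = df.to_numpy().T
        for i in range(8):
            for j in range(8):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-10
                )
        assert np.allclose(d, d.T)


class TestWard:
    def test_two_units_merge_at_their_distance(self):
        df = pd.DataFrame({"a": [0.0, 0.0, 1.0], "b": [1.0, 2.0, 0.0]})
        d = pbm.unit_distance(df)
        tree = pbm.ward_linkage(d)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(d.loc["a", "b"])

    def test_matches_brute_force_oracle(self, rng):
        """Cophenetic structure equals the O(n^3) Lance-Williams oracle."""
        for _ in range(100):
            n = int(rng.integers(3, 13))
            pts = rng.normal(size=(n, 3))
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            dist = pd.DataFrame(D, index=range(n), columns=range(n))
            tree = pbm.ward_linkage(dist.set_axis([str(i) for i in range(n)]).set_axis([str(i) for i in range(n)], axis=1))
            coph_pkg = cophenet(tree.merges)
            coph_oracle = brute_force_ward_cophenetic(D)
            iu = np.triu_indices(n, 1)
            assert np.allclose(coph_pkg, coph_oracle[iu], atol=1e-8)

    def test_heights_monotone(self, rng):
        for _ in range(25):
            pts = rng.normal(size=(10, 4))
            df = pd.DataFrame(pts.T)
            df.columns = [f"u{i}" for i in range(10)]
            tree = pbm.ward_linkage(pbm.unit_distance(df))
            assert (np.diff(tree.heights) >= -1e-12).all()

    def test_separated_clouds_merge_last(self, rng):
        a = rng.normal(0, 0.1, size=(4, 5))
        b = rng.normal(100, 0.1, size=(4, 5))
        df = pd.DataFrame(np.vstack([a, b]).T, columns=[f"u{i}" for i in range(8)])
        tree = pbm.ward_linkage(pbm.unit_distance(df))
        assert tree.heights[-1] > 50 * tree.heights[-2]

    def test_single_unit_errors(self):
        with pytest.raises(ValueError):
            pbm.ward_linkage(pd.DataFrame([[0.0]], index=["a"], columns=["a"]))


class TestCutTree:
    def test_extremes(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 6)), columns=list("abcdef"))
        tree = pbm.ward_linkage(pbm.unit_distance(df))
        assert set(pbm.cut_tree(tree, 1).values()) == {1}
        assert len(set(pbm.cut_tree(tree, 6).values())) == 6
        with pytest.raises(ValueError):
            pbm.cut_tree(tree, 0)
        with pytest.raises(ValueError):
            pbm.cut_tree(tree, 7)

    def test_recovers_planted_blobs(self, rng):
        centers = [0.0, 50.0, 100.0]
        truth, cols = [], []
        for c, center in enumerate(centers):
            for i in range(5):
                cols.append(rng.normal(center, 1.0, size=12))
                truth.append(c)
        df = pd.DataFrame(np.column_stack(cols), columns=[f"u{i}" for i in range(15)])
        tree = pbm.ward_linkage(pbm.unit_distance(df))
        assign = pbm.cut_tree(tree, 3)
        labels = [assign[f"u{i}"] for i in range(15)]
        assert adjusted_rand_score(truth, labels) == 1.0


class TestCorrelations:
    def test_trivial_and_oracle(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"a": x, "b": x, "c": -x, "d": rng.normal(size=20)})
        corr = pbm.unit_correlations(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        # textbook formula oracle
        u, v = df["a"].to_numpy(), df["d"].to_numpy()
        ru = (((u - u.mean()) * (v - v.mean())).sum()) / np.sqrt(
            ((u - u.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum()
        )
        assert corr.loc["a", "d"] == pytest.approx(ru, abs=1e-12)

    def test_zero_variance_flagged_missing(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": 1.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = pbm.unit_correlations(df)
        assert np.isnan(corr.loc["a", "b"])


class TestMDS:
    def _planar_distances(self, rng, n=10):
        pts = rng.uniform(size=(n, 2)) * 10
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return pd.DataFrame(D, index=[f"u{i}" for i in range(n)], columns=[f"u{i}" for i in range(n)])

    def test_embeddable_input_has_tiny_stress(self, rng):
        d = self._planar_distances(rng)
        res = pbm.mds_embed(d, dims=2, seed=0)
        assert res.stress < 0.01
        assert res.coords.shape == (10, 2)

    def test_stress_decreases_with_dimensions(self, rng):
        d = self._planar_distances(rng)
        s1 = pbm.mds_embed(d, dims=1, seed=0).stress
        s2 = pbm.mds_embed(d, dims=2, seed=0).stress
        assert s2 < s1

    def test_rank_invariance_under_scaling(self, rng):
        d = self._planar_distances(rng)
        s = pbm.mds_embed(d, dims=2, seed=0).stress
        s_doubled = pbm.mds_embed(2 * d, dims=2, seed=0).stress
        assert s_doubled == pytest.approx(s, abs=1e-6)


class TestTimeCourse:
    def test_scaled_totals_center_and_planted_ordering(self, design12):
        cfg = pbm.SimConfig(
            n_pairs_per_cell=12,
            n_units=4,
            effect_units={"a": 0.0, "b": 0.0},
            coupling_units=[],
            cluster_latent_sd=0.0,
            time_profile=(0.0, 0.0, 0.0, 0.0),
            seed=3,
        )
        cnt = pbm.generate_counts(design12, list("abcd"), cfg)
        # plant a mate effect at timepoints 2-3 by hand
        mid = design12["timepoint"].isin([2, 3]) & (design12["partner_type"] == "mate")
        cnt.loc[mid.to_numpy(), ["a", "b"]] *= 3
        assign = {"a": 1, "b": 1, "c": 2, "d": 2}
        tc = pbm.cluster_time_course(cnt, assign, design12)
        # z-scored totals sum to ~0 within each cluster
        c1 = tc[tc["cluster"] == 1]
        assert (c1["mean"] * c1["n"]).sum() == pytest.approx(0.0, abs=1e-8)
        for tp in (2, 3):
            m = c1[(c1["partner_type"] == "mate") & (c1["timepoint"] == tp)]["mean"].mean()
            s = c1[(c1["partner_type"] == "sibling") & (c1["timepoint"] == tp)]["mean"].mean()
            assert m > s
        # null cluster has small group means
        c2 = tc[tc["cluster"] == 2]
        assert c2["mean"].abs().max() < 1.0


class TestConnectivityDensity:
    def test_all_ones(self):
        units = list("abcd")
        conn = pd.DataFrame(np.ones((4, 4)), index=units, columns=units)
        per, overall = pbm.connectivity_density(conn, {u: 1 for u in units})
        assert per[1] == 1.0 and overall == 1.0

    def test_two_member_cluster_mean(self):
        units = ["u", "v"]
        conn = pd.DataFrame([[9.0, 0.4], [0.6, 9.0]], index=units, columns=units)
        per, overall = pbm.connectivity_density(conn, {"u": 1, "v": 1})
        assert per[1] == pytest.approx(0.5)

    def test_matches_index_loop_oracle(self, rng):
        units = [f"r{i}" for i in range(12)]
        conn = pd.DataFrame(rng.uniform(size=(12, 12)), index=units, columns=units)
        assign = {u: i % 3 for i, u in enumerate(units)}
        per, overall = pbm.connectivity_density(conn, assign)
        for c in range(3):
            members = [u for u in units if assign[u] == c]
            vals = [
                conn.loc[a, b]
                for a in members
                for b in members
                if a != b
            ]
            assert per[c] == pytest.approx(np.mean(vals), abs=1e-12)
        assert overall == pytest.approx(np.mean(list(per.values())), abs=1e-12)

    def test_small_cluster_skipped(self, rng):
        units = list("abc")
        conn = pd.DataFrame(rng.uniform(size=(3, 3)), index=units, columns=units)
        with pytest.warns(UserWarning, match="skipped"):
            per, _ = pbm.connectivity_density(conn, {"a": 1, "b": 1, "c": 2})
        assert list(per) == [1]


class TestConnectomeMapping:
    def test_identity_ancestor_and_unresolved(self):
        N = pbm.StructureNode
        atlas = pbm.AtlasHierarchy(
            [
                N(1, "root", "root", None),
                N(2, "BST", "bst", 1),
                N(3, "BSTpr", "bstpr", 2),
                N(4, "XX", "xx", 1),
            ]
        )
        with pytest.warns(UserWarning, match="unresolvable"):
            mapping, unresolved = pbm.map_to_connectome(
                ["BST", "BSTpr", "XX"], ["BST"], atlas
            )
        assert mapping == {"BST": "BST", "BSTpr": "BST"}
        assert unresolved == ["XX"]


class TestConnectivityPermutation:
    def test_constant_matrix_p_one(self):
        units = list("abcd")
        conn = pd.DataFrame(np.ones((4, 4)) * 0.3, index=units, columns=units)
        with pytest.warns(UserWarning, match="constant"):
            _, p = pbm.connectivity_permutation_test(conn, {u: 1 for u in units}, n_perm=50, seed=0)
        assert p == 1.0

    def test_exhaustive_four_roi_case(self, rng):
        """Monte-Carlo p within 0.05 of exhaustive over all 24 row shuffles."""
        units = list("abcd")
        M = rng.uniform(size=(4, 4))
        M[:2, :2] += 1.0  # block-dense pair cluster
        conn = pd.DataFrame(M, index=units, columns=units)
        assign = {"a": 1, "b": 1, "c": 2, "d": 2}
        clusters = {1: [0, 1], 2: [2, 3]}

        def density(perm):
            vals = []
            for idx in clusters.values():
                tot = sum(
                    M[perm[i], j] for i in idx for j in idx if i != j
                )
                vals.append(tot / (len(idx) ** 2 - len(idx)))
            return np.mean(vals)

        observed = density(list(range(4)))
        null = [density(list(p)) for p in itertools.permutations(range(4))]
        p_exact = np.mean([v >= observed for v in null])
        _, p_mc = pbm.connectivity_permutation_test(conn, assign, n_perm=4000, seed=5)
        assert p_mc == pytest.approx(p_exact, abs=0.05)

    def test_null_pvalues_uniform_under_shuffled_assignments(self, rng):
        """Random (label-shuffled) cluster assignments give uniform p."""
        from scipy import stats

        units = [f"r{i}" for i in range(12)]
        ps = []
        for rep in range(200):
            conn = pd.DataFrame(
                np.random.default_rng(rep).uniform(size=(12, 12)),
                index=units,
                columns=units,
            )
            labels = np.random.default_rng(1000 + rep).permutation([i % 3 for i in range(12)])
            assign = dict(zip(units, labels))
            _, p = pbm.connectivity_permutation_test(conn, assign, n_perm=99, seed=rep)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_deterministic(self, rng):
        units = [f"r{i}" for i in range(8)]
        conn = pd.DataFrame(rng.uniform(size=(8, 8)), index=units, columns=units)
        assign = {u: i % 2 for i, u in enumerate(units)}
        a = pbm.connectivity_permutation_test(conn, assign, n_perm=200, seed=9)
        b = pbm.connectivity_permutation_test(conn, assign, n_perm=200, seed=9)
        assert a == b
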