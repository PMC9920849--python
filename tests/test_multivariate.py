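"""Correlation PCA, Kaiser retention, UPGMA and Newick export."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gourdstats import (
    TraitSpec,
    biplot_coords,
    cut_clusters,
    euclidean_dissimilarity,
    kaiser_retain,
    mean_impute,
    pca_correlation,
    significant_loadings,
    simulate_trait_table,
    tree_to_newick,
    upgma,
    zscore_standardize,
)
from gourdstats.exceptions import DesignError, GourdstatsError
from gourdstats.traits import landrace_trait_means

from conftest import make_config


def random_frame(rng, n=10, p=4):
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"V{i}" for i in range(p)]
    )


class TestStandardize:
    def test_three_point_column(self):
        z = zscore_standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert z["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_and_zero_mean(self, rng):
        X = random_frame(rng)
        z = zscore_standardize(X)
        z2 = zscore_standardize(z)
        pd.testing.assert_frame_equal(z, z2, rtol=1e-12)
        assert np.abs(z.mean().to_numpy()).max() < 1e-12
        assert np.allclose(z.std(ddof=1), 1.0)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(GourdstatsError, match="flat"):
            zscore_standardize(X)


class TestPcaCorrelation:
    def test_uncorrelated_three_variables(self, rng):
        # large n: correlation matrix ~ identity, eigenvalues ~ (1,1,1)
        X = random_frame(rng, n=20_000, p=3)
        res = pca_correlation(X)
        assert np.allclose(res.eigenvalues, 1.0, atol=0.05)
        assert np.allclose(res.variability, 100 / 3, atol=2.0)

    def test_two_variable_closed_form(self, rng):
        # for a 2x2 correlation matrix the eigenvalues are 1 +/- r
        x = rng.normal(size=4000)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=4000)
        X = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        res = pca_correlation(X)
        assert res.eigenvalues == pytest.approx([1 + r, 1 - r], abs=1e-9)
        assert res.variability == pytest.approx(
            [(1 + r) * 50, (1 - r) * 50], abs=1e-6
        )

    def test_eigenvalue_sum_and_reconstruction(self, rng):
        X = random_frame(rng, n=30, p=6)
        res = pca_correlation(X)
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)
        assert res.cumulative[-1] == pytest.approx(100.0, abs=1e-8)
        assert np.all(np.diff(res.cumulative) >= -1e-12)
        L = res.loadings.to_numpy()
        corr = np.corrcoef(zscore_standardize(X).to_numpy(), rowvar=False)
        assert np.allclose(L @ L.T, corr, atol=1e-8)

    def test_score_variances_equal_eigenvalues(self, rng):
        X = random_frame(rng, n=40, p=5)
        res = pca_correlation(X)
        # sample variance of scores along each axis equals the eigenvalue
        assert np.allclose(
            res.scores.var(ddof=1).to_numpy(), res.eigenvalues, atol=1e-8
        )

    def test_sign_convention_is_deterministic(self, rng):
        X = random_frame(rng, n=25, p=4)
        a = pca_correlation(X)
        b = pca_correlation(X.copy())
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        for j in range(4):
            col = a.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_rank_deficient_input_allowed(self, rng):
        x = rng.normal(size=12)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=12)})
        res = pca_correlation(X)
        assert res.eigenvalues.min() == pytest.approx(0.0, abs=1e-10)


class TestKaiserRetain:
    def test_reference_eigenvalue_sequence_retains_three(self):
        ev = (4.723, 2.468, 1.457, 0.777, 0.35, 0.12, 0.06, 0.02, 0.01, 0.005)
        assert kaiser_retain(ev) == (0, 1, 2)

    def test_boundary_inclusive(self):
        assert kaiser_retain((1.0, 1.0, 1.0)) == (0, 1, 2)

    def test_fallback_retains_first_with_warning(self):
        with pytest.warns(UserWarning):
            assert kaiser_retain((0.9, 0.1)) == (0,)

    def test_empty_rejected(self):
        with pytest.raises(GourdstatsError):
            kaiser_retain(())


class TestSignificantLoadings:
    def test_strict_threshold(self, rng):
        X = random_frame(rng, n=10, p=3)
        res = pca_correlation(X)
        object.__setattr__(
            res, "loadings",
            pd.DataFrame(
                [[0.6, -0.672], [0.0, 0.2]],
                index=["u", "v"], columns=["PC1", "PC2"],
            ),
        )
        mask = significant_loadings(res, threshold=0.6)
        assert not mask.loc["u", "PC1"]  # exactly 0.6 is not significant
        assert mask.loc["u", "PC2"]  # |-0.672| > 0.6
        assert not mask.to_numpy()[1].any()


class TestBiplot:
    def test_scores_and_loadings_on_first_two_axes(self, rng):
        X = random_frame(rng, n=15, p=4)
        res = pca_correlation(X)
        scores, loadings = biplot_coords(res)
        assert list(scores.columns) == ["PC1", "PC2"]
        assert list(loadings.columns) == ["PC1", "PC2"]
        pd.testing.assert_frame_equal(scores, res.scores.iloc[:, :2])


class TestEuclidean:
    def test_identical_rows_zero_distance(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        D = euclidean_dissimilarity(X)
        assert D.loc["a", "b"] == 0.0

    def test_three_four_five(self):
        X = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        assert euclidean_dissimilarity(X).loc["a", "b"] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        X = random_frame(rng, n=10, p=5)
        D = euclidean_dissimilarity(X).to_numpy()
        for i in range(10):
            for j in range(10):
                ref = np.sqrt(((X.iloc[i] - X.iloc[j]) ** 2).sum())
                assert D[i, j] == pytest.approx(ref, abs=1e-12)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)


def upgma_oracle(D, labels):
    """Exhaustive agglomeration: cluster distance recomputed each step as the
    plain mean of all between-cluster leaf distances (the UPGMA definition),
    independent of the recurrence-update implementation."""
    D = np.asarray(D, dtype=float)
    clusters = {i: (frozenset([i]), labels[i]) for i in range(len(labels))}
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            la, lb = clusters[a][0], clusters[b][0]
            d = np.mean([D[i, j] for i in la for j in lb])
            mn = min(clusters[a][1], clusters[b][1])
            mx = max(clusters[a][1], clusters[b][1])
            cand = (d, mn, mx, a, b)
            if best is None or cand < best:
                best = cand
        d, _, _, a, b = best
        merged = clusters[a][0] | clusters[b][0]
        label = min(clusters[a][1], clusters[b][1])
        del clusters[a], clusters[b]
        clusters[next_id] = (merged, label)
        merges.append((frozenset((a, b)) if False else (a, b), d / 2.0, next_id, merged))
        next_id += 1
    return merges


class TestUpgma:
    def test_two_leaves(self):
        tree = upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        assert tree.merges == ((0, 1, 2.0, 2),)

    def test_three_leaf_hand_execution(self):
        D = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 6.0], [8.0, 6.0, 0.0]])
        tree = upgma(D, ["A", "B", "C"])
        (a1, b1, h1, n1), (a2, b2, h2, n2) = tree.merges
        assert {a1, b1} == {0, 1} and h1 == pytest.approx(1.0)
        assert {a2, b2} == {2, 3} and h2 == pytest.approx(3.5)

    def test_matches_exhaustive_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            n = 6
            X = rng.normal(size=(n, 3))
            D = euclidean_dissimilarity(pd.DataFrame(X)).to_numpy()
            labels = [f"L{i}" for i in range(n)]
            tree = upgma(D, labels)
            oracle = upgma_oracle(D, labels)
            for (a, b, h, new), (pair, oh, onew, _members) in zip(tree.merges, oracle):
                assert {a, b} == set(pair)
                assert new == onew
                assert h == pytest.approx(oh, rel=1e-10)

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import pdist

        X = rng.normal(size=(8, 4))
        Z = average(pdist(X))
        tree = upgma(euclidean_dissimilarity(pd.DataFrame(X)))
        heights = sorted(m[2] for m in tree.merges)
        assert np.allclose(heights, sorted(Z[:, 2] / 2.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 9))
    def test_heights_ultrametric_monotone(self, seed, n):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        D = euclidean_dissimilarity(pd.DataFrame(X))
        tree = upgma(D)
        heights = [m[2] for m in tree.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))
        assert len(tree.merges) == n - 1

    def test_invalid_matrices_rejected(self):
        with pytest.raises(DesignError):
            upgma(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(DesignError):
            upgma(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_separated_genotype_groups_recovered(self):
        hits = 0
        n_seeds = 200
        traits = {
            "A": TraitSpec(mu=0.0, sigma2_g=1.0, sigma2_e=1.0),
            "B": TraitSpec(mu=0.0, sigma2_g=1.0, sigma2_e=1.0),
        }
        for seed in range(n_seeds):
            lo = simulate_trait_table(
                make_config(traits=traits, n_landraces=4, n_blocks=2,
                            n_within=1, stages=("S1",), seed=seed)
            )
            hi = simulate_trait_table(
                make_config(traits={
                    "A": TraitSpec(mu=30.0, sigma2_g=1.0, sigma2_e=1.0),
                    "B": TraitSpec(mu=30.0, sigma2_g=1.0, sigma2_e=1.0),
                }, n_landraces=4, n_blocks=2, n_within=1, stages=("S1",),
                    seed=seed + 100_000)
            )
            hi = hi.assign(landrace=hi["landrace"].str.replace("LR", "HI"))
            table = pd.concat([lo, hi], ignore_index=True)
            means = landrace_trait_means(table)
            tree = upgma(euclidean_dissimilarity(means))
            clusters = cut_clusters(tree, 2)
            groups = {}
            for lab, cid in clusters.items():
                groups.setdefault(cid, set()).add(lab[:2])
            if all(len(g) == 1 for g in groups.values()):
                hits += 1
        assert hits / n_seeds >= 0.95


class TestCutClusters:
    @pytest.fixture
    def tri_tree(self):
        D = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 6.0], [8.0, 6.0, 0.0]])
        return upgma(D, ["A", "B", "C"])

    def test_trivial_cuts(self, tri_tree):
        assert set(cut_clusters(tri_tree, 1).values()) == {1}
        assert sorted(cut_clusters(tri_tree, 3).values()) == [1, 2, 3]

    def test_two_cluster_cut(self, tri_tree):
        clusters = cut_clusters(tri_tree, 2)
        assert clusters["A"] == clusters["B"] != clusters["C"]

    def test_out_of_range_rejected(self, tri_tree):
        with pytest.raises(GourdstatsError):
            cut_clusters(tri_tree, 0)
        with pytest.raises(GourdstatsError):
            cut_clusters(tri_tree, 4)


class TestNewick:
    def test_two_leaf_string(self):
        tree = upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        assert tree_to_newick(tree) == "(A:2,B:2);"

    def test_round_trip_with_dendropy(self, rng):
        import dendropy

        X = rng.normal(size=(7, 3))
        tree = upgma(euclidean_dissimilarity(pd.DataFrame(X, index=list("ABCDEFG"))))
        nwk = tree_to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set("ABCDEFG")
        # ultrametric: every root-to-leaf path equals the final merge height
        final_h = tree.merges[-1][2]
        for leaf in parsed.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(final_h, rel=1e-9)

    def test_labels_with_spaces_quoted(self):
        tree = upgma(np.array([[0.0, 2.0], [2.0, 0.0]]), ["BG 19", "KRI"])
        nwk = tree_to_newick(tree)
        assert "'BG 19'" in nwk
        import dendropy

        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {
            "BG 19", "KRI",
        }


class TestMeanImpute:
    def test_fills_with_column_mean_and_warns(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="imputing"):
            out = mean_impute(X)
        assert out.loc[1, "a"] == pytest.approx(2.0)
        assert not out.isna().any().any()
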