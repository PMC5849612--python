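"""Multivariate statistics: pPCA, clustering, ANCOVA, LDA, MANOVA, screening."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wingbeam import comparative_inference as ci
from wingbeam import phylo_model as pm
from wingbeam import synthetic_data as sd


def _star_tree(n, depth=1.0):
    return pm.read_tree("(" + ",".join(f"T{i}:{depth}" for i in range(n)) + ");")


class TestPhylPCA:
    def test_star_tree_equals_ordinary_pca(self, rng):
        n = 40
        tree = _star_tree(n)
        X = pd.DataFrame(
            rng.normal(size=(n, 4)) @ np.diag([1, 2, 3, 4]),
            index=[f"T{i}" for i in range(n)],
            columns=list("abcd"),
        )
        res = ci.phyl_pca(X, tree, mode="cor")
        Z = (X - X.mean()) / X.std(ddof=1)
        evals, evecs = np.linalg.eigh(np.corrcoef(Z.T))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(res.eigenvalues, evals, atol=1e-8)
        scores = Z.to_numpy() @ evecs
        for k in range(4):
            a, b = res.scores.iloc[:, k].to_numpy(), scores[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_matches_phytools_on_nonstar_tree(self, tmp_path, rng):
        newick = "((A:1,B:1):1,(C:0.5,(D:0.2,E:0.2):0.3):1.5);"
        tree = pm.read_tree(newick)
        X = pd.DataFrame(
            rng.normal(size=(5, 4)),
            index=list("ABCDE"),
            columns=[f"v{i}" for i in range(4)],
        )
        res = ci.phyl_pca(X, tree, mode="cor")
        csv = tmp_path / "X.csv"
        out = tmp_path / "scores.csv"
        X.to_csv(csv)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(phytools))
            tree <- read.tree(text="{newick}")
            X <- as.matrix(read.csv("{csv}", row.names=1))
            p <- phyl.pca(tree, X, method="BM", mode="cor")
            write.csv(p$S, "{out}")
            """
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        S = pd.read_csv(out, index_col=0).loc[res.scores.index]
        for k in range(4):
            a = res.scores.iloc[:, k].to_numpy()
            b = S.iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_eigenvalues_sum_to_variable_count(self, default_dataset):
        _, table, tree, _ = default_dataset
        X = ci.analysis_matrix(table.aligned_to(tree))
        res = ci.phyl_pca(X, tree, mode="cor")
        assert res.eigenvalues.sum() == pytest.approx(4.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_collinear_variables_give_zero_eigenvalue(self, rng):
        n = 20
        tree = _star_tree(n)
        base = rng.normal(size=n)
        X = pd.DataFrame(
            {"a": base, "b": 2 * base, "c": rng.normal(size=n)},
            index=[f"T{i}" for i in range(n)],
        )
        res = ci.phyl_pca(X, tree, mode="cor")
        assert res.eigenvalues[-1] == pytest.approx(0.0, abs=1e-10)


class TestPAM:
    def test_equals_bruteforce_on_small_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(n, 2))
            res = ci.pam_cluster(X, 2)
            D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(2))
            best = min(
                D[:, list(m)].min(1).sum()
                for m in itertools.combinations(range(n), 2)
            )
            assert res.cost == pytest.approx(best, abs=1e-9)

    def test_separated_clouds_split_perfectly(self, rng):
        # large n exercises the BUILD+SWAP path
        X = np.vstack(
            [rng.normal(0, 1, size=(110, 3)), rng.normal(12, 1, size=(110, 3))]
        )
        res = ci.pam_cluster(X, 2)
        labels = res.assignments.to_numpy()
        assert len(set(labels[:110])) == 1
        assert len(set(labels[110:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_zero_cost(self, rng):
        X = rng.normal(size=(5, 2))
        res = ci.pam_cluster(X, 5)
        assert res.cost == 0.0
        assert len(set(res.assignments)) == 5


class TestKMeans:
    def test_separated_blobs_perfect(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 4)), rng.normal(15, 1, (50, 4))])
        res = ci.kmeans_cluster(X, 2, seed=0)
        labels = res.assignments.to_numpy()
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1

    def test_k1_centroid_is_grand_mean(self, rng):
        X = rng.normal(size=(30, 4))
        res = ci.kmeans_cluster(X, 1, seed=0)
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0), atol=1e-8)


class TestVolancySuccess:
    def _series(self, values, prefix="t"):
        return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])

    def test_64_of_67_training_taxa_rate(self):
        volant = self._series([True] * 40 + [False] * 27)
        clusters = self._series([0] * 37 + [1] * 3 + [1] * 27)
        rate, miss, _ = ci.volancy_success(clusters, volant)
        assert rate == pytest.approx(95.52, abs=0.01)
        assert len(miss) == 3

    def test_perfect_assignment(self):
        volant = self._series([True] * 5 + [False] * 5)
        clusters = self._series([1] * 5 + [0] * 5)
        rate, miss, _ = ci.volancy_success(clusters, volant)
        assert rate == 100.0 and miss == []

    def test_cluster_relabelling_invariance(self):
        volant = self._series([True] * 6 + [False] * 4)
        clusters = self._series([0] * 6 + [1] * 4)
        r1, m1, _ = ci.volancy_success(clusters, volant)
        r2, m2, _ = ci.volancy_success(1 - clusters, volant)
        assert r1 == r2 and m1 == m2


class TestPhyloAncova:
    def test_star_tree_matches_classical_ancova(self, rng):
        n = 40
        tree = _star_tree(n)
        group = np.repeat(["a", "b", "c", "d"], 10)
        covar = rng.normal(size=n)
        y = rng.normal(size=n)
        res = ci.phylo_ancova(y, group, covar, tree, n_sims=20_000, seed=0)
        p_classical = stats.f.sf(res.f_observed, res.df_group, res.df_resid)
        assert res.p_value == pytest.approx(p_classical, abs=0.015)

    def test_planted_effect_detected(self, rng):
        n = 40
        tree = _star_tree(n)
        group = np.repeat(["a", "b"], 20)
        covar = rng.normal(size=n)
        y = rng.normal(size=n) + np.where(group == "a", 0.0, 6.0)
        res = ci.phylo_ancova(y, group, covar, tree, n_sims=1000, seed=1)
        assert res.p_value <= 0.01

    def test_p_value_estimator_never_zero(self, rng):
        n = 20
        tree = _star_tree(n)
        group = np.repeat(["a", "b"], 10)
        y = np.where(group == "a", 0.0, 100.0) + rng.normal(size=n) * 0.01
        res = ci.phylo_ancova(y, group, rng.normal(size=n), tree, n_sims=100, seed=2)
        assert res.p_value == pytest.approx(1 / 101)

    def test_small_group_rejected(self, rng):
        tree = _star_tree(5)
        with pytest.raises(ValueError, match="fewer than 2"):
            ci.phylo_ancova(
                np.zeros(5),
                np.array(["a", "a", "a", "a", "b"]),
                rng.normal(size=5),
                tree,
                n_sims=100,
            )


class TestLDA:
    def _separated(self, rng, d=8.0):
        X = np.vstack(
            [
                rng.normal(0, 1, (20, 4)),
                rng.normal(d, 1, (20, 4)),
                rng.normal(-d, 1, (20, 4)),
            ]
        )
        idx = [f"t{i}" for i in range(60)]
        groups = pd.Series(["a"] * 20 + ["b"] * 20 + ["c"] * 20, index=idx)
        return pd.DataFrame(X, index=idx, columns=list("wxyz")), groups

    def test_separated_groups_fully_resolved(self, rng):
        X, g = self._separated(rng)
        model = ci.lda_fit(X, g)
        assert model.percent_correct == 100.0
        assert np.diag(model.confusion).sum() == 60

    def test_affine_invariance_of_accuracy(self, rng):
        X, g = self._separated(rng, d=2.0)
        model = ci.lda_fit(X, g)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        shift = rng.normal(size=4) * 10
        Xt = pd.DataFrame(X.to_numpy() @ A + shift, index=X.index, columns=X.columns)
        model_t = ci.lda_fit(Xt, g)
        assert model_t.percent_correct == pytest.approx(model.percent_correct)
        pd.testing.assert_frame_equal(model_t.confusion, model.confusion)

    def test_axis_count_rank_bound(self, rng):
        X, g = self._separated(rng)
        model = ci.lda_fit(X, g)
        assert model.axes.shape[1] == min(3 - 1, 4)

    def test_identical_means_near_chance(self, rng):
        n = 300
        X = pd.DataFrame(
            rng.normal(size=(n, 4)), index=[f"t{i}" for i in range(n)]
        )
        g = pd.Series(["a", "b", "c"] * (n // 3), index=X.index)
        model = ci.lda_fit(X, g)
        assert model.percent_correct < 55.0

    def test_matches_sklearn_classification(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, g = self._separated(rng, d=1.5)
        model = ci.lda_fit(X, g)
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, g)
        ours = model.confusion.to_numpy()
        theirs = pd.crosstab(g, pd.Series(sk.predict(X), index=X.index)).to_numpy()
        np.testing.assert_array_equal(ours, theirs)

    def test_confusion_rows_sum_to_group_sizes(self, rng):
        X, g = self._separated(rng, d=1.0)
        model = ci.lda_fit(X, g)
        assert (model.confusion.sum(axis=1) == g.value_counts().sort_index()).all()


class TestLDAClassify:
    def test_point_at_group_mean(self, rng):
        X = pd.DataFrame(
            np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(9, 1, (20, 4))]),
            index=[f"t{i}" for i in range(40)],
        )
        g = pd.Series(["a"] * 20 + ["b"] * 20, index=X.index)
        model = ci.lda_fit(X, g)
        probe = pd.DataFrame(
            [model.group_means.loc["b"].to_numpy()], index=["m1"], columns=X.columns
        )
        out = ci.lda_classify(model, probe)
        assert out.loc["m1", "assigned"] == "b"
        assert out.loc["m1", "d2_b"] == pytest.approx(0.0, abs=1e-9)

    def test_equidistant_point_flagged_and_first_group_wins(self, rng):
        X = pd.DataFrame(
            np.vstack([rng.normal(-5, 1, (25, 2)), rng.normal(5, 1, (25, 2))]),
            index=[f"t{i}" for i in range(50)],
        )
        g = pd.Series(["a"] * 25 + ["b"] * 25, index=X.index)
        model = ci.lda_fit(X, g)
        mid = model.group_means.mean(axis=0)
        out = ci.lda_classify(
            model, pd.DataFrame([mid.to_numpy()], index=["m"], columns=X.columns)
        )
        assert bool(out.loc["m", "tie"])
        assert out.loc["m", "assigned"] == "a"

    def test_planted_mystery_recovered(self, default_dataset):
        _, table, tree, _ = default_dataset
        df = table.aligned_to(tree)
        model = ci.lda_fit(ci.analysis_matrix(df), df["scheme_close"])
        out = ci.lda_classify(model, ci.analysis_matrix(table.mystery))
        assert (out["assigned"] == "burst").all()


class TestManova:
    def test_single_variable_two_groups_equals_anova(self, rng):
        x = rng.normal(size=30)
        g = pd.Series(["a"] * 15 + ["b"] * 15, index=[f"t{i}" for i in range(30)])
        X = pd.DataFrame({"v": x}, index=g.index)
        res = ci.manova(X, g)
        f_ref = stats.f_oneway(x[:15], x[15:])
        assert res.f_approx == pytest.approx(f_ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(f_ref.pvalue, rel=1e-6)

    def test_matches_statsmodels_wilks(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        n = 45
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("xyz"))
        X.iloc[:15] += 1.0
        g = pd.Series(["a"] * 15 + ["b"] * 15 + ["c"] * 15, index=X.index)
        res = ci.manova(X, g)
        mv = MANOVA.from_formula(
            "x + y + z ~ C(g)", data=X.assign(g=g)
        ).mv_test()
        tbl = mv.results["C(g)"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(tbl.loc["Wilks' lambda", "Value"]), rel=1e-6
        )

    def test_identical_groups_lambda_near_one(self, rng):
        base = rng.normal(size=(12, 2))
        X = pd.DataFrame(np.vstack([base, base]), columns=list("xy"))
        g = pd.Series(["a"] * 12 + ["b"] * 12, index=X.index)
        res = ci.manova(X, g)
        assert res.wilks_lambda > 0.999
        assert res.p_value > 0.9

    def test_separated_groups_lambda_near_zero(self, rng):
        X = pd.DataFrame(
            np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(20, 1, (15, 2))]),
            columns=list("xy"),
        )
        g = pd.Series(["a"] * 15 + ["b"] * 15, index=X.index)
        res = ci.manova(X, g)
        assert res.wilks_lambda < 0.05
        assert res.pairwise["p_corrected"].iloc[0] < 1e-6


@pytest.fixture(scope="module")
def tree40_screen():
    return sd._make_tree(sd.DatasetSpec(tree_shape="birth-death"), 40, 23)


class TestSignalScreen:

    def test_iid_traits_recommend_lda(self, tree40_screen):
        hits = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            X = pd.DataFrame(
                rng.normal(size=(40, 4)),
                index=tree40_screen.tip_labels,
                columns=list("abcd"),
            )
            if ci.screen_phylogenetic_signal(X, tree40_screen).recommendation == "LDA":
                hits += 1
        assert hits >= 0.9 * reps

    def test_bm_traits_recommend_transform(self, tree40_screen):
        hits = 0
        reps = 25
        for rep in range(reps):
            sims = pm.simulate_bm(tree40_screen, 1.0, n_sims=4, seed=200 + rep)
            X = sims.T
            X.columns = list("abcd")
            rec = ci.screen_phylogenetic_signal(X, tree40_screen).recommendation
            if rec == "lambda-transformed DA":
                hits += 1
        assert hits >= 0.9 * reps

    def test_lambda_reported_for_every_variable(self, tree40_screen, rng):
        X = pd.DataFrame(
            rng.normal(size=(40, 4)), index=tree40_screen.tip_labels, columns=list("abcd")
        )
        screen = ci.screen_phylogenetic_signal(X, tree40_screen)
        assert set(screen.lambda_fits) == set("abcd")
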