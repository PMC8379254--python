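import itertools
import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from methylcaps.networks import (
    UNASSIGNED,
    connectivity,
    detect_modules,
    gene_correlation,
    intramodular_hubs,
    moderated_two_group_test,
    module_eigengene,
    pick_soft_threshold,
    power_adjacency,
    topological_overlap,
)


def _frame(X, prefix="g"):
    return pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"{prefix}{j}" for j in range(X.shape[1])],
    )


class TestGeneCorrelation:
    def test_duplicated_gene_gives_unit_offdiagonal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        E = _frame(np.column_stack([x, x]))
        cor = gene_correlation(E)
        assert math.isclose(cor.iloc[0, 1], 1.0, abs_tol=1e-12)

    def test_negated_gene_gives_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        cor = gene_correlation(_frame(np.column_stack([x, -x])))
        assert math.isclose(cor.iloc[0, 1], -1.0, abs_tol=1e-12)

    def test_matches_hand_computed_pearson(self):
        rng = np.random.default_rng(2)
        E = _frame(rng.normal(size=(4, 3)))
        cor = gene_correlation(E)
        for i, j in itertools.combinations(range(3), 2):
            expected = stats.pearsonr(E.iloc[:, i], E.iloc[:, j])[0]
            assert math.isclose(cor.iloc[i, j], expected, abs_tol=1e-12)
        assert np.allclose(cor, cor.T) and np.allclose(np.diag(cor), 1.0)

    def test_constant_gene_dropped_with_warning(self):
        E = _frame(np.random.default_rng(3).normal(size=(5, 3)))
        E["g1"] = 0.7
        with pytest.warns(UserWarning, match="constant"):
            cor = gene_correlation(E)
        assert list(cor.columns) == ["g0", "g2"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            gene_correlation(_frame(np.zeros((2, 3))))


class TestPowerAdjacency:
    def test_half_squared_is_quarter(self):
        cor = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=list("ab"), columns=list("ab"))
        adj = power_adjacency(cor, power=2)
        assert adj.iloc[0, 1] == 0.25

    def test_power_one_is_absolute_correlation(self):
        cor = pd.DataFrame([[1.0, -0.3], [-0.3, 1.0]], index=list("ab"), columns=list("ab"))
        assert power_adjacency(cor, power=1).iloc[0, 1] == 0.3

    def test_entries_decrease_with_power(self):
        rng = np.random.default_rng(4)
        C = np.clip(rng.uniform(-0.99, 0.99, size=(4, 4)), -0.99, 0.99)
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        cor = _frame(C).set_axis(_frame(C).columns, axis=0)
        a2 = power_adjacency(cor, 2).to_numpy()
        a4 = power_adjacency(cor, 4).to_numpy()
        off = ~np.eye(4, dtype=bool)
        assert np.all(a4[off] <= a2[off])

    def test_power_below_one_rejected(self):
        cor = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError, match="power"):
            power_adjacency(cor, power=0.5)


class TestTopologicalOverlap:
    def test_two_gene_saturated_edge(self):
        a = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        tom = topological_overlap(a)
        assert tom.iloc[0, 1] == 1.0  # (0 + 1) / (min(1,1) + 1 - 1)
        assert tom.iloc[0, 0] == 1.0

    def test_zero_adjacency_gives_identity_pattern(self):
        a = _frame(np.zeros((4, 4)))
        a.index = a.columns
        tom = topological_overlap(a).to_numpy()
        assert np.array_equal(tom, np.eye(4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        adj = _frame(A)
        adj.index = adj.columns
        tom = topological_overlap(adj).to_numpy()
        k = A.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                expected = (shared + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
                assert math.isclose(tom[i, j], expected, abs_tol=1e-12)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestModuleDetection:
    def _block_tom(self, sizes, within=0.9, between=0.05, seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        T = np.full((n, n), between) + rng.uniform(-0.02, 0.02, (n, n))
        start = 0
        for s in sizes:
            T[start : start + s, start : start + s] = within + rng.uniform(
                -0.05, 0.05, (s, s)
            )
            start += s
        T = np.clip((T + T.T) / 2, 0, 1)
        np.fill_diagonal(T, 1.0)
        f = _frame(T)
        f.index = f.columns
        return f

    def test_two_perfect_blocks_recovered(self):
        tom = self._block_tom([5, 5])
        modules = detect_modules(tom, n_modules=2)
        assert modules.nunique() == 2
        assert len(set(modules.iloc[:5])) == 1 and len(set(modules.iloc[5:])) == 1

    def test_single_module(self):
        tom = self._block_tom([6])
        modules = detect_modules(tom, n_modules=1)
        assert modules.nunique() == 1

    def test_gene_order_does_not_change_partition(self):
        tom = self._block_tom([4, 4], seed=1)
        perm = np.random.default_rng(2).permutation(8)
        shuffled = tom.iloc[perm, perm]
        m1 = detect_modules(tom, n_modules=2)
        m2 = detect_modules(shuffled, n_modules=2)
        assert adjusted_rand_score(m1[shuffled.index], m2) == 1.0

    def test_singletons_marked_unassigned(self):
        tom = self._block_tom([4, 4], seed=3)
        # isolate one gene from everything
        tom.iloc[0, 1:] = 0.0
        tom.iloc[1:, 0] = 0.0
        modules = detect_modules(tom, n_modules=3)
        assert modules.iloc[0] == UNASSIGNED

    def test_too_many_modules_rejected(self):
        tom = self._block_tom([3])
        with pytest.raises(ValueError, match="exceeds"):
            detect_modules(tom, n_modules=5)

    def test_exactly_one_cut_criterion(self):
        tom = self._block_tom([3])
        with pytest.raises(ValueError, match="exactly one"):
            detect_modules(tom)


class TestEigengene:
    def test_perfectly_correlated_module_explains_all_variance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8)
        E = _frame(np.column_stack([x, 2 * x + 1, -0.5 * x]))
        eig, ve = module_eigengene(E, ["g0", "g1", "g2"])
        assert math.isclose(ve, 1.0, abs_tol=1e-12)

    def test_two_uncorrelated_genes_split_variance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        x, y = x - x.mean(), y - y.mean()
        y -= x * (x @ y) / (x @ x)  # exactly orthogonal
        E = _frame(np.column_stack([x, y]))
        _, ve = module_eigengene(E, ["g0", "g1"])
        assert math.isclose(ve, 0.5, abs_tol=1e-9)

    def test_orientation_positive_against_mean_profile(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        E = _frame(np.column_stack([x, x + rng.normal(0, 0.1, 10)]))
        eig, _ = module_eigengene(E, ["g0", "g1"])
        stdized = (E - E.mean()) / E.std(ddof=1)
        assert np.dot(eig, stdized.mean(axis=1)) > 0

    def test_sign_flip_of_input_leaves_eigengene_unchanged(self):
        rng = np.random.default_rng(8)
        E = _frame(rng.normal(size=(9, 3)))
        e1, _ = module_eigengene(E, list(E.columns))
        e2, _ = module_eigengene(-E, list(E.columns))
        assert np.allclose(e1, -e2) or np.allclose(e1, e2)
        # orientation rule ties the sign to the module mean profile
        stdized = (E - E.mean()) / E.std(ddof=1)
        assert np.dot(e1, stdized.mean(axis=1)) >= 0

    def test_single_gene_module_warns(self):
        E = _frame(np.random.default_rng(9).normal(size=(6, 2)))
        with pytest.warns(UserWarning, match="one gene"):
            eig, ve = module_eigengene(E, ["g0"])
        assert ve == 1.0

    def test_variance_explained_maximal_over_random_directions(self):
        rng = np.random.default_rng(10)
        E = _frame(rng.normal(size=(12, 5)))
        _, ve = module_eigengene(E, list(E.columns))
        stdized = ((E - E.mean()) / E.std(ddof=1)).to_numpy()
        total = np.sum(stdized**2)
        for _ in range(1000):
            v = rng.normal(size=5)
            v /= np.linalg.norm(v)
            proj = stdized @ v
            assert np.sum(proj**2) / total <= ve + 1e-12


class TestHubs:
    def test_star_center_is_top_hub(self):
        n = 5
        A = np.zeros((n, n))
        A[0, 1:] = A[1:, 0] = 1.0
        adj = _frame(A)
        adj.index = adj.columns
        modules = pd.Series(0, index=adj.index)
        hubs = intramodular_hubs(adj, modules, top_n=n)
        assert hubs.iloc[0]["gene"] == "g0"

    def test_equal_weights_rank_lexicographically(self):
        A = np.ones((4, 4))
        adj = _frame(A)
        adj.index = adj.columns
        modules = pd.Series(0, index=adj.index)
        hubs = intramodular_hubs(adj, modules, top_n=4)
        assert hubs["gene"].tolist() == ["g0", "g1", "g2", "g3"]

    def test_matches_hand_summed_connectivity(self):
        rng = np.random.default_rng(11)
        A = rng.random((5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        adj = _frame(A)
        adj.index = adj.columns
        modules = pd.Series([0, 0, 0, 1, 1], index=adj.index)
        hubs = intramodular_hubs(adj, modules, top_n=3)
        m0 = hubs[hubs.module == 0]
        scores = {g: A[i, [0, 1, 2]].sum() for i, g in enumerate(adj.index[:3])}
        expected = sorted(scores, key=lambda g: (-scores[g], g))
        assert m0["gene"].tolist() == expected


class TestModuleRecoveryFromFactors:
    def test_three_planted_factors_recovered(self):
        rng = np.random.default_rng(12)
        n, per = 60, 20
        factors = rng.normal(size=(n, 3))
        cols, truth = [], []
        for m in range(3):
            for _ in range(per):
                cols.append(factors[:, m] + rng.normal(0, 0.4, n))
                truth.append(m)
        E = _frame(np.column_stack(cols))
        cor = gene_correlation(E)
        tom = topological_overlap(power_adjacency(cor, 6))
        modules = detect_modules(tom, n_modules=3)
        assert adjusted_rand_score(truth, modules) >= 0.9

    def test_soft_threshold_pick_returns_valid_power(self):
        rng = np.random.default_rng(13)
        E = _frame(rng.normal(size=(30, 40)))
        power, table = pick_soft_threshold(gene_correlation(E))
        assert power >= 1 and {"power", "r2"} <= set(table.columns)


class TestModeratedTest:
    def _null_matrix(self, n=20, p=50, seed=0):
        rng = np.random.default_rng(seed)
        X = _frame(rng.normal(size=(n, p)), prefix="f")
        groups = np.array([0] * (n // 2) + [1] * (n - n // 2))
        return X, groups

    def test_identical_group_means_give_null_stat(self):
        rng = np.random.default_rng(14)
        half = rng.normal(size=(10, 5))
        X = _frame(np.vstack([half, half]), prefix="f")  # identical groups
        groups = np.array([0] * 10 + [1] * 10)
        tab = moderated_two_group_test(X, groups)
        assert np.allclose(tab["t"], 0.0, atol=1e-12)
        assert np.allclose(tab["p_value"], 1.0)

    def test_zero_prior_df_recovers_ordinary_t(self):
        X, groups = self._null_matrix(seed=15)
        tab = moderated_two_group_test(X, groups, prior=(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(X[groups == 1], X[groups == 0], axis=0)
        assert np.allclose(tab["t"], t_ref, atol=1e-10)
        assert np.allclose(tab["p_value"], p_ref, atol=1e-10)

    def test_bh_step_up_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_adjusted_p_at_least_raw(self):
        X, groups = self._null_matrix(seed=16)
        tab = moderated_two_group_test(X, groups)
        assert (tab["adj_p_value"] >= tab["p_value"] - 1e-15).all()

    def test_type_i_error_calibrated_under_null(self):
        # 10 independent 500-feature null datasets give the empirical rate
        # a Monte-Carlo SE of ~0.003, well inside the 0.05 +/- 0.02 band
        rates = []
        for seed in range(10):
            X, groups = self._null_matrix(n=20, p=500, seed=100 + seed)
            tab = moderated_two_group_test(X, groups)
            rates.append(float((tab["p_value"] < 0.05).mean()))
        assert 0.03 <= float(np.mean(rates)) <= 0.07

    def test_detects_true_shift(self):
        X, groups = self._null_matrix(n=30, p=40, seed=18)
        X.iloc[groups == 1, :5] += 2.0
        tab = moderated_two_group_test(X, groups)
        assert (tab["adj_p_value"][:5] < 0.01).all()
        assert tab["effect"][:5].min() > 1.0

    def test_small_group_rejected(self):
        X, _ = self._null_matrix()
        with pytest.raises(ValueError, match=">= 2"):
            moderated_two_group_test(X, np.array([0] + [1] * 19))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_oracle(self, tmp_path):
        """Independent cross-check of the moderated t against limma/eBayes."""
        rng = np.random.default_rng(19)
        n, p = 16, 30
        X = rng.normal(size=(n, p)) * rng.uniform(0.5, 2.0, size=p)
        groups = np.array([0] * 8 + [1] * 8)
        X[groups == 1, :3] += 1.5
        frame = _frame(X, prefix="f")
        (tmp_path / "x.csv").write_text(
            pd.DataFrame(X.T, index=[f"f{j}" for j in range(p)]).to_csv()
        )
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.csv(commandArgs(TRUE)[1], row.names = 1))
            design <- cbind(1, c(rep(0, 8), rep(1, 8)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],
                              d0 = fit$df.prior, s02 = fit$s2.prior)
            write.csv(out, commandArgs(TRUE)[2])
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "x.csv"),
             str(tmp_path / "out.csv")],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        tab = moderated_two_group_test(frame, groups)
        assert np.allclose(tab["t"], ref["t"], rtol=1e-6)
        assert np.allclose(tab["p_value"], ref["p"], rtol=1e-6)
        assert math.isclose(tab["prior_df"].iloc[0], ref["d0"].iloc[0], rel_tol=1e-4)
        assert math.isclose(tab["prior_var"].iloc[0], ref["s02"].iloc[0], rel_tol=1e-4)
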