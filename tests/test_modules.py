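"""Co-expression networks: soft threshold, TOM, modules, markers, signature."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stemniche as sn
from stemniche.modules import WGCNAParams, _scale_free_fit


def _block_expr(seed=0, n_obs=60, block_sizes=(50, 50), n_noise=100, r=0.85):
    """Metacell-like matrix with planted correlated gene blocks."""
    rng = np.random.default_rng(seed)
    cols, truth = [], []
    for b, size in enumerate(block_sizes):
        driver = rng.normal(size=n_obs)
        lam = np.sqrt(r)
        block = lam * driver[:, None] + np.sqrt(1 - lam**2) * rng.normal(size=(n_obs, size))
        cols.append(block)
        truth += [b + 1] * size
    cols.append(rng.normal(size=(n_obs, n_noise)))
    truth += [0] * n_noise
    X = np.concatenate(cols, axis=1)
    genes = [f"g{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=genes), np.array(truth)


class TestSoftThreshold:
    def test_matches_independent_rescan_of_the_rule(self):
        expr, _ = _block_expr(seed=3)
        params = WGCNAParams(candidate_powers=tuple(range(1, 13)))
        chosen = sn.pick_soft_threshold(expr, params)
        # oracle: re-evaluate the selection rule directly
        cor = np.abs(np.corrcoef(expr.to_numpy(), rowvar=False))
        np.fill_diagonal(cor, 0.0)
        expected = params.soft_power_fallback
        for beta in params.candidate_powers:
            if _scale_free_fit((cor**beta).sum(axis=0)) >= params.scale_free_r2:
                expected = beta
                break
        assert chosen == expected

    def test_unreachable_target_falls_back_to_nine(self):
        expr, _ = _block_expr(seed=4, n_noise=30)
        params = WGCNAParams(scale_free_r2=0.99999)
        assert sn.pick_soft_threshold(expr, params) == 9

    def test_mean_connectivity_decreases_with_power(self):
        expr, _ = _block_expr(seed=5)
        cor = np.abs(np.corrcoef(expr.to_numpy(), rowvar=False))
        np.fill_diagonal(cor, 0.0)
        ks = [(cor**b).sum(axis=0).mean() for b in range(1, 10)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_too_few_metacells_rejected(self):
        with pytest.raises(ValueError, match="metacells"):
            sn.pick_soft_threshold(pd.DataFrame(np.zeros((5, 10))))


class TestTOM:
    def test_complete_graph_gives_unit_overlap(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        tom = sn.tom_matrix(a)
        np.testing.assert_allclose(tom, np.ones((n, n)))

    def test_empty_graph_gives_zero_off_diagonal(self):
        tom = sn.tom_matrix(np.zeros((5, 5)))
        assert np.all(tom[~np.eye(5, dtype=bool)] == 0)
        assert np.all(np.diag(tom) == 1)

    def test_four_gene_toy_matches_formula_by_hand(self):
        a = np.array(
            [
                [0.0, 0.8, 0.3, 0.0],
                [0.8, 0.0, 0.5, 0.2],
                [0.3, 0.5, 0.0, 0.7],
                [0.0, 0.2, 0.7, 0.0],
            ]
        )
        tom = sn.tom_matrix(a)
        k = a.sum(axis=0)
        for j, l in itertools.combinations(range(4), 2):
            shared = sum(a[j, u] * a[u, l] for u in range(4))
            expected = (shared + a[j, l]) / (min(k[j], k[l]) + 1 - a[j, l])
            assert tom[j, l] == pytest.approx(expected)
            assert tom[l, j] == pytest.approx(expected)

    def test_tom_entries_valid_dissimilarity(self):
        expr, _ = _block_expr(seed=6)
        cor = np.abs(np.corrcoef(expr.to_numpy(), rowvar=False))
        np.fill_diagonal(cor, 0.0)
        tom = sn.tom_matrix(cor**6)
        assert np.all((tom >= 0) & (tom <= 1 + 1e-12))
        d = 1 - tom
        assert np.allclose(np.diag(d), 0) and np.allclose(d, d.T)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            sn.tom_matrix(bad)


class TestDetectModules:
    def _modules_for(self, expr, beta=6, **kw):
        cor = np.abs(np.corrcoef(expr.to_numpy(), rowvar=False))
        np.fill_diagonal(cor, 0.0)
        tom = sn.tom_matrix(cor**beta)
        return sn.detect_modules(1 - tom, WGCNAParams(**kw))

    def test_two_planted_blocks_recovered(self):
        expr, truth = _block_expr(seed=7)
        module_of = self._modules_for(expr)
        assert module_of.max() == 2
        for b in (1, 2):
            planted = set(np.nonzero(truth == b)[0])
            best = max(
                len(planted & set(np.nonzero(module_of == m)[0]))
                / len(planted | set(np.nonzero(module_of == m)[0]))
                for m in (1, 2)
            )
            assert best >= 0.8

    def test_independent_genes_left_unassigned(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(60, 150)))
        module_of = self._modules_for(expr)
        assert np.all(module_of == 0)

    def test_planted_lineage_module_found_as_one_module(self):
        lin = sn.simulate_lineage_cells(sn.LineageConfig(n_cells=800, seed=2))
        res = sn.score_stemness(lin, seed=2)
        expr, _ = sn.pseudobulk_by_rank(lin, res.smoothed_score, group_size=20)
        top = expr.var(axis=0).nlargest(250).index
        module_of = self._modules_for(expr[top], min_module_size=20)
        planted = set(lin.uns["module_genes"])
        hits = [
            len(planted & set(top[module_of == m])) for m in range(1, module_of.max() + 1)
        ]
        assert hits and max(hits) >= 0.8 * len(planted)


class TestTraitCorrelation:
    def test_perfect_and_orthogonal_eigengenes(self):
        rng = np.random.default_rng(9)
        trait = rng.normal(size=30)
        ortho = rng.normal(size=30)
        ortho -= ortho.mean() + 0  # center then project out the trait
        t = trait - trait.mean()
        ortho = ortho - ortho.mean()
        ortho -= (ortho @ t) / (t @ t) * t
        eg = pd.DataFrame([trait, ortho], index=[1, 2])
        tc = sn.module_trait_correlation(eg, trait)
        assert tc.loc[1, "r"] == pytest.approx(1.0)
        assert tc.loc[1, "p"] < 1e-30
        assert tc.loc[2, "r"] == pytest.approx(0.0, abs=1e-12)

    def test_p_value_matches_t_distribution(self):
        # r = 0.5 with n = 30 via explicit construction
        rng = np.random.default_rng(10)
        t = rng.normal(size=30)
        t = (t - t.mean()) / t.std()
        o = rng.normal(size=30)
        o -= o.mean()
        o -= (o @ t) / (t @ t) * t
        o /= o.std()
        eg = 0.5 * t + np.sqrt(1 - 0.25) * o
        tc = sn.module_trait_correlation(pd.DataFrame([eg], index=[1]), t)
        assert tc.loc[1, "r"] == pytest.approx(0.5)
        tstat = 0.5 * np.sqrt(28 / (1 - 0.25))
        assert tc.loc[1, "p"] == pytest.approx(2 * stats.t.sf(tstat, df=28))

    def test_too_short_trait_rejected(self):
        with pytest.raises(ValueError):
            sn.module_trait_correlation(pd.DataFrame([[1.0, 2.0]], index=[1]), np.array([1.0, 2.0]))


class TestMarkers:
    def _adata(self, in_vals, out_vals, gene="g0"):
        X = np.array(in_vals + out_vals, dtype=float).reshape(-1, 1)
        a = ad.AnnData(X=X, var=pd.DataFrame(index=[gene]))
        a.layers["lognorm"] = np.log1p(X)
        return a, np.r_[np.ones(len(in_vals), bool), np.zeros(len(out_vals), bool)]

    def test_identical_groups_not_marker(self):
        vals = list(range(1, 11))
        a, mal = self._adata(vals, vals)
        res = sn.malignant_markers(a, mal)
        assert res.table["avg_logFC"].iloc[0] == pytest.approx(0.0)
        assert res.table["p_value"].iloc[0] > 0.9
        assert not res.table["is_marker"].iloc[0]

    def test_exclusive_high_gene_is_marker(self):
        a, mal = self._adata([20] * 10, [0] * 10)
        res = sn.malignant_markers(a, mal)
        assert res.table["is_marker"].iloc[0]

    def test_p_matches_exhaustive_permutation(self):
        rng = np.random.default_rng(11)
        in_vals = list(rng.permutation(np.arange(1.0, 9.0) + 3))
        out_vals = list(rng.permutation(np.arange(8.0, 16.0) + 0.5))
        a, mal = self._adata(in_vals, out_vals)
        res = sn.malignant_markers(a, mal, logfc_screen=0.0)
        # brute-force permutation distribution of the rank-sum statistic
        vals = np.array(in_vals + out_vals)
        ranks = stats.rankdata(vals)
        obs = ranks[:8].sum()
        null = np.array([sum(c) for c in itertools.combinations(ranks, 8)])
        mean = null.mean()
        p_exact = np.mean(np.abs(null - mean) >= abs(obs - mean) - 1e-9)
        assert res.table["p_value"].iloc[0] == pytest.approx(p_exact, rel=1e-6)

    def test_single_group_rejected(self):
        a, _ = self._adata([1] * 5, [2] * 5)
        with pytest.raises(ValueError):
            sn.malignant_markers(a, np.ones(10, bool))


class TestSignature:
    def _modset(self, module_genes, marker_genes, n_obs=30, seed=12):
        rng = np.random.default_rng(seed)
        genes = sorted(set(module_genes) | set(marker_genes) | {"zz1", "zz2"})
        driver = rng.normal(size=n_obs)
        X = np.column_stack(
            [
                0.95 * driver + 0.3 * rng.normal(size=n_obs)
                if g in module_genes
                else rng.normal(size=n_obs)
                for g in genes
            ]
        )
        expr = pd.DataFrame(X, columns=genes)
        module_of = np.array([1 if g in module_genes else 0 for g in genes])
        table = pd.DataFrame(
            {
                "avg_logFC": [1.0 if g in marker_genes else 0.0 for g in genes],
                "p_value": [0.001 if g in marker_genes else 0.9 for g in genes],
                "is_marker": [g in marker_genes for g in genes],
            },
            index=genes,
        )
        return expr, module_of, driver, sn.MarkerResult(table=table)

    def test_intersection_rule(self):
        expr, module_of, trait, markers = self._modset({"A", "B", "C"}, {"B", "C", "D"})
        ms = sn.derive_signature(expr, module_of, trait, markers)
        assert ms.signature == ["B", "C"]
        assert ms.selected_module == 1

    def test_disjoint_sets_give_empty_signature_with_warning(self):
        expr, module_of, trait, markers = self._modset({"A", "B"}, {"D", "E"})
        with pytest.warns(UserWarning, match="empty"):
            ms = sn.derive_signature(expr, module_of, trait, markers)
        assert ms.signature == []

    def test_eigengene_sign_convention(self):
        expr, module_of, trait, markers = self._modset({"A", "B", "C"}, {"B"})
        eg = sn.module_eigengenes(expr, module_of)
        mean_profile = expr[["A", "B", "C"]].mean(axis=1)
        assert np.corrcoef(eg.loc[1], mean_profile)[0, 1] >= 0
        assert np.linalg.norm(eg.loc[1]) == pytest.approx(1.0)
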