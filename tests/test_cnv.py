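"""Reference-relative CNV inference, state discretization, malignant calling."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import stemniche as sn
from stemniche.cnv import CNVParams


def _manual_adata(norm, genes=None, chrom="chr1"):
    norm = np.asarray(norm, dtype=float)
    genes = genes or [f"g{i}" for i in range(norm.shape[1])]
    a = ad.AnnData(
        X=np.expm1(norm).round().astype(int),
        var=pd.DataFrame(
            {"chromosome": chrom, "start": 1000 * np.arange(1, norm.shape[1] + 1)},
            index=genes,
        ),
    )
    a.layers["lognorm"] = norm
    return a


class TestNormalScore:
    def test_silent_spot_scores_zero_and_uniform_spot_scores_v(self):
        markers = list(sn.IMMUNE_MARKERS)
        norm = np.vstack([np.zeros(10), np.full(10, 1.7)])
        a = _manual_adata(norm, genes=markers)
        ns = sn.normal_score(a)
        assert ns[0] == 0.0
        assert ns[1] == pytest.approx(1.7)

    def test_three_spot_toy_hand_means(self):
        genes = ["PTPRC", "CD68", "other"]
        norm = np.array([[1.0, 3.0, 9.0], [0.0, 2.0, 9.0], [4.0, 4.0, 9.0]])
        a = _manual_adata(norm, genes=genes)
        with pytest.warns(UserWarning, match="missing"):
            ns = sn.normal_score(a)
        np.testing.assert_allclose(ns, [2.0, 1.0, 4.0])

    def test_no_marker_measured_rejected(self):
        a = _manual_adata(np.ones((3, 2)), genes=["x", "y"])
        with pytest.raises(ValueError, match="markers"):
            sn.normal_score(a)


class TestSelectReference:
    def test_highest_median_wins(self):
        labels = np.repeat([0, 1, 2], 5)
        scores = np.r_[np.full(5, 0.1), np.full(5, 0.9), np.full(5, 0.3)]
        assert sn.select_reference(labels, scores) == 1

    def test_tie_goes_to_lowest_id(self):
        labels = np.repeat([0, 1], 4)
        scores = np.r_[np.full(4, 0.5), np.full(4, 0.5)]
        assert sn.select_reference(labels, scores) == 0

    def test_immune_region_cluster_selected_on_synthetic_lattice(self, spatial_sample):
        a = spatial_sample.copy()
        ns = sn.normal_score(a)
        labels = sn.initial_clusters(a, seed=0)
        ref = sn.select_reference(labels, ns)
        immune = a.obs["immune_region"].to_numpy()
        # the chosen cluster should capture the designated immune region
        assert (labels[immune] == ref).mean() > 0.9


class TestSmoothing:
    def test_reference_profiles_are_mostly_denoised_to_zero(self):
        rng = np.random.default_rng(0)
        norm = rng.gamma(2, 0.5, size=(40, 60))
        a = _manual_adata(norm)
        ref = np.ones(40, dtype=bool)
        sm = sn.smoothed_cnv_profiles(a, ref, CNVParams(window=5)).to_numpy()
        # entries inside the 1.5-sigma reference band are exactly zero; the
        # surviving tail of the reference's own noise stays small
        assert (sm == 0).mean() > 0.8
        assert np.abs(sm).max() <= CNVParams().clip

    def test_planted_gain_raises_segment_residual(self, spatial_sample):
        a = spatial_sample.copy()
        ref = a.obs["immune_region"].to_numpy()
        sm = sn.smoothed_cnv_profiles(a, ref, CNVParams(window=21))
        seg_genes = [g for g in sm.columns if g in set(a.var_names[0:60])]
        tumor = a.obs["malignant_truth"].to_numpy()
        assert sm.loc[tumor, seg_genes].mean().mean() > 0

    def test_unit_window_without_denoise_is_identity_on_residuals(self):
        rng = np.random.default_rng(1)
        norm = rng.gamma(2, 0.5, size=(30, 40))
        norm[:10] += 0.8
        a = _manual_adata(norm)
        ref = np.r_[np.zeros(10, bool), np.ones(20, bool)]
        params = CNVParams(window=1, denoise_sd=0.0, mean_expr_cutoff=0.0)
        sm = sn.smoothed_cnv_profiles(a, ref, params).to_numpy()
        expr = np.log2(np.expm1(norm) + 1.0)
        resid = np.clip(expr - expr[ref].mean(axis=0), -3, 3)
        resid -= np.median(resid, axis=1, keepdims=True)
        np.testing.assert_allclose(sm, resid, atol=1e-12)

    def test_missing_annotation_rejected(self):
        a = ad.AnnData(X=np.ones((5, 4), dtype=int))
        a.layers["lognorm"] = np.ones((5, 4))
        with pytest.raises(ValueError, match="annotation"):
            sn.smoothed_cnv_profiles(a, np.ones(5, bool))


class TestStates:
    def test_zero_residual_is_neutral_state_three(self):
        sm = pd.DataFrame([[0.0]])
        assert sn.discretize_states(sm).iloc[0, 0] == 3

    def test_high_gain_lands_on_amplified_side(self):
        sm = pd.DataFrame([[0.35, 0.25, 0.15, -0.15, -0.35]])
        states = sn.discretize_states(sm).to_numpy().ravel()
        assert list(states) == [6, 5, 4, 2, 1]
        assert all(s >= 5 for v, s in zip([0.35], states) if v >= 0.3)

    def test_state_scores_enumerate_expected_vector(self):
        # |state - 3| over states 1..6
        assert [abs(s - 3) for s in range(1, 7)] == [2, 1, 0, 1, 2, 3]
        t1, t2, t3 = CNVParams().state_thresholds
        reps = [-t3 - 0.1, -t2, 0.0, t1 + 0.01, t2 + 0.01, t3 + 0.1]
        states = sn.discretize_states(pd.DataFrame([reps])).to_numpy().ravel()
        assert list(states) == [1, 2, 3, 4, 5, 6]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sn.discretize_states(pd.DataFrame([[np.nan]]))


class TestClusterScores:
    def test_neutral_states_score_zero(self):
        states = pd.DataFrame(np.full((6, 10), 3))
        scores = sn.cnv_scores(states, np.repeat([0, 1], 3))
        assert (scores == 0).all()

    def test_uniform_state_five_scores_two_per_gene(self):
        states = pd.DataFrame(np.full((4, 10), 5))
        scores = sn.cnv_scores(states, np.zeros(4, int))
        assert scores[0] == 20

    def test_three_cluster_toy_matches_brute_force(self):
        rng = np.random.default_rng(2)
        states = pd.DataFrame(rng.integers(1, 7, size=(12, 7)))
        labels = np.repeat([0, 1, 2], 4)
        scores = sn.cnv_scores(states, labels)
        for c in range(3):
            member = states.to_numpy()[labels == c]
            expected = 0
            for g in range(7):
                col = member[:, g]
                # modal state, ties to the smallest (bincount argmax convention)
                mode = np.bincount(col, minlength=7).argmax()
                expected += abs(int(mode) - 3)
            assert scores[c] == expected


class TestMalignantCalling:
    def test_planted_tumor_disc_called_accurately(self, spatial_sample):
        a = spatial_sample.copy()
        res = sn.call_malignant_spots(a, seed=1)
        acc = (a.obs["malignant_call"] == a.obs["malignant_truth"]).mean()
        assert acc >= 0.9
        assert len(res.cluster_scores) == CNVParams().n_clusters

    def test_reference_scores_lowest_when_included(self, spatial_sample):
        a = spatial_sample.copy()
        res = sn.call_malignant_spots(a, seed=1)
        ref_mask = a.obs["cnv_cluster"].to_numpy() == -1
        states = res.states
        all_labels = np.where(ref_mask, -1, a.obs["cnv_cluster"].to_numpy())
        scores = sn.cnv_scores(states, all_labels)
        assert scores[-1] == scores.min()

    def test_flat_data_has_no_malignant_clusters(self):
        rng = np.random.default_rng(3)
        sm = pd.DataFrame(np.zeros((40, 30)) + rng.normal(0, 1e-9, size=(40, 30)))
        labels, malignant, scores = sn.cluster_and_call(sm, CNVParams(n_clusters=4), seed=0)
        assert malignant == set()

    def test_stronger_gain_never_lowers_tumor_score(self):
        scores = {}
        for mult in (1.5, 2.0):
            prof = sn.SpotProfiles(
                cnv=sn.CNVGroundTruth(segments=[("chr1", 0, 60, mult)], malignant_fraction=1.0)
            )
            sp = sn.simulate_visium_sample(sn.SpatialConfig(seed=5), prof)
            sm = sn.smoothed_cnv_profiles(sp, sp.obs["immune_region"].to_numpy(),
                                          CNVParams(window=21))
            states = sn.discretize_states(sm, CNVParams(window=21))
            tumor = sp.obs["malignant_truth"].to_numpy().astype(int)
            scores[mult] = sn.cnv_scores(states, tumor)[1]
        assert scores[2.0] >= scores[1.5]
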