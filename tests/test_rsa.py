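"""RDM construction against brute-force oracles, and model-RDM recovery."""

import numpy as np
import pandas as pd
import pytest

from contextval import behavior as B
from contextval import design as D
from contextval import neuralsim as N
from contextval import rsa as R


def _toy_runs(vectors_by_run, counts=None):
    n_runs = len(vectors_by_run)
    n_vox = vectors_by_run[0].shape[1]
    vecs = np.stack(vectors_by_run)
    cnt = counts if counts is not None else np.ones((n_runs, 9), int)
    return R.ConditionPatterns(vectors=vecs, counts=cnt,
                               runs=tuple(range(1, n_runs + 1)))


class TestCrossrunRdm:
    def test_hand_computed_two_condition_toy(self):
        # run1 conditions at 1 and 3 (1 voxel), run2 identical:
        # d01 = mean(|1-3|, |3-1|) = 2, diagonal = 0
        v = np.full((2, 9, 1), np.nan)
        v[0, 0, 0], v[0, 1, 0] = 1.0, 3.0
        v[1, 0, 0], v[1, 1, 0] = 1.0, 3.0
        rdm = R.crossrun_rdm(_toy_runs(list(v)))
        assert rdm.matrix[0, 1] == pytest.approx(2.0)
        assert rdm.matrix[0, 0] == pytest.approx(0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((2, 9, 4))
        rdm = R.crossrun_rdm(_toy_runs(list(v)))
        # independent oracle: explicit double loop over ordered run pairs
        for i in range(9):
            for j in range(9):
                ds = []
                for r in range(2):
                    for s in range(2):
                        if r != s:
                            ds.append(np.sqrt(((v[r, i] - v[s, j]) ** 2).sum()))
                assert rdm.matrix[i, j] == pytest.approx(np.mean(ds), abs=1e-12)

    def test_identical_patterns_give_zero_rdm(self):
        v = np.tile(np.array([0.4, -1.2])[None, None, :], (3, 9, 1))
        rdm = R.crossrun_rdm(_toy_runs(list(v)))
        assert np.allclose(rdm.matrix, 0.0)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((2, 9, 3))
        r1 = R.crossrun_rdm(_toy_runs(list(v)))
        r2 = R.crossrun_rdm(_toy_runs(list(2.0 * v)))
        assert np.allclose(r2.matrix, 2.0 * r1.matrix)

    def test_single_run_rejected(self):
        v = np.zeros((1, 9, 2))
        with pytest.raises(ValueError):
            R.crossrun_rdm(_toy_runs(list(v)))


@pytest.fixture(scope="module")
def pattern_runs():
    design = D.generate_design(seed=4, n_blocks=2, n_candidates=25)
    beh = B.simulate_behavior(design.trials, B.BehaviorParams(), 1, seed=6)
    params = N.NeuralParams(n_voxels=50)
    cb = N.make_codebook(50, seed=9)
    return N.simulate_patterns(design.trials, beh, cb, params, seed=10)


class TestPrepare:
    def test_mean_pattern_subtracted(self, pattern_runs):
        conds = R.prepare_condition_patterns(pattern_runs)
        for r in range(conds.vectors.shape[0]):
            assert np.allclose(np.nanmean(conds.vectors[r], axis=0), 0.0,
                               atol=1e-10)

    def test_unit_variance_residuals_leave_patterns_unchanged(self, pattern_runs):
        # force each voxel's residual sample SD to exactly 1: diagonal
        # normalization is then the identity (up to centering)
        import copy

        runs = copy.deepcopy(pattern_runs)
        for run in runs:
            run.residuals /= run.residuals.std(axis=0, ddof=1)
        conds = R.prepare_condition_patterns(runs)
        lab = runs[0].labels
        mask = (lab["dim"] == "2D") & (lab["accuracy"] == 1)
        sel = mask & (lab["EV"] == 30) & (lab["EV_back"] == 30)
        raw_mean = runs[0].patterns[sel.to_numpy()].mean(axis=0)
        raw_all = [runs[0].patterns[(mask & (lab["EV"] == ev)
                                     & (lab["EV_back"] == evb)).to_numpy()].mean(axis=0)
                   for ev, evb in R.CONDITIONS]
        centered = raw_mean - np.mean(raw_all, axis=0)
        assert np.allclose(conds.vectors[0, 0], centered, atol=1e-10)

    def test_shrinkage_whitens_residual_covariance(self, pattern_runs):
        conds = R.prepare_condition_patterns(pattern_runs, mode="shrinkage")
        run = pattern_runs[0]
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf().fit(run.residuals).covariance_
        evals, evecs = np.linalg.eigh(cov)
        W = evecs @ np.diag(evals ** -0.5) @ evecs.T
        white = run.residuals @ W
        n_vox = run.residuals.shape[1]
        d_raw = np.linalg.norm(np.cov(run.residuals.T) - np.eye(n_vox))
        d_white = np.linalg.norm(np.cov(white.T) - np.eye(n_vox))
        assert d_white < d_raw
        assert np.isfinite(conds.vectors[0]).any()

    def test_unknown_mode_rejected(self, pattern_runs):
        with pytest.raises(ValueError):
            R.prepare_condition_patterns(pattern_runs, mode="magic")


class TestRdmDesign:
    def test_forty_five_unique_cells(self):
        rdm = R.RDM(matrix=np.zeros((9, 9)))
        cells = R.build_rdm_design(rdm)
        assert len(cells) == 45

    def test_covariate_coding_example(self):
        # cell (EV=30/EV_back=50, EV=30/EV_back=70): same EV -> Diagonal_EV=0,
        # VD_EV=0, VD_EVback=20
        rdm = R.RDM(matrix=np.arange(81.0).reshape(9, 9))
        cells = R.build_rdm_design(rdm)
        row = cells[(cells["ev_i"] == 30) & (cells["evback_i"] == 50)
                    & (cells["ev_j"] == 30) & (cells["evback_j"] == 70)].iloc[0]
        assert row["diag_ev"] == 0
        assert row["vd_ev"] == 0
        assert row["vd_evback"] == 20

    def test_max_value_difference(self):
        cells = R.build_rdm_design(R.RDM(matrix=np.zeros((9, 9))))
        assert cells["vd_ev"].max() == 40
        assert set(cells["vd_ev"].unique()) == {0, 20, 40}


class TestFitRdmModels:
    def _cells(self, a_ev, a_back, n_subjects=8, seed=0):
        design = D.generate_design(seed=4, n_blocks=2, n_candidates=25)
        beh = B.simulate_behavior(design.trials, B.BehaviorParams(),
                                  n_subjects, seed=seed)
        params = N.NeuralParams(a_ev=a_ev, a_back=a_back, noise_sd=0.5,
                                n_voxels=80)
        runs = N.simulate_subject_patterns(design.trials, beh, params, seed + 1)
        return R.subject_rdm_cells(runs)

    def test_ev_code_recovered_without_evback(self):
        tab = R.fit_rdm_models(self._cells(a_ev=2.0, a_back=0.0))
        by = tab.set_index("model")
        assert by.loc["diagonal:+diag_ev_z", "p"] < 0.01
        assert by.loc["diagonal:+diag_ev_z", "estimate"] > 0
        assert by.loc["diagonal:+diag_evback_z", "p"] > 0.01

    def test_evback_code_recovered(self):
        tab = R.fit_rdm_models(self._cells(a_ev=1.0, a_back=2.0))
        by = tab.set_index("model")
        assert by.loc["diagonal:+diag_evback_z", "p"] < 0.01
        assert by.loc["diagonal:+diag_evback_z", "estimate"] > 0

    def test_label_permutation_destroys_ev_effect(self):
        cells = self._cells(a_ev=2.5, a_back=0.0, n_subjects=6)
        chi_signal = R.fit_rdm_models(cells).set_index("model") \
            .loc["diagonal:+diag_ev_z", "lr_chi2"]
        rng = np.random.default_rng(42)
        shuffled = cells.copy()
        # permute the covariates across cells within subject (breaks the
        # link between distances and condition labels)
        for k, sub in shuffled.groupby("subject"):
            perm = rng.permutation(len(sub))
            cols = ["diag_ev", "diag_evback", "vd_ev", "vd_evback",
                    "log_invfreq", "freq_level"]
            shuffled.loc[sub.index, cols] = sub.iloc[perm][cols].to_numpy()
        chi_null = R.fit_rdm_models(shuffled).set_index("model") \
            .loc["diagonal:+diag_ev_z", "lr_chi2"]
        assert chi_null < chi_signal / 5

    def test_requires_two_subjects(self):
        cells = R.build_rdm_design(R.RDM(matrix=np.ones((9, 9))))
        cells["subject"] = 0
        with pytest.raises(ValueError):
            R.fit_rdm_models(cells)
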