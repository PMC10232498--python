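"""Linking models: record assembly, similarity, competition, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from contextval import behavior as B
from contextval import decoding as C
from contextval import design as D
from contextval import linking as L
from contextval import neuralsim as N
from contextval._stats import fisher_z


@pytest.fixture(scope="module")
def link_records(design4, behavior_records):
    """Link table for 10 subjects with strong planted competition."""
    params = N.NeuralParams(a_ev=1.5, a_back=1.2, a_ctx=1.2, lam=0.8,
                            moderation=1.0, ctx_gain_sd=0.8, back_gain_sd=0.6,
                            noise_sd=0.7, n_voxels=120)
    sub = behavior_records[behavior_records["subject"] < 10]
    pats = N.simulate_subject_patterns(design4.trials, sub, params, seed=40)
    rng = np.random.default_rng(41)
    val = {k: C.loro_decode(r, "value", seed=int(rng.integers(2**31)))
           for k, r in pats.items()}
    ctx = {k: C.loro_decode(r, "context", seed=int(rng.integers(2**31)))
           for k, r in pats.items()}
    evb = {k: C.ovr_evback_decode(r, seed=int(rng.integers(2**31)))
           for k, r in pats.items()}
    return L.build_link_records(val, ctx, evb, behavior=sub)


class TestBuildRecords:
    def test_p_other_defined_only_when_ev_differs_from_evback(self, link_records):
        has_other = link_records["P_other"].notna()
        expected = (link_records["dim"] == "2D") \
            & (link_records["EV"] != link_records["EV_back"].astype(float))
        assert (has_other == expected).all()

    def test_probabilities_within_clip_range(self, link_records):
        for col in ("P_EV", "P_EVback", "P_other", "P_EVback_2D"):
            vals = link_records[col].dropna()
            assert vals.between(*C.PROB_CLIP).all()

    def test_filter_order_independent(self, link_records):
        df = link_records[(link_records["dim"] == "2D")
                          & (link_records["accuracy"] == 1)]
        a = df[df["EV"] != df["EV_back"].astype(float)]
        a = a[a["other_on_screen"].astype(bool)]
        b = df[df["other_on_screen"].astype(bool)]
        b = b[b["EV"] != b["EV_back"].astype(float)]
        assert set(zip(a["subject"], a["trial"])) == set(zip(b["subject"], b["trial"]))


class TestValueSimilarity:
    def test_graded_code_gives_negative_similarity_slope(self, link_records):
        tab = L.fit_value_similarity(link_records[link_records["accuracy"] == 1])
        row = tab[tab["model"] == "+|EV-class|"].iloc[0]
        assert row["estimate"] < 0
        assert row["p"] < 1e-6

    def test_perceptual_similarity_equals_value_similarity_on_1d(self, link_records):
        long = L.value_similarity_table(link_records)
        one_d = long[long["dim"] == "1D"]
        # 2 - overlap is |EV-class| rescaled to levels on 1D trials
        assert np.allclose(2 - one_d["feature_overlap"],
                           one_d["value_sim"] / 20)

    def test_constant_probabilities_give_flat_slope(self, design4, behavior_records):
        # uniform probabilities for every trial: no similarity structure
        sub = behavior_records[behavior_records["subject"] < 4]
        rows = []
        for k in range(4):
            df = design4.trials.copy()
            df["subject"] = k
            for c in C.VALUE_CLASSES:
                df[f"p_{c}"] = 1 / 3
            df["accuracy"] = 1
            rows.append(df)
        recs = pd.concat(rows, ignore_index=True)
        recs["evback_z"] = 0.0
        long = L.value_similarity_table(recs)
        grouped = long.groupby("value_sim")["P_class"].mean()
        assert np.allclose(grouped, 1 / 3)


class TestCompetition:
    def test_fisher_z_of_zero_is_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_flat_dirichlet_null_is_symmetric(self):
        # under sum-to-one alone, corr(P_EV, P_EVback) == corr(P_EV, P_other):
        # Monte-Carlo oracle with exchangeable class assignment
        rng = np.random.default_rng(7)
        probs = rng.dirichlet(np.ones(3), size=10_000)
        ml = C.mlogit(probs)
        # classes are exchangeable: assign EV/EVback/other uniformly
        roles = np.array([rng.permutation(3) for _ in range(len(ml))])
        p_ev = ml[np.arange(len(ml)), roles[:, 0]]
        p_evb = ml[np.arange(len(ml)), roles[:, 1]]
        p_oth = ml[np.arange(len(ml)), roles[:, 2]]
        r1 = stats.spearmanr(p_ev, p_evb).statistic
        r2 = stats.spearmanr(p_ev, p_oth).statistic
        assert abs(r1 - r2) < 0.05

    def test_planted_competition_gives_asymmetry(self, link_records):
        per, summary = L.competition_correlation(link_records)
        assert summary["mean_z_evback"].iloc[0] < summary["mean_z_other"].iloc[0]

    def test_small_subjects_excluded(self, link_records):
        truncated = link_records.groupby("subject").head(30)
        per, _ = L.competition_correlation(truncated)
        assert per["excluded"].any()


class TestPevModels:
    def test_negative_evback_effect_recovered(self, link_records):
        tab = L.fit_pev_models(link_records)
        row = tab[tab["model"] == "+EV_back"].iloc[0]
        assert row["estimate"] < 0

    def test_positive_context_coupling_recovered(self, link_records):
        tab = L.fit_pev_models(link_records)
        row = tab[tab["model"] == "+logit(P_context)"].iloc[0]
        assert row["estimate"] > 0

    def test_moderation_interaction_positive(self, link_records):
        tab = L.fit_pev_full(link_records)
        row = tab[tab["model"] == "+P_context:P_EVback_2D"].iloc[0]
        assert row["estimate"] > 0

    def test_nesting_absorbs_per_level_constants(self, link_records):
        """Intercept absorption: shifting all responses within one nesting
        level leaves slope estimates unchanged (checked on the linear-algebra
        twin of the nested model, where absorption is exact)."""
        import statsmodels.formula.api as smf

        df = link_records[(link_records["dim"] == "2D")
                          & (link_records["accuracy"] == 1)].dropna(
            subset=["P_EVback_2D_z"]).copy()
        df["nest_cell"] = (df["subject"].astype(str) + "_"
                           + df["EV_back"].astype(int).astype(str))
        # nest_cell is a string column: patsy treats it as categorical
        f = ("P_EV ~ evback_z + logit_P_context_z + P_EVback_2D_z"
             " + nest_cell")
        before = smf.ols(f, df).fit().params
        shifted = df.copy()
        shifted.loc[shifted["EV_back"] == 50, "P_EV"] += 0.07
        after = smf.ols(f, shifted).fit().params
        for term in ("logit_P_context_z", "P_EVback_2D_z"):
            assert after[term] == pytest.approx(before[term], abs=1e-8)


class TestBehaviorLinks:
    def test_tables_produced_with_wrong_trials(self, link_records):
        tab = L.fit_behavior_links(link_records)
        assert {"P_EVback model"} <= set(tab["model"].unique())
        assert any(tab["model"].str.startswith("accuracy[congruent]"))

    def test_all_correct_subset_skipped(self, link_records):
        forced = link_records.copy()
        forced.loc[forced["congruency"] == "congruent", "accuracy"] = 1
        tab = L.fit_behavior_links(forced)
        skipped = tab[(tab["model"] == "accuracy[congruent]")
                      & (tab["term"] == "skipped")]
        assert len(skipped) == 1


class TestSubjectCorrelations:
    def test_identical_columns_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        eff = pd.DataFrame({
            "subject": range(12),
            "z_pev_pevback": x, "slope_cong_rt": x,
            "slope_pctx_pev": x, "slope_evback_pev": x,
            "slope_cong_evback_rt": x, "slope_pback2d_pev": x})
        tab = L.subject_correlations(eff)
        assert np.allclose(tab["r"], 1.0)

    def test_constant_column_reported_missing(self):
        eff = pd.DataFrame({
            "subject": range(12),
            "z_pev_pevback": np.zeros(12),
            "slope_cong_rt": np.arange(12.0),
            "slope_pctx_pev": np.arange(12.0),
            "slope_evback_pev": np.arange(12.0),
            "slope_cong_evback_rt": np.arange(12.0),
            "slope_pback2d_pev": np.arange(12.0)})
        tab = L.subject_correlations(eff)
        row = tab[tab["neural"] == "z_pev_pevback"].iloc[0]
        assert np.isnan(row["r"]) and row["note"] == "constant column"

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            L.subject_correlations(pd.DataFrame({"subject": range(5)}))

    def test_permuted_labels_uncouple(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(400)
        eff = pd.DataFrame({
            "subject": range(400),
            "z_pev_pevback": x,
            "slope_cong_rt": rng.permutation(x),
            "slope_pctx_pev": rng.standard_normal(400),
            "slope_evback_pev": rng.standard_normal(400),
            "slope_cong_evback_rt": rng.standard_normal(400),
            "slope_pback2d_pev": rng.standard_normal(400)})
        tab = L.subject_correlations(eff)
        assert (tab["r"].abs() < 0.15).all()
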