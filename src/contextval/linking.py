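"""Linking decoded probabilities to task variables and behavior.

The decoded class probabilities are treated as the trial-wise strength of
the corresponding neural representations.  This module implements:

* the value-similarity model: the probability assigned to class c decreases
  with |EV - c| (graded value code), with an EV_back interaction, and the
  perceptual feature-overlap control model;
* competition models of P_EV (the probability assigned to the objective
  value): a negative EV_back slope indicates that a stronger background
  value signal suppresses the relevant value representation, a positive
  logit(P_context) slope that a stronger context signal sharpens it, and a
  positive P_context x P_EVback_2D interaction that the context signal
  buffers the competition;
* per-subject correlations between the (multinomial-logit transformed)
  probabilities of EV, EV_back and the third ("Other") value;
* models of behavioral accuracy from the decoded signals with the two-step
  term-selection procedure, run separately for congruent and incongruent
  trials;
* between-subject correlations of neural slopes with behavioral congruency
  effects.

Probabilities are modeled with beta-family regressions (logit link) with
subject fixed intercepts; the engine is recorded in every effect table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

from ._stats import effect_row, effect_table, fisher_z, lr_test, zscore
from .behavior import CONGRUENCY_CODE
from .decoding import VALUE_CLASSES, logit, mlogit

MIN_QUALIFYING_TRIALS = 10


# ---------------------------------------------------------------------------
# record assembly
# ---------------------------------------------------------------------------


def build_link_records(value_probs: dict[int, pd.DataFrame],
                       context_probs: dict[int, pd.DataFrame],
                       evback_probs: dict[int, pd.DataFrame],
                       behavior: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-trial link table across subjects.

    Inputs map subject -> decoder output tables.  Adds: P_EV, P_context
    (logit-transformed and z-scored within subject), the value classifier's
    P_EVback / P_other with multinomial-logit transforms (defined only when
    EV != EV_back), the background classifier's probability of the correct
    EV_back level (z-scored within subject), and the on-screen flag for the
    Other value.
    """
    frames = []
    for k, val in value_probs.items():
        df = val.copy()
        df["subject"] = k
        probs = df[[f"p_{c}" for c in VALUE_CLASSES]].to_numpy()
        ml = mlogit(probs)
        cls = np.asarray(VALUE_CLASSES)
        ev_idx = np.searchsorted(cls, df["EV"].to_numpy())
        n = np.arange(len(df))
        df["P_EV"] = probs[n, ev_idx]
        df["mlogit_P_EV"] = ml[n, ev_idx]
        evb = df["EV_back"].to_numpy(dtype=float)
        has_back = ~np.isnan(evb) & (evb != df["EV"].to_numpy())
        back_idx = np.where(np.isnan(evb), 0, np.searchsorted(cls, np.nan_to_num(evb, nan=30.0)))
        df["P_EVback"] = np.where(has_back, probs[n, back_idx], np.nan)
        df["mlogit_P_EVback"] = np.where(has_back, ml[n, back_idx], np.nan)
        other_idx = np.full(len(df), -1)
        for i in range(len(df)):
            if has_back[i]:
                rest = [j for j in range(3) if j not in (ev_idx[i], back_idx[i])]
                other_idx[i] = rest[0]
        df["P_other"] = np.where(has_back, probs[n, np.maximum(other_idx, 0)], np.nan)
        df["mlogit_P_other"] = np.where(has_back, ml[n, np.maximum(other_idx, 0)], np.nan)
        other_value = np.where(has_back, cls[np.maximum(other_idx, 0)], np.nan)
        rel_hi = df["EV"].to_numpy(dtype=float)
        rel_lo = rel_hi - 20
        irr_l = df["irr_left"].to_numpy(dtype=float)
        irr_r = df["irr_right"].to_numpy(dtype=float)
        df["other_on_screen"] = (
            (other_value == rel_hi) | (other_value == rel_lo)
            | (other_value == irr_l) | (other_value == irr_r))

        ctx = context_probs[k]
        p_ctx = np.where(ctx["context"] == "color", ctx["p_color"], ctx["p_motion"])
        ctx_tab = pd.DataFrame({"trial": ctx["trial"], "P_context": p_ctx})
        df = df.merge(ctx_tab, on="trial", how="left")
        df["logit_P_context"] = logit(df["P_context"])

        evb_tab = evback_probs[k]
        pb = np.full(len(evb_tab), np.nan)
        for c, level in enumerate(VALUE_CLASSES):
            sel = evb_tab["EV_back"] == level
            pb[sel.to_numpy()] = evb_tab.loc[sel, f"pback_{level}"]
        df = df.merge(pd.DataFrame({"trial": evb_tab["trial"], "P_EVback_2D": pb}),
                      on="trial", how="left")
        if behavior is not None:
            beh_k = behavior[behavior["subject"] == k][["trial", "rt"]]
            df = df.merge(beh_k, on="trial", how="left")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    # within-subject scaling of the transformed probabilities
    for col in ("logit_P_context", "P_EVback_2D"):
        out[col + "_z"] = out.groupby("subject")[col].transform(
            lambda x: (x - x.mean()) / x.std() if x.std() > 0 else x * 0.0)
    out["cong_c"] = out["congruency"].map(CONGRUENCY_CODE).fillna(0.0)
    out["ev_z"] = zscore(out["EV"])
    evb = out["EV_back"].astype(float)
    out["evback_z"] = np.where(evb.notna(), (evb - evb.mean()) / evb.std(), 0.0)
    out["trial_z"] = zscore(out["trial"])
    out["side"] = out["choice_side"].map({"left": -1.0, "right": 1.0})
    out["switch_z"] = zscore(out["switch_distance"])
    out["context_c"] = out["context"].map({"color": -1.0, "motion": 1.0})
    return out


def _fit_beta(formula: str, df: pd.DataFrame):
    model = BetaModel.from_formula(formula, df)
    return model.fit(disp=False)


def _two_stage_p(formula_rhs: str, terms, df: pd.DataFrame) -> dict[str, float]:
    """Two-stage inference: one per-subject beta fit, t-test per slope.

    Decoded probabilities are dependent within subject (shared classifier
    weights per fold, sum-to-one coupling across a trial's classes), which
    makes pooled LR tests miscalibrated in both directions; the
    summary-statistics route is calibrated under arbitrary within-subject
    dependence.  ``formula_rhs`` must not contain subject terms; all
    ``terms`` are tested from the same full per-subject fit.
    """
    if isinstance(terms, str):
        terms = [terms]
    coefs = {t: [] for t in terms}
    for _, sub in df.groupby("subject"):
        try:
            fit = _fit_beta(f"{formula_rhs}", sub)
        except Exception:
            continue
        for t in terms:
            coefs[t].append(fit.params.get(t, np.nan))
    out = {}
    for t in terms:
        c = np.asarray(coefs[t], float)
        c = c[np.isfinite(c)]
        out[t] = float(stats.ttest_1samp(c, 0.0).pvalue) if len(c) >= 2 else np.nan
    return out


# ---------------------------------------------------------------------------
# value similarity
# ---------------------------------------------------------------------------


def value_similarity_table(recs: pd.DataFrame) -> pd.DataFrame:
    """Long format: one row per (trial, class) with similarity covariates.

    ``value_sim`` is |EV - class|; ``feature_overlap`` counts features
    shared between the displayed stimuli and the class's 1D training
    exemplars (values {class-20, class} in both dimensions).  On 1D trials
    the two coincide (2 - overlap = |EV - class|/20).
    """
    rows = []
    for c in VALUE_CLASSES:
        sub = recs.copy()
        sub["class_value"] = c
        sub["P_class"] = sub[f"p_{c}"]
        sub["value_sim"] = (sub["EV"] - c).abs()
        train_vals = {c - 20, c}
        rel_hi = sub["EV"].astype(float)
        rel_lo = rel_hi - 20
        overlap = rel_hi.isin(train_vals).astype(int) + rel_lo.isin(train_vals).astype(int)
        irr_l = sub["irr_left"].astype(float)
        irr_r = sub["irr_right"].astype(float)
        overlap = overlap + irr_l.isin(train_vals).fillna(False).astype(int) \
            + irr_r.isin(train_vals).fillna(False).astype(int)
        sub["feature_overlap"] = overlap
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def fit_value_similarity(recs: pd.DataFrame) -> pd.DataFrame:
    """Beta regressions of P_class on value similarity and its EV_back interaction.

    LR tests for |EV - class| and |EV - class| x EV_back; the perceptual
    feature-overlap substitute model is fitted for AIC comparison.
    """
    long = value_similarity_table(recs)
    long = long.dropna(subset=["P_class"])
    long["vsim_z"] = zscore(long["value_sim"])
    long["overlap_z"] = zscore(long["feature_overlap"])
    rows = []
    base = _fit_beta("P_class ~ C(subject)", long)
    m1 = _fit_beta("P_class ~ vsim_z + C(subject)", long)
    chi2, _ = lr_test(base.llf, m1.llf, 1)
    ts = _two_stage_p("P_class ~ vsim_z + vsim_z:evback_z",
                      ["vsim_z", "vsim_z:evback_z"], long)
    p = ts["vsim_z"]
    rows.append(effect_row("+|EV-class|", "vsim_z", estimate=m1.params["vsim_z"],
                           se=m1.bse["vsim_z"], lr_chi2=chi2, df=1, p=p, aic=m1.aic,
                           engine="beta+two-stage-t"))
    m2 = _fit_beta("P_class ~ vsim_z + vsim_z:evback_z + C(subject)", long)
    chi2, _ = lr_test(m1.llf, m2.llf, 1)
    p = ts["vsim_z:evback_z"]
    rows.append(effect_row("+|EV-class|:EV_back", "vsim_z:evback_z",
                           estimate=m2.params["vsim_z:evback_z"],
                           se=m2.bse["vsim_z:evback_z"], lr_chi2=chi2, df=1, p=p,
                           aic=m2.aic, engine="beta+two-stage-t"))
    alt = _fit_beta("P_class ~ overlap_z + C(subject)", long)
    rows.append(effect_row("feature_overlap (alt)", "overlap_z",
                           estimate=alt.params["overlap_z"], se=alt.bse["overlap_z"],
                           aic=alt.aic, engine="beta-fixed-intercepts",
                           note="perceptual-similarity control, AIC vs +|EV-class|"))
    return effect_table(rows)


# ---------------------------------------------------------------------------
# P_EV competition models
# ---------------------------------------------------------------------------


def fit_pev_models(recs: pd.DataFrame) -> pd.DataFrame:
    """Ladder {EV_back} -> {+ logit(P_context)} for P_EV on accurate 2D trials.

    Controls fitted for AIC comparison: minimum irrelevant value,
    Congruency (+ interaction with EV_back), perceptual presence of the
    EV_back feature in the 1D training class, and an EV == EV_back match
    indicator.
    """
    df = recs[(recs["dim"] == "2D") & (recs["accuracy"] == 1)].copy()
    df["irr_min_z"] = zscore(df[["irr_left", "irr_right"]].astype(float).min(axis=1))
    df["evback_feature_shown"] = (
        (df["EV_back"] == df["EV"]) | (df["EV_back"] == df["EV"] - 20)).astype(float)
    df["match"] = (df["EV_back"] == df["EV"]).astype(float)
    rows = []
    base = _fit_beta("P_EV ~ C(subject)", df)
    m1 = _fit_beta("P_EV ~ evback_z + C(subject)", df)
    chi2, _ = lr_test(base.llf, m1.llf, 1)
    ts = _two_stage_p("P_EV ~ evback_z + logit_P_context_z",
                      ["evback_z", "logit_P_context_z"], df)
    p = ts["evback_z"]
    rows.append(effect_row("+EV_back", "evback_z", estimate=m1.params["evback_z"],
                           se=m1.bse["evback_z"], lr_chi2=chi2, df=1, p=p, aic=m1.aic,
                           engine="beta+two-stage-t"))
    m2 = _fit_beta("P_EV ~ evback_z + logit_P_context_z + C(subject)", df)
    chi2, _ = lr_test(m1.llf, m2.llf, 1)
    p = ts["logit_P_context_z"]
    rows.append(effect_row("+logit(P_context)", "logit_P_context_z",
                           estimate=m2.params["logit_P_context_z"],
                           se=m2.bse["logit_P_context_z"], lr_chi2=chi2, df=1, p=p,
                           aic=m2.aic, engine="beta+two-stage-t"))
    controls = {
        "min_irrelevant (alt)": "P_EV ~ irr_min_z + logit_P_context_z + C(subject)",
        "congruency (alt)": "P_EV ~ cong_c + cong_c:evback_z + logit_P_context_z"
                            " + C(subject)",
        "evback_feature_shown (alt)": "P_EV ~ evback_feature_shown"
                                      " + logit_P_context_z + C(subject)",
        "match (alt)": "P_EV ~ evback_z + match + logit_P_context_z + C(subject)",
    }
    for name, f in controls.items():
        fit = _fit_beta(f, df)
        rows.append(effect_row(name, f.split("~")[1].split("+")[0].strip(),
                               aic=fit.aic, engine="beta-fixed-intercepts",
                               note="AIC comparison"))
    return effect_table(rows)


def fit_pev_full(recs: pd.DataFrame) -> pd.DataFrame:
    """P_EV on EV_back, logit(P_context), P_EVback_2D and the moderation term.

    Intercepts are nested within EV_back level per subject; LR test per
    term, the interaction last (a positive interaction means a stronger
    context signal weakens the background competition).
    """
    df = recs[(recs["dim"] == "2D") & (recs["accuracy"] == 1)].dropna(
        subset=["P_EVback_2D_z"]).copy()
    # one intercept per (subject, EV_back level) cell; these absorb the
    # EV_back main effect exactly (with fixed effects the paper-style
    # EV_back slope + nested intercepts are only jointly identifiable
    # under random-effect shrinkage), so the ladder tests the remaining
    # slope terms
    df["nest_cell"] = (df["subject"].astype(str) + "_"
                       + df["EV_back"].astype(float).astype(int).astype(str))
    nest = "C(nest_cell)"
    ladder = [
        ("+logit(P_context)", "logit_P_context_z"),
        ("+P_EVback_2D", "logit_P_context_z + P_EVback_2D_z"),
        ("+P_context:P_EVback_2D",
         "logit_P_context_z + P_EVback_2D_z"
         " + logit_P_context_z:P_EVback_2D_z"),
    ]
    df["evb_lvl"] = df["EV_back"].astype(float).astype(int).astype(str)
    rows = [effect_row("nested intercepts", "C(subject):C(EV_back)",
                       engine="beta-fixed-intercepts-nested",
                       note="EV_back main effect absorbed by nesting")]
    prev = _fit_beta(f"P_EV ~ {nest}", df)
    full_rhs = ladder[-1][1]
    ts = _two_stage_p(f"P_EV ~ {full_rhs} + C(evb_lvl)",
                      [rhs.split(" + ")[-1] for _, rhs in ladder], df)
    for name, rhs in ladder:
        fit = _fit_beta(f"P_EV ~ {rhs} + {nest}", df)
        term = rhs.split(" + ")[-1]
        chi2, _ = lr_test(prev.llf, fit.llf, 1)
        p = ts[term]
        rows.append(effect_row(name, term, estimate=fit.params.get(term, np.nan),
                               se=fit.bse.get(term, np.nan), lr_chi2=chi2, df=1,
                               p=p, aic=fit.aic,
                               engine="beta-nested+two-stage-t"))
        prev = fit
    return effect_table(rows)


# ---------------------------------------------------------------------------
# competition correlations
# ---------------------------------------------------------------------------


def qualifying_trials(recs: pd.DataFrame) -> pd.DataFrame:
    """Accurate 2D trials with EV != EV_back and the Other value on screen."""
    df = recs[(recs["dim"] == "2D") & (recs["accuracy"] == 1)]
    df = df[df["EV"] != df["EV_back"].astype(float)]
    return df[df["other_on_screen"].astype(bool)]


def competition_correlation(recs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject rank correlations of mlogit(P_EV) with mlogit(P_EVback) / mlogit(P_other).

    Returns (per-subject table with Fisher-z values, summary with the paired
    t-test across subjects and the regression-twin AIC comparison).
    Subjects with fewer than 10 qualifying trials are excluded.
    """
    df = qualifying_trials(recs)
    rows = []
    for k, sub in df.groupby("subject"):
        if len(sub) < MIN_QUALIFYING_TRIALS:
            rows.append(dict(subject=k, n=len(sub), excluded=True,
                             rho_evback=np.nan, rho_other=np.nan,
                             z_evback=np.nan, z_other=np.nan))
            continue
        rho_b = stats.spearmanr(sub["mlogit_P_EV"], sub["mlogit_P_EVback"]).statistic
        rho_o = stats.spearmanr(sub["mlogit_P_EV"], sub["mlogit_P_other"]).statistic
        rows.append(dict(subject=k, n=len(sub), excluded=False,
                         rho_evback=rho_b, rho_other=rho_o,
                         z_evback=fisher_z(rho_b), z_other=fisher_z(rho_o)))
    per_subject = pd.DataFrame(rows)
    ok = per_subject[~per_subject["excluded"]]
    t, p = stats.ttest_rel(ok["z_evback"], ok["z_other"])
    m_b = _fit_beta("P_EV ~ mlogit_P_EVback + C(subject)", df)
    m_o = _fit_beta("P_EV ~ mlogit_P_other + C(subject)", df)
    summary = pd.DataFrame([dict(
        mean_z_evback=ok["z_evback"].mean(), mean_z_other=ok["z_other"].mean(),
        t=float(t), p=float(p), n_subjects=len(ok),
        aic_evback_model=m_b.aic, aic_other_model=m_o.aic)])
    return per_subject, summary


# ---------------------------------------------------------------------------
# behavior links
# ---------------------------------------------------------------------------


def fit_behavior_links(recs: pd.DataFrame, include_wrong: bool = True) -> pd.DataFrame:
    """(a) model of the value classifier's P_EVback; (b) accuracy selection.

    (a) includes behaviorally wrong trials: P_EVback ~ EV x EV_back +
    Congruency x Accuracy + nuisances (subject intercepts).  (b) for each
    congruency subset, a binomial accuracy model without congruency terms is
    extended in two steps: first each neural main effect (logit P_context,
    mlogit P_EV, mlogit P_EVback), then the pairwise interactions of the
    retained terms; every step is an LR test.  A subset without any wrong
    trials is skipped with a note.
    """
    rows = []
    df = recs[(recs["dim"] == "2D")].dropna(subset=["mlogit_P_EVback"]).copy()
    if not include_wrong:
        df = df[df["accuracy"] == 1]
    df["acc_c"] = df["accuracy"].astype(float)
    base = _fit_beta("P_EVback ~ trial_z + side + switch_z + context_c"
                     " + C(subject)", df)
    full = _fit_beta("P_EVback ~ ev_z:evback_z + cong_c:acc_c + trial_z + side"
                     " + switch_z + context_c + C(subject)", df)
    chi2, p = lr_test(base.llf, full.llf, 2)
    for term in ("ev_z:evback_z", "cong_c:acc_c"):
        rows.append(effect_row("P_EVback model", term,
                               estimate=full.params.get(term, np.nan),
                               se=full.bse.get(term, np.nan),
                               lr_chi2=chi2, df=2, p=p, aic=full.aic,
                               engine="beta-fixed-intercepts",
                               note="joint LR vs nuisance-only"))

    neural_terms = ["logit_P_context_z", "mlogit_P_EV", "mlogit_P_EVback"]
    for cong_label in ("congruent", "incongruent"):
        sub = recs[(recs["dim"] == "2D") & (recs["congruency"] == cong_label)].dropna(
            subset=["mlogit_P_EVback"]).copy()
        if sub["accuracy"].nunique() < 2:
            rows.append(effect_row(f"accuracy[{cong_label}]", "skipped",
                                   note="no wrong trials in subset"))
            continue
        base_f = "accuracy ~ ev_z + trial_z + side + switch_z + context_c + C(subject)"
        base_fit = smf.glm(base_f, sub, family=sm.families.Binomial()).fit()
        kept = []
        for term in neural_terms:
            fit = smf.glm(base_f + " + " + term, sub,
                          family=sm.families.Binomial()).fit()
            chi2, p = lr_test(base_fit.llf, fit.llf, 1)
            rows.append(effect_row(f"accuracy[{cong_label}] step1", term,
                                   estimate=fit.params.get(term, np.nan),
                                   lr_chi2=chi2, df=1, p=p, aic=fit.aic,
                                   engine="glm-fixed-intercepts"))
            if p < 0.05:
                kept.append(term)
        step2_base_f = base_f + "".join(" + " + t for t in kept)
        step2_base = smf.glm(step2_base_f, sub, family=sm.families.Binomial()).fit()
        import itertools as it

        for a, b in it.combinations(neural_terms, 2):
            fit = smf.glm(step2_base_f + f" + {a}:{b}", sub,
                          family=sm.families.Binomial()).fit()
            chi2, p = lr_test(step2_base.llf, fit.llf, 1)
            rows.append(effect_row(f"accuracy[{cong_label}] step2", f"{a}:{b}",
                                   estimate=fit.params.get(f"{a}:{b}", np.nan),
                                   lr_chi2=chi2, df=1, p=p, aic=fit.aic,
                                   engine="glm-fixed-intercepts"))
    return effect_table(rows)


# ---------------------------------------------------------------------------
# subject-level coupling
# ---------------------------------------------------------------------------


def compute_subject_effects(recs: pd.DataFrame) -> pd.DataFrame:
    """Per-subject slopes and Fisher-z correlations used in Fig.-style scatter.

    Behavioral: OLS slopes of Congruency and Congruency x EV_back on log RT
    (accurate 2D trials).  Neural: OLS slopes of EV_back, logit(P_context)
    and P_EVback_2D on P_EV, and the Fisher-z rank correlation of
    mlogit(P_EV) with mlogit(P_EVback).  Per-subject fits are used
    throughout (the no-random-slope engine fallback).
    """
    rows = []
    for k, sub in recs.groupby("subject"):
        two_d = sub[(sub["dim"] == "2D") & (sub["accuracy"] == 1)].copy()
        if "rt" in two_d.columns and two_d["rt"].notna().any():
            two_d["logrt"] = np.log(two_d["rt"])
            b = smf.ols("logrt ~ ev_z + cong_c + cong_c:evback_z + trial_z + side"
                        " + switch_z + context_c", two_d).fit()
            slope_cong = b.params.get("cong_c", np.nan)
            slope_cong_evback = b.params.get("cong_c:evback_z", np.nan)
        else:
            slope_cong = slope_cong_evback = np.nan
        n1 = smf.ols("P_EV ~ evback_z", two_d).fit()
        n2 = smf.ols("P_EV ~ logit_P_context_z", two_d).fit()
        sub_b = two_d.dropna(subset=["P_EVback_2D_z"])
        n3 = smf.ols("P_EV ~ P_EVback_2D_z", sub_b).fit() if len(sub_b) else None
        qual = qualifying_trials(sub)
        if len(qual) >= MIN_QUALIFYING_TRIALS:
            z = fisher_z(stats.spearmanr(qual["mlogit_P_EV"],
                                         qual["mlogit_P_EVback"]).statistic)
        else:
            z = np.nan
        rows.append(dict(
            subject=k,
            slope_cong_rt=slope_cong, slope_cong_evback_rt=slope_cong_evback,
            slope_evback_pev=n1.params.get("evback_z", np.nan),
            slope_pctx_pev=n2.params.get("logit_P_context_z", np.nan),
            slope_pback2d_pev=n3.params.get("P_EVback_2D_z", np.nan) if n3 is not None
            else np.nan,
            z_pev_pevback=z))
    return pd.DataFrame(rows)


#: (neural column, behavioral column) pairs tested across subjects
SUBJECT_CORRELATION_PAIRS = [
    ("z_pev_pevback", "slope_cong_rt"),
    ("slope_pctx_pev", "slope_cong_rt"),
    ("slope_evback_pev", "slope_cong_evback_rt"),
    ("slope_pback2d_pev", "slope_cong_evback_rt"),
]


def subject_correlations(effects: pd.DataFrame) -> pd.DataFrame:
    """Pearson r with Spearman p between neural and behavioral subject effects."""
    if len(effects) < 10:
        raise ValueError("at least 10 subjects required")
    rows = []
    for a, b in SUBJECT_CORRELATION_PAIRS:
        sub = effects[[a, b]].dropna()
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rows.append(dict(neural=a, behavioral=b, r=np.nan, p_spearman=np.nan,
                             n=len(sub), note="constant column"))
            continue
        r = float(np.corrcoef(sub[a], sub[b])[0, 1])
        p = float(stats.spearmanr(sub[a], sub[b]).pvalue)
        rows.append(dict(neural=a, behavioral=b, r=r, p_spearman=p, n=len(sub),
                         note=""))
    return pd.DataFrame(rows)
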