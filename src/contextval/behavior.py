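"""Trial-wise behavior: generative simulation and model-comparison ladders.

Reaction times follow a log-linear mixed model with a subject random
intercept: the linear predictor carries EV, Congruency, Congruency x EV_back
and Congruency x EV fixed effects plus four nuisance terms (trial index,
target side, trials since the last context switch, context).  Accuracy is
Bernoulli with a logit-linear predictor of the same shape, except the fourth
term is Congruency x switch.  Congruency is effects-coded (incongruent = +1,
congruent = -1, 1D = 0), so a positive RT coefficient means slower
incongruent responses.  All continuous regressors are z-scored before both
simulation and fitting, mirroring the fitting convention.

The fitting ladders add terms one at a time and report likelihood-ratio
tests between adjacent nested models: RT uses a Gaussian mixed model
(subject random intercept, ML); accuracy uses a binomial GLM with subject
fixed intercepts, since no binomial random-intercept likelihood machinery
is available in the Python stack (the engine is recorded in every table).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import effect_row, effect_table, lr_test, zscore

CONGRUENCY_CODE = {"incongruent": 1.0, "congruent": -1.0}


@dataclass
class BehaviorParams:
    """Generative coefficients; defaults plant the qualitative effect pattern."""

    beta0: float = np.log(0.75)      # intercept, log-seconds
    beta_ev: float = -0.03           # faster for higher EV
    beta_cong: float = 0.04          # slower on incongruent trials
    beta_cong_evback: float = 0.025  # congruency effect grows with EV_back
    beta_cong_ev: float = 0.0
    nu_trial: float = -0.01
    nu_side: float = 0.0
    nu_switch: float = -0.005
    nu_context: float = 0.005
    subject_sd: float = 0.08
    resid_sd: float = 0.15
    # accuracy analogues (logit scale); baseline near ceiling (~0.9)
    acc_beta0: float = 2.3
    acc_beta_ev: float = 0.1
    acc_beta_cong: float = -0.35
    acc_beta_cong_evback: float = -0.2
    acc_beta_cong_switch: float = 0.1
    acc_nu_trial: float = 0.0
    acc_nu_side: float = 0.0
    acc_nu_switch: float = 0.15
    acc_nu_context: float = 0.0
    acc_subject_sd: float = 0.3

    def __post_init__(self):
        if self.resid_sd <= 0 or self.subject_sd < 0:
            raise ValueError("residual SD must be > 0 and subject SD >= 0")

    @classmethod
    def null(cls) -> "BehaviorParams":
        """All effects of interest zero (type-I-error calibration)."""
        return cls(beta_ev=0, beta_cong=0, beta_cong_evback=0, beta_cong_ev=0,
                   nu_trial=0, nu_side=0, nu_switch=0, nu_context=0,
                   acc_beta_ev=0, acc_beta_cong=0, acc_beta_cong_evback=0,
                   acc_beta_cong_switch=0, acc_nu_switch=0)

    def to_dict(self) -> dict:
        return asdict(self)


def design_regressors(trials: pd.DataFrame) -> pd.DataFrame:
    """Scaled model regressors for a trial table (1D rows get 0 for 2D terms)."""
    df = pd.DataFrame(index=trials.index)
    df["ev_z"] = zscore(trials["EV"])
    two_d = trials["dim"] == "2D"
    cong = trials["congruency"].map(CONGRUENCY_CODE).fillna(0.0)
    evback = trials["EV_back"].astype(float)
    evback_z = np.zeros(len(trials))
    if two_d.any():
        evback_z[two_d.to_numpy()] = zscore(evback[two_d])
    df["cong_c"] = cong.to_numpy()
    df["evback_z"] = evback_z
    df["trial_z"] = zscore(trials["trial"])
    df["side"] = trials["target_side"].map({"left": -1.0, "right": 1.0}).to_numpy()
    df["switch_z"] = zscore(trials["switch_distance"])
    df["context_c"] = trials["context"].map({"color": -1.0, "motion": 1.0}).to_numpy()
    return df


def simulate_behavior(trials: pd.DataFrame, params: BehaviorParams,
                      n_subjects: int, seed: int) -> pd.DataFrame:
    """Simulate RT/accuracy records for ``n_subjects`` on a shared design."""
    rng = np.random.default_rng(seed)
    X = design_regressors(trials)
    lin_rt = (params.beta0
              + params.beta_ev * X["ev_z"]
              + params.beta_cong * X["cong_c"]
              + params.beta_cong_evback * X["cong_c"] * X["evback_z"]
              + params.beta_cong_ev * X["cong_c"] * X["ev_z"]
              + params.nu_trial * X["trial_z"] + params.nu_side * X["side"]
              + params.nu_switch * X["switch_z"] + params.nu_context * X["context_c"])
    lin_acc = (params.acc_beta0
               + params.acc_beta_ev * X["ev_z"]
               + params.acc_beta_cong * X["cong_c"]
               + params.acc_beta_cong_evback * X["cong_c"] * X["evback_z"]
               + params.acc_beta_cong_switch * X["cong_c"] * X["switch_z"]
               + params.acc_nu_trial * X["trial_z"] + params.acc_nu_side * X["side"]
               + params.acc_nu_switch * X["switch_z"]
               + params.acc_nu_context * X["context_c"])
    frames = []
    for k in range(n_subjects):
        g_rt = params.subject_sd * rng.standard_normal()
        g_acc = params.acc_subject_sd * rng.standard_normal()
        log_rt = lin_rt + g_rt + params.resid_sd * rng.standard_normal(len(trials))
        p_acc = 1.0 / (1.0 + np.exp(-(lin_acc + g_acc)))
        acc = rng.random(len(trials)) < p_acc
        df = trials.copy()
        df["subject"] = k
        df["rt"] = np.exp(log_rt)
        df["accuracy"] = acc.astype(int)
        df["choice_side"] = np.where(
            acc, df["target_side"],
            np.where(df["target_side"] == "left", "right", "left"))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_RT_BASE = "ev_z + trial_z + side + switch_z + context_c"

_RT_LADDER = [
    ("baseline", _RT_BASE),
    ("+Congruency", _RT_BASE + " + cong_c"),
    ("+EV_back", _RT_BASE + " + cong_c + evback_z"),
    ("+Congruency:EV_back", _RT_BASE + " + cong_c + evback_z + cong_c:evback_z"),
]


def _prep_rt_frame(records: pd.DataFrame) -> pd.DataFrame:
    df = records[(records["dim"] == "2D") & (records["accuracy"] == 1)].copy()
    if (df["rt"] <= 0).any():
        raise ValueError("non-positive RTs")
    df["logrt"] = np.log(df["rt"])
    keep = np.abs(df["logrt"] - df["logrt"].mean()) <= 3 * df["logrt"].std()
    df = df[keep]
    X = design_regressors(df)
    return pd.concat([df.reset_index(drop=True), X.reset_index(drop=True)], axis=1)


def fit_rt_ladder(records: pd.DataFrame) -> pd.DataFrame:
    """Nested log-RT mixed models on accurate 2D trials with LR tests.

    Ladder: baseline+EV -> +Congruency -> +EV_back -> +Congruency:EV_back,
    each with the four nuisance terms and a subject random intercept (ML).
    An alternative model replacing EV_back with the overall (mean) irrelevant
    value is fitted for AIC comparison.
    """
    df = _prep_rt_frame(records)
    rows = []
    prev = None
    for name, rhs in _RT_LADDER:
        fit = smf.mixedlm(f"logrt ~ {rhs}", df, groups=df["subject"]).fit(reml=False)
        added = rhs.split(" + ")[-1] if prev is not None else "baseline"
        chi2, p, df_lr = np.nan, np.nan, np.nan
        if prev is not None:
            chi2, p = lr_test(prev.llf, fit.llf, 1)
            df_lr = 1
        term = added if prev is not None else "ev_z"
        rows.append(effect_row(name, term,
                               estimate=fit.params.get(term.replace(" ", ""), np.nan),
                               se=fit.bse.get(term.replace(" ", ""), np.nan),
                               lr_chi2=chi2, df=df_lr, p=p, aic=fit.aic,
                               engine="mixedlm-ml"))
        prev = fit
    # alternative parametrization: overall irrelevant value instead of EV_back
    df["irr_mean_z"] = 0.0
    irr = (df["irr_left"].astype(float) + df["irr_right"].astype(float)) / 2
    df["irr_mean_z"] = zscore(irr)
    alt = smf.mixedlm(
        f"logrt ~ {_RT_BASE} + cong_c + irr_mean_z", df,
        groups=df["subject"]).fit(reml=False)
    rows.append(effect_row("+overall_irrelevant (alt)", "irr_mean_z",
                           estimate=alt.params.get("irr_mean_z", np.nan),
                           se=alt.bse.get("irr_mean_z", np.nan), aic=alt.aic,
                           engine="mixedlm-ml", note="AIC comparison vs +EV_back"))
    return effect_table(rows)


_ACC_BASE = "ev_z + trial_z + side + switch_z + context_c + C(subject)"

_ACC_LADDER = [
    ("baseline", _ACC_BASE),
    ("+Congruency", _ACC_BASE + " + cong_c"),
    ("+Congruency:EV_back", _ACC_BASE + " + cong_c + cong_c:evback_z"),
    ("+Congruency:switch", _ACC_BASE + " + cong_c + cong_c:evback_z"
                                       " + cong_c:switch_z"),
]


def fit_accuracy_ladder(records: pd.DataFrame) -> pd.DataFrame:
    """Binomial ladder mirroring the accuracy model, with LR tests.

    Subject heterogeneity is absorbed by fixed per-subject intercepts.  A
    degenerate all-correct sample is flagged and fitted with an L2-penalized
    (ridge) logistic fit instead of plain ML.
    """
    df = records[records["dim"] == "2D"].copy()
    X = design_regressors(df)
    df = pd.concat([df.reset_index(drop=True), X.reset_index(drop=True)], axis=1)
    separation = df["accuracy"].nunique() < 2
    rows = []
    prev = None
    for name, rhs in _ACC_LADDER:
        model = smf.glm(f"accuracy ~ {rhs}", df, family=sm.families.Binomial())
        if separation:
            fit = model.fit_regularized(alpha=1.0, L1_wt=0.0)
            rows.append(effect_row(name, "separation", engine="glm-ridge",
                                   note="all-correct sample: penalized fit"))
            continue
        fit = model.fit()
        added = rhs.split(" + ")[-1] if prev is not None else "ev_z"
        chi2, p, df_lr = np.nan, np.nan, np.nan
        if prev is not None:
            chi2, p = lr_test(prev.llf, fit.llf, 1)
            df_lr = 1
        rows.append(effect_row(name, added, estimate=fit.params.get(added, np.nan),
                               se=fit.bse.get(added, np.nan), lr_chi2=chi2, df=df_lr,
                               p=p, aic=fit.aic, engine="glm-fixed-intercepts"))
        prev = fit
    return effect_table(rows)


def congruency_contrasts(records: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests on per-subject mean log RT across trial categories.

    Contrasts: incongruent vs 1D, congruent vs 1D, incongruent vs congruent;
    p-values Benjamini-Hochberg adjusted.  Subjects missing a category are
    dropped (noted in the table).
    """
    df = records[records["accuracy"] == 1].copy()
    df["logrt"] = np.log(df["rt"])
    df["category"] = np.where(df["dim"] == "1D", "1D", df["congruency"])
    means = df.groupby(["subject", "category"])["logrt"].mean().unstack()
    n_dropped = int(means.isna().any(axis=1).sum())
    means = means.dropna()
    pairs = [("incongruent", "1D"), ("congruent", "1D"), ("incongruent", "congruent")]
    rows = []
    for a, b in pairs:
        diff = means[a] - means[b]
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0  # identical condition means
        else:
            t, p = stats.ttest_rel(means[a], means[b])
        rows.append(dict(contrast=f"{a} vs {b}", t=float(t), p=float(p),
                         mean_diff=float((means[a] - means[b]).mean()),
                         n=len(means), n_dropped=n_dropped))
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
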