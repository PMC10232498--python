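"""Cross-run representational similarity analysis over (EV, EV_back) conditions.

Per run, accurate 2D trials are averaged into the nine (EV x EV_back)
condition patterns, noise-normalized against the run's residuals (per-voxel
residual SD by default, or shrinkage-covariance whitening), and centered by
subtracting the across-condition mean pattern.  The 9x9 RDM averages the
Euclidean distance between condition patterns over all ordered pairs of
*different* runs, so within-run noise never biases the diagonal; the
diagonal holds same-condition cross-run distances rather than zeros.

The dissimilarities are modeled with gamma-family regressions on cell
covariates: Diagonal indicators (0 = the two conditions share the level,
1 = they differ) and absolute value differences (0/20/40 points), for EV
and EV_back separately, with subject intercepts and frequency-level
intercepts nested in subject.  Design frequency is the number of trials a
condition has per block (EV_back 30/50/70 appear 4/8/12 times), and a
cell's frequency level is the unordered pair of its two conditions'
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.covariance import LedoitWolf

from ._stats import effect_row, effect_table, zscore
from .neuralsim import PatternRun

EV_LEVELS = (30, 50, 70)
CONDITIONS = tuple(product(EV_LEVELS, EV_LEVELS))  # (EV, EV_back)
#: per-block design frequency of each EV_back level
FREQ_BY_EVBACK = {30: 4, 50: 8, 70: 12}


@dataclass
class ConditionPatterns:
    """Condition-mean patterns per run after normalization and centering."""

    vectors: np.ndarray        # (n_runs, 9, n_voxels); NaN rows for missing cells
    counts: np.ndarray         # (n_runs, 9) contributing-trial counts
    runs: tuple[int, ...]


@dataclass
class RDM:
    matrix: np.ndarray         # 9x9 symmetric
    conditions: tuple = CONDITIONS


def prepare_condition_patterns(runs: list[PatternRun],
                               mode: str = "diagonal") -> ConditionPatterns:
    """Average accurate 2D trials into per-run condition patterns.

    ``mode='diagonal'`` scales each voxel by its residual SD; ``'shrinkage'``
    whitens with the inverse matrix square root of a Ledoit-Wolf shrinkage
    estimate of the residual covariance.  The across-condition mean pattern
    is subtracted per run afterwards.  Conditions without trials in a run
    are left as NaN (flagged missing).
    """
    if mode not in ("diagonal", "shrinkage"):
        raise ValueError(f"unknown normalization mode: {mode}")
    n_vox = runs[0].patterns.shape[1]
    vectors = np.full((len(runs), len(CONDITIONS), n_vox), np.nan)
    counts = np.zeros((len(runs), len(CONDITIONS)), int)
    for r, run in enumerate(runs):
        lab = run.labels
        mask = (lab["dim"] == "2D") & (lab["accuracy"] == 1)
        if mode == "diagonal":
            sd = run.residuals.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            W = None
        else:
            cov = LedoitWolf().fit(run.residuals).covariance_
            evals, evecs = np.linalg.eigh(cov)
            W = evecs @ np.diag(evals ** -0.5) @ evecs.T
        for c, (ev, evb) in enumerate(CONDITIONS):
            sel = mask & (lab["EV"] == ev) & (lab["EV_back"] == evb)
            counts[r, c] = int(sel.sum())
            if counts[r, c] == 0:
                continue
            mean_pat = run.patterns[sel.to_numpy()].mean(axis=0)
            vectors[r, c] = mean_pat / sd if W is None else mean_pat @ W
        grand = np.nanmean(vectors[r], axis=0)
        vectors[r] -= grand
    return ConditionPatterns(vectors=vectors,
                             counts=counts, runs=tuple(r.run for r in runs))


def crossrun_rdm(conds: ConditionPatterns) -> RDM:
    """Mean Euclidean distance between conditions across ordered run pairs."""
    n_runs, n_cond, _ = conds.vectors.shape
    if n_runs < 2:
        raise ValueError("cross-run distances require at least two runs")
    acc = np.zeros((n_cond, n_cond))
    cnt = np.zeros((n_cond, n_cond))
    for r in range(n_runs):
        for s in range(n_runs):
            if r == s:
                continue
            d = np.linalg.norm(conds.vectors[r][:, None, :]
                               - conds.vectors[s][None, :, :], axis=-1)
            ok = ~np.isnan(d)
            acc[ok] += d[ok]
            cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        mat = acc / cnt
    mat = (mat + mat.T) / 2.0
    return RDM(matrix=mat)


def build_rdm_design(rdm: RDM, counts: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format cell table: upper triangle plus diagonal (45 cells).

    Columns: dissimilarity, Diagonal indicators (0 = same level), value
    differences, the frequency level (unordered pair of the two conditions'
    per-block design frequencies), and the cell's noise-floor covariate.

    The noise floor: a condition mean over f trials carries per-voxel
    variance proportional to 1/f, and subtracting the across-condition
    mean pattern mixes in (1/81) of every condition's variance, so under
    pure noise the expected cross-run distance of cell (i, j) scales as
    the mean over ordered run pairs (r, s) of

        sqrt((7/9) (1/f_i^r + 1/f_j^s) + (1/81) (S_r + S_s)),

    with S_r the sum of 1/f over the run's nine conditions.  Its log
    enters the gamma models as a covariate with a free slope.  When
    per-run realized counts are given they are used (behaviorally wrong
    trials shift counts off the design frequencies); otherwise the design
    frequencies stand in.
    """
    if counts is not None:
        with np.errstate(divide="ignore"):
            inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), np.nan)
        S = np.nansum(inv, axis=1)
    rows = []
    for i, (ev_i, evb_i) in enumerate(CONDITIONS):
        for j, (ev_j, evb_j) in enumerate(CONDITIONS):
            if j < i:
                continue
            fi, fj = FREQ_BY_EVBACK[evb_i], FREQ_BY_EVBACK[evb_j]
            if counts is not None:
                pair_floors = [
                    np.sqrt((7 / 9) * (inv[r, i] + inv[s, j])
                            + (S[r] + S[s]) / 81.0)
                    for r in range(counts.shape[0])
                    for s in range(counts.shape[0])
                    if r != s and counts[r, i] > 0 and counts[s, j] > 0]
                noise_floor = float(np.mean(pair_floors)) if pair_floors else np.nan
            else:
                s_design = sum(1.0 / FREQ_BY_EVBACK[evb] for _, evb in CONDITIONS)
                noise_floor = float(np.sqrt((7 / 9) * (1.0 / fi + 1.0 / fj)
                                            + 2 * s_design / 81.0))
            rows.append(dict(
                i=i, j=j, ev_i=ev_i, evback_i=evb_i, ev_j=ev_j, evback_j=evb_j,
                d=rdm.matrix[i, j],
                diag_ev=0 if ev_i == ev_j else 1,
                diag_evback=0 if evb_i == evb_j else 1,
                vd_ev=abs(ev_i - ev_j),
                vd_evback=abs(evb_i - evb_j),
                freq_level=f"{min(fi, fj)}_{max(fi, fj)}",
                freq_min=min(fi, fj), freq_max=max(fi, fj),
                log_invfreq=np.log(noise_floor),
            ))
    return pd.DataFrame(rows)


def subject_rdm_cells(pattern_runs: dict[int, list[PatternRun]],
                      mode: str = "diagonal") -> pd.DataFrame:
    """RDM cell tables for many subjects, stacked long with a subject column."""
    frames = []
    for k, runs in pattern_runs.items():
        conds = prepare_condition_patterns(runs, mode=mode)
        cells = build_rdm_design(crossrun_rdm(conds), counts=conds.counts)
        cells.insert(0, "subject", k)
        frames.append(cells)
    return pd.concat(frames, ignore_index=True)


def fit_rdm_models(cells: pd.DataFrame, link: str = "log") -> pd.DataFrame:
    """Gamma-family regressions of dissimilarity on the cell covariates.

    Two hierarchical ladders with LR tests: Diagonal_EV then Diagonal_EVback,
    and ValueDifference_EV then ValueDifference_EVback; subject intercepts
    are fixed effects.  Design frequency enters as a single numeric
    covariate, log(1/f_i + 1/f_j): condition means over f trials carry
    noise variance proportional to 1/f, so under pure noise the expected
    distance scales as sqrt(1/f_i + 1/f_j), which a free slope on this
    covariate absorbs exactly under the log link.  Categorical
    frequency-pair intercepts are not usable with a fixed-effects engine:
    EV_back level determines design frequency, so they would be perfectly
    collinear with the EV_back similarity terms (the paper-style coding
    needs shrinkage/random-effect machinery).  The two full models' AICs
    are comparable (same data, same family).
    """
    if cells["subject"].nunique() < 2:
        raise ValueError("at least two subjects required")
    df = cells.dropna(subset=["d"]).copy()
    if (df["d"] <= 0).any():
        df["d"] = df["d"] + np.finfo(float).eps
    for col in ("diag_ev", "diag_evback", "vd_ev", "vd_evback", "log_invfreq"):
        df[col + "_z"] = zscore(df[col])
    base = "C(subject) + log_invfreq_z"
    ladders = {
        "diagonal": ["diag_ev_z", "diag_evback_z"],
        "value_difference": ["vd_ev_z", "vd_evback_z"],
    }
    linkfun = {"log": sm.families.links.Log(),
               "inverse": sm.families.links.InversePower()}[link]
    family = sm.families.Gamma(linkfun)
    rows = []
    from scipy.stats import ttest_1samp

    for ladder_name, terms in ladders.items():
        # inference: summary-statistics route -- one per-subject gamma fit
        # of the full ladder model, t-test of each coefficient across
        # subjects (calibrated under the within-subject dependence of
        # cross-run distances sharing condition means)
        full_rhs = " + ".join([base.replace("C(subject) + ", "")] + terms) \
            .replace("C(subject)", "1")
        per_subject = {t: [] for t in terms}
        for _, sub in df.groupby("subject"):
            sfit = smf.glm(f"d ~ {full_rhs}", sub, family=family).fit()
            for t in terms:
                per_subject[t].append(sfit.params.get(t, np.nan))
        rhs = base
        prev = smf.glm(f"d ~ {rhs}", df, family=family).fit()
        for term in terms:
            rhs = rhs + " + " + term
            fit = smf.glm(f"d ~ {rhs}", df, family=family).fit()
            # pooled scaled-deviance LR (descriptive: cross-run distances of
            # overlapping condition pairs are dependent within subject,
            # which deflates the pooled statistic)
            chi2 = max(0.0, (prev.deviance - fit.deviance) / fit.scale)
            t, p = ttest_1samp(np.asarray(per_subject[term]), 0.0,
                               nan_policy="omit")
            rows.append(effect_row(f"{ladder_name}:+{term}", term,
                                   estimate=fit.params.get(term, np.nan),
                                   se=fit.bse.get(term, np.nan),
                                   lr_chi2=chi2, df=1, p=float(p), aic=fit.aic,
                                   engine=f"glm-gamma-{link}+two-stage-t"))
            prev = fit
    return effect_table(rows)
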