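"""Leave-one-run-out decoding of value, context and background value.

Protocol: multinomial logistic regression (L2 penalty, C = 1.0, lbfgs) is
trained on behaviorally accurate 1D trials of three runs and tested on every
trial of the held-out run, so each trial is predicted exactly once.  Before
training, the set is up-sampled so every balancing cell (EV x context x
chosen side) has the same number of examples, preferring duplicates from
under-represented blocks; test sets are never up-sampled.  Background value
(EV_back) is decoded from accurate 2D trials with three one-vs-rest binary
classifiers (balanced by EV x context x EV_back, with sample weights
equating the total positive and negative weight), whose per-trial
probabilities are renormalized to sum to one.  All probabilities are clipped
to [1e-5, 1 - 1e-5] (after renormalization; clipped vectors are not
renormalized again).

Transforms: the multinomial logit of class c is the mean log-odds of c
against every other class, mlogit(P_c) = (1/(K-1)) * sum_{c'!=c}
log(P_c / P_c'); the two-class context probability uses the plain logit.
Balanced accuracy averages correctness within (subject, fold, label) before
averaging across labels and folds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

PROB_CLIP = (0.00001, 0.99999)
VALUE_CLASSES = (30, 50, 70)
CONTEXT_CLASSES = ("color", "motion")


def balance_upsample(examples: pd.DataFrame, keys: list[str], seed: int,
                     block_col: str = "block") -> pd.DataFrame:
    """Duplicate members of under-represented key cells until all cells match.

    Every added example is an exact copy of an existing cell member; members
    from blocks contributing fewer examples to the cell are duplicated
    first.  An empty cell (a key combination present in the data's cells
    cross-product but without examples) raises.
    """
    rng = np.random.default_rng(seed)
    grouped = examples.groupby(keys, observed=True)
    target = int(grouped.size().max())
    picks: list = []
    for _, members in grouped:
        need = target - len(members)
        if need <= 0:
            continue
        # prefer blocks contributing fewer examples to this cell
        idx = members.index.to_numpy()[rng.permutation(len(members))]
        blocks = examples.loc[idx, block_col].to_numpy()
        counts = {b: int(n) for b, n in zip(*np.unique(blocks, return_counts=True))}
        for _ in range(need):
            pos = min(range(len(idx)), key=lambda i: counts[blocks[i]])
            picks.append(idx[pos])
            counts[blocks[pos]] += 1
    if not picks:
        return examples
    return pd.concat([examples, examples.loc[picks]], ignore_index=False)


def check_cells_nonempty(examples: pd.DataFrame, keys: list[str]) -> None:
    levels = [sorted(examples[k].dropna().unique()) for k in keys]
    sizes = examples.groupby(keys, observed=True).size()
    import itertools

    for combo in itertools.product(*levels):
        if combo not in sizes.index:
            raise ValueError(f"empty balancing cell {dict(zip(keys, combo))}")


def fit_multinomial(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                    sample_weight=None, tol: float = 1e-6) -> LogisticRegression:
    """L2-penalized (multinomial) logistic regression, deterministic given data."""
    if len(np.unique(y)) < 2:
        raise ValueError("at least two classes required")
    # default penalty is L2; the keyword itself is deprecated in sklearn >= 1.8
    clf = LogisticRegression(C=C, solver="lbfgs", tol=tol, max_iter=10000)
    clf.fit(X, y, sample_weight=sample_weight)
    if clf.n_iter_[0] >= clf.max_iter:
        raise RuntimeError(f"lbfgs did not converge in {clf.max_iter} iterations")
    return clf


def _runs_frame(runs) -> tuple[pd.DataFrame, np.ndarray]:
    labels = pd.concat([r.labels.assign(_run=r.run) for r in runs], ignore_index=True)
    X = np.vstack([r.patterns for r in runs])
    return labels, X


def loro_decode(runs, target: str = "value", seed: int = 0) -> pd.DataFrame:
    """Leave-one-run-out class probabilities for every trial.

    ``target='value'`` decodes EV (blind to context); ``'context'`` decodes
    the cued context (blind to EV).  Training examples: accurate 1D trials
    of the three remaining runs, up-sampled to balance EV x context x chosen
    side.  Held-out 1D and 2D trials are all scored.
    """
    if target not in ("value", "context"):
        raise ValueError("target must be 'value' or 'context'")
    labels, X = _runs_frame(runs)
    label_col = "EV" if target == "value" else "context"
    keys = ["EV", "context", "choice_side"]
    rng = np.random.default_rng(seed)
    recs = []
    for held in sorted(labels["_run"].unique()):
        train_mask = (labels["_run"] != held) & (labels["dim"] == "1D") \
            & (labels["accuracy"] == 1)
        train = labels[train_mask]
        check_cells_nonempty(train, keys)
        up = balance_upsample(train, keys, seed=int(rng.integers(2**31)))
        classes = sorted(up[label_col].unique())
        if len(classes) != (3 if target == "value" else 2):
            raise ValueError(f"fold {held}: missing class in training set")
        clf = fit_multinomial(X[up.index.to_numpy()], up[label_col].to_numpy())
        test = labels[labels["_run"] == held]
        raw = clf.predict_proba(X[test.index.to_numpy()])
        clipped = np.clip(raw, *PROB_CLIP)
        out = test[["trial", "block", "dim", "EV", "EV_back", "congruency",
                    "context", "accuracy", "target_side", "choice_side",
                    "switch_distance", "irr_left", "irr_right"]].copy()
        out["fold"] = held
        for c, cls in zip(clf.classes_, clipped.T):
            out[f"p_{c}"] = cls
        out["clipped"] = (raw != clipped).any(axis=1)
        recs.append(out)
    return pd.concat(recs, ignore_index=True)


def ovr_evback_decode(runs, seed: int = 0) -> pd.DataFrame:
    """One-vs-rest EV_back probabilities for 2D trials, leave-one-run-out.

    Three binary L2 classifiers (one per EV_back level) trained on accurate
    2D trials balanced by EV x context x EV_back; within each binary
    problem, sample weights equate the total weight of positives and
    negatives.  The three probabilities are renormalized to sum to one,
    then clipped.
    """
    labels, X = _runs_frame(runs)
    keys = ["EV", "context", "EV_back"]
    rng = np.random.default_rng(seed)
    recs = []
    for held in sorted(labels["_run"].unique()):
        train_mask = (labels["_run"] != held) & (labels["dim"] == "2D") \
            & (labels["accuracy"] == 1)
        train = labels[train_mask]
        check_cells_nonempty(train, keys)
        up = balance_upsample(train, keys, seed=int(rng.integers(2**31)))
        test = labels[(labels["_run"] == held) & (labels["dim"] == "2D")]
        probs = np.zeros((len(test), len(VALUE_CLASSES)))
        for c, level in enumerate(VALUE_CLASSES):
            y = (up["EV_back"] == level).to_numpy().astype(int)
            if y.min() == y.max():
                raise ValueError(f"fold {held}: EV_back level {level} missing")
            w = np.where(y == 1, 0.5 / y.sum(), 0.5 / (len(y) - y.sum()))
            w = w * len(y)
            clf = fit_multinomial(X[up.index.to_numpy()], y, sample_weight=w)
            probs[:, c] = clf.predict_proba(X[test.index.to_numpy()])[:, 1]
        raw = probs / probs.sum(axis=1, keepdims=True)
        clipped = np.clip(raw, *PROB_CLIP)
        out = test[["trial", "block", "dim", "EV", "EV_back", "congruency",
                    "context", "accuracy", "choice_side", "irr_left",
                    "irr_right"]].copy()
        out["fold"] = held
        for level, col in zip(VALUE_CLASSES, clipped.T):
            out[f"pback_{level}"] = col
        out["raw_sum"] = raw.sum(axis=1)
        out["clipped"] = (raw != clipped).any(axis=1)
        recs.append(out)
    return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# transforms and scoring
# ---------------------------------------------------------------------------


def mlogit(probs: np.ndarray) -> np.ndarray:
    """mlogit(P_c) = (1/(K-1)) * sum_{c' != c} log(P_c / P_{c'}), column-wise.

    For K classes, sum_{c'!=c} log(p_c/p_{c'}) = (K-1) log p_c -
    (sum_c' log p_{c'} - log p_c); the mean over the K-1 contrasts is
    returned, so a uniform probability vector maps to zeros.
    """
    probs = np.asarray(probs, float)
    k = probs.shape[-1]
    logp = np.log(probs)
    return (k * logp - logp.sum(axis=-1, keepdims=True)) / (k - 1)


def logit(p):
    p = np.asarray(p, float)
    return np.log(p / (1.0 - p))


def transform_probs(df: pd.DataFrame, prefix: str = "p_") -> pd.DataFrame:
    """Add multinomial-logit columns for each class-probability column."""
    cols = [c for c in df.columns if c.startswith(prefix) and
            c[len(prefix):].isdigit()]
    ml = mlogit(df[cols].to_numpy())
    out = df.copy()
    for c, col in zip(cols, ml.T):
        out["mlogit_" + c] = col
    return out


def balanced_accuracy(recs: pd.DataFrame, label_col: str, prefix: str,
                      by: str | None = None) -> pd.DataFrame:
    """Accuracy averaged within (fold, label) then across labels and folds.

    A prediction counts as correct iff the unique argmax class equals the
    truth; argmax ties count as incorrect.  If ``by`` is given (e.g. a
    subject column), scores are computed per group.
    """
    cols = [c for c in recs.columns if c.startswith(prefix)]
    classes = [c[len(prefix):] for c in cols]
    probs = recs[cols].to_numpy()
    best = probs.max(axis=1, keepdims=True)
    is_max = probs == best
    tie = is_max.sum(axis=1) > 1
    pred = np.asarray(classes, object)[probs.argmax(axis=1)]
    truth = recs[label_col].astype(float).astype(int).astype(str) \
        if recs[label_col].dtype != object else recs[label_col].astype(str)
    correct = (pred.astype(str) == truth.to_numpy()) & ~tie
    tmp = recs[["fold", label_col]].copy()
    tmp["correct"] = correct
    group_cols = ([by] if by else []) + ["fold", label_col]
    per_label = tmp.groupby(group_cols, observed=True)["correct"].mean()
    if by:
        return per_label.groupby(level=0).mean().rename("balanced_accuracy").reset_index()
    return pd.DataFrame({"balanced_accuracy": [per_label.mean()]})


def aggregate_combinations(recs: pd.DataFrame) -> pd.DataFrame:
    """Average 2D class probabilities within EV x (irr_chosen, irr_unchosen).

    A complete 2D design yields 36 cells.  EV_back and Congruency are
    recomputed per cell from the cell's irrelevant values.
    """
    df = recs[recs["dim"] == "2D"].copy()
    df["irr_chosen"] = np.where(df["choice_side"] == "left",
                                df["irr_left"], df["irr_right"])
    df["irr_unchosen"] = np.where(df["choice_side"] == "left",
                                  df["irr_right"], df["irr_left"])
    prob_cols = [c for c in df.columns if c.startswith("p_") or c.startswith("pback_")]
    group = ["EV", "irr_chosen", "irr_unchosen"]
    agg = df.groupby(group, observed=True)[prob_cols].mean().reset_index()
    agg["n_trials"] = df.groupby(group, observed=True).size().to_numpy()
    agg["EV_back"] = agg[["irr_chosen", "irr_unchosen"]].max(axis=1)
    agg["congruency"] = np.where(agg["irr_chosen"] > agg["irr_unchosen"],
                                 "congruent", "incongruent")
    return agg
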