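"""Adaptive staircase that equalizes detection RTs across stimulus features.

Each of the eight features (four colors, four motion axes) has an adjustable
perceptual parameter theta (motion-coherence fraction or color speed).  After
a block of cued-detection trials, theta is moved proportionally to the
relative deviation of the feature's mean RT from an anchor RT:

    theta' = theta + alpha * theta * (mean_rt - anchor_rt) / anchor_rt

so a feature detected slower than the anchor is made easier (theta up) and a
faster one harder.  The procedure has two adjustment blocks: block 1
(72 trials) computes the anchor from the last 48 accurate trials and applies
one alpha = 1 adjustment per feature; block 2 re-anchors on 24 motion-cued
trials and then adjusts each feature after every three correct answers, with
alpha decreasing from 0.6 to 0.1 in steps of 0.1 (at most six adjustments
per feature).

The simulated observer is a package construct: RT(theta) = a + b / theta +
Gaussian noise, strictly decreasing in theta with analytic equilibrium
theta* = b / (anchor - a).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import COLOR_FEATURES, CONTEXTS, MOTION_AXES

THETA_MIN = 1e-4
ALPHAS = (1.0, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)

FEATURES = tuple((ctx, f) for ctx, feats in
                 zip(CONTEXTS, (COLOR_FEATURES, MOTION_AXES)) for f in feats)


def update_theta(theta: float, mean_rt: float, anchor_rt: float, alpha: float,
                 motion: bool = False) -> float:
    """One proportional staircase step, clamped to the feasible range."""
    if theta <= 0 or mean_rt <= 0 or anchor_rt <= 0 or alpha <= 0:
        raise ValueError("theta, RTs and alpha must be positive")
    new = theta + alpha * theta * (mean_rt - anchor_rt) / anchor_rt
    new = max(new, THETA_MIN)
    if motion:
        new = min(new, 1.0)
    return new


def alpha_schedule(block: int, step: int) -> float:
    """Step size: 1.0 in block 1; 0.6, 0.5, ..., 0.1 across block-2 steps."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if block == 1:
        return 1.0
    return max(0.7 - 0.1 * step, 0.1)


@dataclass
class ObserverModel:
    """Per-feature RT law RT = a + b/theta + eps and Bernoulli accuracy."""

    a: dict[tuple, float]
    b: dict[tuple, float]
    noise_sd: float = 0.08
    accuracy: float = 0.9

    @classmethod
    def homogeneous(cls, a: float = 0.3, b: float = 0.35, **kw) -> "ObserverModel":
        return cls(a={f: a for f in FEATURES}, b={f: b for f in FEATURES}, **kw)

    @classmethod
    def heterogeneous(cls, seed: int, a_mean: float = 0.3, a_sd: float = 0.1,
                      b: float = 0.35, **kw) -> "ObserverModel":
        """Observer with feature-specific RT offsets (what staircasing corrects)."""
        rng = np.random.default_rng(seed)
        a = {f: max(0.05, a_mean + a_sd * rng.standard_normal()) for f in FEATURES}
        return cls(a=a, b={f: b for f in FEATURES}, **kw)

    def rt(self, feature, theta: float, rng: np.random.Generator) -> float:
        rt = self.a[feature] + self.b[feature] / theta + self.noise_sd * rng.standard_normal()
        return max(rt, 0.05)

    def expected_rt(self, feature, theta: float) -> float:
        return self.a[feature] + self.b[feature] / theta


@dataclass
class StaircaseState:
    theta: dict[tuple, float]
    anchor_rt: float | None = None
    n_adjustments: dict[tuple, int] = field(default_factory=dict)


def _cue_sequence(features, n_per_feature, rng):
    seq = [f for f in features for _ in range(n_per_feature)]
    rng.shuffle(seq)
    return seq


def run_staircase(observer: ObserverModel, seed: int,
                  motion_coherence: float = 0.7,
                  color_speed: float = 0.7) -> tuple[pd.DataFrame, StaircaseState, dict]:
    """Simulate both adjustment blocks; returns (trace, final state, summary).

    The trace has one row per trial (block, trial, feature, theta, rt,
    accurate) plus one row per adjustment (phase='adjust').
    """
    rng = np.random.default_rng(seed)
    theta = {(ctx, f): (motion_coherence if ctx == "motion" else color_speed)
             for ctx, f in FEATURES}
    n_adj = {f: 0 for f in FEATURES}
    rows = []

    def run_trials(block, features, n_per_feature):
        trials = []
        for t, feat in enumerate(_cue_sequence(list(features), n_per_feature, rng)):
            rt = observer.rt(feat, theta[feat], rng)
            acc = bool(rng.random() < observer.accuracy)
            trials.append(dict(block=block, feature=feat, rt=rt, accurate=acc,
                               theta=theta[feat], phase="trial"))
        return trials

    # ----- adjustment block 1: 72 trials, one alpha=1 step per feature -----
    block1 = run_trials(1, FEATURES, 9)
    rows += block1
    accurate = [tr for tr in block1 if tr["accurate"]]
    anchor_pool = accurate[-48:]
    warning = False
    if not anchor_pool:
        warning = True
        anchor = None
    else:
        anchor = float(np.mean([tr["rt"] for tr in anchor_pool]))
        for feat in FEATURES:
            rts = [tr["rt"] for tr in block1 if tr["feature"] == feat and tr["accurate"]]
            if not rts:
                continue
            theta[feat] = update_theta(theta[feat], float(np.mean(rts)), anchor,
                                       alpha_schedule(1, 1), motion=feat[0] == "motion")
            rows.append(dict(block=1, feature=feat, rt=np.nan, accurate=None,
                             theta=theta[feat], phase="adjust"))

    # ----- adjustment block 2 -----
    motion_feats = [f for f in FEATURES if f[0] == "motion"]
    color_feats = [f for f in FEATURES if f[0] == "color"]
    anchor_trials = run_trials(2, motion_feats, 6)  # 24 motion-cued anchor trials
    rows += anchor_trials
    acc_rts = [tr["rt"] for tr in anchor_trials if tr["accurate"]]
    if acc_rts:
        anchor = float(np.mean(acc_rts))
    correct_buffer: dict[tuple, list[float]] = {f: [] for f in FEATURES}
    steps = {f: 0 for f in FEATURES}
    for feats in (motion_feats, color_feats):  # 72 motion-cued then 72 color-cued
        for tr in run_trials(2, feats, 18):
            rows.append(tr)
            if not tr["accurate"] or anchor is None:
                continue
            feat = tr["feature"]
            correct_buffer[feat].append(tr["rt"])
            if len(correct_buffer[feat]) == 3 and steps[feat] < 6:
                steps[feat] += 1
                mean_rt = float(np.mean(correct_buffer[feat]))
                theta[feat] = update_theta(theta[feat], mean_rt, anchor,
                                           alpha_schedule(2, steps[feat]),
                                           motion=feat[0] == "motion")
                n_adj[feat] += 1
                correct_buffer[feat] = []
                rows.append(dict(block=2, feature=feat, rt=np.nan, accurate=None,
                                 theta=theta[feat], phase="adjust"))
    if sum(n_adj.values()) == 0:
        warning = True

    trace = pd.DataFrame(rows)
    trace.insert(0, "trial", range(len(trace)))
    state = StaircaseState(theta=theta, anchor_rt=anchor, n_adjustments=n_adj)
    init_theta = {(ctx, f): (motion_coherence if ctx == "motion" else color_speed)
                  for ctx, f in FEATURES}
    summary = dict(
        anchor_rt=anchor,
        warning_no_adjustment=warning,
        adjustments={str(k): v for k, v in n_adj.items()},
        rt_variance_before=float(np.var([observer.expected_rt(f, init_theta[f])
                                         for f in FEATURES])),
        rt_variance_after=float(np.var([observer.expected_rt(f, theta[f])
                                        for f in FEATURES])),
    )
    return trace, state, summary


def variance_reduction_rate(seed: int, n_replicates: int = 100, **observer_kw) -> float:
    """Fraction of heterogeneous-observer replicates with reduced RT variance."""
    root = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_replicates):
        s = int(root.integers(2**31))
        obs = ObserverModel.heterogeneous(seed=s, **observer_kw)
        _, _, summary = run_staircase(obs, seed=s + 1)
        wins += summary["rt_variance_after"] < summary["rt_variance_before"]
    return wins / n_replicates
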