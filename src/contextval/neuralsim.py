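"""Synthetic multivoxel response patterns for a single value-coding ROI.

Each trial's pattern over ``n_voxels`` voxels linearly mixes three codes:

* a graded *relevant-value* code u_rel(EV): unit-norm voxel vectors whose
  pairwise correlation decays as rho^(|v - v'| / 20), so nearby reward
  levels have similar patterns;
* a graded *background-value* code u_back(EV_back) on 2D trials, sharing
  the relevant code with channel overlap omega (omega = 1 reproduces the
  relevant codebook exactly);
* a binary *context* code c(color)/c(motion), orthogonal to all value codes.

Trial-wise gains implement the competition mechanism under study: the
context gain g_ctx is log-normal; the background gain grows with EV_back;
and the relevant gain is suppressed by the background signal with strength
lambda, with the suppression attenuated by a strong context signal
(moderation m):

    g_EV = max(0, a_EV - lambda * exp(-m * g_ctx) * g_back)

Heteroscedastic Gaussian voxel noise is added, and a matched residual
matrix is drawn from the same noise model so that downstream noise
normalization is non-trivial.  Ground-truth gains are exported per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import CONTEXTS, VALUES


@dataclass
class Codebook:
    """Voxel vectors for value and context codes (all unit norm)."""

    u_rel: np.ndarray     # (n_voxels, 4) relevant-value codes, one per reward level
    u_back: np.ndarray    # (n_voxels, 4) background-value codes
    u_ctx: np.ndarray     # (n_voxels, 2) context codes, orthogonal to value codes
    rho: float
    omega: float

    def rel(self, value: int) -> np.ndarray:
        return self.u_rel[:, VALUES.index(value)]

    def back(self, value: int) -> np.ndarray:
        return self.u_back[:, VALUES.index(value)]

    def ctx(self, context: str) -> np.ndarray:
        return self.u_ctx[:, CONTEXTS.index(context)]


def make_codebook(n_voxels: int, rho: float = 0.5, omega: float = 0.7,
                  seed: int = 0) -> Codebook:
    """Construct codes with exact target correlation structure.

    An orthonormal voxel basis (QR of a Gaussian matrix) is mixed through
    the Cholesky factor of the target correlation matrix, so realized inner
    products match rho^(|v-v'|/20) exactly; empirical Pearson correlations
    then match up to the O(1/sqrt(n_voxels)) centering error.
    """
    n_codes = 2 * len(VALUES) + len(CONTEXTS)
    if n_voxels < n_codes:
        raise ValueError(f"n_voxels must be >= {n_codes} to realize the codebook")
    if not (0 <= rho < 1) or not (0 <= omega <= 1):
        raise ValueError("rho must be in [0,1), omega in [0,1]")
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((n_voxels, n_codes)))
    vals = np.asarray(VALUES, float)
    corr = rho ** (np.abs(vals[:, None] - vals[None, :]) / 20.0)
    L = np.linalg.cholesky(corr)  # positive definite for rho < 1
    u_rel = basis[:, 0:4] @ L.T
    w = basis[:, 4:8] @ L.T       # independent codebook, same structure
    u_back = omega * u_rel + np.sqrt(1.0 - omega**2) * w
    u_ctx = basis[:, 8:10]
    return Codebook(u_rel=u_rel, u_back=u_back, u_ctx=u_ctx, rho=rho, omega=omega)


@dataclass
class NeuralParams:
    """Amplitudes, competition/moderation strengths, and the noise model."""

    a_ev: float = 1.0            # relevant-value amplitude
    a_back: float = 0.6          # background-value base amplitude
    a_ctx: float = 1.0           # median context gain (log-normal)
    ctx_gain_sd: float = 0.5     # SD of log context gain across trials
    lam: float = 0.0             # competition: background suppresses relevant gain
    moderation: float = 0.0      # context gain attenuates the competition
    evback_scaling: float = 0.3  # background gain grows with EV_back level
    back_gain_sd: float = 0.4    # SD of log background gain across trials
    noise_sd: float = 1.0        # median voxel noise SD (log-normal across voxels)
    noise_sd_dispersion: float = 0.4
    n_voxels: int = 200
    n_runs: int = 4
    rho: float = 0.5
    omega: float = 0.7
    n_residual: int = 60         # residual rows per run

    def __post_init__(self):
        if min(self.a_ev, self.a_back, self.a_ctx, self.lam, self.moderation) < 0:
            raise ValueError("amplitudes, lambda and moderation must be >= 0")

    @classmethod
    def null(cls, **kw) -> "NeuralParams":
        """Zero signal amplitudes: downstream analyses must be at chance."""
        return cls(a_ev=0.0, a_back=0.0, a_ctx=0.0, ctx_gain_sd=0.0, lam=0.0,
                   moderation=0.0, evback_scaling=0.0, **kw)

    @classmethod
    def paper_like(cls, **kw) -> "NeuralParams":
        """Graded codes with competition and context-gain moderation planted.

        Effect sizes were fixed by a pre-registered-style power analysis of
        the sign checklist (see docs/methods.md): strong enough that the
        qualitative pattern is recoverable from a dozen synthetic subjects,
        while single-trial decoding stays far from ceiling.
        """
        defaults = dict(a_ev=1.6, a_ctx=2.0, lam=1.2, moderation=0.6,
                        a_back=1.2, evback_scaling=0.5, back_gain_sd=0.9,
                        omega=0.9, noise_sd=0.7, ctx_gain_sd=0.8, n_voxels=200)
        defaults.update(kw)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatternRun:
    """Trials x voxels responses for one run plus matched residuals and labels."""

    run: int
    patterns: np.ndarray
    residuals: np.ndarray
    labels: pd.DataFrame
    ground_truth: pd.DataFrame = field(repr=False, default=None)


def _background_gain(params: NeuralParams, ev_back: float) -> float:
    return params.a_back * (1.0 + params.evback_scaling * (ev_back - 50.0) / 20.0)


def simulate_patterns(trials: pd.DataFrame, behavior: pd.DataFrame,
                      codebook: Codebook, params: NeuralParams,
                      seed: int) -> list[PatternRun]:
    """Simulate one subject's per-trial patterns, one ``PatternRun`` per block.

    ``behavior`` must be the same subject's records, row-aligned with
    ``trials`` on the trial index (accuracy and chosen side are copied into
    the run labels).
    """
    rng = np.random.default_rng(seed)
    beh = behavior.set_index("trial")
    sigma = params.noise_sd * np.exp(
        params.noise_sd_dispersion * rng.standard_normal(params.n_voxels))
    runs = []
    for b, block in trials.groupby("block"):
        n = len(block)
        X = np.zeros((n, params.n_voxels))
        gt_rows = []
        for i, (_, tr) in enumerate(block.iterrows()):
            g_ctx = params.a_ctx * np.exp(params.ctx_gain_sd * rng.standard_normal()) \
                if params.a_ctx > 0 else 0.0
            if tr["dim"] == "2D":
                g_back = _background_gain(params, float(tr["EV_back"]))
                if params.back_gain_sd > 0 and g_back > 0:
                    # trial-wise fluctuation of the background signal; its
                    # anti-coupling with the relevant gain (via lam) is what
                    # the probability-correlation analysis detects
                    g_back *= np.exp(params.back_gain_sd * rng.standard_normal())
            else:
                g_back = 0.0
            g_ev = max(0.0, params.a_ev
                       - params.lam * np.exp(-params.moderation * g_ctx) * g_back)
            pattern = g_ctx * codebook.ctx(tr["context"]) + g_ev * codebook.rel(tr["EV"])
            if tr["dim"] == "2D":
                pattern = pattern + g_back * codebook.back(int(tr["EV_back"]))
            X[i] = pattern + sigma * rng.standard_normal(params.n_voxels)
            gt_rows.append(dict(trial=tr["trial"], g_ctx=g_ctx, g_ev=g_ev, g_back=g_back))
        resid = sigma * rng.standard_normal((params.n_residual, params.n_voxels))
        resid -= resid.mean(axis=0)
        labels = block[["trial", "block", "context", "dim", "EV", "EV_back",
                        "congruency", "target_side", "switch_distance",
                        "irr_left", "irr_right"]].copy().reset_index(drop=True)
        labels["accuracy"] = beh.loc[labels["trial"], "accuracy"].to_numpy()
        labels["choice_side"] = beh.loc[labels["trial"], "choice_side"].to_numpy()
        labels["irr_chosen"] = np.where(labels["choice_side"] == "left",
                                        labels["irr_left"], labels["irr_right"])
        labels["irr_unchosen"] = np.where(labels["choice_side"] == "left",
                                          labels["irr_right"], labels["irr_left"])
        runs.append(PatternRun(run=int(b), patterns=X, residuals=resid,
                               labels=labels, ground_truth=pd.DataFrame(gt_rows)))
    return runs


def simulate_subject_patterns(trials: pd.DataFrame, behavior: pd.DataFrame,
                              params: NeuralParams, seed: int) -> dict[int, list[PatternRun]]:
    """Patterns for every subject in ``behavior``; per-subject codebooks."""
    out = {}
    root = np.random.default_rng(seed)
    for k, beh_k in behavior.groupby("subject"):
        cb_seed, pat_seed = root.integers(2**31, size=2)
        cb = make_codebook(params.n_voxels, rho=params.rho, omega=params.omega,
                           seed=int(cb_seed))
        out[int(k)] = simulate_patterns(trials, beh_k, cb, params, int(pat_seed))
    return out


def ground_truth_table(runs: list[PatternRun]) -> pd.DataFrame:
    return pd.concat([r.ground_truth for r in runs], ignore_index=True)


def write_patterns(runs: list[PatternRun], out_dir) -> None:
    """Serialize one subject's runs as patterns_runK.csv plus ground_truth.csv.

    Trial rows carry the label columns followed by one column per voxel.
    Plain CSV keeps the artifacts text-only; at a few hundred voxels per
    run this is the practical ceiling, so the pipeline writes patterns
    only on request.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for run in runs:
        vox = pd.DataFrame(run.patterns,
                           columns=[f"v{i}" for i in range(run.patterns.shape[1])])
        pd.concat([run.labels.reset_index(drop=True), vox], axis=1).to_csv(
            out / f"patterns_run{run.run}.csv", index=False)
    ground_truth_table(runs).to_csv(out / "ground_truth.csv", index=False)
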