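"""Experimental design generation for the context-dependent value task.

The main task shows two random-dot clouds and cues one feature dimension
(color or motion) as the relevant *context*.  Each of the four features per
context is mapped to a reward level in {10, 30, 50, 70} points.  Trials are
either 1D (only the cued dimension carries a feature) or 2D (both dimensions
carry features); the relevant pair always differs by 20 points, so the
expected value of a correct choice (EV) is one of {30, 50, 70}.  On 2D trials
the irrelevant features define a *background* expected value (EV_back, the
maximum of the two ignored values) and a Congruency label (do the irrelevant
features favor the same side as the relevant ones?).  EV, EV_back and
Congruency are orthogonal by construction over the complete 2D condition set.

This module generates value mappings, the per-block trial multisets, the
pseudo-randomized trial order under the sequencing constraints, jittered
event timings, and the HRF-convolved trial-wise estimability (VIF) check.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncexpon

VALUES = (10, 30, 50, 70)
EV_LEVELS = (30, 50, 70)
CONTEXTS = ("color", "motion")
COLOR_FEATURES = ("red", "green", "blue", "orange")
MOTION_AXES = (0, 45, 90, 135)

#: trials per block
N_1D_PER_BLOCK = 36
N_2D_PER_BLOCK = 72

# event durations (seconds)
CUE_DURATION = 0.6
STIM_DURATION = 1.6
OUTCOME_DURATION = 0.8

#: (mean, low, high) of the truncated-exponential inter-event gaps
GAP_CUE_STIM = (0.6, 0.5, 2.5)
GAP_STIM_OUTCOME = (3.4, 1.5, 9.0)
GAP_OUTCOME_CUE = (1.25, 0.7, 6.0)


class DesignGenerationError(RuntimeError):
    """Raised when the constraint set cannot be satisfied within the retry budget."""


# ---------------------------------------------------------------------------
# value mappings
# ---------------------------------------------------------------------------


def _is_cyclic_monotone(values: Sequence[int]) -> bool:
    """True if ``values`` (in axis order) ascend around the cycle in either direction.

    A mapping is excluded when the reward levels, read clockwise or
    counter-clockwise around the motion-axis order, form a rotation of the
    sorted sequence (10, 30, 50, 70).
    """
    v = tuple(values)
    rotations = {v[i:] + v[:i] for i in range(4)}
    ascending = tuple(sorted(v))
    descending = ascending[::-1]
    return ascending in rotations or descending in rotations


def admissible_motion_permutations() -> list[tuple[int, ...]]:
    """All 4! assignments of reward levels to motion axes minus cyclic orderings."""
    return [p for p in itertools.permutations(VALUES) if not _is_cyclic_monotone(p)]


@dataclass(frozen=True)
class ValueMapping:
    """Bijections feature -> reward level for both contexts."""

    color: dict[str, int]
    motion: dict[int, int]

    def __post_init__(self):
        for mapping in (self.color, self.motion):
            if sorted(mapping.values()) != sorted(VALUES):
                raise ValueError("each reward level must be used exactly once per context")

    def feature_of(self, context: str, value: int):
        mapping = self.color if context == "color" else self.motion
        for feat, val in mapping.items():
            if val == value:
                return feat
        raise KeyError(value)

    def to_json(self) -> str:
        return json.dumps(
            {"color": self.color, "motion": {str(k): v for k, v in self.motion.items()}}
        )


def make_value_mapping(seed: int) -> ValueMapping:
    """Uniformly sample an admissible feature->value mapping.

    Color permutations are drawn from all 24; motion permutations from the
    subset that survives the cyclic-order exclusion.
    """
    rng = np.random.default_rng(seed)
    color_perms = list(itertools.permutations(VALUES))
    color = dict(zip(COLOR_FEATURES, color_perms[rng.integers(len(color_perms))]))
    motion_perms = admissible_motion_permutations()
    motion = dict(zip(MOTION_AXES, motion_perms[rng.integers(len(motion_perms))]))
    return ValueMapping(color=color, motion=motion)


# ---------------------------------------------------------------------------
# trial classification and enumeration
# ---------------------------------------------------------------------------


def classify_trial(rel_left: int, rel_right: int, irr_left=None, irr_right=None):
    """Return (EV, EV_back, congruency) for a trial.

    EV is the maximum relevant value; on 2D trials EV_back is the maximum
    irrelevant value and the trial is congruent iff the higher irrelevant
    value sits on the same side as the higher relevant value.  For 1D trials
    EV_back and congruency are ``None``.
    """
    ev = max(rel_left, rel_right)
    if irr_left is None or irr_right is None:
        return ev, None, None
    ev_back = max(irr_left, irr_right)
    rel_side = "left" if rel_left > rel_right else "right"
    irr_side = "left" if irr_left > irr_right else "right"
    congruency = "congruent" if rel_side == irr_side else "incongruent"
    return ev, ev_back, congruency


def enumerate_2d_conditions(relevant_pair: tuple[int, int]) -> list[tuple[int, int]]:
    """All ordered (irr_left, irr_right) pairings for a relevant pair.

    Every ordered pairing of the four irrelevant-feature values with
    irr_left != irr_right is included: 12 pairings.
    """
    lo, hi = sorted(relevant_pair)
    if hi - lo != 20 or hi not in EV_LEVELS:
        raise ValueError(f"relevant pair must differ by 20 points within {VALUES}: {relevant_pair}")
    return [(a, b) for a in VALUES for b in VALUES if a != b]


# ---------------------------------------------------------------------------
# per-block trial multiset
# ---------------------------------------------------------------------------


def _block_trial_pool(rng: np.random.Generator) -> dict[str, list[dict]]:
    """Exact per-block trial multiset, keyed by context.

    1D: per (context, EV) 6 trials, 3 with the target left and 3 right.
    2D: per (context, EV) all 12 ordered irrelevant pairings; for each
    unordered irrelevant pair the two ordered versions share a target side
    (one congruent, one incongruent), and sides are split 3/3 over the six
    unordered pairs.  This makes EV, EV_back and Congruency exactly
    orthogonal and balances target side 6/6 within every (context, EV) cell.
    """
    pool: dict[str, list[dict]] = {ctx: [] for ctx in CONTEXTS}
    unordered = [(hi, lo) for hi, lo in itertools.combinations(sorted(VALUES, reverse=True), 2)]
    for ctx in CONTEXTS:
        for ev in EV_LEVELS:
            for side in ("left", "right"):
                for _ in range(3):
                    rel_l, rel_r = (ev, ev - 20) if side == "left" else (ev - 20, ev)
                    pool[ctx].append(
                        dict(context=ctx, dim="1D", rel_left=rel_l, rel_right=rel_r,
                             irr_left=None, irr_right=None, target_side=side)
                    )
            left_group = rng.permutation(6)[:3]
            for k, (hi, lo) in enumerate(unordered):
                side = "left" if k in left_group else "right"
                rel_l, rel_r = (ev, ev - 20) if side == "left" else (ev - 20, ev)
                for irr_l, irr_r in ((hi, lo), (lo, hi)):
                    pool[ctx].append(
                        dict(context=ctx, dim="2D", rel_left=rel_l, rel_right=rel_r,
                             irr_left=irr_l, irr_right=irr_r, target_side=side)
                    )
    return pool


def _context_run_lengths(rng: np.random.Generator, total: int = 54) -> list[int]:
    """Random composition of ``total`` into parts within [4, 7]."""
    k_lo = -(-total // 7)
    k_hi = total // 4
    k = int(rng.integers(k_lo, k_hi + 1))
    extra = total - 4 * k
    parts = [4] * k
    while extra > 0:
        i = int(rng.integers(k))
        if parts[i] < 7:
            parts[i] += 1
            extra -= 1
    rng.shuffle(parts)
    return parts


def _context_sequence(rng: np.random.Generator) -> list[str]:
    runs_a = _context_run_lengths(rng)
    runs_b = _context_run_lengths(rng)
    while len(runs_b) != len(runs_a):
        runs_b = _context_run_lengths(rng)
    order = list(CONTEXTS) if rng.random() < 0.5 else list(CONTEXTS[::-1])
    seq: list[str] = []
    for la, lb in zip(runs_a, runs_b):
        seq += [order[0]] * la + [order[1]] * lb
    return seq


def _congruency_of(trial: dict):
    return classify_trial(trial["rel_left"], trial["rel_right"],
                          trial["irr_left"], trial["irr_right"])[2]


def _dim_sequence(rng: np.random.Generator, n_1d: int = 18, n_2d: int = 36,
                  max_run: int = 3) -> list[str]:
    """Random order of n_1d 1D + n_2d 2D labels with runs of at most ``max_run``.

    Sequential sampling with a feasibility guard: a dimensionality is only
    drawn if, after drawing it, the remaining majority count can still be
    interleaved (n_major <= max_run * (n_minor + 1)).
    """
    counts = {"1D": n_1d, "2D": n_2d}
    seq: list[str] = []
    run = (None, 0)
    while counts["1D"] + counts["2D"] > 0:
        options = []
        for d in ("1D", "2D"):
            if counts[d] == 0:
                continue
            if run[0] == d and run[1] >= max_run:
                continue
            rest = {k: v - (k == d) for k, v in counts.items()}
            other = "2D" if d == "1D" else "1D"
            new_run = run[1] + 1 if run[0] == d else 1
            # capacity for more d: finish the current run, then max_run per
            # gap between remaining ``other`` trials; and vice versa
            if rest[d] > (max_run - new_run) + max_run * rest[other]:
                continue
            if rest[other] > max_run * (rest[d] + 1):
                continue
            options.append(d)
        if not options:
            return []  # dead end, caller retries
        weights = np.array([counts[d] for d in options], float)
        d = options[int(rng.choice(len(options), p=weights / weights.sum()))]
        seq.append(d)
        run = (d, run[1] + 1 if run[0] == d else 1)
        counts[d] -= 1
    return seq


def _plan_slots(rng: np.random.Generator, max_tries: int = 200) -> list[tuple[str, str]]:
    """(context, dim) slot sequence satisfying the run-length constraints."""
    for _ in range(max_tries):
        ctx_seq = _context_sequence(rng)
        dims = {}
        ok = True
        for ctx in CONTEXTS:
            s = _dim_sequence(rng)
            if not s:
                ok = False
                break
            dims[ctx] = iter(s)
        if not ok:
            continue
        slots = [(ctx, next(dims[ctx])) for ctx in ctx_seq]
        # overall (context-ignoring) dimensionality runs capped at 5
        runs = [len(list(g)) for _, g in itertools.groupby(d for _, d in slots)]
        if all(r <= 5 for r in runs):
            return slots
    raise DesignGenerationError("could not plan a context/dimensionality slot sequence")


def _fill_block(rng: np.random.Generator, max_restarts: int = 500) -> list[dict]:
    """Sequence one block's trial multiset under all ordering constraints.

    A (context, dimensionality) slot plan is drawn first (context runs 4-7,
    <=3 consecutive same-dim trials within a context, <=5 overall); specific
    trials are then assigned greedily under the remaining constraints:
    target side <=4 consecutive, congruent/incongruent <=3 in a row (1D
    trials break the run), and no repeated target feature (context x EV) on
    consecutive trials.  Dead ends restart the assignment.
    """
    for _ in range(max_restarts):
        slots = _plan_slots(rng)
        pool = _block_trial_pool(rng)
        by_key: dict[tuple[str, str], list[dict]] = {}
        for ctx in CONTEXTS:
            for tr in pool[ctx]:
                by_key.setdefault((ctx, tr["dim"]), []).append(tr)
        seq: list[dict] = []
        side_run = (None, 0)
        cong_run = (None, 0)
        ok = True
        for ctx, dim in slots:
            prev = seq[-1] if seq else None
            candidates = []
            for idx, tr in enumerate(by_key[(ctx, dim)]):
                s = tr["target_side"]
                if side_run[0] == s and side_run[1] >= 4:
                    continue
                cong = _congruency_of(tr)
                if cong is not None and cong_run[0] == cong and cong_run[1] >= 3:
                    continue
                if prev is not None and prev["context"] == ctx:
                    if max(prev["rel_left"], prev["rel_right"]) == max(tr["rel_left"],
                                                                       tr["rel_right"]):
                        continue  # identical target feature
                candidates.append(idx)
            if not candidates:
                ok = False
                break
            pick = by_key[(ctx, dim)].pop(candidates[int(rng.integers(len(candidates)))])
            seq.append(pick)
            s = pick["target_side"]
            side_run = (s, side_run[1] + 1 if side_run[0] == s else 1)
            cong = _congruency_of(pick)
            if cong is None:
                cong_run = (None, 0)
            else:
                cong_run = (cong, cong_run[1] + 1 if cong_run[0] == cong else 1)
        if ok:
            return seq
    raise DesignGenerationError(
        "block sequencing failed: no constraint-satisfying order found "
        f"within {max_restarts} restarts"
    )


def _repeat_fractions(df: pd.DataFrame) -> dict[str, float]:
    """Adjacent-trial EV-repeat fractions, overall and within subsets.

    Pairs never straddle a block boundary.  A subset fraction counts
    adjacent pairs in which *both* trials belong to the subset.
    """
    out = {}
    masks = {
        "overall": np.ones(len(df), bool),
        "congruent": (df["congruency"] == "congruent").to_numpy(),
        "incongruent": (df["congruency"] == "incongruent").to_numpy(),
        "1D": (df["dim"] == "1D").to_numpy(),
    }
    same_block = (df["block"].to_numpy()[1:] == df["block"].to_numpy()[:-1])
    ev = df["EV"].to_numpy()
    rep = (ev[1:] == ev[:-1]) & same_block
    for name, m in masks.items():
        pair = m[1:] & m[:-1] & same_block
        out[name] = float(rep[pair].sum() / pair.sum()) if pair.sum() else 0.0
    return out


def _trials_to_frame(blocks: list[list[dict]]) -> pd.DataFrame:
    rows = []
    idx = 0
    for b, block in enumerate(blocks, start=1):
        last_ctx = None
        switch = 0
        for tr in block:
            ev, ev_back, cong = classify_trial(
                tr["rel_left"], tr["rel_right"], tr["irr_left"], tr["irr_right"]
            )
            switch = 0 if tr["context"] != last_ctx else switch + 1
            last_ctx = tr["context"]
            rows.append(
                dict(trial=idx, block=b, context=tr["context"], dim=tr["dim"],
                     rel_left=tr["rel_left"], rel_right=tr["rel_right"],
                     irr_left=tr["irr_left"], irr_right=tr["irr_right"],
                     target_side=tr["target_side"], switch_distance=switch,
                     EV=ev, EV_back=ev_back, congruency=cong)
            )
            idx += 1
    df = pd.DataFrame(rows)
    df["irr_left"] = df["irr_left"].astype(float)
    df["irr_right"] = df["irr_right"].astype(float)
    df["EV_back"] = df["EV_back"].astype(float)
    return df


@dataclass
class Design:
    """A complete generated design: ordered trials (+timings) and the value mapping."""

    trials: pd.DataFrame
    mapping: ValueMapping
    seed: int
    n_candidates: int = 1000
    timings: pd.DataFrame | None = field(default=None)

    @property
    def n_blocks(self) -> int:
        return int(self.trials["block"].max())


def generate_design(seed: int, n_blocks: int = 4, n_candidates: int = 1000,
                    max_repeat_fraction: float = 0.10) -> Design:
    """Generate a pseudo-randomized design.

    ``n_candidates`` constraint-satisfying candidate designs are generated;
    those whose adjacent target-value repeat fraction exceeds
    ``max_repeat_fraction`` (overall or within the congruent, incongruent or
    1D subsets) are discarded, and one survivor is selected by the seed.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    mapping = make_value_mapping(int(rng.integers(2**31)))
    accepted = []
    for _ in range(n_candidates):
        blocks = [_fill_block(rng) for _ in range(n_blocks)]
        df = _trials_to_frame(blocks)
        fracs = _repeat_fractions(df)
        if all(v <= max_repeat_fraction for v in fracs.values()):
            accepted.append(df)
    if not accepted:
        raise DesignGenerationError(
            f"no candidate of {n_candidates} met the <=10% target-value repeat criterion"
        )
    choice = int(np.random.default_rng(seed + 1).integers(len(accepted)))
    return Design(trials=accepted[choice], mapping=mapping, seed=seed,
                  n_candidates=n_candidates)


def validate_design(trials: pd.DataFrame) -> dict[str, bool]:
    """Independent validator for every sequencing and counting constraint."""
    checks: dict[str, bool] = {}
    per_block = trials.groupby("block")
    checks["counts_1d"] = bool((per_block.apply(
        lambda b: (b["dim"] == "1D").sum(), include_groups=False) == N_1D_PER_BLOCK).all())
    checks["counts_2d"] = bool((per_block.apply(
        lambda b: (b["dim"] == "2D").sum(), include_groups=False) == N_2D_PER_BLOCK).all())
    cell = trials.groupby(["block", "context", "EV", "dim"]).size()
    checks["cell_counts"] = bool(
        (cell.xs("1D", level="dim") == 6).all() and (cell.xs("2D", level="dim") == 12).all()
    )
    checks["value_difference_20"] = bool(
        ((trials["rel_left"] - trials["rel_right"]).abs() == 20).all()
    )
    ok_runs, ok_side, ok_cong, ok_feat = True, True, True, True
    for _, b in per_block:
        ctx = b["context"].to_numpy()
        runs = [len(list(g)) for _, g in itertools.groupby(ctx)]
        ok_runs &= all(4 <= r <= 7 for r in runs)
        side_runs = [len(list(g)) for _, g in itertools.groupby(b["target_side"])]
        ok_side &= all(r <= 4 for r in side_runs)
        cong_runs = [
            (k, len(list(g)))
            for k, g in itertools.groupby(b["congruency"].fillna("break"))
        ]
        ok_cong &= all(r <= 3 for k, r in cong_runs if k != "break")
        feat = list(zip(b["context"], b["EV"]))
        ok_feat &= all(feat[i] != feat[i - 1] for i in range(1, len(feat)))
    checks["context_runs_4_7"] = bool(ok_runs)
    checks["side_max_4"] = bool(ok_side)
    checks["congruency_max_3"] = bool(ok_cong)
    checks["no_feature_repeat"] = bool(ok_feat)
    fracs = _repeat_fractions(trials)
    checks["repeat_fraction_10pct"] = all(v <= 0.10 for v in fracs.values())
    two_d = trials[trials["dim"] == "2D"]
    cong_num = two_d["congruency"].map({"congruent": -1, "incongruent": 1}).astype(float)
    checks["orthogonal"] = bool(
        abs(np.corrcoef(two_d["EV"], two_d["EV_back"].astype(float))[0, 1]) < 1e-12
        and abs(np.corrcoef(two_d["EV"], cong_num)[0, 1]) < 1e-12
        and abs(np.corrcoef(two_d["EV_back"].astype(float), cong_num)[0, 1]) < 1e-12
    )
    return checks


# ---------------------------------------------------------------------------
# timings
# ---------------------------------------------------------------------------


def _truncexpon_scale(mean: float, low: float, high: float) -> float:
    """Scale of an exponential restricted to [low, high] with the given mean."""
    width = high - low

    def trunc_mean(scale):
        return truncexpon(b=width / scale, loc=low, scale=scale).mean() - mean

    return brentq(trunc_mean, 1e-3, 1e3)


def sample_truncated_gaps(n: int, spec: tuple[float, float, float],
                          rng: np.random.Generator) -> np.ndarray:
    mean, low, high = spec
    scale = _truncexpon_scale(mean, low, high)
    return truncexpon(b=(high - low) / scale, loc=low, scale=scale).rvs(n, random_state=rng)


def sample_timings(design: Design, seed: int) -> Design:
    """Fill per-trial event onsets with truncated-exponential jitters.

    Each block's clock starts at zero (blocks are separate scanner runs).
    """
    rng = np.random.default_rng(seed)
    trials = design.trials
    if len(trials) == 0:
        design.timings = pd.DataFrame(
            columns=["trial", "block", "cue_onset", "stim_onset", "outcome_onset"])
        return design
    g1 = sample_truncated_gaps(len(trials), GAP_CUE_STIM, rng)
    g2 = sample_truncated_gaps(len(trials), GAP_STIM_OUTCOME, rng)
    g3 = sample_truncated_gaps(len(trials), GAP_OUTCOME_CUE, rng)
    rows = []
    for b, block in trials.groupby("block"):
        t = 0.0
        for pos, (i, _) in enumerate(block.iterrows()):
            cue = t
            stim = cue + CUE_DURATION + g1[i]
            outcome = stim + STIM_DURATION + g2[i]
            t = outcome + OUTCOME_DURATION + g3[i]
            rows.append(dict(trial=int(trials.loc[i, "trial"]), block=b, cue_onset=cue,
                             stim_onset=stim, outcome_onset=outcome))
    design.timings = pd.DataFrame(rows)
    return design


# ---------------------------------------------------------------------------
# trial-wise estimability (VIF)
# ---------------------------------------------------------------------------


def _hrf_kernel(dt: float) -> np.ndarray:
    from nilearn.glm.first_level.hemodynamic_models import glover_hrf

    # glover_hrf samples at tr/oversampling resolution
    return glover_hrf(1.0, oversampling=round(1.0 / dt), time_length=32.0)


def check_estimability(design: Design, tr: float = 1.25, dt: float = 0.05) -> pd.DataFrame:
    """VIF per trial-wise regressor of the HRF-convolved design matrix.

    One boxcar regressor per stimulus (duration 1.6 s), two cue regressors
    split by context and three outcome regressors split by EV, all convolved
    with a canonical double-gamma HRF and sampled at the TR.  VIFs are the
    diagonal of the inverse correlation matrix; a singular design yields
    infinite VIFs rather than an exception.
    """
    if design.timings is None:
        raise ValueError("timings must be sampled before the estimability check")
    trials = design.trials
    timings = design.timings.set_index("trial")
    n_trials = len(trials)
    col_names = (
        [f"stim_{i:03d}" for i in range(n_trials)]
        + [f"cue_{c}" for c in CONTEXTS]
        + [f"outcome_{ev}" for ev in EV_LEVELS]
    )
    kernel = _hrf_kernel(dt)

    # lay blocks out on one fine-grained timeline with a gap between runs
    block_gap = 20.0
    block_dur = {}
    offset = {}
    t0 = 0.0
    for b, tb in timings.groupby("block"):
        dur = float(tb["outcome_onset"].max()) + OUTCOME_DURATION + 10.0
        offset[b] = t0
        block_dur[b] = dur
        t0 += dur + block_gap
    n_fine = int(np.ceil(t0 / dt)) + len(kernel)
    X_fine = np.zeros((n_fine, len(col_names)))

    def add_box(col, onset, duration):
        a = int(round(onset / dt))
        b = int(round((onset + duration) / dt))
        X_fine[a:b, col] += 1.0

    for i, row in trials.iterrows():
        t = timings.loc[row["trial"]]
        off = offset[row["block"]]
        add_box(i, off + t["stim_onset"], STIM_DURATION)
        add_box(n_trials + CONTEXTS.index(row["context"]), off + t["cue_onset"], CUE_DURATION)
        add_box(n_trials + 2 + EV_LEVELS.index(row["EV"]), off + t["outcome_onset"],
                OUTCOME_DURATION)

    from scipy.signal import fftconvolve

    X_conv = fftconvolve(X_fine, kernel[:, None], axes=0)[: n_fine]
    stride = int(round(tr / dt))
    X = X_conv[::stride]
    X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    nonzero = norms > 0
    vif = np.full(len(col_names), np.nan)  # empty regressors have no VIF
    Xn = X[:, nonzero] / norms[nonzero]
    R = Xn.T @ Xn
    try:
        vif[nonzero] = np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        vif[nonzero] = np.inf
    kind = ["stimulus"] * n_trials + ["cue"] * 2 + ["outcome"] * 3
    return pd.DataFrame({"regressor": col_names, "kind": kind, "vif": vif})


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_design(design: Design, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = design.trials
    if design.timings is not None:
        table = table.merge(design.timings.drop(columns="block"), on="trial")
    table.to_csv(out / "design.csv", index=False)
    (out / "mapping.json").write_text(design.mapping.to_json())
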