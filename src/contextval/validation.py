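"""Calibration and recovery suites for the full analysis chain.

Two kinds of end-to-end checks:

* *Null calibration*: with every effect of interest set to zero in the
  generative models, each likelihood-ratio test in the RT ladder, the
  accuracy ladder, the RDM models and the linking models should reject at
  its nominal 5% rate.  Empirical rejection rates are estimated over many
  seeded replicates at reduced problem sizes.

* *Recovery*: with the competition/moderation mechanism planted
  (``NeuralParams.paper_like``), each replicate should reproduce the
  qualitative sign checklist: negative EV_back effect on P_EV,
  corr(P_EV, P_EVback) more negative than corr(P_EV, P_other), positive
  P_context x P_EVback_2D interaction, and a positive behavioral
  Congruency x EV_back interaction on log RT.

A fixed design is shared across replicates within a suite: the task design
is a deterministic study condition, not a random quantity under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior as B
from . import decoding as C
from . import design as D
from . import linking as L
from . import neuralsim as N
from . import rsa as R


def _calibration_design(seed: int, n_blocks: int) -> D.Design:
    return D.generate_design(seed, n_blocks=n_blocks, n_candidates=20)


def behavior_calibration(seed: int, n_reps: int = 200, n_subjects: int = 12,
                         n_blocks: int = 2) -> dict[str, float]:
    """Type-I error of every LR test in the RT and accuracy ladders.

    Two blocks per replicate keep the binomial ladder's error events per
    parameter high enough for the LR chi-square asymptotics (near-ceiling
    accuracy means error events, not trials, are the effective sample).
    """
    design = _calibration_design(101, n_blocks)
    root = np.random.default_rng(seed)
    hits: dict[str, int] = {}
    for _ in range(n_reps):
        rec = B.simulate_behavior(design.trials, B.BehaviorParams.null(),
                                  n_subjects, int(root.integers(2**31)))
        rt = B.fit_rt_ladder(rec)
        acc = B.fit_accuracy_ladder(rec)
        for tab, tag in ((rt, "rt"), (acc, "acc")):
            for _, row in tab.iterrows():
                if np.isnan(row["lr_chi2"]) or not row["model"].startswith("+"):
                    continue
                key = f"{tag}:{row['model']}"
                hits[key] = hits.get(key, 0) + (row["p"] < 0.05)
    return {k: v / n_reps for k, v in hits.items()}


def rdm_calibration(seed: int, n_reps: int = 200, n_subjects: int = 6,
                    n_voxels: int = 60, n_blocks: int = 2) -> dict[str, float]:
    """Type-I error of the four RDM LR tests under pure-noise patterns."""
    design = _calibration_design(102, n_blocks)
    root = np.random.default_rng(seed)
    hits: dict[str, int] = {}
    for _ in range(n_reps):
        beh = B.simulate_behavior(design.trials, B.BehaviorParams.null(),
                                  n_subjects, int(root.integers(2**31)))
        runs = N.simulate_subject_patterns(
            design.trials, beh, N.NeuralParams.null(n_voxels=n_voxels),
            int(root.integers(2**31)))
        tab = R.fit_rdm_models(R.subject_rdm_cells(runs))
        for _, row in tab.iterrows():
            hits[row["model"]] = hits.get(row["model"], 0) + (row["p"] < 0.05)
    return {k: v / n_reps for k, v in hits.items()}


def _decode_all(pattern_runs, rng):
    val = {k: C.loro_decode(r, "value", seed=int(rng.integers(2**31)))
           for k, r in pattern_runs.items()}
    ctx = {k: C.loro_decode(r, "context", seed=int(rng.integers(2**31)))
           for k, r in pattern_runs.items()}
    evb = {k: C.ovr_evback_decode(r, seed=int(rng.integers(2**31)))
           for k, r in pattern_runs.items()}
    return val, ctx, evb


def linking_calibration(seed: int, n_reps: int = 200, n_subjects: int = 4,
                        n_voxels: int = 40, n_blocks: int = 2) -> dict[str, float]:
    """Type-I error of the linking LR tests on decoded null patterns.

    Patterns carry no signal, so the decoded probabilities are exchangeable
    noise; every LR test on them should reject at the nominal rate.  The
    null behavior runs near-perfect accuracy so every balancing cell stays
    populated in the two-fold training sets (the accuracy level is
    irrelevant to the statistics under calibration); a replicate that still
    hits an empty cell is redrawn.
    """
    design = _calibration_design(103, n_blocks)
    root = np.random.default_rng(seed)
    hits: dict[str, int] = {}
    n_done = 0
    tested = [
        ("pev", "+EV_back"), ("pev", "+logit(P_context)"),
        ("pev_full", "+logit(P_context)"), ("pev_full", "+P_EVback_2D"),
        ("pev_full", "+P_context:P_EVback_2D"),
        ("vsim", "+|EV-class|"), ("vsim", "+|EV-class|:EV_back"),
    ]
    params = B.BehaviorParams.null()
    params.acc_beta0 = 4.5  # near-ceiling accuracy keeps training cells full
    while n_done < n_reps:
        beh = B.simulate_behavior(design.trials, params, n_subjects,
                                  int(root.integers(2**31)))
        runs = N.simulate_subject_patterns(
            design.trials, beh, N.NeuralParams.null(n_voxels=n_voxels),
            int(root.integers(2**31)))
        rng = np.random.default_rng(int(root.integers(2**31)))
        try:
            val, ctx, evb = _decode_all(runs, rng)
        except ValueError:
            continue  # empty balancing cell in this draw
        recs = L.build_link_records(val, ctx, evb, behavior=beh)
        tabs = {
            "pev": L.fit_pev_models(recs),
            "pev_full": L.fit_pev_full(recs),
            "vsim": L.fit_value_similarity(
                recs[(recs["dim"] == "2D") & (recs["accuracy"] == 1)]),
        }
        for tag, model in tested:
            tab = tabs[tag]
            row = tab[tab["model"] == model]
            if len(row) and not np.isnan(row["p"].iloc[0]):
                key = f"{tag}:{model}"
                hits[key] = hits.get(key, 0) + (row["p"].iloc[0] < 0.05)
        n_done += 1
    return {k: v / n_reps for k, v in hits.items()}


def recovery_rates(seed: int, n_reps: int = 50, n_subjects: int = 12,
                   n_voxels: int = 150) -> dict:
    """Fraction of replicates reproducing the qualitative sign checklist."""
    design = _calibration_design(104, 4)
    root = np.random.default_rng(seed)
    checks = []
    for _ in range(n_reps):
        beh = B.simulate_behavior(design.trials, B.BehaviorParams(),
                                  n_subjects, int(root.integers(2**31)))
        runs = N.simulate_subject_patterns(
            design.trials, beh, N.NeuralParams.paper_like(n_voxels=n_voxels),
            int(root.integers(2**31)))
        rng = np.random.default_rng(int(root.integers(2**31)))
        val, ctx, evb = _decode_all(runs, rng)
        recs = L.build_link_records(val, ctx, evb, behavior=beh)
        pev = L.fit_pev_models(recs)
        pev_full = L.fit_pev_full(recs)
        _, comp = L.competition_correlation(recs)
        rt = B.fit_rt_ladder(beh)
        checks.append(dict(
            evback_on_pev_negative=float(
                pev.loc[pev["model"] == "+EV_back", "estimate"].iloc[0]) < 0,
            corr_evback_more_negative=float(comp["mean_z_evback"].iloc[0])
            < float(comp["mean_z_other"].iloc[0]),
            moderation_positive=float(
                pev_full.loc[pev_full["model"] == "+P_context:P_EVback_2D",
                             "estimate"].iloc[0]) > 0,
            behavior_cong_evback_positive=float(
                rt.loc[rt["model"] == "+Congruency:EV_back",
                       "estimate"].iloc[0]) > 0,
        ))
    df = pd.DataFrame(checks)
    out = {k: float(v) for k, v in df.mean().items()}
    out["all_checks"] = float(df.all(axis=1).mean())
    out["n_reps"] = n_reps
    return out
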