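"""End-to-end orchestration: design -> behavior -> patterns -> RSA/decoding -> linking.

Stages run in dependency order with per-stage sub-seeds spawned
deterministically from a master seed; every intermediate table can be
written to an output directory and a consolidated ``report.json`` summarizes
the effect tables and validation checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as B
from . import decoding as C
from . import design as D
from . import linking as L
from . import neuralsim as N
from . import rsa as R

log = logging.getLogger("contextval")


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 12
    n_blocks: int = 4
    n_candidates: int = 50
    n_voxels: int = 150
    normalization: str = "diagonal"
    check_vif: bool = False
    behavior_params: dict = field(default_factory=dict)
    neural_params: dict = field(default_factory=dict)
    neural_preset: str = "paper_like"   # paper_like | null | custom
    out_dir: str | None = None

    def make_behavior_params(self) -> B.BehaviorParams:
        if self.neural_preset == "null":
            base = B.BehaviorParams.null().to_dict()
        else:
            base = B.BehaviorParams().to_dict()
        base.update(self.behavior_params)
        return B.BehaviorParams(**base)

    def make_neural_params(self) -> N.NeuralParams:
        preset = {"paper_like": N.NeuralParams.paper_like,
                  "null": N.NeuralParams.null,
                  "custom": N.NeuralParams}[self.neural_preset]
        return preset(n_voxels=self.n_voxels, **self.neural_params)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _subseeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(master).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (and writes it if out_dir)."""
    s_design, s_timing, s_beh, s_pat, s_dec = _subseeds(config.seed, 5)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}

    log.info("stage design: seed=%d", s_design)
    design = D.generate_design(s_design, n_blocks=config.n_blocks,
                               n_candidates=config.n_candidates)
    design = D.sample_timings(design, s_timing)
    report["design_checks"] = D.validate_design(design.trials)
    if out:
        D.write_design(design, out)
    if config.check_vif:
        vif = D.check_estimability(design)
        stim = vif[vif["kind"] == "stimulus"]["vif"]
        report["vif"] = {"max": float(stim.max()), "mean": float(stim.mean())}
        if out:
            vif.to_csv(out / "vif.csv", index=False)

    log.info("stage behavior")
    bparams = config.make_behavior_params()
    records = B.simulate_behavior(design.trials, bparams, config.n_subjects, s_beh)
    rt_tab = B.fit_rt_ladder(records)
    acc_tab = B.fit_accuracy_ladder(records)
    contrasts = B.congruency_contrasts(records)
    if out:
        records.to_csv(out / "behavior.csv", index=False)
        rt_tab.to_csv(out / "rt_ladder.csv", index=False)
        acc_tab.to_csv(out / "acc_ladder.csv", index=False)
        contrasts.to_csv(out / "contrasts.csv", index=False)

    log.info("stage patterns")
    nparams = config.make_neural_params()
    pattern_runs = N.simulate_subject_patterns(design.trials, records, nparams, s_pat)

    log.info("stage rsa")
    cells = R.subject_rdm_cells(pattern_runs, mode=config.normalization)
    rdm_tab = R.fit_rdm_models(cells)
    if out:
        cells.to_csv(out / "rdm_cells.csv", index=False)
        rdm_tab.to_csv(out / "rdm_effects.csv", index=False)

    log.info("stage decoding")
    rng = np.random.default_rng(s_dec)
    val, ctx, evb = {}, {}, {}
    for k, runs in pattern_runs.items():
        val[k] = C.loro_decode(runs, "value", seed=int(rng.integers(2**31)))
        ctx[k] = C.loro_decode(runs, "context", seed=int(rng.integers(2**31)))
        evb[k] = C.ovr_evback_decode(runs, seed=int(rng.integers(2**31)))
    bal_val = pd.concat([C.balanced_accuracy(v, "EV", "p_").assign(subject=k)
                         for k, v in val.items()])
    bal_ctx = pd.concat([C.balanced_accuracy(c, "context", "p_").assign(subject=k)
                         for k, c in ctx.items()])
    report["balanced_accuracy"] = {
        "value": float(bal_val["balanced_accuracy"].mean()),
        "context": float(bal_ctx["balanced_accuracy"].mean()),
    }
    if out:
        pd.concat([v.assign(subject=k) for k, v in val.items()]).to_csv(
            out / "probs_value.csv", index=False)
        pd.concat([c.assign(subject=k) for k, c in ctx.items()]).to_csv(
            out / "probs_context.csv", index=False)
        pd.concat([e.assign(subject=k) for k, e in evb.items()]).to_csv(
            out / "probs_evback.csv", index=False)
        pd.concat([bal_val, bal_ctx], keys=["value", "context"]).to_csv(
            out / "balanced_accuracy.csv")
        agg = pd.concat([
            C.aggregate_combinations(v[v["accuracy"] == 1]).assign(subject=k)
            for k, v in val.items()])
        agg.to_csv(out / "probs_aggregated.csv", index=False)

    log.info("stage linking")
    recs = L.build_link_records(val, ctx, evb, behavior=records)
    pev = L.fit_pev_models(recs)
    pev_full = L.fit_pev_full(recs)
    per_subj, comp = L.competition_correlation(recs)
    effects = L.compute_subject_effects(recs)
    if out:
        recs.to_csv(out / "link_records.csv", index=False)
        pev.to_csv(out / "link_effects.csv", index=False)
        effects.to_csv(out / "subject_effects.csv", index=False)
        if len(effects) >= 10:
            L.subject_correlations(effects).to_csv(
                out / "subject_correlations.csv", index=False)

    report["sign_checklist"] = sign_checklist(rt_tab, pev, pev_full, comp)
    report["effect_tables"] = {
        "rt_ladder": rt_tab.to_dict("records"),
        "acc_ladder": acc_tab.to_dict("records"),
        "rdm": rdm_tab.to_dict("records"),
        "pev": pev.to_dict("records"),
        "pev_full": pev_full.to_dict("records"),
        "competition": comp.to_dict("records"),
    }
    if out:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def sign_checklist(rt_tab: pd.DataFrame, pev: pd.DataFrame, pev_full: pd.DataFrame,
                   comp: pd.DataFrame) -> dict:
    """Qualitative sign pattern of the competition/moderation mechanism.

    negative EV_back effect on P_EV; corr(P_EV, P_EVback) more negative than
    corr(P_EV, P_other); positive P_context x P_EVback_2D interaction;
    positive behavioral Congruency x EV_back interaction on log RT.
    """
    def est(tab, model):
        return float(tab.loc[tab["model"] == model, "estimate"].iloc[0])

    return {
        "evback_on_pev_negative": est(pev, "+EV_back") < 0,
        "corr_evback_more_negative":
            float(comp["mean_z_evback"].iloc[0]) < float(comp["mean_z_other"].iloc[0]),
        "moderation_positive": est(pev_full, "+P_context:P_EVback_2D") > 0,
        "behavior_cong_evback_positive": est(rt_tab, "+Congruency:EV_back") > 0,
    }


def validate_outputs(directory: str | Path) -> pd.DataFrame:
    """Re-verify design invariants and file schemas of a completed run."""
    d = Path(directory)
    checks = []

    def add(name, ok, note=""):
        checks.append(dict(check=name, passed=bool(ok), note=note))

    required = ["design.csv", "mapping.json", "behavior.csv", "report.json"]
    for f in required:
        add(f"file:{f}", (d / f).exists())
    if (d / "design.csv").exists():
        trials = pd.read_csv(d / "design.csv")
        for name, ok in D.validate_design(trials).items():
            add(f"design:{name}", ok)
        if {"cue_onset", "stim_onset"}.issubset(trials.columns):
            add("timing:order", bool((trials["stim_onset"] > trials["cue_onset"]).all()))
    if (d / "behavior.csv").exists():
        beh = pd.read_csv(d / "behavior.csv")
        add("behavior:rt_positive", bool((beh["rt"] > 0).all()))
        add("behavior:accuracy_binary", set(beh["accuracy"].unique()) <= {0, 1})
    return pd.DataFrame(checks)
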