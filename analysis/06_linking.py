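"""Link decoded probabilities to task variables and behavior.

Full pipeline on 12 synthetic subjects with planted competition and
moderation; reports the P_EV models, competition correlations, behavior
links and between-subject coupling, plus the qualitative sign checklist.
"""

import json
from pathlib import Path

import numpy as np

from contextval import behavior as B
from contextval import decoding as C
from contextval import design as D
from contextval import linking as L
from contextval import neuralsim as N
from contextval.pipeline import sign_checklist

OUT = Path(__file__).resolve().parents[1] / "results" / "linking"
SEED = 2024


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    design = D.generate_design(SEED, n_blocks=4, n_candidates=50)
    records = B.simulate_behavior(design.trials, B.BehaviorParams(),
                                  n_subjects=12, seed=SEED + 2)
    runs = N.simulate_subject_patterns(design.trials, records,
                                       N.NeuralParams.paper_like(), SEED + 3)
    rng = np.random.default_rng(SEED + 4)
    val = {k: C.loro_decode(r, "value", seed=int(rng.integers(2**31)))
           for k, r in runs.items()}
    ctx = {k: C.loro_decode(r, "context", seed=int(rng.integers(2**31)))
           for k, r in runs.items()}
    evb = {k: C.ovr_evback_decode(r, seed=int(rng.integers(2**31)))
           for k, r in runs.items()}
    recs = L.build_link_records(val, ctx, evb, behavior=records)

    pev = L.fit_pev_models(recs)
    pev.to_csv(OUT / "link_effects.csv", index=False)
    print("P_EV competition ladder:")
    print(pev[["model", "estimate", "lr_chi2", "p", "aic"]].to_string(index=False))

    pev_full = L.fit_pev_full(recs)
    print("\nmoderation model (nested intercepts):")
    print(pev_full[["model", "estimate", "lr_chi2", "p"]].to_string(index=False))

    per_subj, comp = L.competition_correlation(recs)
    per_subj.to_csv(OUT / "competition_per_subject.csv", index=False)
    print("\ncompetition correlations:")
    print(comp.round(3).to_string(index=False))

    links = L.fit_behavior_links(recs)
    links.to_csv(OUT / "behavior_links.csv", index=False)

    effects = L.compute_subject_effects(recs)
    effects.to_csv(OUT / "subject_effects.csv", index=False)
    corr = L.subject_correlations(effects)
    corr.to_csv(OUT / "subject_correlations.csv", index=False)
    print("\nbetween-subject coupling:")
    print(corr.to_string(index=False))

    rt = B.fit_rt_ladder(records)
    checklist = sign_checklist(rt, pev, pev_full, comp)
    (OUT / "sign_checklist.json").write_text(json.dumps(checklist, indent=2))
    print("\nsign checklist:", checklist)


if __name__ == "__main__":
    main()
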