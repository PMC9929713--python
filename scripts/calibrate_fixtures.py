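"""Regenerate the canonical mood fixture files from their frozen parameters.

The four archetypes are defined by a small set of interpretable knobs
(baseline signal probabilities, environment persistence, per-channel
amplification gain and attenuation factor, preference prior, discount).
The numeric values below were chosen by a coarse grid/random search over
those knobs (see docs/methods.md, "Calibration") so that the solved models
reproduce the canonical structural results:

* healthy  — exactly six belief nodes at the default solver settings
             (k = 20 grid, merge tolerance 0.02, uniform start belief),
             amplification of belief-consistent signals at the certain
             nodes and attenuation of belief-inconsistent signals at the
             uncertain nodes, and no one-sided absorbing component;
* depression — a terminal high-stress loop (every node above p = 0.5)
             whose nodes all attenuate pleasure signals, with the stress
             expectation high in every state under every action;
* mania    — the exact mirror image of depression;
* anxiety  — every likelihood row strictly flatter than its healthy
             counterpart, and a single intermediate-belief terminal node
             closed under both observations, reached while amplifying
             belief-consistent signals;
* orderings — mean stress probability depression > anxiety > healthy >
             mania, and value at the uniform belief healthy > depression =
             mania > anxiety.

Run from the repository root:

    python scripts/calibrate_fixtures.py [--check]

Without ``--check`` the fixture YAML files under src/moodpomdp/fixtures/
are rewritten; with ``--check`` the structural properties above are
re-verified against the shipped files and a non-zero exit signals drift.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np
import yaml

from moodpomdp.graph import absorbing_components, build_policy_graph
from moodpomdp.model import model_to_dict
from moodpomdp.moods import (
    build_mood_parameterization,
    mirror_model,
    row_entropies,
)
from moodpomdp.sim import graph_stationary_occupancy
from moodpomdp.solve import extract_policy, solve_grid

FIXTURE_VERSION = 1

#: frozen calibration outcome — the canonical numeric values of the study
FROZEN = {
    "healthy": dict(
        stress_signal_given_stressful=0.8,
        stress_signal_given_not_stressful=0.2,
        stay_stressful=0.88,
        stay_not_stressful=0.88,
        amplify_gain=10.0,
        attenuate_factor=0.2,
    ),
    "depression": dict(
        stress_signal_given_stressful=0.84,
        stress_signal_given_not_stressful=0.72,
        stay_stressful=0.95,
        stay_not_stressful=0.6,
        amplify_gain=(1.2, 1.5),
        attenuate_factor=(0.9, 0.55),
    ),
    "anxiety": dict(
        stress_signal_given_stressful=0.535,
        stress_signal_given_not_stressful=0.505,
        stay_stressful=0.83,
        stay_not_stressful=0.72,
        amplify_gain=2.0,
        attenuate_factor=0.85,
    ),
}
PREFERENCE_PLEASURE = 0.51
DISCOUNT = 0.95


def build_models():
    models = {
        name: build_mood_parameterization(
            name,
            preference_pleasure=PREFERENCE_PLEASURE,
            discount=DISCOUNT,
            **knobs,
        ).to_model()
        for name, knobs in FROZEN.items()
    }
    models["mania"] = mirror_model(models["depression"])
    return models


def verify(models) -> list[str]:
    """Re-check every structural calibration target; returns failures."""
    failures: list[str] = []

    def check(cond: bool, msg: str) -> None:
        if not cond:
            failures.append(msg)

    solved = {}
    for name, m in models.items():
        V = solve_grid(m, resolution=20)
        pol = extract_policy(m, V)
        g = build_policy_graph(m, pol)
        solved[name] = (m, V, g)

    mh, Vh, gh = solved["healthy"]
    check(gh.n_nodes == 6, f"healthy graph has {gh.n_nodes} nodes, expected 6")
    for n in gh.nodes:
        if n.p_stress >= 0.7:
            check(n.action == "amplify_stress", f"healthy node {n.p_stress:.2f} not AmSS")
        elif n.p_stress <= 0.3:
            check(n.action == "amplify_pleasure", f"healthy node {n.p_stress:.2f} not AmPS")
        elif n.p_stress >= 0.5:
            check(n.action == "attenuate_pleasure" or n.p_stress == 0.5,
                  f"healthy node {n.p_stress:.2f} not AtPS")
        else:
            check(n.action == "attenuate_stress", f"healthy node {n.p_stress:.2f} not AtSS")
    for t in absorbing_components(gh):
        ps = [n.p_stress for n in gh.nodes if n.id in t]
        check(max(ps) >= 0.7 and min(ps) <= 0.3, "healthy has a one-sided trap")

    md, Vd, gd = solved["depression"]
    ps = {n.id: n.p_stress for n in gd.nodes}
    act = {n.id: n.action for n in gd.nodes}
    traps = [t for t in absorbing_components(gd) if all(ps[i] > 0.5 for i in t)]
    check(bool(traps), "depression lacks a high-stress terminal component")
    if traps:
        check(all(act[i] == "attenuate_pleasure" for i in traps[0]),
              "depression trap does not attenuate pleasure")
    check(md.likelihood[:, :, 0].min() > mh.likelihood[mh.action_index("wait"),
                                                       mh.state_index("not_stressful"),
                                                       mh.observation_index("stress_signal")],
          "depression stress expectation not high under every action")

    mx, Vx, gx = solved["anxiety"]
    check(bool(np.all(row_entropies(mx) > row_entropies(mh))),
          "anxiety rows not uniformly flatter than healthy")
    psx = {n.id: n.p_stress for n in gx.nodes}
    one = [t for t in absorbing_components(gx) if len(t) == 1 and 0.35 < psx[min(t)] < 0.65]
    check(bool(one), "anxiety lacks an intermediate single-node trap")

    means = {k: graph_stationary_occupancy(g).p_stress_mean(g) for k, (_, _, g) in solved.items()}
    vals = {k: V.value(g.b0) for k, (_, V, g) in solved.items()}
    check(means["depression"] > means["anxiety"] > means["healthy"] > means["mania"],
          f"mean stress ordering violated: {means}")
    check(vals["healthy"] == max(vals.values()), f"healthy reward not highest: {vals}")
    check(vals["depression"] > vals["anxiety"] and vals["mania"] > vals["anxiety"],
          f"depression/mania reward not above anxiety: {vals}")
    return failures


def fixture_doc(name: str, model) -> dict:
    doc = model_to_dict(model)
    meta: dict = {"version": FIXTURE_VERSION,
                  "preference_pleasure": PREFERENCE_PLEASURE}
    if name == "mania":
        meta["mirror_of"] = "depression"
    else:
        meta["builder"] = {k: list(v) if isinstance(v, tuple) else v
                           for k, v in FROZEN[name].items()}
    doc["metadata"] = meta
    return doc


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--check", action="store_true",
                        help="verify shipped fixtures instead of rewriting them")
    parser.add_argument("--out", default="src/moodpomdp/fixtures",
                        help="fixture directory")
    args = parser.parse_args()

    models = build_models()
    failures = verify(models)
    for msg in failures:
        print(f"FAIL: {msg}", file=sys.stderr)

    out = Path(args.out)
    if args.check:
        from moodpomdp.moods import load_fixture

        for name, model in models.items():
            shipped = load_fixture(name)
            same = (
                np.allclose(shipped.transition, model.transition, atol=1e-15)
                and np.allclose(shipped.likelihood, model.likelihood, atol=1e-15)
                and np.allclose(shipped.reward, model.reward, atol=1e-12)
            )
            if not same:
                failures.append(f"shipped fixture {name} drifted from frozen parameters")
                print(f"FAIL: fixture {name} drifted", file=sys.stderr)
    else:
        out.mkdir(parents=True, exist_ok=True)
        for name, model in models.items():
            path = out / f"{name}.yaml"
            with open(path, "w") as fh:
                yaml.safe_dump(fixture_doc(name, model), fh, sort_keys=False)
            print(f"wrote {path}")
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
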