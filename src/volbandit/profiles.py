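"""Seeded end-to-end runs of the experiment pipelines.

A profile bundles the task design (which experiment), the population used
to simulate agents, the models to fit and the sampler settings.  ``exp1``,
``exp2`` and ``exp3`` mirror the three experiments at full scale; ``ci_small``
is a minutes-scale reduction of the exp1 pipeline for smoke runs.  One
master seed is split into per-stage child seeds through
``numpy.random.SeedSequence.spawn`` so that any stage can be re-run
reproducibly.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .behavior import block_reward_contrast, lose_switch_rates, participant_summary
from .comparison import compare_models, compute_elpd_loo
from .hierarchy import build_model, sample_posterior
from .io import file_checksum, write_posterior, write_trials
from .models import ALL_MODELS, model_from_key, simulate_choices
from .studies import (
    posterior_predictive_check,
    recovery_population,
    relabel_population,
    sample_population,
)
from .task import experiment_phases, generate_participants, learning_phase

STAGES = ("simulate", "fit", "compare", "behavior", "ppc")
_STAGE_DEPS = {
    "fit": ("simulate",),
    "compare": ("fit",),
    "behavior": ("simulate",),
    "ppc": ("fit",),
}

PROFILES: dict[str, dict] = {
    "exp1": {
        "experiment": "exp1",
        "n_participants": 36,
        "models": [m.key for m in ALL_MODELS],
        "fit_kwargs": {"n_chains": 4, "n_iter": 4000, "n_burn_in": 1000},
    },
    "exp2": {
        "experiment": "exp2",
        "n_participants": 51,
        "models": [m.key for m in ALL_MODELS],
        "fit_kwargs": {"n_chains": 4, "n_iter": 4000, "n_burn_in": 1000},
    },
    "exp3": {
        "experiment": "exp3",
        "n_participants": 129,
        "models": [m.key for m in ALL_MODELS],
        "fit_kwargs": {"n_chains": 4, "n_iter": 4000, "n_burn_in": 1000},
    },
    "ci_small": {
        "experiment": "ci_small",
        "n_participants": 8,
        "models": ["env_dual", "shared_single"],
        "fit_kwargs": {"n_chains": 2, "n_iter": 500, "n_burn_in": 200},
    },
}


def profile_phases(name: str):
    if name == "ci_small":
        return [learning_phase(2, 60, stable_p=0.75)]
    return experiment_phases(name)


@dataclass
class RunManifest:
    profile: str
    seed: int
    stages: list[str]
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def run_experiment_profile(
    profile: str,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
    seed: int = 0,
) -> RunManifest:
    """Execute simulate -> fit -> compare (-> behavior, ppc) for a profile."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {list(PROFILES)}")
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}")
        for dep in _STAGE_DEPS.get(st, ()):
            if dep not in stages:
                raise ValueError(f"stage {st!r} requires stage {dep!r}")
    cfg = PROFILES[profile]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(profile=profile, seed=seed, stages=list(stages), config=cfg)
    master = np.random.SeedSequence(seed)
    sim_seed, fit_seed, ppc_seed = master.spawn(3)

    def stamp(stage):
        manifest.timestamps[stage] = datetime.datetime.now().isoformat()

    def register(stage, path):
        manifest.outputs.setdefault(stage, {})[path.name] = file_checksum(path)

    data = None
    gen_model = model_from_key("env_dual")
    if "simulate" in stages:
        rng = np.random.default_rng(sim_seed)
        phases = profile_phases(profile)
        frames = []
        means, sds = recovery_population(gen_model)
        population = sample_population(gen_model, means, sds, cfg["n_participants"], rng)
        for phase in phases:
            d = generate_participants(phase, cfg["n_participants"], rng)
            # later phases reuse the same simulated individuals
            pop = relabel_population(population, d["environment"].unique())
            d = simulate_choices(d, gen_model, pop, rng)
            frames.append(d)
        import pandas as pd

        data = pd.concat(frames, ignore_index=True)
        path = outdir / "trials.csv"
        write_trials(data, path)
        register("simulate", path)
        stamp("simulate")

    posts = {}
    if "fit" in stages:
        learn = data[data["phase"] == "learning"]
        for key, fs in zip(cfg["models"], fit_seed.spawn(len(cfg["models"]))):
            model = build_model(learn, model_from_key(key))
            post = sample_posterior(
                model, seed=int(fs.generate_state(1)[0] % 2**31), **cfg["fit_kwargs"]
            )
            posts[key] = post
            csv_path = outdir / f"posterior_{key}.csv"
            json_path = outdir / f"diagnostics_{key}.json"
            write_posterior(post, csv_path, json_path)
            register("fit", csv_path)
            register("fit", json_path)
        stamp("fit")

    if "compare" in stages:
        results = {k: compute_elpd_loo(p.pointwise_loglik()) for k, p in posts.items()}
        table = compare_models(results)
        path = outdir / "comparison.csv"
        table.to_csv(path, index=False)
        register("compare", path)
        stamp("compare")

    if "behavior" in stages:
        learn = data[data["phase"] == "learning"]
        summary = participant_summary(data)
        ls = lose_switch_rates(learn)
        out = {
            "lose_switch_test": ls["test"].as_dict() if ls["test"] else None,
            "block_reward_contrast": None,
        }
        if learn["block"].nunique() >= 2:
            brc = block_reward_contrast(learn)
            out["block_reward_contrast"] = (
                brc["test"].as_dict() if brc["test"] else None
            )
        spath = outdir / "participants.csv"
        summary.to_csv(spath, index=False)
        jpath = outdir / "behavior_tests.json"
        with open(jpath, "w") as fh:
            json.dump(out, fh, indent=2)
        register("behavior", spath)
        register("behavior", jpath)
        stamp("behavior")

    if "ppc" in stages:
        key = cfg["models"][0]
        learn = data[data["phase"] == "learning"]
        ppc = posterior_predictive_check(
            posts[key], learn, max_draws=500,
            seed=int(ppc_seed.generate_state(1)[0] % 2**31),
        )
        path = outdir / "ppc.json"
        with open(path, "w") as fh:
            json.dump(
                {
                    "model": key,
                    "correlation": ppc["correlation"],
                },
                fh,
                indent=2,
            )
        register("ppc", path)
        stamp("ppc")

    manifest.save(outdir / "manifest.json")
    return manifest
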