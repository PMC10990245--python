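"""Simulation studies: reward-rate grids, model recovery, parameter
recovery, and posterior predictive checks.

These studies close the loop around the fitting machinery: the reward-rate
grids establish that the stable and volatile casinos genuinely reward
different learning rates; model recovery verifies that the six-way model
comparison identifies the generating model; parameter recovery verifies that
individual parameters are estimable from the experimental design; and the
posterior predictive check compares observed with model-simulated reward
rates per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter

from . import _kernels
from .comparison import compare_models, compute_elpd_loo
from .hierarchy import PosteriorDraws, build_model, sample_posterior
from .models import (
    ALL_MODELS,
    PARAM_BOUNDS,
    ModelSpec,
    ParameterSet,
    simulate_choices,
)
from .task import CasinoConfig, PhaseConfig, _casino_schedule, generate_participants

# ---------------------------------------------------------------------------
# Reward-rate grids
# ---------------------------------------------------------------------------


@dataclass
class RewardRateGrid:
    """Mean reward rate per parameter-grid cell in one environment."""

    environment: str
    axes: dict[str, np.ndarray]         # 1 or 2 varying parameters
    fixed: dict[str, float]
    values: np.ndarray                  # shape = tuple of axis lengths
    n_replicates: int
    n_trials: int

    def smoothed(self, size: int = 3) -> np.ndarray:
        """Moving-average copy for presentation; assertions use raw cells."""
        return uniform_filter(self.values, size=size, mode="nearest")

    def argmax_cell(self) -> dict[str, float]:
        idx = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        names = list(self.axes)
        return {name: float(self.axes[name][i]) for name, i in zip(names, idx)}


def reward_rate_grid(
    spec: ModelSpec,
    casino: CasinoConfig,
    axes: Mapping[str, Sequence[float]],
    rng: np.random.Generator,
    fixed: Mapping[str, float] | None = None,
    n_trials: int = 120,
    n_replicates: int = 200,
) -> RewardRateGrid:
    """Simulate mean reward rate over a parameter grid in one casino.

    Each replicate is a fresh block of ``n_trials`` within-casino trials of
    the given casino alone; replicates share schedules and choice noise
    across cells (common random numbers).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    fixed = dict(fixed or {})
    names = spec.param_names
    axes = {k: np.asarray(v, dtype=float) for k, v in axes.items()}
    if set(axes) | set(fixed) != set(names):
        raise ValueError(f"axes+fixed must cover exactly {names}")
    mesh = np.meshgrid(*axes.values(), indexing="ij")
    shape = mesh[0].shape
    n_cells = mesh[0].size
    cellparams = np.empty((n_cells, len(names)))
    for p, name in enumerate(names):
        if name in axes:
            cellparams[:, p] = mesh[list(axes).index(name)].ravel()
        else:
            cellparams[:, p] = fixed[name]

    winning = np.empty((n_replicates, n_trials), dtype=np.int64)
    for rep in range(n_replicates):
        _, winning[rep] = _casino_schedule(casino, n_trials, rng)
    u = rng.random((n_replicates, n_trials))
    values = _kernels._reward_rate_cells(spec.kind_code, cellparams, winning, u)
    return RewardRateGrid(
        environment=casino.label,
        axes=axes,
        fixed=fixed,
        values=values.reshape(shape),
        n_replicates=n_replicates,
        n_trials=n_trials,
    )


def optimal_region_summary(grids: Mapping[str, RewardRateGrid]) -> dict:
    """Argmax cells per environment and the qualitative ordering of the
    optimal learning rates (volatile optimum at a higher rate)."""
    summary: dict = {"argmax": {}, "max_reward_rate": {}}
    for env, grid in grids.items():
        summary["argmax"][env] = grid.argmax_cell()
        summary["max_reward_rate"][env] = float(grid.values.max())
    if set(grids) == {"stable", "volatile"}:
        lr_axis = next(iter(grids["stable"].axes))
        a_s = summary["argmax"]["stable"][lr_axis]
        a_v = summary["argmax"]["volatile"][lr_axis]
        if a_s == a_v:
            summary["volatile_optimum_higher"] = None
        else:
            summary["volatile_optimum_higher"] = bool(a_v > a_s)
        summary["optimum_gap"] = abs(
            summary["max_reward_rate"]["volatile"]
            - summary["max_reward_rate"]["stable"]
        )
    return summary


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


def _trunc_normal(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_population(
    spec: ModelSpec,
    means: Mapping,
    sds: Mapping,
    n_participants: int,
    rng: np.random.Generator,
) -> dict[int, ParameterSet]:
    """Draw individual parameter sets from group-level normals truncated to
    the parameter bounds (bounded scale)."""

    def draw_block(mean_blk, sd_blk):
        return {
            name: _trunc_normal(
                mean_blk[name], sd_blk[name], *PARAM_BOUNDS[name],
                n_participants, rng,
            )
            for name in spec.param_names
        }

    if spec.env_specific:
        per_env = {env: draw_block(means[env], sds[env]) for env in means}
        return {
            i: ParameterSet(
                spec,
                {
                    env: {k: float(v[i]) for k, v in blk.items()}
                    for env, blk in per_env.items()
                },
            )
            for i in range(n_participants)
        }
    blk = draw_block(means, sds)
    return {
        i: ParameterSet(spec, {k: float(v[i]) for k, v in blk.items()})
        for i in range(n_participants)
    }


def relabel_population(
    population: Mapping[int, ParameterSet], labels: Sequence[str]
) -> dict[int, ParameterSet]:
    """Map environment-specific parameter sets onto new environment labels
    (sorted source labels onto sorted targets, e.g. stable/volatile onto the
    control phase's A/B).  Shared parameter sets pass through unchanged."""
    out: dict[int, ParameterSet] = {}
    targets = sorted(labels)
    for pid, pset in population.items():
        if not pset.spec.env_specific:
            out[pid] = pset
            continue
        src = sorted(pset.values)
        out[pid] = ParameterSet(
            pset.spec, {new: pset.values[old] for new, old in zip(targets, src)}
        )
    return out


def recovery_population(spec: ModelSpec) -> tuple[Mapping, Mapping]:
    """Group-level means and SDs used in the model-recovery study.

    Environment-specific models: learning rates 0.4 (stable) / 0.6
    (volatile), inverse temperatures 3.5 / 4.5, higher-order rates 0;
    shared models: 0.5, 4 and 0.  SDs: 0.2 for learning rates, 2 for
    inverse temperatures, 0.1 for higher-order rates.
    """

    def blk(lr_mean, beta_mean):
        means = {}
        sds = {}
        for name in spec.param_names:
            if name == "beta":
                means[name], sds[name] = beta_mean, 2.0
            elif name == "eta":
                means[name], sds[name] = 0.0, 0.1
            else:
                means[name], sds[name] = lr_mean, 0.2
        return means, sds

    if spec.env_specific:
        m_s, s_s = blk(0.4, 3.5)
        m_v, s_v = blk(0.6, 4.5)
        return {"stable": m_s, "volatile": m_v}, {"stable": s_s, "volatile": s_v}
    return blk(0.5, 4.0)


# ---------------------------------------------------------------------------
# Model recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Result of a model- or parameter-recovery study."""

    kind: str
    matrix: pd.DataFrame | None = None          # model recovery
    correlations: pd.DataFrame | None = None    # parameter recovery
    metadata: dict = field(default_factory=dict)
    details: list = field(default_factory=list)


def model_recovery_study(
    n_datasets_per_model: int = 10,
    n_participants: int = 36,
    phase: PhaseConfig | None = None,
    models: Sequence[ModelSpec] = ALL_MODELS,
    fit_kwargs: Mapping | None = None,
    seed: int | None = None,
) -> RecoveryReport:
    """Simulate datasets from each model and tabulate which model wins.

    For every dataset all candidate models are fitted and ranked by elpd;
    the row-stochastic matrix reports how often each candidate ends up on
    top.  Non-converged fits are recorded and the dataset flagged.
    """
    from .task import learning_phase

    phase = phase or learning_phase(2, 240, stable_p=0.75)
    fit_kwargs = dict(fit_kwargs or {})
    master = np.random.SeedSequence(seed)
    counts = pd.DataFrame(
        0.0, index=[m.key for m in models], columns=[m.key for m in models]
    )
    details = []
    for gen_model in models:
        means, sds = recovery_population(gen_model)
        for ds_seeds in master.spawn(n_datasets_per_model):
            sim_seed, *fit_seeds = ds_seeds.spawn(1 + len(models))
            rng = np.random.default_rng(sim_seed)
            population = sample_population(gen_model, means, sds, n_participants, rng)
            data = generate_participants(phase, n_participants, rng)
            data = simulate_choices(data, gen_model, population, rng)
            results = {}
            flagged = []
            for fit_model, fs in zip(models, fit_seeds):
                post = sample_posterior(
                    build_model(data, fit_model),
                    seed=int(fs.generate_state(1)[0] % 2**31),
                    **fit_kwargs,
                )
                if not post.diagnostics["rhat_ok"]:
                    flagged.append(fit_model.key)
                results[fit_model.key] = compute_elpd_loo(post.pointwise_loglik())
            table = compare_models(results)
            best = table.iloc[0]["Model"]
            counts.loc[gen_model.key, best] += 1
            details.append(
                {
                    "generating": gen_model.key,
                    "best": best,
                    "non_converged": flagged,
                    "table": table,
                }
            )
    matrix = counts.div(counts.sum(axis=1), axis=0)
    return RecoveryReport(
        kind="model",
        matrix=matrix,
        metadata={
            "n_datasets_per_model": n_datasets_per_model,
            "n_participants": n_participants,
            "seed": seed,
            "fit_kwargs": fit_kwargs,
        },
        details=details,
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def single_casino_phase(
    casino: CasinoConfig, n_blocks: int, trials_per_casino_block: int
) -> PhaseConfig:
    """Learning-phase shell for a one-environment simulation: the partner
    casino exists only to satisfy the balanced design and is ignored."""
    other = CasinoConfig("_unused", casino.p_reward, "stable")
    return PhaseConfig(
        "learning", n_blocks, 2 * trials_per_casino_block, (casino, other)
    )


def _single_casino_trials(
    casino: CasinoConfig,
    n_blocks: int,
    trials_per_casino_block: int,
    n_participants: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    phase = single_casino_phase(casino, n_blocks, trials_per_casino_block)
    data = generate_participants(phase, n_participants, rng)
    data = data[data["environment"] == casino.label].reset_index(drop=True)
    return data


def parameter_recovery_study(
    casino: CasinoConfig,
    combos: Sequence[tuple[float, float, float]] | None = None,
    n_participants: int = 36,
    n_blocks: int = 2,
    trials_per_casino_block: int = 120,
    sds: tuple[float, float, float] = (0.2, 0.2, 2.0),
    fit_kwargs: Mapping | None = None,
    seed: int | None = None,
) -> RecoveryReport:
    """Recoverability of the dual-learning-rate parameters in one casino.

    Each combo ``(alpha_pos, alpha_neg, beta)`` is a group-level mean; a
    dataset of ``n_participants`` truncated-normal individuals is simulated
    and refitted with the dual model, and true individual parameters are
    correlated with individual-level posterior means, pooled over combos.
    The full grid crosses {0.2, 0.4, 0.6, 0.8}^2 x {2, 4, 6, 8}.
    """
    if combos is None:
        combos = [
            (ap, an, b)
            for ap in (0.2, 0.4, 0.6, 0.8)
            for an in (0.2, 0.4, 0.6, 0.8)
            for b in (2.0, 4.0, 6.0, 8.0)
        ]
    fit_kwargs = dict(fit_kwargs or {})
    spec = ModelSpec(env_specific=False, lr_kind="dual")
    master = np.random.SeedSequence(seed)
    truth_frames = []
    est_frames = []
    for combo, ds_seed in zip(combos, master.spawn(len(combos))):
        sim_seed, fit_seed = ds_seed.spawn(2)
        rng = np.random.default_rng(sim_seed)
        means = dict(zip(("alpha_pos", "alpha_neg", "beta"), combo))
        sd_map = dict(zip(("alpha_pos", "alpha_neg", "beta"), sds))
        population = sample_population(spec, means, sd_map, n_participants, rng)
        data = _single_casino_trials(
            casino, n_blocks, trials_per_casino_block, n_participants, rng
        )
        data = simulate_choices(data, spec, population, rng)
        post = sample_posterior(
            build_model(data, spec),
            seed=int(fit_seed.generate_state(1)[0] % 2**31),
            **fit_kwargs,
        )
        est = post.individual_posterior_means()
        est["combo"] = [combo] * len(est)
        est_frames.append(est)
        truth_frames.append(
            pd.DataFrame(
                [
                    {
                        "participant_id": pid,
                        "parameter": name,
                        "true": pset.values[name],
                        "combo": combo,
                    }
                    for pid, pset in population.items()
                    for name in spec.param_names
                ]
            )
        )
    truth = pd.concat(truth_frames, ignore_index=True)
    est = pd.concat(est_frames, ignore_index=True)
    merged = truth.merge(est, on=["combo", "participant_id", "parameter"])
    corr = (
        merged.groupby("parameter")
        .apply(
            lambda g: float(np.corrcoef(g["true"], g["mean"])[0, 1]),
            include_groups=False,
        )
        .rename("correlation")
        .reset_index()
    )
    corr["environment"] = casino.label
    return RecoveryReport(
        kind="parameter",
        correlations=corr,
        metadata={
            "environment": casino.label,
            "n_combos": len(combos),
            "n_participants": n_participants,
            "n_true_values": len(combos) * n_participants,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Posterior predictive check
# ---------------------------------------------------------------------------


def posterior_predictive_check(
    post: PosteriorDraws,
    data: pd.DataFrame,
    max_draws: int | None = None,
    seed: int | None = None,
) -> dict:
    """Simulate choices from each joint posterior draw and compare reward
    rates with the observed ones, per environment.

    Returns per-participant observed and simulated mean reward rates, the
    per-participant central 95% interval of simulated rates, and the
    Pearson correlation between observed and simulated rates across
    participants per environment.
    """
    m = post.model
    obs = data.loc[m.obs_index]
    if sorted(obs["participant_id"].unique()) != list(m.participants):
        raise ValueError("data do not match the fitted model's participants")
    winning = obs.sort_values(["participant_id", "trial"], kind="stable")[
        "winning_machine"
    ].to_numpy(np.int64)
    flat = post.draws.reshape(-1, post.draws.shape[-1])
    if max_draws is not None and len(flat) > max_draws:
        idx = np.linspace(0, len(flat) - 1, max_draws).astype(int)
        flat = flat[idx]
    rng = np.random.default_rng(seed)
    env_mask = {
        env: (m.env == i).astype(bool) for i, env in enumerate(m.env_labels)
    }
    sums = {env: np.zeros((len(flat), m.N)) for env in m.env_labels}
    choice_buf = np.empty(m.n_obs, dtype=np.int64)
    reward_buf = np.empty(m.n_obs, dtype=np.int64)
    for d, x in enumerate(flat):
        theta = m.theta_from_vector(x)
        u = rng.random(m.n_obs)
        _kernels._simulate(
            m.spec.kind_code, theta, m.env, m.cell, m.newpair, winning,
            m.offsets, u, choice_buf, reward_buf,
        )
        for env, mask in env_mask.items():
            for i in range(m.N):
                seg = slice(m.offsets[i], m.offsets[i + 1])
                msk = mask[seg]
                sums[env][d, i] = reward_buf[seg][msk].mean()
    result: dict = {"per_participant": {}, "correlation": {}}
    ordered = obs.sort_values(["participant_id", "trial"], kind="stable")
    reward_obs = ordered["reward"].to_numpy(float)
    for env, mask in env_mask.items():
        observed = np.array(
            [
                reward_obs[m.offsets[i] : m.offsets[i + 1]][
                    mask[m.offsets[i] : m.offsets[i + 1]]
                ].mean()
                for i in range(m.N)
            ]
        )
        simulated = sums[env]
        result["per_participant"][env] = pd.DataFrame(
            {
                "participant_id": m.participants,
                "observed": observed,
                "simulated_mean": simulated.mean(axis=0),
                "simulated_lo": np.quantile(simulated, 0.025, axis=0),
                "simulated_hi": np.quantile(simulated, 0.975, axis=0),
            }
        )
        result["correlation"][env] = float(
            np.corrcoef(observed, simulated.mean(axis=0))[0, 1]
        )
    return result
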