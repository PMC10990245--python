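"""Rescorla-Wagner model variants for the two-casino bandit.

Six models arise from crossing two factors:

* learning-rate kind — *single* (one rate :math:`\\alpha`), *dual*
  (separate rates :math:`\\alpha^+ / \\alpha^-` after rewarded / unrewarded
  trials), or *variable* (the effective rate tracks recent absolute
  prediction errors via a higher-order rate :math:`\\eta`);
* environment specificity — one copy of every free parameter per casino,
  or a single copy shared across casinos.

Value updating follows the delta rule
:math:`Q_{t+1} = Q_t + \\alpha (r_t - Q_t)` with rewards :math:`r_t \\in
\\{0, 1\\}`, and choices follow a softmax with inverse temperature
:math:`\\beta \\in [0, 10]`.  Q-values start at 0 and reset at every block
boundary (each block introduces new machines); in the variable models the
effective learning rate is learner state and persists across blocks within
a phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "alpha_pos": (0.0, 1.0),
    "alpha_neg": (0.0, 1.0),
    "eta": (0.0, 1.0),
    "beta": (0.0, 10.0),
}

LR_KINDS = ("single", "dual", "variable")
_KIND_CODE = {"single": 0, "dual": 1, "variable": 2}


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model variants."""

    env_specific: bool
    lr_kind: str

    def __post_init__(self) -> None:
        if self.lr_kind not in LR_KINDS:
            raise ValueError(f"unknown lr_kind {self.lr_kind!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        """Free parameters per parameter cell; beta always last."""
        return {
            "single": ("alpha", "beta"),
            "dual": ("alpha_pos", "alpha_neg", "beta"),
            "variable": ("alpha", "eta", "beta"),
        }[self.lr_kind]

    @property
    def n_lr_params(self) -> int:
        """Learning-rate-like parameters per cell (everything except beta)."""
        return len(self.param_names) - 1

    @property
    def kind_code(self) -> int:
        return _KIND_CODE[self.lr_kind]

    @property
    def name(self) -> str:
        prefix = "Environment-specific" if self.env_specific else "Non-environment-specific"
        return f"{prefix} {self.lr_kind} learning rate model"

    @property
    def key(self) -> str:
        return ("env_" if self.env_specific else "shared_") + self.lr_kind


#: all six variants, in the conventional presentation order
ALL_MODELS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(env_specific, kind)
    for env_specific in (True, False)
    for kind in ("single", "dual", "variable")
)


def model_from_key(key: str) -> ModelSpec:
    for m in ALL_MODELS:
        if m.key == key:
            return m
    raise ValueError(f"unknown model key {key!r}")


@dataclass(frozen=True)
class ParameterSet:
    """Bounded parameter values for one agent.

    ``values`` maps parameter name -> value for non-environment-specific
    models, or environment label -> {parameter name -> value} for
    environment-specific ones.
    """

    spec: ModelSpec
    values: Mapping

    def __post_init__(self) -> None:
        names = set(self.spec.param_names)
        blocks = self.values.values() if self.spec.env_specific else [self.values]
        for blk in blocks:
            if set(blk) != names:
                raise ValueError(
                    f"parameters {sorted(blk)} do not match spec {sorted(names)}"
                )
            for name, v in blk.items():
                lo, hi = PARAM_BOUNDS[name]
                if not lo <= v <= hi:
                    raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def for_env(self, env: str) -> Mapping[str, float]:
        if self.spec.env_specific:
            try:
                return self.values[env]
            except KeyError:
                raise KeyError(f"no parameters for environment {env!r}") from None
        return self.values


# ---------------------------------------------------------------------------
# Elementary update and choice rules
# ---------------------------------------------------------------------------

def delta_update(q: float, reward: float, alpha: float) -> float:
    """Delta rule: ``q + alpha * (reward - q)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    return q + alpha * (reward - q)


def dual_delta_update(
    q: float, reward: float, alpha_pos: float, alpha_neg: float
) -> float:
    """Delta rule with separate rates after rewarded / unrewarded trials."""
    if not (0.0 <= alpha_pos <= 1.0 and 0.0 <= alpha_neg <= 1.0):
        raise ValueError("learning rates must lie in [0, 1]")
    return delta_update(q, reward, alpha_pos if reward == 1 else alpha_neg)


def variable_lr_update(
    alpha: float, q_chosen: float, reward: float, eta: float
) -> float:
    """Higher-order rule: the learning rate drifts toward the absolute
    prediction error, ``eta * |r - q| + (1 - eta) * alpha``."""
    if not (0.0 <= alpha <= 1.0 and 0.0 <= eta <= 1.0 and 0.0 <= q_chosen <= 1.0):
        raise ValueError("alpha, eta, q_chosen must lie in [0, 1]")
    return eta * abs(reward - q_chosen) + (1.0 - eta) * alpha


def softmax_prob(q_a: float, q_b: float, beta: float) -> float:
    """Probability of choosing machine *a* under the softmax rule."""
    m = max(beta * q_a, beta * q_b)
    ea = math.exp(beta * q_a - m)
    eb = math.exp(beta * q_b - m)
    return ea / (ea + eb)


# ---------------------------------------------------------------------------
# Sequential agent state
# ---------------------------------------------------------------------------

class _Agent:
    """Q-values per casino (reset per block) and, for variable models, an
    evolving learning rate per parameter cell (persists across blocks)."""

    def __init__(self, spec: ModelSpec, params: ParameterSet):
        if params.spec != spec:
            raise ValueError("parameter set does not match model spec")
        self.spec = spec
        self.params = params
        self.q: dict[str, list[float]] = {}
        self.block: dict[str, int] = {}
        self.alpha_t: dict[str, float] = {}  # variable models only

    def _cell(self, env: str) -> str:
        return env if self.spec.env_specific else "__shared__"

    def _q(self, env: str, block: int) -> list[float]:
        if self.block.get(env) != block:
            self.q[env] = [0.0, 0.0]
            self.block[env] = block
        return self.q[env]

    def choice_probs(self, env: str, block: int) -> tuple[float, float]:
        q = self._q(env, block)
        p0 = softmax_prob(q[0], q[1], self.params.for_env(env)["beta"])
        return p0, 1.0 - p0

    def update(self, env: str, block: int, choice: int, reward: float) -> None:
        q = self._q(env, block)
        p = self.params.for_env(env)
        kind = self.spec.lr_kind
        if kind == "single":
            q[choice] = delta_update(q[choice], reward, p["alpha"])
        elif kind == "dual":
            q[choice] = dual_delta_update(
                q[choice], reward, p["alpha_pos"], p["alpha_neg"]
            )
        else:
            cell = self._cell(env)
            alpha = self.alpha_t.setdefault(cell, p["alpha"])
            q_old = q[choice]
            q[choice] = delta_update(q_old, reward, alpha)
            self.alpha_t[cell] = variable_lr_update(alpha, q_old, reward, p["eta"])


def _check_sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["participant_id", "phase", "trial"], kind="stable")


def simulate_choices(
    trials: pd.DataFrame,
    spec: ModelSpec,
    params: ParameterSet | Mapping[int, ParameterSet],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate choices and rewards for a trial table.

    ``params`` is either one :class:`ParameterSet` (applied to every
    participant) or a mapping participant_id -> ParameterSet.  Rewards are
    anticorrelated: ``reward = 1`` iff the choice equals ``winning_machine``.
    State is per environment and persists across interleaved trials.
    """
    out = trials.copy()
    ordered = _check_sorted(out)
    choices = np.empty(len(ordered), dtype=np.int64)
    rewards = np.empty(len(ordered), dtype=np.int64)
    pos = 0
    for (pid, _phase), grp in ordered.groupby(["participant_id", "phase"], sort=False):
        pset = params[pid] if isinstance(params, Mapping) else params
        agent = _Agent(spec, pset)
        for row in grp.itertuples(index=False):
            p0, _ = agent.choice_probs(row.environment, row.block)
            c = 0 if rng.random() < p0 else 1
            r = int(c == row.winning_machine)
            agent.update(row.environment, row.block, c, r)
            choices[pos] = c
            rewards[pos] = r
            pos += 1
    out.loc[ordered.index, "choice"] = choices.astype(float)
    out.loc[ordered.index, "reward"] = rewards.astype(float)
    return out


def pointwise_loglik(
    trials: pd.DataFrame,
    spec: ModelSpec,
    params: ParameterSet | Mapping[int, ParameterSet],
) -> np.ndarray:
    """Log-probability of each observed choice, aligned with ``trials``.

    Trials with a missing choice contribute NaN and trigger no value update.
    State evolution is identical to :func:`simulate_choices` but conditioned
    on the recorded choices and rewards.
    """
    ordered = _check_sorted(trials)
    ll = np.full(len(trials), np.nan)
    out_index = {idx: i for i, idx in enumerate(trials.index)}
    for (pid, _phase), grp in ordered.groupby(["participant_id", "phase"], sort=False):
        pset = params[pid] if isinstance(params, Mapping) else params
        agent = _Agent(spec, pset)
        for idx, row in zip(grp.index, grp.itertuples(index=False)):
            if pd.isna(row.choice):
                continue
            c = int(row.choice)
            probs = agent.choice_probs(row.environment, row.block)
            ll[out_index[idx]] = math.log(probs[c])
            agent.update(row.environment, row.block, c, float(row.reward))
    return ll
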