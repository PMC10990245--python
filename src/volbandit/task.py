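"""Trial sequences and reward schedules for the two-casino bandit task.

Participants alternate trial-by-trial between two casinos ("environments"),
each housing a two-armed bandit with anticorrelated binary rewards: on every
trial exactly one machine wins.  A casino is *stable* (the better machine is
fixed for a whole block), *volatile* (the reward contingency reverses every
16-24 within-casino trials), or *intermediate* (test phase: exactly two
reversals, spaced 29-37 within-casino trials apart).  Each block introduces a
fresh machine pair in each casino.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical column order of the long-format trial table
TRIAL_COLUMNS = [
    "participant_id",
    "phase",
    "block",
    "trial",
    "environment",
    "within_casino_trial",
    "correct_machine",
    "winning_machine",
    "choice",
    "reward",
]

VOLATILITIES = ("stable", "volatile", "intermediate")


@dataclass(frozen=True)
class CasinoConfig:
    """Reward schedule of one casino.

    Parameters
    ----------
    label:
        Environment label ("stable", "volatile", "A", "B", ...).
    p_reward:
        Probability, in (0.5, 1], that the currently-correct machine wins on
        a given trial.  The other machine wins with probability
        ``1 - p_reward`` (rewards are anticorrelated).
    volatility:
        "stable" (no reversals within a block), "volatile" (reversals at
        iid-uniform intervals from ``switch_interval``), or "intermediate"
        (exactly two reversals per block at intervals from
        ``switch_interval``).
    switch_interval:
        Closed integer range ``(lo, hi)`` of within-casino trials between
        reversals; required unless stable.
    """

    label: str
    p_reward: float
    volatility: str = "stable"
    switch_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.p_reward <= 1.0:
            raise ValueError(f"p_reward must be in (0.5, 1], got {self.p_reward}")
        if self.volatility not in VOLATILITIES:
            raise ValueError(f"unknown volatility {self.volatility!r}")
        if self.volatility != "stable":
            if self.switch_interval is None:
                raise ValueError(f"{self.volatility} casino needs a switch_interval")
            lo, hi = self.switch_interval
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid switch_interval {self.switch_interval}")

    @property
    def max_switches(self) -> int | None:
        """Cap on reversals per block: 2 for intermediate casinos, else None."""
        return 2 if self.volatility == "intermediate" else None


@dataclass(frozen=True)
class PhaseConfig:
    """One experimental phase: ``n_blocks`` blocks of ``trials_per_block``
    trials, split equally between two casinos."""

    phase_kind: str  # "learning" | "control" | "test"
    n_blocks: int
    trials_per_block: int
    casinos: tuple[CasinoConfig, CasinoConfig]

    def __post_init__(self) -> None:
        if self.phase_kind not in ("learning", "control", "test"):
            raise ValueError(f"unknown phase_kind {self.phase_kind!r}")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.trials_per_block % 2 != 0:
            raise ValueError("trials_per_block must be even (balanced casinos)")
        if len(self.casinos) != 2:
            raise ValueError("a phase has exactly two casinos")
        if self.casinos[0].label == self.casinos[1].label:
            raise ValueError("casino labels must differ")


def generate_casino_sequence(trials_per_block: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced random casino order for one block.

    Returns an int array of 0/1 casino indices with exactly
    ``trials_per_block / 2`` trials of each casino, uniformly permuted.
    """
    if trials_per_block % 2 != 0:
        raise ValueError("trials_per_block must be even")
    half = trials_per_block // 2
    seq = np.repeat(np.array([0, 1], dtype=np.int64), half)
    return rng.permutation(seq)


def generate_switch_points(
    n_within_casino_trials: int,
    interval_range: tuple[int, int],
    rng: np.random.Generator,
    max_switches: int | None = None,
) -> list[int]:
    """Within-casino trial indices at which the correct machine reverses.

    Gaps between successive reversals (including the gap before the first)
    are iid uniform integers on the closed ``interval_range``.  A reversal at
    index ``s`` means the correct machine changes between within-casino trials
    ``s - 1`` and ``s`` (0-based).  Reversals at or beyond the horizon are
    dropped; ``max_switches`` caps the count (test-phase casinos use 2).
    """
    lo, hi = interval_range
    if lo > hi or lo < 1:
        raise ValueError(f"invalid interval_range {interval_range}")
    points: list[int] = []
    t = 0
    while True:
        t += int(rng.integers(lo, hi + 1))
        if t >= n_within_casino_trials:
            break
        points.append(t)
        if max_switches is not None and len(points) >= max_switches:
            break
    return points


def _casino_schedule(
    casino: CasinoConfig, n_trials: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per within-casino trial: (correct_machine, winning_machine)."""
    first_correct = int(rng.integers(2))
    if casino.volatility == "stable":
        switches: list[int] = []
    else:
        switches = generate_switch_points(
            n_trials, casino.switch_interval, rng, max_switches=casino.max_switches
        )
    correct = np.full(n_trials, first_correct, dtype=np.int64)
    for s in switches:
        correct[s:] = 1 - correct[s:]
    # anticorrelated rewards: winner is the correct machine w.p. p_reward
    wins_correct = rng.random(n_trials) < casino.p_reward
    winning = np.where(wins_correct, correct, 1 - correct)
    return correct, winning


def generate_phase(
    config: PhaseConfig,
    rng: np.random.Generator,
    participant_id: int = 0,
) -> pd.DataFrame:
    """Generate one participant's trial table for a phase.

    ``choice`` and ``reward`` are left missing (NaN); ``winning_machine`` is
    realised from the schedule.  Each block draws a fresh machine pair (new
    schedule, coin-flip initial correct machine) per casino.
    """
    half = config.trials_per_block // 2
    frames = []
    for block in range(config.n_blocks):
        order = generate_casino_sequence(config.trials_per_block, rng)
        correct = np.empty(config.trials_per_block, dtype=np.int64)
        winning = np.empty(config.trials_per_block, dtype=np.int64)
        within = np.empty(config.trials_per_block, dtype=np.int64)
        for ci, casino in enumerate(config.casinos):
            idx = np.flatnonzero(order == ci)
            c, w = _casino_schedule(casino, half, rng)
            correct[idx] = c
            winning[idx] = w
            within[idx] = np.arange(half)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "phase": config.phase_kind,
                    "block": block,
                    "trial": block * config.trials_per_block
                    + np.arange(config.trials_per_block),
                    "environment": np.array(
                        [config.casinos[c].label for c in order], dtype=object
                    ),
                    "within_casino_trial": within,
                    "correct_machine": correct,
                    "winning_machine": winning,
                    "choice": np.nan,
                    "reward": np.nan,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def generate_participants(
    config: PhaseConfig, n_participants: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Stack :func:`generate_phase` for several participants."""
    return pd.concat(
        [generate_phase(config, rng, participant_id=i) for i in range(n_participants)],
        ignore_index=True,
    )


def run_length_distribution(
    sequences: Iterable[Sequence] | Iterable[np.ndarray],
) -> dict[int, float]:
    """Pooled distribution of maximal same-casino run lengths.

    Returns a mapping run length -> fraction of runs, over all sequences.
    """
    counts: dict[int, int] = {}
    total = 0
    empty = True
    for seq in sequences:
        arr = np.asarray(seq)
        if arr.size == 0:
            continue
        empty = False
        change = np.flatnonzero(arr[1:] != arr[:-1])
        bounds = np.concatenate(([-1], change, [arr.size - 1]))
        lengths = np.diff(bounds)
        for ln in lengths:
            counts[int(ln)] = counts.get(int(ln), 0) + 1
            total += 1
    if empty:
        raise ValueError("no sequences given")
    return {k: v / total for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------

def learning_phase(
    n_blocks: int,
    trials_per_block: int,
    stable_p: float = 0.80,
    volatile_p: float = 0.90,
    switch_interval: tuple[int, int] = (16, 24),
) -> PhaseConfig:
    """Learning phase: one stable and one volatile casino."""
    return PhaseConfig(
        "learning",
        n_blocks,
        trials_per_block,
        (
            CasinoConfig("stable", stable_p, "stable"),
            CasinoConfig("volatile", volatile_p, "volatile", switch_interval),
        ),
    )


def experiment_phases(name: str) -> list[PhaseConfig]:
    """Phase structure of the three experiments.

    - exp1: learning 2x240 (stable 75/25, volatile 90/10 switching every
      16-24), then a control phase 1x240 with two stable 75/25 casinos.
    - exp2: learning 4x200, stable at 80/20.
    - exp3: learning 3x200 (as exp2), then a test phase 1x200 in which both
      casinos run at 85/15 and reverse exactly twice, every 29-37 trials.
    """
    if name == "exp1":
        return [
            learning_phase(2, 240, stable_p=0.75),
            PhaseConfig(
                "control",
                1,
                240,
                (CasinoConfig("A", 0.75), CasinoConfig("B", 0.75)),
            ),
        ]
    if name == "exp2":
        return [learning_phase(4, 200, stable_p=0.80)]
    if name == "exp3":
        test = PhaseConfig(
            "test",
            1,
            200,
            (
                CasinoConfig("stable", 0.85, "intermediate", (29, 37)),
                CasinoConfig("volatile", 0.85, "intermediate", (29, 37)),
            ),
        )
        return [learning_phase(3, 200, stable_p=0.80), test]
    raise ValueError(f"unknown experiment {name!r}")
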