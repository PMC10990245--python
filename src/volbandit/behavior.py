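"""Model-free behavioural statistics.

Covers the chance-level inclusion criterion, lose-switch rates (the
probability of switching machines after an unrewarded within-casino trial),
post-reversal choice accuracy in the test phase, and block-wise reward-rate
contrasts.  Tests follow the conventions of the analyses they implement:
chi-square inclusion at alpha = 0.05 with a directional requirement, paired
one-tailed t-tests in the direction of the hypothesis, and uncorrected 2x2
chi-squares per post-reversal trial position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float

    def as_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p": self.p_value}


def exclusion_filter(wins: int, trials: int, alpha_level: float = 0.05) -> bool:
    """Chance-level inclusion decision for one environment.

    One-degree-of-freedom chi-square of wins against trials/2; a participant
    is included only when the test is significant *and* the reward rate
    exceeds 0.5 ("significantly higher than chance").
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if wins < 0 or wins > trials:
        raise ValueError(f"wins={wins} outside [0, {trials}]")
    chi2, p = stats.chisquare([wins, trials - wins])
    return bool(p < alpha_level and wins / trials > 0.5)


def participant_summary(data: pd.DataFrame, alpha_level: float = 0.05) -> pd.DataFrame:
    """Per-participant reward rates and inclusion flags.

    Inclusion requires above-chance reward rates in *every* learning-phase
    environment; trials with missing choices are dropped.
    """
    df = data.dropna(subset=["choice"])
    rows = []
    for pid, grp in df.groupby("participant_id"):
        learn = grp[grp["phase"] == "learning"]
        env_rates = {}
        include = True
        reason = ""
        for env, g in learn.groupby("environment"):
            wins = int(g["reward"].sum())
            n = len(g)
            env_rates[env] = wins / n
            if not exclusion_filter(wins, n, alpha_level):
                include = False
                reason = f"at chance in {env!r}"
        rows.append(
            {
                "participant_id": pid,
                **{f"reward_rate_{env}": r for env, r in env_rates.items()},
                "included": include,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def _within_casino_pairs(grp: pd.DataFrame) -> pd.DataFrame:
    """Consecutive within-casino trial pairs inside a block."""
    g = grp.sort_values("trial", kind="stable")
    prev = g.shift(1)
    ok = (
        (prev["block"] == g["block"])
        & (g["within_casino_trial"] == prev["within_casino_trial"] + 1)
        & prev["choice"].notna()
        & g["choice"].notna()
    )
    out = pd.DataFrame(
        {
            "prev_reward": prev["reward"],
            "switched": (g["choice"] != prev["choice"]).astype(float),
        }
    )
    return out[ok.to_numpy(bool)]


def lose_switch_rates(data: pd.DataFrame) -> dict:
    """Per-participant lose-switch rates per environment, with a paired
    one-tailed t-test that the volatile rate exceeds the stable rate.

    A switch is counted when the choice on a within-casino trial differs
    from the immediately preceding within-casino trial of the same block,
    conditioned on that earlier trial being unrewarded.  Participants
    without qualifying pairs in an environment are dropped from the test.
    """
    rates = []
    for (pid, env), grp in data.groupby(["participant_id", "environment"]):
        pairs = _within_casino_pairs(grp)
        losses = pairs[pairs["prev_reward"] == 0]
        rates.append(
            {
                "participant_id": pid,
                "environment": env,
                "n_losses": len(losses),
                "lose_switch_rate": losses["switched"].mean() if len(losses) else np.nan,
            }
        )
    table = pd.DataFrame(rates)
    wide = table.pivot(
        index="participant_id", columns="environment", values="lose_switch_rate"
    )
    result: dict = {"rates": table, "test": None, "dropped": []}
    if {"stable", "volatile"} <= set(wide.columns):
        paired = wide[["stable", "volatile"]].dropna()
        result["dropped"] = sorted(set(wide.index) - set(paired.index))
        if len(paired) >= 2:
            t = stats.ttest_rel(
                paired["volatile"], paired["stable"], alternative="greater"
            )
            result["test"] = TestResult(float(t.statistic), len(paired) - 1,
                                        float(t.pvalue))
    return result


def post_switch_accuracy(data: pd.DataFrame, horizon: int = 10) -> pd.DataFrame:
    """Proportion of participants choosing the correct machine on the first
    ``horizon`` within-casino trials after each reversal, per environment,
    with an uncorrected 2x2 chi-square comparing environments per position.

    Reversal points are recovered from the recorded ``correct_machine``
    schedule of each participant x block x environment stream.
    """
    rows = []
    for (pid, env, block), grp in data.groupby(
        ["participant_id", "environment", "block"]
    ):
        g = grp.sort_values("within_casino_trial", kind="stable")
        correct = g["correct_machine"].to_numpy()
        switches = np.flatnonzero(np.diff(correct) != 0) + 1
        for s_idx, s in enumerate(switches):
            seg = g.iloc[s : s + horizon]
            for pos, row in enumerate(seg.itertuples(index=False), start=1):
                if pd.isna(row.choice):
                    continue
                rows.append(
                    {
                        "participant_id": pid,
                        "environment": env,
                        "switch": s_idx,
                        "position": pos,
                        "correct": float(row.choice == row.correct_machine),
                    }
                )
    long = pd.DataFrame(rows)
    if long.empty:
        raise ValueError("no post-reversal trials found")
    out = []
    envs = sorted(long["environment"].unique())
    for (switch, pos), grp in long.groupby(["switch", "position"]):
        rec = {"switch": switch, "position": pos}
        table = []
        for env in envs:
            g = grp[grp["environment"] == env]
            rec[f"prop_correct_{env}"] = g["correct"].mean()
            rec[f"n_{env}"] = len(g)
            table.append([g["correct"].sum(), (1 - g["correct"]).sum()])
        if len(envs) == 2:
            arr = np.asarray(table, dtype=float)
            if arr.sum(axis=1).min() > 0:
                if (arr.sum(axis=0) > 0).all():
                    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
                    rec["chi2"], rec["p"] = float(chi2), float(p)
                else:
                    # a zero margin (e.g. everyone correct): no association
                    rec["chi2"], rec["p"] = 0.0, 1.0
        out.append(rec)
    return pd.DataFrame(out).sort_values(["switch", "position"]).reset_index(drop=True)


def block_reward_contrast(data: pd.DataFrame) -> dict:
    """Paired one-tailed t-test of reward rate, last vs first block."""
    df = data.dropna(subset=["choice"])
    blocks = sorted(df["block"].unique())
    if len(blocks) < 2:
        raise ValueError("need at least two blocks")
    first, last = blocks[0], blocks[-1]
    rates = (
        df[df["block"].isin([first, last])]
        .groupby(["participant_id", "block"])["reward"]
        .mean()
        .unstack("block")
        .dropna()
    )
    diff = rates[last] - rates[first]
    if np.allclose(diff.var(ddof=1), 0.0):
        return {"rates": rates, "test": None, "degenerate": True}
    t = stats.ttest_rel(rates[last], rates[first], alternative="greater")
    return {
        "rates": rates,
        "test": TestResult(float(t.statistic), len(rates) - 1, float(t.pvalue)),
        "degenerate": False,
    }
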