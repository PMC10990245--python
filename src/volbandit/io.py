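"""Readers and writers for the long-format trial CSV and run artifacts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import TRIAL_COLUMNS

_INT_COLUMNS = ["block", "trial", "within_casino_trial", "correct_machine",
                "winning_machine"]
_BINARY_COLUMNS = ["correct_machine", "winning_machine"]


def write_trials(records: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the canonical column order (extra columns
    preserved after the canonical ones)."""
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trial table lacks columns {missing}")
    extra = [c for c in records.columns if c not in TRIAL_COLUMNS]
    records[TRIAL_COLUMNS + extra].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Unknown columns are preserved; missing choices (empty cells) are kept
    as NaN.  Malformed rows are rejected with their 1-based line numbers.
    """
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"bad header: missing column {col!r}")
    bad_lines: list[int] = []
    for col in _INT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if col in _BINARY_COLUMNS:
            bad |= ~vals.isin([0, 1])
        bad_lines.extend(df.index[bad] + 2)  # header is line 1
    for col in ("choice", "reward"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ~vals.isin([0, 1])
        bad_lines.extend(df.index[bad] + 2)
    # anticorrelated rewards: reward == (choice == winning_machine)
    obs = df["choice"].notna() & df["reward"].notna()
    mismatch = obs & (
        df["reward"] != (df["choice"] == df["winning_machine"]).astype(float)
    )
    bad_lines.extend(df.index[mismatch] + 2)
    if bad_lines:
        shown = sorted(set(int(b) for b in bad_lines))[:20]
        raise ValueError(f"malformed rows at lines {shown}")
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(np.int64)
    return df


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_posterior(post, csv_path: str | Path, json_path: str | Path) -> None:
    """Persist group-level posterior draws (long CSV) and diagnostics (JSON)."""
    m = post.model
    n_chains, n_kept, _ = post.draws.shape
    frames = []
    for cell in m.cells:
        for name in m.param_names:
            mu = post.group_mean_draws(name, cell).reshape(n_chains, n_kept)
            sd = post.group_sd_draws(name, cell).reshape(n_chains, n_kept)
            for label, arr in (("mu", mu), ("sigma", sd)):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": np.repeat(np.arange(n_chains), n_kept),
                            "draw": np.tile(np.arange(n_kept), n_chains),
                            "parameter": f"{label}[{cell}][{name}]",
                            "value": arr.ravel(),
                        }
                    )
                )
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(post.diagnostics, fh, indent=2, default=str)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
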