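"""Out-of-sample predictive fit via Pareto-smoothed importance sampling.

Each fitted model yields a draws x observations matrix of pointwise
log-likelihoods (one observation per trial).  PSIS-LOO turns this into the
expected log pointwise predictive density (elpd); following the original
tables, the column is labelled "LOOIC" and reported on the elpd (log) scale,
so *higher is better*.  Two models differ decisively when the difference
exceeds twice the standard error of the pointwise differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PARETO_K_WARN = 0.7


@dataclass
class LOOResult:
    """PSIS-LOO estimate for one model."""

    elpd: float
    se: float
    pointwise: np.ndarray     # per-observation elpd contributions
    pareto_k: np.ndarray      # per-observation Pareto shape diagnostics
    n_obs: int

    @property
    def n_high_pareto_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


def compute_elpd_loo(pointwise_loglik: np.ndarray) -> LOOResult:
    """PSIS-LOO from a pointwise log-likelihood array.

    Accepts (chains, draws, observations) or (draws, observations); the
    latter is treated as a single chain.  Non-finite entries are rejected
    with the offending observation index.
    """
    import arviz as az

    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 2:
        ll = ll[None, :, :]
    if ll.ndim != 3:
        raise ValueError(f"expected 2- or 3-d array, got shape {ll.shape}")
    if ll.shape[0] * ll.shape[1] < 2:
        raise ValueError("need at least two posterior draws")
    bad = ~np.isfinite(ll)
    if bad.any():
        obs = int(np.argwhere(bad)[0][2])
        raise ValueError(f"non-finite log-likelihood at observation {obs}")
    idata = az.from_dict(
        posterior={"_dummy": np.zeros(ll.shape[:2])},
        log_likelihood={"obs": ll},
    )
    res = az.loo(idata, pointwise=True)
    return LOOResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i.values),
        pareto_k=np.asarray(res.pareto_k.values),
        n_obs=ll.shape[2],
    )


def compare_models(results: dict[str, LOOResult]) -> pd.DataFrame:
    """Ranked comparison table.

    Columns mirror the conventional report: Model, LOOIC (elpd, higher
    better), SE, dLOOIC (top minus model, >= 0), dSE (SE of the pointwise
    elpd difference against the top model), and ``decisive`` (dLOOIC >
    2 * dSE).  All models must be fitted to the same observations in the
    same order.
    """
    if not results:
        raise ValueError("no models to compare")
    n_obs = {name: r.n_obs for name, r in results.items()}
    if len(set(n_obs.values())) != 1:
        raise ValueError(f"observation counts differ across models: {n_obs}")
    ranked = sorted(results.items(), key=lambda kv: kv[1].elpd, reverse=True)
    top_name, top = ranked[0]
    rows = []
    for name, r in ranked:
        diff = top.pointwise - r.pointwise
        d_elpd = float(np.sum(diff))
        d_se = float(np.sqrt(len(diff) * np.var(diff))) if name != top_name else 0.0
        rows.append(
            {
                "Model": name,
                "LOOIC": r.elpd,
                "SE": r.se,
                "dLOOIC": 0.0 if name == top_name else d_elpd,
                "dSE": d_se,
                "decisive": bool(name != top_name and d_elpd > 2.0 * d_se),
                "n_high_pareto_k": r.n_high_pareto_k,
            }
        )
    return pd.DataFrame(rows)
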