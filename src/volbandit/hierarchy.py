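"""Hierarchical Bayesian estimation of the bandit models.

For every combination of phase and environment (a *parameter cell*),
individual-level parameters are drawn from a group-level normal on an
unbounded (probit) scale and mapped to their bounded range through the
standard normal CDF:

.. math::

    \\theta_{ij} = \\mathrm{lo}_j + (\\mathrm{hi}_j - \\mathrm{lo}_j)\\,
        \\Phi(\\mu_j + \\sigma_j z_{ij}),

a non-centred parameterisation with :math:`z_{ij} \\sim N(0, 1)`.  Group
means carry uniform priors between the parameter bounds (equivalently,
standard normal priors on the probit scale), group SDs carry half-Cauchy(0, 5)
priors.  Sampling uses the package's Hamiltonian Monte Carlo implementation;
convergence is checked with the Gelman-Rubin statistic (flagged at 1.1).

Fits are per phase; block-wise fits replicate the cell structure per block
within one joint model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import _kernels
from .hmc import sample_chain
from .models import PARAM_BOUNDS, ModelSpec

RHAT_THRESHOLD = 1.1


def probit_to_bounds(raw, lower: float, upper: float):
    """Map an unbounded value into (lower, upper) via the normal CDF."""
    if lower >= upper:
        raise ValueError(f"need lower < upper, got [{lower}, {upper}]")
    return lower + (upper - lower) * ndtr(raw)


class HierarchicalModel:
    """Joint log-density over group means, group SDs and individual raws.

    Built from a single-phase trial table; see :func:`build_model`.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, by_block: bool = False):
        phases = data["phase"].unique()
        if len(phases) != 1:
            raise ValueError(
                f"fit one phase at a time (got {sorted(phases)}); "
                "phases are modelled separately"
            )
        self.spec = spec
        self.phase = phases[0]
        self.by_block = by_block
        self.param_names = spec.param_names
        self.P = len(self.param_names)
        self.lo = np.array([PARAM_BOUNDS[p][0] for p in self.param_names])
        self.hi = np.array([PARAM_BOUNDS[p][1] for p in self.param_names])

        df = data.dropna(subset=["choice"]).sort_values(
            ["participant_id", "trial"], kind="stable"
        )
        if df.empty:
            raise ValueError("no observed choices in data")
        self.participants = np.array(sorted(df["participant_id"].unique()))
        self.env_labels = sorted(df["environment"].unique())
        if len(self.env_labels) > 2:
            raise ValueError(f"more than two environments: {self.env_labels}")
        blocks = sorted(df["block"].unique())

        # parameter cells
        env_cells: list[Hashable] = (
            list(self.env_labels) if spec.env_specific else ["all"]
        )
        if by_block:
            self.cells = [(b, e) for b in blocks for e in env_cells]
            cell_of = {(b, e): i for i, (b, e) in enumerate(self.cells)}

            def trial_cell(block, env):
                return cell_of[(block, env if spec.env_specific else "all")]

        else:
            self.cells = list(env_cells)
            cell_of = {e: i for i, e in enumerate(self.cells)}

            def trial_cell(block, env):
                return cell_of[env if spec.env_specific else "all"]

        self.C = len(self.cells)

        env_idx = {e: i for i, e in enumerate(self.env_labels)}
        pid_idx = {p: i for i, p in enumerate(self.participants)}
        n = len(df)
        self.env = df["environment"].map(env_idx).to_numpy(np.int64)
        self.cell = np.array(
            [trial_cell(b, e) for b, e in zip(df["block"], df["environment"])],
            dtype=np.int64,
        )
        self.choice = df["choice"].to_numpy(np.int64)
        self.reward = df["reward"].to_numpy(np.int64)
        pid_arr = df["participant_id"].map(pid_idx).to_numpy(np.int64)
        counts = np.bincount(pid_arr, minlength=len(self.participants))
        self.offsets = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        # first kept trial of each (participant, block, casino) machine pair
        pair_key = pd.DataFrame(
            {
                "pid": df["participant_id"].to_numpy(),
                "block": df["block"].to_numpy(),
                "env": df["environment"].to_numpy(),
            }
        )
        self.newpair = (~pair_key.duplicated()).to_numpy()
        self.obs_index = df.index.to_numpy()

        percell = (
            pd.DataFrame({"pid": pid_arr, "cell": self.cell})
            .groupby(["pid", "cell"])
            .size()
        )
        for i, pid in enumerate(self.participants):
            for c in range(self.C):
                if (i, c) not in percell.index:
                    raise ValueError(
                        f"participant {pid!r} has no trials in cell "
                        f"{self.cells[c]!r}"
                    )

        self.N = len(self.participants)
        self.n_obs = n
        self.dim = self.C * self.P * (2 + self.N)

    # -- parameter vector layout ------------------------------------------
    def mu_index(self, cell: Hashable, param: str) -> int:
        return self.cells.index(cell) * self.P + self.param_names.index(param)

    def sigma_index(self, cell: Hashable, param: str) -> int:
        return self.C * self.P + self.mu_index(cell, param)

    def z_index(self, i_sub: int, cell: Hashable, param: str) -> int:
        c = self.cells.index(cell)
        p = self.param_names.index(param)
        return 2 * self.C * self.P + (i_sub * self.C + c) * self.P + p

    def bounds_of(self, param: str) -> tuple[float, float]:
        p = self.param_names.index(param)
        return float(self.lo[p]), float(self.hi[p])

    # -- densities ---------------------------------------------------------
    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        return _kernels._posterior_logp_grad(
            x, self.spec.kind_code, self.lo, self.hi, self.env, self.cell,
            self.newpair, self.choice, self.reward, self.offsets,
            self.N, self.C, self.P,
        )

    def logp(self, x: np.ndarray) -> float:
        return self.logp_grad(x)[0]

    def theta_from_vector(self, x: np.ndarray) -> np.ndarray:
        """Bounded individual parameters (N, C, P) at one sampling point."""
        ncp = self.C * self.P
        mu = x[:ncp].reshape(self.C, self.P)
        sig = np.exp(x[ncp : 2 * ncp]).reshape(self.C, self.P)
        z = x[2 * ncp :].reshape(self.N, self.C, self.P)
        return self.lo + (self.hi - self.lo) * ndtr(mu + sig * z)

    def pointwise_ll(self, thetas: np.ndarray) -> np.ndarray:
        """Per-trial log-likelihoods for a stack of (N, C, P) thetas."""
        thetas = np.asarray(thetas)
        out = np.empty((thetas.shape[0], self.n_obs))
        _kernels._pointwise_ll_draws(
            self.spec.kind_code, thetas, self.env, self.cell, self.newpair,
            self.choice, self.reward, self.offsets, out,
        )
        return out

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        ncp = self.C * self.P
        x = np.empty(self.dim)
        x[:ncp] = 0.2 * rng.standard_normal(ncp)
        x[ncp : 2 * ncp] = np.log(0.5) + 0.2 * rng.standard_normal(ncp)
        x[2 * ncp :] = 0.2 * rng.standard_normal(self.dim - 2 * ncp)
        return x


def build_model(
    data: pd.DataFrame, spec: ModelSpec, by_block: bool = False
) -> HierarchicalModel:
    """Assemble the joint hierarchical log-density for one phase of data."""
    return HierarchicalModel(data, spec, by_block=by_block)


@dataclass
class PosteriorDraws:
    """Posterior samples (chains x draws x sampling dimension) plus helpers."""

    model: HierarchicalModel
    draws: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    _pointwise: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def _flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def group_mean_draws(self, param: str, cell: Hashable | None = None) -> np.ndarray:
        """Draws of the group-level mean on the bounded scale."""
        cell = self._resolve_cell(cell)
        lo, hi = self.model.bounds_of(param)
        mu = self._flat()[:, self.model.mu_index(cell, param)]
        return probit_to_bounds(mu, lo, hi)

    def group_sd_draws(self, param: str, cell: Hashable | None = None) -> np.ndarray:
        """Draws of the group SD on the probit (unbounded) scale."""
        cell = self._resolve_cell(cell)
        return np.exp(self._flat()[:, self.model.sigma_index(cell, param)])

    def _resolve_cell(self, cell: Hashable | None) -> Hashable:
        if cell is None:
            if len(self.model.cells) != 1:
                raise ValueError(f"specify one of the cells {self.model.cells}")
            return self.model.cells[0]
        return cell

    def individual_posterior_means(self) -> pd.DataFrame:
        """Posterior mean of every bounded individual parameter."""
        m = self.model
        thetas = np.stack([m.theta_from_vector(x) for x in self._flat()])
        means = thetas.mean(axis=0)  # (N, C, P)
        rows = []
        for i, pid in enumerate(m.participants):
            for c, cell in enumerate(m.cells):
                for p, name in enumerate(m.param_names):
                    rows.append(
                        {
                            "participant_id": pid,
                            "cell": cell,
                            "parameter": name,
                            "mean": means[i, c, p],
                        }
                    )
        return pd.DataFrame(rows)

    def pointwise_loglik(self) -> np.ndarray:
        """Per-trial log-likelihood, shape (n_chains, n_kept, n_obs)."""
        if self._pointwise is None:
            m = self.model
            flat = self._flat()
            thetas = np.stack([m.theta_from_vector(x) for x in flat])
            ll = m.pointwise_ll(thetas)
            self._pointwise = ll.reshape(
                self.draws.shape[0], self.draws.shape[1], m.n_obs
            )
        return self._pointwise

    def to_inference_data(self):
        import arviz as az

        posterior = {}
        m = self.model
        for cell in m.cells:
            for name in m.param_names:
                lo, hi = m.bounds_of(name)
                mu = self.draws[:, :, m.mu_index(cell, name)]
                posterior[f"mu[{cell}][{name}]"] = probit_to_bounds(mu, lo, hi)
        return az.from_dict(
            posterior=posterior, log_likelihood={"obs": self.pointwise_loglik()}
        )

    def max_rhat(self) -> float:
        return self.diagnostics["max_rhat"]


def _compute_rhat(draws: np.ndarray) -> float:
    """Max split-R-hat over all sampling dimensions (via arviz)."""
    import arviz as az

    rh = az.rhat(az.convert_to_dataset({"x": draws}))
    return float(np.nanmax(rh["x"].values))


def sample_posterior(
    model: HierarchicalModel,
    n_chains: int = 4,
    n_iter: int = 4000,
    n_burn_in: int = 1000,
    seed: int | None = None,
    target_accept: float = 0.8,
    max_leapfrog: int = 64,
    traj_len: float = 2.4,
) -> PosteriorDraws:
    """Draw posterior samples with adaptive HMC.

    ``n_iter`` counts all iterations per chain; the first ``n_burn_in`` are
    discarded as warmup (defaults follow 4 chains x 4000 with 1000 burn-in,
    i.e. 12,000 retained draws).  The fit is flagged, not rejected, when any
    Gelman-Rubin statistic reaches 1.1 or divergences occur.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains = []
    stats = []
    for s in seeds:
        rng = np.random.default_rng(s)
        res = sample_chain(
            model.logp_grad,
            model.initial_point(rng),
            n_iter=n_iter,
            n_warmup=n_burn_in,
            rng=rng,
            target_accept=target_accept,
            max_leapfrog=max_leapfrog,
            traj_len=traj_len,
        )
        chains.append(res.draws)
        stats.append(res)
    draws = np.stack(chains)
    max_rhat = _compute_rhat(draws) if n_chains > 1 else float("nan")
    divergences = int(sum(r.divergences for r in stats))
    diagnostics = {
        "max_rhat": max_rhat,
        "rhat_ok": not (max_rhat >= RHAT_THRESHOLD),
        "divergences": divergences,
        "accept_rate": float(np.mean([r.accept_rate for r in stats])),
        "step_sizes": [r.step_size for r in stats],
        "n_chains": n_chains,
        "n_iter": n_iter,
        "n_burn_in": n_burn_in,
    }
    return PosteriorDraws(model=model, draws=draws, diagnostics=diagnostics)


def posterior_prob_greater(draws_a: np.ndarray, draws_b: np.ndarray) -> float:
    """Fraction of matched posterior draws with ``a > b`` (strict).

    A value above 0.95 corresponds to a one-tailed p-value below 0.05.
    """
    a = np.asarray(draws_a)
    b = np.asarray(draws_b)
    if a.shape != b.shape:
        raise ValueError(f"draw shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean(a > b))


def blockwise_fit(
    data: pd.DataFrame, spec: ModelSpec, **sample_kwargs
) -> PosteriorDraws:
    """One joint fit with block-specific group distributions per cell."""
    model = build_model(data, spec, by_block=True)
    return sample_posterior(model, **sample_kwargs)


def interaction_contrast(
    post: PosteriorDraws, first_block: int, last_block: int
) -> float:
    """Environment x block interaction on the (dual) learning rates.

    Per draw, averages the volatile-minus-stable gap over the positive and
    negative learning rates, and returns the fraction of draws in which the
    gap is larger in ``last_block`` than in ``first_block``.
    """
    m = post.model
    if m.spec.lr_kind != "dual" or not m.spec.env_specific:
        raise ValueError("interaction contrast needs the env-specific dual model")
    stable, volatile = m.env_labels
    diffs = []
    for block in (first_block, last_block):
        for env in (stable, volatile):
            if (block, env) not in m.cells:
                raise ValueError(f"no cell for block {block}, environment {env!r}")
        gap = np.zeros(post.n_draws)
        for param in ("alpha_pos", "alpha_neg"):
            gap += post.group_mean_draws(param, (block, volatile)) - \
                post.group_mean_draws(param, (block, stable))
        diffs.append(gap / 2.0)
    return float(np.mean(diffs[1] - diffs[0] > 0))
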