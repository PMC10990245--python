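"""Adaptive Hamiltonian Monte Carlo.

A self-contained gradient-based sampler in the Stan tradition: leapfrog
integration with a diagonal mass matrix, dual-averaging step-size adaptation
toward a target acceptance rate, and windowed estimation of the posterior
variances during warmup.  Trajectory lengths are jittered to avoid
resonances.  Divergent transitions (energy error > 1000) are counted and
surfaced, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class ChainResult:
    draws: np.ndarray            # (n_kept, dim)
    accept_rate: float
    divergences: int
    step_size: float
    mass_var: np.ndarray = field(repr=False, default=None)


def _find_initial_step(logp_grad: LogpGrad, x: np.ndarray, var: np.ndarray,
                       rng: np.random.Generator) -> float:
    """Double/halve a trial step size until the one-step acceptance
    probability crosses 1/2 (the usual heuristic)."""
    eps = 0.1
    logp0, grad0 = logp_grad(x)
    p = rng.standard_normal(x.size) / np.sqrt(var)
    h0 = -logp0 + 0.5 * np.sum(p * p * var)

    def energy_after(eps: float) -> float:
        p1 = p + 0.5 * eps * grad0
        x1 = x + eps * p1 * var
        logp1, grad1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * grad1
        return -logp1 + 0.5 * np.sum(p1 * p1 * var)

    h = energy_after(eps)
    if not np.isfinite(h):
        accept = 0.0
    else:
        accept = min(1.0, np.exp(h0 - h))
    direction = 1 if accept > 0.5 else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        h = energy_after(eps)
        accept = 0.0 if not np.isfinite(h) else min(1.0, np.exp(h0 - h))
        if (direction == 1 and accept <= 0.5) or (direction == -1 and accept >= 0.5):
            break
    return eps


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    traj_len: float = 1.2,
    max_leapfrog: int = 64,
) -> ChainResult:
    """Run one HMC chain; returns the ``n_iter - n_warmup`` post-warmup draws."""
    if not 0 < n_warmup < n_iter:
        raise ValueError("need 0 < n_warmup < n_iter")
    x = np.array(x0, dtype=float)
    dim = x.size
    var = np.ones(dim)                       # posterior variance estimate
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite density")

    eps = _find_initial_step(logp_grad, x, var, rng)
    # dual averaging state (Hoffman & Gelman 2014 defaults)
    mu_da = np.log(10.0 * eps)
    h_bar, log_eps_bar, da_count = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # warmup windows: step size only / variance windows / step size only
    w_early = max(1, int(0.15 * n_warmup))
    w_mid = max(w_early + 1, int(0.5 * n_warmup))
    w_late = max(w_mid + 1, int(0.9 * n_warmup))
    welford_n, welford_m, welford_s = 0, np.zeros(dim), np.zeros(dim)

    draws = np.empty((n_iter - n_warmup, dim))
    accepts = 0
    divergences = 0
    kept = 0

    for it in range(n_iter):
        warm = it < n_warmup
        l_nom = int(np.clip(round(traj_len / eps), 1, max_leapfrog))
        l_lo = max(1, int(0.5 * l_nom))
        n_leap = int(rng.integers(l_lo, l_nom + 1))

        p0 = rng.standard_normal(dim) / np.sqrt(var)
        h0 = -logp + 0.5 * np.sum(p0 * p0 * var)
        xp, gp, pp = x, grad, p0
        diverged = False
        pp = pp + 0.5 * eps * gp
        for step in range(n_leap):
            xp = xp + eps * pp * var
            lp, gp = logp_grad(xp)
            if not np.isfinite(lp):
                diverged = True
                break
            pp = pp + (eps if step < n_leap - 1 else 0.5 * eps) * gp
        if not diverged:
            h1 = -lp + 0.5 * np.sum(pp * pp * var)
            delta_h = h0 - h1
            if not np.isfinite(delta_h) or delta_h < -1000.0:
                diverged = True
        if diverged:
            accept_prob = 0.0
        else:
            accept_prob = min(1.0, np.exp(min(0.0, delta_h)))
            if rng.random() < accept_prob:
                x, logp, grad = xp, lp, gp
                if not warm:
                    accepts += 1
        if diverged and not warm:
            divergences += 1

        if warm:
            da_count += 1
            h_bar = (1.0 - 1.0 / (da_count + t0)) * h_bar + (
                target_accept - accept_prob
            ) / (da_count + t0)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w_early <= it < w_late:
                welford_n += 1
                d = x - welford_m
                welford_m += d / welford_n
                welford_s += d * (x - welford_m)
            if it + 1 in (w_mid, w_late) and welford_n > 4:
                var = welford_s / (welford_n - 1) + 1e-8
                welford_n, welford_m, welford_s = 0, np.zeros(dim), np.zeros(dim)
                mu_da = np.log(10.0 * eps)
                h_bar, log_eps_bar, da_count = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[kept] = x
            kept += 1

    n_kept = n_iter - n_warmup
    return ChainResult(
        draws=draws,
        accept_rate=accepts / n_kept,
        divergences=divergences,
        step_size=eps,
        mass_var=var,
    )
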