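"""Numba-compiled likelihood, gradient and simulation kernels.

All kernels operate on packed per-fit arrays (one entry per non-missing
trial, participants concatenated):

* ``env``      — casino index (0/1) identifying the Q-value pair in play;
* ``cell``     — parameter-cell index (environment and, for block-wise
  fits, block) whose parameters govern this trial;
* ``newpair``  — True on the first trial of a (block, casino) machine pair:
  that casino's Q-values reset to 0 before the trial;
* ``choice`` / ``reward`` / ``winning`` — 0/1 trial outcomes;
* ``offsets`` — participant boundaries, ``offsets[i]:offsets[i+1]``.

``theta`` holds bounded parameters with shape (n_sub, n_cells, P); learning
rate-like parameters come first and the inverse temperature is last
(``P - 1``).  Model kinds: 0 = single, 1 = dual, 2 = variable.

Gradients of the per-participant log-likelihood with respect to the bounded
parameters are accumulated by forward-mode differentiation through the
Q-value (and, for the variable models, learning-rate) recursions.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
_LOG_HALF_CAUCHY_NORM = math.log(2.0 / (math.pi * 5.0))
_LOG_STD_NORMAL_NORM = -0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _loglik_grad_theta(kind, theta, env, cell, newpair, choice, reward, offsets,
                       ll_out, grad_out):
    """Per-participant log-likelihood and gradient w.r.t. bounded theta."""
    n_sub, n_cells, P = theta.shape
    n_lr = P - 1
    grad_out[:] = 0.0
    for i in range(n_sub):
        Q = np.zeros((2, 2))
        dQ = np.zeros((2, 2, 2))          # d Q[env, machine] / d lr-param k
        alpha_t = np.zeros(n_cells)
        dalpha = np.zeros((n_cells, 2))   # d alpha_t / d (alpha0, eta)
        alpha_set = np.zeros(n_cells, np.uint8)
        ll = 0.0
        for t in range(offsets[i], offsets[i + 1]):
            e = env[t]
            c = cell[t]
            ch = choice[t]
            r = reward[t]
            if newpair[t]:
                for m in range(2):
                    Q[e, m] = 0.0
                    for k in range(2):
                        dQ[e, m, k] = 0.0
            beta = theta[i, c, P - 1]
            q0 = Q[e, 0]
            q1 = Q[e, 1]
            mx = beta * q0 if q0 > q1 else beta * q1
            z0 = math.exp(beta * q0 - mx)
            z1 = math.exp(beta * q1 - mx)
            Z = z0 + z1
            p0 = z0 / Z
            p1 = z1 / Z
            pch = p0 if ch == 0 else p1
            ll += math.log(pch)
            qch = Q[e, ch]
            qbar = p0 * q0 + p1 * q1
            grad_out[i, c, P - 1] += qch - qbar
            for k in range(n_lr):
                grad_out[i, c, k] += beta * (
                    dQ[e, ch, k] - (p0 * dQ[e, 0, k] + p1 * dQ[e, 1, k])
                )
            pe = r - qch
            if kind == 0:
                a = theta[i, c, 0]
                dQ[e, ch, 0] = (1.0 - a) * dQ[e, ch, 0] + pe
                Q[e, ch] = qch + a * pe
            elif kind == 1:
                ap = theta[i, c, 0]
                an = theta[i, c, 1]
                a = ap if r == 1 else an
                dQ[e, ch, 0] = (1.0 - a) * dQ[e, ch, 0] + (pe if r == 1 else 0.0)
                dQ[e, ch, 1] = (1.0 - a) * dQ[e, ch, 1] + (pe if r == 0 else 0.0)
                Q[e, ch] = qch + a * pe
            else:
                if alpha_set[c] == 0:
                    alpha_t[c] = theta[i, c, 0]
                    dalpha[c, 0] = 1.0
                    dalpha[c, 1] = 0.0
                    alpha_set[c] = 1
                a = alpha_t[c]
                eta = theta[i, c, 1]
                s = 1.0 if r == 1 else -1.0          # sign of pe (Q in [0,1])
                abspe = s * pe
                # learning-rate recursion uses the pre-update Q
                da0 = -eta * s * dQ[e, ch, 0] + (1.0 - eta) * dalpha[c, 0]
                da1 = -eta * s * dQ[e, ch, 1] + (1.0 - eta) * dalpha[c, 1] \
                    + (abspe - a)
                dQ[e, ch, 0] = (1.0 - a) * dQ[e, ch, 0] + pe * dalpha[c, 0]
                dQ[e, ch, 1] = (1.0 - a) * dQ[e, ch, 1] + pe * dalpha[c, 1]
                Q[e, ch] = qch + a * pe
                alpha_t[c] = eta * abspe + (1.0 - eta) * a
                dalpha[c, 0] = da0
                dalpha[c, 1] = da1
        ll_out[i] = ll


@njit(cache=True)
def _pointwise_ll(kind, theta, env, cell, newpair, choice, reward, offsets, out):
    """Per-trial log-likelihood for one bounded theta (no gradients)."""
    n_sub, n_cells, P = theta.shape
    for i in range(n_sub):
        Q = np.zeros((2, 2))
        alpha_t = np.zeros(n_cells)
        alpha_set = np.zeros(n_cells, np.uint8)
        for t in range(offsets[i], offsets[i + 1]):
            e = env[t]
            c = cell[t]
            ch = choice[t]
            r = reward[t]
            if newpair[t]:
                Q[e, 0] = 0.0
                Q[e, 1] = 0.0
            beta = theta[i, c, P - 1]
            q0 = Q[e, 0]
            q1 = Q[e, 1]
            mx = beta * q0 if q0 > q1 else beta * q1
            z0 = math.exp(beta * q0 - mx)
            z1 = math.exp(beta * q1 - mx)
            pch = (z0 if ch == 0 else z1) / (z0 + z1)
            out[t] = math.log(pch)
            qch = Q[e, ch]
            pe = r - qch
            if kind == 0:
                a = theta[i, c, 0]
            elif kind == 1:
                a = theta[i, c, 0] if r == 1 else theta[i, c, 1]
            else:
                if alpha_set[c] == 0:
                    alpha_t[c] = theta[i, c, 0]
                    alpha_set[c] = 1
                a = alpha_t[c]
                eta = theta[i, c, 1]
                alpha_t[c] = eta * abs(pe) + (1.0 - eta) * a
            Q[e, ch] = qch + a * pe


@njit(cache=True)
def _pointwise_ll_draws(kind, thetas, env, cell, newpair, choice, reward,
                        offsets, out):
    """Per-trial log-likelihood for a stack of draws: out is (n_draws, n_obs)."""
    for d in range(thetas.shape[0]):
        _pointwise_ll(kind, thetas[d], env, cell, newpair, choice, reward,
                      offsets, out[d])


@njit(cache=True)
def _simulate(kind, theta, env, cell, newpair, winning, offsets, u,
              choice_out, reward_out):
    """Forward-simulate choices; u are iid Uniform(0,1) per trial."""
    n_sub, n_cells, P = theta.shape
    for i in range(n_sub):
        Q = np.zeros((2, 2))
        alpha_t = np.zeros(n_cells)
        alpha_set = np.zeros(n_cells, np.uint8)
        for t in range(offsets[i], offsets[i + 1]):
            e = env[t]
            c = cell[t]
            if newpair[t]:
                Q[e, 0] = 0.0
                Q[e, 1] = 0.0
            beta = theta[i, c, P - 1]
            q0 = Q[e, 0]
            q1 = Q[e, 1]
            mx = beta * q0 if q0 > q1 else beta * q1
            z0 = math.exp(beta * q0 - mx)
            z1 = math.exp(beta * q1 - mx)
            p0 = z0 / (z0 + z1)
            ch = 0 if u[t] < p0 else 1
            r = 1 if ch == winning[t] else 0
            choice_out[t] = ch
            reward_out[t] = r
            qch = Q[e, ch]
            pe = r - qch
            if kind == 0:
                a = theta[i, c, 0]
            elif kind == 1:
                a = theta[i, c, 0] if r == 1 else theta[i, c, 1]
            else:
                if alpha_set[c] == 0:
                    alpha_t[c] = theta[i, c, 0]
                    alpha_set[c] = 1
                a = alpha_t[c]
                eta = theta[i, c, 1]
                alpha_t[c] = eta * abs(pe) + (1.0 - eta) * a
            Q[e, ch] = qch + a * pe


@njit(cache=True)
def _reward_rate_cells(kind, cellparams, winning, u):
    """Mean reward rate per parameter cell over single-casino blocks.

    ``winning`` and ``u`` are (n_replicates, n_trials); each replicate is one
    fresh block (Q starts at 0, variable learning rate starts at alpha).
    Common random numbers across cells reduce between-cell noise.
    """
    n_cells, P = cellparams.shape
    n_rep, n_trials = winning.shape
    out = np.zeros(n_cells)
    for cidx in range(n_cells):
        beta = cellparams[cidx, P - 1]
        total = 0.0
        for rep in range(n_rep):
            q0 = 0.0
            q1 = 0.0
            alpha_t = cellparams[cidx, 0]
            for t in range(n_trials):
                mx = beta * q0 if q0 > q1 else beta * q1
                z0 = math.exp(beta * q0 - mx)
                z1 = math.exp(beta * q1 - mx)
                p0 = z0 / (z0 + z1)
                ch = 0 if u[rep, t] < p0 else 1
                r = 1.0 if ch == winning[rep, t] else 0.0
                total += r
                qch = q0 if ch == 0 else q1
                pe = r - qch
                if kind == 0:
                    a = cellparams[cidx, 0]
                elif kind == 1:
                    a = cellparams[cidx, 0] if r == 1.0 else cellparams[cidx, 1]
                else:
                    a = alpha_t
                    eta = cellparams[cidx, 1]
                    alpha_t = eta * abs(pe) + (1.0 - eta) * a
                if ch == 0:
                    q0 = qch + a * pe
                else:
                    q1 = qch + a * pe
        out[cidx] = total / (n_rep * n_trials)
    return out


@njit(cache=True)
def _posterior_logp_grad(x, kind, lo, hi, env, cell, newpair, choice, reward,
                         offsets, n_sub, n_cells, P):
    """Joint log-density and gradient of the hierarchical model.

    Sampling-space vector ``x`` = [mu (C*P), log sigma (C*P), z (N*C*P)].
    Individual bounded parameter: theta = lo + (hi - lo) * Phi(mu + sigma*z).
    Priors: mu ~ N(0, 1) (uniform on the bounded scale after the probit
    map), sigma ~ half-Cauchy(0, 5) with log-scale Jacobian, z ~ N(0, 1).
    """
    ncp = n_cells * P
    logp = 0.0
    grad = np.zeros_like(x)
    sig = np.empty(ncp)
    theta = np.empty((n_sub, n_cells, P))
    dth_dxi = np.empty((n_sub, n_cells, P))
    for j in range(ncp):
        mu = x[j]
        ls = x[ncp + j]
        s = math.exp(ls)
        sig[j] = s
        logp += _LOG_STD_NORMAL_NORM - 0.5 * mu * mu
        grad[j] += -mu
        logp += _LOG_HALF_CAUCHY_NORM - math.log1p((s / 5.0) ** 2) + ls
        grad[ncp + j] += 1.0 - 2.0 * s * s / (25.0 + s * s)
    for i in range(n_sub):
        for c in range(n_cells):
            for p in range(P):
                j = c * P + p
                zi = x[2 * ncp + (i * n_cells + c) * P + p]
                logp += _LOG_STD_NORMAL_NORM - 0.5 * zi * zi
                grad[2 * ncp + (i * n_cells + c) * P + p] += -zi
                xi = x[j] + sig[j] * zi
                Phi = 0.5 * math.erfc(-xi / _SQRT2)
                theta[i, c, p] = lo[p] + (hi[p] - lo[p]) * Phi
                dth_dxi[i, c, p] = (hi[p] - lo[p]) * _INV_SQRT_2PI * math.exp(
                    -0.5 * xi * xi
                )
    ll = np.empty(n_sub)
    gtheta = np.empty((n_sub, n_cells, P))
    _loglik_grad_theta(kind, theta, env, cell, newpair, choice, reward,
                       offsets, ll, gtheta)
    for i in range(n_sub):
        logp += ll[i]
        for c in range(n_cells):
            for p in range(P):
                j = c * P + p
                zi = x[2 * ncp + (i * n_cells + c) * P + p]
                g = gtheta[i, c, p] * dth_dxi[i, c, p]
                grad[j] += g
                grad[ncp + j] += g * sig[j] * zi
                grad[2 * ncp + (i * n_cells + c) * P + p] += g * sig[j]
    return logp, grad
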