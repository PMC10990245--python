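import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtr

from conftest import make_trials
from volbandit.hierarchy import (
    HierarchicalModel,
    build_model,
    posterior_prob_greater,
    probit_to_bounds,
    sample_posterior,
)
from volbandit.hmc import sample_chain
from volbandit.models import ModelSpec, ParameterSet, pointwise_loglik


class TestProbitTransform:
    def test_midpoint(self):
        assert probit_to_bounds(0.0, 0.0, 10.0) == pytest.approx(5.0)

    def test_monotone_limits(self):
        assert probit_to_bounds(40.0, 0.0, 1.0) == pytest.approx(1.0)
        assert probit_to_bounds(-40.0, 0.0, 1.0) == pytest.approx(0.0)
        xs = probit_to_bounds(np.linspace(-3, 3, 50), 0.0, 1.0)
        assert np.all(np.diff(xs) > 0)

    def test_normal_quantile(self):
        assert probit_to_bounds(1.6449, 0.0, 1.0) == pytest.approx(0.95, abs=1e-4)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            probit_to_bounds(0.0, 1.0, 1.0)


def _fixture_two_participants():
    frames = []
    rng = np.random.default_rng(21)
    for pid in range(2):
        env = ["stable", "volatile"] * 2
        choices = list(rng.integers(2, size=4))
        winning = list(rng.integers(2, size=4))
        rewards = [float(c == w) for c, w in zip(choices, winning)]
        df = make_trials(env, choices=choices, rewards=rewards, winning=winning)
        df["participant_id"] = pid
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestJointDensity:
    def test_matches_term_by_term_composition(self):
        """The joint log-density equals priors plus likelihood composed by
        hand from scipy distributions and the sequential likelihood."""
        data = _fixture_two_participants()
        spec = ModelSpec(True, "dual")
        model = build_model(data, spec)
        rng = np.random.default_rng(22)
        x = rng.normal(size=model.dim)

        ncp = model.C * model.P
        mu = x[:ncp].reshape(model.C, model.P)
        log_sig = x[ncp : 2 * ncp].reshape(model.C, model.P)
        sig = np.exp(log_sig)
        z = x[2 * ncp :].reshape(model.N, model.C, model.P)

        expected = 0.0
        expected += stats.norm.logpdf(mu).sum()
        expected += stats.halfcauchy(scale=5).logpdf(sig).sum() + log_sig.sum()
        expected += stats.norm.logpdf(z).sum()
        for i, pid in enumerate(model.participants):
            values = {}
            for c, cell in enumerate(model.cells):
                blk = {}
                for p, name in enumerate(model.param_names):
                    lo, hi = model.bounds_of(name)
                    blk[name] = lo + (hi - lo) * float(
                        ndtr(mu[c, p] + sig[c, p] * z[i, c, p])
                    )
                values[cell] = blk
            pset = ParameterSet(spec, values)
            ll = pointwise_loglik(data[data["participant_id"] == pid], spec, pset)
            expected += np.nansum(ll)

        assert model.logp(x) == pytest.approx(expected, abs=1e-9)

    def test_multiplicity_of_cells(self):
        data = _fixture_two_participants()
        assert build_model(data, ModelSpec(True, "single")).cells == [
            "stable", "volatile",
        ]
        assert build_model(data, ModelSpec(False, "single")).cells == ["all"]

    def test_empty_cell_rejected(self):
        data = _fixture_two_participants()
        unbalanced = data[
            ~((data["participant_id"] == 1) & (data["environment"] == "volatile"))
        ]
        with pytest.raises(ValueError, match="no trials in cell"):
            build_model(unbalanced, ModelSpec(True, "single"))

    def test_mixed_phases_rejected(self):
        data = _fixture_two_participants()
        other = data.copy()
        other["phase"] = "control"
        with pytest.raises(ValueError, match="one phase"):
            build_model(pd.concat([data, other]), ModelSpec(False, "single"))

    def test_gradient_matches_finite_differences(self):
        data = _fixture_two_participants()
        model = build_model(data, ModelSpec(True, "variable"))
        rng = np.random.default_rng(23)
        x = 0.3 * rng.normal(size=model.dim)
        _, g = model.logp_grad(x)
        eps = 1e-6
        for i in rng.choice(model.dim, size=10, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (model.logp(xp) - model.logp(xm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-5, rel=1e-4)


class TestSampler:
    def test_conjugate_gaussian_target(self):
        """On a known Gaussian target, HMC recovers mean and SD."""
        mean = np.array([3.0, -1.0])
        sd = np.array([2.0, 0.5])

        def logp_grad(x):
            z = (x - mean) / sd
            return float(-0.5 * np.sum(z * z)), -z / sd

        res = sample_chain(
            logp_grad, np.zeros(2), n_iter=4000, n_warmup=1000,
            rng=np.random.default_rng(3),
        )
        draws = res.draws
        ess_floor = 200.0
        for j in range(2):
            mcse = sd[j] / math.sqrt(ess_floor)
            assert abs(draws[:, j].mean() - mean[j]) < 3 * mcse
            assert abs(draws[:, j].std() - sd[j]) < 0.15 * sd[j]

    def test_same_seed_same_draws(self, dual_dataset):
        data, spec, _ = dual_dataset
        small = data[data["participant_id"] < 3]
        model = build_model(small, spec)
        a = sample_posterior(model, n_chains=2, n_iter=120, n_burn_in=60, seed=5)
        b = sample_posterior(model, n_chains=2, n_iter=120, n_burn_in=60, seed=5)
        assert np.array_equal(a.draws, b.draws)

    def test_default_settings_retain_12000_draws(self):
        df = make_trials(
            ["stable", "volatile"] * 3,
            choices=[0, 1, 0, 0, 1, 1],
            rewards=[1.0, 0.0, 1.0, 1.0, 0.0, 1.0],
            winning=[0, 0, 0, 0, 0, 1],
        )
        model = build_model(df, ModelSpec(False, "single"))
        post = sample_posterior(model, seed=1, max_leapfrog=16)
        assert post.n_draws == 12000
        assert post.draws.shape[:2] == (4, 3000)

    def test_bounded_draws_respect_bounds(self, dual_fit):
        post, _ = dual_fit
        for cell in ("stable", "volatile"):
            for name, hi in (("alpha_pos", 1.0), ("alpha_neg", 1.0), ("beta", 10.0)):
                d = post.group_mean_draws(name, cell)
                assert d.min() >= 0.0 and d.max() <= hi

    def test_recovers_group_means(self, dual_fit, dual_dataset):
        post, _ = dual_fit
        _, _, pop = dual_dataset
        for cell in ("stable", "volatile"):
            for name in ("alpha_neg", "beta"):
                truth = np.mean([pop[p].values[cell][name] for p in pop])
                est = post.group_mean_draws(name, cell).mean()
                scale = 10.0 if name == "beta" else 1.0
                assert abs(est - truth) < 0.2 * scale


class TestContrasts:
    def test_posterior_prob_greater(self):
        rng = np.random.default_rng(31)
        b = rng.normal(size=1000)
        assert posterior_prob_greater(b + 1.0, b) == 1.0
        sym = posterior_prob_greater(rng.normal(size=20000), rng.normal(size=20000))
        assert abs(sym - 0.5) < 0.02
        with pytest.raises(ValueError):
            posterior_prob_greater(np.zeros(3), np.zeros(4))

    def test_volatile_rates_higher(self, dual_fit):
        """Data generated with higher volatile learning rates yield a
        volatile > stable posterior contrast well above one half."""
        post, _ = dual_fit
        p = posterior_prob_greater(
            post.group_mean_draws("alpha_neg", "volatile"),
            post.group_mean_draws("alpha_neg", "stable"),
        )
        assert p > 0.8


class TestBlockwise:
    def test_single_block_equals_plain_fit(self, dual_dataset):
        data, spec, _ = dual_dataset
        one_block = data[(data["block"] == 0) & (data["participant_id"] < 4)]
        plain = build_model(one_block, spec)
        byblock = build_model(one_block, spec, by_block=True)
        assert byblock.cells == [(0, "stable"), (0, "volatile")]
        a = sample_posterior(plain, n_chains=1, n_iter=100, n_burn_in=50, seed=7)
        b = sample_posterior(byblock, n_chains=1, n_iter=100, n_burn_in=50, seed=7)
        assert np.array_equal(a.draws, b.draws)

    def test_recovers_growing_gap(self):
        """Data whose volatile-vs-stable learning-rate gap widens from the
        first to the second block yield a high environment x block
        interaction probability and a wider per-block posterior gap."""
        from volbandit.hierarchy import blockwise_fit, interaction_contrast
        from volbandit.models import simulate_choices
        from volbandit.studies import sample_population
        from volbandit.task import generate_participants, learning_phase

        rng = np.random.default_rng(71)
        spec = ModelSpec(True, "dual")
        phase = learning_phase(2, 240, stable_p=0.75)
        data = generate_participants(phase, 12, rng)
        sds = {e: {"alpha_pos": 0.1, "alpha_neg": 0.1, "beta": 1.0}
               for e in ("stable", "volatile")}

        def means(gap):
            return {
                "stable": {"alpha_pos": 0.45 - gap / 2, "alpha_neg": 0.45 - gap / 2,
                           "beta": 4.0},
                "volatile": {"alpha_pos": 0.45 + gap / 2, "alpha_neg": 0.45 + gap / 2,
                             "beta": 4.0},
            }

        frames = []
        for block, gap in ((0, 0.0), (1, 0.45)):
            pop = sample_population(spec, means(gap), sds, 12, rng)
            frames.append(
                simulate_choices(data[data["block"] == block], spec, pop, rng)
            )
        sim = pd.concat(frames, ignore_index=True)
        post = blockwise_fit(
            sim, spec, n_chains=2, n_iter=400, n_burn_in=180, seed=3,
            traj_len=1.6,
        )

        def gap_of(block):
            g = np.zeros(post.n_draws)
            for p in ("alpha_pos", "alpha_neg"):
                g += post.group_mean_draws(p, (block, "volatile")) - \
                    post.group_mean_draws(p, (block, "stable"))
            return g.mean() / 2

        assert gap_of(1) > gap_of(0)
        assert interaction_contrast(post, 0, 1) > 0.9

    def test_blockwise_cells_replicated(self, dual_dataset):
        data, spec, _ = dual_dataset
        model = build_model(data[data["participant_id"] < 3], spec, by_block=True)
        assert len(model.cells) == 2 * data["block"].nunique()


class TestInteractionContrast:
    class _StubModel:
        def __init__(self):
            self.spec = ModelSpec(True, "dual")
            self.env_labels = ["stable", "volatile"]
            self.param_names = ("alpha_pos", "alpha_neg", "beta")
            self.cells = [(b, e) for b in (0, 1) for e in self.env_labels]
            self.P = 3
            self.C = 4

        def mu_index(self, cell, param):
            return self.cells.index(cell) * self.P + self.param_names.index(param)

        def sigma_index(self, cell, param):
            return self.C * self.P + self.mu_index(cell, param)

        def bounds_of(self, param):
            return (0.0, 10.0) if param == "beta" else (0.0, 1.0)

    def _draws_from_mu(self, mus):
        # mus: (n_draws, C*P) raw group means; pad sigma/z with zeros
        from volbandit.hierarchy import PosteriorDraws

        stub = self._StubModel()
        n = mus.shape[0]
        draws = np.zeros((1, n, 2 * stub.C * stub.P))
        draws[0, :, : stub.C * stub.P] = mus
        return PosteriorDraws(model=stub, draws=draws)

    def test_shift_gives_probability_one(self):
        from volbandit.hierarchy import interaction_contrast

        stub = self._StubModel()
        rng = np.random.default_rng(41)
        mus = rng.normal(size=(200, stub.C * stub.P))
        # make the block-1 volatile rates exceed block-1 stable by a margin
        for param in ("alpha_pos", "alpha_neg"):
            i_s = stub.mu_index((1, "stable"), param)
            i_v = stub.mu_index((1, "volatile"), param)
            i0s = stub.mu_index((0, "stable"), param)
            i0v = stub.mu_index((0, "volatile"), param)
            mus[:, i0v] = mus[:, i0s]            # no gap in block 0
            mus[:, i_v] = mus[:, i_s] + 1.0      # clear gap in block 1
        post = self._draws_from_mu(mus)
        assert interaction_contrast(post, 0, 1) == 1.0

    def test_exchangeable_blocks_near_half(self):
        from volbandit.hierarchy import interaction_contrast

        stub = self._StubModel()
        rng = np.random.default_rng(42)
        mus = rng.normal(size=(4000, stub.C * stub.P))
        post = self._draws_from_mu(mus)
        assert abs(interaction_contrast(post, 0, 1) - 0.5) < 0.05

    def test_wrong_model_rejected(self, dual_dataset):
        from volbandit.hierarchy import interaction_contrast

        stub = self._StubModel()
        stub.spec = ModelSpec(True, "single")
        post = self._draws_from_mu(np.zeros((10, stub.C * stub.P)))
        post.model = stub
        with pytest.raises(ValueError):
            interaction_contrast(post, 0, 1)


class TestShrinkage:
    def test_sparse_participant_pulled_toward_group(self, dual_dataset):
        """An individual with few trials shrinks toward the group mean
        relative to its individual maximum-likelihood estimate."""
        from scipy.optimize import minimize_scalar

        data, _, _ = dual_dataset
        spec = ModelSpec(False, "single")
        # participant 0 keeps only 30 trials
        keep = data[
            (data["participant_id"] > 0) | (data["trial"] < 30)
        ].copy()
        model = build_model(keep, spec)
        post = sample_posterior(
            model, n_chains=2, n_iter=300, n_burn_in=150, seed=17, traj_len=1.6
        )
        means = post.individual_posterior_means()
        alpha_post = float(
            means[
                (means["participant_id"] == 0) & (means["parameter"] == "alpha")
            ]["mean"].iloc[0]
        )
        group = float(post.group_mean_draws("alpha", "all").mean())
        sparse = keep[keep["participant_id"] == 0]
        beta_post = float(
            means[
                (means["participant_id"] == 0) & (means["parameter"] == "beta")
            ]["mean"].iloc[0]
        )

        def nll(alpha):
            pset = ParameterSet(spec, {"alpha": alpha, "beta": beta_post})
            return -np.nansum(pointwise_loglik(sparse, spec, pset))

        mle = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded").x
        assert abs(alpha_post - group) <= abs(mle - group) + 0.02
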