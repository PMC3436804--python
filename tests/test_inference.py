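"""Likelihood, MLE, adaptive-Metropolis sampling and KDE entropy."""

import numpy as np
import pytest
from scipy import stats

import trajoed as tj
from trajoed.data import Dataset, Measurement
from trajoed.inference import (
    MleResult,
    PosteriorSample,
    adaptive_metropolis,
    estimate_entropy,
    gelman_rubin,
)

LOG_SQRT = 0.5 * np.log(2 * np.pi)


def decay_dataset(model, experiment, theta, sigma, seed, times=None, n_rep=3):
    times = list(experiment.time_grid[:6]) if times is None else times
    ms = tj.generate_data(
        model, theta, experiment, [("x", t) for t in times],
        sigma=sigma, n_replicates=n_rep, seed=seed,
    )
    return Dataset(ms, sigma_true=sigma)


class TestLogLikelihood:
    def test_perfect_fit_reaches_density_maximum(self, decay_model, decay_experiment):
        """Noiseless data at the generating theta: every replicate sits at
        the mode and contributes -log(sigma sqrt(2 pi))."""
        theta = np.array([-0.3])
        ds = decay_dataset(decay_model, decay_experiment, theta, 0.0, 1)
        sigma = 0.15
        ll = tj.log_likelihood(theta, ds, sigma, decay_model,
                               {1: decay_experiment})
        expected = ds.n_values * (-(np.log(sigma) + LOG_SQRT))
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_one_sigma_offset_replicate(self, decay_model, decay_experiment):
        sigma = 0.2
        theta = np.array([-0.3])
        y = np.exp(-(10 ** -0.3) * 1.0)
        z = y * 10 ** sigma  # log10 residual of exactly one sigma
        ds = Dataset([Measurement(1, "x", 1.0, (float(z),))])
        ll = tj.log_likelihood(theta, ds, sigma, decay_model,
                               {1: decay_experiment})
        assert ll == pytest.approx(-(np.log(sigma) + LOG_SQRT) - 0.5, abs=1e-8)

    def test_additivity_over_datasets(self, decay_model, decay_experiment):
        """Independence: the likelihood of two concatenated datasets is the
        sum of the parts (kept exact by separating experiments so the
        solver sees identical time requests either way)."""
        theta = np.array([-0.1])
        exp2 = tj.Experiment(2, decay_experiment.input,
                             decay_experiment.outputs,
                             decay_experiment.time_grid)
        d1 = decay_dataset(decay_model, decay_experiment, theta, 0.1, 1,
                           times=[0.25, 0.5])
        ms2 = tj.generate_data(decay_model, theta, exp2,
                               [("x", 1.0), ("x", 2.0)], 0.1, seed=2)
        d2 = Dataset(ms2)
        both = Dataset(d1.measurements + d2.measurements)
        emap = {1: decay_experiment, 2: exp2}
        ll = tj.log_likelihood(theta, both, 0.1, decay_model, emap)
        ll12 = (tj.log_likelihood(theta, d1, 0.1, decay_model, emap)
                + tj.log_likelihood(theta, d2, 0.1, decay_model, emap))
        assert ll == pytest.approx(ll12, rel=1e-12)

    def test_simulation_failure_maps_to_minus_inf(self, decay_experiment):
        model = tj.OdeModel(
            name="blowup", state_names=("x",), output_names=("x",),
            param_names=("k",), fixed_params={},
            vector_field=lambda x, u, k, t: k * x ** 3,
            output_map=lambda s: np.asarray(s),
            initial_state=lambda u, k: np.array([10.0]),
        )
        ds = Dataset([Measurement(1, "x", 1.0, (1.0,))])
        ll = tj.log_likelihood(np.array([3.0]), ds, 0.1, model,
                               {1: decay_experiment})
        assert ll == -np.inf


class TestFindMle:
    def test_noiseless_decay_recovers_truth(self, decay_model, decay_experiment):
        theta_true = np.array([-0.3])
        ds = decay_dataset(decay_model, decay_experiment, theta_true, 0.0, 1)
        prior = tj.Prior((-2.3,), (1.7,))
        res = tj.find_mle(ds, 0.1, decay_model, prior, {1: decay_experiment},
                          n_starts=3, seed=0)
        assert res.theta[0] == pytest.approx(theta_true[0], abs=1e-4)

    def test_noisy_decay_matches_grid_search_oracle(self, decay_model, decay_experiment):
        theta_true = np.array([-0.3])
        ds = decay_dataset(decay_model, decay_experiment, theta_true, 0.2, 5)
        prior = tj.Prior((-2.3,), (1.7,))
        emap = {1: decay_experiment}
        res = tj.find_mle(ds, 0.2, decay_model, prior, emap, n_starts=3, seed=0)
        grid = np.linspace(-2.3, 1.7, 10_000)
        lls = [tj.log_likelihood(np.array([g]), ds, 0.2, decay_model, emap)
               for g in grid]
        assert res.theta[0] == pytest.approx(grid[int(np.argmax(lls))],
                                             abs=2 * (grid[1] - grid[0]))


class TestAdaptiveMetropolis:
    def test_gaussian_target_moments(self):
        """2-D correlated Gaussian: sample mean within 5% of scale, sample
        covariance within 5% of the target's."""
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        prec = np.linalg.inv(cov)

        def logt(x):
            d = x - mean
            return -0.5 * d @ prec @ d

        chains, _, acc = adaptive_metropolis(
            logt, np.zeros((4, 2)), 30_000, seed=3
        )
        draws = chains[:, 10_000:].reshape(-1, 2)
        scale = np.sqrt(np.diag(cov))
        assert np.allclose(draws.mean(axis=0), mean, atol=0.05 * scale)
        assert np.allclose(np.cov(draws.T), cov, rtol=0.05, atol=0.05)
        # acceptance settles in the healthy random-walk range
        assert np.all((acc > 0.1) & (acc < 0.5))

    def test_prior_only_posterior_is_uniform(self):
        """With no data the posterior equals the log-uniform prior: thinned
        marginal histograms pass a chi-square uniformity test."""
        prior = tj.Prior((-2.0, 0.0), (2.0, 4.0))

        def logt(x):
            return prior.log_pdf(x)

        chains, _, _ = adaptive_metropolis(
            logt, np.array([[0.0, 2.0]] * 4), 40_000, seed=4
        )
        draws = chains[:, 20_000::40].reshape(-1, 2)  # heavy thinning
        for j, (lo, up) in enumerate([(-2, 2), (0, 4)]):
            counts, _ = np.histogram(draws[:, j], bins=8, range=(lo, up))
            _, p = stats.chisquare(counts)
            assert p > 0.01

    def test_infeasible_start_rejected(self):
        with pytest.raises(ValueError):
            adaptive_metropolis(lambda x: -np.inf, np.zeros((2, 1)), 100)


class TestSamplePosterior:
    def test_decay_posterior_concentrates_near_truth(self, decay_model, decay_experiment):
        theta_true = np.array([-0.3])
        ds = decay_dataset(decay_model, decay_experiment, theta_true, 0.05, 2)
        prior = tj.Prior((-2.3,), (1.7,))
        post = tj.sample_posterior(
            ds, 0.05, decay_model, prior, {1: decay_experiment},
            n_chains=3, n_steps=2000, seed=0, rhat_threshold=1.1,
        )
        assert post.n >= 1000
        assert abs(np.median(post.draws) - theta_true[0]) < 0.05
        assert all(prior.contains(t) for t in post.draws[::100])

    def test_convergence_failure_raises(self, decay_model, decay_experiment):
        """A bimodal, widely separated target with far-apart starts cannot
        pass screening at tiny chain lengths."""

        def run():
            prior = tj.Prior((-50.0,), (50.0,))
            ds = decay_dataset(decay_model, decay_experiment,
                               np.array([-0.3]), 0.05, 2)
            return tj.sample_posterior(
                ds, 1e-6, decay_model, prior, {1: decay_experiment},
                n_chains=2, n_steps=300, seed=1, rhat_threshold=1.01,
                init="prior", adapt_start=1000,
            )

        with pytest.raises(RuntimeError):
            run()

    def test_allow_partial_returns_flagged_sample(self, decay_model, decay_experiment):
        """When screening cannot pass, allow_partial returns the best
        chain subset with every chain flagged non-converged instead of
        raising."""
        prior = tj.Prior((-50.0,), (50.0,))
        ds = decay_dataset(decay_model, decay_experiment,
                           np.array([-0.3]), 0.05, 2)
        post = tj.sample_posterior(
            ds, 1e-6, decay_model, prior, {1: decay_experiment},
            n_chains=2, n_steps=300, seed=1, rhat_threshold=1.0001,
            init="prior", adapt_start=1000, max_extensions=0,
            allow_partial=True,
        )
        assert post.n >= 1
        assert not any(post.converged.values())
        assert post.diagnostics["partial"] is True

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        ps = PosteriorSample(
            draws=rng.normal(size=(50, 3)),
            log_posterior=rng.normal(size=50),
            chain_ids=np.repeat([0, 1], 25),
            converged={0: True, 1: True},
            diagnostics={"rhat": [1.0, 1.0, 1.0]},
            param_names=("a", "b", "c"),
        )
        ps.to_csv(tmp_path / "p.csv", sidecar=str(tmp_path / "p.json"))
        back = PosteriorSample.from_csv(tmp_path / "p.csv",
                                        sidecar=str(tmp_path / "p.json"))
        assert np.allclose(back.draws, ps.draws)
        assert back.param_names == ("a", "b", "c")
        assert back.converged == {0: True, 1: True}


class TestGelmanRubin:
    def test_identical_distributions_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 5000, 2))
        assert np.all(gelman_rubin(chains) < 1.02)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 2000, 1))
        chains[1] += 5.0
        assert gelman_rubin(chains)[0] > 2.0


class TestEstimateEntropy:
    def test_uniform_box_entropy(self):
        """12-D prior-box sample vs the closed-form d*ln(width)."""
        rng = np.random.default_rng(9)
        draws = rng.uniform(-2, 2, size=(30_000, 12))
        sup = (np.full(12, -2.0), np.full(12, 2.0))
        S = estimate_entropy(draws, n_eval=500, seed=0, support=sup)
        assert S == pytest.approx(12 * np.log(4), abs=0.5)

    def test_gaussian_entropy(self):
        rng = np.random.default_rng(10)
        draws = rng.standard_normal((50_000, 2))
        S = estimate_entropy(draws, n_eval=1000, seed=0)
        assert S == pytest.approx(np.log(2 * np.pi * np.e), abs=0.1)

    def test_scaling_law_tenfold_shrink(self):
        rng = np.random.default_rng(11)
        d = 3
        draws = rng.standard_normal((20_000, d))
        drop = estimate_entropy(draws, seed=0) - estimate_entropy(
            draws * 0.1, seed=0
        )
        assert drop == pytest.approx(d * np.log(10), abs=0.1)

    def test_bias_decreases_with_sample_size(self):
        rng = np.random.default_rng(12)
        target = np.log(2 * np.pi * np.e)
        big = rng.standard_normal((60_000, 2))
        biases = [
            abs(estimate_entropy(big[:n], n_eval=min(n, 1000), seed=0) - target)
            for n in (600, 6000, 60_000)
        ]
        assert biases[0] > biases[1] > biases[2]

    def test_degenerate_dimension_floored(self):
        rng = np.random.default_rng(13)
        draws = np.column_stack([rng.standard_normal(500), np.ones(500)])
        S = estimate_entropy(draws, n_eval=200, seed=0)
        assert np.isfinite(S)

    def test_agrees_with_scipy_kde_in_1d(self):
        """Dual route: in 1-D our product KDE uses the same Silverman
        factor as scipy.stats.gaussian_kde; the resulting entropy
        estimates agree closely."""
        rng = np.random.default_rng(14)
        x = rng.standard_normal(5000)
        ours = estimate_entropy(x[:, None], n_eval=1000, seed=0)
        kde = stats.gaussian_kde(x, bw_method="silverman")
        theirs = -np.mean(np.log(kde(x[:1000])))
        assert ours == pytest.approx(theirs, abs=0.05)


class TestMleNonUniqueness:
    def test_sparse_golgi_data_yields_unstable_mle(self, golgi_model, golgi_catalogue):
        """With sparse data the 12-parameter model is sloppy: restarts end
        far apart in parameter space at comparable likelihood."""
        from trajoed.golgi import TRUE_THETA

        emap = {e.index: e for e in golgi_catalogue}
        init = emap[14]
        reqs = [(o, t) for o in init.outputs[:3] for t in (24.0, 72.0)]
        ds = Dataset(
            tj.generate_data(golgi_model, TRUE_THETA, init, reqs, 0.15, seed=3),
            sigma_true=0.15,
        )
        prior = tj.Prior.centered(TRUE_THETA)
        res = tj.find_mle(ds, 0.15, golgi_model, prior, emap,
                          n_starts=4, seed=1, maxiter=60)
        assert isinstance(res, MleResult)
        good = [(th, ll) for th, ll in res.all_optima
                if ll > res.log_likelihood - 10.0]
        assert len(good) >= 2
        sep = max(
            np.max(np.abs(a[0] - b[0]))
            for i, a in enumerate(good)
            for b in good[i + 1:]
        )
        assert sep > 0.5
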