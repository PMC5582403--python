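"""Priors, proposals, burn-in, and the Metropolis sampler."""

import numpy as np
import pytest
import scipy.stats as st

import burstfit.inference as inf
from burstfit import (
    Chain,
    PriorSpec,
    StateSpace,
    default_sigma,
    detect_burn_in,
    fit_mcmc,
    log_prior,
    metropolis_run,
    moment_init,
    posterior_summary,
    propose,
    simulate_snapshots,
)
from burstfit.selection import candidate_parameter_sets

FREE = ("k1_U", "k1_S", "k0", "mu0", "mu1")


class TestPrior:
    def test_flat_inside_box(self):
        prior = PriorSpec()
        assert log_prior(np.array([0.1, 1.0, 0.1, 0.01, 2.0]), FREE, prior) == 0.0

    def test_below_floor_rejected(self):
        prior = PriorSpec()
        theta = np.array([1e-9, 1.0, 0.1, 0.01, 2.0])
        assert log_prior(theta, FREE, prior) == -np.inf

    def test_transcription_cap(self):
        prior = PriorSpec(mu_max=18.0)
        theta = np.array([0.1, 1.0, 0.1, 0.01, 20.0])
        assert log_prior(theta, FREE, prior) == -np.inf
        # switching rates are not capped
        theta = np.array([100.0, 1.0, 0.1, 0.01, 2.0])
        assert log_prior(theta, FREE, prior) == 0.0

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            PriorSpec(lower_bound=1.0, mu_max=0.5)


class TestPropose:
    def test_zero_sigma_returns_current(self, rng):
        theta = np.array([1.0, 2.0])
        out = propose(theta, np.zeros((2, 2)), rng)
        assert np.array_equal(out, theta)

    def test_default_sigma_scales(self):
        sig = default_sigma(FREE)
        assert np.diag(sig) == pytest.approx([1e-5, 1e-5, 1e-5, 1e-5, 1e-3])

    def test_sample_covariance_matches(self, rng):
        sigma = np.diag([1e-5, 1e-3])
        draws = np.array([propose(np.zeros(2), sigma, rng) for _ in range(30_000)])
        cov = np.cov(draws.T)
        assert np.diag(cov) == pytest.approx(np.diag(sigma), rel=0.05)

    def test_non_psd_rejected(self, rng):
        with pytest.raises(ValueError):
            propose(np.zeros(2), np.array([[1.0, 0.0], [0.0, -1.0]]), rng)


def _mock_chain(loglik, thetas=None):
    loglik = np.asarray(loglik, float)
    T = len(loglik)
    if thetas is None:
        thetas = np.zeros((T, 1))
    return Chain(
        thetas=thetas,
        loglik=loglik,
        accepted=np.ones(T, bool),
        free_names=("x",) if thetas.shape[1] == 1 else tuple(f"x{i}" for i in range(thetas.shape[1])),
        sigma=np.eye(thetas.shape[1]),
        seed=0,
    )


class TestBurnIn:
    def test_constant_loglik_has_no_burn_in(self):
        assert detect_burn_in(_mock_chain(np.full(200, -50.0))) == 0

    def test_band_entry_rule(self):
        """Burn-in ends at the first index within 0.5% of the maximum."""
        ll = np.array([-200.0, -150.0, -101.0, -100.4, -100.1] + [-100.0] * 195)
        assert detect_burn_in(_mock_chain(ll)) == 3  # threshold -100.5

    def test_monotone_climb_stays_in_band(self):
        t = np.arange(400)
        ll = -100.0 - 400.0 * np.exp(-t / 20.0)  # plateaus in the first half
        idx = detect_burn_in(_mock_chain(ll))
        threshold = -100 - 0.005 * 100
        assert np.all(ll[idx:] >= threshold)
        assert ll[idx - 1] < threshold

    def test_capped_at_half(self):
        ll = np.concatenate([np.full(900, -1000.0), np.full(100, -100.0)])
        with pytest.warns(RuntimeWarning):
            assert detect_burn_in(_mock_chain(ll)) == 500


class TestPosteriorSummary:
    def test_degenerate_chain(self):
        chain = _mock_chain(np.zeros(50), thetas=np.full((50, 1), 3.14))
        s = posterior_summary(chain)
        assert s.loc["x", "mean"] == pytest.approx(3.14)
        assert s.loc["x", "sd"] == pytest.approx(0.0, abs=1e-12)
        assert s.loc["x", "ci95_low"] == pytest.approx(s.loc["x", "ci95_high"])

    def test_normal_chain_moments(self, rng):
        x = rng.normal(5.0, 1.0, size=(20_000, 1))
        s = posterior_summary(_mock_chain(np.zeros(len(x)), thetas=x))
        se = 1.0 / np.sqrt(len(x))
        assert abs(s.loc["x", "mean"] - 5.0) <= 3 * se
        assert s.loc["x", "sd"] == pytest.approx(1.0, rel=0.05)

    def test_empty_segment_rejected(self):
        chain = _mock_chain(np.zeros(10))
        chain.burn_in_index = 10
        with pytest.raises(ValueError):
            posterior_summary(chain)


@pytest.fixture(scope="module")
def tiny_fit_setup(k1_preset):
    space = StateSpace(M=80, p=3)
    data = simulate_snapshots(k1_preset, space, (0, 5, 15, 25), 200, seed=21)
    template = candidate_parameter_sets(delta=0.05, subsets=(("k1",),))["k1_stim"]
    return data, template, space


class TestMetropolis:
    def test_same_seed_is_bitwise_identical(self, tiny_fit_setup):
        data, template, space = tiny_fit_setup
        init = moment_init(data, template)
        kw = dict(prior=PriorSpec(), sigma=default_sigma(init.free_names), T=150, seed=9)
        c1 = metropolis_run(data, init, space, **kw)
        c2 = metropolis_run(data, init, space, **kw)
        assert np.array_equal(c1.thetas, c2.thetas)
        assert np.array_equal(c1.loglik, c2.loglik)
        assert np.array_equal(c1.accepted, c2.accepted)

    def test_rejected_steps_repeat_state(self, tiny_fit_setup):
        data, template, space = tiny_fit_setup
        init = moment_init(data, template)
        chain = metropolis_run(
            data, init, space, sigma=default_sigma(init.free_names), T=200, seed=4
        )
        rejected = ~chain.accepted[1:]
        same = np.all(chain.thetas[1:][rejected] == chain.thetas[:-1][rejected], axis=1)
        assert same.all()

    def test_infinite_start_rejected(self, tiny_fit_setup):
        data, template, space = tiny_fit_setup
        bad = template.with_free_vector(np.array([17.0, 17.0, 17.0, 17.0, 17.0]))
        with pytest.raises(ValueError, match="starting point"):
            metropolis_run(data, bad, space, T=10, seed=0)

    def test_uniform_box_stationary_law(self, tiny_fit_setup, monkeypatch):
        """With a constant likelihood the posterior is the flat prior: the
        mu1 marginal must converge to Uniform(0, mu_max)."""
        data, template, space = tiny_fit_setup
        monkeypatch.setattr(inf, "log_likelihood", lambda *a, **k: 0.0)
        prior = PriorSpec(mu_max=18.0)
        init = template.with_free_vector(np.array([0.5, 0.5, 0.5, 9.0, 9.0]))
        sigma = np.diag([0.25, 0.25, 0.25, 4.0, 4.0])
        chain = metropolis_run(data, init, space, prior=prior, sigma=sigma, T=200_000, seed=2)
        mu1 = chain.thetas[20_000::20, 4]
        ks = st.kstest(mu1, st.uniform(0, 18).cdf).statistic
        assert ks <= 0.05

    def test_two_level_posterior_occupancy(self, tiny_fit_setup, monkeypatch):
        """Piecewise-constant two-level posterior: occupancy of the high
        region matches its posterior mass within Monte-Carlo error."""
        data, template, space = tiny_fit_setup
        q = 0.75  # relative mass of the low-mu1 half of the box
        def two_level(d, params, s):
            return np.log(q) if params.values_U["mu1"] < 9.0 else np.log(1 - q)
        monkeypatch.setattr(inf, "log_likelihood", two_level)
        init = template.with_free_vector(np.array([0.5, 0.5, 0.5, 9.0, 5.0]))
        sigma = np.diag([0.01, 0.01, 0.01, 0.01, 9.0])
        chain = metropolis_run(data, init, space, prior=PriorSpec(), sigma=sigma, T=60_000, seed=8)
        occ = np.mean(chain.thetas[5000:, 4] < 9.0)
        assert occ == pytest.approx(q, abs=0.04)


class TestFitPipeline:
    def test_posterior_concentrates_with_more_cells(self, k1_preset):
        space = StateSpace(M=80, p=3)
        template = candidate_parameter_sets(delta=0.05, subsets=(("k1",),))["k1_stim"]
        widths = {}
        for n in (30, 300):
            data = simulate_snapshots(k1_preset, space, (0, 5, 15, 25), n, seed=31)
            chain = fit_mcmc(data, template, space, T=1500, seed=5)
            s = posterior_summary(chain)
            widths[n] = (s["ci95_high"] - s["ci95_low"]).median()
        assert widths[300] < widths[30]

    def test_replica_intervals_overlap(self, k1_preset):
        space = StateSpace(M=60, p=3)
        data = simulate_snapshots(k1_preset, space, (0, 5, 15, 25), 200, seed=21)
        template = candidate_parameter_sets(delta=0.05, subsets=(("k1",),))["k1_stim"]
        summaries = []
        for rep in range(3):
            chain = fit_mcmc(data, template, space, T=15_000, seed=50 + rep, init_jitter=0.1)
            summaries.append(posterior_summary(chain))
        for comp in summaries[0].index:
            lo = max(s.loc[comp, "ci95_low"] for s in summaries)
            hi = min(s.loc[comp, "ci95_high"] for s in summaries)
            assert lo <= hi, f"replica 95% intervals disjoint for {comp}"

    def test_moment_init_is_in_right_basin(self, tiny_fit_setup):
        data, template, space = tiny_fit_setup
        init = moment_init(data, template)
        vals = dict(zip(init.free_names, init.to_free_vector()))
        assert vals["mu1"] > vals["mu0"]
        assert vals["k1_S"] > vals["k1_U"]
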