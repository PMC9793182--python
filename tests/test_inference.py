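import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest

from photonfret import (
    BernoulliLoadSampler,
    CompositeGenerator,
    ParametricRateSampler,
    PhotonTrace,
    PhotophysicsSpec,
    PriorSpec,
    PulsedTransitionSampler,
    SystemKinetics,
    build_composite_generator,
    load_conditional,
    log_likelihood_continuous,
    mh_step_log_rate,
    simulate_pulsed_trace,
    simulate_trace,
)

LD, LA = 277000.0, 285000.0


def toy_gen(lex, ld):
    m = np.array([[-lex, lex], [ld, -ld]])
    masks = np.zeros((1, 2, 2), dtype=bool)
    masks[0, 1, 0] = True
    exc = np.zeros((2, 2), dtype=bool)
    exc[0, 1] = True
    return CompositeGenerator(
        matrix=m, radiative_masks=masks, excitation_mask=exc,
        channel_names=("donor",), n_system_states=1, n_photo_states=2,
    )


class TestMhStepLogRate:
    def test_zero_sigma_proposal_always_accepted(self):
        rng = np.random.default_rng(0)
        new, accepted, _ = mh_step_log_rate(2.0, lambda v: 0.0, 0.0, rng)
        assert accepted and new == 2.0

    def test_flat_posterior_acceptance_matches_jacobian_oracle(self):
        """With a flat conditional, acceptance is min{1, lambda*/lambda}; the
        empirical acceptance rate matches direct Monte Carlo of
        E[min(1, e^Z)], Z ~ N(0, sigma^2)."""
        sigma = 0.7
        rng = np.random.default_rng(1)
        n = 40000
        accepted = 0
        for _ in range(n):
            _, acc, _ = mh_step_log_rate(
                1.0, lambda v: 0.0, sigma, rng, current_log_posterior=0.0
            )
            accepted += acc
        z = np.random.default_rng(2).standard_normal(200000) * sigma
        expected = np.minimum(1.0, np.exp(z)).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert accepted / n == pytest.approx(expected, abs=4 * se)

    def test_nonfinite_current_state_is_hard_failure(self):
        rng = np.random.default_rng(0)
        with pytest.raises(FloatingPointError):
            mh_step_log_rate(1.0, lambda v: -np.inf, 0.5, rng)


class TestLoadConditional:
    def test_equal_likelihoods_reduce_to_prior(self):
        prior = PriorSpec(max_states=5, expected_states=1.0)
        q = load_conditional(-100.0, -100.0, prior.load_success)
        assert q == pytest.approx(prior.load_success)

    def test_zero_off_likelihood_forces_on(self):
        assert load_conditional(-50.0, -np.inf, 0.2) == pytest.approx(1.0)

    def test_prior_free_variant_is_likelihood_ratio(self):
        q = load_conditional(np.log(3.0), np.log(1.0), 0.9, include_prior=False)
        assert q == pytest.approx(0.75)


class TestPriorRecovery:
    def test_chain_marginals_recover_gamma_priors_on_empty_data(self):
        """With no photons (constant likelihood) every rate's marginal chain
        is its Gamma prior; checked by KS on thinned draws."""
        trace = PhotonTrace(times=[], channels=[], t_start=0.0, t_end=0.0)
        est = ParametricRateSampler(
            n_states=2, sample_excitation=False, draws=8000, random_state=5
        ).fit(trace)
        for col, ref in [("sys_1->2", 1.0), ("sys_2->1", 1.0), ("fret_1", 1e6)]:
            x = est.samples_[col].values[1600::16]
            p = kstest(x, gamma_dist(a=1.0, scale=ref).cdf).pvalue
            assert p > 0.01, f"{col}: KS p = {p}"
            assert x.mean() == pytest.approx(ref, rel=0.2)


class TestGridPosteriorConsistency:
    def test_mcmc_matches_grid_quadrature_on_toy(self):
        """Two free rates, 200 photons: MCMC moments match a dense grid
        evaluation of the normalized posterior."""
        truth = (2.0, 20.0)
        trace = simulate_trace(toy_gen(*truth), n_photons=200, rng=9)
        refs = (5.0, 20.0)

        def logpost(lex, ld):
            return (
                log_likelihood_continuous(toy_gen(lex, ld), trace)
                - lex / refs[0]
                - ld / refs[1]
            )

        gx = np.linspace(np.log(0.5), np.log(8.0), 70)
        gy = np.linspace(np.log(4.0), np.log(80.0), 70)
        grid = np.array(
            [[logpost(np.exp(x), np.exp(y)) + x + y for y in gy] for x in gx]
        )
        w = np.exp(grid - grid.max())
        w /= w.sum()
        grid_means = (w.sum(1) @ np.exp(gx), w.sum(0) @ np.exp(gy))

        rng = np.random.default_rng(3)
        lex, ld = 1.0, 10.0
        cur = logpost(lex, ld)
        chain = []
        for _ in range(4000):
            for i in (0, 1):
                val = (lex, ld)[i]

                def lp(v, i=i):
                    args = (v, ld) if i == 0 else (lex, v)
                    return logpost(*args)

                new, _, cur = mh_step_log_rate(
                    val, lp, 0.3, rng, current_log_posterior=cur
                )
                if i == 0:
                    lex = new
                else:
                    ld = new
            chain.append((lex, ld))
        mcmc_means = np.array(chain[800:]).mean(axis=0)
        assert mcmc_means[0] == pytest.approx(grid_means[0], rel=0.05)
        assert mcmc_means[1] == pytest.approx(grid_means[1], rel=0.05)


@pytest.fixture(scope="module")
def short_benchmark_trace():
    ld = 277000.0
    from photonfret import efficiency_to_fret_rate

    gen = build_composite_generator(
        SystemKinetics([[0.0, 1.0], [2.0, 0.0]]),
        PhotophysicsSpec(
            10.0, ld, 285000.0,
            tuple(efficiency_to_fret_rate(e, ld) for e in (0.09, 0.29)),
        ),
    )
    return simulate_trace(gen, n_photons=3000, rng=13)


class TestParametricSampler:
    def test_seed_determinism(self, short_benchmark_trace):
        kw = dict(n_states=2, donor_relax_rate=LD, acceptor_relax_rate=LA,
                  draws=30, random_state=77)
        a = ParametricRateSampler(**kw).fit(short_benchmark_trace)
        b = ParametricRateSampler(**kw).fit(short_benchmark_trace)
        assert a.samples_.equals(b.samples_)
        np.testing.assert_array_equal(a.log_posterior_, b.log_posterior_)

    def test_sklearn_param_protocol(self):
        est = ParametricRateSampler(draws=10)
        params = est.get_params()
        assert params["draws"] == 10
        est.set_params(draws=20)
        assert est.draws == 20

    def test_acceptance_blocks_in_sane_range(self, short_benchmark_trace):
        est = ParametricRateSampler(
            n_states=2, donor_relax_rate=LD, acceptor_relax_rate=LA,
            draws=120, random_state=3,
        ).fit(short_benchmark_trace)
        for block in ("fret", "sys"):
            assert 0.05 < est.acceptance_[block] < 0.9

    def test_summary_reports_derived_quantities(self, short_benchmark_trace):
        est = ParametricRateSampler(
            n_states=2, donor_relax_rate=LD, acceptor_relax_rate=LA,
            draws=40, random_state=1,
        ).fit(short_benchmark_trace)
        s = est.summary()
        for row in ("efficiency_1", "efficiency_2", "escape_1", "escape_2"):
            assert row in s.index
        assert (s["q5"] <= s["q95"]).all()


class TestBernoulliLoadSampler:
    def test_loads_valid_and_at_least_one_active(self):
        gen = build_composite_generator(
            SystemKinetics([[0.0]]),
            PhotophysicsSpec(10.0, LD, LA, (70000.0,)),
        )
        trace = simulate_trace(gen, n_photons=1500, rng=2)
        est = BernoulliLoadSampler(
            max_states=3, donor_relax_rate=LD, acceptor_relax_rate=LA,
            draws=50, random_state=8,
        ).fit(trace)
        assert set(np.unique(est.loads_)) <= {0, 1}
        assert np.all(est.loads_.sum(axis=1) >= 1)
        assert est.samples_.shape[0] == 50

    def test_constant_likelihood_load_frequency_matches_prior(self):
        """On empty data the load conditionals reduce to the Bernoulli prior
        with success gamma / (gamma + max_states - 1)."""
        trace = PhotonTrace(times=[], channels=[], t_start=0.0, t_end=0.0)
        est = BernoulliLoadSampler(
            max_states=5, expected_states=2.5, donor_relax_rate=LD,
            acceptor_relax_rate=LA, draws=400, random_state=9,
        ).fit(trace)
        p = 2.5 / (2.5 + 4)  # = load prior success
        freq = est.loads_[100:].mean()
        # the at-least-one-active constraint biases the frequency slightly up
        assert p - 0.03 < freq < p + 0.10

    def test_seed_determinism(self):
        gen = build_composite_generator(
            SystemKinetics([[0.0]]),
            PhotophysicsSpec(10.0, LD, LA, (70000.0,)),
        )
        trace = simulate_trace(gen, n_photons=800, rng=4)
        kw = dict(max_states=3, donor_relax_rate=LD, acceptor_relax_rate=LA,
                  draws=25, random_state=10)
        a = BernoulliLoadSampler(**kw).fit(trace)
        b = BernoulliLoadSampler(**kw).fit(trace)
        assert a.samples_.equals(b.samples_)
        np.testing.assert_array_equal(a.loads_, b.loads_)


class TestPulsedTransitionSampler:
    @pytest.fixture(scope="class")
    def single_state_ptrace(self):
        p_ex, tau, dp = 0.005, 2.5e-5, 2.5e-6
        lex = -np.log1p(-p_ex) / dp
        gen = build_composite_generator(
            SystemKinetics([[0.0]]),
            PhotophysicsSpec(lex, LD, LA, (70000.0,)),
        )
        return simulate_pulsed_trace(gen, tau, dp, 60000, rng=3)

    def test_single_state_data_gives_one_effective_state(self, single_state_ptrace):
        est = PulsedTransitionSampler(
            max_states=3, detection_probability=0.005,
            donor_relax_rate=LD, acceptor_relax_rate=LA,
            draws=200, random_state=1,
        ).fit(single_state_ptrace)
        assert est.n_states_ == 1

    def test_rows_are_simplex_valid(self, single_state_ptrace):
        est = PulsedTransitionSampler(
            max_states=3, detection_probability=0.005,
            donor_relax_rate=LD, acceptor_relax_rate=LA,
            draws=40, random_state=2,
        ).fit(single_state_ptrace)
        pi = est.pi_samples_
        assert np.all(pi >= 0)
        np.testing.assert_allclose(pi.sum(axis=2), 1.0, atol=1e-9)
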