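import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import poisson

from photonfret import (
    BinnedTrace,
    DetectorModel,
    PhotonTrace,
    PoissonBinModel,
    PulsedTrace,
    SystemKinetics,
    log_likelihood_binned,
    log_likelihood_continuous,
    log_likelihood_dead_time,
    log_likelihood_irf,
    log_likelihood_pulsed,
    photon_budget_index,
    simulate_trace,
)
from photonfret.likelihood import PHOTON_BUDGET_ADEQUATE, reduced_generators


def worked_example_trace():
    # channel 1 (acceptor) photon at 0.05 ms, channel 2 (donor) at 0.15 ms
    return PhotonTrace(times=[0.05, 0.15], channels=[0, 1], t_end=0.15)


class TestWorkedExample:
    def test_likelihood_value(self, worked_example_exact_gen):
        """The two-photon pedagogical trace gives L / eps^2 = 3.06."""
        rho0 = np.array([1.0, 0, 0, 0, 0, 0])
        ll = log_likelihood_continuous(
            worked_example_exact_gen, worked_example_trace(), rho_start=rho0,
            include_end=False,
        )
        assert np.exp(ll) == pytest.approx(3.06, abs=0.005)

    def test_likelihood_value_with_printed_matrix(self, worked_example_gen):
        """The rounded (printed) matrix agrees to three significant figures."""
        rho0 = np.array([1.0, 0, 0, 0, 0, 0])
        ll = log_likelihood_continuous(
            worked_example_gen, worked_example_trace(), rho_start=rho0,
            include_end=False,
        )
        assert np.exp(ll) == pytest.approx(3.06, rel=0.005)

    def test_intermediate_propagator_elements(self, worked_example_gen):
        g_non, _ = reduced_generators(worked_example_gen, None)
        assert expm(0.05 * g_non)[0, 0] == pytest.approx(0.55, abs=0.005)
        assert expm(0.10 * g_non)[0, 0] == pytest.approx(0.30, abs=0.005)
        # the other cited elements of rows 1 and 4
        assert expm(0.05 * g_non)[0, 3] == pytest.approx(0.06, abs=0.005)
        assert expm(0.05 * g_non)[3, 3] == pytest.approx(0.58, abs=0.005)


class TestNormalization:
    def test_no_detection_gives_unit_likelihood(self, worked_example_gen):
        """With all detection matrices identically one, L = 1 for any trace."""
        rng = np.random.default_rng(11)
        blind = DetectorModel(routing=np.zeros((2, 2)))  # nothing registers
        for _ in range(20):
            rates = rng.uniform(0.1, 5.0, size=2)
            fret = rng.uniform(1e3, 1e5, size=2)
            from photonfret import PhotophysicsSpec, build_composite_generator

            gen = build_composite_generator(
                SystemKinetics([[0.0, rates[0]], [rates[1], 0.0]]),
                PhotophysicsSpec(10.0, 2.77e5, 2.85e5, tuple(fret)),
            )
            duration = rng.uniform(0.1, 50.0)
            trace = PhotonTrace(times=[], channels=[], t_start=0.0, t_end=duration)
            ll = log_likelihood_continuous(gen, trace, det=blind)
            assert abs(ll) < 1e-10

    def test_order_sensitivity(self, worked_example_gen):
        """Swapping two photons' channels changes the likelihood.

        A reversible chain at stationarity has an exchangeable two-point
        law, so the probe starts out of equilibrium where the photon order
        carries information.
        """
        rho0 = np.array([1.0, 0, 0, 0, 0, 0])
        t1 = PhotonTrace(times=[0.05, 0.15], channels=[0, 1], t_end=0.4)
        t2 = PhotonTrace(times=[0.05, 0.15], channels=[1, 0], t_end=0.4)
        l1 = log_likelihood_continuous(worked_example_gen, t1, rho_start=rho0)
        l2 = log_likelihood_continuous(worked_example_gen, t2, rho_start=rho0)
        assert abs(l1 - l2) > 1e-2

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            PhotonTrace(times=[0.2, 0.1], channels=[0, 1])


def toy_single_channel_gen(lex=1.0, ld=10.0):
    from photonfret import CompositeGenerator

    matrix = np.array([[-lex, lex], [ld, -ld]])
    masks = np.zeros((1, 2, 2), dtype=bool)
    masks[0, 1, 0] = True
    exc = np.zeros((2, 2), dtype=bool)
    exc[0, 1] = True
    return CompositeGenerator(
        matrix=matrix, radiative_masks=masks, excitation_mask=exc,
        channel_names=("donor",), n_system_states=1, n_photo_states=2,
    )


def discretized_product_oracle(gen, trace, n_windows_per_gap):
    """Second-order-HMM product: reduced propagators on a fine regular grid.

    L = rho_start * prod_n [exp(eps G) (.) D_n] * 1, with the photon windows
    carrying the radiative detection matrix; divided by eps^K.
    """
    g = gen.matrix
    rho = np.zeros(g.shape[0])
    rho[0] = 1.0
    d_non = np.ones_like(g)
    for c in range(gen.n_channels):
        d_non[gen.radiative_masks[c]] = 0.0
    loglik = 0.0
    t_prev = trace.t_start
    for k in range(trace.n_photons):
        gap = trace.times[k] - t_prev
        eps = gap / n_windows_per_gap
        p_non = expm(eps * g) * d_non
        p_rad = expm(eps * g) * gen.radiative_masks[trace.channels[k]]
        # n nonradiative windows spanning the gap, then the photon's own
        # O(eps) window, log-scaled
        eigs, v = np.linalg.eig(p_non)
        w = np.linalg.inv(v)
        u = (rho.astype(complex) @ v) * eigs**n_windows_per_gap
        rho = (u @ w).real @ p_rad
        p = rho.sum()
        loglik += np.log(p) - np.log(eps)  # drop one eps per photon
        rho /= p
        t_prev = trace.times[k]
    return loglik


class TestDiscretizationOracle:
    def test_matches_fine_grid_product(self):
        """Continuum likelihood equals the eps -> 0 limit of the window product."""
        gen = toy_single_channel_gen(lex=0.05, ld=0.1)
        trace = PhotonTrace(times=[0.1, 0.25, 0.45], channels=[0, 0, 0], t_end=0.45)
        rho0 = np.array([1.0, 0.0])
        exact = log_likelihood_continuous(gen, trace, rho_start=rho0, include_end=False)
        oracle = discretized_product_oracle(gen, trace, 2**16)
        assert np.exp(oracle) == pytest.approx(np.exp(exact), rel=1e-6)

    def test_first_order_convergence_rate(self):
        gen = toy_single_channel_gen()
        trace = PhotonTrace(times=[0.31, 0.72, 1.13], channels=[0, 0, 0], t_end=1.13)
        rho0 = np.array([1.0, 0.0])
        exact = log_likelihood_continuous(gen, trace, rho_start=rho0, include_end=False)
        err = [abs(discretized_product_oracle(gen, trace, 2**k) - exact) for k in (8, 9, 10)]
        ratios = [err[i] / err[i + 1] for i in range(2)]
        for r in ratios:  # halving eps should halve the error (O(eps))
            assert 1.6 < r < 2.4

    def test_scaled_recursion_equals_naive_product(self, worked_example_gen):
        """Where the raw product does not underflow, sum of log normalizers
        equals the log of the naive matrix product."""
        trace = PhotonTrace(times=[0.05, 0.15, 0.4], channels=[0, 1, 1], t_end=0.5)
        rho0 = steady = np.array([0.3, 0.0, 0.0, 0.7, 0.0, 0.0])
        g_non, g_rads = reduced_generators(worked_example_gen, None)
        rho = rho0.copy()
        t_prev = 0.0
        for t, c in zip(trace.times, trace.channels):
            rho = rho @ expm((t - t_prev) * g_non) @ g_rads[c]
            t_prev = t
        naive = (rho @ expm((0.5 - t_prev) * g_non)).sum()
        ll = log_likelihood_continuous(worked_example_gen, trace, rho_start=rho0)
        assert ll == pytest.approx(np.log(naive), abs=1e-10)


class TestDeadTime:
    def test_zero_dead_time_matches_continuous(self, worked_example_gen):
        det = DetectorModel(routing=np.eye(2), dead_times=[0.0, 0.0])
        trace = PhotonTrace(times=[0.05, 0.15], channels=[0, 1], t_end=0.2)
        assert log_likelihood_dead_time(
            worked_example_gen, trace, det
        ) == pytest.approx(
            log_likelihood_continuous(worked_example_gen, trace, det), abs=1e-12
        )

    def test_single_channel_dead_window_is_full_generator(self):
        """With one ideal channel a dead detector blocks nothing observable,
        so the dead-window propagator is the exponential of the full G."""
        from photonfret.likelihood import _dead_window_generator

        gen = toy_single_channel_gen()
        det = DetectorModel(routing=np.eye(1), dead_times=[0.02])
        np.testing.assert_allclose(
            _dead_window_generator(gen, det, 0), gen.matrix, atol=1e-12
        )

    def test_matches_explicit_matrix_product(self, worked_example_gen):
        from photonfret.likelihood import _dead_window_generator

        det = DetectorModel(routing=np.eye(2), dead_times=[0.01, 0.01])
        trace = PhotonTrace(times=[0.05, 0.15], channels=[0, 1], t_end=0.3)
        g_non, g_rads = reduced_generators(worked_example_gen, det)
        rho = np.array(
            [x for x in __import__("photonfret").steady_state(worked_example_gen)]
        )
        d0 = expm(0.01 * _dead_window_generator(worked_example_gen, det, 0))
        d1 = expm(0.01 * _dead_window_generator(worked_example_gen, det, 1))
        value = (
            rho
            @ expm(0.05 * g_non) @ g_rads[0] @ d0
            @ expm((0.10 - 0.01) * g_non) @ g_rads[1] @ d1
            @ expm((0.15 - 0.01) * g_non)
        ).sum()
        ll = log_likelihood_dead_time(worked_example_gen, trace, det)
        assert ll == pytest.approx(np.log(value), abs=1e-10)

    def test_photon_inside_own_dead_window_rejected(self, worked_example_gen):
        det = DetectorModel(routing=np.eye(2), dead_times=[0.2, 0.2])
        trace = PhotonTrace(times=[0.05, 0.15], channels=[0, 0], t_end=0.3)
        with pytest.raises(ValueError):
            log_likelihood_dead_time(worked_example_gen, trace, det)


class TestIrf:
    def test_delta_irf_matches_dead_time_likelihood(self, worked_example_gen):
        det = DetectorModel(routing=np.eye(2), dead_times=[0.001, 0.001])
        trace = PhotonTrace(times=[0.05, 0.15], channels=[0, 1], t_end=0.3)
        assert log_likelihood_irf(
            worked_example_gen, trace, det
        ) == pytest.approx(
            log_likelihood_dead_time(worked_example_gen, trace, det), abs=1e-12
        )

    def test_two_bin_irf_averages_shifted_products(self, worked_example_gen):
        tau = 1e-4
        det = DetectorModel(
            routing=np.eye(2),
            irf_delays=np.array([0.0, tau]),
            irf_weights=np.array([0.5, 0.5]),
        )
        trace = PhotonTrace(times=[0.05], channels=[1], t_end=0.05)
        g_non, g_rads = reduced_generators(worked_example_gen, det)
        from photonfret import steady_state
        from photonfret.likelihood import _dead_window_generator

        rho = steady_state(worked_example_gen)
        dead = _dead_window_generator(worked_example_gen, det, 1)
        branches = (
            rho @ expm(0.05 * g_non) @ g_rads[1] @ expm(0.0 * dead),
            rho @ expm((0.05 - tau) * g_non) @ g_rads[1] @ expm(tau * dead),
        )
        expected = np.log(0.5 * branches[0].sum() + 0.5 * branches[1].sum())
        ll = log_likelihood_irf(worked_example_gen, trace, det, include_end=False)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_irf_aware_profile_recovers_true_rate(self):
        """On jittered single-fluorophore data (IRF support well below the
        interphoton gaps) the convolved likelihood peaks at the true
        relaxation rate."""
        import warnings

        ld_true = 2e6  # ms^-1 (2 ns^-1)
        gen = toy_single_channel_gen(lex=2e5, ld=ld_true)
        det = DetectorModel.with_truncated_gaussian_irf(
            routing=np.eye(1), mean=4.8e-8, width=2.4e-8, support=9.6e-8,
            resolution=1.6e-8,
        )
        trace = simulate_trace(gen, det=det, n_photons=6000, rng=5)
        grid = ld_true * np.array([0.55, 0.75, 1.0, 1.35, 1.8])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aware = [
                log_likelihood_irf(toy_single_channel_gen(lex=2e5, ld=ld), trace, det)
                for ld in grid
            ]
        assert grid[int(np.argmax(aware))] == ld_true


class TestBinned:
    def test_single_state_is_product_of_poissons(self):
        system = SystemKinetics([[0.0]])
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=(50, 2))
        binned = BinnedTrace(bin_size=1.0, counts=counts)
        model = PoissonBinModel(10.0, [0.2], bin_size=1.0)
        ll = log_likelihood_binned(system, model, binned)
        expected = (
            poisson.logpmf(counts[:, 0], 10.0 * 0.2).sum()
            + poisson.logpmf(counts[:, 1], 10.0 * 0.8).sum()
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_system_propagator_rows_are_stochastic(self):
        system = SystemKinetics([[0.0, 1.0], [2.0, 0.0]])
        pi = expm(0.05 * system.generator)
        np.testing.assert_allclose(pi.sum(axis=1), 1.0, atol=1e-12)

    def test_warns_outside_slow_kinetics_regime(self):
        system = SystemKinetics([[0.0, 100.0], [100.0, 0.0]])
        binned = BinnedTrace(bin_size=0.1, counts=np.zeros((5, 2), dtype=int))
        model = PoissonBinModel(10.0, [0.1, 0.3], bin_size=0.1)
        with pytest.warns(UserWarning):
            log_likelihood_binned(system, model, binned)

    def test_slow_kinetics_ranking_agrees_with_photon_likelihood(self, benchmark_gen):
        """True rates beat perturbed rates under both representations."""
        trace = simulate_trace(benchmark_gen, n_photons=20000, rng=7)
        # bin the photon trace
        eps = 1.0
        n_bins = int(np.ceil(trace.t_end / eps))
        counts = np.zeros((n_bins, 2), dtype=int)
        idx = np.minimum((trace.times / eps).astype(int), n_bins - 1)
        for i, c in zip(idx, trace.channels):
            counts[i, c] += 1
        binned = BinnedTrace(bin_size=eps, counts=counts)
        true_sys = SystemKinetics([[0.0, 1.0], [2.0, 0.0]])
        pert_sys = SystemKinetics([[0.0, 10.0], [20.0, 0.0]])
        model = PoissonBinModel(10.0, [0.09, 0.29], bin_size=eps)
        d_binned = log_likelihood_binned(true_sys, model, binned) - log_likelihood_binned(
            pert_sys, model, binned
        )
        from photonfret import PhotophysicsSpec, build_composite_generator, efficiency_to_fret_rate

        fr = tuple(efficiency_to_fret_rate(e, 2.77e5) for e in (0.09, 0.29))
        pert_gen = build_composite_generator(
            pert_sys, PhotophysicsSpec(10.0, 2.77e5, 2.85e5, fr)
        )
        d_photon = log_likelihood_continuous(
            benchmark_gen, trace
        ) - log_likelihood_continuous(pert_gen, trace)
        assert np.sign(d_binned) == np.sign(d_photon) == 1.0


class TestPulsed:
    def test_dark_unobserved_likelihood_is_one(self):
        gen = toy_single_channel_gen(lex=0.0, ld=10.0)
        ptrace = PulsedTrace(
            period=1.0, pulse_width=0.1, n_pulses=50,
            pulse_indices=[], microtimes=[], channels=[],
        )
        assert log_likelihood_pulsed(gen, ptrace) == pytest.approx(0.0, abs=1e-10)

    def test_single_dark_period_photon_matches_explicit_product(self):
        gen = toy_single_channel_gen(lex=5.0, ld=50.0)
        mu, tau, dp = 0.4, 1.0, 0.1
        ptrace = PulsedTrace(
            period=tau, pulse_width=dp, n_pulses=1,
            pulse_indices=[0], microtimes=[mu], channels=[0],
        )
        from photonfret import dark_generator, steady_state

        g_non, g_rads = reduced_generators(gen, None)
        g_dark = dark_generator(gen).matrix.copy()
        g_dark[1, 0] = 0.0  # nonradiative masking of the dark generator
        rho = steady_state(gen)
        value = (
            rho
            @ expm(dp * g_non)
            @ expm((mu - dp) * g_dark)
            @ g_rads[0]
            @ expm((tau - mu) * g_dark)
        ).sum()
        assert log_likelihood_pulsed(gen, ptrace) == pytest.approx(
            np.log(value), abs=1e-10
        )

    def test_continuous_illumination_limit(self, worked_example_gen):
        """pulse_width = period with constant excitation reduces the pulse
        product to the continuous-illumination likelihood."""
        tau = 0.05
        times = np.array([0.012, 0.111, 0.234])
        channels = np.array([0, 1, 0])
        idx = (times / tau).astype(np.int64)
        n_pulses = 6
        ptrace = PulsedTrace(
            period=tau, pulse_width=np.nextafter(tau, 0), n_pulses=n_pulses,
            pulse_indices=idx, microtimes=times - idx * tau, channels=channels,
        )
        trace = PhotonTrace(times=times, channels=channels, t_end=n_pulses * tau)
        assert log_likelihood_pulsed(worked_example_gen, ptrace) == pytest.approx(
            log_likelihood_continuous(worked_example_gen, trace), abs=1e-8
        )

    def test_microtime_beyond_period_rejected(self):
        with pytest.raises(ValueError):
            PulsedTrace(
                period=1.0, pulse_width=0.1, n_pulses=3,
                pulse_indices=[0], microtimes=[1.5], channels=[0],
            )


class TestPhotonBudgetIndex:
    def test_direct_arithmetic(self):
        assert photon_budget_index(1e5, 10.0, 2.0, 2) == pytest.approx(2.5e5)

    def test_linearity_in_photon_count(self):
        one = photon_budget_index(1e5, 10.0, 2.0, 2)
        assert photon_budget_index(2e5, 10.0, 2.0, 2) == pytest.approx(2 * one)

    def test_adequacy_threshold(self):
        assert photon_budget_index(4e5, 10.0, 2.0, 2) >= PHOTON_BUDGET_ADEQUATE
        assert photon_budget_index(1e4, 10.0, 2.0, 2) < PHOTON_BUDGET_ADEQUATE

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            photon_budget_index(1e5, 10.0, 0.0, 2)
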