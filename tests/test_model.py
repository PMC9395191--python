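import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from microswitch.connectivity import ConnectivityMatrix, scale_by_G
from microswitch.model import (
    DivergenceError,
    ModelParams,
    StimulusProtocol,
    linearized_frequency,
    simulate,
    steady_state,
    transfer,
    transfer_deriv,
)
from microswitch.populations import POPULATIONS, index_of


def zero_matrix():
    return ConnectivityMatrix(np.zeros((8, 8)))


class TestTransfer:
    def test_removable_singularity_evaluates_to_limit(self):
        assert transfer(0.0, a=1.0, b=1.0) == pytest.approx(1.0, abs=1e-12)
        assert transfer(0.0, a=2.0, b=3.0) == pytest.approx(6.0, abs=1e-9)

    def test_reference_values(self):
        # 10 / (1 - e^-10), checked against high-precision evaluation
        assert transfer(10.0) == pytest.approx(10.000454019910096, abs=1e-9)
        assert transfer(5.0) == pytest.approx(5.0 / (1.0 - np.exp(-5.0)), rel=1e-12)

    def test_limits_and_overflow_safety(self):
        assert transfer(-1e6) == 0.0
        assert transfer(1e6) == pytest.approx(1e6, rel=1e-9)
        x = np.array([-1e308, -750.0, -1.0, 0.0, 1.0, 750.0, 1e308])
        y = transfer(x)
        assert np.all(np.isfinite(y)) and np.all(y >= 0)

    @given(st.floats(min_value=-50, max_value=49.5))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing(self, x):
        assert transfer(x + 0.5) > transfer(x)

    def test_derivative_matches_numerical_gradient(self):
        xs = np.array([-20.0, -3.0, -0.5, -1e-7, 0.0, 1e-7, 0.5, 3.0, 20.0])
        h = 1e-6
        num = (transfer(xs + h, a=1.3, b=0.7) - transfer(xs - h, a=1.3, b=0.7)) / (2 * h)
        # atol reflects central-difference round-off near the origin
        assert np.allclose(transfer_deriv(xs, a=1.3, b=0.7), num, atol=1e-4)


class TestSimulate:
    def test_decoupled_relaxation_matches_closed_form(self):
        """With C = 0 and no noise each population relaxes exponentially to
        transfer(I_ext) with its own time constant."""
        params = ModelParams(sigma=0.0)
        stim = StimulusProtocol(baseline=np.full(8, 3.0))
        tr = simulate(zero_matrix(), params, stim, 600.0, record_stride=10)
        target = transfer(3.0)
        # continuous exponential, up to O(dt/tau) Euler discretization error
        expected = target * (1 - np.exp(-tr.time[:, None] / params.tau[None, :]))
        assert np.allclose(tr.rates, expected, atol=2e-2)
        # exact discrete closed form of the Euler recursion
        n_steps = (tr.time[:, None] / params.dt).round()
        discrete = target * (1 - (1 - params.dt / params.tau[None, :]) ** n_steps)
        assert np.allclose(tr.rates, discrete, atol=1e-9)
        assert np.allclose(tr.rates[-1], target, atol=1e-6)

    def test_bit_identical_under_same_seed(self, fixture_C, params, base_stim):
        C = scale_by_G(fixture_C, 100.0)
        a = simulate(C, params, base_stim, 500.0, seed=5)
        b = simulate(C, params, base_stim, 500.0, seed=5)
        c = simulate(C, params, base_stim, 500.0, seed=6)
        assert np.array_equal(a.rates, b.rates)
        assert not np.array_equal(a.rates, c.rates)

    def test_terminal_state_solves_fixed_point_equation(self, random_matrices,
                                                        base_stim):
        """The noise-free terminal state satisfies r = phi(Wr + I) and agrees
        with an independent root solve."""
        params = ModelParams(sigma=0.0)
        for k, C0 in enumerate(random_matrices[:6]):
            C = scale_by_G(C0, 50.0 + 60.0 * k)
            ss = steady_state(C, params, base_stim)
            drive = base_stim.constant_drive()
            resid = ss.rates - transfer(C.W @ ss.rates + drive)
            assert np.max(np.abs(resid)) < 1e-4
            sol = optimize.root(
                lambda r: r - transfer(C.W @ r + drive), ss.rates, tol=1e-12)
            assert sol.success
            assert np.allclose(ss.rates, sol.x, atol=1e-4)

    def test_divergence_raises_with_blowup_time(self, base_stim):
        W = np.zeros((8, 8))
        W[0, 0] = 5.0  # runaway recurrent excitation
        with pytest.raises(DivergenceError) as err:
            simulate(ConnectivityMatrix(W), ModelParams(sigma=0.0),
                     base_stim, 1000.0)
        assert 0 < err.value.time_ms < 1000.0

    def test_rates_stay_nonnegative_without_noise(self, fixture_C, base_stim):
        tr = simulate(scale_by_G(fixture_C, 300.0), ModelParams(sigma=0.0),
                      base_stim, 1000.0)
        assert tr.rates.min() >= -1e-12

    def test_noise_excursions_are_small(self, fixture_C, base_stim, params):
        tr = simulate(scale_by_G(fixture_C, 300.0), params, base_stim,
                      2000.0, seed=3)
        assert tr.rates.min() > -0.05  # O(sigma) transient excursions only

    def test_halving_dt_barely_moves_the_fixed_point(self, fixture_C, base_stim):
        C = scale_by_G(fixture_C, 100.0)
        r1 = steady_state(C, ModelParams(sigma=0.0, dt=0.1), base_stim).rates
        r2 = steady_state(C, ModelParams(sigma=0.0, dt=0.05), base_stim).rates
        assert np.max(np.abs(r1 - r2)) < 1e-4

    def test_permutation_equivariance(self, fixture_C, base_stim):
        """Relabeling populations together with C, tau and I_ext permutes the
        noise-free trajectory accordingly."""
        perm = np.array([4, 5, 6, 7, 0, 1, 2, 3])  # swap layers
        C = scale_by_G(fixture_C, 150.0)
        params = ModelParams(sigma=0.0)
        tr = simulate(C, params, base_stim, 300.0)
        Cp = ConnectivityMatrix(C.W[np.ix_(perm, perm)])
        params_p = ModelParams(sigma=0.0, tau=params.tau[perm])
        stim_p = StimulusProtocol(baseline=base_stim.baseline[perm])
        tr_p = simulate(Cp, params_p, stim_p, 300.0)
        assert np.allclose(tr_p.rates, tr.rates[:, perm], atol=1e-12)

    def test_stepped_stimulus_windows(self):
        params = ModelParams(sigma=0.0)
        stim = StimulusProtocol(baseline=np.zeros(8),
                                steps=[(100.0, 200.0, np.full(8, 4.0))])
        tr = simulate(zero_matrix(), params, stim, 300.0)
        k = index_of("PYR_sup")
        mid = tr.rates[np.searchsorted(tr.time, 199.0), k]
        end = tr.rates[-1, k]
        assert mid > 2.0 and end < mid

    def test_binary_cache_round_trip(self, fixture_C, params, base_stim,
                                      tmp_path):
        tr = simulate(scale_by_G(fixture_C, 100.0), params, base_stim, 300.0,
                      seed=9, record_stride=10)
        path = tmp_path / "trace.npz"
        tr.save(path)
        back = tr.load(path)
        assert np.array_equal(back.rates, tr.rates)
        assert np.array_equal(back.time, tr.time)
        assert back.seed == 9 and back.G == tr.G
        assert np.array_equal(back.params.tau, tr.params.tau)

    def test_overlapping_windows_rejected(self):
        stim = StimulusProtocol(steps=[(0.0, 100.0, np.ones(8)),
                                       (50.0, 150.0, np.ones(8))])
        with pytest.raises(ValueError, match="overlap"):
            simulate(zero_matrix(), ModelParams(), stim, 200.0)


class TestSteadyState:
    def test_zero_matrix_closed_form(self, base_stim):
        params = ModelParams(sigma=0.0, a=1.0, b=1.0)
        ss = steady_state(zero_matrix(), params, base_stim)
        assert ss.converged
        for lbl in POPULATIONS:
            expected = transfer(5.0) if lbl.startswith("PYR") else transfer(0.0)
            assert ss.rates[index_of(lbl)] == pytest.approx(expected, abs=1e-6)

    def test_warm_start_at_fixed_point_is_invariant(self, fixture_C, base_stim):
        C = scale_by_G(fixture_C, 100.0)
        params = ModelParams(sigma=0.0)
        ss = steady_state(C, params, base_stim)
        again = steady_state(C, params, base_stim, duration=500.0,
                             initial_rates=ss.rates)
        assert np.allclose(again.rates, ss.rates, atol=1e-8)

    def test_stochastic_mean_matches_deterministic_fixed_point(
            self, fixture_C, base_stim):
        C = scale_by_G(fixture_C, 30.0)  # well below the oscillatory regime
        det = steady_state(C, ModelParams(sigma=0.0), base_stim).rates
        traces = [simulate(C, ModelParams(), base_stim, 4000.0, seed=s,
                           record_stride=10) for s in range(5)]
        means = np.array([t.mean_rates(discard_ms=1000.0) for t in traces])
        grand = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / np.sqrt(len(means)) + 1e-4
        assert np.all(np.abs(grand - det) < 5 * se)


class TestLinearizedFrequency:
    def test_zero_matrix_has_no_resonance(self, base_stim):
        assert linearized_frequency(zero_matrix(), ModelParams(), base_stim) is None

    def test_two_population_toy_matches_quadratic_eigenvalues(self):
        """E-I pair: the Jacobian is effectively 2x2 and its complex pair is
        available in closed form from the quadratic characteristic equation."""
        W = np.zeros((8, 8))
        e, i = index_of("PYR_sup"), index_of("PV_sup")
        W[i, e] = 2.0
        W[e, i] = -2.5
        params = ModelParams(tau=np.full(8, 10.0), sigma=0.0)
        stim = StimulusProtocol(baseline=np.zeros(8))
        C = ConnectivityMatrix(W)
        # closed-form fixed point of the pair, solved independently
        sol = optimize.root(
            lambda r: r - transfer(np.array([W[e, i] * r[1], W[i, e] * r[0]])),
            np.array([1.0, 1.0]), tol=1e-13)
        re, ri = sol.x
        se = transfer_deriv(W[e, i] * ri)
        si = transfer_deriv(W[i, e] * re)
        # lambda = (-1 +- sqrt(se*si*W_ei*W_ie)) / tau ; product negative -> complex
        disc = se * si * W[e, i] * W[i, e]
        assert disc < 0
        expected = np.sqrt(-disc) / 10.0 / (2 * np.pi) * 1000.0
        got = linearized_frequency(C, params, stim)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_fixture_resonance_lies_in_gamma_band_at_moderate_G(
            self, fixture_C, base_stim):
        f = linearized_frequency(scale_by_G(fixture_C, 100.0),
                                 ModelParams(), base_stim)
        assert f is not None and 30.0 < f < 180.0
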