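import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import poisson

from schlogl.analysis import detect_switches, kl_divergence
from schlogl.cme import (bimodal_range, cme_rates, coexistence_B_stochastic,
                         distribution_histogram, entropy_production_microscopic,
                         fluctuation_curve, is_bimodal, potential_derivative,
                         simulate_ssa, stationary_distribution,
                         stochastic_potential, switching_rates,
                         trajectory_histogram, trajectory_pmf)
from schlogl.containers import Histogram1D, Trajectory
from schlogl.deterministic import (entropy_production_macroscopic,
                                   steady_states)
from schlogl.params import standard_parameters

DETAILED_BALANCE_B = 1.0 / 6.0


class TestCMERates:
    def test_reference_values(self):
        p = standard_parameters(4.0)
        assert cme_rates(3, p, 10.0) == pytest.approx((5.0, 2.4, 9.0, 0.06))

    def test_combinatorial_zeros(self):
        p = standard_parameters(4.0)
        assert cme_rates(0, p, 10.0)[1:] == pytest.approx((0.0, 0.0, 0.0))
        assert cme_rates(2, p, 10.0)[3] == 0.0


def _generator_nullspace(params, V, X_max):
    """Brute-force stationary distribution from the truncated generator."""
    X = np.arange(X_max + 1, dtype=float)
    bc, ba, dl, dt = cme_rates(X, params, V)
    up, down = bc + ba, dl + dt
    A = np.zeros((X_max + 1, X_max + 1))
    for i in range(X_max + 1):
        if i < X_max:
            A[i + 1, i] += up[i]
            A[i, i] -= up[i]
        if i > 0:
            A[i - 1, i] += down[i]
            A[i, i] -= down[i]
    A[-1, :] = 1.0  # replace one equation by normalization
    b = np.zeros(X_max + 1)
    b[-1] = 1.0
    return np.linalg.solve(A, b)


class TestStationaryDistribution:
    @pytest.mark.parametrize("B,V", [(4.0, 10.0), (3.7, 30.0), (3.4, 10.0)])
    def test_recursion_equals_generator_nullspace(self, B, V):
        p = standard_parameters(B)
        d = stationary_distribution(p, V)
        ref = _generator_nullspace(p, V, d.X_max)
        assert 0.5 * np.abs(d.p - ref).sum() < 1e-10

    def test_normalized_with_small_boundary_mass(self):
        d = stationary_distribution(standard_parameters(4.0), 10.0)
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.p[-1] < 1e-12 * d.p.max()
        assert np.all(d.p >= 0)

    def test_poisson_limit(self):
        p = standard_parameters(1.0, k_plus2=0.0, k_minus2=0.0)
        d = stationary_distribution(p, 10.0)
        mean = 0.5 * 10.0 / 3.0
        ref = poisson.pmf(d.X, mean)
        assert 0.5 * np.abs(d.p - ref).sum() < 1e-10
        assert d.p[1] / d.p[0] == pytest.approx(mean)

    def test_first_recursion_step(self):
        d = stationary_distribution(standard_parameters(3.7), 10.0)
        assert d.p[1] / d.p[0] == pytest.approx(5.0 / 3.0)

    def test_bimodal_at_reference_point(self):
        d = stationary_distribution(standard_parameters(4.0), 10.0)
        assert is_bimodal(d).bimodal


class TestStochasticPotential:
    def test_slope_vanishes_at_steady_states(self, std):
        for r in steady_states(std).roots:
            assert abs(potential_derivative(r, std)) < 1e-8

    def test_curvature_signs(self, std):
        ss = steady_states(std)
        h = 1e-5
        for r, stable in zip(ss.roots, ss.stability):
            d2 = (potential_derivative(r + h, std)
                  - potential_derivative(r - h, std)) / (2 * h)
            assert (d2 > 0) == stable

    def test_closed_form_matches_quadrature_of_slope(self, std):
        xs = np.array([0.5, 1.0, 1.5, 2.5])
        sp = stochastic_potential(np.append(0.1, xs), std)
        for x, phi in zip(xs, sp.phi[1:]):
            q, _ = quad(lambda u: potential_derivative(u, std), 0.1, x)
            assert phi - sp.phi[0] == pytest.approx(q, abs=1e-6)

    def test_slope_matches_finite_difference_of_closed_form(self, std):
        h = 1e-6
        sp = stochastic_potential(np.array([1.0 - h, 1.0 + h]), std)
        fd = (sp.phi[1] - sp.phi[0]) / (2 * h)
        assert fd == pytest.approx(potential_derivative(1.0, std), abs=1e-6)

    def test_slope_negative_near_origin(self, std):
        assert potential_derivative(1e-6, std) < 0.0

    def test_origin_rejected(self, std):
        with pytest.raises(ValueError):
            stochastic_potential(np.array([0.0, 1.0]), std)

    @pytest.mark.parametrize("V,tv_bound", [(30.0, 0.06), (100.0, 0.025)])
    def test_wkb_form_approaches_exact_distribution(self, V, tv_bound):
        p = standard_parameters(4.0)
        d = stationary_distribution(p, V)
        X = np.arange(1, d.X_max + 1)
        sp = stochastic_potential(X / V, p)
        w = np.log(sp.prefactor) - V * sp.phi
        q = np.concatenate(([0.0], np.exp(w - w.max())))
        q /= q.sum()
        tv = 0.5 * np.abs(q - d.p).sum()
        assert tv < tv_bound
        # same modes to within one grid cell, and tighter with larger V
        assert abs(int(np.argmax(q)) - int(np.argmax(d.p))) <= 1


class TestSwitchingRates:
    def test_rates_decrease_with_volume_on_both_sides(self):
        for B in (3.6, 3.8):
            r10 = switching_rates(standard_parameters(B), 10.0)
            r30 = switching_rates(standard_parameters(B), 30.0)
            assert r30.rate_low_to_high < r10.rate_low_to_high
            assert r30.rate_high_to_low < r10.rate_high_to_low

    def test_monostable_rejected(self):
        with pytest.raises(ValueError):
            switching_rates(standard_parameters(1.0), 10.0)

    def test_mfpt_agrees_with_ssa_dwell_times(self):
        # long conventional run at V=10, B=4.0: compare the inverse mean dwell
        # time in the low basin against the exact low->high MFPT rate
        p = standard_parameters(4.0)
        traj = simulate_ssa(p, "conventional", V=10.0, t_max=30_000.0, seed=7,
                            record_dt=0.05)
        rec = detect_switches(traj, p, 10.0)
        assert rec.n_switches >= 100
        t_all = np.concatenate((rec.times, [traj.t_max]))
        dwell = np.diff(np.concatenate(([0.0], t_all)))
        # dwell[i] precedes switch i; direction of switch i tells the basin
        low_dwell = [d for d, s in zip(dwell[:-1], rec.directions)
                     if s == "low->high"]
        rate_emp = 1.0 / np.mean(low_dwell)
        rate_exact = switching_rates(p, 10.0).rate_low_to_high
        assert 0.5 < rate_emp / rate_exact < 2.0


class TestMaxwellConstruction:
    def test_equal_potential_value(self, std):
        B = coexistence_B_stochastic(std, method="equal-potential",
                                     bracket=(3.4, 4.0))
        assert B == pytest.approx(3.5551, abs=1e-3)

    def test_equal_rates_value_at_V30(self, std):
        B = coexistence_B_stochastic(std, V=30.0, method="equal-rates",
                                     bracket=(3.4, 4.0))
        assert B == pytest.approx(3.6983, abs=1e-3)

    def test_methods_converge_with_volume(self, std):
        b_pot = coexistence_B_stochastic(std, method="equal-potential",
                                         bracket=(3.4, 4.0))
        b10 = coexistence_B_stochastic(std, V=10.0, bracket=(3.4, 4.4))
        b100 = coexistence_B_stochastic(std, V=100.0, bracket=(3.4, 4.0))
        assert abs(b100 - b_pot) < abs(b10 - b_pot)

    def test_no_crossing_rejected(self, std):
        with pytest.raises(ValueError):
            coexistence_B_stochastic(std, V=30.0, bracket=(3.75, 3.95))


class TestMicroscopicEntropyProduction:
    def test_zero_at_detailed_balance(self):
        p = standard_parameters(DETAILED_BALANCE_B)
        d = stationary_distribution(p, 10.0)
        assert entropy_production_microscopic(d, p) == pytest.approx(0.0, abs=1e-10)

    def test_positive_out_of_equilibrium(self):
        p = standard_parameters(4.0)
        d = stationary_distribution(p, 10.0)
        assert entropy_production_microscopic(d, p) > 0.0

    def test_per_volume_approaches_macroscopic_rate(self):
        p = standard_parameters(4.0)
        macro = entropy_production_macroscopic(steady_states(p).high, p)
        errs = []
        for V in (30.0, 100.0):
            d = stationary_distribution(p, V)
            errs.append(abs(entropy_production_microscopic(d, p) / V - macro) / macro)
        assert errs[1] < errs[0]
        assert errs[1] < 0.02


class TestFluctuationCurve:
    def test_variance_has_single_interior_maximum_near_coexistence(self, std):
        df = fluctuation_curve(std, 30.0, np.arange(3.3, 4.3, 0.02))
        v = df["var"].to_numpy()
        peaks = [i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] >= v[i + 1]]
        assert len(peaks) == 1
        assert 3.5 < df["B"].iloc[peaks[0]] < 3.9

    def test_poisson_limit_cv(self):
        p = standard_parameters(1.0, k_plus2=0.0, k_minus2=0.0)
        df = fluctuation_curve(p, 10.0, [1.0])
        assert df["cv"].iloc[0] == pytest.approx(1.0 / math.sqrt(5.0 / 3.0),
                                                 rel=1e-6)


class TestSSA:
    def test_reference_run_switches(self):
        p = standard_parameters(4.0)
        traj = simulate_ssa(p, "conventional", V=10.0, t_max=10_000.0, seed=3,
                            record_dt=0.1)
        assert detect_switches(traj, p, 10.0).n_switches >= 1

    def test_event_recording_and_determinism(self):
        p = standard_parameters(4.0)
        t1 = simulate_ssa(p, "conventional", V=10.0, t_max=50.0, seed=5)
        t2 = simulate_ssa(p, "conventional", V=10.0, t_max=50.0, seed=5)
        np.testing.assert_array_equal(t1.times, t2.times)
        np.testing.assert_array_equal(t1.X, t2.X)
        # every event changes X by one of the allowed jumps
        assert set(np.unique(np.diff(t1.X))) <= {-1, 1}

    def test_histogram_converges_to_exact(self):
        p = standard_parameters(4.0)
        traj = simulate_ssa(p, "conventional", V=10.0, t_max=5000.0, seed=9,
                            record_dt=0.05)
        d = stationary_distribution(p, 10.0)
        emp = trajectory_pmf(traj, 0.1, X_max=d.X_max)
        ref = distribution_histogram(d)
        ref = Histogram1D(edges=ref.edges,
                          weights=ref.weights * emp.weights.sum())
        assert kl_divergence(ref, emp) < 0.05

    def test_unknown_scheme_rejected(self, std):
        with pytest.raises(ValueError):
            simulate_ssa(std, scheme="nonsense")


class TestTrajectoryHistogram:
    def test_constant_trajectory_single_bin(self):
        traj = Trajectory(times=[0.0, 1.0, 2.0], X=[5, 5, 5], X2=[0, 0, 0],
                          scheme="conventional", V=10.0, t_max=3.0)
        h = trajectory_histogram(traj, burn_in_fraction=0.0, bin_width=0.1)
        assert (h.weights > 0).sum() == 1

    def test_square_wave_equal_dwell(self):
        times = np.arange(0.0, 10.0, 0.5)
        X = np.where(np.arange(len(times)) % 2 == 0, 2, 20)
        traj = Trajectory(times=times, X=X, X2=np.zeros_like(X),
                          scheme="conventional", V=10.0, t_max=10.0)
        h = trajectory_histogram(traj, burn_in_fraction=0.0, bin_width=0.1)
        occupied = h.weights[h.weights > 0]
        assert len(occupied) == 2
        assert occupied[0] == pytest.approx(occupied[1])

    def test_burn_in_validation(self):
        traj = Trajectory(times=[0.0], X=[1], X2=[0], scheme="conventional",
                          V=1.0, t_max=1.0)
        with pytest.raises(ValueError):
            trajectory_histogram(traj, burn_in_fraction=1.0)

    def test_high_state_mass_grows_with_volume_at_B4(self):
        # beyond the coexistence point of V=10 the high basin gains weight
        p = standard_parameters(4.2)
        masses = []
        for V in (10.0, 30.0):
            d = stationary_distribution(p, V)
            n_mid = int(round(steady_states(p).middle * V))
            masses.append(d.p[n_mid:].sum())
        assert masses[1] > masses[0]


class TestBimodalRange:
    def test_reference_interval_contains_coexistence(self, std):
        rng = bimodal_range(std, 10.0, B_range=(3.4, 5.0), step=0.05)
        assert rng is not None
        assert rng[0] <= 3.7 <= rng[1]

    def test_no_feedback_no_bimodality(self):
        p = standard_parameters(3.7, k_minus2=0.0)
        assert bimodal_range(p, 10.0, B_range=(3.0, 5.0), step=0.2) is None

    def test_interval_inside_macroscopic_window_at_V30(self, std):
        rng = bimodal_range(std, 30.0, B_range=(3.0, 4.6), step=0.05)
        assert rng is not None
        assert 3.2772 < rng[0] and rng[1] < 4.8400
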