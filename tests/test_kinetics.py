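"""Population and label-fraction dynamics of the linked compartments."""

import numpy as np
import pytest

import memokin as mk
from memokin.exceptions import DomainError
from conftest import random_kinetic_parameters


def _euler_population(params, x0, t_end, dt=1e-7):
    """Independent brute-force oracle: forward Euler via matrix powers.

    t_end must be a multiple of dt so no grid mismatch enters."""
    a = np.array([
        [params.p1 - params.z1s, 0.0],
        [params.m, params.p2 - params.z2s],
    ])
    n = int(round(t_end / dt))
    step = np.eye(2) + dt * a
    return np.linalg.matrix_power(step, n) @ np.array([x0.x1, x0.x2])


class TestPopulation:
    def test_balanced_birth_death_is_constant(self):
        params = mk.KineticParameters(p1=0.01, z1s=0.01, p2=0.02, z2s=0.02, mR=0.0)
        out = mk.population_trajectories(
            params, mk.PopulationState(100.0, 50.0), [0, 10, 100]
        )
        for state in out:
            assert state.x1 == pytest.approx(100.0, rel=1e-12)
            assert state.x2 == pytest.approx(50.0, rel=1e-12)

    def test_isolated_target_pool_decays_exponentially(self):
        params = mk.KineticParameters(p1=0.0, z1s=0.0, p2=0.0, z2s=0.03, mR=0.0)
        out = mk.population_trajectories(
            params, mk.PopulationState(0.0, 80.0), [25.0]
        )
        assert out[0].x2 == pytest.approx(80.0 * np.exp(-0.03 * 25.0), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_small_step_euler_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = random_kinetic_parameters(rng)
        x0 = mk.PopulationState(rng.uniform(10, 200), rng.uniform(10, 200))
        dt = 1e-7
        times = np.round(np.sort(rng.uniform(0.5, 20.0, 5)) / dt) * dt
        out = mk.population_trajectories(params, x0, times)
        for state, t in zip(out, times):
            oracle = _euler_population(params, x0, t)
            assert state.x1 == pytest.approx(oracle[0], rel=1e-6)
            assert state.x2 == pytest.approx(oracle[1], rel=1e-6)

    def test_negative_initial_rejected(self):
        with pytest.raises(DomainError):
            mk.PopulationState(-1.0, 2.0)


class TestLabelFractions:
    times = 7.0 * np.array([1, 3, 5, 7, 8, 10, 14, 18], dtype=float)

    def test_no_proliferation_means_no_label(self, spec_curve):
        params = mk.KineticParameters(p1=0.0, z1s=0.01, p2=0.01, z2s=0.01, mR=0.0)
        traj = mk.label_fraction_trajectories(params, spec_curve, self.times)
        assert np.allclose(traj.L1, 0.0)

    def test_starts_at_zero(self, spec_curve, cd4_median_params):
        traj = mk.label_fraction_trajectories(
            cd4_median_params, spec_curve, [0.0, 7.0]
        )
        assert traj.L1[0] == 0.0 and traj.L2[0] == 0.0

    def test_constant_forcing_steady_state(self):
        # U == f throughout: L1 -> p1 bw f / z1* = 0.005*3.5*0.015/0.01
        curve = mk.BodyWaterCurve(f=0.015, delta=0.02, beta=0.015, tau=1e5)
        params = mk.KineticParameters(p1=0.005, z1s=0.01, p2=0.0, z2s=0.01, mR=0.0)
        traj = mk.label_fraction_trajectories(params, curve, [5000.0])
        assert traj.L1[0] == pytest.approx(0.02625, rel=1e-9)

    def test_conversion_feeds_target_without_its_own_division(self, spec_curve):
        params = mk.KineticParameters(p1=0.01, z1s=0.01, p2=0.0, z2s=0.01, mR=0.01)
        traj = mk.label_fraction_trajectories(params, spec_curve, self.times)
        assert np.all(traj.L2 > 0.0)

    def test_l2_decouples_from_source_when_mr_zero(self, spec_curve):
        a = mk.KineticParameters(p1=0.01, z1s=0.02, p2=0.006, z2s=0.016, mR=0.0)
        b = mk.KineticParameters(p1=0.03, z1s=0.001, p2=0.006, z2s=0.016, mR=0.0)
        ta = mk.label_fraction_trajectories(a, spec_curve, self.times)
        tb = mk.label_fraction_trajectories(b, spec_curve, self.times)
        np.testing.assert_allclose(ta.L2, tb.L2, rtol=1e-12)

    def test_linear_in_amplification_factor(self, spec_curve):
        base = dict(p1=0.005, z1s=0.014, p2=0.006, z2s=0.016, mR=0.002)
        one = mk.label_fraction_trajectories(
            mk.KineticParameters(**base, bw=3.5), spec_curve, self.times
        )
        two = mk.label_fraction_trajectories(
            mk.KineticParameters(**base, bw=7.0), spec_curve, self.times
        )
        np.testing.assert_allclose(2.0 * one.L1, two.L1, rtol=1e-12)
        np.testing.assert_allclose(2.0 * one.L2, two.L2, rtol=1e-12)

    def test_label_decays_after_washout(self, spec_curve, cd4_median_params):
        late = np.array([200.0, 400.0, 800.0])
        traj = mk.label_fraction_trajectories(cd4_median_params, spec_curve, late)
        assert np.all(np.diff(traj.L1) < 0)
        assert np.all(np.diff(traj.L2) < 0)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_closed_form_agrees_with_integration(self, spec_curve, seed):
        rng = np.random.default_rng(seed)
        params = random_kinetic_parameters(rng)
        closed = mk.label_fraction_trajectories(
            params, spec_curve, self.times, method="closed"
        )
        ode = mk.label_fraction_trajectories(
            params, spec_curve, self.times, method="ode"
        )
        assert np.max(np.abs(closed.L1 - ode.L1)) < 1e-8
        assert np.max(np.abs(closed.L2 - ode.L2)) < 1e-8

    def test_conversion_without_division_variant_differs(self, spec_curve):
        params = mk.KineticParameters(p1=0.01, z1s=0.02, p2=0.003,
                                      z2s=0.016, mR=0.05)
        coincident = mk.label_fraction_trajectories(
            params, spec_curve, self.times
        )
        alt = mk.label_fraction_trajectories(
            params, spec_curve, self.times,
            method="ode", variant="conversion_without_division",
        )
        np.testing.assert_allclose(alt.L1, coincident.L1, atol=1e-9)
        assert np.max(np.abs(alt.L2 - coincident.L2)) > 1e-4


class TestUptakePair:
    def test_reported_target_coefficient_is_p2_plus_mr(self):
        # published DW01 CD4 row: p2 = 0.59, mR = 0.02 %/day
        params = mk.KineticParameters(
            p1=0.0033, z1s=0.0088, p2=0.0059, z2s=0.0124, mR=0.0002
        )
        src, tgt = mk.label_uptake_rate_pair(params)
        assert src == pytest.approx(0.0033)
        assert tgt == pytest.approx(0.0061)

    def test_reduces_to_proliferation_rates_without_conversion(self):
        params = mk.KineticParameters(p1=0.01, z1s=0.01, p2=0.02, z2s=0.01, mR=0.0)
        assert mk.label_uptake_rate_pair(params) == (0.01, 0.02)

    def test_zero_rates_give_zero_pair(self):
        params = mk.KineticParameters(p1=0.0, z1s=0.01, p2=0.0, z2s=0.01, mR=0.0)
        assert mk.label_uptake_rate_pair(params) == (0.0, 0.0)
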