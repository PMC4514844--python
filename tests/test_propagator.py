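"""Propagation matrix assembly and time stepping."""

import math

import numpy as np
import pytest
from scipy.special import erfc

from gdqprop.exact import PhysicalParams, always_on_profile, flux_factor
from gdqprop.propagator import (AlwaysOnSource, BernoulliSource,
                                DivergenceError, ReactionParams,
                                ScheduleSource, SimulationState,
                                ThresholdFeedbackSource, assemble,
                                load_matrix, run, save_matrix, step,
                                step_reaction)


@pytest.fixture
def zero_state(small_P):
    return SimulationState(rho=np.zeros(small_P.grid.I))


class TestAssembly:
    def test_origin_row_is_zero_and_source_is_one(self, small_P):
        # W(0, .) == 0, so the R = 0 row never propagates anything; the
        # source vector still carries erfc(0) = 1 there
        row0 = small_P.W.getrow(0)
        assert row0.nnz == 0
        assert small_P.s[0] == 1.0

    def test_uniform_concentration_fixed_point(self, small_P):
        # quadrature reproduces the first moment exactly and stencils are
        # exact for degree 1, so c*R is invariant under free diffusion
        R = small_P.grid.points
        err = np.max(np.abs(small_P.dense @ R - R)) / R[-1]
        assert err < 1e-12

    def test_sparsity_bound(self, small_P, optimal_P):
        for P in (small_P, optimal_P):
            assert P.nnz <= P.grid.I * (P.NF + P.N)

    def test_single_exact_propagation_of_erfc(self, optimal_P):
        """One application of W to F*erfc(R) plus the source term must give
        the two-step profile F*erfc(R/sqrt(2)) within the validated error
        budget of this configuration."""
        R = optimal_P.grid.points
        F = 2.0
        rho2 = optimal_P.dense @ (F * erfc(R)) + F * optimal_P.s
        err = np.max(np.abs(rho2 - F * erfc(R / math.sqrt(2)))) / F
        assert err < 1e-4

    def test_stencil_too_large_rejected(self, small_grid):
        with pytest.raises(ValueError):
            assemble(small_grid, 4, small_grid.I + 1)


class TestStep:
    def test_first_step_is_exact(self, small_P, zero_state):
        # W @ 0 = 0: no interpolation error on the first step
        st = step(zero_state, small_P, 1, 3.0)
        np.testing.assert_array_equal(st.rho, 3.0 * small_P.s)
        assert st.step == 1
        assert st.chi_history == [1]

    def test_off_source_keeps_zero(self, small_P, zero_state):
        st = step(zero_state, small_P, 0, 5.0)
        np.testing.assert_array_equal(st.rho, np.zeros(small_P.grid.I))

    def test_linearity(self, small_P):
        rng = np.random.default_rng(0)
        a = rng.normal(size=small_P.grid.I)
        b = rng.normal(size=small_P.grid.I)
        sa = step(SimulationState(rho=a), small_P, 0, 1.0).rho
        sb = step(SimulationState(rho=b), small_P, 0, 1.0).rho
        sab = step(SimulationState(rho=a + b), small_P, 0, 1.0).rho
        np.testing.assert_allclose(sab, sa + sb, atol=1e-12)

    def test_ten_on_steps_track_closed_form(self, optimal_P):
        st = SimulationState(rho=np.zeros(optimal_P.grid.I))
        for _ in range(10):
            st = step(st, optimal_P, 1, 1.0)
        err = np.max(np.abs(st.rho -
                            always_on_profile(optimal_P.grid.points, 10)))
        assert err < 1e-5

    def test_divergence_raises(self, small_P):
        st = SimulationState(rho=np.full(small_P.grid.I, 1e12),
                             chi_history=[1], F_history=[1.0], step=1)
        with pytest.raises(DivergenceError):
            step(st, small_P, 1, 1.0)

    def test_dt_enters_only_through_flux_factor(self, small_P):
        # the same W serves any dt (unconditional stability): only the
        # flux factor and the physical mapping change
        fast = PhysicalParams(D=1e-9, dt=1e-7, j=1e7)
        slow = PhysicalParams(D=1e-9, dt=4e-7, j=1e7)
        assert flux_factor(fast) == pytest.approx(2 * flux_factor(slow))
        t_fast = run(small_P, fast, AlwaysOnSource(1e7), 3, record_every=1)
        t_slow = run(small_P, slow, AlwaysOnSource(1e7), 3, record_every=1)
        np.testing.assert_allclose(t_fast.rho, 2 * t_slow.rho, rtol=1e-12)


class TestReactionStep:
    rp = ReactionParams(k_on=1e8, k_off=1e3, b_free=1e-3, B_bound=1e-4)

    def test_zero_rates_reduce_to_diffusion(self, small_P, zero_state):
        off = ReactionParams(k_on=0.0, k_off=0.0, b_free=0.0, B_bound=0.0)
        a = step(zero_state, small_P, 1, 1.0).rho
        b = step_reaction(zero_state, small_P, 1, 1.0, off, 1e-7).rho
        np.testing.assert_array_equal(a, b)

    def test_unbinding_source_is_kernel_normalized(self, small_P, zero_state):
        # one step from rho = 0 with the source off: the heat kernel
        # integrates to 1 over R^3, so a uniform c = k_off*B*dt appears
        dt = 1e-9
        st = step_reaction(zero_state, small_P, 0, 0.0, self.rp, dt)
        R = small_P.grid.points
        np.testing.assert_allclose(st.rho[1:] / R[1:],
                                   self.rp.k_off * self.rp.B_bound * dt,
                                   rtol=1e-10)

    def test_chemical_equilibrium_is_fixed_point(self, small_P):
        c_eq = self.rp.k_off * self.rp.B_bound / (self.rp.k_on * self.rp.b_free)
        st = SimulationState(rho=c_eq * small_P.grid.points)
        st2 = step_reaction(st, small_P, 0, 0.0, self.rp, 1e-9)
        np.testing.assert_allclose(st2.rho, st.rho, atol=1e-12 * c_eq)

    def test_one_step_truncation_is_second_order(self, small_P):
        """Against the exact uniform relaxation c(dt) = c_eq(1 - e^{-kt}),
        the one-point time quadrature has O(dt^2) local error: halving dt
        must shrink the residual ~4x."""
        k = self.rp.k_on * self.rp.b_free
        c_eq = self.rp.k_off * self.rp.B_bound / k
        res = []
        for dt in (4e-9, 2e-9, 1e-9):
            st = step_reaction(SimulationState(rho=np.zeros(small_P.grid.I)),
                               small_P, 0, 0.0, self.rp, dt)
            c_sim = st.rho[5] / small_P.grid.points[5]
            res.append(abs(c_sim - c_eq * (1 - math.exp(-k * dt))))
        assert 3.0 < res[0] / res[1] < 5.5
        assert 3.0 < res[1] / res[2] < 5.5

    def test_contraction_precondition(self, small_P, zero_state):
        with pytest.raises(ValueError):
            step_reaction(zero_state, small_P, 0, 0.0, self.rp, 1.0)

    def test_printed_factor_toggle(self, small_P, zero_state):
        dt = 1e-9
        st1 = step_reaction(zero_state, small_P, 0, 0.0, self.rp, dt)
        st4 = step_reaction(zero_state, small_P, 0, 0.0, self.rp, dt,
                            buffer_source_multiplier=4.0)
        np.testing.assert_allclose(st4.rho, 4 * st1.rho, rtol=1e-13)


class TestRun:
    params = PhysicalParams(D=1e-9, dt=1e-7, j=1e7, c0=0.0, c0_unit="M")

    def test_single_always_on_step(self, small_P):
        traj = run(small_P, self.params, AlwaysOnSource(1e7), 1, unit="M")
        F = flux_factor(self.params, unit="M")
        np.testing.assert_allclose(traj.rho[-1], F * small_P.s, rtol=1e-14)

    def test_same_seed_is_bit_identical(self, small_P):
        t1 = run(small_P, self.params, BernoulliSource(0.5, 1e7), 25, seed=11,
                 unit="M")
        t2 = run(small_P, self.params, BernoulliSource(0.5, 1e7), 25, seed=11,
                 unit="M")
        np.testing.assert_array_equal(t1.rho, t2.rho)
        np.testing.assert_array_equal(t1.history.chi, t2.history.chi)

    def test_schedule_source_replay(self, small_P):
        chi = np.array([1, 1, 0, 1, 0, 0, 1, 1, 0, 1])
        traj = run(small_P, self.params, ScheduleSource(chi, 1e7), 10,
                   unit="M")
        np.testing.assert_array_equal(traj.history.chi, chi)

    def test_feedback_gate_consistent_with_recorded_profile(self, small_P):
        """Replay oracle: rerunning the realized chi history through the
        plain stepper must reproduce the feedback trajectory."""
        F = flux_factor(self.params, unit="M")
        src = ThresholdFeedbackSource(j=1e7, sense_index=3,
                                      threshold=0.5 * F)
        traj = run(small_P, self.params, src, 40, unit="M")
        chi = traj.history.chi
        assert chi.min() == 0 and chi.max() == 1  # the gate actually toggles
        st = SimulationState(rho=np.zeros(small_P.grid.I))
        for n in range(40):
            st = step(st, small_P, chi[n], F)
        np.testing.assert_array_equal(st.rho, traj.rho[-1])

    def test_record_every(self, small_P):
        traj = run(small_P, self.params, AlwaysOnSource(1e7), 10,
                   record_every=4, unit="M")
        assert traj.steps.tolist() == [4, 8, 10]

    def test_trajectory_csv(self, small_P, tmp_path):
        traj = run(small_P, self.params, AlwaysOnSource(1e7), 3, unit="M")
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert df.shape == (3, 3 + small_P.grid.I)
        np.testing.assert_allclose(df.iloc[-1, 3:].to_numpy(), traj.rho[-1])


def test_matrix_cache_roundtrip(small_P, tmp_path):
    path = tmp_path / "matrix.json"
    save_matrix(path, small_P)
    back = load_matrix(path)
    assert back.nnz == small_P.nnz
    np.testing.assert_array_equal(back.W.toarray(), small_P.W.toarray())
    np.testing.assert_array_equal(back.s, small_P.s)
    assert (back.N, back.NF) == (small_P.N, small_P.NF)
    np.testing.assert_array_equal(back.grid.points, small_P.grid.points)
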