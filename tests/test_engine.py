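"""Solver-level tests: rate-matrix assembly, RK4 vs matrix exponential,
equilibrium distributions, conservation."""

import numpy as np
import pytest

from navgate import engine
from navgate.engine import (RateMatrix, StabilityError, assemble_rate_matrix,
                            equilibrium, integrate, peak_conducting,
                            solve_oracle)
from navgate.model import ChannelModel, ModelError, Transition
from navgate.tetracube import build_free_model, state_name

from conftest import random_rate_matrix


def two_state(k12: float, k21: float) -> RateMatrix:
    return RateMatrix(states=("a", "b"),
                      Q=np.array([[-k12, k21], [k12, -k21]]))


class TestAssembly:
    def test_symmetric_two_state_matrix(self):
        model = ChannelModel(
            name="toy", states=("a", "b"),
            transitions=(Transition("a", "b", lambda v: 5.0),
                         Transition("b", "a", lambda v: 5.0)),
            conducting=frozenset({"a"}))
        rm = assemble_rate_matrix(model, None, -80.0)
        np.testing.assert_allclose(rm.Q, [[-5.0, 5.0], [5.0, -5.0]])
        rm.validate()

    def test_unknown_state_reference_raises(self):
        with pytest.raises(ModelError):
            ChannelModel(name="bad", states=("a",),
                         transitions=(Transition("a", "zz", lambda v: 1.0),),
                         conducting=frozenset({"a"}))

    def test_zero_concentration_kills_binding_only(self, cube, prototypes):
        drug0 = prototypes["FI_fb"].at(0.0)
        rm = assemble_rate_matrix(cube, drug0, -80.0)
        rm.validate()
        ext = cube.with_drug(drug0)
        i_free = ext.states.index(state_name((True, True, True)))
        i_bound = ext.states.index(state_name((True, True, True), bound=True))
        assert rm.Q[i_bound, i_free] == 0.0  # association off
        assert rm.Q[i_free, i_bound] == pytest.approx(100.0)  # kd intact

    def test_association_scales_linearly_with_concentration(self, cube, prototypes):
        d1 = prototypes["FI_fb"].at(10.0)
        d2 = prototypes["FI_fb"].at(20.0)
        q1 = assemble_rate_matrix(cube, d1, -70.0)
        q2 = assemble_rate_matrix(cube, d2, -70.0)
        ext = cube.with_drug(d1)
        for s in cube.states:
            i, j = ext.states.index(s + "*D"), ext.states.index(s)
            assert q2.Q[i, j] == pytest.approx(2.0 * q1.Q[i, j])

    def test_resting_association_rate_of_fast_prototype(self, cube, prototypes):
        # ka = 0.5 /s/uM at 30 uM gives 15/s into the resting state
        rm = assemble_rate_matrix(cube, prototypes["FI_fb"], -150.0)
        ext = cube.with_drug(prototypes["FI_fb"])
        rest = state_name((False, True, True))
        i, j = ext.states.index(rest + "*D"), ext.states.index(rest)
        assert rm.Q[i, j] == pytest.approx(15.0)

    def test_column_sums_vanish_for_extended_model(self, cube, prototypes):
        rm = assemble_rate_matrix(cube, prototypes["SI_sb"], -20.0)
        rm.validate()
        assert rm.Q.shape == (16, 16)


class TestIntegrate:
    def test_symmetric_model_converges_to_uniform(self):
        rm = two_state(5.0, 5.0)
        traj = integrate([(rm, 2.0)], np.array([1.0, 0.0]))
        np.testing.assert_allclose(traj.occupancies[-1], [0.5, 0.5], atol=1e-9)

    def test_zero_duration_schedule_is_identity(self):
        rm = two_state(5.0, 5.0)
        p0 = np.array([0.25, 0.75])
        traj = integrate([(rm, 0.0)], p0)
        np.testing.assert_allclose(traj.occupancies[-1], p0)

    def test_rk4_matches_oracle_on_random_models(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(2, 6)
            rm = random_rate_matrix(rng, int(n))
            p0 = rng.dirichlet(np.ones(int(n)))
            t = float(rng.uniform(0.01, 0.5))
            traj = integrate([(rm, t)], p0)
            oracle = solve_oracle(rm, t, p0)
            np.testing.assert_allclose(traj.occupancies[-1], oracle, atol=1e-6)

    def test_conservation_along_trajectory(self, cube):
        rm = assemble_rate_matrix(cube, None, -20.0)
        traj = integrate([(rm, 0.5)], equilibrium(
            assemble_rate_matrix(cube, None, -150.0)))
        sums = traj.occupancies.sum(axis=1)
        assert np.abs(sums - 1.0).max() <= 1e-6

    def test_oversized_step_raises_with_advice(self):
        rm = two_state(3000.0, 3000.0)
        with pytest.raises(StabilityError):
            integrate([(rm, 1.0)], np.array([1.0, 0.0]), step=0.01)

    def test_stationarity_from_equilibrium(self, cube):
        rm = assemble_rate_matrix(cube, None, -60.0)
        eq = equilibrium(rm)
        traj = integrate([(rm, 0.05)], eq)
        assert np.abs(traj.occupancies[-1] - eq).max() < 1e-8


class TestOracle:
    def test_t_zero_returns_initial(self):
        rm = two_state(2.0, 7.0)
        p0 = np.array([0.9, 0.1])
        np.testing.assert_allclose(solve_oracle(rm, 0.0, p0), p0)

    def test_irreversible_decay_half_life(self):
        # a -> b at rate 1: after ln 2 seconds half has moved
        rm = two_state(1.0, 0.0)
        p = solve_oracle(rm, np.log(2.0), np.array([1.0, 0.0]))
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)

    def test_long_time_limit_is_equilibrium(self):
        rm = two_state(2.0, 1.0)
        p = solve_oracle(rm, 100.0, np.array([1.0, 0.0]))
        np.testing.assert_allclose(p, equilibrium(rm), atol=1e-10)


class TestEquilibrium:
    def test_detailed_balance_two_state(self):
        np.testing.assert_allclose(
            equilibrium(two_state(2.0, 1.0)), [1.0 / 3.0, 2.0 / 3.0])

    def test_nullspace_identity(self, cube):
        rm = assemble_rate_matrix(cube, None, -45.0)
        eq = equilibrium(rm)
        assert np.abs(rm.Q @ eq).max() < 1e-10 * np.abs(rm.Q).max()

    def test_resting_state_dominates_at_hyperpolarization(self, cube):
        # all gates in their resting conformation at -150 mV
        rm = assemble_rate_matrix(cube, None, -150.0)
        eq = equilibrium(rm)
        rest = cube.states.index(state_name((False, True, True)))
        assert eq[rest] > 0.95

    def test_reducible_matrix_raises(self):
        rm = RateMatrix(states=("a", "b"),
                        Q=np.array([[-1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ModelError):
            equilibrium(rm)


def test_peak_conducting_matches_dense_trajectory(cube):
    rm0 = assemble_rate_matrix(cube, None, -150.0)
    rm1 = assemble_rate_matrix(cube, None, 0.0)
    p0 = equilibrium(rm0)
    peak, p_end = peak_conducting(rm1, cube, p0, 0.010)
    # dense reference via the oracle on a fine grid
    cidx = [rm1.states.index(s) for s in cube.conducting]
    dense = max(solve_oracle(rm1, t, p0)[cidx].sum()
                for t in np.linspace(0, 0.004, 801))
    assert peak == pytest.approx(dense, rel=1e-4)
    np.testing.assert_allclose(p_end, solve_oracle(rm1, 0.010, p0), atol=1e-8)
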