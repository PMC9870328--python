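"""Right-hand sides, Euler stepping, equilibria, and the PLS cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pqnsim.dynamics import (
    NeuronState,
    SimulationError,
    StimulusProgram,
    derivatives,
    euler_step,
    eval_eta,
    eval_piecewise_quadratic,
    find_equilibrium,
    pls_core,
    pls_derivatives,
    simulate,
)
from pqnsim.params import ModeID, PQNParams, complete_parameters, load_mode_params


class TestPiecewiseQuadratic:
    def test_vertex_value_on_negative_branch(self):
        branch = (3.0, -1.0, 0.7, 1.0, 0.0, 0.0)
        assert eval_piecewise_quadratic(-1.0, branch, 0.0) == pytest.approx(0.7)

    def test_completed_toy_junction_continuity(self):
        branch = (1.0, -1.0, 0.0, 2.0, -0.5, 0.5)
        assert eval_piecewise_quadratic(-1e-12, branch, 0.0) == pytest.approx(1.0)
        assert eval_piecewise_quadratic(0.0, branch, 0.0) == pytest.approx(1.0)

    def test_positive_branch_substitution(self):
        branch = (1.0, -1.0, 0.0, 2.0, -0.5, 0.5)
        assert eval_piecewise_quadratic(1.0, branch, 0.0) == pytest.approx(5.0)


class TestEta:
    @pytest.fixture
    def lts(self):
        return load_mode_params("lts")

    def test_below_threshold_gives_eta0(self, lts):
        assert eval_eta(lts.r_u - 1e-9, lts) == lts.eta0

    def test_at_threshold_gives_eta1(self, lts):
        # the switch is right-inclusive: u >= r_u selects eta1
        assert eval_eta(lts.r_u, lts) == lts.eta1

    def test_wrong_variant_rejected(self, toy2var):
        with pytest.raises(ValueError, match="FOUR_VAR_EXT"):
            eval_eta(0.0, toy2var)


class TestDerivatives:
    def test_hand_computed_two_var(self, toy2var):
        # f(-1)=1, g(-1)=2, phi=tau=1, I0=0
        assert derivatives(NeuronState(-1.0, 0.0), 0.0, toy2var) == pytest.approx((1.0, 2.0))

    def test_stimulus_scales_into_dv_only(self, toy2var):
        assert derivatives(NeuronState(-1.0, 0.0), 0.5, toy2var) == pytest.approx((1.5, 2.0))

    def test_equilibrium_gives_zero_vector(self, toy2var_eq):
        eq = find_equilibrium(toy2var_eq)
        der = derivatives(eq, 0.0, toy2var_eq)
        assert np.allclose(der, 0.0, atol=1e-10)

    def test_state_variant_mismatch(self, toy2var):
        with pytest.raises(ValueError, match="does not match"):
            derivatives(NeuronState(0.0, 0.0, q=0.0), 0.0, toy2var)


class TestEulerStep:
    def test_hand_computed_update(self, toy2var):
        s1 = euler_step(NeuronState(-1.0, 0.0), 0.0, toy2var, dt=0.1)
        assert (s1.v, s1.n) == pytest.approx((-0.9, 0.2))

    def test_zero_dt_is_identity(self, toy2var):
        s = NeuronState(-1.0, 0.3)
        s1 = euler_step(s, 0.0, toy2var, dt=0.0)
        assert (s1.v, s1.n) == (s.v, s.n)


class TestSimulate:
    def test_grid_point_count(self, toy2var):
        tr = simulate(toy2var, None, t_max=1.0, init=NeuronState(0.0, 0.0), dt=1e-4)
        assert len(tr) == 10001
        assert tr.times[0] == 0.0
        assert np.allclose(np.diff(tr.times), 1e-4)

    def test_rest_stays_at_rest(self, toy2var_eq):
        tr = simulate(toy2var_eq, None, t_max=0.05)
        assert np.all(tr.v == tr.v[0])
        assert tr.meta["init"] == "equilibrium"

    def test_deterministic_and_byte_identical(self, toy_oscillator):
        stim = StimulusProgram.step(0.01, 0.4)
        a = simulate(toy_oscillator, stim, t_max=0.2)
        b = simulate(toy_oscillator, stim, t_max=0.2)
        assert a.v.tobytes() == b.v.tobytes()
        assert a.n.tobytes() == b.n.tobytes()

    def test_divergence_reports_step_index(self, toy2var):
        # v' = v^2 with v0 large blows up in finite time
        with pytest.raises(SimulationError) as exc:
            simulate(toy2var, None, t_max=1.0, init=NeuronState(50.0, 0.0), dt=1e-2)
        assert exc.value.step is not None

    def test_limit_cycle_isis_are_stable(self, toy_oscillator):
        """After the transient, consecutive cycle lengths agree within 2 dt."""
        from pqnsim.analysis import detect_spikes

        tr = simulate(toy_oscillator, StimulusProgram.constant(0.4), t_max=1.0)
        times = [t for t in detect_spikes(tr).times if t > 0.5]
        isis = np.diff(times)
        assert len(isis) >= 10
        assert np.max(np.abs(np.diff(isis))) <= 2 * toy_oscillator.dt

    def test_euler_first_order_convergence(self, toy2var):
        """Halving dt roughly halves the global error against a dt/64 reference."""
        init = NeuronState(-1.0, 0.0)
        t_end = 0.5

        def final_v(dt):
            tr = simulate(toy2var, None, t_max=t_end, init=init, dt=dt)
            return tr.v[-1]

        ref = final_v(1e-2 / 64)
        e1 = abs(final_v(1e-2) - ref)
        e2 = abs(final_v(5e-3) - ref)
        assert 1.7 <= e1 / e2 <= 2.3


class TestFindEquilibrium:
    def test_leftmost_root_of_toy_system(self, toy2var_eq):
        # -v^2 + 0.25 = 0 has roots +-0.5; the leftmost is -0.5, n = g(-0.5)
        eq = find_equilibrium(toy2var_eq, bracket=(-2.0, 2.0))
        assert eq.v == pytest.approx(-0.5)
        assert eq.n == pytest.approx(0.5)

    def test_no_sign_change_returns_none(self, toy2var):
        # I0=-1: residual -v^2 - 1 has no real root
        from dataclasses import replace

        p = complete_parameters(replace(toy2var, I0=-1.0, b_fp=None))
        assert find_equilibrium(p, bracket=(-2.0, 2.0)) is None

    def test_equilibrium_is_fixed_point_of_stepper(self, toy2var_eq):
        eq = find_equilibrium(toy2var_eq)
        s1 = euler_step(eq, 0.0, toy2var_eq, dt=1e-3)
        assert abs(s1.v - eq.v) < 1e-12
        assert abs(s1.n - eq.n) < 1e-12

    def test_invalid_bracket(self, toy2var):
        with pytest.raises(ValueError, match="bracket"):
            find_equilibrium(toy2var, bracket=(2.0, -2.0))


class TestPLSCore:
    def test_p1_at_origin_offset(self):
        assert pls_core("P1", 3.0, 3.0) == 0.0

    def test_l1_affine(self):
        assert pls_core("L1", 2.0, 0.0, 1.0, 0.5) == pytest.approx(2.0)

    def test_s1_right_inclusive(self):
        # at the threshold the step takes its upper value
        assert pls_core("S1", 1.5, 1.5, "lo", "hi") == "hi"
        assert pls_core("S1", 1.5 - 1e-12, 1.5, "lo", "hi") == "lo"


def _random_params(rng, mode):
    kw = dict(
        mode=mode,
        phi=rng.uniform(0.5, 3), tau=rng.uniform(0.5, 2),
        I0=0.0,  # the PLS formulation omits the bias term
        k=rng.uniform(0.5, 2),
        a_fn=rng.uniform(0.5, 3), b_fn=rng.uniform(-1, 1), c_fn=rng.uniform(-1, 1),
        a_fp=rng.choice([-1, 1]) * rng.uniform(0.5, 3),
        a_gn=rng.uniform(0.5, 3), b_gn=rng.uniform(-1, 1), c_gn=rng.uniform(-1, 1),
        a_gp=rng.uniform(0.5, 3), r_g=rng.uniform(-0.5, 0.5),
    )
    if mode is not ModeID.TOY2VAR:
        kw.update(
            eps_q=rng.uniform(0.01, 1),
            a_hn=rng.uniform(0.5, 3), b_hn=rng.uniform(-1, 1), c_hn=rng.uniform(-1, 1),
            a_hp=rng.uniform(0.5, 3), r_h=rng.uniform(-0.5, 0.5),
        )
    if mode in (ModeID.PB, ModeID.LTS):
        kw.update(eps_u=rng.uniform(0.01, 1), v0=rng.uniform(-1, 1),
                  alpha_u=rng.uniform(0.5, 2))
    if mode is ModeID.LTS:
        kw.update(eta0=rng.uniform(0.3, 3), eta1=rng.uniform(0.3, 3),
                  r_u=rng.uniform(-0.5, 0.5))
    return complete_parameters(PQNParams(**kw))


@pytest.mark.parametrize("mode", [ModeID.TOY2VAR, ModeID.TOY3VAR, ModeID.PB, ModeID.LTS])
def test_pls_formulation_matches_direct_rhs(mode):
    """The P1/L1/S1 assembly equals the direct equations pointwise (I0=0).

    Randomized parameters and states for each variant; agreement to 1e-12.
    """
    rng = np.random.default_rng(20260930)
    for _ in range(50):
        p = _random_params(rng, mode)
        nstate = {ModeID.TOY2VAR: 2, ModeID.TOY3VAR: 3}.get(mode, 4)
        vals = rng.uniform(-2, 2, size=nstate)
        s = NeuronState(*vals)
        I = rng.uniform(-1, 1)
        direct = derivatives(s, I, p)
        via_pls = pls_derivatives(s, I, p)
        assert np.allclose(direct, via_pls, rtol=0, atol=1e-12), (p, s, I)
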