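"""Hill-type muscles, joint moments and forward dynamics."""

import dataclasses
import math

import numpy as np
import pytest

from emgmm.activation import EmgEnvelope
from emgmm.model import (
    MCP_LIMITS,
    WRIST_LIMITS,
    DynamicsConfig,
    JointState,
    ModelDegeneracyError,
    ModelParameters,
    MuscleParameters,
    ce_length,
    forward_dynamics_step,
    joint_moments,
    muscle_force,
    simulate_activation_matrix,
    simulate_cycle,
    vector_to_matrix,
)
from emgmm.synthetic import make_generic_params


class TestParameters:
    def test_generic_is_valid(self, generic):
        generic.validate()
        assert generic["ECRL"].ma_mcp == 0.0
        assert generic["FCR"].ma_mcp == 0.0

    def test_flatten_roundtrip_is_bijection(self, generic, rng):
        bl, bu = ModelParameters.bounds_vectors()
        assert bl.shape == bu.shape == (22,)
        assert np.all(bl < bu)
        vec = rng.uniform(bl, bu)
        assert np.array_equal(ModelParameters.from_vector(vec).to_vector(), vec)
        assert ModelParameters.from_vector(generic.to_vector()) == generic

    def test_out_of_bounds_rejected(self, generic):
        bad = dataclasses.replace(generic["ECRL"], l_opt=0.6)
        with pytest.raises(ValueError, match="l_opt"):
            bad.validate()

    def test_structural_zero_enforced(self, generic):
        bad = dataclasses.replace(generic["FCR"], ma_mcp=0.01)
        with pytest.raises(ValueError, match="ma_mcp"):
            bad.validate()

    def test_vector_to_matrix_restores_structural_zeros(self, generic):
        mat = vector_to_matrix(generic.to_vector())
        assert np.array_equal(mat, generic.to_matrix())
        assert mat[0, 3] == mat[2, 3] == 0.0  # ECRL and FCR ma_mcp

    def test_json_roundtrip(self, generic, tmp_path):
        path = tmp_path / "p.json"
        generic.save(path)
        assert ModelParameters.load(path) == generic


class TestCeLength:
    def test_neutral_posture(self, generic):
        m = generic["EDC"]
        got = ce_length(m, JointState(0.0, 0.0))
        assert got == pytest.approx(m.l_theta0 / 100.0 * m.l_opt)

    def test_flexor_shortens_under_flexion(self, generic):
        m = dataclasses.replace(generic["FCR"], ma_wrist=0.05)
        neutral = ce_length(m, JointState(0.0, 0.0))
        flexed = ce_length(m, JointState(math.degrees(1.0), 0.0))
        assert neutral - flexed == pytest.approx(0.05)

    def test_extensor_lengthens_under_flexion(self, generic):
        m = dataclasses.replace(generic["ECRL"], ma_wrist=0.05)
        neutral = ce_length(m, JointState(0.0, 0.0))
        flexed = ce_length(m, JointState(math.degrees(1.0), 0.0))
        assert flexed - neutral == pytest.approx(0.05)

    def test_degenerate_length_raises(self):
        m = MuscleParameters("FDS", l_opt=0.1, F0_CE=10, ma_wrist=0.05,
                             ma_mcp=0.05, l_theta0=75, K_PEE=10)
        with pytest.raises(ModelDegeneracyError):
            ce_length(m, JointState(75.0, 90.0))


class TestMuscleForce:
    def test_passive_slack_gives_zero(self, generic):
        m = generic["FDS"]
        assert muscle_force(0.0, m, JointState(0.0, 45.0)) >= 0.0
        # at/below optimal length with zero activation: exactly zero
        short = dataclasses.replace(m, l_theta0=90.0)
        assert muscle_force(0.0, short, JointState(0.0, 0.0)) == 0.0

    def test_peak_isometric_force(self, generic):
        m = dataclasses.replace(generic["ECRL"], l_theta0=100.0)
        assert muscle_force(1.0, m, JointState(0.0, 0.0)) == pytest.approx(m.F0_CE)

    def test_passive_quadratic_law(self):
        # stretched 0.1 m beyond optimal with K = 100 N/m^2 -> 1.0 N
        m = MuscleParameters("FCR", l_opt=0.2, F0_CE=100, ma_wrist=0.03,
                             ma_mcp=0.0, l_theta0=100 * 0.3 / 0.2, K_PEE=100)
        f = muscle_force(0.0, m, JointState(0.0, 0.0))
        assert f == pytest.approx(100 * 0.1 ** 2)

    def test_invalid_activation_rejected(self, generic):
        with pytest.raises(ValueError):
            muscle_force(1.5, generic["EDC"], JointState())


class TestJointMoments:
    def test_zero_forces(self, generic):
        assert joint_moments(np.zeros(4), generic) == (0.0, 0.0)

    def test_balanced_antagonists_cancel(self, generic):
        # generic moment arms are equal across muscles
        m_w, m_m = joint_moments(np.array([10.0, 10.0, 10.0, 10.0]), generic)
        assert m_w == pytest.approx(0.0)
        assert m_m == pytest.approx(0.0)

    def test_single_flexor(self, generic):
        fcr = dataclasses.replace(generic["FCR"], ma_wrist=0.02)
        params = ModelParameters(tuple(
            fcr if m.name == "FCR" else m for m in generic.muscles))
        m_w, m_m = joint_moments(np.array([0.0, 0.0, 100.0, 0.0]), params)
        assert m_w == pytest.approx(2.0)
        assert m_m == 0.0  # FCR does not cross the MCP


class TestForwardDynamics:
    def test_equilibrium_is_fixed_point(self, dynamics):
        s = JointState(10.0, 45.0, 0.0, 0.0)
        out = forward_dynamics_step(s, (0.0, 0.0), dynamics)
        assert out == s

    def test_undamped_velocity_grows_linearly(self):
        dyn = DynamicsConfig(b_wrist=0.0, b_mcp=0.0)
        s = JointState(0.0, 45.0, 0.0, 0.0)
        out = forward_dynamics_step(s, (0.1, 0.0), dyn)
        expected = math.degrees(0.1 / dyn.I_wrist * dyn.dt)
        assert out.omega_wrist == pytest.approx(expected)

    def test_sustained_moment_clamps_at_limit(self, dynamics):
        s = JointState(70.0, 45.0, 0.0, 0.0)
        for _ in range(300):
            s = forward_dynamics_step(s, (5.0, 0.0), dynamics)
        assert s.theta_wrist == WRIST_LIMITS[1]
        assert s.omega_wrist == 0.0


class TestSimulateCycle:
    def test_zero_emg_from_equilibrium_holds_posture(self, generic, constants):
        # at the neutral posture every muscle sits at its slack length, so
        # zero activation produces no force at all
        emg = EmgEnvelope(np.zeros((300, 4)))
        est = simulate_cycle(emg, generic, constants,
                             init=JointState(0.0, 0.0, 0.0, 0.0))
        assert np.all(est.wrist_deg == 0.0)
        assert np.all(est.mcp_deg == 0.0)

    def test_deterministic(self, generic, constants, rng):
        emg = EmgEnvelope(rng.uniform(0, 0.8, size=(500, 4)))
        a = simulate_cycle(emg, generic, constants)
        b = simulate_cycle(emg, generic, constants)
        assert np.array_equal(a.wrist_deg, b.wrist_deg)
        assert np.array_equal(a.mcp_deg, b.mcp_deg)

    def test_kernel_matches_stepwise_reference(self, generic, constants, rng):
        """The jitted cycle kernel must agree with chaining the elementary
        public operations sample by sample."""
        from emgmm.activation import activation_from_envelope

        emg = EmgEnvelope(rng.uniform(0, 0.6, size=(120, 4)))
        est = simulate_cycle(emg, generic, constants)
        act = activation_from_envelope(emg.data, constants)
        s = JointState()
        wrist, mcp = [], []
        for t in range(act.shape[0]):
            forces = [muscle_force(act[t, j], m, s)
                      for j, m in enumerate(generic.muscles)]
            s = forward_dynamics_step(s, joint_moments(np.array(forces), generic))
            wrist.append(s.theta_wrist)
            mcp.append(s.theta_mcp)
        assert np.allclose(est.wrist_deg, wrist, atol=1e-9)
        assert np.allclose(est.mcp_deg, mcp, atol=1e-9)

    def test_angles_respect_joint_limits(self, generic, constants, rng):
        emg = EmgEnvelope(rng.uniform(0, 1.0, size=(1000, 4)))
        est = simulate_cycle(emg, generic, constants)
        assert est.wrist_deg.min() >= WRIST_LIMITS[0]
        assert est.wrist_deg.max() <= WRIST_LIMITS[1]
        assert est.mcp_deg.min() >= MCP_LIMITS[0]
        assert est.mcp_deg.max() <= MCP_LIMITS[1]

    @pytest.mark.parametrize("channel,joint,increases", [
        (0, "wrist", False),   # ECRL extends the wrist
        (2, "wrist", True),    # FCR flexes the wrist
        (1, "mcp", False),     # EDC extends the MCP
        (3, "mcp", True),      # FDS flexes the MCP
    ])
    def test_moment_sign_convention(self, generic, constants, channel, joint,
                                    increases):
        emg = np.zeros((200, 4))
        emg[:, channel] = 0.5
        est = simulate_cycle(EmgEnvelope(emg), generic, constants)
        series = est.wrist_deg if joint == "wrist" else est.mcp_deg
        start = 0.0 if joint == "wrist" else 45.0
        if increases:
            assert series[-1] > start
        else:
            assert series[-1] < start

    def test_integrator_halved_step_converges(self, generic, constants,
                                              subject, dynamics):
        """Halving dt (two substeps per EMG sample) moves end-of-cycle
        angles by less than a degree."""
        from emgmm.rl import cycle_activation
        from emgmm.synthetic import generate_subject_cycles

        cycle = generate_subject_cycles(subject, 1, sigma_deg=0.0)[0]
        act = cycle_activation(cycle, constants)
        mat = generic.to_matrix()
        w1, m1, _ = simulate_activation_matrix(act, mat, dynamics)
        half = DynamicsConfig(dt=dynamics.dt / 2)
        w2, m2, _ = simulate_activation_matrix(np.repeat(act, 2, axis=0), mat,
                                               half)
        assert abs(w1[-1] - w2[-1]) < 1.0
        assert abs(m1[-1] - m2[-1]) < 1.0

    def test_degenerate_parameters_raise_or_clamp(self, constants):
        # shortest possible FDS with a maximal MCP moment arm: its CE length
        # hits zero once the MCP flexes past ~86 degrees
        vec = ModelParameters.bounds_vectors()[0].copy()
        idx = {mf: i for i, mf in enumerate(ModelParameters.vector_index())}
        vec[idx[("FDS", "F0_CE")]] = 1000.0
        vec[idx[("FDS", "ma_mcp")]] = 0.05
        params = ModelParameters.from_vector(vec)
        emg = np.zeros((200, 4))
        emg[:, 3] = 1.0  # strong FDS drives MCP far into flexion
        with pytest.raises(ModelDegeneracyError):
            simulate_cycle(EmgEnvelope(emg), params, constants)
        est = simulate_cycle(EmgEnvelope(emg), params, constants,
                             on_degenerate="clamp")
        assert np.isfinite(est.wrist_deg).all()


def test_generic_params_are_midpoints():
    g = make_generic_params()
    assert g["ECRL"].l_opt == pytest.approx(0.3)
    assert g["EDC"].F0_CE == pytest.approx(505.0)
    assert g["FDS"].K_PEE == pytest.approx(105.0)
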