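"""Hill-type muscle mechanics: activation dynamics, force generation,
moment arms (tendon-excursion identity), compressive components."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneeload.model import MuscleTendonUnit, build_default_model
from kneeload.muscle import (
    GeometryError,
    activation_dynamics,
    compressive_component,
    force_components,
    force_velocity,
    moment_arm,
    musculotendon_length,
    quasistatic_tendon_force,
    rigid_tendon_force,
)

DT = 1e-4


class TestActivationDynamics:
    def test_fixed_point(self):
        e = np.full(500, 0.4)
        a = activation_dynamics(e, a0=0.4, dt=DT)
        assert np.allclose(a, 0.4, atol=1e-12)

    def test_activation_step_time_constant(self):
        t = np.arange(0, 0.1, DT)
        a = activation_dynamics(np.ones_like(t), a0=0.0, dt=DT)
        assert a[int(0.015 / DT)] == pytest.approx(1 - np.exp(-1), abs=1e-3)

    def test_deactivation_step_time_constant(self):
        t = np.arange(0, 0.3, DT)
        a = activation_dynamics(np.zeros_like(t), a0=1.0, dt=DT)
        assert a[int(0.060 / DT)] == pytest.approx(np.exp(-1), abs=1e-3)

    def test_large_dt_warns(self):
        with pytest.warns(RuntimeWarning):
            activation_dynamics(np.ones(10), 0.0, dt=0.01)

    def test_invalid_excitation_rejected(self):
        with pytest.raises(ValueError):
            activation_dynamics(np.array([0.5, 1.4]), 0.0, DT)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_trajectories_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        e = np.clip(rng.uniform(-0.1, 1.1, 300), 0, 1)
        a = activation_dynamics(e, a0=rng.uniform(0, 1), dt=1e-3,
                                tau_act=0.015, tau_deact=0.060)
        assert np.all((a >= 0) & (a <= 1))


class TestMomentArms:
    def test_constant_coefficient(self):
        mtu = MuscleTendonUnit("flat", 100, 0.1, 0.2, 0.0,
                               {"knee": (0.03,)}, None)
        for q in (-0.5, 0.0, 1.2):
            assert moment_arm(mtu, "knee", q) == pytest.approx(0.03)

    def test_unspanned_joint_rejected(self, model70):
        with pytest.raises(ValueError):
            moment_arm(model70.muscles["soleus"], "knee", 0.1)

    def test_tendon_excursion_identity_all_muscles(self, model70):
        # r_j = -d(l_mt)/d(q_j) for every muscle over the motion range
        rng = np.random.default_rng(2)
        eps = 1e-7
        for mtu in model70.muscles.values():
            for _ in range(5):
                q = {"hip": rng.uniform(-0.5, 1.0),
                     "knee": rng.uniform(0.0, 2.0),
                     "ankle": rng.uniform(-0.6, 0.5)}
                for joint in mtu.moment_arm_coeffs:
                    qp, qm = dict(q), dict(q)
                    qp[joint] += eps
                    qm[joint] -= eps
                    dl = (musculotendon_length(mtu, qp)
                          - musculotendon_length(mtu, qm)) / (2 * eps)
                    r = moment_arm(mtu, joint, q[joint])
                    assert -dl == pytest.approx(r, rel=1e-6, abs=1e-10)

    def test_vasti_are_knee_extensors_across_range(self, model70):
        for name in ("vasmed", "vaslat", "vasint"):
            mtu = model70.muscles[name]
            q = np.linspace(0.0, 2.0, 50)
            assert np.all(moment_arm(mtu, "knee", q) < 0)


class TestRigidTendonForce:
    def _ref_posture(self, model):
        return model.config["reference_posture"]

    def test_zero_activation_at_optimal_length_gives_zero(self, model70):
        ref = self._ref_posture(model70)
        qdot = {j: 0.0 for j in ref}
        for mtu in model70.muscles.values():
            f = rigid_tendon_force(mtu, ref, qdot, 0.0,
                                   model70.config["hill_curves"], ref)
            assert f == pytest.approx(0.0, abs=1e-9)

    def test_peak_isometric_force_definition(self):
        # unpennated muscle at optimal length, zero velocity, full drive
        mtu = MuscleTendonUnit("flat", 1234.0, 0.1, 0.2, 0.0,
                               {"knee": (0.03,)}, None,
                               l_anchor=0.2 + 0.1)
        ref = {"knee": 0.35}
        f = rigid_tendon_force(mtu, {"knee": 0.35}, {"knee": 0.0}, 1.0,
                               ref_posture=ref)
        assert f == pytest.approx(1234.0, rel=1e-12)

    def test_force_vanishes_at_max_shortening(self, model70):
        hill = model70.config["hill_curves"]
        mtu = model70.muscles["vaslat"]
        ref = self._ref_posture(model70)
        # knee extending fast enough to drive fiber shortening past v_max
        # (v_fiber = cos(penn) * v_mt = -cos(penn) * r * qdot; the extensor
        # arm is negative, so extension means negative qdot)
        r = moment_arm(mtu, "knee", ref["knee"])
        qdot_needed = 1.3 * hill["v_max"] * mtu.l_opt / r
        assert qdot_needed < 0
        f = rigid_tendon_force(mtu, ref, {"knee": qdot_needed}, 1.0, hill, ref)
        f0 = rigid_tendon_force(mtu, ref, {"knee": 0.0}, 1.0, hill, ref)
        assert f < 0.05 * f0

    def test_monotone_in_activation(self, model70):
        mtu = model70.muscles["gasmed"]
        ref = self._ref_posture(model70)
        qdot = {j: 0.3 for j in ref}
        forces = [rigid_tendon_force(mtu, ref, qdot, a,
                                     model70.config["hill_curves"], ref)
                  for a in np.linspace(0, 1, 11)]
        assert np.all(np.diff(forces) >= 0)

    def test_nonpositive_fiber_projection_errors(self):
        mtu = MuscleTendonUnit("short", 100.0, 0.05, 0.3, 0.0,
                               {"knee": (0.3,)}, None, l_anchor=0.35)
        with pytest.raises(GeometryError, match="short"):
            # huge flexion shortens the path past the tendon slack length
            rigid_tendon_force(mtu, {"knee": 2.0}, {"knee": 0.0}, 0.5,
                               ref_posture={"knee": 0.0})


def test_force_velocity_curve_anchors():
    assert force_velocity(0.0) == pytest.approx(1.0)
    assert force_velocity(-12.0, v_max=12.0) == pytest.approx(0.0)
    assert force_velocity(1e9) == pytest.approx(1.4, abs=1e-3)  # eccentric plateau
    # continuity at zero velocity
    assert force_velocity(-1e-9) == pytest.approx(force_velocity(1e-9), abs=1e-6)


class TestCompressiveComponent:
    def test_zero_force_gives_zero(self, model70):
        assert compressive_component(model70.muscles["vaslat"], 0.5, 0.0) == 0.0

    def test_fraction_times_force(self):
        mtu = MuscleTendonUnit("x", 100, 0.1, 0.1, 0.0,
                               {"knee": (0.03,)}, (0.9,))
        assert compressive_component(mtu, 0.7, 1000.0) == pytest.approx(900.0)

    def test_non_knee_spanning_returns_zero(self, model70):
        for angle in (0.0, 0.5, 1.5):
            assert compressive_component(model70.muscles["soleus"], angle,
                                         500.0) == 0.0

    def test_fractions_within_unit_interval_over_rom(self, model70):
        lo, hi = model70.config["joint_range"]["knee"]
        q = np.linspace(lo, hi, 100)
        for mtu in model70.muscles.values():
            frac = compressive_component(mtu, q, np.ones_like(q))
            assert np.all((frac >= 0) & (frac <= 1))


def test_quasistatic_tendon_close_to_rigid_in_statics(model70):
    """A stiff (4% strain) tendon barely changes static force estimates."""
    ref = model70.config["reference_posture"]
    qdot = {j: 0.0 for j in ref}
    for name in ("vaslat", "bflh"):
        mtu = model70.muscles[name]
        rigid = rigid_tendon_force(mtu, ref, qdot, 0.6,
                                   model70.config["hill_curves"], ref)
        elastic = quasistatic_tendon_force(mtu, ref, 0.6,
                                           model70.config["hill_curves"],
                                           ref_posture=ref)
        assert elastic == pytest.approx(rigid, rel=0.15)
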