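"""Planar whole-body kinematics, inverse dynamics, and the muscle-free
(intersegmental) knee joint reaction.

The skeleton is a sagittal 9-DOF linkage: the hip point translates with the
trunk DOFs, the head-arms-trunk (HAT) segment extends upward, and each leg
hangs as a thigh-shank-foot chain.  Net joint moments come from recursive
Newton-Euler with central-difference accelerations (filter-then-
differentiate); the intersegmental contribution to compressive tibiofemoral
force is the free-body reaction of the foot+shank subsystem under GRF,
gravity and inertial loads, projected onto the tibia long axis (compression
positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .model import MusculoskeletalModel


class InputError(ValueError):
    pass


def lowpass(signal: np.ndarray, fs: float, fc: float = 8.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (GRF and kinematics pre-filter)."""
    if fs <= 2 * fc:
        raise InputError(f"sampling rate {fs} Hz too low for fc={fc} Hz")
    sos = butter(order, fc, btype="lowpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=0)


def _second_derivative(p: np.ndarray, dt: float) -> np.ndarray:
    """Second central difference along axis 0; one-sided at the endpoints."""
    a = np.empty_like(p)
    a[1:-1] = (p[2:] - 2 * p[1:-1] + p[:-2]) / dt**2
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def _gradient(p: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(p, dt, axis=0)


def _cross2(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    return r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]


@dataclass
class PlanarKinematics:
    """Segment positions, absolute angles and accelerations over time."""

    dt: float
    joints: dict[str, np.ndarray]    # (n, 2) positions: hip, knee_r, ankle_r, toe_r, ...
    coms: dict[str, np.ndarray]      # (n, 2) per segment
    angles: dict[str, np.ndarray]    # absolute segment angles (n,)
    com_acc: dict[str, np.ndarray]
    ang_acc: dict[str, np.ndarray]

    @property
    def n(self) -> int:
        return next(iter(self.coms.values())).shape[0]


def compute_kinematics(
    model: MusculoskeletalModel, q: dict[str, np.ndarray], dt: float
) -> PlanarKinematics:
    """Forward kinematics of the planar chain from generalized coordinates.

    ``q`` maps DOF names (trunk_x, trunk_y, trunk_rot, hip/knee/ankle per
    side) to time series in SI units/radians.
    """
    hip = np.stack([np.asarray(q["trunk_x"], float),
                    np.asarray(q["trunk_y"], float)], axis=-1)
    phi = np.asarray(q["trunk_rot"], dtype=float)

    hat = model.segments["HAT"]
    u_hat = np.stack([np.sin(phi), np.cos(phi)], axis=-1)  # hip -> head
    joints: dict[str, np.ndarray] = {"hip": hip}
    coms = {"HAT": hip + hat.com_offset * u_hat}
    angles = {"HAT": phi}

    for side in ("r", "l"):
        th = model.segments[f"thigh_{side}"]
        sh = model.segments[f"shank_{side}"]
        ft = model.segments[f"foot_{side}"]
        th_abs = phi + np.asarray(q[f"hip_{side}"], float)
        sh_abs = th_abs - np.asarray(q[f"knee_{side}"], float)
        ft_abs = sh_abs + np.asarray(q[f"ankle_{side}"], float)

        def down(theta):
            return np.stack([np.sin(theta), -np.cos(theta)], axis=-1)

        d_th, d_sh = down(th_abs), down(sh_abs)
        e_ft = np.stack([np.cos(ft_abs), np.sin(ft_abs)], axis=-1)
        knee = hip + th.length * d_th
        ankle = knee + sh.length * d_sh
        toe = ankle + ft.length * e_ft
        joints[f"knee_{side}"] = knee
        joints[f"ankle_{side}"] = ankle
        joints[f"toe_{side}"] = toe
        coms[f"thigh_{side}"] = hip + th.com_offset * d_th
        coms[f"shank_{side}"] = knee + sh.com_offset * d_sh
        coms[f"foot_{side}"] = ankle + ft.com_offset * e_ft
        angles[f"thigh_{side}"] = th_abs
        angles[f"shank_{side}"] = sh_abs
        angles[f"foot_{side}"] = ft_abs

    com_acc = {k: _second_derivative(v, dt) for k, v in coms.items()}
    ang_acc = {k: _second_derivative(v, dt) for k, v in angles.items()}
    return PlanarKinematics(dt=dt, joints=joints, coms=coms, angles=angles,
                            com_acc=com_acc, ang_acc=ang_acc)


@dataclass
class JointMomentTrace:
    """Net joint moments (flexion-positive, N*m) plus joint reaction forces."""

    time: np.ndarray
    moments: dict[str, np.ndarray]       # hip/knee/ankle per side
    joint_forces: dict[str, np.ndarray]  # proximal-on-distal force, (n, 2)
    kinematics: PlanarKinematics


def _grf_arrays(grf: dict, n: int) -> tuple[np.ndarray, np.ndarray]:
    f = np.stack([np.asarray(grf.get("fx", np.zeros(n)), float),
                  np.asarray(grf.get("fy", np.zeros(n)), float)], axis=-1)
    cop = np.stack([np.asarray(grf.get("cop_x", np.zeros(n)), float),
                    np.zeros(n)], axis=-1)
    return f, cop


def inverse_dynamics(
    model: MusculoskeletalModel,
    q: dict[str, np.ndarray],
    grf: dict,
    dt: float,
    grf_left: dict | None = None,
) -> JointMomentTrace:
    """Recursive Newton-Euler net joint moments on the planar chain.

    ``grf`` applies to the right foot ({fx, fy, cop_x}); an optional
    ``grf_left`` applies to the left.  Gravity is 9.80665 m/s^2.  Moments
    are reported conjugate to the flexion-positive joint coordinates.
    """
    for name, series in q.items():
        if np.any(~np.isfinite(np.asarray(series, float))):
            raise InputError(f"NaN/inf in coordinate {name!r}")
    kin = compute_kinematics(model, q, dt)
    n = kin.n
    g_vec = np.array([0.0, -model.gravity])
    time = np.arange(n) * dt

    moments: dict[str, np.ndarray] = {}
    forces: dict[str, np.ndarray] = {}
    for side, grf_side in (("r", grf), ("l", grf_left)):
        f_ext, cop = _grf_arrays(grf_side or {}, n)
        ft = model.segments[f"foot_{side}"]
        sh = model.segments[f"shank_{side}"]
        th = model.segments[f"thigh_{side}"]

        ankle = kin.joints[f"ankle_{side}"]
        knee = kin.joints[f"knee_{side}"]
        hip = kin.joints["hip"]

        # foot
        com = kin.coms[f"foot_{side}"]
        f_ankle = ft.mass * kin.com_acc[f"foot_{side}"] - ft.mass * g_vec - f_ext
        m_ankle = (
            ft.inertia_com * kin.ang_acc[f"foot_{side}"]
            - _cross2(ankle - com, f_ankle)
            - _cross2(cop - com, f_ext)
        )
        # shank
        com = kin.coms[f"shank_{side}"]
        f_knee = sh.mass * kin.com_acc[f"shank_{side}"] - sh.mass * g_vec + f_ankle
        m_knee = (
            sh.inertia_com * kin.ang_acc[f"shank_{side}"]
            + m_ankle
            - _cross2(knee - com, f_knee)
            - _cross2(ankle - com, -f_ankle)
        )
        # thigh
        com = kin.coms[f"thigh_{side}"]
        f_hip = th.mass * kin.com_acc[f"thigh_{side}"] - th.mass * g_vec + f_knee
        m_hip = (
            th.inertia_com * kin.ang_acc[f"thigh_{side}"]
            + m_knee
            - _cross2(hip - com, f_hip)
            - _cross2(knee - com, -f_knee)
        )

        # map z-moments to flexion-positive generalized coordinates
        moments[f"ankle_{side}"] = m_ankle
        moments[f"knee_{side}"] = -m_knee
        moments[f"hip_{side}"] = m_hip
        forces[f"ankle_{side}"] = f_ankle
        forces[f"knee_{side}"] = f_knee
        forces[f"hip_{side}"] = f_hip
    return JointMomentTrace(time=time, moments=moments, joint_forces=forces,
                            kinematics=kin)


@dataclass
class IntersegmentalTrace:
    """Axial knee force from the muscle-free (torque-driven) free body."""

    time: np.ndarray
    axial_force: np.ndarray  # N, compression positive
    force_vec: np.ndarray    # (n, 2) femur-on-tibia force, lab frame


def intersegmental_reaction(
    model: MusculoskeletalModel,
    q: dict[str, np.ndarray],
    grf: dict,
    dt: float,
    side: str = "r",
) -> IntersegmentalTrace:
    """Knee reaction on the tibia with all muscles replaced by pure torques.

    Free body of the foot+shank subsystem under GRF, gravity and inertial
    loads; the returned axial force is the projection of the femur-on-tibia
    force onto the tibia long axis (knee -> ankle), compression positive.
    By construction it is independent of every muscle parameter.
    """
    kin = compute_kinematics(model, q, dt)
    n = kin.n
    g_vec = np.array([0.0, -model.gravity])
    f_ext, _ = _grf_arrays(grf, n)
    ft = model.segments[f"foot_{side}"]
    sh = model.segments[f"shank_{side}"]
    f_knee = (
        sh.mass * kin.com_acc[f"shank_{side}"]
        + ft.mass * kin.com_acc[f"foot_{side}"]
        - (sh.mass + ft.mass) * g_vec
        - f_ext
    )
    theta = kin.angles[f"shank_{side}"]
    u_tibia = np.stack([np.sin(theta), -np.cos(theta)], axis=-1)  # knee -> ankle
    axial = np.einsum("ij,ij->i", f_knee, u_tibia)
    return IntersegmentalTrace(time=np.arange(n) * dt, axial_force=axial,
                               force_vec=f_knee)


def whole_body_residual(
    model: MusculoskeletalModel,
    q: dict[str, np.ndarray],
    dt: float,
    external_forces: np.ndarray,
) -> np.ndarray:
    """|sum_i m_i a_i - (F_ext + M g)| at interior samples (N).

    Newton's second law for the whole body; ``external_forces`` is the (n, 2)
    total external force (all ground reactions summed).
    """
    kin = compute_kinematics(model, q, dt)
    g_vec = np.array([0.0, -model.gravity])
    total = np.zeros_like(external_forces, dtype=float)
    for name, seg in model.segments.items():
        total += seg.mass * kin.com_acc[name]
    resid = total - (np.asarray(external_forces, float)
                     + model.total_mass * g_vec)
    return np.linalg.norm(resid[1:-1], axis=-1)
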