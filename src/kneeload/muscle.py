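"""Hill-type muscle mechanics: activation dynamics, rigid-tendon force,
moment arms, and compressive force components.

With prescribed kinematics and a rigid tendon, tendon force is an explicit
(affine) function of activation,

    F = f_max * [a * f_L(l~) * f_V(v~) + f_pass(l~)] * cos(pennation),

which keeps the moment constraints of the EMG-informed optimization linear
in activation.  Musculotendon length is the analytic integral of the
moment-arm polynomials (tendon-excursion identity holds by construction),
anchored so the fiber sits at optimal length in a mid-stance reference
posture.  A quasi-static elastic tendon (configurable strain at one
normalized force) is available for fidelity checks.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import MuscleTendonUnit

DEFAULT_HILL = {
    "fl_width": 0.45,
    "v_max": 10.0,
    "fv_a": 0.25,
    "fv_flen": 1.4,
    "passive_k": 4.0,
    "passive_strain": 0.6,
}

DEFAULT_REF_POSTURE = {"hip": 0.2, "knee": 0.35, "ankle": 0.0}


class GeometryError(ValueError):
    pass


def activation_dynamics(
    e: np.ndarray,
    a0: float,
    dt: float,
    tau_act: float = 0.015,
    tau_deact: float = 0.060,
) -> np.ndarray:
    """First-order activation dynamics, trapezoidal integration.

    da/dt = (e - a)/tau with tau = tau_act while excitation exceeds
    activation and tau_deact otherwise.  Output clipped to [0, 1].
    """
    e = np.asarray(e, dtype=float)
    if np.any((e < -1e-12) | (e > 1 + 1e-12)):
        raise ValueError("excitations must lie in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= min(tau_act, tau_deact) / 2:
        warnings.warn(
            f"dt={dt:g} s is large relative to tau_act={tau_act:g} s; "
            "activation integration may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    a = np.empty_like(e)
    a[0] = np.clip(a0, 0.0, 1.0)
    for i in range(e.size - 1):
        # trapezoidal step; the rate constant on each side of the step uses
        # the excitation/activation comparison at that node
        tau_i = tau_act if e[i] > a[i] else tau_deact
        for tau_n in (tau_act, tau_deact):
            num = a[i] * (1 - dt / (2 * tau_i)) + dt / 2 * (
                e[i] / tau_i + e[i + 1] / tau_n
            )
            cand = num / (1 + dt / (2 * tau_n))
            consistent = (e[i + 1] > cand) == (tau_n == tau_act)
            if consistent:
                break
        a[i + 1] = min(1.0, max(0.0, cand))
    return a


def invert_activation(
    a: np.ndarray, dt: float, tau_act: float = 0.015, tau_deact: float = 0.060
) -> np.ndarray:
    """Excitation implied by an activation trajectory (finite-difference
    rate inversion): e = a + tau(da/dt) * da/dt."""
    a = np.asarray(a, dtype=float)
    adot = np.gradient(a, dt)
    tau = np.where(adot > 0, tau_act, tau_deact)
    return a + tau * adot


def moment_arm(mtu: MuscleTendonUnit, joint: str, q) -> np.ndarray | float:
    """Moment arm (m) about a spanned joint; positive = flexor."""
    if joint not in mtu.moment_arm_coeffs:
        raise ValueError(f"muscle {mtu.name} does not span joint {joint!r}")
    c = np.asarray(mtu.moment_arm_coeffs[joint], dtype=float)
    return np.polynomial.polynomial.polyval(q, c)


def musculotendon_length(
    mtu: MuscleTendonUnit, q: dict, ref_posture: dict | None = None
):
    """Musculotendon length from the moment-arm integral.

    l(q) = l_anchor - sum_j int_{q_ref,j}^{q_j} r_j(u) du, so that
    r_j = -dl/dq_j exactly (a positive, flexor, arm shortens the muscle as
    the joint flexes) and the fiber is at optimal length at the reference
    posture.
    """
    ref = DEFAULT_REF_POSTURE if ref_posture is None else ref_posture
    length = mtu.l_anchor
    for joint, coeffs in mtu.moment_arm_coeffs.items():
        c = np.asarray(coeffs, dtype=float)
        anti = np.concatenate([[0.0], c / np.arange(1, c.size + 1)])
        qj = np.asarray(q[joint], dtype=float)
        length = length - (
            np.polynomial.polynomial.polyval(qj, anti)
            - np.polynomial.polynomial.polyval(ref[joint], anti)
        )
    return length


def musculotendon_velocity(mtu: MuscleTendonUnit, q: dict, qdot: dict):
    """d l_mt/dt = - sum_j r_j(q_j) qdot_j."""
    v = 0.0
    for joint in mtu.moment_arm_coeffs:
        v = v - moment_arm(mtu, joint, np.asarray(q[joint], dtype=float)) * np.asarray(
            qdot[joint], dtype=float
        )
    return v


def _fiber_state(mtu: MuscleTendonUnit, l_mt):
    """Rigid-tendon fiber length and pennation cosine."""
    w = mtu.l_opt * np.sin(mtu.pennation_opt)  # constant-thickness pennation
    proj = np.asarray(l_mt, dtype=float) - mtu.l_slack
    if np.any(proj <= 0):
        raise GeometryError(
            f"muscle {mtu.name}: musculotendon length {np.min(l_mt):.4f} m "
            "leaves a nonpositive fiber projection"
        )
    l_fiber = np.sqrt(proj**2 + w**2)
    cos_penn = proj / l_fiber
    return l_fiber, cos_penn


def active_force_length(l_norm, width: float = 0.45):
    return np.exp(-(((np.asarray(l_norm) - 1.0) / width) ** 2))


def force_velocity(v_norm, v_max: float = 10.0, a_f: float = 0.25,
                   f_len: float = 1.4):
    """Hill hyperbola (concentric) with a C1-matched eccentric branch.

    ``v_norm`` is fiber velocity in optimal fiber lengths per second,
    shortening negative; clamps to 0 beyond maximal shortening velocity.
    """
    v = np.asarray(v_norm, dtype=float)
    conc = np.clip((v_max + v) / (v_max - v / a_f), 0.0, None)
    c = (f_len - 1.0) * v_max * a_f / (a_f + 1.0)
    ecc = 1.0 + (f_len - 1.0) * v / (v + c)
    return np.where(v <= 0, conc, ecc)


def passive_force_length(l_norm, k: float = 4.0, strain: float = 0.6):
    l = np.asarray(l_norm, dtype=float)
    fp = (np.exp(k * (l - 1.0) / strain) - 1.0) / (np.exp(k) - 1.0)
    return np.where(l > 1.0, fp, 0.0)


def force_components(
    mtu: MuscleTendonUnit,
    q: dict,
    qdot: dict,
    hill: dict | None = None,
    ref_posture: dict | None = None,
):
    """Active gain and passive offset of the affine force-activation map.

    Returns (F_act, F_pas) such that tendon force = F_act * a + F_pas, N.
    """
    h = DEFAULT_HILL if hill is None else hill
    l_mt = musculotendon_length(mtu, q, ref_posture)
    v_mt = musculotendon_velocity(mtu, q, qdot)
    l_fiber, cos_penn = _fiber_state(mtu, l_mt)
    l_norm = l_fiber / mtu.l_opt
    # rigid tendon: d l_fiber/dt = cos(pennation) * d l_mt/dt
    v_norm = cos_penn * v_mt / mtu.l_opt
    fl = active_force_length(l_norm, h["fl_width"])
    fv = force_velocity(v_norm, h["v_max"], h["fv_a"], h["fv_flen"])
    fp = passive_force_length(l_norm, h["passive_k"], h["passive_strain"])
    f_act = mtu.f_max * fl * fv * cos_penn
    f_pas = mtu.f_max * fp * cos_penn
    return f_act, f_pas


def rigid_tendon_force(
    mtu: MuscleTendonUnit,
    q: dict,
    qdot: dict,
    a,
    hill: dict | None = None,
    ref_posture: dict | None = None,
):
    """Tendon force (N) for activation ``a`` at the given kinematic state."""
    a = np.asarray(a, dtype=float)
    if np.any((a < -1e-12) | (a > 1 + 1e-12)):
        raise ValueError("activation must lie in [0, 1]")
    f_act, f_pas = force_components(mtu, q, qdot, hill, ref_posture)
    return f_act * a + f_pas


def quasistatic_tendon_force(
    mtu: MuscleTendonUnit,
    q: dict,
    a: float,
    hill: dict | None = None,
    strain_at_fmax: float = 0.04,
    ref_posture: dict | None = None,
    tol: float = 1e-10,
) -> float:
    """Tendon force with a quasi-static elastic tendon (fiber velocity 0).

    Solves the fiber/tendon equilibrium f_t(l_t) = [a f_L + f_pass] cos(penn)
    for a tendon with the given strain at one normalized force (quadratic
    tendon curve), by bisection on the fiber projection.  Intended for
    fidelity checks against the rigid-tendon default, not for the
    optimization stages (force is no longer affine in activation).
    """
    h = DEFAULT_HILL if hill is None else hill
    l_mt = float(musculotendon_length(mtu, q, ref_posture))
    w = mtu.l_opt * np.sin(mtu.pennation_opt)

    def tendon_force(l_t):
        # quadratic tendon: zero below slack, f_max at the given strain
        eps = l_t / mtu.l_slack - 1.0
        return mtu.f_max * np.clip(eps / strain_at_fmax, 0.0, None) ** 2 \
            if eps > 0 else 0.0

    def residual(proj):
        l_fiber = np.sqrt(proj**2 + w**2)
        cos_p = proj / l_fiber
        l_norm = l_fiber / mtu.l_opt
        f_muscle = mtu.f_max * (
            a * active_force_length(l_norm, h["fl_width"])
            + passive_force_length(l_norm, h["passive_k"], h["passive_strain"])
        ) * cos_p
        return f_muscle - tendon_force(l_mt - proj)

    lo, hi = 1e-6, l_mt - 1e-9 * mtu.l_slack if mtu.l_slack > 0 else l_mt
    if mtu.l_slack == 0:
        return rigid_tendon_force(mtu, q, {j: 0.0 for j in q}, a, hill,
                                  ref_posture)
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:  # no crossing: tendon slack, muscle force ~ 0
        return float(tendon_force(l_mt - lo))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = residual(mid)
        if abs(fm) < tol * mtu.f_max or hi - lo < 1e-14:
            break
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return float(tendon_force(l_mt - 0.5 * (lo + hi)))


def compressive_component(mtu: MuscleTendonUnit, knee_angle, force):
    """Compressive tibiofemoral component of a muscle force (N).

    The configured polynomial in knee angle gives the fraction of tendon
    force directed along the tibia long axis; non-knee-spanning muscles
    contribute zero.
    """
    if mtu.compressive_coeffs is None or not mtu.spans_knee:
        return np.zeros_like(np.asarray(force, dtype=float)) + 0.0
    frac = np.polynomial.polynomial.polyval(
        np.asarray(knee_angle, dtype=float),
        np.asarray(mtu.compressive_coeffs, dtype=float),
    )
    return frac * np.asarray(force, dtype=float)
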