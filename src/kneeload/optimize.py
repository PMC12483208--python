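"""Two-stage EMG-informed optimization over one stance phase.

The problem solved here is the core computation of the pipeline: find
adjusted muscle excitations e(t), activations a(t), reserve torques r(t)
(and, in the Calibration stage, per-muscle EMG scale factors s in
[0.5, 1]) minimizing

    J = w1*J_excitation + w2*J_knee/ankle + w3*J_reserve + w4*J_EMG,

subject to activation dynamics and per-DOF moment equality
sum_m F_m(a)*r_m + r_dof = M_ID at every collocation node, with
e, a in [0, 1].  All integrals run over the stance window.

Numerical strategy.  With a rigid tendon and prescribed kinematics, tendon
force is affine in activation, so for a fixed activation-dynamics switching
pattern (tau_act where excitation exceeds activation, tau_deact otherwise)
the trapezoidal forward map a = A(sigma) e is linear, reserves can be
eliminated analytically from the moment equalities (they are free,
penalized variables), and the transcription collapses to a bound-
constrained convex quadratic program in the node excitations.  The QP is
solved by an active-set method on the normal equations; the switching
pattern is iterated to consistency.  Calibration adds the bilinear scale
factors via block-coordinate descent (closed-form bounded update for s)
from three multistarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .config import ALL_MUSCLES, CHANNEL_MAP, MEASURED_MUSCLES

#: DOFs actuated by the modeled muscles (right leg), heavy/light penalty split
KNEE_ANKLE_DOFS = ("knee", "ankle")
OTHER_MUSCLE_DOFS = ("hip",)
MUSCLE_DOF_ORDER = ("knee", "ankle", "hip")

SCALE_BOUNDS = (0.5, 1.0)


class AssemblyError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class OptWeights:
    """Objective weights for one stage.

    Calibration puts high weight on excitation effort (submaximal-MVC
    inflation must not be absorbed into excitations) and on knee/ankle
    reserve effort; Execution relaxes both so EMG tracking dominates; the
    tracking weight w4 is common to the stages.
    """

    w1: float  # excitation effort
    w2: float  # knee/ankle reserve effort
    w3: float  # remaining reserve effort
    w4: float  # EMG tracking

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("objective weights must be nonnegative")

    @classmethod
    def calibration(cls) -> "OptWeights":
        return cls(w1=10.0, w2=10000.0, w3=0.01, w4=1.0)

    @classmethod
    def execution(cls) -> "OptWeights":
        return cls(w1=0.1, w2=100.0, w3=1e-4, w4=1.0)


@dataclass
class ScaleFactors:
    """Per-measured-muscle EMG scale factors in [0.5, 1]."""

    factors: dict[str, float]
    per_stride: list[dict[str, float]] = field(default_factory=list)

    def for_reference(self, muscle: str) -> float:
        """Scale factor applying to a reference signal (mapped muscles share
        their source channel's factor)."""
        return self.factors[CHANNEL_MAP.get(muscle, muscle)]


def transcription_counts(n_nodes: int, n_muscles: int, n_muscle_dofs: int,
                         n_reserve_dofs: int, calibration: bool,
                         n_scales: int = len(MEASURED_MUSCLES)) -> tuple[int, int]:
    """Variable/constraint counts of the full direct-collocation transcription.

    Variables: e and a per muscle per node, one reserve per reserve DOF per
    node, plus the scale factors in Calibration.  Constraints: trapezoidal
    activation dynamics between consecutive nodes and one moment equality
    per muscle-actuated DOF per node.
    """
    n_vars = 2 * n_muscles * n_nodes + n_reserve_dofs * n_nodes
    if calibration:
        n_vars += n_scales
    n_cons = n_muscles * (n_nodes - 1) + n_muscle_dofs * n_nodes
    return n_vars, n_cons


class EmgInformedModel:
    """Discretized EMG-informed stance problem (the Model object).

    Construct via :func:`assemble_ocp` (or directly from node arrays) and
    call :meth:`fit` to obtain an :class:`EmgInformedResults`.
    """

    def __init__(
        self,
        time: np.ndarray,                  # node times, s (uniform)
        f_active: np.ndarray,              # (M, N) force per unit activation
        f_passive: np.ndarray,             # (M, N)
        arms: dict[str, np.ndarray],       # dof -> (M, N) moment arms
        moments: dict[str, np.ndarray],    # dof -> (N,) inverse-dynamics moments
        reference: np.ndarray | None,      # (M, N) reference excitations or None
        weights: OptWeights,
        stage: str = "execution",
        muscles: list[str] | None = None,
        other_reserves: dict[str, np.ndarray] | None = None,
        tau_act: float = 0.015,
        tau_deact: float = 0.060,
        torque_scale: float = 70.0,
    ):
        self.time = np.asarray(time, dtype=float)
        self.n_nodes = self.time.size
        if self.n_nodes < 3:
            raise AssemblyError("need at least 3 collocation nodes")
        self.h = float(self.time[1] - self.time[0])
        self.muscles = list(ALL_MUSCLES) if muscles is None else muscles
        self.n_muscles = len(self.muscles)
        self.f_active = np.asarray(f_active, dtype=float)
        self.f_passive = np.asarray(f_passive, dtype=float)
        if self.f_active.shape != (self.n_muscles, self.n_nodes):
            raise AssemblyError("f_active shape mismatch")
        self.arms = {d: np.asarray(v, dtype=float) for d, v in arms.items()}
        self.moments = {d: np.asarray(v, dtype=float) for d, v in moments.items()}
        for d in MUSCLE_DOF_ORDER:
            if d not in self.moments:
                raise AssemblyError(f"missing inverse-dynamics moments for {d!r}")
        self.stage = stage
        if stage not in ("calibration", "execution"):
            raise AssemblyError(f"unknown stage {stage!r}")
        self.weights = weights
        if reference is None and weights.w4 > 0:
            raise AssemblyError("EMG tracking weighted but no reference given")
        self.reference = None if reference is None else np.asarray(reference, float)
        self.other_reserves = other_reserves or {}
        self.tau_act = tau_act
        self.tau_deact = tau_deact
        # reserve torques enter the objective normalized by body mass
        # (N*m/kg), the convention used for reporting reserve magnitudes;
        # keeps the weight ordering meaningful across subject sizes
        self.torque_scale = float(torque_scale)

        # trapezoidal quadrature weights
        w = np.full(self.n_nodes, self.h)
        w[0] = w[-1] = self.h / 2
        self.quad = w

        # scale-factor grouping: measured muscles own a factor; mapped
        # muscles track their source's factor
        self.scale_names = [m for m in MEASURED_MUSCLES if m in self.muscles]
        self.scale_index = {}
        for i, m in enumerate(self.muscles):
            src = CHANNEL_MAP.get(m, m)
            if src in self.scale_names:
                self.scale_index[i] = self.scale_names.index(src)

        self.n_variables, self.n_constraints = transcription_counts(
            self.n_nodes, self.n_muscles, len(MUSCLE_DOF_ORDER),
            len(MUSCLE_DOF_ORDER), stage == "calibration", len(self.scale_names)
        )

    # -- linear algebra pieces -------------------------------------------

    def _activation_matrix(self, tau: np.ndarray) -> np.ndarray:
        """Forward trapezoidal activation map a = A e for one muscle, given
        per-node rate constants; a_0 = e_0 (initial equilibrium)."""
        n, h = self.n_nodes, self.h
        A = np.zeros((n, n))
        A[0, 0] = 1.0
        for i in range(n - 1):
            c_next = 1.0 + h / (2 * tau[i + 1])
            A[i + 1] = A[i] * (1.0 - h / (2 * tau[i])) / c_next
            A[i + 1, i] += h / (2 * tau[i]) / c_next
            A[i + 1, i + 1] += h / (2 * tau[i + 1]) / c_next
        return A

    @property
    def _with_scales(self) -> bool:
        return self.stage == "calibration" and self.reference is not None

    def _assemble_qp(self, A_blocks: list[np.ndarray]):
        """Normal-equation matrix/vector of the QP.

        Variables are the stacked node excitations, plus (Calibration) the
        scale factors appended at the tail: the tracking residual
        e - s*ref is linear in (e, s) jointly, so the whole stage is one
        convex bound-constrained QP per switching pattern.
        """
        wts, n, m = self.weights, self.n_nodes, self.n_muscles
        n_e = m * n
        n_s = len(self.scale_names) if self._with_scales else 0
        nv = n_e + n_s
        sqw = self.quad
        H = np.zeros((nv, nv))
        g = np.zeros(nv)
        diag = np.zeros(nv)
        for k in range(m):
            diag[k * n:(k + 1) * n] = wts.w1 * sqw
        if self.reference is not None and wts.w4 > 0:
            for k in range(m):
                sl = slice(k * n, (k + 1) * n)
                diag[sl] += wts.w4 * sqw
                if self._with_scales:
                    idx = n_e + self.scale_index[k]
                    H[sl, idx] += -wts.w4 * sqw * self.reference[k]
                    H[idx, sl] += -wts.w4 * sqw * self.reference[k]
                    diag[idx] += wts.w4 * np.sum(sqw * self.reference[k] ** 2)
                else:
                    # execution: reference enters with unit scale
                    g[sl] += wts.w4 * sqw * self.reference[k]
        H[np.diag_indices(nv)] += diag

        for dof in MUSCLE_DOF_ORDER:
            w_dof = wts.w2 if dof in KNEE_ANKLE_DOFS else wts.w3
            if w_dof == 0:
                continue
            # reserve residual R_i = b_i - sum_m G[m,i] * (A_m e_m)_i,
            # in mass-normalized torque units
            G = self.arms[dof] * self.f_active / self.torque_scale   # (M, N)
            b = (self.moments[dof]
                 - np.sum(self.arms[dof] * self.f_passive, axis=0)) / self.torque_scale
            B = np.zeros((n, nv))
            for k in range(m):
                B[:, k * n:(k + 1) * n] = -G[k][:, None] * A_blocks[k]
            WB = (w_dof * sqw)[:, None] * B
            H += B.T @ WB
            g += -B.T @ (w_dof * sqw * b)  # residual = b + B e
        return H, g

    def _bounds(self):
        n_e = self.n_muscles * self.n_nodes
        if not self._with_scales:
            return np.zeros(n_e), np.ones(n_e)
        n_s = len(self.scale_names)
        lb = np.concatenate([np.zeros(n_e), np.full(n_s, SCALE_BOUNDS[0])])
        ub = np.concatenate([np.ones(n_e), np.full(n_s, SCALE_BOUNDS[1])])
        return lb, ub

    @staticmethod
    def _solve_box_qp(H: np.ndarray, g: np.ndarray, x0: np.ndarray,
                      lb: np.ndarray, ub: np.ndarray,
                      max_iter: int = 80) -> np.ndarray:
        """min 1/2 x'Hx - g'x  s.t. lb <= x <= ub, primal active set."""
        x = np.clip(x0, lb, ub)
        nv = g.size
        lower = np.zeros(nv, dtype=bool)
        upper = np.zeros(nv, dtype=bool)
        for _ in range(max_iter):
            fixed = lower | upper
            free = ~fixed
            rhs = g[free] - H[np.ix_(free, fixed)] @ x[fixed] if fixed.any() else g[free]
            c, low = cho_factor(H[np.ix_(free, free)], check_finite=False)
            xf = cho_solve((c, low), rhs, check_finite=False)
            x[free] = xf
            viol_lo = free & (x < lb)
            viol_hi = free & (x > ub)
            if viol_lo.any() or viol_hi.any():
                x[viol_lo] = lb[viol_lo]
                x[viol_hi] = ub[viol_hi]
                lower |= viol_lo
                upper |= viol_hi
                continue
            grad = H @ x - g
            release_lo = lower & (grad < -1e-10)
            release_hi = upper & (grad > 1e-10)
            if release_lo.any() or release_hi.any():
                lower &= ~release_lo
                upper &= ~release_hi
                continue
            break
        return np.clip(x, lb, ub)

    def _tau_from_pattern(self, rising: np.ndarray) -> np.ndarray:
        return np.where(rising, self.tau_act, self.tau_deact)

    def _initial_pattern(self) -> np.ndarray:
        """Switching pattern consistent with the reference excitations.

        Obtained by running the trapezoidal activation map on the reference
        and iterating the excitation/activation comparison to a fixed point
        (converges in a few sweeps); starts the QP's pattern iteration near
        the solution's own pattern.
        """
        pattern = np.zeros((self.n_muscles, self.n_nodes), dtype=bool)
        if self.reference is None:
            return pattern
        e = self.reference
        for _ in range(8):
            a = np.stack([
                self._activation_matrix(self._tau_from_pattern(pattern[k])) @ e[k]
                for k in range(self.n_muscles)
            ])
            new_pattern = e > a
            if np.array_equal(new_pattern, pattern):
                break
            pattern = new_pattern
        return pattern

    def _solve_joint(self, pattern, s0: float, max_pattern_iter=10):
        """Solve the (convex, per-pattern) QP, iterating the switching
        pattern to consistency; return the best solution found."""
        n_e = self.n_muscles * self.n_nodes
        lb, ub = self._bounds()
        x0 = np.empty(lb.size)
        if self.reference is not None:
            x0[:n_e] = self.reference.ravel()
        else:
            x0[:n_e] = 0.1
        if self._with_scales:
            x0[n_e:] = s0
        best = None
        for _ in range(max_pattern_iter):
            A_blocks = [self._activation_matrix(self._tau_from_pattern(pattern[k]))
                        for k in range(self.n_muscles)]
            H, g = self._assemble_qp(A_blocks)
            x = self._solve_box_qp(H, g, x0, lb, ub)
            J = 0.5 * x @ H @ x - g @ x
            if best is None or J < best[0] - 1e-14:
                best = (J, x.copy(), [A.copy() for A in A_blocks])
            e = x[:n_e].reshape(self.n_muscles, self.n_nodes)
            a = np.stack([A_blocks[k] @ e[k] for k in range(self.n_muscles)])
            new_pattern = e > a
            if np.array_equal(new_pattern, pattern):
                break
            pattern = new_pattern
            x0 = x
        _, x, A_blocks = best
        e = x[:n_e].reshape(self.n_muscles, self.n_nodes)
        a = np.stack([A_blocks[k] @ e[k] for k in range(self.n_muscles)])
        scales = x[n_e:] if self._with_scales else None
        return e, a, scales

    # -- public fitting interface ----------------------------------------

    def fit(self, multistarts=(0.5, 0.75, 1.0)) -> "EmgInformedResults":
        """Solve the stance problem.

        For a fixed activation-dynamics switching pattern the problem is a
        convex bound-constrained QP (jointly in excitations and, for
        Calibration, the scale factors); the pattern is iterated to
        consistency.  Multistart values seed the scale factors' initial
        point (the optimum of the convex subproblem does not depend on it;
        retained as insurance against pattern-iteration cycling).
        """
        if self.stage == "execution":
            e, a, _ = self._solve_joint(self._initial_pattern(), s0=1.0)
            return self._package(e, a, scales=None)

        best = None
        for s0 in multistarts:
            e, a, scales = self._solve_joint(self._initial_pattern(), s0=float(s0))
            J = self._objective(e, a, scales)["total"]
            if best is None or J < best[0]:
                best = (J, e, a, scales)
        _, e, a, scales = best
        return self._package(e, a, scales)

    # -- diagnostics ------------------------------------------------------

    def _reserves(self, a: np.ndarray) -> dict[str, np.ndarray]:
        res = {}
        for dof in MUSCLE_DOF_ORDER:
            muscle_moment = np.sum(
                self.arms[dof] * (self.f_active * a + self.f_passive), axis=0
            )
            res[dof] = self.moments[dof] - muscle_moment
        for name, series in self.other_reserves.items():
            res[name] = np.asarray(series, dtype=float)
        return res

    def _objective(self, e, a, scales) -> dict[str, float]:
        reserves = self._reserves(a)
        ts = self.torque_scale
        j_exc = float(np.sum(self.quad * np.sum(e**2, axis=0)))
        j_ka = float(sum(np.sum(self.quad * (reserves[d] / ts) ** 2)
                         for d in KNEE_ANKLE_DOFS))
        j_res = float(sum(
            np.sum(self.quad * (r / ts) ** 2)
            for d, r in reserves.items() if d not in KNEE_ANKLE_DOFS
        ))
        if self.reference is not None:
            s_full = np.ones(self.n_muscles)
            if scales is not None:
                for k, idx in self.scale_index.items():
                    s_full[k] = scales[idx]
            err = e - s_full[:, None] * self.reference
            j_emg = float(np.sum(self.quad * np.sum(err**2, axis=0)))
        else:
            j_emg = 0.0
        w = self.weights
        total = w.w1 * j_exc + w.w2 * j_ka + w.w3 * j_res + w.w4 * j_emg
        return {"J_excitation": j_exc, "J_knee_ankle": j_ka,
                "J_reserve": j_res, "J_EMG": j_emg, "total": total}

    def _package(self, e, a, scales) -> "EmgInformedResults":
        reserves = self._reserves(a)
        terms = self._objective(e, a, scales)
        muscle_forces = self.f_active * a + self.f_passive
        # moment equality holds identically: reserves are defined as the
        # residual; verify numerically anyway
        viol = 0.0
        for dof in MUSCLE_DOF_ORDER:
            mm = np.sum(self.arms[dof] * muscle_forces, axis=0)
            viol = max(viol, float(np.max(np.abs(mm + reserves[dof] - self.moments[dof]))))
        scale_dict = None
        if scales is not None:
            scale_dict = {name: float(s) for name, s in zip(self.scale_names, scales)}
        return EmgInformedResults(
            model=self,
            excitations={m: e[k] for k, m in enumerate(self.muscles)},
            activations={m: a[k] for k, m in enumerate(self.muscles)},
            muscle_forces={m: muscle_forces[k] for k, m in enumerate(self.muscles)},
            reserves=reserves,
            objective=terms,
            scale_factors=scale_dict,
            constraint_violation=viol,
        )


@dataclass
class EmgInformedResults:
    """Solution of one stance problem (the Results object)."""

    model: EmgInformedModel
    excitations: dict[str, np.ndarray]
    activations: dict[str, np.ndarray]
    muscle_forces: dict[str, np.ndarray]
    reserves: dict[str, np.ndarray]
    objective: dict[str, float]
    scale_factors: dict[str, float] | None
    constraint_violation: float

    @property
    def stance_window(self) -> tuple[float, float]:
        return float(self.model.time[0]), float(self.model.time[-1])

    def tracking_rmse(self, roi: tuple[float, float] = (10.0, 90.0)) -> float:
        """Average RMS error between excitations and the (scaled) reference
        over the stance region of interest."""
        if self.model.reference is None:
            raise ValueError("no reference excitations in this problem")
        ref = self.model.reference.copy()
        if self.scale_factors is not None:
            for k, idx in self.model.scale_index.items():
                ref[k] *= self.scale_factors[self.model.scale_names[idx]]
        e = np.stack([self.excitations[m] for m in self.model.muscles])
        return tracking_rmse(e, ref, roi)

    def summary(self) -> str:
        lines = [
            f"EMG-informed {self.model.stage} solve",
            f"  nodes: {self.model.n_nodes}, muscles: {self.model.n_muscles}, "
            f"stance {self.stance_window[0]:.3f}-{self.stance_window[1]:.3f} s",
            f"  objective: total={self.objective['total']:.6g}  "
            f"(J_exc={self.objective['J_excitation']:.4g}, "
            f"J_knee/ankle={self.objective['J_knee_ankle']:.4g}, "
            f"J_reserve={self.objective['J_reserve']:.4g}, "
            f"J_EMG={self.objective['J_EMG']:.4g})",
            f"  moment-equality violation: {self.constraint_violation:.2e} N*m",
        ]
        if self.scale_factors is not None:
            pretty = ", ".join(f"{k}={v:.3f}" for k, v in self.scale_factors.items())
            lines.append(f"  EMG scale factors: {pretty}")
        for dof in KNEE_ANKLE_DOFS:
            r = self.reserves[dof]
            lines.append(
                f"  {dof} reserve torque: peak |r| = {np.max(np.abs(r)):.3f} N*m"
            )
        return "\n".join(lines)


def tracking_rmse(e: np.ndarray, reference: np.ndarray,
                  roi: tuple[float, float] = (10.0, 90.0)) -> float:
    """RMS excitation-tracking error per muscle over the ROI, averaged
    across muscles.  Series are indexed on an implicit 0-100% stance grid."""
    e = np.atleast_2d(np.asarray(e, dtype=float))
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    n = e.shape[1]
    pct = np.linspace(0, 100, n)
    mask = (pct >= roi[0]) & (pct <= roi[1])
    if not mask.any():
        raise ValueError(f"empty region of interest {roi}")
    err = e[:, mask] - ref[:, mask]
    return float(np.mean(np.sqrt(np.mean(err**2, axis=1))))


def assemble_ocp(
    model,
    q_nodes: dict[str, np.ndarray],
    qdot_nodes: dict[str, np.ndarray],
    moments: dict[str, np.ndarray],
    time: np.ndarray,
    reference: dict[str, np.ndarray] | None,
    weights: OptWeights,
    stage: str = "execution",
    other_reserves: dict[str, np.ndarray] | None = None,
) -> EmgInformedModel:
    """Build the discretized stance problem from node kinematics.

    ``q_nodes``/``qdot_nodes`` map right-leg joint names (hip/knee/ankle) to
    angle series at the collocation nodes; ``moments`` are the inverse-
    dynamics net moments at the same nodes (flexion-positive);
    ``reference`` maps the 12 reference muscles to delayed, normalized
    excitations.
    """
    from .muscle import force_components, moment_arm

    muscles = list(model.muscles)
    n = np.asarray(time).size
    hill = model.config.get("hill_curves")
    ref_posture = model.config.get("reference_posture")
    f_act = np.zeros((len(muscles), n))
    f_pas = np.zeros((len(muscles), n))
    arms = {d: np.zeros((len(muscles), n)) for d in MUSCLE_DOF_ORDER}
    for k, name in enumerate(muscles):
        mtu = model.muscles[name]
        fa, fp = force_components(mtu, q_nodes, qdot_nodes, hill, ref_posture)
        f_act[k] = fa
        f_pas[k] = fp
        for dof in mtu.moment_arm_coeffs:
            arms[dof][k] = moment_arm(mtu, dof, np.asarray(q_nodes[dof], float))
    ref_arr = None
    if reference is not None:
        ref_arr = np.stack([np.asarray(reference[m], float) for m in muscles])
    act_cfg = model.config.get("activation", {})
    return EmgInformedModel(
        time=time,
        f_active=f_act,
        f_passive=f_pas,
        arms=arms,
        moments=moments,
        reference=ref_arr,
        weights=weights,
        stage=stage,
        muscles=muscles,
        other_reserves=other_reserves,
        tau_act=act_cfg.get("tau_act", 0.015),
        tau_deact=act_cfg.get("tau_deact", 0.060),
        torque_scale=model.subject.mass,
    )


def solve_calibration(problems: list[EmgInformedModel],
                      multistarts=(0.5, 0.75, 1.0)) -> ScaleFactors:
    """Calibrate EMG scale factors on unloaded strides.

    Each stride is solved independently; the per-muscle factors are
    averaged arithmetically across strides (the mean of bounded values is
    bounded).  Strides whose solve fails are dropped with a warning; if all
    fail, calibration errors out.
    """
    import warnings

    per_stride: list[dict[str, float]] = []
    for i, prob in enumerate(problems):
        if prob.stage != "calibration":
            raise AssemblyError("solve_calibration requires calibration-stage problems")
        try:
            res = prob.fit(multistarts=multistarts)
        except Exception as exc:  # noqa: BLE001 - surfaced as warning per stride
            warnings.warn(f"calibration stride {i} dropped: {exc}", RuntimeWarning,
                          stacklevel=2)
            continue
        per_stride.append(res.scale_factors)
    if not per_stride:
        raise ConvergenceError("all calibration strides failed to solve")
    names = per_stride[0].keys()
    mean = {m: float(np.clip(np.mean([s[m] for s in per_stride]), *SCALE_BOUNDS))
            for m in names}
    return ScaleFactors(factors=mean, per_stride=per_stride)


def solve_execution(problem: EmgInformedModel,
                    scale_factors: ScaleFactors) -> EmgInformedResults:
    """Execution-stage solve: reference scaled by calibrated factors."""
    if problem.stage != "execution":
        raise AssemblyError("solve_execution requires an execution-stage problem")
    if problem.reference is None:
        raise AssemblyError("execution requires reference excitations")
    scaled = problem.reference.copy()
    for k, m in enumerate(problem.muscles):
        scaled[k] = scaled[k] * scale_factors.for_reference(m)
    scaled_problem = EmgInformedModel(
        time=problem.time, f_active=problem.f_active, f_passive=problem.f_passive,
        arms=problem.arms, moments=problem.moments, reference=scaled,
        weights=problem.weights, stage="execution", muscles=problem.muscles,
        other_reserves=problem.other_reserves, tau_act=problem.tau_act,
        tau_deact=problem.tau_deact, torque_scale=problem.torque_scale,
    )
    return scaled_problem.fit()
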