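"""Planar musculoskeletal model: segments, joints, muscles, and added mass.

The model is a 9-DOF sagittal-plane linkage (HAT translation x/y + rotation,
and hip/knee/ankle flexion per leg) carrying 12 muscle-tendon units on the
right leg.  Added-mass hardware (steel rods) is modeled as a point mass per
loaded segment, placed at a configurable fraction of segment length, with
segment mass, COM and planar inertia updated accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import ConfigurationError, default_model_config, validate_model_config

#: generalized coordinates, in order
DOF_NAMES = [
    "trunk_x", "trunk_y", "trunk_rot",
    "hip_r", "knee_r", "ankle_r",
    "hip_l", "knee_l", "ankle_l",
]

#: right-leg joints spanned by muscles (flexion-positive coordinates)
MUSCLE_DOFS = ["hip", "knee", "ankle"]


@dataclass(frozen=True)
class SubjectAnthropometry:
    subject_id: str
    mass: float    # kg
    height: float  # m

    def __post_init__(self):
        if self.mass <= 0 or self.height <= 0:
            raise ValueError(
                f"subject {self.subject_id!r}: mass and height must be positive"
            )

    @property
    def body_weight(self) -> float:
        """Body weight in N (unaugmented)."""
        from .config import GRAVITY

        return self.mass * GRAVITY


@dataclass(frozen=True)
class SegmentInertia:
    """Planar rigid segment: mass, length, COM offset and scalar inertia.

    ``com_offset`` is measured from the proximal joint along the segment
    axis; ``inertia_com`` is the planar (z) moment of inertia about the COM.
    """

    name: str
    mass: float
    length: float
    com_offset: float
    inertia_com: float

    def __post_init__(self):
        if self.mass < 0 or self.inertia_com < 0:
            raise ValueError(f"segment {self.name}: negative mass or inertia")
        if not (0.0 <= self.com_offset <= self.length):
            raise ValueError(
                f"segment {self.name}: com_offset {self.com_offset} outside "
                f"[0, {self.length}]"
            )


@dataclass(frozen=True)
class MuscleTendonUnit:
    name: str
    f_max: float
    l_opt: float
    l_slack: float
    pennation_opt: float
    moment_arm_coeffs: dict[str, tuple[float, ...]]  # joint -> ascending poly, m
    compressive_coeffs: tuple[float, ...] | None     # knee-angle poly, or None
    l_anchor: float = 0.0  # musculotendon length at the reference posture

    def __post_init__(self):
        if self.f_max <= 0 or self.l_opt <= 0 or self.l_slack < 0:
            raise ValueError(f"muscle {self.name}: invalid parameters")

    @property
    def spans_knee(self) -> bool:
        return "knee" in self.moment_arm_coeffs


@dataclass(frozen=True)
class RodSet:
    """Combination of 300 g and 75 g steel rods approximating a target mass."""

    n_large: int
    n_small: int
    target: float  # g

    @property
    def total_mass(self) -> float:
        return 300.0 * self.n_large + 75.0 * self.n_small

    @property
    def discrepancy(self) -> float:
        """Achieved minus target mass, g."""
        return self.total_mass - self.target


@dataclass(frozen=True)
class LoadingCondition:
    """Added mass per leg, expressed in % of body weight per segment."""

    name: str
    m_thigh: float = 0.0
    m_shank: float = 0.0
    m_foot: float = 0.0
    attachment: dict[str, float] | None = None  # fraction of segment length

    def __post_init__(self):
        if min(self.m_thigh, self.m_shank, self.m_foot) < 0:
            raise ValueError(f"condition {self.name}: negative added mass")

    @property
    def total_pct(self) -> float:
        return self.m_thigh + self.m_shank + self.m_foot

    def masses(self) -> dict[str, float]:
        return {"thigh": self.m_thigh, "shank": self.m_shank, "foot": self.m_foot}


#: the nine study loading conditions (% BW per leg)
STUDY_CONDITIONS = [
    LoadingCondition("none"),
    LoadingCondition("thigh_low", m_thigh=2.0),
    LoadingCondition("thigh_high", m_thigh=4.0),
    LoadingCondition("shank_low", m_shank=1.5),
    LoadingCondition("shank_high", m_shank=3.0),
    LoadingCondition("foot_low", m_foot=1.0),
    LoadingCondition("foot_high", m_foot=2.0),
    LoadingCondition("all_low", m_thigh=2.0, m_shank=1.5, m_foot=1.0),
    LoadingCondition("all_high", m_thigh=4.0, m_shank=3.0, m_foot=2.0),
]


@dataclass(frozen=True)
class MusculoskeletalModel:
    subject: SubjectAnthropometry
    segments: dict[str, SegmentInertia]  # HAT, thigh_r/l, shank_r/l, foot_r/l
    muscles: dict[str, MuscleTendonUnit]
    config: dict = field(repr=False, default_factory=dict)
    condition: LoadingCondition | None = None

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    @property
    def gravity(self) -> float:
        return self.config.get("gravity", 9.80665)

    def segment(self, base: str, side: str = "r") -> SegmentInertia:
        return self.segments["HAT" if base == "HAT" else f"{base}_{side}"]


def _poly(coeffs, q):
    return np.polynomial.polynomial.polyval(q, np.asarray(coeffs, dtype=float))


def _poly_antideriv(coeffs):
    c = np.asarray(coeffs, dtype=float)
    return np.concatenate([[0.0], c / np.arange(1, c.size + 1)])


def build_default_model(
    subject: SubjectAnthropometry, config: dict | None = None
) -> MusculoskeletalModel:
    """Build the planar model for a subject from anthropometric fractions.

    Segment masses, lengths, COM offsets and inertias are fractions of the
    subject's mass and height; the 12 muscles are attached with the
    configured parameter tables.  Deterministic for a fixed configuration.
    """
    cfg = default_model_config() if config is None else config
    validate_model_config(cfg)

    segments: dict[str, SegmentInertia] = {}
    for base, fr in cfg["segment_fractions"].items():
        mass = fr["mass"] * subject.mass
        length = fr["length"] * subject.height
        com = fr["com"] * length
        inertia = mass * (fr["rog"] * length) ** 2
        if base == "HAT":
            segments["HAT"] = SegmentInertia("HAT", mass, length, com, inertia)
        else:
            for side in ("r", "l"):
                segments[f"{base}_{side}"] = SegmentInertia(
                    f"{base}_{side}", mass, length, com, inertia
                )

    qref = cfg["reference_posture"]
    muscles: dict[str, MuscleTendonUnit] = {}
    for name, tab in cfg["muscles"].items():
        arms = {j: tuple(c) for j, c in tab["moment_arms"].items()}
        comp = tuple(tab["compressive"]) if tab.get("compressive") else None
        l_anchor = tab["l_slack"] + tab["l_opt"] * np.cos(tab["pennation"])
        muscles[name] = MuscleTendonUnit(
            name=name,
            f_max=float(tab["f_max"]),
            l_opt=float(tab["l_opt"]),
            l_slack=float(tab["l_slack"]),
            pennation_opt=float(tab["pennation"]),
            moment_arm_coeffs=arms,
            compressive_coeffs=comp,
            l_anchor=float(l_anchor),
        )
        for joint in arms:
            if joint not in MUSCLE_DOFS:
                raise ConfigurationError(
                    f"muscle {name}: spans unknown joint {joint!r}"
                )
    _ = qref  # anchor posture is applied in muscle kinematics
    return MusculoskeletalModel(subject, segments, muscles, cfg)


def scale_muscle_strength(
    model: MusculoskeletalModel,
    reference_mass: float | None = None,
    reference_height: float | None = None,
) -> MusculoskeletalModel:
    """Scale peak isometric forces by (mass*height)/(ref_mass*ref_height).

    This is the mass-height product scaling of muscle volume over fiber
    length; all other parameters are unchanged.
    """
    ref = model.config.get("reference", {})
    reference_mass = reference_mass if reference_mass is not None else ref.get("mass")
    reference_height = (
        reference_height if reference_height is not None else ref.get("height")
    )
    if not reference_mass or not reference_height or reference_mass <= 0 or reference_height <= 0:
        raise ValueError("reference mass and height must be positive")
    factor = (model.subject.mass * model.subject.height) / (
        reference_mass * reference_height
    )
    muscles = {
        name: replace(m, f_max=m.f_max * factor) for name, m in model.muscles.items()
    }
    return replace(model, muscles=muscles)


def rod_combination(target: float) -> RodSet:
    """Best combination of 300 g / 75 g rods for a target mass (grams).

    Exhaustive search over all candidate combinations minimizing
    |achieved - target|; ties broken first toward smaller total mass, then
    toward fewer rods.  Because four small rods weigh exactly one large
    rod (but count as more rods), an optimal combination never uses more
    than three small rods, which bounds the search.  The achievable
    discrepancy never exceeds 37.5 g (half the 75 g granularity).
    """
    if target < 0:
        raise ValueError("target mass must be nonnegative")
    max_large = int(np.ceil(target / 300.0)) + 1
    best = None
    for nl in range(max_large + 1):
        for ns in range(4):
            total = 300.0 * nl + 75.0 * ns
            key = (abs(total - target), total, nl + ns)
            if best is None or key < best[0]:
                best = (key, nl, ns)
    _, nl, ns = best
    return RodSet(n_large=nl, n_small=ns, target=float(target))


def apply_added_mass(
    model: MusculoskeletalModel, condition: LoadingCondition
) -> MusculoskeletalModel:
    """Attach the condition's added mass to both legs' segments.

    Each loaded segment gains a point mass of (pct/100)*subject mass at the
    attachment point; segment mass, mass-weighted COM offset and COM inertia
    (parallel-axis theorem) are updated.  Total model mass increases by
    2 * sum of per-leg added masses exactly.
    """
    attach_default = model.config.get("attachment_fraction", 0.43)
    segments = dict(model.segments)
    for base, pct in condition.masses().items():
        if pct == 0.0:
            continue
        frac = (condition.attachment or {}).get(base, attach_default)
        if not (0.0 <= frac <= 1.0):
            raise ValueError(
                f"attachment fraction {frac} for {base} outside [0, 1]"
            )
        m_add = pct / 100.0 * model.subject.mass
        for side in ("r", "l"):
            seg = segments[f"{base}_{side}"]
            attach = frac * seg.length
            new_mass = seg.mass + m_add
            new_com = (seg.mass * seg.com_offset + m_add * attach) / new_mass
            # parallel-axis: shift both the original segment and the point
            # mass to the new COM
            inertia = (
                seg.inertia_com
                + seg.mass * (seg.com_offset - new_com) ** 2
                + m_add * (attach - new_com) ** 2
            )
            segments[f"{base}_{side}"] = SegmentInertia(
                seg.name, new_mass, seg.length, new_com, inertia
            )
    return replace(model, segments=segments, condition=condition)
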