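"""Default model configuration and YAML round-trip helpers.

The planar model is parameterized entirely by this configuration: anthropometric
segment fractions, the 12 muscle-tendon parameter tables, Hill-curve
coefficients, and sign/angle conventions.  Every number here is an editable
default drawn from standard anthropometric and muscle-parameter tables; none
is asserted as ground truth for any particular dataset.

Angle conventions (flexion-positive generalized coordinates, radians):
  hip: flexion positive (thigh forward); knee: 0 at full extension, flexion
  positive; ankle: dorsiflexion positive.  Stance is normalized 0-100% from
  heel strike to toe-off.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: gravitational acceleration, m/s^2
GRAVITY = 9.80665

#: the nine surface-EMG channels measured on the right leg
MEASURED_MUSCLES = [
    "soleus",
    "gasmed",
    "gaslat",
    "tibant",
    "semiten",
    "bflh",
    "vasmed",
    "vaslat",
    "recfem",
]

#: mapping of measured channels onto adjacent unmeasured muscles
CHANNEL_MAP = {
    "vasint": "vasmed",
    "bfsh": "bflh",
    "semimem": "semiten",
}

#: the 12 modeled muscle-tendon units (measured 9 + mapped 3)
ALL_MUSCLES = MEASURED_MUSCLES + list(CHANNEL_MAP)

# Segment fractions: mass as a fraction of body mass, length as a fraction of
# height, COM offset and radius of gyration as fractions of segment length
# (from the proximal joint).  Standard gait-analysis anthropometric tables.
_SEGMENT_FRACTIONS = {
    "HAT":   {"mass": 0.678, "length": 0.295, "com": 0.450, "rog": 0.496},
    "thigh": {"mass": 0.100, "length": 0.245, "com": 0.433, "rog": 0.323},
    "shank": {"mass": 0.0465, "length": 0.246, "com": 0.433, "rog": 0.302},
    "foot":  {"mass": 0.0145, "length": 0.152, "com": 0.500, "rog": 0.475},
}

# Muscle parameter table.  f_max in N (for the reference 75 kg / 1.70 m
# anthropometry), lengths in m, pennation in rad.  Moment-arm polynomials are
# ascending coefficients in the spanned joint's flexion-positive angle, in m,
# positive = flexor.  Compressive polynomials give the fraction of tendon
# force directed along the tibia long axis as a function of knee angle
# (quadriceps values include the patellar-tendon redirection).
_MUSCLES = {
    "soleus":  {"f_max": 6030.0, "l_opt": 0.100, "l_slack": 0.240, "pennation": 0.44,
                "moment_arms": {"ankle": [-0.046, 0.008]}, "compressive": None},
    "gasmed":  {"f_max": 2650.0, "l_opt": 0.090, "l_slack": 0.380, "pennation": 0.30,
                "moment_arms": {"ankle": [-0.044, 0.008], "knee": [0.018, 0.004]},
                "compressive": [0.88, -0.10]},
    "gaslat":  {"f_max": 1160.0, "l_opt": 0.100, "l_slack": 0.360, "pennation": 0.21,
                "moment_arms": {"ankle": [-0.043, 0.008], "knee": [0.016, 0.004]},
                "compressive": [0.88, -0.10]},
    "tibant":  {"f_max": 1540.0, "l_opt": 0.090, "l_slack": 0.220, "pennation": 0.17,
                "moment_arms": {"ankle": [0.040, -0.005]}, "compressive": None},
    "semiten": {"f_max": 700.0, "l_opt": 0.193, "l_slack": 0.250, "pennation": 0.22,
                "moment_arms": {"knee": [0.042, -0.010], "hip": [-0.055, -0.005]},
                "compressive": [0.85, -0.18]},
    # the three unmeasured muscles are parameter clones of the adjacent
    # measured muscle whose EMG channel they share (shared innervation);
    # strict convexity of the redundancy problem then assigns identical
    # excitations to each pair
    "semimem": {"f_max": 700.0, "l_opt": 0.193, "l_slack": 0.250, "pennation": 0.22,
                "moment_arms": {"knee": [0.042, -0.010], "hip": [-0.055, -0.005]},
                "compressive": [0.85, -0.18]},
    "bflh":    {"f_max": 1520.0, "l_opt": 0.110, "l_slack": 0.320, "pennation": 0.20,
                "moment_arms": {"knee": [0.032, -0.008], "hip": [-0.052, -0.005]},
                "compressive": [0.85, -0.18]},
    "bfsh":    {"f_max": 1520.0, "l_opt": 0.110, "l_slack": 0.320, "pennation": 0.20,
                "moment_arms": {"knee": [0.032, -0.008], "hip": [-0.052, -0.005]},
                "compressive": [0.85, -0.18]},
    "vasmed":  {"f_max": 2200.0, "l_opt": 0.100, "l_slack": 0.110, "pennation": 0.42,
                "moment_arms": {"knee": [-0.042, 0.004]}, "compressive": [0.55, 0.20, -0.05]},
    "vaslat":  {"f_max": 3180.0, "l_opt": 0.100, "l_slack": 0.130, "pennation": 0.32,
                "moment_arms": {"knee": [-0.046, 0.004]}, "compressive": [0.55, 0.20, -0.05]},
    "vasint":  {"f_max": 2200.0, "l_opt": 0.100, "l_slack": 0.110, "pennation": 0.42,
                "moment_arms": {"knee": [-0.042, 0.004]}, "compressive": [0.55, 0.20, -0.05]},
    "recfem":  {"f_max": 1440.0, "l_opt": 0.110, "l_slack": 0.320, "pennation": 0.24,
                "moment_arms": {"knee": [-0.044, 0.004], "hip": [0.050, -0.008]},
                "compressive": [0.55, 0.20, -0.05]},
}


DEFAULT_MODEL_CONFIG = {
    "reference": {"mass": 75.0, "height": 1.70},
    "gravity": GRAVITY,
    "segment_fractions": _SEGMENT_FRACTIONS,
    "muscles": _MUSCLES,
    # posture at which each muscle's fiber is anchored at optimal length
    "reference_posture": {"hip": 0.2, "knee": 0.35, "ankle": 0.0},
    "joint_range": {"hip": [-0.6, 1.2], "knee": [0.0, 2.1], "ankle": [-0.8, 0.6]},
    "hill_curves": {
        "fl_width": 0.45,       # Gaussian active force-length width
        "v_max": 12.0,          # max shortening velocity, l_opt / s
        "fv_a": 0.35,           # Hill hyperbola curvature
        "fv_flen": 1.4,         # eccentric force plateau
        "passive_k": 4.0,       # passive exponential shape
        "passive_strain": 0.6,  # strain at which passive force reaches f_max
    },
    "activation": {"tau_act": 0.015, "tau_deact": 0.060},
    # tendon model: "rigid" (default) or "quasistatic" elastic with the
    # given strain at one normalized tendon force
    "tendon": {"model": "rigid", "strain_at_fmax": 0.04},
    # rod attachment point as a fraction of segment length from the proximal
    # joint ("approximate mass center" placement)
    "attachment_fraction": 0.43,
    "angle_convention": "flexion-positive; knee 0 at full extension; "
                        "ankle dorsiflexion positive; radians",
}


class ConfigurationError(ValueError):
    """Raised for missing or inconsistent configuration entries."""


def default_model_config() -> dict:
    """Return a deep copy of the default model configuration."""
    return copy.deepcopy(DEFAULT_MODEL_CONFIG)


def load_model_config(path: str | Path) -> dict:
    """Load a model configuration from YAML, validating required sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_model_config(cfg)
    return cfg


def save_model_config(cfg: dict, path: str | Path) -> None:
    """Write a configuration to YAML.

    Uses the default (non-flow) style so the write -> read round trip is
    bit-exact for the numeric payload.
    """
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def validate_model_config(cfg: dict) -> None:
    for key in ("reference", "segment_fractions", "muscles", "hill_curves"):
        if key not in cfg:
            raise ConfigurationError(f"model config missing section {key!r}")
    for seg, fr in cfg["segment_fractions"].items():
        for field in ("mass", "length", "com", "rog"):
            v = fr.get(field)
            if v is None or v < 0:
                raise ConfigurationError(
                    f"segment {seg!r}: fraction {field!r} missing or negative"
                )
    total = cfg["segment_fractions"]["HAT"]["mass"] + 2 * sum(
        cfg["segment_fractions"][s]["mass"] for s in ("thigh", "shank", "foot")
    )
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"segment mass fractions must sum to 1 (got {total:.6f})"
        )
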