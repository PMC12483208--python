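"""Shared fixtures: subjects, models, and (session-cached) synthetic trials."""

import numpy as np
import pytest

from kneeload.model import (
    LoadingCondition,
    SubjectAnthropometry,
    apply_added_mass,
    build_default_model,
    scale_muscle_strength,
)
from kneeload.synth import ResponseModel, generate_stride


@pytest.fixture(scope="session")
def subject70():
    return SubjectAnthropometry("S01", 70.0, 1.75)


@pytest.fixture(scope="session")
def model70(subject70):
    return build_default_model(subject70)


@pytest.fixture(scope="session")
def noiseless_response():
    return ResponseModel(noise_sd=0.0, subject_offset_sd=0.0, emg_noise_sd=0.0)


@pytest.fixture(scope="session")
def trial_none(subject70, noiseless_response):
    """Noiseless unloaded trial with ground truth."""
    return generate_stride(subject70, LoadingCondition("none"),
                           noiseless_response, seed=1)


@pytest.fixture(scope="session")
def trial_foot(subject70, noiseless_response):
    """Noiseless 1% BW per foot trial with ground truth."""
    return generate_stride(subject70, LoadingCondition("foot_low", m_foot=1.0),
                           noiseless_response, seed=1)


@pytest.fixture(scope="session")
def loaded_model70(subject70, trial_foot):
    return apply_added_mass(
        scale_muscle_strength(build_default_model(subject70)),
        trial_foot.condition)


@pytest.fixture()
def static_q():
    """Upright static posture time series (all angles zero, hip 1 m up)."""
    n = 51
    q = {k: np.zeros(n) for k in (
        "trunk_x", "trunk_y", "trunk_rot",
        "hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")}
    q["trunk_y"] = q["trunk_y"] + 1.0
    return q


def stance_nodes_from_truth(trial, model):
    """Rebuild the execution-stage node arrays a pipeline would see,
    directly from the (unfiltered) trial data."""
    from kneeload.dynamics import intersegmental_reaction, inverse_dynamics
    from kneeload.optimize import MUSCLE_DOF_ORDER

    dt = 1.0 / trial.fs_angles
    idt = inverse_dynamics(model, trial.q, trial.grf_100, dt)
    inter = intersegmental_reaction(model, trial.q, trial.grf_100, dt)
    t_nodes = trial.truth.node_time
    t_ang = trial.time_angles

    def at(series):
        return np.interp(t_nodes, t_ang, series)

    q_nodes = {d: at(trial.q[f"{d}_r"]) for d in ("hip", "knee", "ankle")}
    qd_nodes = {d: at(np.gradient(trial.q[f"{d}_r"], dt))
                for d in ("hip", "knee", "ankle")}
    moments = {d: at(idt.moments[f"{d}_r"]) for d in MUSCLE_DOF_ORDER}
    return q_nodes, qd_nodes, moments, at(inter.axial_force), t_nodes
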