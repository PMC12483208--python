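"""EMG-informed optimization: transcription, feasibility, recovery of known
excitations and scale factors, objective structure."""

import numpy as np
import pytest

from conftest import stance_nodes_from_truth
from kneeload.config import ALL_MUSCLES, CHANNEL_MAP
from kneeload.optimize import (
    AssemblyError,
    OptWeights,
    assemble_ocp,
    solve_calibration,
    solve_execution,
    tracking_rmse,
    transcription_counts,
)


@pytest.fixture(scope="module")
def stance_foot(trial_foot, loaded_model70):
    q, qd, moments, inter, t_nodes = stance_nodes_from_truth(
        trial_foot, loaded_model70)
    return dict(q=q, qd=qd, moments=moments, inter=inter, t_nodes=t_nodes)


def _problem(model, stance, reference, weights, stage):
    return assemble_ocp(model, stance["q"], stance["qd"], stance["moments"],
                        stance["t_nodes"], reference, weights, stage)


def truth_reference(trial, scale=1.0):
    return {m: np.clip(trial.truth.true_excitations[CHANNEL_MAP.get(m, m)] / scale,
                       0, 1) for m in ALL_MUSCLES}


class TestAssembly:
    def test_transcription_counting_oracle(self, loaded_model70, stance_foot, trial_foot):
        prob = _problem(loaded_model70, stance_foot,
                        truth_reference(trial_foot),
                        OptWeights.calibration(), "calibration")
        N, M, D = 51, 12, 3
        # independent count: e and a per muscle-node, one reserve per
        # actuated DOF per node, 9 scale factors; activation defects between
        # nodes plus one moment equality per DOF per node
        assert prob.n_variables == 2 * M * N + D * N + 9
        assert prob.n_constraints == M * (N - 1) + D * N
        assert (prob.n_variables, prob.n_constraints) == transcription_counts(
            N, M, D, D, True, 9)

    def test_execution_has_no_scale_variables(self, loaded_model70, stance_foot,
                                              trial_foot):
        prob = _problem(loaded_model70, stance_foot, truth_reference(trial_foot),
                        OptWeights.execution(), "execution")
        assert prob.n_variables == 2 * 12 * 51 + 3 * 51
        res = prob.fit()
        assert res.scale_factors is None

    def test_tracking_without_reference_rejected(self, loaded_model70, stance_foot):
        with pytest.raises(AssemblyError):
            _problem(loaded_model70, stance_foot, None,
                     OptWeights.execution(), "execution")

    def test_unknown_stage_rejected(self, loaded_model70, stance_foot, trial_foot):
        with pytest.raises(AssemblyError):
            _problem(loaded_model70, stance_foot, truth_reference(trial_foot),
                     OptWeights.execution(), "warmup")


class TestExecution:
    def test_noiseless_recovery_of_true_excitations(self, loaded_model70,
                                                    stance_foot, trial_foot):
        prob = _problem(loaded_model70, stance_foot, truth_reference(trial_foot),
                        OptWeights.execution(), "execution")
        res = prob.fit()
        rms = np.mean([np.sqrt(np.mean(
            (res.excitations[m] - trial_foot.truth.true_excitations[m]) ** 2))
            for m in ALL_MUSCLES])
        assert rms < 0.01

    def test_reserves_below_five_percent_of_peak_knee_moment(
            self, loaded_model70, stance_foot, trial_foot):
        prob = _problem(loaded_model70, stance_foot, truth_reference(trial_foot),
                        OptWeights.execution(), "execution")
        res = prob.fit()
        bound = 0.05 * np.max(np.abs(stance_foot["moments"]["knee"]))
        for dof in ("knee", "ankle"):
            assert np.max(np.abs(res.reserves[dof][5:-5])) <= bound

    def test_moment_equality_feasibility(self, loaded_model70, stance_foot,
                                         trial_foot):
        prob = _problem(loaded_model70, stance_foot, truth_reference(trial_foot),
                        OptWeights.execution(), "execution")
        res = prob.fit()
        assert res.constraint_violation < 1e-6

    def test_objective_decomposition_identity(self, loaded_model70, stance_foot,
                                              trial_foot):
        prob = _problem(loaded_model70, stance_foot, truth_reference(trial_foot),
                        OptWeights.execution(), "execution")
        res = prob.fit()
        w = prob.weights
        total = (w.w1 * res.objective["J_excitation"]
                 + w.w2 * res.objective["J_knee_ankle"]
                 + w.w3 * res.objective["J_reserve"]
                 + w.w4 * res.objective["J_EMG"])
        assert res.objective["total"] == pytest.approx(total, rel=1e-10)
        assert all(v >= 0 for k, v in res.objective.items())

    def test_uniform_weight_scaling_leaves_solution(self, loaded_model70,
                                                    stance_foot, trial_foot):
        ref = truth_reference(trial_foot)
        w = OptWeights.execution()
        w10 = OptWeights(10 * w.w1, 10 * w.w2, 10 * w.w3, 10 * w.w4)
        r1 = _problem(loaded_model70, stance_foot, ref, w, "execution").fit()
        r2 = _problem(loaded_model70, stance_foot, ref, w10, "execution").fit()
        for m in ALL_MUSCLES:
            assert np.max(np.abs(r1.excitations[m] - r2.excitations[m])) < 1e-6

    def test_doubling_w2_does_not_increase_knee_ankle_term(
            self, loaded_model70, stance_foot, trial_foot):
        ref = truth_reference(trial_foot, scale=0.7)  # imperfect reference
        w = OptWeights.execution()
        w2x = OptWeights(w.w1, 2 * w.w2, w.w3, w.w4)
        j1 = _problem(loaded_model70, stance_foot, ref, w, "execution").fit()
        j2 = _problem(loaded_model70, stance_foot, ref, w2x, "execution").fit()
        assert j2.objective["J_knee_ankle"] <= j1.objective["J_knee_ankle"] + 1e-12

    def test_minimum_effort_mode_without_tracking(self, loaded_model70,
                                                  stance_foot):
        # w4 = 0 and no reference reduces to static-optimization-with-dynamics
        prob = _problem(loaded_model70, stance_foot, None,
                        OptWeights(1.0, 1000.0, 0.001, 0.0), "execution")
        res = prob.fit()
        assert res.objective["J_EMG"] == 0.0
        assert res.constraint_violation < 1e-6


class TestCalibration:
    def test_known_inflation_recovered(self, loaded_model70, stance_foot,
                                       trial_foot):
        prob = _problem(loaded_model70, stance_foot,
                        truth_reference(trial_foot, scale=0.8),
                        OptWeights.calibration(), "calibration")
        sf = solve_calibration([prob])
        errs = [abs(v - 0.8) for v in sf.factors.values()]
        assert np.mean(errs) <= 0.02

    def test_uninflated_reference_pins_at_upper_bound(self, loaded_model70,
                                                      stance_foot, trial_foot):
        prob = _problem(loaded_model70, stance_foot, truth_reference(trial_foot),
                        OptWeights.calibration(), "calibration")
        sf = solve_calibration([prob])
        for v in sf.factors.values():
            assert v == pytest.approx(1.0, abs=1e-3)

    def test_triple_inflation_pins_at_lower_bound(self, loaded_model70,
                                                  stance_foot, trial_foot):
        prob = _problem(loaded_model70, stance_foot,
                        truth_reference(trial_foot, scale=1 / 3),
                        OptWeights.calibration(), "calibration")
        sf = solve_calibration([prob])
        for v in sf.factors.values():
            assert v == pytest.approx(0.5, abs=1e-3)

    def test_factors_averaged_across_strides(self, loaded_model70, stance_foot,
                                             trial_foot):
        p1 = _problem(loaded_model70, stance_foot,
                      truth_reference(trial_foot, scale=0.8),
                      OptWeights.calibration(), "calibration")
        p2 = _problem(loaded_model70, stance_foot,
                      truth_reference(trial_foot, scale=0.9),
                      OptWeights.calibration(), "calibration")
        sf = solve_calibration([p1, p2])
        assert len(sf.per_stride) == 2
        for m, v in sf.factors.items():
            mean = np.mean([s[m] for s in sf.per_stride])
            assert v == pytest.approx(mean)
            assert 0.5 <= v <= 1.0

    def test_execution_applies_scale_factors(self, loaded_model70, stance_foot,
                                             trial_foot):
        calib = _problem(loaded_model70, stance_foot,
                         truth_reference(trial_foot, scale=0.8),
                         OptWeights.calibration(), "calibration")
        sf = solve_calibration([calib])
        exe = _problem(loaded_model70, stance_foot,
                       truth_reference(trial_foot, scale=0.8),
                       OptWeights.execution(), "execution")
        res = solve_execution(exe, sf)
        rms = np.mean([np.sqrt(np.mean(
            (res.excitations[m] - trial_foot.truth.true_excitations[m]) ** 2))
            for m in ALL_MUSCLES])
        assert rms < 0.01


class TestTrackingRmse:
    def test_perfect_tracking_is_zero(self):
        e = np.random.default_rng(0).uniform(0, 1, (12, 101))
        assert tracking_rmse(e, e) == 0.0

    def test_constant_offset_closed_form(self):
        e = np.full((12, 101), 0.3)
        ref = e - 0.02
        assert tracking_rmse(e, ref) == pytest.approx(0.02, abs=1e-12)

    def test_empty_roi_rejected(self):
        e = np.zeros((2, 50))
        with pytest.raises(ValueError):
            tracking_rmse(e, e, roi=(40.0, 40.1))
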