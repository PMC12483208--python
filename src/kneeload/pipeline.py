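"""End-to-end pipeline driver: synthesis/ingest -> EMG processing ->
inverse dynamics -> Calibration -> Execution -> contact force -> statistics.

`run_pipeline` reproduces the study flow on synthetic data: a cohort walks
all loading conditions (the no-mass condition twice, opening and closing
the protocol); per subject, EMG scale factors are calibrated on unloaded
strides; every trial is solved in Execution mode; contact-force peaks are
reduced to percent changes and fed to the through-origin regressions and
the random-intercept mixed models.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ALL_MUSCLES, MEASURED_MUSCLES, default_model_config
from .contact import extract_peaks, total_contact_force
from .dynamics import intersegmental_reaction, inverse_dynamics, lowpass
from .emg import apply_delay, detect_stance, map_channels, EmgEnvelopeSet
from .model import (
    LoadingCondition,
    STUDY_CONDITIONS,
    SubjectAnthropometry,
    apply_added_mass,
    build_default_model,
    scale_muscle_strength,
)
from .optimize import (
    MUSCLE_DOF_ORDER,
    OptWeights,
    assemble_ocp,
    solve_calibration,
    solve_execution,
)
from .stats import (
    fit_origin_regression,
    fit_random_intercept_lmm,
    percent_change,
)
from .synth import GaitTrial, ResponseModel, generate_cohort, generate_stride

log = logging.getLogger("kneeload")


@dataclass
class PipelineConfig:
    n_subjects: int = 10
    conditions: list[LoadingCondition] = field(
        default_factory=lambda: list(STUDY_CONDITIONS))
    n_strides: int = 3               # strides analyzed per condition
    n_calibration_strides: int = 3   # unloaded strides used for calibration
    n_nodes: int = 51
    seed: int = 0
    response: ResponseModel = field(default_factory=ResponseModel)
    submax_range: tuple[float, float] = (1.1, 1.8)
    calibration_weights: OptWeights = field(default_factory=OptWeights.calibration)
    execution_weights: OptWeights = field(default_factory=OptWeights.execution)
    baseline_policy: str = "mean"
    outdir: str | None = None
    write_artifacts: bool = False
    model_config: dict | None = None


@dataclass
class StanceData:
    """Processed single-stance inputs for the optimization stages."""

    model: object
    time_nodes: np.ndarray
    q_nodes: dict[str, np.ndarray]
    qdot_nodes: dict[str, np.ndarray]
    moments: dict[str, np.ndarray]
    other_reserves: dict[str, np.ndarray]
    reference: dict[str, np.ndarray]
    knee_angle: np.ndarray
    interseg_axial: np.ndarray
    segmentation: object


def process_trial(trial: GaitTrial, model, n_nodes: int = 51,
                  stance_index: int | None = None) -> StanceData:
    """Filter, segment and resample one trial into stance-node arrays.

    GRF is low-pass filtered at 8 Hz and interpolated onto the kinematic
    time base; synthetic EMG arrives in envelope form, so processing
    applies the electromechanical-delay shift and channel mapping only.
    """
    dt = 1.0 / trial.fs_angles
    t_ang = trial.time_angles

    fy_f = lowpass(trial.grf["fy"], trial.fs_grf)
    fx_f = lowpass(trial.grf["fx"], trial.fs_grf)
    seg = detect_stance(np.clip(fy_f, 0.0, None), trial.fs_grf)
    idx = trial.analyzed_stance if stance_index is None else stance_index
    if idx >= seg.n_stances:
        idx = seg.n_stances - 1
    hs, to = seg.events[idx]

    grf_100 = {
        "fx": np.interp(t_ang, trial.time_grf, fx_f),
        "fy": np.interp(t_ang, trial.time_grf, fy_f),
        "cop_x": trial.grf_100["cop_x"],
    }
    q_filt = {k: lowpass(v, trial.fs_angles) for k, v in trial.q.items()}
    idt = inverse_dynamics(model, q_filt, grf_100, dt)
    inter = intersegmental_reaction(model, q_filt, grf_100, dt)

    t_nodes = np.linspace(hs, to, n_nodes)

    def at(series, tbase=t_ang):
        return np.interp(t_nodes, tbase, series)

    q_nodes = {d: at(q_filt[f"{d}_r"]) for d in ("hip", "knee", "ankle")}
    qdot_nodes = {d: at(np.gradient(q_filt[f"{d}_r"], dt))
                  for d in ("hip", "knee", "ankle")}
    moments = {d: at(idt.moments[f"{d}_r"]) for d in MUSCLE_DOF_ORDER}
    other = {f"{d}_l": at(idt.moments[f"{d}_l"]) for d in ("hip", "knee", "ankle")}

    # EMG: delay-compensate, map 9 channels to the 12 reference muscles
    delayed = {m: apply_delay(trial.emg[m], trial.fs_grf) for m in MEASURED_MUSCLES}
    env = EmgEnvelopeSet(fs=trial.fs_grf, channels=delayed)
    mapped = map_channels(env)
    reference = {m: at(mapped[m], tbase=trial.time_grf) for m in ALL_MUSCLES}

    return StanceData(
        model=model, time_nodes=t_nodes, q_nodes=q_nodes,
        qdot_nodes=qdot_nodes, moments=moments, other_reserves=other,
        reference=reference, knee_angle=q_nodes["knee"],
        interseg_axial=at(inter.axial_force), segmentation=seg,
    )


def _subject_submax(cfg: PipelineConfig, subject_index: int) -> dict[str, float]:
    rng = np.random.default_rng(np.random.SeedSequence(
        [cfg.seed & 0x7FFFFFFF, 9001, subject_index]))
    lo, hi = cfg.submax_range
    return {m: float(rng.uniform(lo, hi)) for m in MEASURED_MUSCLES}


@dataclass
class PipelineReport:
    outcomes: pd.DataFrame
    regressions: dict
    mixed_models: dict
    scale_factors: dict
    diagnostics: dict
    timings: dict

    def to_json_dict(self) -> dict:
        def reg_dict(r):
            return {"coefficients": r.coefficients, "conf_int": r.conf_int,
                    "p_values": r.p_values, "pearson_r": r.pearson_r,
                    "n_obs": r.n_obs}
        return {
            "regressions": {k: reg_dict(v) for k, v in self.regressions.items()},
            "mixed_models": {
                k: {"fixed_effects": v.fixed_effects, "p_values": v.p_values,
                    "random_intercept_var": v.random_intercept_var,
                    "residual_var": v.residual_var}
                for k, v in self.mixed_models.items()},
            "scale_factors": self.scale_factors,
            "diagnostics": self.diagnostics,
            "seed_manifest": self.diagnostics.get("seed_manifest", {}),
        }


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run the full synthetic study and return fitted statistics."""
    t_start = _time.time()
    cohort = generate_cohort(cfg.n_subjects, cfg.seed)
    rows = []
    scale_factors_all = {}
    diag = {"tracking_rmse": [], "reserve_peak_fraction": [],
            "seed_manifest": {"seed": cfg.seed, "n_subjects": cfg.n_subjects}}
    timings = {}

    for si, subject in enumerate(cohort):
        t_sub = _time.time()
        submax = _subject_submax(cfg, si)
        trials: list[tuple[str, int, GaitTrial]] = []
        for condition in cfg.conditions:
            reps = (2 if condition.total_pct == 0 else 1)
            for rep in range(reps):
                for k in range(cfg.n_strides):
                    t_index = rep * 100 + k
                    trial = generate_stride(
                        subject, condition, cfg.response, seed=cfg.seed,
                        model_config=cfg.model_config, n_nodes=cfg.n_nodes,
                        trial_index=t_index, submax_factor=submax,
                    )
                    trials.append((condition.name, t_index, trial))

        # calibration on unloaded strides
        calib_problems = []
        for name, t_index, trial in trials:
            if name != "none" or t_index >= 100:
                continue
            if len(calib_problems) >= cfg.n_calibration_strides:
                break
            model = apply_added_mass(
                scale_muscle_strength(build_default_model(subject, cfg.model_config)),
                trial.condition)
            sd = process_trial(trial, model, cfg.n_nodes)
            calib_problems.append(assemble_ocp(
                model, sd.q_nodes, sd.qdot_nodes, sd.moments, sd.time_nodes,
                sd.reference, cfg.calibration_weights, "calibration",
                other_reserves=sd.other_reserves))
        sf = solve_calibration(calib_problems)
        scale_factors_all[subject.subject_id] = sf.factors
        log.info("subject %s calibrated: %s", subject.subject_id,
                 {k: round(v, 3) for k, v in sf.factors.items()})

        # execution on every stride
        per_stride_rows = []
        for name, t_index, trial in trials:
            model = apply_added_mass(
                scale_muscle_strength(build_default_model(subject, cfg.model_config)),
                trial.condition)
            sd = process_trial(trial, model, cfg.n_nodes)
            prob = assemble_ocp(model, sd.q_nodes, sd.qdot_nodes, sd.moments,
                                sd.time_nodes, sd.reference,
                                cfg.execution_weights, "execution",
                                other_reserves=sd.other_reserves)
            res = solve_execution(prob, sf)
            trace = total_contact_force(res.muscle_forces, sd.knee_angle,
                                        sd.interseg_axial, model)
            peaks = extract_peaks(trace)
            diag["tracking_rmse"].append(res.tracking_rmse())
            peak_knee = float(np.max(np.abs(sd.moments["knee"])))
            res_peak = max(float(np.max(np.abs(res.reserves[d][5:-5])))
                           for d in ("knee", "ankle"))
            diag["reserve_peak_fraction"].append(res_peak / peak_knee)
            m = trial.condition.masses()
            per_stride_rows.append({
                "subject_id": subject.subject_id, "condition": name,
                "trial": t_index // 100, "stride": t_index % 100,
                "m_thigh": m["thigh"], "m_shank": m["shank"], "m_foot": m["foot"],
                "early_peak": peaks.early_peak, "late_peak": peaks.late_peak,
                "stride_time": trial.stride_time,
                "duty_factor": (sd.segmentation.duty_factor
                                if sd.segmentation.duty_factor else np.nan),
                "true_early": trial.truth.true_peaks[0] if trial.truth else np.nan,
                "true_late": trial.truth.true_peaks[1] if trial.truth else np.nan,
            })
        df = pd.DataFrame(per_stride_rows)
        # average strides within each condition-trial
        rows.append(df.groupby(
            ["subject_id", "condition", "trial"], as_index=False).mean(
                numeric_only=True))
        timings[subject.subject_id] = _time.time() - t_sub
        log.info("subject %s done in %.1f s", subject.subject_id,
                 timings[subject.subject_id])

    outcomes = pd.concat(rows, ignore_index=True)

    regressions = {}
    mixed_models = {}
    for peak in ("early_peak", "late_peak"):
        pct = percent_change(outcomes, peak, baseline_policy=cfg.baseline_policy)
        # collapse the two baseline trials to one zero row per subject
        agg = pct.groupby(["subject_id", "condition"], as_index=False).mean(
            numeric_only=True)
        regressions[peak] = fit_origin_regression(
            agg[f"{peak}_pct"], agg[["m_thigh", "m_shank", "m_foot"]].to_numpy())
        mixed_models[peak] = fit_random_intercept_lmm(
            agg[peak], agg[["m_thigh", "m_shank", "m_foot"]].to_numpy(),
            agg["subject_id"].to_numpy())
    pct_st = percent_change(outcomes, "stride_time",
                            baseline_policy=cfg.baseline_policy)
    agg_st = pct_st.groupby(["subject_id", "condition"], as_index=False).mean(
        numeric_only=True)
    regressions["stride_time"] = fit_origin_regression(
        agg_st["stride_time_pct"],
        agg_st[["m_thigh", "m_shank", "m_foot"]].to_numpy())

    diag["mean_tracking_rmse"] = float(np.mean(diag["tracking_rmse"]))
    diag["max_reserve_peak_fraction"] = float(np.max(diag["reserve_peak_fraction"]))
    timings["total"] = _time.time() - t_start

    report = PipelineReport(
        outcomes=outcomes, regressions=regressions, mixed_models=mixed_models,
        scale_factors=scale_factors_all, diagnostics=diag, timings=timings,
    )
    if cfg.outdir:
        _write_outputs(report, cfg)
    return report


def _write_outputs(report: PipelineReport, cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.outcomes.to_csv(outdir / "outcomes.csv", index=False)
    payload = report.to_json_dict()
    payload["timings"] = report.timings
    with open(outdir / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    log.info("wrote %s", outdir / "results.json")


def write_trial_sto(trial: GaitTrial, outdir: str | Path) -> None:
    """Write a trial's kinematics and GRF as STO/MOT files + EMG CSV."""
    from .sto import StoTable, write_sto

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = f"{trial.subject.subject_id}_{trial.condition.name}"
    qkeys = list(trial.q)
    ang = StoTable(
        name=f"{base}_angles",
        labels=["time"] + qkeys,
        data=np.column_stack([trial.time_angles] + [trial.q[k] for k in qkeys]),
    )
    write_sto(ang, outdir / f"{base}_angles.sto")
    grf = StoTable(
        name=f"{base}_grf",
        labels=["time", "fx", "fy", "cop_x"],
        data=np.column_stack([trial.time_grf, trial.grf["fx"],
                              trial.grf["fy"],
                              np.interp(trial.time_grf, trial.time_angles,
                                        trial.grf_100["cop_x"])]),
    )
    write_sto(grf, outdir / f"{base}_grf.mot")
    emg = pd.DataFrame({"time": trial.time_grf, **trial.emg})
    emg.to_csv(outdir / f"{base}_emg.csv", index=False)
    if trial.truth is not None:
        sidecar = {
            "true_peaks": list(trial.truth.true_peaks),
            "target_pct": list(trial.truth.target_pct),
            "true_scale_factors": trial.truth.true_scale_factors,
            "stride_time": trial.stride_time,
        }
        with open(outdir / f"{base}_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=float)
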