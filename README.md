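# kneeload

EMG-informed estimation of compressive tibiofemoral (knee) contact force
under added lower-limb mass, with a fully synthetic gait-study generator and
the statistical models that relate added segment mass to changes in peak
knee load.

## Who this is for

Researchers studying how worn mass — footwear, braces, exoskeletons —
changes knee joint loading during walking. Knee contact force cannot be
measured in the intact knee; the state of the art estimates it from
musculoskeletal simulation informed by surface electromyography (EMG). This
package implements that pipeline at desk scale on a planar sagittal model,
plus a synthetic data generator with *known ground truth* so every stage is
verifiable without motion-capture data.

## The model

**Skeleton.** A 9-DOF planar linkage: head-arms-trunk translation (x, y)
and rotation, plus hip/knee/ankle flexion per leg. Twelve muscle-tendon
units actuate the right leg (soleus, gastrocnemii, tibialis anterior,
hamstrings, vasti, rectus femoris); every other DOF is torque-driven.
Added mass is a point mass per loaded segment (steel rods: 300 g and 75 g
increments), updating segment mass, COM and planar inertia by the
parallel-axis theorem.

**Muscle mechanics.** Hill-type with rigid tendon: tendon force
`F = f_max [a f_L(l̃) f_V(ṽ) + f_pass(l̃)] cos(α)`, first-order activation
dynamics (τ_act = 15 ms, τ_deact = 60 ms), polynomial moment arms obeying
the tendon-excursion identity `r = −∂l_MT/∂q` exactly.

**The EMG-informed optimization.** Over one stance phase, with kinematics
and ground reactions prescribed, solve for adjusted excitations e(t),
reserve torques r(t) and (Calibration stage only) per-muscle EMG scale
factors s ∈ [0.5, 1] minimizing

```
J = w1·J_excitation + w2·J_knee/ankle + w3·J_reserve + w4·J_EMG
```

subject to activation dynamics and per-DOF moment equality
`Σ_m F_m(a) r_m + r_dof = M_ID` at every collocation node. Calibration runs
on unloaded strides with heavy penalties on excitation effort and
knee/ankle reserves (submaximal MVC normalization inflates EMG; the scale
factors shrink it back); Execution applies the averaged scale factors to
every trial. With a rigid tendon the transcription collapses to a convex
bound-constrained QP per activation-dynamics switching pattern, solved by
an active set on the normal equations — no NLP solver needed.

**Contact force.** Total compressive tibiofemoral force = intersegmental
axial reaction (muscle-free free-body of foot+shank, projected on the tibia
axis) + Σ knee-spanning muscles' compressive components, in body weights on
a 101-point stance grid. Early/late-stance peaks are maxima within 15–40%
and 60–90% of stance.

**Statistics.** Percent change of each subject's peaks from their unloaded
baseline, regressed through the origin on added mass per segment
(`%Δ = a_thigh·m_thigh + a_shank·m_shank + a_foot·m_foot`, % BW per leg),
with 95% CIs, p-values and Pearson r; random-intercept mixed models for
condition effects; coefficient-wise CI propagation for the all-segment
interaction check; and the a-priori power analysis (minimum detectable R²
via the noncentral-F distribution).

## Worked example

One synthetic subject walking with 1% of body weight added per foot,
calibrated and solved end to end:

```python
from kneeload import (SubjectAnthropometry, LoadingCondition, ResponseModel,
                      build_default_model, scale_muscle_strength,
                      apply_added_mass, generate_stride, assemble_ocp,
                      solve_calibration, solve_execution, OptWeights,
                      total_contact_force, extract_peaks, min_detectable_r2)
from kneeload.pipeline import process_trial

subject = SubjectAnthropometry("S01", mass=70.0, height=1.75)
condition = LoadingCondition("foot_low", m_foot=1.0)   # 1% BW per foot
response = ResponseModel(noise_sd=0.0, subject_offset_sd=0.0)

trial = generate_stride(subject, condition, response, seed=1)
model = apply_added_mass(scale_muscle_strength(build_default_model(subject)),
                         condition)
stance = process_trial(trial, model)

calib = assemble_ocp(model, stance.q_nodes, stance.qdot_nodes, stance.moments,
                     stance.time_nodes, stance.reference,
                     OptWeights.calibration(), "calibration",
                     other_reserves=stance.other_reserves)
factors = solve_calibration([calib])
prob = assemble_ocp(model, stance.q_nodes, stance.qdot_nodes, stance.moments,
                    stance.time_nodes, stance.reference,
                    OptWeights.execution(), "execution",
                    other_reserves=stance.other_reserves)
solution = solve_execution(prob, factors)
trace = total_contact_force(solution.muscle_forces, stance.knee_angle,
                            stance.interseg_axial, model)
peaks = extract_peaks(trace)
print(f"early-stance peak: {peaks.early_peak:.2f} BW at {peaks.early_location:.0f}% stance")
print(f"late-stance peak:  {peaks.late_peak:.2f} BW at {peaks.late_location:.0f}% stance")
print(f"true peaks:        {trial.truth.true_peaks[0]:.2f} / {trial.truth.true_peaks[1]:.2f} BW")
print(f"EMG tracking RMSE: {solution.tracking_rmse():.4f}")
print(f"min detectable R2 (n=60, p=3): {min_detectable_r2(60, 3):.4f}")
```

prints

```
early-stance peak: 4.23 BW at 28% stance
late-stance peak:  3.59 BW at 66% stance
true peaks:        4.23 / 3.62 BW
EMG tracking RMSE: 0.0085
min detectable R2 (n=60, p=3): 0.1696
```

The pipeline recovers the generator's true contact-force peaks to within a
couple of percent, the excitation tracking error is far below the 0.05
quality bound, and the power analysis says a 60-observation, 3-predictor
regression detects effects explaining ≥ 17% of variance at 80% power.

The full study — a 10-subject cohort across all nine loading conditions,
calibration, execution, contact forces and the through-origin regressions —
runs with:

```bash
kneeload run --n-subjects 10 --seed 0 --outdir out/
```

A `kneeload` CLI also exposes the individual stages
(`synth | emg-process | id | calibrate | execute | contact | stats`).

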