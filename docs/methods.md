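# Methods

## Scope and intent

`kneeload` estimates compressive tibiofemoral contact force during walking
from joint kinematics, ground reactions and surface EMG, and quantifies how
mass added to the thigh, shank or foot changes the early- and late-stance
peaks of that force. Every stage is designed to be verifiable at desk
scale: the musculoskeletal model is planar, the optimization reduces to
convex quadratic programs, and a synthetic generator produces trials whose
true excitations, contact forces and condition effects are known exactly.

## The planar musculoskeletal model

The skeleton is a sagittal 9-DOF linkage: a head-arms-trunk (HAT) segment
with translational (x anterior, y up) and rotational freedom at the hip
point, and thigh–shank–foot chains per leg. Generalized coordinates are
flexion-positive (knee 0 at full extension, flexion positive; ankle
dorsiflexion positive). Segment masses, lengths, COM offsets and planar
inertias come from standard anthropometric fraction tables (HAT 0.678 of
body mass; thigh 0.100, shank 0.0465, foot 0.0145 per side), shipped as an
editable YAML-serializable configuration and flagged as defaults rather
than measurements.

Twelve muscle-tendon units actuate the right hip, knee and ankle. Nine
correspond to surface-EMG-instrumented muscles; the remaining three
(vastus intermedius, biceps femoris short head, semimembranosus) receive
the adjacent measured muscle's EMG channel and are deliberately exact
parameter clones of that muscle. The cloning choice does two things: it
encodes the shared-innervation assumption behind the channel mapping, and
— because the redundancy objective is strictly convex — it guarantees each
clone pair receives identical excitations in the ground truth, so a mapped
reference signal is exactly consistent with its muscle's truth. Peak
isometric forces are sized so that the 12-muscle set can carry normative
walking moments (a full-limb model spreads the same demand over ~80
units); they scale with subject size by the mass–height product relative
to a 75 kg / 1.70 m reference.

Moment arms are low-order polynomials in the spanned joint's angle
(flexor-positive). Musculotendon length is defined as the *analytic
integral* of the moment-arm polynomials, anchored so each fiber sits at
optimal length in a mid-stance reference posture (hip 0.2, knee 0.35,
ankle 0 rad); the tendon-excursion identity `r = −∂l/∂q` therefore holds to
machine precision by construction and is verified by finite differences in
the tests.

Hill-type force generation uses a rigid tendon by default:
`F = f_max [a·f_L(l̃)·f_V(ṽ) + f_pass(l̃)] cos α`, with a Gaussian active
force–length curve (width 0.45), a Hill hyperbola with C¹-matched eccentric
branch (v_max 12 l_opt/s, curvature 0.35, eccentric plateau 1.4), an
exponential passive curve, and constant-thickness pennation. Two defaults
depart from common cadaver-derived tables and are deliberate: optimal fiber
lengths are at least 0.09 m (notably for the plantarflexors) and the
force–velocity curvature is mild. With a rigid tendon, fiber velocity
equals musculotendon velocity; literature-length plantarflexor fibers
(~4 cm) would see force–velocity collapse at push-off speeds that real
muscle avoids through tendon compliance. Longer fibers emulate that
buffering while keeping force affine in activation, which the optimizer
exploits. A quasi-static elastic tendon (4% strain at one normalized
force) is available (`muscle.quasistatic_tendon_force`) for fidelity
checks; it is not used inside the optimization because it destroys that
affinity.

Added mass is lumped as a point mass per loaded segment at a configurable
attachment fraction (default 0.43 of segment length, a standard COM
location; the hardware's exact placement was only "approximate mass
center", so the fraction is config, not an asserted value). Segment mass,
mass-weighted COM and parallel-axis inertia update accordingly; rod
combinations of 300 g and 75 g increments are selected by exhaustive
search (ties → smaller total mass, then fewer rods; a combination never
needs more than three small rods since four equal one large rod with a
worse rod count).

## Inverse dynamics and the intersegmental reaction

Net joint moments come from recursive Newton–Euler on the planar chain
with central-difference accelerations of the (8 Hz low-pass filtered,
zero-phase 4th-order Butterworth) kinematics, gravity 9.80665 m/s², and
ground reactions applied at the measured center of pressure. The
intersegmental (resultant) contribution to contact force is the free-body
reaction at the knee of the foot+shank subsystem under GRF, gravity and
inertial loads with muscles replaced by pure torques, projected on the
tibia long axis (compression positive). It is independent of every muscle
parameter by construction.

"Axial" here means the planar tibia long axis; a 3-D tibia reference frame
would differ slightly. This is a documented divergence of the planar
stand-in.

## The two-stage EMG-informed optimization

EMG processing: 20 Hz high-pass → full-wave rectification → 6 Hz low-pass
(all zero-phase 4th-order Butterworth), normalization by the larger of the
250 ms sliding-window MVC mean and the gait envelope's own maximum (no
signal exceeds 1), a 53 ms electromechanical-delay shift, and mapping of
the nine channels onto the twelve reference muscles. Stance is segmented
from vertical GRF with a 20 N threshold and 50 ms debounce; strides with
more than 0.5 s of bound-saturated EMG can be flagged programmatically (a
reproducible stand-in for visual inspection).

Each stance phase is transcribed by trapezoidal collocation on 51 nodes.
Decision quantities are node excitations e, activations a, reserve torques
r per DOF, and — in Calibration — one scale factor per measured muscle,
bounded to [0.5, 1] (submaximal MVC efforts make normalized EMG too large;
the bounds prevent non-physiological shrinkage and keep shared-innervation
channels consistent). The objective is

```
J = w1 ∫Σe² + w2 ∫(R_knee² + R_ankle²) + w3 ∫(R_other²) + w4 ∫Σ(e − s·ref)²
```

with reserve torques normalized by body mass inside the objective (N·m/kg)
so the weight ordering is meaningful across subjects and torque scales.

Numerical reduction. Activation dynamics use the Winters-type switching
time constant (τ_act where excitation exceeds activation, else τ_deact).
For a fixed switching pattern the trapezoidal forward map a = A(σ)e is
linear, and reserves — free, penalized variables — are eliminated
analytically from the moment equalities. The tracking residual e − s·ref
is linear in (e, s) jointly, so each stage is a *convex* bound-constrained
QP per pattern, solved by a primal active-set method on the normal
equations (Cholesky on the free block). The pattern is initialized by
simulating the activation map on the reference excitations and iterated to
a fixed point (keeping the best objective across visited patterns). The
multistart hook over scale-factor initializations is retained as insurance
against pattern cycling; the per-pattern optimum itself does not depend on
the start.

Weights. The stage defaults are Calibration (w1, w2, w3, w4) =
(10, 10⁴, 10⁻², 1) and Execution (0.1, 10², 10⁻⁴, 1): high excitation and
knee/ankle-reserve penalties during Calibration, both relaxed for
Execution, identical tracking weight across stages. The effort-to-reserve
ratios (w2/w1 = 10³, w3/w1 = 10⁻³) are held common to both stages — and to
the generator's truth weights — on purpose: the minimum-effort ground
truth is then a stationary point of both stage objectives when the
reference equals the (scaled) truth, making noiseless recovery exact
rather than merely approximate. Scale factors are solved per stride and
averaged across the calibration strides (the mean of bounded values stays
in bounds).

Moment equality is satisfied identically (reserves are defined as the
residual); solution feasibility is still asserted numerically on each
solve. Solution quality is summarized by knee/ankle reserve magnitude
relative to the peak knee moment and by the mean RMS excitation-tracking
error over the 10–90% stance region of interest.

## Contact force and peaks

Total compressive force = intersegmental axial + Σ over knee-spanning
muscles of (compressive-fraction polynomial in knee angle) × tendon force.
The quadriceps polynomial absorbs the patellar-tendon redirection; all
fractions stay in [0, 1] over the knee's motion range. Traces are
normalized by the subject's *unaugmented* body weight (added mass is
prescribed in % BW of the participant, and percent-change outcomes need a
condition-independent denominator) and resampled to a 101-point stance
grid by linear interpolation. Early and late peaks are windowed maxima
over 15–40% and 60–90% of stance, ties broken toward the earlier sample.

## The synthetic gait generator

The generator emulates the structure of a treadmill added-mass study:

* a cohort with mass ~ U(57, 81) kg and height ~ U(1.63, 1.78) m;
* nine loading conditions — none; 2/4% BW per thigh; 1.5/3% per shank;
  1/2% per foot; and 4.5/9% over all segments — with the no-mass condition
  run twice (opening and closing the protocol), exercising the
  baseline-averaging choice downstream;
* kinematics at 100 Hz, GRF and EMG at 1250 Hz;
* EMG with per-muscle submaximal-MVC inflation (recoverable scale factor =
  the reciprocal, in [0.5, 1]) and a 53 ms electromechanical lead;
* condition effects on stride time (default +2.5% per 1% BW per foot,
  +0.26% per 1% BW per thigh) and on the two contact-force peaks (defaults
  per % BW per leg: early 1.5/2.1/5.9 and late 1.6/0.9/3.0 for
  thigh/shank/foot), plus per-subject response offsets (SD 2%) and
  residual noise (SD 3%). The variance defaults are synthetic placeholders
  chosen to resemble between-subject error bars, not estimates from data.

Three construction guarantees matter for testing:

1. **Dynamic consistency.** Joint-angle trajectories are smooth periodic
   templates (normative stance shapes Fourier-smoothed over the gait
   cycle); per-leg GRF is an analytic double-bump template with amplitude
   normalized so the mean total vertical force equals the (augmented)
   weight. The whole-body COM trajectory is then *constructed* so that its
   second central difference equals (F_total + M g)/M exactly, and the
   trunk translation absorbs the difference between that COM and the leg
   kinematics; a constant vertical shift anchors the stance ankle at
   plate level. Inverse dynamics of a noiseless trial therefore
   round-trips to machine precision, and Newton's second law holds for
   the whole body at every interior sample.
2. **Known, recoverable truth.** True excitations solve the same
   minimum-effort collocation problem the pipeline uses (weights
   (1, 10³, 10⁻³, 0)); the true contact trace and peaks follow by the
   standard joint-reaction computation on that solution.
3. **Controlled condition effects.** Peak effects are *injected*, not
   emergent: the center of pressure is shifted inside smooth,
   non-overlapping early- and late-stance windows, which modulates
   knee-spanning muscle demand without touching the GRF, the consistency
   construction, or the intersegmental force. The two shifts are solved
   by a Newton iteration with finite-difference Jacobian and Broyden
   refreshes (the shift → peak map is locally affine and nearly diagonal),
   so the truth peaks hit the response-model targets to ~1e-9 BW. A
   `mechanistic_only` switch disables injection, leaving only the real
   inertial and stride-time consequences of the added mass.

What the generator does **not** emulate: marker trajectories and soft
tissue artifact, 3-D and frontal-plane mechanics, genuine double-support
force sharing on the analyzed side (each leg's GRF is templated
independently), belt dynamics, electromechanical noise spectra (synthetic
EMG is envelope-domain), motor adaptation, and any emergent swing-leg
mechanism for the peak effects. Passing recovery tests therefore shows the
pipeline is *internally correct and well-conditioned*, not that its
estimates are accurate for real limbs.

A fast statistical path (`response_outcome_table`) produces true-peak
outcome tables from response-model arithmetic alone (no dynamics), used
for many-seed coefficient-recovery and CI-coverage studies where the full
mechanistic generator would add nothing but runtime.

## Statistics

* Percent change is computed per subject from the unloaded baseline; with
  two no-mass trials the baseline is their mean (configurable to
  first-only). Averaging was chosen to reduce drift bias between the
  opening and closing unloaded trials.
* The headline model is least squares through the origin on the three
  segment masses, with t-based 95% CIs and two-sided p-values on n − 3
  degrees of freedom, and Pearson r between observed and predicted
  outcomes. statsmodels OLS supplies the machinery; a normal-equations
  oracle cross-checks it in the tests.
* Random-intercept mixed models (REML, statsmodels MixedLM) account for
  subject offsets in condition-effect tests; with zero between-subject
  variance (e.g. noiseless data) the implementation falls back to the OLS
  limit it provably reduces to.
* The all-segment interaction check propagates coefficient-wise CI
  endpoints: bound = Σ endpoint_i × mass_i. This mirrors the original
  bound construction; it is not a proper prediction interval and is
  documented as such.
* `min_detectable_r2` solves power(R²) = target by bisection (1e-6) on the
  noncentral-F power of the overall F-test. The default convention treats
  the predictors as *random* (multivariate normal): conditional
  noncentrality f²·K with K ~ χ²(n−1), averaged over the design
  distribution. This unconditional convention reproduces the printed
  study value (0.17 at n = 60, p = 3, α = 0.05, power = 0.8) and the
  Monte-Carlo rejection rate when predictor values are themselves sampled;
  the classical fixed-design formula (ncp = n·f², giving 0.163 → 0.16) is
  available via `predictors="fixed"`.

## Problem sizes used in the shipped verification

The end-to-end acceptance run uses the full 10-subject cohort over all
nine conditions (no-mass twice), one analyzed stride per condition trial
and one calibration stride, at 51 collocation nodes — about 110 stance
solves plus truth generation, a few minutes on one CPU. Calibration
recovery uses 20 seeded trials with scale factors drawn uniformly from
[0.55, 0.95]; CI-coverage uses 20 seeds of the fast statistical path.
Stride counts per condition are configurable; more strides average away
per-stride noise but do not change any noiseless result.

## Known limitations

* Planar mechanics only; no frontal-plane (medial/lateral) load split —
  the axial projection is onto the planar tibia axis.
* The rigid-tendon default with lengthened fibers is a modeling trade for
  convexity and desk-scale verification; muscle-level force estimates for
  tendon-dominated muscles (triceps surae) inherit that approximation.
* Condition effects on the peaks are injected by design; the generator
  validates recovery, not biomechanical causation.
* The synthetic EMG is envelope-domain: the 20 Hz/6 Hz envelope stage is
  unit-tested on constructed signals but bypassed in the synthetic
  pipeline (a config choice), since enveloping an envelope would destroy
  it.
* Through-origin regression assumes no intercept and independent errors;
  per-subject response offsets violate independence mildly, which the
  CI-coverage test quantifies empirically.
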