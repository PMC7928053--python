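# Methods

This note documents the models, numerical choices and known limitations
behind `myomhe`, in the spirit of a model-description appendix: what the
package computes, which knobs matter, and what the synthetic experiments
do and do not show about real data.

## Musculoskeletal model

The flagship model (`myomhe.model.arm_model`, config
`src/myomhe/data/arm4d19.yaml`) is a serial chain: a fixed thorax, a
humerus with three glenohumeral revolute DoFs (plane of elevation,
elevation, axial rotation) and a forearm (ulna + radius bodies) with one
elbow-flexion DoF. Joint limits are [−π/2, π/2], [−2, π/2], [−π/2, π/2]
and [−0.5, 2.1] rad in that order. Eight markers sit on the humerus
(4), ulna (3) and radius (1), away from large soft-tissue regions.

Nineteen Hill-type muscle elements actuate the chain (pectoralis major ×
3, latissimus dorsi × 3, deltoid × 3, supraspinatus, infraspinatus,
subscapularis, triceps × 3, brachioradialis, brachialis, biceps × 2).
Lines of action are polylines through via points; no wrapping surfaces
and no pennation. Maximum isometric forces follow the Holzbaur upper-
limb dataset; attachment coordinates are plausible hand-placed values
(documented placeholders — the study design is self-consistent, so the
reference data and the estimator always share the same model, and no
anthropometric claim rests on the coordinates). The middle deltoid
carries a via point arcing over the humeral head; without it the model
has no effective abductor moment at the arm-down posture.

### Hill muscle

Rigid tendon: fiber length $\ell_f = \ell_{mt} - \ell_{ts}$, normalized
by the optimal fiber length $\ell_o$. Force:

* active force–length $f_l(\tilde\ell) = \exp(-(\tilde\ell-1)^2/0.45)$;
* force–velocity $f_v(\tilde v) = 1 + \operatorname{asinh}(3\tilde v) /
  \operatorname{asinh}(3)$, smooth, $f_v(0)=1$, $f_v(-1)=0$;
* passive $f_p(\tilde\ell) = (e^{4(\tilde\ell-1)}-1)/(e^{2.8}-1)$ for
  $\tilde\ell>1$, exactly zero below (one $C^0$ kink at slack length).

$F = F_{iso}\,(a\,f_l f_v + f_p)$. Activation dynamics
$\dot a = (e-a)/\tau$, with $\tau$ blending smoothly (logistic width
0.02) between $\tau_{act}=15$ ms and $\tau_{deact}=60$ ms so the ODE is
differentiable; the electromechanical delay (20 ms) is applied as a
time shift of the EMG stream in the activation-driven formulation.

Optimal-fiber and tendon-slack lengths are calibrated once from the
geometry: over the task workspace, $\ell_o = \max(4\,\Delta\ell/2,
5\,\text{cm})$ (with $\Delta\ell$ the musculotendon excursion) and
$\ell_{ts}$ centered so the mid-range fiber length is optimal. This
keeps every element within $\tilde\ell \in [0.75, 1.25]$, i.e. near
optimal force-generation and with moderate passive stretch — an earlier,
wider calibration produced passive torques several times the task
torques and an unsolvable redundancy problem.

### Rigid-body dynamics

Mass matrix by Jacobian assembly ($M = \sum_b m_b J_v^\top J_v +
J_\omega^\top I_b^w J_\omega$), bias forces by a world-frame
Newton–Euler sweep with zero joint acceleration, muscle torques
$\tau = R^\top F$ with moment arms $R = -\partial \ell_{mt}/\partial q$
computed analytically from point Jacobians. The batched state
derivative is additionally implemented as a numba kernel (complex128)
used by the optimal-control layer; the numpy implementation is the
reference and the test suite asserts agreement to ~1e-10 relative.

## Transcription and solver

All optimal-control problems (reference generation, MHE windows,
full-window baseline) use direct multiple shooting: states at the nodes
and piecewise-constant controls per interval are decision variables,
linked by RK4 continuity defects. Defect Jacobians come from
complex-step differentiation through the integrator (exact for the
discrete map, no step-size tuning), batched over all intervals and
directions.

The solver is a Gauss–Newton SQP specialized to this structure:

* equality-constrained QPs with simple bounds, solved by a primal
  active-set method on the bounds (sparse LU of the equilibrated,
  iteratively refined KKT system; constraint rows whose variables are
  all pinned are dropped);
* globalization by a filter line search (feasibility/cost dominance
  with small margins, a feasibility-growth cap of 1.2·θ + 1e-3 per
  step) plus Levenberg damping that stiffens when steps get truncated;
* stopping on KKT tolerances, on cost stationarity at a feasible point,
  or on a 25-iteration cost-and-feasibility plateau;
* a minimum-norm Newton restoration ("projection onto the dynamics
  manifold"): solve $JJ^\top y = -c$ and step along $J^\top y$ over the
  non-fixed, non-bound-active variables. This perfectly scaled
  subproblem converges to machine-level defects where the cost-laden
  KKT systems (weights spanning $10^{-4}$ to $10^9$) stall around
  1e-4–1e-8, and is what guarantees the dynamic-consistency property
  of both the reference datasets (defects < 1e-8) and the stored MHE
  chains (< 1e-6).

Hard bound constraints keep excitations in [0, 1] and joint angles
within the model limits. Equality-fixed variables (imposed boundary
kinematics, the MHE initial-state constraint) are implemented as
degenerate bounds.

## Reference motion (synthetic ground truth)

The reference is a cyclic elbow flexion–extension with modest shoulder
movement: joint kinematics are imposed at the initial and final instants
(identical postures, zero velocity) and at mid-cycle, and the muscle
excitations are found by least effort — quadratic penalties on
excitations and activations about a 2 % resting tone (which keeps the
least-effort solution strictly inside the [0, 1] bounds), a small
velocity penalty, and a steady-start coupling $a_0 \approx e_0$ so a
measurement stream cut at $t = 0$ carries no hidden activation
transient. Co-contraction levels impose one-sided (softplus-smoothed)
minimum-excitation floors {0, 0.1, 0.2, 0.3} on the five triceps/biceps
elements; the levels are solved as a homotopy (each warm-started from
the previous) and the co-contracted levels softly track the plain
level's joint trajectory (weight 1e3), which keeps the four kinematic
profiles within well under 1 deg RMSE of each other.

Flagship scale is 8 s / 800 shooting intervals (100 Hz). Desk scales
(1.6–2 s cycles at the same 100 Hz rate; exact sizes per use in the
"Desk-scale problem sizes" section) reduce the task amplitudes (~0.4×)
so the joint velocities match the slow-motion regime of an 8 s
full-amplitude cycle;
at full amplitude a 2 s cycle has ~4× the velocities and becomes a
qualitatively harder (more dynamic) estimation problem than the study
design intends. The initial guess is deterministic: a cosine profile
through the imposed postures, activations from per-node non-negative
least-squares static optimization, excitations from inverted activation
dynamics.

Cost weights (config entries): control 100, velocity 1, activation 1,
co-contraction floor 1e4, kinematic coupling 1e3.

## Noise simulator

EMG: the clean excitations are corrupted in the Fourier domain — every
one-sided coefficient at |f| ≤ 2.125 Hz receives an independent complex
Gaussian perturbation (DC and Nyquist kept real), the signal is
inverse-transformed and clipped to [0, 1]. Levels none/low/mid/high use
σ ∈ {0, 0.05, 0.1, 0.2} per coefficient under a normalization that makes
the injected *time-domain* noise std duration-invariant and equal to the
flagship-scale value (≈ 0.47 σ, i.e. ≈ 0.02/0.04/0.09 excitation units
for low/mid/high); without this anchoring the same per-coefficient rule
injects 2.3× more noise at desk scale than at flagship scale.

Markers: placement error, not jitter — each marker's local position is
displaced once per trial by an isotropic Gaussian offset (per-axis std
σ/√3, σ ∈ {0, 2, 5, 10} mm), and the reference kinematics are
re-simulated on the displaced ("surrogate") model. Soft-tissue artifact
is deliberately not modelled. Clean ground truth is never mutated, and
identical seeds reproduce trials bit-exactly.

## Moving-horizon estimator

Window of N measurement frames = N shooting nodes (N−1 intervals);
default N = 7. Per-node cost: marker tracking (ω_m = 1e9 or 1e7, the
two printed variants), EMG tracking (ω_e = 1e3) or squared-excitation
minimization (weight 10), velocity regularization 1e-2, control
regularization 1e-2, and a 1e-4 activation regularization whose only
purpose is conditioning (the activation states are otherwise cost-free
and their unobservable directions make the window NLP singular). The
regularization weights are deliberately small: at 1e-1-scale they
measurably bias the redundant activations and force estimates on
noiseless data.

Loop mechanics: the first window is solved cold from an inverse-
kinematics guess (activations by integrating the activation ODE under
the measured EMG); in the EMG-tracking variants its initial activations
are pinned to the first EMG sample — a steady-start prior consistent
with the reference protocol, because the initial activation state is
essentially unobservable from one short window. Each subsequent window
shifts by one frame, fixes
the initial state to the previous solution's second state, warm-starts
from the shifted previous solution with the new tail node *predicted*
by integrating the model under the held last control, and re-solves.
After every solve the solution is projected back onto the dynamics
manifold; a window counts as converged when the final defects are
≤ 1e-6 and the projection was a small correction. After a failed
window the chain re-anchors: the next window restarts cold (no initial-
state constraint), with the initial activations pinned to the
EMG-history-integrated value — without this, one failed window poisons
every subsequent initial-state constraint. Runs report the convergence
rate; a run is "achieved" above 90 %.

Real-time emulation: streams are subsampled before estimation. The
window sweep maps window size to a subsample factor via an assumed
solve-rate line (≈30 Hz at window 3 down to ≈10 Hz at window 20 on a
100 Hz stream; window 7 ≈ 25 Hz), mirroring how a slower estimator
ingests sparser data; wall-clock performance itself is logged but never
evaluated. Grid experiments fix window 7 and subsample 4.

## Evaluation campaign

Pooled RMSE (over channels and time, inner join on timestamps) for
joint angles (deg), muscle forces (N) and markers (m). The full
crossed design is 4 marker-noise × 4 EMG-noise × 4 co-contraction
levels × repetitions (default 30) × cost variants; trials with ≤ 90 %
window convergence are flagged and excluded from statistics.
Fixed-effects factorial ANOVA (statsmodels) with Bonferroni-corrected
Welch post-hoc t-tests (reporting threshold p < 0.001) summarize factor
effects.

## Desk-scale problem sizes

Chosen once, as the package's own trade-off between statistical
resolution and a desktop/CI runtime:

* test suite: planar 2-DoF/6-muscle fixture at 2 s / 100 nodes (50 Hz)
  for all solver/estimator unit and property tests; the arm at
  1.6 s / 160 nodes for the acceptance-level tests, with a
  2-repetition noisy grid;
* acceptance script: arm at 1.6 s / 160 nodes (100 Hz); noiseless
  window-7 run on the full stream; noisy grid with all four EMG-noise
  levels × mid marker noise, 2 seeded repetitions per condition at
  25 Hz, window-solve budget 8 SQP iterations. The EMG-tracking
  variant runs on the mid co-contraction reference and the
  excitation-minimizing variant on the high level (its binding
  condition).

## What the synthetic experiments show — and what they do not

The design is deliberately self-consistent: the estimator uses the same
musculoskeletal model (geometry, Hill parameters, inertia) that
generated the data, as the validation of record does. Passing the
noiseless experiments therefore demonstrates the estimator mechanism
(observability through the window, dynamic consistency, warm-start
behaviour), not robustness to model error. The noise experiments add
realistic measurement corruption — low-frequency EMG noise and
constant marker-placement offsets — but not soft-tissue artifact,
model-parameter error, or EMG normalization error, all of which
dominate real recordings. Force errors under high simulated EMG noise
scale directly with the assumed noise magnitude times the muscles'
force gain (~0.09 × F_iso × f_l ≈ 40–60 N pooled at the high level
here); absolute force-error figures should be read with that
sensitivity in mind.

## Known limitations

* No muscle wrapping, pennation or tendon compliance; straight-line
  via-point geometry only.
* The glenohumeral Euler-like axis sequence degenerates at zero
  elevation (mass-matrix conditioning ~1e6 nearby); the default task
  avoids that region.
* The excitation-minimizing variant converges less reliably than the
  EMG-tracking variants (broad weak-curvature subspaces); it runs with
  a persistent Levenberg floor and a larger iteration budget.
* Estimation accuracy at subsampled rates is floored by the
  piecewise-constant control discretization (the reference varies its
  excitations at 100 Hz; a 25 Hz window cannot represent that), worth
  a few N of pooled force RMSE independent of noise.
* Marker files are CSV only (wide format, meters); no binary
  motion-capture container is read or written.
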