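# myomhe

Real-time-style, dynamically consistent estimation of muscle forces from
EMG envelopes and skin-marker trajectories, using moving-horizon
estimation (MHE) on a Hill-type musculoskeletal arm model.

## The problem

Muscle forces cannot be measured non-invasively. Inverse methods (static
optimization) estimate them frame by frame from kinematics, but the
resulting force histories ignore activation dynamics, are corrupted by
double-differentiated marker noise, and systematically miss
co-contraction (simultaneous agonist/antagonist activity produces no net
joint torque, so a least-activation criterion reports none of it).
Forward, optimal-control approaches fix all three problems but have been
considered too slow for online use.

`myomhe` implements the moving-horizon middle ground. At every time step
the estimator solves a small optimal-control problem over the most
recent window of measurements:

$$
\min_{\mathbf{x},\,\mathbf{u}} \int_0^T L(\mathbf{x},\mathbf{u})\,dt
\quad \text{s.t.} \quad
\dot{\mathbf{x}} = f(\mathbf{x},\mathbf{u}),\;
\mathbf{u} \in [0,1]^{19},\;
\mathbf{q} \in \mathcal{Q},\;
\mathbf{x}(0) = \mathbf{x}_0 ,
$$

where the state $\mathbf{x} = (\mathbf{q}, \dot{\mathbf{q}},
\mathbf{a})$ stacks joint angles, velocities and muscle activations, the
controls $\mathbf{u}$ are neural excitations, and the running cost $L$
tracks measured marker positions $\mathbf{m}^*$ (weight
$\omega_m = 10^7$ or $10^9$) and measured EMG envelopes
$\mathbf{emg}^*$ (weight $\omega_e$), or — in the classical
least-excitation variant — minimizes $\|\mathbf{u}\|^2$ instead of
tracking EMG. When a new sample arrives, the oldest is discarded, the
initial state is constrained to the second state of the previous
solution (this is what makes the chained estimates *dynamically
consistent*: the stored sequence exactly satisfies the model ODE under
integration), the previous solution is shifted as a warm start, and the
window is re-solved.

Everything needed to study the estimator is included:

* a 4-DoF arm (glenohumeral plane of elevation / elevation / axial
  rotation + elbow flexion) driven by 19 Hill-type muscle elements with
  8 skin markers, shipped as a YAML config;
* a reference-motion generator that solves a cyclic optimal-control
  problem (direct multiple shooting, 800 intervals / 8 s / 100 Hz at
  flagship scale) at four co-contraction levels (minimum-excitation
  floors 0 / 0.1 / 0.2 / 0.3 on the triceps/biceps pair);
* an experimental-noise simulator: low-frequency Fourier-domain EMG
  noise (coefficients below 2.125 Hz) and marker *placement* error
  (one 0/2/5/10 mm draw per trial on a surrogate model);
* the evaluation campaign: window-size sweep, crossed marker-noise ×
  EMG-noise × co-contraction grid with seeded repetitions, pooled RMSE
  scoring, the >90 %-convergence trial filter, and two-/three-way ANOVA
  with Bonferroni post-hocs.

The direct-multiple-shooting transcription and the Gauss–Newton SQP
solver (sparse KKT systems, complex-step derivatives through a
numba-compiled dynamics kernel, filter line search, Levenberg damping,
minimum-norm feasibility restoration) are part of the package.

## Worked example

```python
import numpy as np
from myomhe.model import arm_model, CompiledModel
from myomhe.reference import solve_reference_family
from myomhe.mhe import run_mhe, MheProblem, MeasurementStream
from myomhe.evaluate import score_estimate

model = arm_model()                       # 4 DoFs, 19 muscles, 8 markers
cm = CompiledModel(model)

# ground truth: cyclic motion by optimal control (desk scale: 2 s, 100 Hz)
fam = solve_reference_family(model, levels=("none",), duration_s=2.0,
                             n_nodes=200)
reference, _ = fam["none"]

# estimate from the (here noiseless) EMG + marker streams, window 7
stream = MeasurementStream.from_reference(reference)
result = run_mhe(cm, stream, MheProblem(window=7))
print(f"convergence rate {result.convergence_rate:.1%}")
score = score_estimate(cm, result, reference)
print(f"joint angles {score['rmse_q_deg']:.2e} deg, "
      f"forces {score['rmse_force_n']:.3f} N, "
      f"markers {score['rmse_markers_m']*1e3:.2e} mm")
```

Output from this exact script:

```
convergence rate 100.0%
joint angles 4.96e-05 deg, forces 0.058 N, markers 9.68e-05 mm
```

i.e. on self-generated noiseless data the window-7 estimator recovers
the reference joint angles to ~5e-5 degrees, the 19 muscle-force
trajectories to ~0.06 N pooled RMSE, and the marker trajectories to
~1e-4 mm, with every window solve converging.

The same pipeline is scriptable from the shell:

```bash
myomhe generate-reference --duration 2 --nodes 200 --cocontraction mid --out ref/
myomhe corrupt --reference ref/ --emg-level mid --marker-level mid --seed 7 --out noisy/
myomhe estimate --markers noisy/markers.csv --emg noisy/emg.csv --window 7 --subsample 4 --out est/
```

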