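# hydroschool

Agent-based simulation and analysis of fish schools whose members interact
through vision *and* through the water they stir.

## The problem

Schooling fish align with and attract to the neighbours they can see, but
every swimmer also sheds a dipolar flow field that advects and reorients
everyone else.  How do cohesion, the range of behavioural correlations, and
the speed at which "we are turning" propagates through the group depend on
group size and on the strength of these flow interactions?  This package
implements the model and the full measurement stack for those questions,
for researchers in collective animal behaviour and active matter.

## The model

Swimmer i at `x_i` with heading `p_i = (cos θ_i, sin θ_i)`:

    dx_i/dt = U p_i + U_i
    dθ_i    = ( ⟨ r_ij sin θ_ij + Ia sin φ_ij ⟩_i + Ω_i ) dt + In dW_t

* `⟨·⟩_i` — mean over i's Voronoi neighbours, weighted by the frontal
  visual field `1 + γ cos θ_ij` (rear blind spot at γ = 1);
* attraction (`r_ij sin θ_ij`, intensity 1 by non-dimensionalisation) and
  alignment (`Ia sin φ_ij`);
* `U_i` — superposed dipolar flow of all other swimmers,
  `(If/π)[p_j⊥ sin 2θ_ji + p_j cos 2θ_ji]/r_ij²`, with
  `Ω_i = p_i · (dU_i/dx) · p_i⊥` the flow-gradient reorientation;
* `In` — rotational noise.  `If = π(a/2)²U` encodes the bodylength a.

Time integration is explicit Euler–Maruyama at `dt = 10⁻²` with the
Voronoi graph rebuilt every step and the O(N²) dipole sum in a compiled
kernel; runs are bitwise reproducible under a fixed seed.

The analysis modules provide the polar order parameter P, school geometry
(length L, NND/VND, density), FFT split/merge timing, HDBSCAN cluster
identification and tracking, the velocity-fluctuation correlation C(r)
with its zero-crossing length ξ (scale-free: ξ ≈ L/3 in cohesive polarized
schools), and collective-turn analysis: pairwise turning delays from
curvature cross-correlation, turning ranks, and the information-transfer
speed c from the rank-distance `d = sqrt(o/ρ)` versus absolute turn time.
Two lattice models predict ballistic information transfer analytically:
a front-biased alignment model with speed `c = γ α Ia/2` and a 1-D
dipole-lattice model with speed ∝ `If/α²`.

## Worked example

```python
import numpy as np
from hydroschool import ModelParams, SimConfig, run, polarization
from hydroschool.correlations import xi_L_points

cfg = SimConfig(N=100, T=200.0,
                params=ModelParams(Ia=9.0, In=0.5, If=0.01, seed=1),
                record_stride=100)
traj = run(cfg)                      # ~20 s on one core

P = np.mean([polarization(traj.theta[f])
             for f in range(traj.n_frames // 5, traj.n_frames)])
speed = np.linalg.norm(traj.v.mean(axis=1), axis=-1)[traj.n_frames // 5:].mean()
print(f"P = {P:.3f}, school speed = {speed:.3f} U")

pts = np.array(xi_L_points(traj, p_min=0.9,
                           frame_range=slice(traj.n_frames // 5, None)))
print(f"snapshots: {len(pts)}, mean L = {pts[:, 0].mean():.1f}, "
      f"mean xi = {pts[:, 1].mean():.2f}, "
      f"mean xi/L = {(pts[:, 1] / pts[:, 0]).mean():.2f}")
```

prints

    P = 0.965, school speed = 1.142 U
    snapshots: 161, mean L = 9.1, mean xi = 1.91, mean xi/L = 0.21

i.e. a school of 100 swimmers at the cohesive-regime intensities stays
highly polarized (P ≈ 0.96), swims ~15% faster than an individual (each
swimmer surfs the dipole fields of the others), and its velocity
fluctuations are positively correlated over a finite fraction of the
school length; across sizes and intensities ξ grows with L — the
scale-free signature.

A CLI wraps the same functionality:

    hydroschool simulate --config run.toml --out traj.h5 --seed 42
    hydroschool analyze stats --traj traj.h5 --out stats.csv
    hydroschool analyze turns --traj traj.h5 --out turns.json
    hydroschool theory align-speed --ia 9 --alpha 1 --gamma 1

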