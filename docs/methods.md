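# Methods

## Model

Each of N swimmers is a self-propelled particle in the unbounded plane with
position `x_i` and heading `p_i = (cos θ_i, sin θ_i)`, moving at unit speed
relative to the local flow:

    dx_i/dt = U p_i + U_i ,
    dθ_i    = ( ⟨ r_ij sin θ_ij + Ia sin φ_ij ⟩_i + Ω_i ) dt + In dW_t .

`r_ij` is the pair distance, `θ_ij` the viewing angle of j from i (bearing
relative to i's heading) and `φ_ij = θ_j − θ_i` the heading difference.
`⟨·⟩_i` averages over i's first-shell Voronoi neighbours with the frontal
visual weight `1 + γ cos θ_ij` (γ = 1 by default: weight 2 dead ahead, 0
dead behind).  The first term inside the average is attraction (intensity
normalised to 1 by the choice of units), the second alignment with
intensity `Ia`.  `In` scales rotational white noise.

Every swimmer sheds a potential-dipole far field.  In complex notation
(`z = x + iy`) the conjugate velocity of swimmer j's dipole is

    f_j(z) = (If/π) e^{iθ_j} / (z − z_j)² ,       u_x − i u_y = f_j(z),

which is the same 1/r² field as the `p⊥ sin 2θ_ji + p cos 2θ_ji` form.
`U_i` superposes all `j ≠ i`.  Swimmers also reorient with the local flow
gradient, `Ω_i = p_i · (dU_i/dx) · p_i⊥`.  Because each dipole field is
incompressible and irrotational, the ambient Jacobian is the symmetric
traceless matrix `[[A, −B], [−B, −A]]` with `A + iB = Σ_j f_j'(z_i)`, so

    Ω_i = −(A sin 2θ_i + B cos 2θ_i),

evaluated in closed form (a central-difference oracle checks it to 1e−5 in
tests).  The dipole intensity encodes the swimmer bodylength through
`If = π (a/2)² U`; `If = 0.01` corresponds to `a = 0.11`.

Parameters and defaults: `Ia = 9`, `In = 0.5`, `If = 0.01` (the published
cohesive-regime values), `γ = 1`, `U = 1`, `dt = 0.01`.

## Integration

Explicit Euler–Maruyama at `dt = 10⁻²` with one standard-normal draw per
swimmer per step (`θ` increment `√dt · In · N(0,1)`), the Voronoi graph
(SciPy Delaunay) rebuilt every step, and the O(N²) pair sum evaluated by a
compiled serial kernel with a fixed accumulation order, so runs are bitwise
reproducible under a fixed seed.  Pair distances below 10⁻² trigger a
near-field warning; below 10⁻⁶ the step aborts (the dipole sum would blow
up silently otherwise).  Angles are wrapped to (−π, π] throughout; if a
swimmer's total visual weight vanishes (all neighbours exactly behind, a
measure-zero configuration) its drift is defined as 0 by continuity.

Initial conditions: positions uniform on a disk of area N/density
(density 1 by default — the steady state does not depend on it), headings
uniform or aligned.  Recording stride defaults to 100 steps (1 time unit);
turn analyses use stride 10.

## Analysis stack

* **Polarization** `P = |Σ p_j|/N`; split/merge timing from the dominant
  FFT frequency of dP/dt with all frequencies above 0.5 discarded
  (a low-pass that removes individual-level noise).
* **Frame statistics**: school length L = max pair distance (computed on
  hull vertices), mean nearest-neighbour distance (NND), mean distance to
  Voronoi neighbours (VND), density = N / convex-hull area.  The hull
  density slightly overestimates interior density for small N; users can
  substitute a Voronoi-cell estimate.
* **Clustering**: HDBSCAN on raw positions.  Two deliberate deviations from
  library defaults: `allow_single_cluster=True` (the default tree pruning
  can never report one cluster, but a cohesive school is exactly that) and
  `min_samples=5` (the default sheds most of a uniform school's border as
  noise).  `min_cluster_size` defaults to 20.  Frame-to-frame identity by
  greedy maximal-overlap matching (≥ 50% shared members).
* **Correlations**: fluctuations `δv_i = v_i − ⟨v⟩` (zero-sum by
  construction); C(r) by distance binning (default bin width L/50, the
  r = 0 bin holding the i = j terms and fixing C(0) = 1; empty bins are
  NaN, not 0).  The correlation length ξ is the first zero crossing,
  linearly interpolated.  Snapshots enter the ξ–L ensemble only when
  P > 0.9.  A falling ξ/L at sustained P is the fragmentation precursor.
* **Turns**: per-swimmer trajectory curvature
  `κ = (ẋÿ − ẏẍ)/(ẋ² + ẏ²)^{3/2}` by central differences (endpoints
  dropped, near-zero-speed samples NaN).  Pairwise turning delay τ_ij =
  argmax of the curvature cross-correlation (FFT-batched, 3-point parabolic
  refinement; τ_ij < 0 when i turns first; τ is antisymmetric and additive
  on clean data, and the mean triangle violation is reported as a noise
  diagnostic).  Swimmers are ranked by how many others they precede; the
  absolute turn time of swimmer i averages `t_j + τ_ij` over all
  higher-ranked j.  Information distance `d = sqrt(o/ρ)` (the radius of the
  disk holding the o swimmers already turned at density ρ; ρ is the
  cluster's hull density averaged over the event window).  The speed c is
  the OLS slope of d on t from t = 0 until d reaches 80% of its maximum —
  a deterministic stand-in for the visual "early and intermediate times".

Two analysis choices matter on noisy data and are therefore explicit
parameters of `analyze_turn`: the curvature series is Gaussian-smoothed
(default s.d. 1 time unit — the raw per-sample curvature of a simulated
swimmer is dominated by the `In √dt` heading noise), and the padded
detection window can be trimmed to ±15 time units around the group
heading-rate peak (`core_half_time`), because a meandering school has
several turning episodes per window and the cross-correlation must lock
onto a single one.  Neither choice biases the scripted-turn fixtures,
which are recovered to < 1% at c* ∈ {2, 10, 30}.

Turn detection flags windows in which a tracked cluster's circular mean
heading changes by more than π/4 within 50 time units while at least 90%
of the membership is retained; qualifying windows are taken greedily and
non-overlapping (padding 25 time units each side).

## Continuum lattice models

For a highly polarized school, writing `θ_i = θ̄ + φ_i` and placing
swimmers on a lattice of spacing α aligned with the motion:

* **Alignment model** (vision only): the focal swimmer relaxes toward its
  front/left/back/right neighbours with weights `1 ± γ cos φ` /
  `1 ± γ sin φ` (sum exactly 4), giving diffusion `α² Ia/4 Δφ` plus
  anisotropic advection.  A longitudinal perturbation travels front-to-back
  at `c = γ α Ia / 2` — ballistic information transfer caused purely by the
  visual front bias, with no inertia.  The lattice integrator reproduces
  the closed form within 5% over a 4× range of Ia and α; the nonlinear
  transverse term `φ ∂φ/∂y` is retained but is O(φ) smaller.
* **Hydrodynamic model** (flow only): dipoles on a periodic 1-D lattice;
  for a perturbation of wavelength Kα the infinite dipole sum reduces to
  the kernel `cos(πm/K)/sin³(πm/K)` over one wavelength, acting on
  `sin(φ_j − 2φ_i)`.  Perturbations advect while being amplified, with
  speed ∝ If/α² (verified by factor-4 runs; the wavenumber-dependent
  constant is measured from a reference run, not assumed).

Both integrators use explicit Euler at a tenth of the stability bound and
guard the linearization (`|φ| < 0.3`).

## Synthetic fixtures

* `make_scripted_turn`: swimmers on a uniform disk; a turn of given angle
  (smooth cosine ramp over 4 time units) starts at the centre swimmer and
  propagates radially, onset at `t = √π r / c*` plus optional jitter.  The
  √π converts physical radius to the rank metric `sqrt(o/ρ)` (on a uniform
  disk `o(r) = ρπr²`), so the pipeline's fitted speed estimates c* itself;
  this keeps the fixture's ground truth in the same metric the analysis
  reports.
* `make_correlated_fluctuations`: a phase-spiral mode
  `δv = (cos kx, sin kx)` whose pair product is exactly `cos(kΔx)`,
  azimuthally averaging to `J0(kr)`; k solves `J0(k ξ*) = m(k)²` with
  `m = 2J1(kR)/(kR)` the disk mean, so the expected crossing after mean
  removal sits exactly at ξ*.  Noise rescales C without moving the
  crossing.
* `make_two_blob_split`: one rigid blob whose scripted halves acquire
  transverse velocity ±s/2 at t_split (s is not capped by the unit swimmer
  speed — the fixture scripts kinematics, not model dynamics).

What the fixtures do *not* emulate: feedback between the analysis
observables and the dynamics, density inhomogeneity, cluster shape
irregularity, or correlated (non-white) timing jitter.  Passing fixture
tests therefore validates the analysis operators, not the emergent
behaviour — that is what the reduced-scale simulation tests are for.

## Reduced problem sizes

The published study integrates up to 50,000 swimmers for T = 1000 on a
56-core machine.  This package's test and reproduction protocol uses
N = 100 (T = 200), N = 300 (T = 150, five (Ia, In) sets) and N = 1000
(T = 150), with the first 20% of each run discarded as transient.  At
these sizes the cohesive-regime observables (P ≥ 0.95 at N = 100, school
speed 1.20 and 1.08 at N = 100 and 1000) reproduce the published values.

## Known limitations

* The fragmentation regime proper (N ≳ 10⁴) is out of reach of the reduced
  protocol; split/merge statistics are exercised on scripted fixtures and
  small schools only.
* Measured information-transfer speeds in spontaneous turns of the reduced
  simulations are c ≈ 1–4 U, consistent with this package's own continuum
  prediction `c = γ α Ia/2` with α = measured VND ≈ 0.4, but well below
  the ~10–25 U reported at the same intensities in the original study,
  whose turn-event selection was manual and whose exact delay-extraction
  settings are not published.  The pairwise-delay pipeline recovers
  scripted speeds to < 1%, and an independent front/back slab
  cross-correlation of heading rate gives the same ~2 U on the same runs,
  so the discrepancy is not an artifact of the delay estimator.  The
  per-swimmer turn-time jitter induced by rotational noise (~0.5–1 time
  unit at In = 0.5) is an intrinsic floor on the resolvable delay spread
  at these group sizes.
* The ξ–L ensemble at reduced N spans a narrower range of L than the
  original multi-hour ensemble; the fitted slope is correspondingly less
  stable.
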