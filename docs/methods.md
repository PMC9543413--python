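# Methods

## The adaptive flat-histogram method

The package computes free energies W(ξ) over a set of reaction coordinates
ξ = (ξ1..ξd) by iterated adaptive biasing.  Equal sampling along ξ requires
W(ξ) + U(ξ) = const, i.e. the ideal bias is U = −W.  Since W is unknown, the
campaign starts unbiased (U1 = 0), estimates the probability density P1(ξ)
from MD sampling, Boltzmann-inverts it (W1 = −k_B T ln P1), and applies
U2 = −W1 to the next iteration.  Biased densities are unbiased through
P ∝ P′ exp(U/k_B T), and within each iteration the histograms of K parallel
replicas are combined by the weighted histogram analysis method (WHAM; with
one shared bias per iteration this reduces exactly to unbiasing the pooled
histogram).  Iterations stop when the max/min ratio of visited-bin counts —
the flatness ratio — drops below a threshold (default 3, configurable;
the shipped dimer presets use 2.5).

Two estimator details matter in practice and are defaults here:

- **Effective per-bin bias.**  The force applied to the dynamics comes from
  a spline of U, which varies within a bin.  Each bin is therefore unbiased
  with the *mean applied* (interpolated) bias of the samples that fell in
  it, not the bin-center value; unvisited bins fall back to the grid value.
- **Final estimate by cross-iteration WHAM.**  The reported W is the WHAM
  combination of every iteration's pooled histogram under its own (known)
  bias, which uses all sampling.  `final_wham=False` reports the literal
  negative of the last bias instead.

Empty-bin policy: never-visited bins are assigned W = max(visited W) + k_B T
(−ln 0 being undefined); the flatness ratio is computed over visited bins
only.  Bias updates are undamped (U_{n+1} = −W_n); a mixing factor
(`bias_mix`) is available as a robustness escape hatch for noisy budgets.

## Reaction-coordinate graphs

RCs are declared as directed colored graphs whose leaves are atoms and
whose internal nodes are centers of mass, vectors, cross-product normals,
distances, angles and dihedrals.  Values flow bottom-up; biasing forces flow
top-down by the chain rule, each edge contributing its local partial
derivative, so the force on an atom is the sum over graph paths of products
of edge derivatives (the derivative-matrix formulation exposed by
`derivative_matrix` / `path_product_jacobian` computes the same Jacobian
from explicit path products and is tested against the reverse-mode result
and against central finite differences to 1e−6 relative).

Numerical choices:

- Angles are degrees externally, radians internally; all Jacobians are in
  external units.
- The angle gradient −(b̂2 − cosθ b̂1)/(|b1| sinθ) is the exact derivative of
  θ = arccos(b̂1·b̂2); it is singular at θ = 0/180°, where (and whenever a
  vector norm falls below 1e−8 Å) the step's derivative contribution is
  zeroed and a warning logged rather than aborting a running replica.
- Dihedrals support two conventions.  `arccos` follows the printed
  definition φ = arccos(m̂·n̂) ∈ [0°, 180°]; its gradient inherits the
  1/sinφ singularity at the fold.  `signed` extends to [0°, 360°) with the
  sign of (m⃗×n⃗)·r⃗ and computes gradients with the standard torsion
  formulas, which are regular at 0/180°.  The 4D water-dimer preset uses
  the signed convention on a periodic φ grid, because the system spends
  most of its time near φ = 180° — exactly where the arccos gradient
  diverges.
- Degenerate geometries therefore silently lose their biasing force for
  the affected step; campaigns on angular grids rely on this to survive
  transient near-linear configurations.

## Bias grids and splines

Grids are per-dimension (min, max, n_bins ≥ 4, periodic flag); periodic is
meant for angular coordinates.  ∂U/∂ξ at arbitrary ξ comes from a
tensor-product cubic B-spline interpolant of the bin-center values (natural
boundaries on bounded dimensions — `b_spline` mode uses not-a-knot —
periodic closure on periodic ones; node values are reproduced to machine
precision).  Outside the grid the spline is not extrapolated: a harmonic
wall (default 10 kcal/mol per squared RC unit) pushes the coordinate back,
and out-of-grid samples are not binned.  The walls stand one bin-width
*outside* the grid edge: a wall flush with the edge turns the outermost
bins into reflecting pockets that measurably pile up samples (we observed
2–3× overcounts in the last radial bin) and contaminate edge free energies.

During campaigns the applied spline gradient is clamped per dimension to
the largest adjacent-node slope of the current bias: cubic-spline ringing
between a deep never-visited bin and its visited neighbour can spike far
beyond any node-to-node difference and eject a replica.  Should a replica
still blow up (non-finite coordinates), it is marked failed, parked, and
excluded from the WHAM combination with a logged warning; the iteration
continues with the surviving replicas.

## The toy MD engine

A self-contained engine exists so the method can be exercised end-to-end
without external software.  Units are AKMA-style (Å, amu, kcal/mol; the
consistent time unit is 48.888 fs; the API uses fs).

**Water model.**  Flexible three-site water: standard TIP3P charges and
Lennard-Jones parameters with harmonic bonds (k = 450 kcal/mol/Å²,
r0 = 0.9572 Å) and angle (k = 55 kcal/mol/rad², θ0 = 104.52°) — the
standard flexible constants, editable on `WaterForceField`.  Intermolecular
LJ + Coulomb over all 9 pairs; no cutoff is needed for a dimer.  Boundary
options: a 12 Å cubic periodic box with minimum-image convention (the
classical-protocol default), a soft spherical cavity (harmonic beyond a
radius about the origin), or open.  In the box, the RC wall at r ≈ 6 Å
keeps the raw O–O distance below half the box edge, so the unwrapped RC is
consistent with minimum-image forces.

**Integrators and thermostats.**  Velocity-Verlet; the biasing force enters
through an `extra_force` hook evaluated with every force evaluation — the
insertion point an adaptive-bias library occupies inside an MD package's
step update.  Thermostats: Langevin via the BAOAB splitting (configurational
error stays ~1% even at ω·Δt ≈ 0.6, which the flexible O–H stretch reaches
at 1 fs), single-chain Nose-Hoover (coupling time τ, sub-stepped), plain
velocity rescaling, or none (NVE; symplectic drift < 1e−3 over 2·10⁴ steps
is enforced in tests).

**Thermostat choice for the dimer campaigns — a measured trade-off.**  On a
6-atom system a *single* Nose-Hoover chain is not ergodic: cross-checking
against Metropolis Monte Carlo of the identical model (exact canonical
sampling, no integrator error) showed that NH campaigns recover the radial
well depth near the classical reference protocol's value, while Langevin
(BAOAB) campaigns agree with the Monte-Carlo truth (≈ −2.4 kcal/mol for the
flexible model in the 12 Å box, measured against the r > 5 Å plateau) but
NH visibly distorts the *angular* free energies: the (θ1, φ) minima shift
from the Monte-Carlo positions (θ1 ≈ 52°/128°) toward 70–90°.  The shipped
presets therefore run the 1D/2D radial reproduction campaigns under the
classical reference protocol (Nose-Hoover, τ = 0.1 ps, 10 sub-steps,
velocity-Verlet, 1 fs, 15 iterations for 1D) — like-for-like with the
protocol they reproduce — and the 4D campaign under Langevin/BAOAB
(friction 0.01 fs⁻¹), where angular fidelity is the point.  Both defaults
are overridable per campaign.

**Analytic systems.**  Single particles whose Cartesian coordinates are the
RCs, with closed-form potentials (double well a(x²−1)², harmonic), make
convergence testable against exact answers: the shipped double-well
campaign recovers W to RMSD < 0.1 kcal/mol at the default budget, and
imposing U = −W exactly yields visit counts that pass a χ² uniformity test
on decorrelated samples.

## Campaign mechanics

Replicas are logically independent: each (iteration, replica) pair derives
its own RNG streams (state initialisation and thermostat noise separately)
from the campaign master seed, and the combination step is a pure function
of the count arrays.  For speed the engine integrates all replicas together
over a leading batch axis; this is bit-identical to serial execution
because every stochastic draw comes from the owning replica's generator.
Replica coordinates continue from each iteration's end states by default
(`reinitialize=True` redraws).  Campaigns checkpoint per iteration and
resume to an identical bias sequence.  A divergence guard aborts when the
flatness ratio worsens by more than 2× on three successive iterations.

## Desk-scale study conditions and what they can show

The shipped dimer presets run 16 replicas × 20 ps per iteration (1 fs
steps) — 1/20 of the published-scale classical protocol (128 × 50 ps),
which is provided as numbers to pass in, not as the default.  Grids:
1D r ∈ [2.2, 6.0] Å × 64 bins; 2D adds the dipole angle [0°, 180°] × 36;
4D coarse 16 × 12 × 12 × 15 over (r, θ1, θ2, φ) — θ bins 15° wide so the
hydrogen-bond landmarks (≈52°, ≈128°) and φ = 180° sit on bin centers;
the full-scale 32 × 18 × 18 × 18 grid is available.

At this budget the *location* of the radial minimum (2.82 Å bin,
reference 2.9 Å), the well depth, the φ = 180° torsional minimum and the
θ1 ≈ 52°/128° angular minima are all stable across seeds.  Two quantities
are budget-limited and stay so by honest measurement:

- The converged flatness ratio.  The grid's r < 2.4 Å bins sit ~25–30
  kcal/mol above the well; flattening them demands the bias be learned to
  ~50 k_B T accuracy there.  With ~3·10⁵ samples per iteration and RC
  correlation times of ~0.5–1 ps, the effective per-bin sample counts put
  a statistical floor of roughly 8–15 on the final-iteration max/min
  ratio — dominated entirely by those two frontier bins (the remaining 62
  bins are flat to ~1.5:1).  The reference ratio (2.5:1) needs the full
  20× sampling.
- The well depth under canonical sampling is ≈ −2.4 kcal/mol for this
  *flexible* model (Monte-Carlo cross-check; a near-rigid variant gives
  ≈ −2.2), deeper than the rigid-model reference −1.88; the NH protocol
  campaigns land at ≈ −2.1–−2.3.

The synthetic systems emulate barrier crossing, multi-well structure and
orientational order of a hydrogen-bonded dimer; they do not emulate bulk
solvation, long-range electrostatics beyond minimum image, bond
constraints, or any electronic-structure effect, so passing tests
demonstrate the correctness of the machinery (graphs, forces, WHAM,
updates, analyses) — not transferability of the toy force field.

## Analyses

- `find_minima`: local minima over visited bins with the full 3^d−1
  neighborhood, periodic wrap where declared; ties broken by lexicographic
  bin index.
- `boltzmann_project`: W_proj = −k_B T ln Σ exp(−W/k_B T) over dropped
  dimensions, min-shifted; exact order-independence is a tested invariant.
- `dipole_autocorrelation`: Q(t) = ⟨D(0)·D(t)⟩ with D = Σqᵢxᵢ over both
  molecules, FFT-accelerated over time origins; raw (unnormalized) by
  default with a normalized option.
- `fit_exponential`: unweighted least squares of e^{−(t+x)/τ} (single) or
  e^{−(t+x1)/τ1} + e^{−(t+x2)/τ2} (double, relabeled so τ1 < τ2), fitted
  from lag 0 to the first lag below 0.05·Q(0).  The printed forms carry
  the amplitude inside the exponent as a time offset; the fit runs on
  Q/Q(0) and folds the scale back into the offsets (x ← x − τ ln c), so
  reported parameters describe the raw decay.  Standard errors come from
  the covariance of the fit.
- `classify_configuration`: nearest-template assignment of (r, θ1, θ2, φ)
  frames to Chain/Cyclic/Bifurcated hydrogen-bond geometries (templates
  (65.5°, 118.3°), (81.9°, 84.5°), (172.4°, 7.9°), symmetric under
  molecule exchange), with ±20° angular windows; r > 5 Å is unbound,
  anything else `other`.

## Known limitations

- Single-chain Nose-Hoover on few-atom systems is non-ergodic (see above);
  NH chains are not implemented.
- Rigid water (SHAKE/RATTLE) is out of scope; the flexible model's well is
  measurably deeper than rigid TIP3P's.
- WHAM assumes per-bin biases; the per-sample (binless) estimator (MBAR)
  is not implemented — the effective-bias refinement recovers most of the
  difference at these bin widths.
- No Ewald summation; minimum-image Coulomb only, adequate for a dimer.
- Error bars on W (bootstrap over replicas) are not provided.
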