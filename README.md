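# fearcf

Adaptive flat-histogram free energies over graph-defined reaction
coordinates, with a self-contained toy MD engine (flexible three-site water
dimer and analytic test potentials).

## The problem

Resolving a molecular mechanism usually means computing a free-energy
surface W(ξ) over several geometrically coupled reaction coordinates (RCs)
— distances, angles between vectors, dihedrals between plane normals —
rather than a single distance.  Two difficulties dominate: driving the
system to visit high-energy regions at all, and mapping a potential defined
on RCs back onto forces on atoms when each RC is a deep composition of
geometric primitives.

This package addresses both.  Sampling uses an iterated adaptive bias: at
convergence the bias cancels the free energy,

    W(ξ) + U(ξ) = 0,

so each iteration estimates P(ξ) from K parallel biased replicas (combined
by WHAM), inverts it (W = −k_B T ln P), and applies U ← −W to the next
iteration, until the RC histogram is flat (max/min visited-bin count ratio
below threshold).  Forces come from the chain rule,

    ∇U(ξ) = (∂U/∂ξ)(∂ξ/∂x⃗),

with ∂U/∂ξ from a tensor-product cubic spline of the bias grid and ∂ξ/∂x⃗
evaluated by walking the RC *graph*: RCs are declared as directed colored
graphs whose leaves are atoms and whose internal nodes are centers of mass,
vectors, cross-product normals, distances, angles and dihedrals; the atomic
biasing force is the sum over graph paths of products of per-edge partial
derivatives.

The worked system is the water dimer: a 1D (O–O distance), 2D (COM distance
+ dipole angle) and 4D (r, θ1, θ2, φ) description of hydrogen-bond
geometry, plus the analyses used to interpret such surfaces — Boltzmann
projections, minima location, dipole–dipole autocorrelation with
single/double exponential relaxation fits, trajectory projection onto the
FEV, and Chain/Cyclic/Bifurcated hydrogen-bond classification.

## Worked example

Recover the free energy of a particle on the double well
W(x) = a(x²−1)², a = 2 kcal/mol, at 300 K (k_B T ≈ 0.6 kcal/mol — a 3.4
k_B T barrier):

```python
import numpy as np
from fearcf import double_well_campaign

res = double_well_campaign(a=2.0, master_seed=7, K=8,
                           n_steps=20_000, n_iterations=6)
x = res.fev.spec.dims[0].centers
Wtrue = 2.0 * (x**2 - 1)**2
Wtrue -= Wtrue.min()
sel = Wtrue < 5
West = res.fev.W - res.fev.W[sel].mean() + Wtrue[sel].mean()
print("flatness history:",
      " ".join("%.2f" % f for f in res.flatness_history))
print("RMSD vs analytic W: %.3f kcal/mol"
      % np.sqrt(np.mean((West[sel] - Wtrue[sel])**2)))
```

prints

```
flatness history: 203.37 311.24 8.20 3.57 4.00 4.12
RMSD vs analytic W: 0.069 kcal/mol
```

The first iteration is unbiased and almost never leaves the starting well
(ratio 203:1); by the fourth the landscape is sampled nearly flat (3.6:1),
and the recovered W matches the analytic double well to 0.07 kcal/mol —
the barrier estimate at x = 0 comes out at 2.13 kcal/mol against the true
2.00.

The classical water-dimer campaigns work the same way:

```python
from fearcf import water_dimer_campaign
from fearcf.analysis import boltzmann_project

res = water_dimer_campaign(1, master_seed=1)   # 16 replicas x 20 ps x 15 iter
r = res.fev.spec.dims[0].centers
print("minimum at r = %.2f Å" % r[res.fev.W.argmin()])

res4 = water_dimer_campaign(4, master_seed=1)  # (r, θ1, θ2, φ), coarse grid
proj = boltzmann_project(res4.fev, ("theta1", "phi"))
```

The 1D minimum lands in the bin at 2.82 Å (reference: 2.9 Å) with a well
of roughly −2.2 kcal/mol against the r > 5 Å plateau, and the projected 4D
surface puts the hydrogen-bond minima at θ1 ≈ 52°/128°, φ = 180°.

There is also a CLI for config-driven runs and post-processing:

```sh
fearcf run campaign.yaml
fearcf analyze minima out/fev.txt
fearcf analyze project out/fev.txt --keep theta1,phi --out proj.txt
fearcf fev convert out/fev.txt out/fev.h5
```

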