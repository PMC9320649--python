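# cellforce

Membrane-force estimation from cell-migration movies by optimal control of a
phase-field model.

Migrating cells move by generating forces at their membrane: actin
polymerisation pushes the leading edge outward (protrusion) while
myosin-driven contraction pulls the rear inward (retraction). These forces
are hard to measure directly. `cellforce` infers them from ordinary
time-lapse microscopy: it fits a mechanical model of the moving cell
boundary to the segmented frames of a movie and reads the forcing required
for the fit as an estimate of the spatio-temporal membrane force.

## Model

The cell is a phase field φ(x̄, t̄) on the unit square: φ ≈ +1 inside, −1
outside, with the membrane at the zero level set. Its dynamics are the
forced, volume-constrained Allen–Cahn equation (a diffuse-interface
approximation of forced mean-curvature flow), in dimensionless form

    ε̄τ̄ ∂φ/∂t̄ = δ̄ε̄ Δφ − (δ̄/ε̄) G′(φ) + η̄ + λ,     ∇φ·ν = 0 on ∂Ω̄,

with G(φ) = ¼(1−φ²)² the double-well potential, ε̄ the interfacial width,
τ̄ the friction against the substrate, δ̄ the membrane surface tension, η̄
the unknown membrane force (positive = protrusive) and λ(t̄) a spatially
constant multiplier tracking the observed cell area. Physical scales enter
through a characteristic length L (domain side), time T (movie duration)
and force F: τ̄ = τL²/(FT), δ̄ = δ/F, η = η̄·F/L (pN/µm).

For each pair of consecutive frames the force is found by minimising

    J(η̄; φ) = (θ/2)∫∫ η̄² + ½ Σᵢ ∫ (φ(t̄ᵢ) − φ_obs,i)²

subject to the dynamics, via projected gradient descent with the exact
discrete adjoint; the control is supported on a band around the membrane
(the actin cortex). Pairs are chained: the fitted end state of one pair
initialises the next. Post-processing yields membrane length, centroid,
per-pair protrusion/retraction totals in pN, and a diffuse-interface Euler
number that counts cells and flags division or fusion events.

## Worked example

Recover a known polarised force from a synthetic observation generated by
the forward model itself (the standard "inverse crime" verification):

```python
import numpy as np
from cellforce import (GridSpec, DimensionlessParams, PhysicalParams,
                       optimize_pair, force_summary, centroid)
from cellforce.synthetic_data import make_translating_disk_pair

grid = GridSpec(n=64)
params = DimensionlessParams(eps_bar=0.06, tau_bar=2.0, delta_bar=1.0,
                             theta=1e-4, RTS=10, substeps=2)

# a cell pushed rightward by a dipolar membrane force, observed one frame later
phi0, targets, eta_true = make_translating_disk_pair(grid, params,
                                                     amplitude=10.0, duration=0.1)
fit = optimize_pair(phi0, targets.observations[0], params, grid, pair_duration=0.1)

phys = PhysicalParams(delta=10.0, tau=2.62, eps=1.0, L=100.0,
                      T_total=600.0, TI=60.0, F=10.0)
row = force_summary(fit, phys, frame_pair="1-2", grid=grid)

print(f"misfit: {fit.objective_history[0]:.3f} -> {fit.objective.misfit_term:.2e}")
print(f"fitted centroid: {centroid(fit.trajectory.states[-1], grid)}")
print(f"target centroid: {centroid(targets.observations[0], grid)}")
print(f"avg membrane length: {row.avg_membrane_length_um:.1f} um")
print(f"protrusion: {row.total_protrusion_pN:.0f} pN over {row.protrusion_pct:.1f}% of the membrane")
print(f"retraction: {row.total_retraction_pN:.0f} pN over {row.retraction_pct:.1f}%")
```

prints

```
misfit: 0.316 -> 1.66e-04
fitted centroid: (0.6584249243975581, 0.5000297329729291)
target centroid: (0.6610563555080033, 0.49999999999999994)
avg membrane length: 157.2 um
protrusion: 318 pN over 71.1% of the membrane
retraction: 108 pN over 28.9%
```

The optimiser cuts the data misfit by a factor ~1900 and places the fitted
cell within a sixth of a grid cell of the target. The force table reads as
one row of the per-frame-pair summary: with these scales the reconstructed
motion needs ~318 pN of protrusive force spread over 71% of a 157 µm
membrane, balanced by ~108 pN of retraction at the rear.

## Command line

```sh
cellforce generate -o movie/ --kind division --frames 9   # synthetic movie + ground truth
cellforce segment movie/ -o masks/                        # Otsu + edge masks
cellforce track movie/ --config cfg.yaml -o out/          # full pipeline
cellforce count out/pair_1-2.tif -o euler.csv             # cell-count trace
```

`track` writes `forces.csv` (columns `frame_pair, avg_membrane_length_um,
total_protrusion_pN, protrusion_pct, total_retraction_pN, retraction_pct`),
`euler.csv`, per-pair state/control TIFF stacks and a JSON manifest. Sample
dataset configurations are in `configs/`.

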