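# Methods

## Model

A migrating cell is represented by a phase field φ on the unit square
Ω̄ = [0,1]², with φ ≈ +1 in the cell bulk, −1 in the extracellular medium
and the membrane at the zero level set, smeared over a transition layer of
width ~ε̄. The dynamics are the forced, volume-constrained Allen–Cahn
equation

    ε̄τ̄ ∂φ/∂t̄ = δ̄ε̄ Δφ − (δ̄/ε̄) G′(φ) + η̄ + λ(t̄),   ∇φ·ν = 0 on ∂Ω̄,

with G(φ) = ¼(1−φ²)². This is the diffuse-interface form of a force
balance on the membrane: surface tension δ̄ drives curvature-based
relaxation, τ̄ is friction against the substrate, η̄ is the active membrane
force density (protrusive where positive, retractive where negative), and
λ is a spatially constant multiplier that tracks a prescribed cell "mass"
(mean of φ, i.e. cell area). The mass target interpolates linearly between
the segmented areas of consecutive frames — it is a tracking constraint,
not conservation, because real cells change area from frame to frame.

Physical parameters (surface tension δ in pN, friction τ in pN·s/µm²,
membrane thickness ε in µm) are mapped to the dimensionless set by the
characteristic length L (domain side, µm), time T (tracked duration, s)
and force F (pN):

    τ̄ = τL²/(FT),   δ̄ = δ/F,   ε̄ = ε/L,   η = η̄·F/L  [pN/µm].

Defaults take δ = F = 10 pN (δ̄ = 1), the top of the commonly reported
1–10 pN surface-tension range, and τ ≈ 2.62 pN·s/µm². The numerical
interfacial width ε̄ is normally set per dataset (it must stay resolved on
the grid) rather than from the physical ratio ε/L; both routes are
supported and the per-dataset value wins when supplied. The model works in
two dimensions, treating the cell as a slab of constant 0.1 µm height.

## Inverse problem

Given segmented observations φ_obs,i at times t̄ᵢ, the membrane force
minimises

    J(η̄; φ) = (θ/2)∫₀¹∫Ω̄ η̄² dx̄ dt̄ + ½ Σᵢ ∫Ω̄ (φ(t̄ᵢ) − φ_obs,i)² dx̄,

subject to the forward dynamics. θ > 0 (default 1e-3) regularises the
otherwise ill-posed control problem; larger θ shrinks the recovered force.
Frames are fitted pair by pair — RTS reconstructed time steps are inserted
between consecutive frames (10 for the fast datasets, 5 for the slow
multicell one) and the fitted end state of each pair initialises the next —
rather than jointly over all frames, which keeps cost linear in movie
length.

## Discretisation and the adjoint

* Uniform vertex-centred grid (n×n, spacing h = 1/(n−1)), five-point
  Laplacian with ghost-node reflection for the homogeneous Neumann
  condition.
* Semi-implicit IMEX stepping: the Laplacian is implicit, G′ and η̄ are
  explicit. The implicit operator I − a·Δ is diagonal in the type-I cosine
  (DCT-I) basis, which diagonalises the reflected-ghost stencil exactly, so
  every implicit solve (and its transpose) is a direct spectral solve with
  no factorisation or iteration error.
* The explicit potential term bounds the step: dt ≤ ε̄²τ̄/δ̄ (G″ ≤ 2 in the
  bulk). Each reconstructed step is subdivided into `substeps` solver steps;
  the pipeline picks substeps automatically with a safety factor of 0.5.
  The splitting is first-order in time: relative interface-position errors
  scale like dt·δ̄/(ε̄²τ̄), which is why benchmark runs use dt well below
  the stability bound.
* The volume constraint is a post-step projection: add the constant that
  sets mean(φ) to the target. Because the Neumann Laplacian annihilates
  constants this is the exact discrete Lagrange multiplier, with
  λⁿ = ε̄τ̄·shift/dt, and the mass is matched to machine precision.
* The gradient of J is computed discretize-then-optimize: one backward
  sweep of the exact transpose of the discrete forward step (transposed
  spectral solve, G″ frozen at the stored states, transposed mean
  projection, data residuals injected at observation steps). The adjoint
  gradient matches central finite differences of the discrete objective to
  ~1e-7 relative error, which is the finite-difference truncation floor.
* Minimisation is projected gradient descent from η̄ = 0 with Armijo
  backtracking (c = 1e-4, shrink 0.5, growing trial step) on the
  L²-preconditioned gradient. The control is piecewise constant per
  reconstructed step, nodal in space, and projected onto the interfacial
  band {|φ| < 0.95} of the current trajectory, recomputed each outer
  iteration — forces act only in the cortex near the membrane. Accepted
  steps make J non-increasing by construction; the loop stops at max_iter
  (200) or when the relative decrease of J falls below tol (1e-6).

Quadrature for all space integrals is the trapezoidal rule on grid nodes
(equivalently, the midpoint rule on cells with corner-averaged values);
"mass" uses the plain node mean, matching the projection.

## Segmentation and phase-field construction

Frames are segmented by a combination of Otsu thresholding and edge
detection: Gaussian presmooth (σ = 1.5 px) → Otsu threshold at the
half-contrast level (the boundary authority: its contour is sub-pixel
accurate on two-level images) → union with the hole-filled closure of the
Sobel gradient-magnitude edge map, eroded 4 px so it only contributes
regions whose interior the intensity threshold missed → hole filling →
removal of components under 50 px. The edge threshold is the 90th
percentile of the gradient, floored at 10% of the peak gradient (a bare
percentile marks wide bands of numerically-zero gradients in clean images).
A raw union with the edge band was measured to dilate every mask by 2–3 px
(IoU ≤ 0.93 even on noiseless disks), which is why the edge term is eroded
and the Otsu boundary is authoritative.

Masks become phase fields via the signed Euclidean distance (positive
inside), rescaled by pixel_size/L, bilinearly resampled onto the solver
grid (image rows are flipped once so ȳ increases upward) and mapped
through the equilibrium profile φ = tanh(d/(√2 ε̄)). Frame 1 provides the
initial condition; frames 2…N are targets at t̄ᵢ = i·TI/T.

## Geometric outputs

* Membrane contour: marching squares at level 0 on bilinear interpolation
  (saddle cells disambiguated by the corner-average rule); length in µm is
  the dimensionless arclength × L.
* Centroid: mean position weighted by (1+φ)/2.
* Force summary per frame pair: for each reconstructed step, the control is
  sampled at contour-segment midpoints; a segment of dimensionless length
  ℓ with control η̄ contributes η̄·F·ℓ pN (η̄·F/L pN/µm × ℓ·L µm).
  Positive parts sum to the protrusion total, negative to retraction;
  percentages are arclength fractions averaged uniformly over steps, so
  they always partition the membrane. λ is a global constant volume force
  and is excluded from the totals.
* Cell counting: the Euler characteristic of {φ > 0} from the band
  integral

      N = 1/(4πc) ∫_{|φ|<c} [ −Δφ + ∇|∇φ|²·∇φ / (2|∇φ|²) ] dx̄,

  whose integrand is κ|∇φ| (Gauss–Bonnet along each level line). Every
  level s ∈ (−c, c) contributes 2πχ and the band has level measure 2c,
  hence the 1/(4πc) normalisation so one cell gives N ≈ 1. Default
  c = 0.8 keeps the band inside the tanh transition at all dataset ε̄
  values. Derivatives are central differences; nodes with |∇φ|² below
  1e-12 × max are excluded. Division/fusion events are steps where the
  rounded trace changes. The formula assumes the bulk reaches beyond ±c:
  features thinner than the full tanh transition (e.g. a ring narrower
  than ~5ε̄) never leave the band and corrupt the integral.

## Synthetic data

The generators emulate the study conditions end to end with known ground
truth: bright cells (foreground 0.8) on a dark background (0.2) with
Gaussian noise σ = 0.05 and 8-bit quantisation — two intensity modes that
Otsu separates robustly; translating disks (area-constant masks, exact
per-frame displacement); pinch-off movies where one blob splits into two
at a recorded frame (the first frame whose rendered mask is disconnected —
the observable event, since the analytic tangency can fall between frames);
and inverse-crime target sequences produced by the forward model under a
known dipolar force (protrusion at the front, retraction at the rear — the
canonical polarised-migration pattern). All generators are pure functions
of their parameters and one seed. For inverse-crime verification the
regularisation is set to θ = 1e-4 so the data term dominates and recovery
quality reflects the optimiser, the standard setting for verifying an
inverse solver on its own forward data.

What the synthetic movies do not emulate: uneven illumination, texture
inside cells, point-spread blur, shot noise, cell–cell contacts and
overlap. Passing the suite therefore demonstrates correctness of the
numerics and of the segmentation on clean two-level imagery, not
segmentation robustness on difficult microscopy.

## Verification benchmarks and known limitations

`cellforce.verification` packages the independent oracles: the
finite-difference gradient check; mass-projection exactness; the
components-minus-holes pixel-labelling oracle for the Euler number (max
deviation 0.026 over 20 random blob fields at 256²); the closed-form force
line integral on a circle (0.001% error); division detection; inverse-crime
recovery (misfit ÷1900, centroid within 0.17 cells at 64², RTS 10); and
the shrinking-circle benchmark against the sharp-interface law
R(t̄)² = R0² − 2(δ̄/τ̄)t̄.

The shrinking-circle comparison has a genuine validity boundary worth
stating precisely. The Allen–Cahn equation approximates mean-curvature
flow only up to O((ε̄/R)²) corrections. An ε̄-exact 1-D radial reference
(implicit tridiagonal solver, dr = 1e-4, dt = 1e-6, interface resolved by
~280 points) deviates from the sharp law by 0.5% at R ≈ 8ε̄, 1.9% at
R ≈ 5.4ε̄, 3.7% at R ≈ 4.3ε̄ and 13% at R ≈ 3ε̄ — the diffuse circle
shrinks faster than the sharp one as R approaches the interface width,
regardless of discretisation quality. The 2-D solver (256², ε̄ = 0.02,
dt = 5e-6) matches the law to 0.06–0.23% at checkpoints with R ≥ 8ε̄ and
to ~3% at its final checkpoint R ≈ 3.25ε̄, consistent with the reference.
A 2%-agreement test is therefore meaningful only while R ≳ 5.5ε̄; the
benchmark that runs to R ≈ 3.25ε̄ honestly reports the larger deviation.

Other limitations: uniform serial grid (no adaptivity, no parallelism, no
3-D); first-order time splitting; no simultaneous all-frame optimisation;
segmentation has no illumination correction or learned component; absolute
force magnitudes scale with the (data-set dependent) choice of θ, so
between-condition comparisons should hold θ fixed.
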