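# Methods

`melon4d` simulates the interphase nucleus as a set of immiscible liquid
phases on a fixed three-dimensional grid and then measures the geometry
of the heterochromatin compartments that emerge.  This note records the
model, the numerical scheme, the parameter choices, and what the
reduced-scale test problems do and do not demonstrate.

## Model

### Order parameters

The nucleus interior is partitioned by smooth indicator fields
("phase fields") on Ω = [0,Lx]×[0,Ly]×[0,Lz]:

* φ_i(r,t), i = 1…N — one field per chromosomal territory (CT), ≈1
  inside the territory, ≈0 outside;
* ψ1(r,t), ψ2(r,t) — facultative (fHC) and constitutive (cHC)
  heterochromatin; euchromatin is the implicit remainder
  ψ3 = 1 − ψ1 − ψ2 and is never stored;
* η(r) — the static nucleus indicator, 0 inside an oblate ellipsoid
  with semiaxes (a, b, c), 1 outside, with a tanh envelope profile
  η = ½[1 + tanh((r_ell − 1)/(2√2 ε_η))], r_ell the elliptic radius.
  The η = ½ isocontour is the nuclear envelope.  η never evolves.

### Free energy

All fields relax the functional F = F_B + F_I (units of kBT, lengths
in μm).  F_B is a multi-well Ginzburg-Landau energy with volume
constraints:

    F_B = ∫ [ Σ_i (ε_φ²/2)|∇φ_i|² + Σ_j (ε_ψj²/2)|∇ψ_j|² + f(φ,ψ) ] dΩ
        + a1 (V_N − Σ_i V_i)² + a2 Σ_i (V_i − V̄_i)²
        + a3 Σ_i (v_i − v̄_i)² + a4 Σ_i (w_i − w̄_i)²,

with the quartic wells f = Σ_i φ_i²(1−φ_i)²/4 + Σ_j ψ_j²(1−ψ_j)²/4 and
compartment volumes measured through the quintic interpolant
h(x) = x³(10 − 15x + 6x²):

    V_i = ∫ h(φ_i),   v_i = ∫ h(ψ1)h(φ_i),   w_i = ∫ h(ψ2)h(φ_i).

h(0)=0, h(1)=1, h'(0)=h'(1)=0, so volume measurement does not displace
the bulk minima.  F_I carries the couplings:

    F_I = β0 Σ_i ∫ h(η)[1−h(η)] h(φ_i)               envelope confinement
        + β0ψ ∫ h(η)[1−h(η)] [h(ψ1) + h(ψ2)]         envelope confinement (HC)
        + β_φ Σ_{i≠j} ∫ h(φ_i)h(φ_j)                 CT-CT exclusion
        + β_ψ1ψ2 ∫ h(ψ1)h(ψ2)                        fHC-cHC exclusion
        + ∫ [1 − Σ_i h(φ_i)][β_ψ1 h(ψ1) + β_ψ2 h(ψ2)]  HC outside CTs
        + ∫ ∇h(η)·[γ1 ∇h(ψ1) + γ2 ∇h(ψ2)]            lamina adhesion.

The CT-CT sum runs over ordered pairs (each unordered pair twice).
γ1 = γ2 = 0 means no lamina adhesion; the adhesion integral is the only
component that may be negative.

The β0ψ term (default β0ψ = β0) extends the envelope confinement to the
heterochromatin fields.  The nuclear envelope is impermeable to
chromatin, but the remaining couplings only penalize ψ outside
*territories*, with nothing specific to the envelope: a ψ blob pushed
fully outside the nucleus during a violent transient sits at a local
minimum (h' and the well derivative both vanish at ψ = 1) and never
returns.  The confinement shell is the natural barrier; setting
β0ψ = 0 recovers the bare functional.

### Dynamics

Non-conserved (Allen-Cahn) gradient flow, with white noise on the
heterochromatin fields only:

    ∂φ_i/∂t = −L_φ δF/δφ_i,
    ∂ψ_j/∂t = −L_ψj δF/δψ_j + ζ_j,   ⟨ζ_j ζ_j⟩ = A_j δ(r−r′)δ(t−t′).

Equations are nondimensionalized by a length l = 1 μm and a time
τ = 0.005 s; mobilities are dimensionless and equal (L = 1) by default,
and the interface coefficients follow from the diffusion bookkeeping
D = L ε²: with D_φ = 20 μm²/s and D_ψ = 12 μm²/s this gives
ε_φ² = 0.10 and ε_ψ² = 0.06 (interface widths 2√2 ε ≈ 0.89 and
0.69 μm).  ε may also be set directly in the config, bypassing the
relation.

## Numerics

**Discretization.** Uniform cell-centered Cartesian grid; midpoint
(voxel-sum) quadrature for every integral; face differences for
gradient energies and the matching compact 7-point Laplacian, which is
their exact adjoint.  Volumes therefore carry O(spacing) interface
error, and test tolerances scale accordingly.  Boundary conditions are
zero-flux (mirror) by default, periodic optionally; the η confinement
keeps all dynamics away from the domain faces, which is what makes the
choice immaterial in practice.

**Functional derivatives.** Derived analytically from the *discrete*
energy, so they equal the gradient of `free_energy` to machine
precision.  The core correctness test perturbs single voxels of random
small-grid states and compares against central finite differences for
every coupling switched on in isolation (relative error ≤ 1e−5).

**Saturated occupancy.** Inside the functional, h is evaluated
saturated: h(x<0) = 0, h(x>1) = 1, h' = 0 outside [0,1].  Allen-Cahn
fields transiently leave [0,1] (nothing hard-bounds them), and the raw
quintic's growth there (h' ~ 30x⁴) converts small undershoots into
runaway coupling forces.  Saturation is the physical occupancy reading
and is C¹ (h'(0)=h'(1)=0), so energy smoothness and the derivative
oracle are unaffected.  The quartic wells themselves stay unsaturated —
they provide the restoring force toward [0,1].  The public
`interpolation_h` remains the raw polynomial.

**Time stepping.**  Two schemes:

* `semi-implicit-spectral` (default): the stiff −ε²∇² term is treated
  implicitly in transform space — DCT-II for zero-flux boundaries (it
  diagonalizes exactly the compact mirror-BC Laplacian), FFT for
  periodic — everything else explicitly.  Stable at the reference
  dt = 0.04 where explicit Euler is not.
* `explicit-euler`: retained as a cross-check; enforces
  dt ≤ C h²/(L ε²) with C = 1/6 (3D diffusive bound) at run start.

Each nominal step is accepted adaptively: an attempt producing
non-finite values, |field| > 3, or (noise off) a total-energy increase
beyond 1e−11 relative is retried as 2^k substeps of dt/2^k, escalating
k (≤12) and relaxing it after success.  Freshly seeded states with
strong CT-CT exclusion are far stiffer than anything later in a run;
the halving typically engages for a few dozen initial steps and then
stays off.  With noise off this makes the energy non-increasing at
every accepted step — the discrete descent property of the gradient
flow, which the test suite asserts on all presets.

**Noise.**  White noise is discretized as independent Gaussian
increments of standard deviation sqrt(A·dt/ΔV) per voxel, applied after
the deterministic update, ψ fields only; the suite verifies this
variance scaling.  Note the ΔV^(−1/2) growth: at the reference
amplitude A = 5 and any grid this package can hold, voxel-level white
noise dwarfs the fields themselves, so presets default to
`noise_on: false` and treat A as the stored amplitude of the physical
model rather than a usable per-voxel setting.  Runs that want thermal
agitation should choose A ≪ 1 at reduced meshes.  Noise is never
projected to preserve ψ1 + ψ2 ≤ 1; the soft exclusion penalty handles
it.

## Geometry and initial conditions

The reference nucleus is the oblate ellipsoid a = 2.5, b = 4,
c = 1.2 μm centered in a 6×9×3 μm box (V_N = (4/3)πabc ≈ 50.27 μm³),
meshed at 180×225×90; reduced-resolution work divides the mesh per
axis.  ε_η = 0.04 (ellipsoidal units) keeps the h-quadrature bias of
the nuclear volume below 1% on the reference mesh while the envelope
still fits the box with half a width of margin on every axis — the
printed domain is tight and does not admit a full-width margin.

Initial conditions are deterministic.  N = 8 territories are seeded as
tanh spheres at the reference coordinates, radius chosen so the spheres
sum to V_N; overlapping spheres are renormalized to Σφ ≤ 1, and all
seeds are multiplied by the nucleus interior (1 − η) because chromatin
outside the envelope feels no restoring force (the confinement density
h(η)(1−h(η)) vanishes there).  One printed seed center lies just
outside the ellipsoid surface (r_ell ≈ 1.09); seeding warns about
centers in the envelope shell and errors only beyond one envelope
width.  Heterochromatin starts as one sphere per CT center
(two-component) or as a cHC core with an fHC shell (three-component);
radii are solved by bisection against the φ-weighted occupancy
integral ∫h(ψ)h(φ), so the seeded HC volume matches the prescribed
fraction (25% of V_N) to well under 1% rather than the few-10% error a
sharp-interface estimate would give.

Default volume targets: V̄_i = V_N/N; v̄_i + w̄_i = 0.25·V_N/N per CT,
split between fHC and cHC by the seeded cHC share (0 in two-component
presets, ½ in the three-component preset).

## Presets

* `two-component-conventional` — single HC type ψ1, β_ψ1 = 0.1,
  β_φ = 40, no adhesion.  The reference relaxation.
* `two-component-adhesive` — adds lamina adhesion γ1 = 1.0.  The γ
  value is not dictated by the model; 1.0 was chosen by exploration as
  firmly in the strongly-adhesive regime (adhesion energy comparable
  to the other interfacial scales), where HC visibly enriches at the
  envelope within desk-scale horizons.
* `three-component` — fHC and cHC resolved: weak fHC-EC coupling
  (β_ψ1 = 0.1) so fHC droplets can travel, strong cHC-EC coupling
  (β_ψ2 = 4.5) pinning cHC inside territories, strong subtype demixing
  (β_ψ1ψ2 = 4.5).

## Morphometry

Droplets are connected components (face adjacency) of
{field ≥ 0.5} — 0.5 is the level-set convention for every interface.
Volume is voxel count × ΔV; surface area comes from a marching-cubes
triangulation of the 0.5 isosurface (voxel-face counting would bias
sphericity low); the centroid is field-weighted.  Sphericity
Ψ = π^(1/3)(6V)^(2/3)/S is 1 for a ball and scale-invariant, which the
suite checks on rasterized shapes.  Each droplet is assigned to the
chromosome whose h(φ_i) is largest at its centroid ("shared" when the
top two are within 0.1).

Radial profiles average a field in slabs along the major (y, b = 4 μm),
minor (x, a = 2.5 μm) or z (c = 1.2 μm) axis inside a cylinder of
0.5 μm radius around that axis.  Distance CDFs collect centroid-centroid
distances between droplets owned by different chromosomes, once per
unordered pair.

Architecture classification (thresholds configurable, defaults stated):

1. **disconnected-within-CT** — droplet count ≥ 0.75 N and no droplet
   spans a territory boundary (a droplet "spans" when ≥2 territories
   each dominate ≥10% of its voxels);
2. **connected-interior** — count ≤ max(2, ⌈N/4⌉) and mean centroid
   elliptic radius ≤ 0.5;
3. **connected-across-boundaries** — otherwise, when some droplet spans
   a boundary; residual cases fall back by centroid radius.

The three regimes correspond to the architectures spanned by varying
CT-CT exclusion against chromatin-type cohesion: droplets caged inside
territories, droplets merged in the nuclear interior, and droplets
bridging territory boundaries.

## Problem sizes used in tests and the acceptance script

Full-mesh work in this package is limited to static geometry
(η construction, volume quadrature).  Dynamical test problems run at
reduced meshes — divisor 4 (45×56×22) for the constrained relaxation,
the corner sweep and the adhesion comparison; divisor 6 (30×37×15)
for the per-preset descent runs — with horizons of 500–2000 dt = 0.04
steps.  These sizes were chosen as the smallest that keep the ψ
interface (≈0.69 μm) resolved by ≥3 voxels and let the volume
penalties bind; the methods are identical at all meshes.

The sweep preset crosses β_φ ∈ {10, 80} with β_ψ ∈ {0.1, 4.5}.  At
reduced scale the three regimes land as follows: weak type cohesion
(β_ψ = 0.1) merges HC into a single interior droplet at either β_φ;
strong cohesion with well-separated territories (β_φ = 80, where the
exclusion suppresses CT intermingling) cages one droplet per
territory; strong cohesion with intermingling territories (β_φ = 10)
leaves droplets bridging territory boundaries.

What the reduced problems show: constraint satisfaction (HC fraction,
nuclear filling), monotone energy descent, interface profiles matching
the closed form, qualitative regime contrast between coupling corners,
and adhesion-driven peripheral enrichment.  What they do not show:
converged droplet-size and sphericity *distributions* of the long-time
full-mesh model — those require the full 180×225×90 mesh and orders of
magnitude longer horizons, and are inherently stochastic.  The
machinery for those read-outs (mode extraction over droplet ensembles)
is instead validated on synthetic droplet ensembles with known modes.

## Known limitations

* The fixed η cannot represent envelope deformation or growth.
* Non-conserved dynamics plus per-CT volume penalties approximate, but
  do not enforce, HC mass conservation; the a-coefficients set how
  tightly.
* Droplet identity is not tracked across time (no fusion genealogy).
* At coarse sweep meshes the regime boundaries shift relative to the
  full mesh; corner contrasts, not boundary locations, are meaningful.
* The white-noise discretization is physically meaningful only for
  amplitudes far below the reference A = 5 (see Noise above).
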