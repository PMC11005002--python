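# melon4d

A multiphase liquid ("phase-field") simulator of the eukaryotic nucleus,
with a volumetric analysis suite for the heterochromatin compartments it
produces.

## The problem

In interphase nuclei, chromosomes occupy distinct territories, and
chromatin microphase-separates into euchromatin (EC) and heterochromatin
(HC) compartments — the latter split into constitutive (cHC) and
facultative (fHC) subtypes.  Where HC ends up — hugging the nuclear
envelope (the conventional architecture), collapsed at the center
(inverted), or in a few large clusters (senescent) — follows from a
competition between chromatin-chromatin cohesion, territory-territory
exclusion, and HC-lamina adhesion.  `melon4d` models this competition
directly, for people who want a mechanistic, tunable 3D sandbox for
nuclear-architecture hypotheses rather than a polymer-resolution model.

## The model

Each chromosomal territory is a smooth indicator field φᵢ ∈ [0,1]
(i = 1…N), heterochromatin subtypes are fields ψ₁ (fHC) and ψ₂ (cHC),
and the nucleus is a fixed oblate ellipsoid encoded by a static field η
(0 inside, 1 outside).  All fields relax a Ginzburg-Landau free energy

F = ∫ [ Σᵢ (ε²_φ/2)|∇φᵢ|² + Σⱼ (ε²_ψ/2)|∇ψⱼ|² + f(φ,ψ) ] dΩ
  + a₁(V_N − ΣᵢVᵢ)² + a₂Σᵢ(Vᵢ−V̄ᵢ)² + a₃Σᵢ(vᵢ−v̄ᵢ)² + a₄Σᵢ(wᵢ−w̄ᵢ)²
  + β₀ Σᵢ ∫ h(η)(1−h(η)) h(φᵢ) + β_φ Σ_{i≠j} ∫ h(φᵢ)h(φⱼ)
  + β_ψ1ψ2 ∫ h(ψ₁)h(ψ₂) + ∫ (1−Σᵢh(φᵢ))(β_ψ1 h(ψ₁) + β_ψ2 h(ψ₂))
  + ∫ ∇h(η)·(γ₁∇h(ψ₁) + γ₂∇h(ψ₂)),

by stochastic Allen-Cahn gradient flow ∂u/∂t = −L_u δF/δu (+ white
noise on ψ only), where f is a sum of quartic double wells,
h(x) = x³(10−15x+6x²) is the occupancy interpolant, and
Vᵢ = ∫h(φᵢ), vᵢ = ∫h(ψ₁)h(φᵢ), wᵢ = ∫h(ψ₂)h(φᵢ) are compartment
volumes with prescribed targets.  The β-terms impose envelope
confinement and excluded-volume couplings; the γ-term is lamina
adhesion.  See `docs/methods.md` for the full account, parameter table
and numerical scheme (semi-implicit spectral stepping on a regular
grid with an exact discrete-gradient contract).

The reference setup is an interphase fly nucleus: semiaxes
2.5 × 4 × 1.2 μm (V_N ≈ 50.27 μm³) in a 6 × 9 × 3 μm box at 180×225×90
voxels, N = 8 territories at fixed seed coordinates, 25% HC fraction,
dimensionless time step 0.04 (τ = 0.005 s, l = 1 μm).

The analysis suite extracts labeled HC droplets (volume, marching-cubes
surface area, sphericity Ψ = π^⅓(6V)^⅔/S, owning chromosome), radial
density profiles along the nucleus axes, cross-chromosome
centroid-distance CDFs, and a three-regime architecture classification
(droplets caged in territories / merged in the interior / bridging
territory boundaries) swept over coupling strengths into phase-diagram
tables.

## Worked example

Relax a two-component nucleus at quarter resolution in the "caged"
coupling regime (strong chromatin-type cohesion β_ψ = 4.5, strongly
excluding, well-separated territories β_φ = 80) and look at the
heterochromatin droplets:

```python
from melon4d import load_config, run_from_config, label_droplets

cfg = load_config(text="", overrides={
    "grid": {"resolution_divisor": 4},
    "parameters": {"beta_phi": 80.0, "beta_psi1": 4.5},
    "integrator": {"n_steps": 600, "energy_every": 50},
})
traj = run_from_config(cfg)
grid = cfg.build_grid()
params = cfg.build_parameters()

from melon4d import compartment_volumes
V, v, w = compartment_volumes(traj.final_state, grid)
print(f"CT volume total : {V.sum():.2f} um^3 (target {params.nuclear_volume:.2f})")
print(f"HC fraction     : {100 * (v.sum() + w.sum()) / params.nuclear_volume:.1f} %")

ds = label_droplets(traj.final_state.psi1, grid, phi=traj.final_state.phi)
print(f"droplets        : {len(ds)}")
print(ds.table[["volume_um3", "sphericity"]].describe().loc[["mean", "std"]])
```

Output from this exact snippet (~3 minutes on one core):

```
CT volume total : 50.16 um^3 (target 50.27)
HC fraction     : 21.9 %
droplets        : 8
      volume_um3  sphericity
mean    1.443506    1.001050
std     0.019941    0.013316
```

Eight droplets — one caged inside each territory, the disconnected
architecture — with mean droplet volume ≈1.44 μm³ and sphericity ≈1
(nearly perfect balls, as strong type cohesion minimizes their surface).
Total territory volume matches the prescribed nuclear volume to 0.2%;
the heterochromatin fraction sits a few points below its 25% target at
this horizon because the strong-coupling regime trades some
constraint satisfaction for interfacial energy.  At the default
couplings (β_ψ = 0.1) the same script instead produces a single merged
droplet at the nuclear center — the interior-connected architecture.

The same machinery from the shell:

```bash
melon4d fixtures --size small --out demo          # miniature configs
melon4d run --config demo/two-component-conventional_small.yaml \
            --steps 200 --out demo/run
melon4d analyze --trajectory demo/run             # droplets.csv, profiles, morphology.json
melon4d sweep --plan plan.yaml                    # phase_diagram.csv
```

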