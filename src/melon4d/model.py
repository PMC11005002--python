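"""Free-energy functional of the multiphase liquid nucleus model.

The nucleus is described by non-conserved order parameters: one field φ_i
per chromosomal territory (CT), two heterochromatin fields ψ1 (facultative
HC) and ψ2 (constitutive HC / chromocenter), and a static indicator η that
is 0 inside the nucleus and 1 outside.  Euchromatin is implicit,
ψ3 = 1 − ψ1 − ψ2, and never stored.

The total free energy F = F_B + F_I (in units of kBT, lengths in μm)
contains

F_B:  Σ_i (ε_φ²/2)|∇φ_i|² + Σ_j (ε_ψj²/2)|∇ψ_j|² + f(φ,ψ)   (integrated)
      + a1 [V_N − Σ_i V_i]² + a2 Σ_i [V_i − V̄_i]²
      + a3 Σ_i [v_i − v̄_i]² + a4 Σ_i [w_i − w̄_i]²

with the multi-well bulk density f = Σ_i φ_i²(1−φ_i)²/4 + Σ_j ψ_j²(1−ψ_j)²/4
and compartment volumes V_i = ∫ h(φ_i), v_i = ∫ h(ψ1)h(φ_i),
w_i = ∫ h(ψ2)h(φ_i) measured through the interpolant
h(x) = x³(10 − 15x + 6x²).

F_I:  β0 Σ_i ∫ h(η)[1−h(η)] h(φ_i)                (envelope confinement)
      + β_φ Σ_{i≠j} ∫ h(φ_i) h(φ_j)              (CT–CT exclusion)
      + β_ψ1ψ2 ∫ h(ψ1) h(ψ2)                      (fHC–cHC exclusion)
      + ∫ [1 − Σ_i h(φ_i)] [β_ψ1 h(ψ1) + β_ψ2 h(ψ2)]   (HC outside CTs)
      + ∫ ∇h(η) · [γ1 ∇h(ψ1) + γ2 ∇h(ψ2)]        (lamina adhesion)

The CT–CT exclusion sum runs over ordered pairs i≠j (each unordered pair
counted twice), matching the functional derivative implemented below.

Functional derivatives δF/δφ_i, δF/δψ_j are derived analytically from the
*discretized* energy (face-difference gradients, midpoint quadrature), so
they agree with single-voxel finite differences of :func:`free_energy` to
near machine precision — the core correctness contract of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .grid import SimulationGrid

__all__ = [
    "ModelParameters",
    "FieldState",
    "EnergyBreakdown",
    "interpolation_h",
    "interpolation_h_prime",
    "bulk_density",
    "compartment_volumes",
    "free_energy",
    "functional_derivatives",
]


# ----------------------------------------------------------------------
# parameters
# ----------------------------------------------------------------------

#: Reference physical scales: 1 μm spatial resolution, 5 ms relaxation time.
DEFAULT_LENGTH_SCALE_UM = 1.0
DEFAULT_TIME_SCALE_S = 0.005

#: In-vivo-motivated diffusion coefficients (μm²/s): CTs 20, HC subtypes 12.
DEFAULT_D_PHI = 20.0
DEFAULT_D_PSI = 12.0


@dataclass
class ModelParameters:
    """Every coefficient of the free energy plus noise amplitudes and targets.

    Gradient coefficients ε may be given directly; when left ``None`` they
    are derived from the diffusion-coefficient bookkeeping D = L·ε² after
    nondimensionalization (ε² = D·τ/(L·l²)), with the mobilities L
    dimensionless and equal by default.

    Target volumes are in μm³.  ``target_V`` defaults to V_N/N per CT;
    ``target_v``/``target_w`` split the heterochromatin volume fraction
    (25% of V_N by default) between fHC and cHC per preset.
    """

    n_chromosomes: int = 8

    # mobilities (dimensionless; time unit τ absorbs the physical scale)
    L_phi: float = 1.0
    L_psi1: float = 1.0
    L_psi2: float = 1.0

    # physical scales and diffusion coefficients used to derive ε
    length_scale: float = DEFAULT_LENGTH_SCALE_UM    # l, μm
    time_scale: float = DEFAULT_TIME_SCALE_S         # τ, s
    D_phi: float = DEFAULT_D_PHI                     # μm²/s
    D_psi1: float = DEFAULT_D_PSI
    D_psi2: float = DEFAULT_D_PSI

    # gradient (interface-width) coefficients; None → derived from D = L·ε²
    eps_phi: Optional[float] = None
    eps_psi1: Optional[float] = None
    eps_psi2: Optional[float] = None

    # volume-constraint coefficients
    a1: float = 0.16
    a2: float = 2.0
    a3: float = 2.0
    a4: float = 2.0

    # coupling strengths
    beta0: float = 16.7          # envelope confinement of territories
    #: envelope confinement of the heterochromatin fields; None → beta0.
    #: The envelope is impermeable to chromatin: without this term a ψ
    #: blob pushed outside the nucleus feels no restoring force at all
    #: (both well derivatives vanish there) and persists indefinitely.
    beta0_psi: Optional[float] = None
    beta_phi: float = 40.0       # CT-CT exclusion
    beta_psi1: float = 0.1       # fHC outside CTs
    beta_psi2: float = 0.0       # cHC outside CTs
    beta_psi1psi2: float = 0.0   # fHC-cHC exclusion

    # lamina adhesion strengths (0 → no adhesion)
    gamma1: float = 0.0
    gamma2: float = 0.0

    # interface-fluctuation amplitudes (white-noise strength on ψ1, ψ2)
    noise_amp1: float = 5.0
    noise_amp2: float = 5.0

    # prescribed volumes, μm³
    nuclear_volume: float = 50.26
    #: total heterochromatin volume fraction of V_N behind the default targets
    hc_fraction: float = 0.25
    #: share of the HC budget assigned to the cHC (ψ2) targets
    chc_split: float = 0.0
    target_V: Optional[Sequence[float]] = None
    target_v: Optional[Sequence[float]] = None
    target_w: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        for name in ("L_phi", "L_psi1", "L_psi2", "a1", "a2", "a3", "a4",
                     "beta0", "beta_phi", "beta_psi1", "beta_psi2",
                     "beta_psi1psi2", "gamma1", "gamma2",
                     "noise_amp1", "noise_amp2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("eps_phi", "eps_psi1", "eps_psi2", "beta0_psi"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")

    # -- derived interface widths -------------------------------------

    def _derived_eps(self, D: float, L: float) -> float:
        # dimensionless D̃ = D τ / l²; D̃ = L ε² → ε = sqrt(D̃ / L)
        d_tilde = D * self.time_scale / self.length_scale**2
        return math.sqrt(d_tilde / L)

    @property
    def eps_phi_value(self) -> float:
        return self.eps_phi if self.eps_phi is not None \
            else self._derived_eps(self.D_phi, self.L_phi)

    @property
    def eps_psi1_value(self) -> float:
        return self.eps_psi1 if self.eps_psi1 is not None \
            else self._derived_eps(self.D_psi1, self.L_psi1)

    @property
    def beta0_psi_value(self) -> float:
        return self.beta0 if self.beta0_psi is None else self.beta0_psi

    @property
    def eps_psi2_value(self) -> float:
        return self.eps_psi2 if self.eps_psi2 is not None \
            else self._derived_eps(self.D_psi2, self.L_psi2)

    # -- volume targets ------------------------------------------------

    def resolved_targets(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(V̄_i, v̄_i, w̄_i) arrays of length N with defaults filled in.

        Defaults: V̄_i = V_N/N; v̄_i + w̄_i = hc_fraction·V_N/N, split
        (1 − chc_split) : chc_split between fHC (ψ1) and cHC (ψ2).
        """
        n = self.n_chromosomes
        if self.target_V is not None:
            V = np.asarray(self.target_V, dtype=float)
        else:
            V = np.full(n, self.nuclear_volume / n)
        hc_per_ct = self.hc_fraction * self.nuclear_volume / n
        if self.target_v is not None:
            v = np.asarray(self.target_v, dtype=float)
        elif self.target_w is not None:
            w_tmp = np.asarray(self.target_w, dtype=float)
            v = np.maximum(hc_per_ct - w_tmp, 0.0)
        else:
            v = np.full(n, (1.0 - self.chc_split) * hc_per_ct)
        if self.target_w is not None:
            w = np.asarray(self.target_w, dtype=float)
        elif self.target_v is not None:
            w = np.zeros(n)
        else:
            w = np.full(n, self.chc_split * hc_per_ct)
        for arr, name in ((V, "target_V"), (v, "target_v"), (w, "target_w")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length n_chromosomes={n}")
        return V, v, w


# ----------------------------------------------------------------------
# field state
# ----------------------------------------------------------------------

@dataclass
class FieldState:
    """All order parameters at one instant.

    ``phi`` is stacked ``(N, nx, ny, nz)``; ``psi1``/``psi2``/``eta`` have
    the grid shape.  η is time-independent by contract: dynamics copies
    the reference, never mutates it.
    """

    phi: np.ndarray
    psi1: np.ndarray
    psi2: np.ndarray
    eta: np.ndarray
    time: float = 0.0

    #: permitted over/undershoot outside [0, 1] before validation complains
    overshoot_tol: float = 0.15

    @property
    def n_chromosomes(self) -> int:
        return self.phi.shape[0]

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.psi1.shape

    def validate(self, grid: Optional[SimulationGrid] = None,
                 check_range: bool = True) -> None:
        shape = self.psi1.shape
        if self.phi.ndim != 4 or self.phi.shape[1:] != shape:
            raise ValueError("phi must be stacked (N, nx, ny, nz) matching psi1")
        for name in ("psi2", "eta"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} "
                                 f"!= grid shape {shape}")
        if grid is not None and shape != grid.shape:
            raise ValueError(f"fields shaped {shape} do not live on grid "
                             f"{grid.shape}")
        if not check_range:
            return
        lo, hi = -self.overshoot_tol, 1.0 + self.overshoot_tol
        for name in ("phi", "psi1", "psi2"):
            arr = getattr(self, name)
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name}")
            if arr.min() < lo or arr.max() > hi:
                raise ValueError(
                    f"{name} leaves [{lo:.3g}, {hi:.3g}] "
                    f"(range [{arr.min():.3g}, {arr.max():.3g}])")

    def copy(self) -> "FieldState":
        return FieldState(self.phi.copy(), self.psi1.copy(), self.psi2.copy(),
                          self.eta, self.time, self.overshoot_tol)


# ----------------------------------------------------------------------
# elementary functions
# ----------------------------------------------------------------------

def interpolation_h(x):
    """Volume interpolant h(x) = x³(10 − 15x + 6x²).

    h(0)=0, h(1)=1 and h'(0)=h'(1)=0, so measuring volumes through h does
    not shift the bulk free-energy minima at 0 and 1.
    """
    x = np.asarray(x, dtype=float)
    out = x * x * x * (10.0 + x * (-15.0 + 6.0 * x))
    return out if out.ndim else float(out)


def interpolation_h_prime(x):
    """h'(x) = 30 x² (1 − x)²."""
    x = np.asarray(x, dtype=float)
    out = 30.0 * x * x * (1.0 - x) ** 2
    return out if out.ndim else float(out)


def _h_sat(x: np.ndarray) -> np.ndarray:
    """Saturated occupancy interpolant: h clamped to its well values.

    Allen-Cahn fields transiently over/undershoot [0, 1]; outside that
    range the raw quintic grows like 6x⁵ and its derivative like 30x⁴,
    which turns harmless undershoots into runaway coupling forces.  The
    occupancy reading of h makes saturation the physical choice, and
    because h'(0) = h'(1) = 0 the saturated interpolant is C¹ — the
    free energy stays C¹ and the analytic derivatives remain the exact
    gradient of the discrete functional.
    """
    return interpolation_h(np.clip(x, 0.0, 1.0))


def _h_sat_prime(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    inside = (x >= 0.0) & (x <= 1.0)
    return np.where(inside, 30.0 * x * x * (1.0 - x) ** 2, 0.0)


def _double_well(x: np.ndarray) -> np.ndarray:
    return x * x * (1.0 - x) ** 2 / 4.0


def _double_well_prime(x: np.ndarray) -> np.ndarray:
    return x * (1.0 - x) * (1.0 - 2.0 * x) / 2.0


def bulk_density(fields: FieldState) -> np.ndarray:
    """Multi-well bulk energy density f(φ,ψ) = Σ_i φ_i²(1−φ_i)²/4 + Σ_j ψ_j²(1−ψ_j)²/4."""
    f = _double_well(fields.phi).sum(axis=0)
    f += _double_well(fields.psi1)
    f += _double_well(fields.psi2)
    return f


def compartment_volumes(fields: FieldState, grid: SimulationGrid
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(V_i, v_i, w_i) per CT in μm³ by midpoint quadrature.

    V_i = ∫ h(φ_i), v_i = ∫ h(ψ1) h(φ_i), w_i = ∫ h(ψ2) h(φ_i).
    """
    dv = grid.voxel_volume
    h_phi = _h_sat(fields.phi)             # (N, ...)
    h_psi1 = _h_sat(fields.psi1)
    h_psi2 = _h_sat(fields.psi2)
    V = h_phi.sum(axis=(1, 2, 3)) * dv
    v = (h_phi * h_psi1).sum(axis=(1, 2, 3)) * dv
    w = (h_phi * h_psi2).sum(axis=(1, 2, 3)) * dv
    return V, v, w


# ----------------------------------------------------------------------
# free energy
# ----------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    """All components of F, individually and summed (units of kBT)."""

    gradient_energy: float
    bulk_energy: float
    volume_penalty_a1: float
    volume_penalty_a2: float
    volume_penalty_a3: float
    volume_penalty_a4: float
    confinement_energy: float
    ct_exclusion: float
    hc_exclusion: float
    hc_outside_ct: float
    adhesion_energy: float

    @property
    def volume_penalty(self) -> float:
        return (self.volume_penalty_a1 + self.volume_penalty_a2
                + self.volume_penalty_a3 + self.volume_penalty_a4)

    @property
    def total(self) -> float:
        return (self.gradient_energy + self.bulk_energy + self.volume_penalty
                + self.confinement_energy + self.ct_exclusion
                + self.hc_exclusion + self.hc_outside_ct
                + self.adhesion_energy)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in (
            "gradient_energy", "bulk_energy",
            "volume_penalty_a1", "volume_penalty_a2",
            "volume_penalty_a3", "volume_penalty_a4",
            "confinement_energy", "ct_exclusion", "hc_exclusion",
            "hc_outside_ct", "adhesion_energy")}
        d["total"] = self.total
        return d


def free_energy(fields: FieldState, params: ModelParameters,
                grid: SimulationGrid) -> EnergyBreakdown:
    """Evaluate every term of the discrete free energy F_B + F_I."""
    fields.validate(grid, check_range=False)
    if fields.n_chromosomes != params.n_chromosomes:
        raise ValueError(f"state has {fields.n_chromosomes} CT fields but "
                         f"params.n_chromosomes={params.n_chromosomes}")

    eps2_phi = params.eps_phi_value ** 2
    eps2_psi1 = params.eps_psi1_value ** 2
    eps2_psi2 = params.eps_psi2_value ** 2

    grad = 0.0
    for i in range(fields.n_chromosomes):
        grad += 0.5 * eps2_phi * grid.gradient_squared_integral(fields.phi[i])
    grad += 0.5 * eps2_psi1 * grid.gradient_squared_integral(fields.psi1)
    grad += 0.5 * eps2_psi2 * grid.gradient_squared_integral(fields.psi2)

    bulk = grid.integrate(bulk_density(fields))

    V, v, w = compartment_volumes(fields, grid)
    Vbar, vbar, wbar = params.resolved_targets()
    pen1 = params.a1 * (params.nuclear_volume - V.sum()) ** 2
    pen2 = params.a2 * float(np.sum((V - Vbar) ** 2))
    pen3 = params.a3 * float(np.sum((v - vbar) ** 2))
    pen4 = params.a4 * float(np.sum((w - wbar) ** 2))

    h_phi = _h_sat(fields.phi)
    h_psi1 = _h_sat(fields.psi1)
    h_psi2 = _h_sat(fields.psi2)
    h_eta = _h_sat(fields.eta)
    sum_h_phi = h_phi.sum(axis=0)

    envelope_density = h_eta * (1.0 - h_eta)
    confinement = params.beta0 * grid.integrate(
        envelope_density * sum_h_phi)
    confinement += params.beta0_psi_value * grid.integrate(
        envelope_density * (h_psi1 + h_psi2))

    # ordered-pair sum Σ_{i≠j} h(φi)h(φj) = (Σh)² − Σh²
    ct_excl = params.beta_phi * grid.integrate(
        sum_h_phi * sum_h_phi - (h_phi * h_phi).sum(axis=0))

    hc_excl = params.beta_psi1psi2 * grid.integrate(h_psi1 * h_psi2)

    hc_out = grid.integrate((1.0 - sum_h_phi)
                            * (params.beta_psi1 * h_psi1
                               + params.beta_psi2 * h_psi2))

    if params.gamma1 == 0.0 and params.gamma2 == 0.0:
        adhesion = 0.0
    else:
        adhesion = 0.0
        if params.gamma1 > 0.0:
            adhesion += params.gamma1 * grid.adhesion_integral(h_eta, h_psi1)
        if params.gamma2 > 0.0:
            adhesion += params.gamma2 * grid.adhesion_integral(h_eta, h_psi2)

    return EnergyBreakdown(
        gradient_energy=grad, bulk_energy=bulk,
        volume_penalty_a1=pen1, volume_penalty_a2=pen2,
        volume_penalty_a3=pen3, volume_penalty_a4=pen4,
        confinement_energy=confinement, ct_exclusion=ct_excl,
        hc_exclusion=hc_excl, hc_outside_ct=hc_out,
        adhesion_energy=adhesion)


# ----------------------------------------------------------------------
# functional derivatives
# ----------------------------------------------------------------------

def functional_derivatives(fields: FieldState, params: ModelParameters,
                           grid: SimulationGrid,
                           include_laplacian: bool = True,
                           ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic variational derivatives (δF/δφ_i, δF/δψ1, δF/δψ2).

    Returned per unit volume: the gradient of the discrete energy with
    respect to a voxel value, divided by the voxel volume.  With
    ``include_laplacian=False`` the leading −ε²∇² term is omitted (the
    semi-implicit integrator treats it implicitly in transform space).
    """
    fields.validate(grid, check_range=False)
    n = fields.n_chromosomes
    if n != params.n_chromosomes:
        raise ValueError("n_chromosomes mismatch between state and params")

    V, v, w = compartment_volumes(fields, grid)
    Vbar, vbar, wbar = params.resolved_targets()

    h_phi = _h_sat(fields.phi)
    hp_phi = _h_sat_prime(fields.phi)
    h_psi1 = _h_sat(fields.psi1)
    hp_psi1 = _h_sat_prime(fields.psi1)
    h_psi2 = _h_sat(fields.psi2)
    hp_psi2 = _h_sat_prime(fields.psi2)
    h_eta = _h_sat(fields.eta)
    sum_h_phi = h_phi.sum(axis=0)

    vol_defect = params.nuclear_volume - V.sum()
    envelope_density = h_eta * (1.0 - h_eta)
    confinement_density = params.beta0 * envelope_density
    psi_confinement = params.beta0_psi_value * envelope_density
    hc_weight = params.beta_psi1 * h_psi1 + params.beta_psi2 * h_psi2

    dphi = np.empty_like(fields.phi)
    for i in range(n):
        react = (-2.0 * params.a1 * vol_defect
                 + 2.0 * params.a2 * (V[i] - Vbar[i])
                 + 2.0 * params.a3 * (v[i] - vbar[i]) * h_psi1
                 + 2.0 * params.a4 * (w[i] - wbar[i]) * h_psi2
                 + confinement_density
                 + 2.0 * params.beta_phi * (sum_h_phi - h_phi[i])
                 - hc_weight)
        dphi[i] = _double_well_prime(fields.phi[i]) + hp_phi[i] * react
        if include_laplacian:
            dphi[i] -= params.eps_phi_value ** 2 * grid.laplacian(fields.phi[i])

    # ψ1
    react1 = (2.0 * params.a3 * np.tensordot((v - vbar), h_phi, axes=(0, 0))
              + params.beta_psi1psi2 * h_psi2
              + params.beta_psi1 * (1.0 - sum_h_phi)
              + psi_confinement)
    dpsi1 = _double_well_prime(fields.psi1) + hp_psi1 * react1
    if params.gamma1 > 0.0:
        dpsi1 -= params.gamma1 * hp_psi1 * grid.laplacian(h_eta)
    if include_laplacian:
        dpsi1 -= params.eps_psi1_value ** 2 * grid.laplacian(fields.psi1)

    # ψ2
    react2 = (2.0 * params.a4 * np.tensordot((w - wbar), h_phi, axes=(0, 0))
              + params.beta_psi1psi2 * h_psi1
              + params.beta_psi2 * (1.0 - sum_h_phi)
              + psi_confinement)
    dpsi2 = _double_well_prime(fields.psi2) + hp_psi2 * react2
    if params.gamma2 > 0.0:
        dpsi2 -= params.gamma2 * hp_psi2 * grid.laplacian(h_eta)
    if include_laplacian:
        dpsi2 -= params.eps_psi2_value ** 2 * grid.laplacian(fields.psi2)

    return dphi, dpsi1, dpsi2
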