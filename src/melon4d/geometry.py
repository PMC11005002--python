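"""Nucleus geometry and initial conditions.

The nucleus is a fixed oblate ellipsoid described by the static indicator
field η: 0 inside, 1 outside, with the envelope at the η = 1/2 isocontour,

    η(r) = ½ [1 + tanh((r_ell − 1) / (2√2 ε_η))],
    r_ell = sqrt((x/a)² + (y/b)² + (z/c)²),

so the transition is centered on the ellipsoid surface r_ell = 1 and has
width 2√2 ε_η in ellipsoidal units.  The reference geometry models an
interphase fly nucleus: a = 2.5, b = 4, c = 1.2 μm, V_N = (4/3)πabc
≈ 50.26 μm³.

Initial conditions seed N tanh-profile spheres for the chromosomal
territories at prescribed centers, each carrying a heterochromatin core
(one ψ1 sphere in the two-component model; a ψ2 core with a ψ1 shell in
the three-component model).  Seeding is deterministic — stochasticity
enters only through the dynamics noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .grid import SimulationGrid
from .model import FieldState, ModelParameters, interpolation_h

__all__ = [
    "NucleusGeometry",
    "SeedLayout",
    "DEFAULT_CT_CENTERS",
    "build_nucleus_indicator",
    "seed_initial_state",
]

SQRT8 = 2.0 * math.sqrt(2.0)

#: Reference coordinates (μm) of the eight chromosomal territories.
DEFAULT_CT_CENTERS: Tuple[Tuple[float, float, float], ...] = (
    (3.0, 1.2, 1.5),
    (1.2, 2.9, 1.5),
    (2.7, 3.25, 0.26),
    (4.5, 2.5, 1.5),
    (3.2, 5.4, 1.5),
    (4.8, 6.0, 1.5),
    (3.0, 8.2, 1.5),
    (1.35, 6.1, 1.5),
)


class GeometryError(ValueError):
    """Raised when a geometry does not fit the computational domain."""


@dataclass(frozen=True)
class NucleusGeometry:
    """Oblate ellipsoidal nucleus with a diffuse envelope.

    ``eps_eta`` controls the envelope width (2√2 ε_η in ellipsoidal
    units); the default 0.04 keeps the envelope thin enough for accurate
    volume quadrature while staying resolved on the reference mesh and
    fitting the tight 6×9×3 μm domain.
    """

    a: float = 2.5
    b: float = 4.0
    c: float = 1.2
    eps_eta: float = 0.04
    center: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0 or self.eps_eta <= 0:
            raise GeometryError("semiaxes and eps_eta must be positive")

    @property
    def semiaxes(self) -> Tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def volume(self) -> float:
        """Analytic nuclear volume (4/3)πabc in μm³."""
        return 4.0 / 3.0 * math.pi * self.a * self.b * self.c

    def resolved_center(self, grid: SimulationGrid) -> Tuple[float, float, float]:
        return self.center if self.center is not None else grid.center

    def elliptic_radius(self, grid: SimulationGrid) -> np.ndarray:
        """r_ell = sqrt((x/a)²+(y/b)²+(z/c)²) on the grid's cell centers."""
        cx, cy, cz = self.resolved_center(grid)
        X, Y, Z = grid.meshgrid()
        return np.sqrt(((X - cx) / self.a) ** 2 + ((Y - cy) / self.b) ** 2
                       + ((Z - cz) / self.c) ** 2)

    def elliptic_radius_of(self, point: Sequence[float],
                           grid: SimulationGrid) -> float:
        cx, cy, cz = self.resolved_center(grid)
        x, y, z = point
        return math.sqrt(((x - cx) / self.a) ** 2 + ((y - cy) / self.b) ** 2
                         + ((z - cz) / self.c) ** 2)

    def check_fits(self, grid: SimulationGrid) -> None:
        """Require at least half an envelope width of margin on every axis."""
        cx, cy, cz = self.resolved_center(grid)
        margin = math.sqrt(2.0) * self.eps_eta  # half of 2√2 ε_η
        for semi, c0, L, name in ((self.a, cx, grid.extents[0], "x"),
                                  (self.b, cy, grid.extents[1], "y"),
                                  (self.c, cz, grid.extents[2], "z")):
            room = min(c0, L - c0)
            if room / semi - 1.0 < margin:
                raise GeometryError(
                    f"ellipsoid semiaxis {semi} μm along {name} leaves "
                    f"margin {room/semi - 1:.3f} < √2·ε_η = {margin:.3f} "
                    f"(envelope touches the domain boundary)")


def build_nucleus_indicator(grid: SimulationGrid,
                            geom: NucleusGeometry) -> np.ndarray:
    """The static indicator η: ≈0 deep inside, ≈1 far outside, ½ on the surface."""
    geom.check_fits(grid)
    r = geom.elliptic_radius(grid)
    return 0.5 * (1.0 + np.tanh((r - 1.0) / (SQRT8 * geom.eps_eta)))


@dataclass
class SeedLayout:
    """Placement and sizes of the initial CT and heterochromatin spheres.

    ``ct_radius`` and HC core radii default to ``None`` and are then
    solved from the volume budget: CT radii so that N spheres fill V_N,
    HC radii so that total heterochromatin is ``hc_fraction``·V_N (split
    between a cHC core and an fHC shell when ``chc_fraction`` > 0).
    """

    ct_centers: Tuple[Tuple[float, float, float], ...] = DEFAULT_CT_CENTERS
    ct_radius: Optional[float] = None
    hc_core_radius: Optional[float] = None
    hc_fraction: float = 0.25
    #: fraction of the HC budget carried by the constitutive (ψ2) core
    chc_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.ct_centers = tuple(tuple(float(v) for v in c)
                                for c in self.ct_centers)
        if not 0.0 <= self.hc_fraction < 1.0:
            raise ValueError("hc_fraction must be in [0, 1)")
        if not 0.0 <= self.chc_fraction <= 1.0:
            raise ValueError("chc_fraction must be in [0, 1]")

    @property
    def n_territories(self) -> int:
        return len(self.ct_centers)


def _tanh_sphere(grid: SimulationGrid, center: Sequence[float],
                 radius: float, eps: float) -> np.ndarray:
    """≈1 inside a sphere of given radius, tanh transition of width 2√2 ε."""
    X, Y, Z = grid.meshgrid()
    r = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2
                + (Z - center[2]) ** 2)
    return 0.5 * (1.0 - np.tanh((r - radius) / (SQRT8 * eps)))


def _bisect_radius(measure, target: float, lo: float, hi: float,
                   tol: float) -> float:
    """Monotone bisection on a measured-volume function of the radius.

    Returns ``hi`` when even the largest radius under-delivers (the
    caller then takes the largest geometry that fits).
    """
    if measure(hi) < target:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if measure(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def seed_initial_state(grid: SimulationGrid, geom: NucleusGeometry,
                       layout: SeedLayout, params: ModelParameters,
                       ) -> FieldState:
    """Deterministic initial condition: CT spheres with HC cores.

    Each φ_i is a tanh sphere around its center; ψ2 (when ``chc_fraction``
    > 0) is a concentric core inside each CT, and ψ1 the surrounding
    shell, so ψ1 + ψ2 ≤ 1 everywhere.  Radii are solved numerically so
    the initial heterochromatin volume matches ``hc_fraction``·V_N.
    """
    if layout.n_territories != params.n_chromosomes:
        raise ValueError(f"{layout.n_territories} seed centers for "
                         f"{params.n_chromosomes} chromosomes")
    eta = build_nucleus_indicator(grid, geom)

    # placement sanity: warn near/through the envelope, error only when a
    # center lies more than one envelope width beyond the surface
    margin = SQRT8 * geom.eps_eta
    outside = []
    for k, ctr in enumerate(layout.ct_centers):
        r = geom.elliptic_radius_of(ctr, grid)
        if r >= 1.0 + margin:
            raise GeometryError(f"seed center {k} at r_ell={r:.3f} lies "
                                "beyond the nuclear envelope")
        if r >= 1.0:
            outside.append((k, r))
    if outside:
        warnings.warn(f"seed centers in the envelope shell (index, r_ell): "
                      f"{[(k, round(r, 3)) for k, r in outside]}",
                      stacklevel=2)

    eps_phi = params.eps_phi_value
    eps_psi = params.eps_psi1_value
    VN = geom.volume

    ct_radius = layout.ct_radius
    if ct_radius is None:
        ct_radius = (3.0 * VN / layout.n_territories
                     / (4.0 * math.pi)) ** (1.0 / 3.0)

    close_pairs = 0
    centers = layout.ct_centers
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = math.dist(centers[i], centers[j])
            if d < 2.0 * ct_radius:
                close_pairs += 1
    if close_pairs:
        warnings.warn(f"{close_pairs} seed-sphere pairs overlap "
                      "(the dynamics resolves overlaps)", stacklevel=2)

    shape = grid.shape
    phi = np.empty((layout.n_territories,) + shape)
    for i, ctr in enumerate(centers):
        phi[i] = _tanh_sphere(grid, ctr, ct_radius, eps_phi)
    # where seed spheres overlap, renormalize so Σφ ≤ 1: the exclusion
    # coupling then starts from a physical (non-interpenetrating) state
    total = phi.sum(axis=0)
    phi /= np.maximum(total, 1.0)
    # confine seeds to the nucleus interior: chromatin outside the
    # envelope feels no restoring force (the confinement density
    # h(η)[1−h(η)] vanishes there), so stray seed mass would persist
    interior = 1.0 - eta
    phi *= interior

    psi1 = np.zeros(shape)
    psi2 = np.zeros(shape)
    if layout.hc_fraction > 0.0:
        hc_total = layout.hc_fraction * VN
        chc_total = layout.chc_fraction * hc_total
        fhc_total = hc_total - chc_total
        # the HC volumes that matter are the per-CT occupancies
        # v_i = ∫ h(ψ1)h(φ_i): solve radii against the φ-weighted measure
        ct_weight = interpolation_h(phi).sum(axis=0)

        def raster_cores(radius: float) -> np.ndarray:
            out = np.zeros(shape)
            for ctr in centers:
                out += _tanh_sphere(grid, ctr, radius, eps_psi)
            return np.clip(out, 0.0, 1.0) * interior

        def measure(field: np.ndarray) -> float:
            return grid.integrate(interpolation_h(field) * ct_weight)

        est = (3.0 * hc_total / len(centers) / (4.0 * math.pi)) ** (1.0 / 3.0)
        r_core = 0.0
        if chc_total > 0.0:
            if layout.hc_core_radius is not None and layout.chc_fraction == 1.0:
                r_core = layout.hc_core_radius
            else:
                r_core = _bisect_radius(lambda r: measure(raster_cores(r)),
                                        chc_total, 0.1 * est, 2.0 * est + 1.0,
                                        1e-4 * est)
            psi2 = raster_cores(r_core)
        if fhc_total > 0.0:
            def raster_shell(r_outer: float) -> np.ndarray:
                out = np.zeros(shape)
                for ctr in centers:
                    outer = _tanh_sphere(grid, ctr, r_outer, eps_psi)
                    inner = (_tanh_sphere(grid, ctr, r_core, eps_psi)
                             if r_core > 0 else 0.0)
                    out += np.clip(outer - inner, 0.0, 1.0)
                return np.clip(out, 0.0, 1.0) * interior

            if layout.hc_core_radius is not None and layout.chc_fraction == 0.0:
                r_outer = layout.hc_core_radius
            else:
                # thin shells never reach height 1, so the outer radius is
                # solved on the shell construction itself
                r_outer = _bisect_radius(lambda r: measure(raster_shell(r)),
                                         fhc_total, max(r_core, 0.1 * est),
                                         max(r_core, est) + 2.0, 1e-4 * est)
            psi1 = raster_shell(r_outer)
        # shells and cores of *different* territories may overlap when
        # solved radii grow; renormalize so ψ1 + ψ2 ≤ 1 pointwise
        both = psi1 + psi2
        scale = 1.0 / np.maximum(both, 1.0)
        psi1 *= scale
        psi2 *= scale
    np.clip(psi1, 0.0, 1.0, out=psi1)
    np.clip(psi2, 0.0, 1.0, out=psi2)
    np.clip(phi, 0.0, 1.0, out=phi)

    return FieldState(phi=phi, psi1=psi1, psi2=psi2, eta=eta, time=0.0)
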