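"""Free-energy functional: interpolant, bulk density, volumes, derivatives.

The decisive check is the finite-difference oracle: for every energy
term switched on in isolation, the analytic variational derivative must
match brute-force single-voxel differentiation of the discrete energy.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melon4d import (FieldState,
                     SimulationGrid, bulk_density, compartment_volumes,
                     free_energy, functional_derivatives, interpolation_h,
                     interpolation_h_prime)

from conftest import free_params, smooth_random_state, uniform_state


# ----------------------------------------------------------------------
# interpolant
# ----------------------------------------------------------------------

class TestInterpolant:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0),
                                            (0.5, 0.5)])
    def test_key_values(self, x, expected):
        assert interpolation_h(x) == pytest.approx(expected, abs=1e-15)

    def test_flat_at_both_wells(self):
        # h'(0) = h'(1) = 0 keeps the bulk minima at 0 and 1
        assert interpolation_h_prime(0.0) == 0.0
        assert interpolation_h_prime(1.0) == 0.0
        for x0 in (0.0, 1.0):
            fd = (interpolation_h(x0 + 1e-6) - interpolation_h(x0 - 1e-6)) / 2e-6
            assert abs(fd) < 1e-8

    def test_derivative_consistent_and_monotone(self):
        x = np.linspace(-0.2, 1.2, 141)
        fd = np.gradient(interpolation_h(x), x)[1:-1]   # interior: 2nd order
        assert np.allclose(fd, interpolation_h_prime(x)[1:-1], atol=5e-3)
        inside = (x >= 0) & (x <= 1)
        assert (interpolation_h_prime(x[inside]) >= 0).all()

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_maps_unit_interval_to_itself(self, x):
        # float roundoff at the upper well can exceed 1 by ~1 ulp
        assert -1e-12 <= interpolation_h(x) <= 1.0 + 1e-12


# ----------------------------------------------------------------------
# bulk density
# ----------------------------------------------------------------------

class TestBulkDensity:
    def test_well_minima_are_zero(self, small_grid):
        for val in (0.0, 1.0):
            state = uniform_state(small_grid, 3, val, val, val)
            assert np.all(bulk_density(state) == 0.0)

    def test_half_field_value(self, small_grid):
        # single field at 1/2: (0.25 · 0.25)/4 = 0.015625
        state = uniform_state(small_grid, 1, phi_val=0.5)
        assert bulk_density(state) == pytest.approx(0.015625)

    def test_nonnegative_and_zero_only_at_wells(self, small_grid):
        state = smooth_random_state(small_grid, 2, seed=7)
        f = bulk_density(state)
        assert (f >= 0).all()
        assert (f > 0).all()      # random fields sit strictly between wells


# ----------------------------------------------------------------------
# compartment volumes
# ----------------------------------------------------------------------

class TestCompartmentVolumes:
    def setup_method(self):
        self.grid = SimulationGrid((12, 18, 6), (6.0, 9.0, 3.0))

    def test_full_field_gives_domain_volume(self):
        state = uniform_state(self.grid, 1, phi_val=1.0)
        V, v, w = compartment_volumes(state, self.grid)
        assert V[0] == pytest.approx(162.0)       # 6·9·3 μm³
        assert v[0] == 0.0 and w[0] == 0.0

    def test_empty_field_gives_zero(self):
        state = uniform_state(self.grid, 1)
        V, v, w = compartment_volumes(state, self.grid)
        assert V[0] == v[0] == w[0] == 0.0

    def test_half_psi_occupancy(self):
        state = uniform_state(self.grid, 1, phi_val=1.0, psi1_val=0.5)
        _, v, _ = compartment_volumes(state, self.grid)
        assert v[0] == pytest.approx(0.5 * 162.0)  # h(1/2) = 1/2

    def test_hc_volumes_bounded_by_ct_volume(self, small_grid):
        state = smooth_random_state(small_grid, 3, seed=3)
        V, v, w = compartment_volumes(state, small_grid)
        tol = 1e-9
        assert (v <= V + tol).all() and (w <= V + tol).all()
        assert (V >= 0).all() and (v >= 0).all() and (w >= 0).all()


# ----------------------------------------------------------------------
# free energy
# ----------------------------------------------------------------------

class TestFreeEnergy:
    def test_zero_state_zero_energy(self, small_grid):
        params = free_params(2)
        state = uniform_state(small_grid, 2)
        eb = free_energy(state, params, small_grid)
        assert eb.total == 0.0

    def test_no_adhesion_term_without_gamma(self, small_grid, random_state):
        params = free_params(2, eps_phi=0.3, eps_psi1=0.2, eps_psi2=0.2,
                             beta0=16.7, beta_phi=40.0)
        eb = free_energy(random_state, params, small_grid)
        assert eb.adhesion_energy == 0.0

    def test_components_sign_and_sum(self, small_grid, random_state):
        params = free_params(2, eps_phi=0.3, eps_psi1=0.2, eps_psi2=0.2,
                             a1=0.16, a2=2.0, a3=2.0, a4=2.0, beta0=16.7,
                             beta_phi=40.0, beta_psi1=0.1, beta_psi2=0.3,
                             beta_psi1psi2=1.0, gamma1=2.0, gamma2=1.0)
        eb = free_energy(random_state, params, small_grid)
        for name in ("gradient_energy", "bulk_energy", "volume_penalty_a1",
                     "volume_penalty_a2", "volume_penalty_a3",
                     "volume_penalty_a4", "confinement_energy",
                     "ct_exclusion", "hc_exclusion", "hc_outside_ct"):
            assert getattr(eb, name) >= 0.0, name
        component_sum = sum(getattr(eb, n) for n in (
            "gradient_energy", "bulk_energy", "volume_penalty_a1",
            "volume_penalty_a2", "volume_penalty_a3", "volume_penalty_a4",
            "confinement_energy", "ct_exclusion", "hc_exclusion",
            "hc_outside_ct", "adhesion_energy"))
        assert eb.total == pytest.approx(component_sum, rel=1e-12)

    @pytest.mark.parametrize("coeff,component", [
        ("beta0", "confinement_energy"),
        ("beta_phi", "ct_exclusion"),
        ("beta_psi1psi2", "hc_exclusion"),
        ("a1", "volume_penalty_a1"),
        ("a2", "volume_penalty_a2"),
        ("a3", "volume_penalty_a3"),
        ("a4", "volume_penalty_a4"),
    ])
    def test_zero_coefficient_removes_component(self, small_grid,
                                                random_state, coeff,
                                                component):
        on = {c: 1.0 for c in ("a1", "a2", "a3", "a4", "beta0", "beta_phi",
                               "beta_psi1", "beta_psi2", "beta_psi1psi2",
                               "gamma1", "gamma2")}
        params_on = free_params(2, **on)
        params_off = free_params(2, **{**on, coeff: 0.0})
        eb_on = free_energy(random_state, params_on, small_grid)
        eb_off = free_energy(random_state, params_off, small_grid)
        assert getattr(eb_on, component) > 0.0
        assert getattr(eb_off, component) == 0.0

    def test_shape_mismatch_is_structural_error(self, small_grid):
        state = uniform_state(SimulationGrid((6, 6, 6), (2.0, 2.0, 2.0)), 2)
        with pytest.raises(ValueError, match="grid"):
            free_energy(state, free_params(2), small_grid)

    def test_interface_energy_matches_closed_form(self):
        # flat 1D equilibrium profile u = ½[1 − tanh(x/(2√2 ε))] has
        # interfacial energy σ = ε/(6√2) per unit cross-section
        eps = 0.3
        n = 512
        grid = SimulationGrid((n, 1, 1), (12.0, 1.0, 1.0))
        x = grid.axes[0]
        u = 0.5 * (1.0 - np.tanh((x - 6.0) / (2.0 * math.sqrt(2.0) * eps)))
        state = uniform_state(grid, 1)
        state.phi[0] = u[:, None, None]
        params = free_params(1, eps_phi=eps)
        eb = free_energy(state, params, grid)
        sigma = eps / (6.0 * math.sqrt(2.0))
        assert (eb.gradient_energy + eb.bulk_energy) == pytest.approx(
            sigma, rel=0.01)


# ----------------------------------------------------------------------
# the derivative oracle
# ----------------------------------------------------------------------

ORACLE_TERMS = {
    "gradient": dict(eps_phi=0.3, eps_psi1=0.25, eps_psi2=0.25),
    "a1": dict(a1=0.16),
    "a2": dict(a2=2.0),
    "a3": dict(a3=2.0),
    "a4": dict(a4=2.0),
    "beta0": dict(beta0=16.7, beta0_psi=0.0),
    "beta0_psi": dict(beta0_psi=3.0),
    "beta_phi": dict(beta_phi=40.0),
    "beta_psi1": dict(beta_psi1=0.1),
    "beta_psi2": dict(beta_psi2=0.5),
    "beta_psi1psi2": dict(beta_psi1psi2=1.0),
    "gamma1": dict(gamma1=2.0),
    "gamma2": dict(gamma2=1.5),
    "all": dict(eps_phi=0.3, eps_psi1=0.25, eps_psi2=0.25, a1=0.16,
                a2=2.0, a3=2.0, a4=2.0, beta0=16.7, beta_phi=40.0,
                beta_psi1=0.1, beta_psi2=0.5, beta_psi1psi2=1.0,
                gamma1=2.0, gamma2=1.5),
}


def finite_difference_derivative(state, params, grid, field, index, idx,
                                 probe=1e-4):
    """Central difference of the total energy under one voxel perturbation."""

    def energy(delta):
        st = state.copy()
        if field == "phi":
            st.phi[index][idx] += delta
        else:
            getattr(st, field)[idx] += delta
        return free_energy(st, params, grid).total

    return (energy(probe) - energy(-probe)) / (2.0 * probe
                                               * grid.voxel_volume)


@pytest.mark.parametrize("term", list(ORACLE_TERMS))
def test_functional_derivative_matches_finite_differences(small_grid, term):
    """Analytic δF/δu vs single-voxel differentiation, each term isolated."""
    state = smooth_random_state(small_grid, 2, seed=42)
    params = free_params(2, nuclear_volume=8.0,
                         target_V=[3.0, 3.0], target_v=[0.8, 0.8],
                         target_w=[0.5, 0.5], **ORACLE_TERMS[term])
    dphi, dpsi1, dpsi2 = functional_derivatives(state, params, small_grid)
    rng = np.random.default_rng(1)
    for field, index, analytic in [("phi", 0, dphi[0]), ("phi", 1, dphi[1]),
                                   ("psi1", None, dpsi1),
                                   ("psi2", None, dpsi2)]:
        scale = max(np.abs(analytic).max(), 1e-10)
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in small_grid.shape)
            fd = finite_difference_derivative(state, params, small_grid,
                                              field, index, idx)
            assert abs(fd - analytic[idx]) / scale < 1e-5, \
                f"{term}/{field}[{index}] at {idx}"


def test_derivative_vanishes_at_uniform_well(small_grid):
    """A uniform field at a well bottom feels no force when free."""
    state = uniform_state(small_grid, 2)
    dphi, dpsi1, dpsi2 = functional_derivatives(state, free_params(2),
                                                small_grid)
    assert np.all(dphi == 0.0) and np.all(dpsi1 == 0.0) \
        and np.all(dpsi2 == 0.0)


def test_adhesion_force_lives_on_interface_overlap(mini_grid, mini_geometry):
    """γ∇h(η)·∇h(ψ) acts only where both interfacial shells overlap."""
    from melon4d import build_nucleus_indicator
    eta = build_nucleus_indicator(mini_grid, mini_geometry)
    # ψ1 fills the nucleus: its interface shell coincides with η's
    psi1 = 1.0 - eta
    state = FieldState(phi=np.zeros((1,) + mini_grid.shape), psi1=psi1,
                       psi2=np.zeros(mini_grid.shape), eta=eta)
    _, d_with, _ = functional_derivatives(state, free_params(1, gamma1=2.0),
                                          mini_grid)
    _, d_without, _ = functional_derivatives(state, free_params(1),
                                             mini_grid)
    adhesion_force = d_with - d_without
    assert np.abs(adhesion_force).max() > 0.0
    # deep bulk (ψ1 ≈ 1, η ≈ 0) and far outside (ψ1 ≈ 0): h' kills the term
    bulk = eta < 1e-3
    outside = eta > 1.0 - 1e-3
    assert np.abs(adhesion_force[bulk]).max() < 1e-6
    assert np.abs(adhesion_force[outside]).max() < 1e-6
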