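"""Physics invariants of the PNP solver.

These checks pin the solver to closed forms and symmetries rather than to
any measured number: the Ohmic limit of an (almost) uniform channel, zero
current and Debye-scaled screening at equilibrium, absence of rectification
without fixed charge, charge-conjugation symmetry, exact discrete current
conservation, concentration positivity, and mesh convergence.
"""

import math

import numpy as np
import pytest

from aptapore.constants import FARADAY, GAS_CONSTANT, TEMPERATURE
from aptapore.errors import PreconditionError
from aptapore.iv import rectification_coefficient
from aptapore.pnp import (AptamerLayer, MeshOptions, PnpSolver, PoreGeometry,
                          SolverOptions, binary_electrolyte, simulate_iv,
                          solve_pnp)


def nernst_einstein_kappa(species):
    return (FARADAY ** 2 / (GAS_CONSTANT * TEMPERATURE)) * sum(
        s.valence ** 2 * s.diffusivity * s.bulk_concentration for s in species)


@pytest.fixture(scope="module")
def charged_solution(pore_geom_module, pbs_binary_module):
    """One converged +0.25 V solve with a charged layer, shared by checks."""
    layer = AptamerLayer(thickness=5.5e-9, volume_charge_density=-1.6e7)
    opts = SolverOptions(mesh=MeshOptions(n_r=64, n_theta=28))
    return solve_pnp(pore_geom_module, layer, pbs_binary_module, 0.25, opts)


@pytest.fixture(scope="module")
def pore_geom_module():
    return PoreGeometry(tip_radius=4.6e-9, half_cone_angle=0.0926,
                        taper_length=5e-6)


@pytest.fixture(scope="module")
def pbs_binary_module():
    return binary_electrolyte(171.5)


class TestOhmicLimit:
    def test_zero_bias_zero_current(self, pore_geom_module, pbs_binary_module,
                                    fast_options):
        sol = solve_pnp(pore_geom_module, None, pbs_binary_module, 0.0,
                        fast_options)
        i_ref = abs(solve_pnp(pore_geom_module, None, pbs_binary_module, 0.1,
                              fast_options).total_current)
        assert abs(sol.total_current) < 1e-6 * i_ref

    def test_near_cylinder_matches_kappa_a_over_l(self):
        """A barely tapering channel reproduces the kappa*A/L conductance."""
        # 200 nm radius, 0.002 rad half-angle over 1 um: radius changes by 1%
        geom = PoreGeometry(tip_radius=200e-9, half_cone_angle=0.002,
                            taper_length=1e-6)
        species = binary_electrolyte(171.5)
        opts = SolverOptions(mesh=MeshOptions(n_r=60, n_theta=16))
        sol = solve_pnp(geom, None, species, 0.05, opts)
        kappa = nernst_einstein_kappa(species)
        r_mean = math.sqrt(geom.tip_radius * geom.base_radius)
        g_closed = kappa * math.pi * r_mean ** 2 / geom.taper_length
        g_model = sol.total_current / 0.05
        assert g_model == pytest.approx(g_closed, rel=0.02)

    def test_uncharged_cone_does_not_rectify(self, pore_geom_module,
                                             pbs_binary_module, fast_options):
        iv = simulate_iv(pore_geom_module, None, pbs_binary_module,
                         [-0.5, 0.0, 0.5], fast_options)
        assert abs(rectification_coefficient(iv)) < 0.01

    def test_doubling_concentration_halves_resistance(self, pore_geom_module,
                                                      fast_options):
        from aptapore.pnp import resistance
        r1 = resistance(pore_geom_module, None, binary_electrolyte(171.5),
                        fast_options)
        r2 = resistance(pore_geom_module, None, binary_electrolyte(343.0),
                        fast_options)
        assert r1 / r2 == pytest.approx(2.0, rel=0.05)


class TestChargedLayer:
    def test_negative_layer_gives_negative_rectification(
            self, pore_geom_module, pbs_binary_module, fast_options):
        layer = AptamerLayer(thickness=5.5e-9, volume_charge_density=-1.6e7)
        iv = simulate_iv(pore_geom_module, layer, pbs_binary_module,
                         [-0.5, 0.0, 0.5], fast_options)
        assert rectification_coefficient(iv) < -0.2

    def test_charge_conjugation_symmetry(self, pore_geom_module,
                                         symmetric_electrolyte, fast_options):
        """Negating the layer charge maps I(V) -> -I(-V) exactly for a
        symmetric binary electrolyte (equal cation/anion diffusivities)."""
        neg = AptamerLayer(thickness=5.5e-9, volume_charge_density=-1.6e7)
        pos = AptamerLayer(thickness=5.5e-9, volume_charge_density=+1.6e7)
        v = [-0.5, -0.25, 0.0, 0.25, 0.5]
        iv_neg = simulate_iv(pore_geom_module, neg, symmetric_electrolyte, v,
                             fast_options)
        iv_pos = simulate_iv(pore_geom_module, pos, symmetric_electrolyte, v,
                             fast_options)
        assert np.allclose(iv_pos.current, -iv_neg.current[::-1], rtol=1e-4)
        r_neg = rectification_coefficient(iv_neg)
        r_pos = rectification_coefficient(iv_pos)
        assert r_pos == pytest.approx(-r_neg, rel=0.05)
        assert r_neg < 0 < r_pos

    def test_current_conservation_through_cross_sections(self, charged_solution):
        assert charged_solution.conservation_error < 0.01  # spec bound
        assert charged_solution.conservation_error < 1e-8  # FV is exact

    def test_concentrations_strictly_positive(self, charged_solution):
        for c in charged_solution.concentrations.values():
            assert c.min() > 0.0

    def test_equilibrium_wall_screening_has_debye_scale(self):
        """At zero bias the wall-adjacent potential decays radially with the
        Debye length (low charge => linearized double layer)."""
        from aptapore.electrokinetics import debye_length
        geom = PoreGeometry(tip_radius=30e-9, half_cone_angle=0.0926,
                            taper_length=2e-6)
        species = binary_electrolyte(10.0)  # lam_D ~ 3 nm: resolvable
        layer = AptamerLayer(thickness=2e-9, volume_charge_density=-2e5,
                             extent=2e-6)
        opts = SolverOptions(mesh=MeshOptions(n_r=70, n_theta=48,
                                              wall_resolution=0.8e-9))
        sol = solve_pnp(geom, layer, species, 0.0, opts)
        lam_expected = debye_length(0.5 * 2 * 10.0 / 1e3) * 1e-9  # m
        # radial potential profile at a mid-taper cross-section
        i = np.searchsorted(sol.r_centers, 0.5 * (sol.r_centers[0] +
                                                  sol.r_centers[-1]))
        r_slice = sol.r_centers[i]
        dist_wall = r_slice * np.sin(geom.half_cone_angle -
                                     sol.theta_centers)
        phi = sol.phi[i, :] - sol.phi[i, 0]
        # fit the exponential tail outside the layer, a few lam_D wide
        sel = (dist_wall > 2e-9 + 0.5 * lam_expected) & \
              (dist_wall < 2e-9 + 2.5 * lam_expected)
        y = np.log(np.abs(phi[sel]))
        slope = np.polyfit(dist_wall[sel], y, 1)[0]
        lam_fit = -1.0 / slope
        assert lam_fit == pytest.approx(lam_expected, rel=0.15)

    def test_zero_bias_current_vanishes_with_charge(self, pore_geom_module,
                                                    pbs_binary_module,
                                                    fast_options):
        layer = AptamerLayer(thickness=5.5e-9, volume_charge_density=-1.6e7)
        sol = solve_pnp(pore_geom_module, layer, pbs_binary_module, 0.0,
                        fast_options)
        assert abs(sol.total_current) < 1e-13


class TestNumerics:
    def test_grid_convergence_under_mesh_halving(self, pore_geom_module,
                                                 pbs_binary_module):
        layer = AptamerLayer(thickness=5.5e-9, volume_charge_density=-1.6e7)
        base = SolverOptions(mesh=MeshOptions(n_r=64, n_theta=28))
        i_coarse = solve_pnp(pore_geom_module, layer, pbs_binary_module, 0.5,
                             base).total_current
        i_fine = solve_pnp(pore_geom_module, layer, pbs_binary_module, 0.5,
                           base.refined(2.0)).total_current
        assert abs(i_fine - i_coarse) / abs(i_fine) < 0.02

    def test_under_resolved_mesh_is_flagged(self, pore_geom_module,
                                            pbs_binary_module):
        opts = SolverOptions(mesh=MeshOptions(n_r=24, n_theta=6,
                                              wall_resolution=5e-9))
        sol = solve_pnp(pore_geom_module, None, pbs_binary_module, 0.1, opts)
        assert any("Debye" in w for w in sol.warnings)

    def test_non_electroneutral_bulk_rejected(self, pore_geom_module):
        from aptapore.pnp import IonSpecies
        bad = [IonSpecies("cat", 1, 1.33e-9, 171.5),
               IonSpecies("an", -1, 2.03e-9, 100.0)]
        with pytest.raises(PreconditionError):
            PnpSolver(pore_geom_module, None, bad)

    def test_bias_beyond_one_volt_rejected(self, pore_geom_module,
                                           pbs_binary_module, fast_options):
        solver = PnpSolver(pore_geom_module, None, pbs_binary_module,
                           fast_options)
        with pytest.raises(PreconditionError):
            solver.solve(1.5)

    def test_node_table_shape(self, charged_solution):
        df = charged_solution.node_table()
        assert {"z_m", "radial_m", "phi_V", "c_cation_mol_m3",
                "c_anion_mol_m3"} <= set(df.columns)
        assert len(df) == charged_solution.phi.size
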