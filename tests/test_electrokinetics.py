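"""Closed-form electrokinetics: ionic strength, Debye, conductivity, Dukhin."""

import math

import pytest

from aptapore.electrokinetics import (PBS_1X, ElectrolyteComposition, Salt,
                                      SurfaceState, aptamer_packing,
                                      bulk_conductivity, current_partition,
                                      debye_length, dukhin_number,
                                      ionic_strength,
                                      surface_charge_from_layer)
from aptapore.errors import PreconditionError
from aptapore.pnp import AptamerLayer, PoreGeometry, binary_electrolyte


class TestIonicStrength:
    def test_one_to_one_salt(self):
        comp = ElectrolyteComposition((Salt("NaCl", 0.1, ((1, 1), (-1, 1))),))
        assert ionic_strength(comp) == pytest.approx(0.100)

    def test_divalent_salt(self):
        comp = ElectrolyteComposition((Salt("Na2HPO4", 0.010, ((1, 2), (-2, 1))),))
        assert ionic_strength(comp) == pytest.approx(0.030)

    def test_full_pbs_recipe(self):
        assert ionic_strength(PBS_1X) == pytest.approx(0.1715, abs=1e-4)

    def test_additive_over_salts(self):
        parts = [ElectrolyteComposition((s,)) for s in PBS_1X.salts]
        assert sum(ionic_strength(p) for p in parts) == pytest.approx(
            ionic_strength(PBS_1X), rel=1e-12)

    def test_non_electroneutral_salt_rejected(self):
        with pytest.raises(PreconditionError):
            Salt("bad", 0.1, ((1, 1), (-2, 1)))


class TestDebyeLength:
    def test_tenth_molar(self):
        # 0.304/sqrt(0.1) nm at 298 K in water
        assert debye_length(0.1) == pytest.approx(0.96, abs=0.01)

    def test_pbs_screening_length(self):
        lam = debye_length(ionic_strength(PBS_1X))
        assert lam == pytest.approx(0.73, abs=0.02)

    def test_square_root_law_exact(self):
        i = 0.05
        assert debye_length(4 * i) == pytest.approx(debye_length(i) / 2, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(PreconditionError):
            debye_length(0.0)


class TestBulkConductivity:
    def test_zero_concentration(self):
        assert bulk_conductivity(binary_electrolyte(0.0)) == 0.0

    def test_nernst_einstein_value(self):
        # (F^2/RT) * 170 * (1.33 + 2.03)e-9 = 2.15 S/m (ideal-solution value)
        kappa = bulk_conductivity(binary_electrolyte(170.0))
        assert kappa == pytest.approx(2.15, abs=0.01)

    def test_linear_in_concentration(self):
        k1 = bulk_conductivity(binary_electrolyte(100.0))
        k3 = bulk_conductivity(binary_electrolyte(300.0))
        assert k3 == pytest.approx(3 * k1, rel=1e-12)


class TestDukhin:
    def test_uncharged_surface(self):
        st = SurfaceState(sigma=0.0, counterion_mobility=5e-8, pore_radius=4.6e-9)
        assert dukhin_number(st, 1.6) == 0.0

    def test_hand_evaluated_value(self):
        st = SurfaceState(sigma=0.1, counterion_mobility=5e-8, pore_radius=4.6e-9)
        assert dukhin_number(st, 1.6) == pytest.approx(0.679, abs=0.01)

    def test_inverse_radius_scaling(self):
        st = SurfaceState(sigma=0.1, counterion_mobility=5e-8, pore_radius=4.6e-9)
        st_half = SurfaceState(sigma=0.1, counterion_mobility=5e-8,
                               pore_radius=2.3e-9)
        assert dukhin_number(st_half, 1.6) == pytest.approx(
            2 * dukhin_number(st, 1.6), rel=1e-12)

    def test_invariant_under_joint_scaling(self):
        st = SurfaceState(sigma=0.1, counterion_mobility=5e-8, pore_radius=4.6e-9)
        st_k = SurfaceState(sigma=0.3, counterion_mobility=5e-8, pore_radius=4.6e-9)
        assert dukhin_number(st_k, 3 * 1.6) == pytest.approx(
            dukhin_number(st, 1.6), rel=1e-12)


class TestSurfaceCharge:
    def test_product_of_density_and_thickness(self):
        layer = AptamerLayer(thickness=5e-9, volume_charge_density=-1e7)
        assert surface_charge_from_layer(layer) == pytest.approx(-0.05)

    def test_zero_charge(self):
        assert surface_charge_from_layer(
            AptamerLayer(thickness=5e-9, volume_charge_density=0.0)) == 0.0

    def test_doubling_thickness_doubles_sigma(self):
        l1 = AptamerLayer(thickness=5e-9, volume_charge_density=-1e7)
        l2 = AptamerLayer(thickness=10e-9, volume_charge_density=-1e7)
        assert surface_charge_from_layer(l2) == pytest.approx(
            2 * surface_charge_from_layer(l1), rel=1e-12)


class TestAptamerPacking:
    def test_footprint_filling_whole_band(self):
        a = 4.6
        assert aptamer_packing(2 * math.pi * a, 2.0, a) == 1

    def test_hand_counted_tiling(self):
        # 2x2 nm footprints on the 2 nm band of a 4.6 nm tip
        assert aptamer_packing(2.0, 2.0, 4.6) == 14

    def test_monotone_in_footprint_area(self):
        counts = [aptamer_packing(w, 2.0, 4.6) for w in (1.0, 2.0, 4.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] >= 2 * counts[1]  # doubling width at least halves

    def test_oversized_footprint_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert aptamer_packing(100.0, 2.0, 4.6) == 0


class TestCurrentPartition:
    def geom(self):
        return PoreGeometry(tip_radius=4.6e-9, half_cone_angle=0.0926)

    def test_zero_thickness_layer(self):
        layer = AptamerLayer(thickness=0.0, volume_charge_density=-1e7)
        part = current_partition(1e-9, layer, self.geom(),
                                 binary_electrolyte(171.5), 0.5)
        assert part.i_excluded == 0.0 and part.i_aptamer == 0.0

    def test_transparent_uncharged_layer(self):
        layer = AptamerLayer(thickness=5e-9, volume_charge_density=0.0,
                             diffusivity_scale=1.0)
        part = current_partition(1e-9, layer, self.geom(),
                                 binary_electrolyte(171.5), 0.5)
        assert part.i_excluded == 0.0 and part.i_aptamer == 0.0

    def test_dopamine_defaults_ordering(self):
        layer = AptamerLayer(thickness=5.5e-9, volume_charge_density=-1.6e7,
                             diffusivity_scale=0.89)
        part = current_partition(1.36e-9, layer, self.geom(),
                                 binary_electrolyte(171.5), 0.5)
        assert part.i_excluded > 0 and part.i_aptamer > 0
        assert part.i_excluded + part.i_aptamer < 1.36e-9
        assert part.variant  # formula variant is always named
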