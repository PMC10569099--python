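"""Closed-form electrokinetic quantities for charged nanopores.

Back-of-the-envelope companions to the full PNP model: ionic strength and
Debye screening length of the electrolyte, Nernst-Einstein bulk conductivity,
the Dukhin number (surface vs bulk conductance in a channel of radius a),
geometric aptamer packing at the tip, and a documented variant of the
excluded/in-layer current partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .constants import (AVOGADRO, BOLTZMANN, ELEMENTARY_CHARGE, FARADAY,
                        GAS_CONSTANT, TEMPERATURE, VACUUM_PERMITTIVITY,
                        WATER_REL_PERMITTIVITY)
from .errors import PreconditionError
from .pnp.model import AptamerLayer, IonSpecies, PoreGeometry

__all__ = [
    "Salt",
    "ElectrolyteComposition",
    "SurfaceState",
    "PBS_1X",
    "ionic_strength",
    "debye_length",
    "bulk_conductivity",
    "dukhin_number",
    "surface_charge_from_layer",
    "aptamer_packing",
    "current_partition",
]


@dataclass(frozen=True)
class Salt:
    """A fully dissociating salt: name, molar concentration, ion list.

    ``ions`` is a sequence of (valence, stoichiometry) pairs; e.g. Na2HPO4 is
    [(+1, 2), (-2, 1)].
    """

    name: str
    concentration: float  # mol/L
    ions: tuple

    def __post_init__(self):
        if self.concentration < 0:
            raise PreconditionError(f"{self.name}: negative concentration")
        net = sum(z * nu for z, nu in self.ions)
        if net != 0:
            raise PreconditionError(f"{self.name}: salt is not electroneutral (net {net})")


@dataclass(frozen=True)
class ElectrolyteComposition:
    salts: tuple
    temperature: float = TEMPERATURE


#: The printed 1x PBS recipe: 137 mM NaCl, 2.7 mM KCl, 10 mM Na2HPO4,
#: 1.8 mM KH2PO4, phosphates taken at their nominal valences.
PBS_1X = ElectrolyteComposition(salts=(
    Salt("NaCl", 0.137, ((+1, 1), (-1, 1))),
    Salt("KCl", 0.0027, ((+1, 1), (-1, 1))),
    Salt("Na2HPO4", 0.010, ((+1, 2), (-2, 1))),
    Salt("KH2PO4", 0.0018, ((+1, 1), (-1, 1))),
))


@dataclass(frozen=True)
class SurfaceState:
    """Equivalent surface description for the Dukhin number."""

    sigma: float  # C/m^2, signed
    counterion_mobility: float  # m^2/(V s)
    pore_radius: float  # m

    def __post_init__(self):
        if self.pore_radius <= 0 or self.counterion_mobility <= 0:
            raise PreconditionError("pore_radius and mobility must be positive")


def ionic_strength(comp: ElectrolyteComposition) -> float:
    """I = 1/2 sum c_i z_i^2 over fully dissociated ions, in mol/L."""
    total = 0.0
    for salt in comp.salts:
        for z, nu in salt.ions:
            total += salt.concentration * nu * z * z
    return 0.5 * total


def debye_length(I: float, T: float = TEMPERATURE) -> float:
    """Debye screening length in nm for ionic strength ``I`` (mol/L).

    lambda_D = sqrt(eps0*eps_r*kB*T / (2*NA*e^2*I*1e3)); in water at 298 K
    this is the familiar 0.304/sqrt(I) nm.
    """
    if I <= 0:
        raise PreconditionError("ionic strength must be positive")
    lam = math.sqrt(VACUUM_PERMITTIVITY * WATER_REL_PERMITTIVITY * BOLTZMANN * T /
                    (2.0 * AVOGADRO * ELEMENTARY_CHARGE ** 2 * I * 1e3))
    return lam * 1e9


def bulk_conductivity(species: Sequence[IonSpecies], T: float = TEMPERATURE) -> float:
    """Nernst-Einstein conductivity kappa = (F^2/RT) sum z^2 D c, in S/m.

    ``c`` in mol/m^3.  Ideal-solution value; measured conductivities of
    physiological saline run ~25% lower (activity effects are out of scope).
    """
    return (FARADAY ** 2 / (GAS_CONSTANT * T)) * sum(
        s.valence ** 2 * s.diffusivity * s.bulk_concentration for s in species)


def dukhin_number(state: SurfaceState, kappa_bulk: float) -> float:
    """Du = |sigma| * mu_counterion / (kappa_bulk * a) (Bikerman form).

    Du > 1 flags surface-conduction dominance in the channel.
    """
    if kappa_bulk <= 0:
        raise PreconditionError("bulk conductivity must be positive")
    return abs(state.sigma) * state.counterion_mobility / (kappa_bulk * state.pore_radius)


def surface_charge_from_layer(layer: AptamerLayer) -> float:
    """Collapse a volumetric wall layer to equivalent surface charge rho*t (C/m^2)."""
    return layer.volume_charge_density * layer.thickness


def aptamer_packing(footprint_width: float, footprint_depth: float,
                    tip_radius: float) -> int:
    """Maximal number of aptamer footprints in a one-footprint-deep tip band.

    The aptamer's MD-derived bounding rectangle (width x depth, nm) is tiled
    on the band of the inner tip wall of depth equal to the footprint depth:
    count = floor(2*pi*a*depth / (width*depth)).  Returns 0 with a warning if
    a single footprint does not fit the band.
    """
    if footprint_width <= 0 or footprint_depth <= 0 or tip_radius <= 0:
        raise PreconditionError("dimensions must be positive")
    band_area = 2.0 * math.pi * tip_radius * footprint_depth
    if footprint_width > 2.0 * math.pi * tip_radius:
        warnings.warn("aptamer footprint exceeds the tip circumference; none fit")
        return 0
    return int(math.floor(band_area / (footprint_width * footprint_depth)))


@dataclass(frozen=True)
class CurrentPartition:
    """Result of :func:`current_partition`, tagged with the formula variant."""

    i_excluded: float
    i_aptamer: float
    variant: str = "access-field-v1"


def current_partition(I_bulk: float, layer: AptamerLayer, geom: PoreGeometry,
                      species: Sequence[IonSpecies], bias: float,
                      T: float = TEMPERATURE) -> CurrentPartition:
    """Partition the measured current into excluded and in-layer parts.

    Documented variant ("access-field-v1"): the layer annulus at the tip
    opening has area A_layer = pi*(a^2 - max(a-t, 0)^2); the current excluded
    by the DNA volume is the bulk current scaled by the annulus fraction and
    the permeability deficit, I_excluded = I_bulk * (A_layer/A_pore) *
    (1 - diffusivity_scale).  The in-layer current is carried by counterions
    at concentration |rho|/F with scaled mobility under the access field
    E = I_bulk / (4*kappa*a^2) of the pore mouth.  The formulas are
    interface-stable so alternative partitions can be swapped in.
    """
    a = geom.tip_radius
    t = layer.thickness
    if t == 0.0:
        return CurrentPartition(0.0, 0.0)
    a_pore = math.pi * a * a
    a_layer = math.pi * (a * a - max(a - t, 0.0) ** 2)
    i_excluded = abs(I_bulk) * (a_layer / a_pore) * (1.0 - layer.diffusivity_scale)

    kappa = bulk_conductivity(species, T)
    cations = [s for s in species if (s.valence > 0) == (layer.volume_charge_density < 0)]
    if not cations:
        raise PreconditionError("no counterion species for the layer charge sign")
    c_tot = sum(s.bulk_concentration for s in cations)
    d_counter = (sum(s.diffusivity * s.bulk_concentration for s in cations) / c_tot
                 if c_tot > 0 else cations[0].diffusivity)
    c_counter = abs(layer.volume_charge_density) / FARADAY  # mol/m^3
    kappa_layer = (FARADAY ** 2 / (GAS_CONSTANT * T)) * d_counter * \
        layer.diffusivity_scale * c_counter
    e_access = abs(I_bulk) / (4.0 * kappa * a * a)
    i_aptamer = kappa_layer * a_layer * e_access
    return CurrentPartition(i_excluded, i_aptamer)
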