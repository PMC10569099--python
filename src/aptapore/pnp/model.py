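"""Domain types for the conical-nanopore PNP model (SI units)."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ..constants import D_CL, D_NA
from ..errors import PreconditionError

__all__ = [
    "PoreGeometry",
    "IonSpecies",
    "AptamerLayer",
    "binary_electrolyte",
    "pbs_like_electrolyte",
    "check_electroneutral",
]


@dataclass(frozen=True)
class PoreGeometry:
    """Axisymmetric conical nanopipette tip.

    tip_radius : m — radius of the pore opening (half the EM-visible diameter).
    half_cone_angle : rad — inner half-angle of the taper; quartz pipettes
        pulled to ~10 nm openings have 5–10 degrees.
    taper_length : m — modelled length of the cone; beyond a few microns the
        taper no longer contributes to the tip-dominated resistance.
    reservoir_radius : m — nominal extent of the bulk baths providing the
        Dirichlet boundary values (documented scale; the reduced domain
        terminates in spherical caps carrying those values).
    """

    tip_radius: float
    half_cone_angle: float
    taper_length: float = 5e-6
    reservoir_radius: float | None = None

    def __post_init__(self):
        if self.tip_radius <= 0 or self.taper_length <= 0:
            raise PreconditionError("geometry lengths must be positive")
        if not (0 < self.half_cone_angle < math.pi / 4):
            raise PreconditionError("half_cone_angle must lie in (0, pi/4)")
        if self.reservoir_radius is None:
            object.__setattr__(self, "reservoir_radius", 20.0 * self.tip_radius)
        elif self.reservoir_radius < 20.0 * self.tip_radius:
            raise PreconditionError("reservoir_radius must be >= 20 x tip_radius")

    @property
    def base_radius(self) -> float:
        """Pore radius at the barrel end of the modelled taper."""
        return self.tip_radius + self.taper_length * math.tan(self.half_cone_angle)

    def wall_radius(self, z: float | np.ndarray):
        """Inner wall radius at axial distance z from the tip."""
        return self.tip_radius + np.tan(self.half_cone_angle) * np.asarray(z)


@dataclass(frozen=True)
class IonSpecies:
    """One mobile ion: valence, diffusivity (m^2/s), bulk conc (mol/m^3)."""

    name: str
    valence: int
    diffusivity: float
    bulk_concentration: float

    def __post_init__(self):
        if self.diffusivity <= 0:
            raise PreconditionError("diffusivity must be positive")
        if self.bulk_concentration < 0:
            raise PreconditionError("concentration must be non-negative")
        if self.valence == 0:
            raise PreconditionError("neutral species carry no current; omit them")


@dataclass(frozen=True)
class AptamerLayer:
    """Ion-permeable charged wall layer standing in for tethered aptamers.

    thickness : m — wall-normal extent.  May exceed the tip radius, in which
        case the layer fills the whole cross-section near the tip (the
        membership test is "distance to wall <= thickness").
    volume_charge_density : C/m^3 — negative for DNA phosphate backbones.
    diffusivity_scale : in (0, 1] — in-layer ion diffusivities are scaled by
        this factor (a denser DNA bundle is a less permeable medium).
    extent : m — length of wall, measured from the tip, that carries the
        layer.  Although the functionalization chemistry coats the whole
        inner wall, only the tip-adjacent charge shapes transport, and the
        strong measured rectification is reproducible in this reduced model
        only with a tip-localized layer; the default covers the final 200 nm
        of the taper.  Set ``extent=math.inf`` to coat the whole wall.
    """

    thickness: float
    volume_charge_density: float
    diffusivity_scale: float = 1.0
    extent: float = 200e-9

    def __post_init__(self):
        if self.thickness < 0:
            raise PreconditionError("thickness must be non-negative")
        if not (0 < self.diffusivity_scale <= 1.0):
            raise PreconditionError("diffusivity_scale must lie in (0, 1]")
        if self.extent <= 0:
            raise PreconditionError("extent must be positive")

    def with_charge(self, rho: float) -> "AptamerLayer":
        return replace(self, volume_charge_density=float(rho))


def check_electroneutral(species: Sequence[IonSpecies], tol: float = 1e-9) -> None:
    """Raise unless the bulk composition is electroneutral (sum z*c = 0)."""
    total = sum(s.valence * s.bulk_concentration for s in species)
    scale = max((abs(s.valence * s.bulk_concentration) for s in species), default=1.0)
    if scale > 0 and abs(total) > tol * scale:
        raise PreconditionError(f"bulk species are not electroneutral (sum z*c = {total:g})")


def binary_electrolyte(concentration: float, d_cation: float = D_NA,
                       d_anion: float = D_CL) -> list[IonSpecies]:
    """Symmetric 1:1 electrolyte at ``concentration`` mol/m^3 (NaCl-like).

    1x PBS is reduced to this with concentration equal to its ionic strength
    (~171.5 mol/m^3): bulk conductivity, the controlling parameter, is then
    matched without carrying four salts through the solver.
    """
    return [
        IonSpecies("cation", +1, d_cation, float(concentration)),
        IonSpecies("anion", -1, d_anion, float(concentration)),
    ]


def pbs_like_electrolyte() -> list[IonSpecies]:
    """The default binary reduction of 1x PBS (ionic strength 171.5 mol/m^3)."""
    return binary_electrolyte(171.5)
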