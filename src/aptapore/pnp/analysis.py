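"""Higher-level PNP experiments: I-V sweeps, resistance, sizing, sensing.

These functions wrap :class:`~aptapore.pnp.solver.PnpSolver` into the
quantities an experimentalist actually quotes: simulated I-V curves and
their rectification, low-bias slope resistance, pore diameter inferred from
a measured resistance, the free->bound aptamer-layer bookkeeping derived
from MD thicknesses, the binding-induced percent current change, and the
layer-thickness sweep that locates the optimal aptamer/pore configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ..constants import V_EVAL_DEFAULT
from ..errors import PreconditionError, RangeError
from ..iv import IVCurve, rectification_coefficient, sensor_response
from .model import AptamerLayer, IonSpecies, PoreGeometry
from .solver import PnpSolver, SolverOptions

__all__ = [
    "simulate_iv",
    "resistance",
    "access_resistance",
    "pore_size_from_resistance",
    "layer_from_md",
    "binding_response",
    "optimal_layer_thickness",
    "calibrate_charge_density",
    "calibrate_half_cone_angle",
]


def simulate_iv(geom: PoreGeometry, layer: AptamerLayer | None,
                species: Sequence[IonSpecies], voltages: Sequence[float],
                options: SolverOptions | None = None,
                label: str = "pnp model") -> IVCurve:
    """Solve the PNP model at each bias and assemble the model I-V curve.

    Biases are solved in continuation order (ascending magnitude per sign)
    so every solve warm-starts from its neighbour; the returned curve is
    sorted by voltage.
    """
    v = np.asarray(sorted(float(x) for x in voltages))
    if v.size < 2:
        raise PreconditionError("need at least two voltages for a curve")
    solver = PnpSolver(geom, layer, species, options)
    currents = {}
    for branch in (sorted(x for x in v if x >= 0), sorted((x for x in v if x < 0), key=abs)):
        for b in branch:
            currents[b] = solver.solve(b).total_current
    return IVCurve(v, np.array([currents[x] for x in v]), label=label)


def _nernst_einstein_kappa(species: Sequence[IonSpecies], temperature: float) -> float:
    from ..constants import FARADAY, GAS_CONSTANT
    return (FARADAY ** 2 / (GAS_CONSTANT * temperature)) * sum(
        s.valence ** 2 * s.diffusivity * s.bulk_concentration for s in species)


def access_resistance(geom: PoreGeometry, species: Sequence[IonSpecies],
                      temperature: float | None = None) -> float:
    """Series access (spreading) resistance of the bath, 1/(4 kappa a), ohms.

    The reduced solver domain ends at the pore mouth; this is the classical
    correction for the converging field in the unmeshed bath half-space.
    """
    from ..constants import TEMPERATURE
    kappa = _nernst_einstein_kappa(species, temperature or TEMPERATURE)
    return 1.0 / (4.0 * kappa * geom.tip_radius)


def resistance(geom: PoreGeometry, layer: AptamerLayer | None,
               species: Sequence[IonSpecies],
               options: SolverOptions | None = None,
               probe_bias: float = 0.01,
               include_access: bool = False) -> float:
    """Low-bias slope resistance from solves at +-``probe_bias`` volts.

    ``include_access=True`` adds the analytic 1/(4 kappa a) bath correction
    (appropriate when comparing with a measured pipette resistance; left off
    for closed-form Ohmic checks on the meshed domain alone).
    """
    solver = PnpSolver(geom, layer, species, options)
    i_pos = solver.solve(+probe_bias).total_current
    i_neg = solver.solve(-probe_bias).total_current
    if i_pos == i_neg:
        raise PreconditionError("degenerate I-V slope; check the configuration")
    r = 2.0 * probe_bias / (i_pos - i_neg)
    if include_access:
        r += access_resistance(geom, species,
                               (options or SolverOptions()).temperature)
    return r


def pore_size_from_resistance(R_target: float, geom_template: PoreGeometry,
                              species: Sequence[IonSpecies],
                              options: SolverOptions | None = None,
                              include_access: bool = True,
                              rtol: float = 5e-3,
                              bracket: tuple = (0.25, 4.0)) -> float:
    """Tip *diameter* (m) whose uncharged-pore resistance matches ``R_target``.

    Bisection on the tip radius of ``geom_template`` (walls uncharged, cone
    angle and taper fixed) until the simulated low-bias resistance matches
    within ``rtol``.  Raises :class:`RangeError` if the bracket
    ``(lo*radius, hi*radius)`` does not straddle the target.
    """
    if R_target <= 0:
        raise PreconditionError("target resistance must be positive")
    a0 = geom_template.tip_radius

    def f(a: float) -> float:
        geom = replace(geom_template, tip_radius=a, reservoir_radius=None)
        return math.log(resistance(geom, None, species, options,
                                   include_access=include_access) / R_target)

    lo, hi = bracket[0] * a0, bracket[1] * a0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise RangeError(
            f"resistance bracket [{math.exp(f_hi) * R_target:.3g}, "
            f"{math.exp(f_lo) * R_target:.3g}] ohm does not contain the target")
    a = brentq(f, lo, hi, rtol=rtol)
    return 2.0 * a


def layer_from_md(thickness_free: float, thickness_bound: float,
                  free_layer: AptamerLayer) -> tuple[AptamerLayer, float]:
    """Bound-state layer from MD thicknesses, conserving total charge.

    The layer compresses (dopamine) or expands (serotonin) from
    ``thickness_free`` to ``thickness_bound``; the number of charges is
    unchanged, so the volume charge density scales by t_free/t_bound, and the
    in-layer ion diffusivity scales proportionally the other way (a denser
    bundle is less permeable), clipped to the physical ceiling of 1.

    Returns ``(bound_layer, fractional_density_change)`` where the reported
    fraction follows the (t_free - t_bound)/t_free convention: 5.5 -> 4.9 nm
    reads as a ~11 % density increase.
    """
    if thickness_free <= 0 or thickness_bound <= 0:
        raise PreconditionError("thicknesses must be positive")
    ratio = thickness_free / thickness_bound
    new_scale = free_layer.diffusivity_scale / ratio
    if new_scale > 1.0:
        warnings.warn("diffusivity_scale clipped to 1 for the expanded layer")
        new_scale = 1.0
    bound = replace(
        free_layer,
        thickness=float(thickness_bound),
        volume_charge_density=free_layer.volume_charge_density * ratio,
        diffusivity_scale=new_scale,
    )
    frac = (thickness_free - thickness_bound) / thickness_free
    return bound, frac


def binding_response(geom: PoreGeometry, free_layer: AptamerLayer,
                     bound_layer: AptamerLayer, species: Sequence[IonSpecies],
                     v_eval: float = V_EVAL_DEFAULT,
                     options: SolverOptions | None = None) -> float:
    """Percent current change at +``v_eval`` between free and bound states.

    Negative = current decrease upon binding (the dopamine direction).
    """
    i_free = PnpSolver(geom, free_layer, species, options).solve(+abs(v_eval))
    i_bound = PnpSolver(geom, bound_layer, species, options).solve(+abs(v_eval))
    if i_free.total_current == 0.0:
        raise PreconditionError("zero free-state current; response undefined")
    return 100.0 * (i_bound.total_current - i_free.total_current) / \
        abs(i_free.total_current)


def optimal_layer_thickness(geom: PoreGeometry, compression_fraction: float,
                            thickness_grid: Sequence[float],
                            species: Sequence[IonSpecies],
                            v_eval: float = V_EVAL_DEFAULT,
                            charge_density: float = -2e7,
                            diffusivity_scale: float = 1.0,
                            extent: float = 200e-9,
                            options: SolverOptions | None = None,
                            return_responses: bool = False):
    """Initial layer thickness maximizing |binding response| on this pore.

    Every grid thickness t gets the same free-state volume charge density and
    the same fractional compression t -> t*(1 - compression_fraction) with
    charge-conserving density/diffusivity scaling; the grid argmax of the
    absolute percent current change at +``v_eval`` is returned (ties broken
    toward the thinner layer).  An interior maximum is expected: thin layers
    barely perturb the pore, layers much thicker than the tip radius change
    little upon compression.
    """
    grid = [float(t) for t in thickness_grid]
    if not grid:
        raise PreconditionError("empty thickness grid")
    if not (0.0 < compression_fraction < 1.0):
        raise PreconditionError("compression_fraction must lie in (0, 1)")
    responses = []
    for t in grid:
        free = AptamerLayer(thickness=t, volume_charge_density=charge_density,
                            diffusivity_scale=diffusivity_scale, extent=extent)
        bound, _ = layer_from_md(t, t * (1.0 - compression_fraction), free)
        responses.append(binding_response(geom, free, bound, species,
                                          v_eval=v_eval, options=options))
    resp = np.array(responses)
    if np.all(resp == 0.0):
        warnings.warn("all responses are zero; the optimum is degenerate")
    order = np.lexsort((grid, -np.abs(resp)))  # max |response|, then smaller t
    best = float(grid[int(order[0])])
    if return_responses:
        return best, dict(zip(grid, responses))
    return best


def calibrate_charge_density(geom: PoreGeometry, thickness: float,
                             species: Sequence[IonSpecies],
                             target_r: float = -0.5,
                             v_eval: float = V_EVAL_DEFAULT,
                             diffusivity_scale: float = 1.0,
                             extent: float = 200e-9,
                             options: SolverOptions | None = None,
                             log10_bounds: tuple = (5.0, 8.5),
                             rtol: float = 5e-3) -> float:
    """Volume charge density (C/m^3) reproducing a measured rectification.

    Root-finds |rho| on a log10 grid so that the simulated rectification
    coefficient of the free-state pore at +-``v_eval`` equals ``target_r``
    (e.g. the -0.5 of the dopamine-aptamer sensor).  The sign of the charge
    follows the sign of ``target_r`` (DNA layers are negative).
    """
    if target_r == 0.0:
        return 0.0
    sign = -1.0 if target_r < 0 else 1.0

    def r_of(x: float) -> float:
        layer = AptamerLayer(thickness=thickness,
                             volume_charge_density=sign * 10.0 ** x,
                             diffusivity_scale=diffusivity_scale, extent=extent)
        iv = simulate_iv(geom, layer, species, [-v_eval, -v_eval / 2, 0.0,
                                                v_eval / 2, v_eval],
                         options=options)
        return rectification_coefficient(iv, v_eval)

    lo, hi = log10_bounds
    f_lo = r_of(lo) - target_r
    f_hi = r_of(hi) - target_r
    if f_lo * f_hi > 0:
        raise RangeError(
            f"target r={target_r:g} not bracketed by charge densities "
            f"1e{lo:g}..1e{hi:g} C/m^3 (r spans {f_lo + target_r:.3g}.."
            f"{f_hi + target_r:.3g})")
    x = brentq(lambda t: r_of(t) - target_r, lo, hi, xtol=5e-3, rtol=rtol)
    return sign * 10.0 ** x


def calibrate_half_cone_angle(R_target: float, tip_radius: float,
                              species: Sequence[IonSpecies],
                              taper_length: float = 5e-6,
                              options: SolverOptions | None = None,
                              include_access: bool = True,
                              bounds: tuple = (0.01, 0.6)) -> float:
    """Half-cone angle (rad) at which a given tip radius shows ``R_target``.

    The EM-derived taper angle of the study's pipettes is not published; this
    helper pins it to the measured resistance instead (e.g. 367 Mohm for a
    9.2 nm opening in PBS) so geometry stays a config parameter, not a
    hard-coded constant.
    """

    def f(angle: float) -> float:
        geom = PoreGeometry(tip_radius=tip_radius, half_cone_angle=angle,
                            taper_length=taper_length)
        return math.log(resistance(geom, None, species, options,
                                   include_access=include_access) / R_target)

    f_lo, f_hi = f(bounds[0]), f(bounds[1])
    if f_lo * f_hi > 0:
        raise RangeError("target resistance not reachable within the angle bounds")
    return brentq(f, bounds[0], bounds[1], rtol=1e-3)
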