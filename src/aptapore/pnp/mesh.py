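"""Structured axisymmetric mesh for the conical pore, in spherical shells.

A cone of half-angle theta is the natural domain of spherical coordinates
centred on its apex: the pore interior is {R_tip <= R <= R_base,
0 <= theta <= half_angle} and the inner wall is the coordinate surface
theta = half_angle, so a structured (R, theta) grid is orthogonal, walls and
axis are single grid lines, and two-point flux finite volumes are consistent.
The tip cap R = R_tip (spherical, radius a/sin(theta_c) from the apex) and
the barrel cap R = R_base carry the bulk Dirichlet values.

Grading: cells shrink geometrically toward the tip in R and toward the wall
in theta, so the charged layer and the screening cloud at the wall are
resolved where they matter (the final ~200 nm of the taper) without meshing
the whole 5 um taper at Debye resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from ..errors import PreconditionError
from .model import AptamerLayer, PoreGeometry

__all__ = ["MeshOptions", "ConeMesh", "build_mesh"]


@dataclass(frozen=True)
class MeshOptions:
    """Resolution knobs for :func:`build_mesh`.

    n_r, n_theta : cell counts in the radial (axial-like) and polar
        (wall-normal-like) directions.
    dr_tip : m — radial cell size at the tip cap (None: tip_radius / 5).
    wall_resolution : m — physical wall-normal spacing of the first cell off
        the wall, enforced at the far end of the charged region where the
        constraint is most severe (None: tip_radius / 8; the solver warns if
        this exceeds a third of the Debye length).
    """

    n_r: int = 90
    n_theta: int = 36
    dr_tip: float | None = None
    wall_resolution: float | None = None

    def refined(self, factor: float = 2.0) -> "MeshOptions":
        """Mesh with all spacings divided by ``factor`` (for convergence tests)."""
        return replace(
            self,
            n_r=int(round(self.n_r * factor)),
            n_theta=int(round(self.n_theta * factor)),
            dr_tip=None if self.dr_tip is None else self.dr_tip / factor,
            wall_resolution=(None if self.wall_resolution is None
                             else self.wall_resolution / factor),
        )


def _geometric_edges(total: float, n: int, d0: float) -> np.ndarray:
    """Edges of n cells spanning ``total`` with first cell ``d0``, geometric."""
    if n * d0 >= total:
        return np.linspace(0.0, total, n + 1)

    def f(g):
        return d0 * (g ** n - 1.0) / (g - 1.0) - total

    g = brentq(f, 1.0 + 1e-12, 4.0, xtol=1e-14)
    steps = d0 * g ** np.arange(n)
    edges = np.concatenate(([0.0], np.cumsum(steps)))
    edges[-1] = total
    return edges


class ConeMesh:
    """Geometry arrays of the (R, theta) grid; all lengths in metres.

    Flattened cell index p = i * n_theta + j with i the R index (0 at the
    tip) and j the theta index (0 on the axis, n_theta-1 at the wall).
    """

    def __init__(self, geom: PoreGeometry, opts: MeshOptions):
        theta_c = geom.half_cone_angle
        r_tip = geom.tip_radius / math.sin(theta_c)
        r_base = r_tip + geom.taper_length
        dr0 = opts.dr_tip if opts.dr_tip is not None else geom.tip_radius / 5.0
        dth_wall_ref = (opts.wall_resolution if opts.wall_resolution is not None
                        else geom.tip_radius / 8.0)

        self.geom = geom
        self.opts = opts
        self.theta_c = theta_c
        self.n_r, self.n_th = opts.n_r, opts.n_theta

        self.r_edges = r_tip + _geometric_edges(r_base - r_tip, opts.n_r, dr0)
        self.r_cent = 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

        # wall-normal spacing constraint applies at the far end of the tip
        # region (largest R where fine structure exists)
        r_ref = min(r_tip + 250e-9, r_base)
        dth_wall = dth_wall_ref / r_ref
        th_from_wall = _geometric_edges(theta_c, opts.n_theta, dth_wall)
        self.th_edges = theta_c - th_from_wall[::-1]
        self.th_edges[0] = 0.0
        self.th_cent = 0.5 * (self.th_edges[:-1] + self.th_edges[1:])
        self.wall_spacing = dth_wall * r_ref  # physical first-cell height

        # volumes and face areas (full 2*pi azimuthal revolution)
        cos_diff = np.cos(self.th_edges[:-1]) - np.cos(self.th_edges[1:])  # (n_th,)
        r3_diff = self.r_edges[1:] ** 3 - self.r_edges[:-1] ** 3  # (n_r,)
        self.volume = (2.0 * math.pi / 3.0) * np.outer(r3_diff, cos_diff)
        #: area of the spherical face at r_edges[i] bounding theta cell j
        self.area_r = 2.0 * math.pi * np.outer(self.r_edges ** 2, cos_diff)
        #: area of the conical face at th_edges[j] within radial cell i
        r2_diff = self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2
        self.area_th = math.pi * np.outer(r2_diff, np.sin(self.th_edges))

        # centre-to-centre distances
        self.dist_r = np.diff(self.r_cent)  # (n_r-1,)
        self.dist_r_tip = self.r_cent[0] - self.r_edges[0]
        self.dist_r_base = self.r_edges[-1] - self.r_cent[-1]
        self.dist_th = np.outer(self.r_cent, np.diff(self.th_cent))  # (n_r, n_th-1)

    @property
    def shape(self) -> tuple:
        return (self.n_r, self.n_th)

    @property
    def n_cells(self) -> int:
        return self.n_r * self.n_th

    def wall_distance(self) -> np.ndarray:
        """Wall-normal distance of each cell centre, shape (n_r, n_th)."""
        return np.outer(self.r_cent, np.ones(self.n_th)) * \
            np.sin(self.theta_c - self.th_cent)[None, :]

    def tip_distance(self) -> np.ndarray:
        """Distance of each cell centre from the tip cap, shape (n_r, n_th)."""
        return np.broadcast_to((self.r_cent - self.r_edges[0])[:, None],
                               (self.n_r, self.n_th)).copy()

    def layer_mask(self, layer: AptamerLayer | None) -> np.ndarray:
        """Boolean mask of cells inside the aptamer layer.

        Membership is "within ``layer.thickness`` of the wall and within
        ``layer.extent`` of the tip"; where the layer is thicker than the
        local pore radius it fills the entire cross-section.
        """
        if layer is None or layer.thickness == 0.0:
            return np.zeros(self.shape, dtype=bool)
        return (self.wall_distance() <= layer.thickness) & \
            (self.tip_distance() <= layer.extent)


def build_mesh(geom: PoreGeometry, opts: MeshOptions | None = None) -> ConeMesh:
    opts = opts or MeshOptions()
    if opts.n_r < 4 or opts.n_theta < 4:
        raise PreconditionError("mesh needs at least 4 cells per direction")
    return ConeMesh(geom, opts)
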