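"""Steady-state Poisson-Nernst-Planck solver on the conical-pore mesh.

Model
-----
Coupled electrostatics and ion transport on the axisymmetric cone:

    -div(eps grad phi) = F sum_i z_i c_i + rho_layer(x)
    div( -D_i(x) grad c_i - (z_i F / RT) D_i(x) c_i grad phi ) = 0

with ``rho_layer`` the fixed aptamer charge density inside the wall layer and
``D_i`` scaled down inside it.  Bulk Dirichlet values (concentrations and
potential) are imposed on the spherical caps: the tip cap is the grounded
bath, the barrel cap carries the applied bias.  Walls and axis are zero-flux
and zero normal field.

Numerics
--------
Two-point-flux finite volumes on the orthogonal (R, theta) grid;
Scharfetter-Gummel exponential fitting for the ion fluxes (M-matrix, hence
strictly positive concentrations); Gummel outer iteration in which the
Poisson step is solved with Newton on the Boltzmann-damped charge
``c_i * exp(-z_i dphi / Vt)`` — the classic stabilization that makes the
fixed point robust at biases of tens of thermal voltages.  Applied bias is
ramped in steps, re-using the previous fields, so a 0.5 V solve is a short
homotopy from equilibrium.  Convergence is declared on the joint criterion
"max potential update < phi_tol and relative current change < current_tol".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..constants import (AVOGADRO, BOLTZMANN, ELEMENTARY_CHARGE, FARADAY,
                         GAS_CONSTANT, TEMPERATURE, VACUUM_PERMITTIVITY,
                         WATER_REL_PERMITTIVITY)
from ..errors import ConvergenceError, PreconditionError
from .mesh import ConeMesh, MeshOptions, build_mesh
from .model import AptamerLayer, IonSpecies, PoreGeometry, check_electroneutral

__all__ = ["SolverOptions", "PnpSolution", "PnpSolver", "solve_pnp"]


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls of the PNP solve."""

    mesh: MeshOptions = field(default_factory=MeshOptions)
    temperature: float = TEMPERATURE
    rel_permittivity: float = WATER_REL_PERMITTIVITY
    max_outer: int = 500
    phi_tol: float = 1e-7  # V, max Gummel update
    current_tol: float = 1e-6  # relative current change between iterations
    current_floor: float = 1e-14  # A, below this the current criterion is waived
    newton_tol: float = 1e-9  # V, inner Poisson-Newton update
    max_newton: int = 30
    bias_step: float = 0.1  # V, continuation step
    relax: float = 1.0  # under-relaxation of the potential update

    def refined(self, factor: float = 2.0) -> "SolverOptions":
        return replace(self, mesh=self.mesh.refined(factor))


@dataclass
class PnpSolution:
    """Converged fields and diagnostics of one bias point.

    ``phi`` and each concentration field have shape (n_r, n_theta); use
    :meth:`node_table` for a flat delimited-text-friendly view.
    """

    r_centers: np.ndarray  # m, distance from the cone apex
    theta_centers: np.ndarray  # rad, 0 on the axis
    phi: np.ndarray  # V
    concentrations: dict  # name -> mol/m^3
    total_current: float  # A, positive = conventional current into the bath at positive bias
    bias: float  # V
    iterations: int
    residual: float
    current_profile: np.ndarray  # A at each radial face level
    converged: bool = True
    warnings: list = field(default_factory=list)

    @property
    def conservation_error(self) -> float:
        """Relative spread of the current across axial cross-sections."""
        prof = self.current_profile
        scale = max(abs(prof).max(), 1e-300)
        return float((prof.max() - prof.min()) / scale)

    def node_table(self) -> pd.DataFrame:
        """Flat per-cell table: position (m), potential (V), concentrations (mol/m^3)."""
        rr, tt = np.meshgrid(self.r_centers, self.theta_centers, indexing="ij")
        data = {
            "z_m": (rr * np.cos(tt)).ravel(),
            "radial_m": (rr * np.sin(tt)).ravel(),
            "phi_V": self.phi.ravel(),
        }
        for name, c in self.concentrations.items():
            data[f"c_{name}_mol_m3"] = c.ravel()
        return pd.DataFrame(data)


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), stable through x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - 0.5 * x[small]
    xs = np.clip(x[~small], -500.0, 500.0)
    out[~small] = xs / np.expm1(xs)
    return out


class PnpSolver:
    """Assembles and solves the PNP system for one pore configuration.

    Re-usable across biases: :meth:`solve` ramps from the last converged
    state, which makes I-V sweeps and calibration loops cheap.
    """

    def __init__(self, geom: PoreGeometry, layer: AptamerLayer | None,
                 species: Sequence[IonSpecies],
                 options: SolverOptions | None = None):
        if not species:
            raise PreconditionError("at least one ion species is required")
        check_electroneutral(species)
        self.options = options or SolverOptions()
        self.geom = geom
        self.layer = layer
        self.species = list(species)
        self.mesh: ConeMesh = build_mesh(geom, self.options.mesh)
        self.vt = GAS_CONSTANT * self.options.temperature / FARADAY
        self.eps = VACUUM_PERMITTIVITY * self.options.rel_permittivity

        m = self.mesh
        self._mask = m.layer_mask(layer)
        self.rho_fixed = np.where(
            self._mask, 0.0 if layer is None else layer.volume_charge_density, 0.0)
        scale = 1.0 if layer is None else layer.diffusivity_scale
        self._dscale = np.where(self._mask, scale, 1.0)

        self._build_faces()
        self._poisson_matrix()
        self._mesh_warnings = []
        lam = self._debye_length()
        if m.wall_spacing > lam / 3.0:
            self._mesh_warnings.append(
                f"wall-normal spacing {m.wall_spacing * 1e9:.3g} nm exceeds a third of "
                f"the Debye length {lam * 1e9:.3g} nm; double layers are under-resolved")
        # warm-start state
        self._phi = np.zeros(m.n_cells)
        self._conc = {s.name: np.full(m.n_cells, s.bulk_concentration)
                      for s in self.species}
        self._bias = 0.0
        self._equilibrated = False

    # -- geometry-dependent assembly ------------------------------------

    def _debye_length(self) -> float:
        ionic = 0.5 * sum(s.valence ** 2 * s.bulk_concentration for s in self.species)
        if ionic <= 0:
            return math.inf
        return math.sqrt(self.eps * GAS_CONSTANT * self.options.temperature /
                         (2.0 * FARADAY ** 2 * ionic))

    def _build_faces(self):
        """Face lists: (cell P, cell N or -1 for Dirichlet, area/dist, D scale)."""
        m = self.mesh
        n_r, n_th = m.shape
        idx = np.arange(m.n_cells).reshape(n_r, n_th)

        p_list, n_list, geo_list = [], [], []
        # radial interior faces
        P = idx[:-1, :].ravel()
        N = idx[1:, :].ravel()
        geo = (m.area_r[1:-1, :] / m.dist_r[:, None]).ravel()
        p_list.append(P); n_list.append(N); geo_list.append(geo)
        # polar interior faces
        P2 = idx[:, :-1].ravel()
        N2 = idx[:, 1:].ravel()
        geo2 = (m.area_th[:, 1:-1] / m.dist_th).ravel()
        p_list.append(P2); n_list.append(N2); geo_list.append(geo2)

        self.face_p = np.concatenate(p_list)
        self.face_n = np.concatenate(n_list)
        self.face_geo = np.concatenate(geo_list)  # area / distance
        dsf = self._dscale.ravel()
        self.face_dscale = 2.0 * dsf[self.face_p] * dsf[self.face_n] / (
            dsf[self.face_p] + dsf[self.face_n])  # harmonic mean across the layer edge

        # Dirichlet faces: tip cap (bath, phi=0) and base cap (phi=bias)
        self.tip_cells = idx[0, :]
        self.base_cells = idx[-1, :]
        self.tip_geo = m.area_r[0, :] / m.dist_r_tip
        self.base_geo = m.area_r[-1, :] / m.dist_r_base
        self.tip_dscale = dsf[self.tip_cells]
        self.base_dscale = dsf[self.base_cells]

        # radial faces grouped by level, for the current profile
        self._radial_faces = slice(0, (n_r - 1) * n_th)

    def _poisson_matrix(self):
        n = self.mesh.n_cells
        g = self.eps * self.face_geo
        rows = np.concatenate([self.face_p, self.face_n, self.face_p, self.face_n])
        cols = np.concatenate([self.face_p, self.face_n, self.face_n, self.face_p])
        vals = np.concatenate([g, g, -g, -g])
        diag_b = np.zeros(n)
        np.add.at(diag_b, self.tip_cells, self.eps * self.tip_geo)
        np.add.at(diag_b, self.base_cells, self.eps * self.base_geo)
        L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        self._L = L + sp.diags(diag_b)
        self._dirichlet_conduct = diag_b  # times phi_bc gives the rhs term
        # unit Laplace (ohmic) profile: phi for 1 V at the base, uncharged
        # medium; used to seed each bias step with the correct far field,
        # which the Boltzmann-damped Poisson step then preserves exactly in
        # electroneutral regions.
        rhs_unit = np.zeros(n)
        rhs_unit[self.base_cells] = self.eps * self.base_geo
        self._laplace_unit = spla.spsolve(self._L.tocsc(), rhs_unit)

    # -- physics steps ---------------------------------------------------

    def _poisson_newton(self, phi, conc, bias):
        """Newton solve of the Boltzmann-damped Poisson equation."""
        m = self.mesh
        vol = m.volume.ravel()
        rho_f = self.rho_fixed.ravel()
        phi_bc = np.zeros(m.n_cells)
        phi_bc[self.base_cells] = bias
        rhs_dir = self._dirichlet_conduct * phi_bc

        phi_ref = phi.copy()
        z = np.array([s.valence for s in self.species], dtype=float)
        c_ref = np.stack([conc[s.name] for s in self.species])

        for _ in range(self.options.max_newton):
            dphi = np.clip((phi - phi_ref) / self.vt, -60.0, 60.0)
            boltz = np.exp(-z[:, None] * dphi[None, :])
            rho_mob = FARADAY * np.sum(z[:, None] * c_ref * boltz, axis=0)
            q = vol * (rho_mob + rho_f)
            resid = self._L @ phi - rhs_dir - q
            dq = vol * (FARADAY / self.vt) * np.sum(
                z[:, None] ** 2 * c_ref * boltz, axis=0)
            J = self._L + sp.diags(dq)
            delta = spla.spsolve(J.tocsc(), -resid)
            step = np.clip(delta, -10.0 * self.vt, 10.0 * self.vt)
            phi = phi + step
            if np.abs(step).max() < self.options.newton_tol:
                break
        return phi

    def _transport_solve(self, phi, bias):
        """Scharfetter-Gummel solve of each species' continuity equation."""
        m = self.mesh
        n = m.n_cells
        conc = {}
        phi_tip, phi_base = 0.0, bias
        for s in self.species:
            z = s.valence
            # SG flux from P to N: J = (D/d)[B(u) c_P - B(-u) c_N],
            # u = z (phi_N - phi_P) / Vt
            u = z * (phi[self.face_n] - phi[self.face_p]) / self.vt
            t = s.diffusivity * self.face_dscale * self.face_geo
            b_m = _bernoulli(-u)
            b_p = _bernoulli(u)
            rows = np.concatenate([self.face_p, self.face_p,
                                   self.face_n, self.face_n])
            cols = np.concatenate([self.face_p, self.face_n,
                                   self.face_n, self.face_p])
            vals = np.concatenate([t * b_p, -t * b_m, t * b_m, -t * b_p])
            diag_b = np.zeros(n)
            rhs = np.zeros(n)
            for cells, geo, dsc, phi_b in (
                    (self.tip_cells, self.tip_geo, self.tip_dscale, phi_tip),
                    (self.base_cells, self.base_geo, self.base_dscale, phi_base)):
                tb = s.diffusivity * dsc * geo
                ub = z * (phi_b - phi[cells]) / self.vt
                np.add.at(diag_b, cells, tb * _bernoulli(ub))
                np.add.at(rhs, cells, tb * _bernoulli(-ub) * s.bulk_concentration)
            A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr() \
                + sp.diags(diag_b)
            conc[s.name] = spla.spsolve(A.tocsc(), rhs)
        return conc

    def _current_profile(self, phi, conc, bias) -> np.ndarray:
        """Total ionic current through every radial face level (A).

        Positive current = conventional current flowing from the biased
        barrel reservoir through the tip into the bath.
        """
        m = self.mesh
        n_r, n_th = m.shape
        prof = np.zeros(n_r + 1)
        for s in self.species:
            z = s.valence
            # interior radial faces
            P = np.arange(m.n_cells).reshape(n_r, n_th)[:-1, :]
            N = np.arange(m.n_cells).reshape(n_r, n_th)[1:, :]
            u = z * (phi[N.ravel()] - phi[P.ravel()]) / self.vt
            dsf = self._dscale.ravel()
            dsc = 2.0 * dsf[P.ravel()] * dsf[N.ravel()] / (dsf[P.ravel()] + dsf[N.ravel()])
            t = s.diffusivity * dsc * (m.area_r[1:-1, :] / m.dist_r[:, None]).ravel()
            j = t * (_bernoulli(u) * conc[s.name][P.ravel()] -
                     _bernoulli(-u) * conc[s.name][N.ravel()])
            prof[1:-1] += FARADAY * z * j.reshape(n_r - 1, n_th).sum(axis=1)
            # boundary faces
            for lev, cells, geo, dsc_b, phi_b, outward in (
                    (0, self.tip_cells, self.tip_geo, self.tip_dscale, 0.0, -1.0),
                    (n_r, self.base_cells, self.base_geo, self.base_dscale, bias, +1.0)):
                tb = s.diffusivity * dsc_b * geo
                ub = z * (phi_b - phi[cells]) / self.vt
                j_out = tb * (_bernoulli(ub) * conc[s.name][cells] -
                              _bernoulli(-ub) * s.bulk_concentration)
                # j_out is flux out of the cell; convert to flux in +R direction
                prof[lev] += FARADAY * z * float(np.sum(outward * j_out))
        return -prof  # +R points bath -> barrel; report barrel -> bath as positive

    # -- outer iteration -------------------------------------------------

    def _gummel(self, bias, phi, conc):
        opts = self.options
        i_old = None
        history = []
        relax = opts.relax
        for it in range(1, opts.max_outer + 1):
            phi_new = self._poisson_newton(phi, conc, bias)
            if relax != 1.0:
                phi_new = phi + relax * (phi_new - phi)
            conc = self._transport_solve(phi_new, bias)
            prof = self._current_profile(phi_new, conc, bias)
            i_new = float(prof[0])
            dphi = float(np.abs(phi_new - phi).max())
            if i_old is None:
                di_rel = math.inf
            else:
                di_rel = abs(i_new - i_old) / max(abs(i_new), opts.current_floor)
            history.append((dphi, di_rel))
            phi = phi_new
            current_ok = di_rel < opts.current_tol or abs(i_new) < opts.current_floor
            if dphi < opts.phi_tol and current_ok:
                return phi, conc, prof, it, max(dphi, 0.0)
            i_old = i_new
        raise ConvergenceError(
            f"Gummel iteration did not converge in {opts.max_outer} steps at "
            f"bias {bias:g} V (last dphi={history[-1][0]:.3g} V, "
            f"dI/I={history[-1][1]:.3g})", residual_history=history)

    def solve(self, bias: float) -> PnpSolution:
        """Converged solution at ``bias`` volts (ramped from the last state)."""
        if abs(bias) > 1.0:
            raise PreconditionError("|bias| must be <= 1 V")
        opts = self.options
        # restart the homotopy if the sign flipped or we jumped backwards
        if not self._equilibrated or self._bias * bias < 0 or \
                abs(bias) < abs(self._bias) - 1e-12:
            self._phi = np.zeros(self.mesh.n_cells)
            self._conc = {s.name: np.full(self.mesh.n_cells, s.bulk_concentration)
                          for s in self.species}
            self._bias = 0.0
            phi, conc, prof, its, res = self._gummel(0.0, self._phi, self._conc)
            self._phi, self._conc = phi, conc
            self._equilibrated = True

        total_its = 0
        span = bias - self._bias
        n_steps = max(1, int(math.ceil(abs(span) / opts.bias_step - 1e-12)))
        phi, conc = self._phi, self._conc
        prof = None
        b_prev = self._bias
        for k in range(1, n_steps + 1):
            b = self._bias + span * k / n_steps
            phi = phi + (b - b_prev) * self._laplace_unit
            phi, conc, prof, its, res = self._gummel(b, phi, conc)
            total_its += its
            b_prev = b
        if prof is None:  # bias == current state; re-converge in place
            phi, conc, prof, its, res = self._gummel(bias, phi, conc)
            total_its = its
        self._phi, self._conc, self._bias = phi, conc, bias

        n_r, n_th = self.mesh.shape
        sol = PnpSolution(
            r_centers=self.mesh.r_cent.copy(),
            theta_centers=self.mesh.th_cent.copy(),
            phi=phi.reshape(n_r, n_th).copy(),
            concentrations={k: v.reshape(n_r, n_th).copy() for k, v in conc.items()},
            total_current=float(prof[0]),
            bias=float(bias),
            iterations=total_its,
            residual=res,
            current_profile=prof.copy(),
            warnings=list(self._mesh_warnings),
        )
        if (min(c.min() for c in conc.values()) <= 0.0):
            sol.warnings.append("non-positive concentration encountered")
        return sol


def solve_pnp(geom: PoreGeometry, layer: AptamerLayer | None,
              species: Sequence[IonSpecies], bias: float,
              options: SolverOptions | None = None) -> PnpSolution:
    """One-shot convenience wrapper around :class:`PnpSolver`."""
    return PnpSolver(geom, layer, species, options).solve(bias)
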