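"""Pressure drop along a stenosed vessel under steady laminar flow.

Two solvers operate on the same 1-D area discretization (`FlowMesh`):

``solve_pressure_drop``
    The production reduced-order model.  Mass conservation fixes the mean
    velocity in every cell from the hyperemic inlet velocity; the pressure
    drop accumulates a per-cell Poiseuille viscous term
    dP = 8 mu Q / (pi r^4) ds plus a Borda-Carnot expansion loss
    rho (V_up - V_down)^2 / 2 wherever the lumen area increases (flow
    separation downstream of a stenosis throat).

``stokes_oracle``
    An independent finite-difference solution of steady axisymmetric
    creeping flow (streamfunction-vorticity form of the Stokes equations)
    on the same geometry, used in tests to guard the reduced-order model
    against gross error.  Its pressure drop is obtained from the viscous
    dissipation identity dP * Q = dissipation, which holds for creeping
    flow with fully developed inlet/outlet profiles.

Internal computation is in SI; results are reported in mmHg via
1 mmHg = 133.322 Pa, applied exactly once at the end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import simpson

from .geometry import FlowMesh

__all__ = [
    "FluidProperties",
    "FlowProblem",
    "PressureDrop",
    "solve_pressure_drop",
    "stokes_oracle",
    "MMHG_PA",
]

MMHG_PA = 133.322  # Pa per mmHg
_FLOW_EPS_MM3_S = 1e-9  # flows below this (mm^3/s) are treated as zero


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as a Newtonian fluid.

    Defaults are standard values for whole blood: density 1050 kg/m^3,
    dynamic viscosity 3.5 mPa.s.
    """

    density: float = 1050.0  # kg/m^3
    viscosity: float = 3.5e-3  # Pa.s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")


@dataclass(frozen=True)
class FlowProblem:
    """A flow mesh with hyperemic inlet velocity (mm/s) and fluid properties."""

    mesh: FlowMesh
    inlet_velocity: float  # Vhyp, mm/s
    fluid: FluidProperties = FluidProperties()

    def __post_init__(self) -> None:
        if not np.isfinite(self.inlet_velocity) or self.inlet_velocity < 0:
            raise ValueError("inlet velocity must be finite and non-negative")


@dataclass(frozen=True)
class PressureDrop:
    """Cumulative pressure drop from the inlet to each cell (mmHg)."""

    cumulative_dp: np.ndarray  # at cell centers, mmHg
    total_dp: float
    viscous_component: float
    loss_component: float

    def to_dict(self, mesh: FlowMesh | None = None) -> dict:
        d = {
            "total_dp_mmHg": self.total_dp,
            "viscous_mmHg": self.viscous_component,
            "loss_mmHg": self.loss_component,
        }
        if mesh is not None:
            d["profile"] = [
                {"s_mm": float(s), "dp_mmHg": float(p)}
                for s, p in zip(mesh.cell_s, self.cumulative_dp)
            ]
        return d


def solve_pressure_drop(problem: FlowProblem) -> PressureDrop:
    """Reduced-order pressure drop: Poiseuille viscous term + expansion losses."""
    mesh = problem.mesh
    keep = mesh.cell_ds > 0
    if not np.all(keep):
        warnings.warn("dropping zero-length cells from flow mesh", stacklevel=2)
    area_m2 = mesh.cell_area[keep] * 1e-6
    ds_m = mesh.cell_ds[keep] * 1e-3
    if area_m2.size == 0:
        raise ValueError("flow mesh has no cells of positive length")

    v_in = problem.inlet_velocity * 1e-3  # m/s
    q = v_in * area_m2[0]  # m^3/s
    n = area_m2.size
    if q * 1e9 * 1e3 < _FLOW_EPS_MM3_S:  # q in mm^3/s = q_SI * 1e9
        zeros = np.zeros(mesh.n_cells)
        return PressureDrop(cumulative_dp=zeros, total_dp=0.0, viscous_component=0.0, loss_component=0.0)

    mu = problem.fluid.viscosity
    rho = problem.fluid.density
    r_m = np.sqrt(area_m2 / np.pi)
    v = q / area_m2  # mean velocity per cell

    dp_visc = 8.0 * mu * q / (np.pi * r_m**4) * ds_m  # Pa per cell
    # Borda-Carnot separation loss over each contiguous expanding region:
    # rho (V_start - V_end)^2 / 2 per region, attributed incrementally along
    # the region (telescoping, so the total is grid-independent and the
    # cumulative profile stays monotone)
    dp_loss_if = np.zeros(n)
    i = 1
    while i < n:
        if area_m2[i] > area_m2[i - 1]:
            start = i - 1
            while i < n and area_m2[i] > area_m2[i - 1]:
                dp_loss_if[i] = 0.5 * rho * (
                    (v[start] - v[i]) ** 2 - (v[start] - v[i - 1]) ** 2
                )
                i += 1
        else:
            i += 1

    cumulative = np.cumsum(dp_visc + dp_loss_if) / MMHG_PA
    viscous = float(dp_visc.sum() / MMHG_PA)
    loss = float(dp_loss_if.sum() / MMHG_PA)
    if not np.all(keep):  # re-expand to the original cell count
        full = np.zeros(mesh.n_cells)
        full[keep] = cumulative
        # carry forward over dropped cells
        for i in range(1, mesh.n_cells):
            if not keep[i]:
                full[i] = full[i - 1]
        cumulative = full
    return PressureDrop(
        cumulative_dp=cumulative,
        total_dp=viscous + loss,
        viscous_component=viscous,
        loss_component=loss,
    )


# ---------------------------------------------------------------------------
# Axisymmetric creeping-flow oracle


def _d1(n: int, h: float) -> sp.csr_matrix:
    """Second-order first-derivative matrix with one-sided ends."""
    d = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        d[i, i - 1], d[i, i + 1] = -0.5, 0.5
    d[0, 0], d[0, 1], d[0, 2] = -1.5, 2.0, -0.5
    d[n - 1, n - 1], d[n - 1, n - 2], d[n - 1, n - 3] = 1.5, -2.0, 0.5
    return (d / h).tocsr()


def _d2(n: int, h: float) -> sp.csr_matrix:
    """Compact 3-point second-derivative matrix (boundary rows are replaced
    by boundary conditions downstream, so their stencils are immaterial)."""
    d = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        d[i, i - 1], d[i, i], d[i, i + 1] = 1.0, -2.0, 1.0
    d[0, 0], d[0, 1], d[0, 2] = 1.0, -2.0, 1.0
    d[n - 1, n - 3], d[n - 1, n - 2], d[n - 1, n - 1] = 1.0, -2.0, 1.0
    return (d / h**2).tocsr()


def stokes_oracle(problem: FlowProblem, grid_resolution: tuple[int, int] = (161, 41)) -> PressureDrop:
    """Finite-difference solution of steady axisymmetric creeping flow.

    Solves E^2 psi = chi, E^2 chi = 0 (Stokes streamfunction-vorticity) on a
    body-fitted grid (z, eta=r/R(z)), with Poiseuille profiles imposed at
    inlet and outlet and no-slip on the wall.  The total pressure drop is
    recovered from the dissipation identity dP = Phi / Q.  Valid only at low
    Reynolds number (creeping flow); the geometry must be axisymmetric,
    which the 1-D area mesh guarantees by construction (mesh sanity is
    still validated).  Intended for tests at coarse, desk-scale grids.
    """
    mesh = problem.mesh
    if np.any(~np.isfinite(mesh.cell_area)) or np.any(mesh.cell_area <= 0):
        raise ValueError("mesh areas must be finite and positive (axisymmetric lumen)")
    nz, nr = grid_resolution
    if nz < 11 or nr < 11:
        raise ValueError("grid_resolution too coarse; need at least 11 x 11")

    # geometry in SI
    s_m = mesh.cell_s * 1e-3
    r_prof_m = np.sqrt(mesh.cell_area * 1e-6 / np.pi)
    length = float(mesh.cell_ds.sum() * 1e-3)
    z = np.linspace(0.0, length, nz)
    rw = np.interp(z, s_m, r_prof_m)  # wall radius R(z), clamped ends
    drw = np.gradient(rw, z)

    v_in = problem.inlet_velocity * 1e-3
    q = v_in * np.pi * rw[0] ** 2
    if q * 1e9 < _FLOW_EPS_MM3_S:
        zeros = np.zeros(mesh.n_cells)
        return PressureDrop(zeros, 0.0, 0.0, 0.0)

    eta = np.linspace(0.0, 1.0, nr)
    hz, he = z[1] - z[0], eta[1] - eta[0]

    # 2-D operators on psi(z, eta) flattened with z-major ordering
    dz1 = sp.kron(_d1(nz, hz), sp.identity(nr), format="csr")
    de1 = sp.kron(sp.identity(nz), _d1(nr, he), format="csr")
    dz2 = sp.kron(_d2(nz, hz), sp.identity(nr), format="csr")
    de2 = sp.kron(sp.identity(nz), _d2(nr, he), format="csr")
    dze = dz1 @ de1  # mixed derivative (composition is fine for cross terms)

    ee = np.meshgrid(z, eta, indexing="ij")[1]
    rw2 = np.repeat(rw, nr)
    drw2 = np.repeat(drw, nr)
    d2rw2 = np.repeat(np.gradient(drw, z), nr)
    ev = ee.ravel()
    rv = ev * rw2  # physical radius at each node

    def diag(v: np.ndarray) -> sp.csr_matrix:
        return sp.diags(v).tocsr()

    d_r = diag(1.0 / rw2) @ de1
    d_z = dz1 - diag(ev * drw2 / rw2) @ de1
    r_safe = np.where(rv > 0, rv, 1.0)
    # E^2 = d^2/dz^2|r + d^2/dr^2 - (1/r) d/dr expanded in (z, eta) with
    # r = eta R(z): a = R'/R, b = eta a, giving
    # (d/dz|r)^2 = dzz - 2b dz deta + b^2 detadeta + eta(2a^2 - R''/R) deta
    a_c = drw2 / rw2
    b_c = ev * a_c
    e2 = (
        dz2
        - 2.0 * diag(b_c) @ dze
        + diag(b_c**2 + 1.0 / rw2**2) @ de2
        + diag(ev * (2.0 * a_c**2 - d2rw2 / rw2) - 1.0 / (r_safe * rw2)) @ de1
    )

    n = nz * nr
    idx = np.arange(n).reshape(nz, nr)
    axis = idx[:, 0]
    wall = idx[:, -1]
    inlet = idx[0, :]
    outlet = idx[-1, :]
    interior_mask = np.ones(n, dtype=bool)
    interior_mask[np.concatenate([axis, wall, inlet, outlet])] = False

    ident = sp.identity(n, format="csr")

    def keep_rows(mat: sp.csr_matrix, rows: np.ndarray) -> sp.csr_matrix:
        mask = sp.diags(rows.astype(float)).tocsr()
        return mask @ mat

    intr = interior_mask
    # psi-block equations: interior -> E2 psi - chi = 0; boundaries -> Dirichlet psi
    bmask = ~intr
    a11 = keep_rows(e2, intr) + keep_rows(ident, bmask)
    a12 = keep_rows(-ident, intr)
    rhs_psi = np.zeros(n)
    rhs_psi[wall] = q / (2.0 * np.pi)
    # Poiseuille psi(eta) = (Q/2pi)(2 eta^2 - eta^4) at inlet and outlet
    rhs_psi[inlet] = (q / (2.0 * np.pi)) * (2.0 * eta**2 - eta**4)
    rhs_psi[outlet] = rhs_psi[inlet]
    rhs_psi[axis] = 0.0

    # chi-block equations: interior -> E2 chi = 0; axis -> chi = 0;
    # inlet/outlet -> analytic Poiseuille chi = E2 psi = -4 Vbar r^2/R^2;
    # wall -> Thom closure: with psi_eta = 0 (no slip) and psi constant along
    # the wall, E2 psi reduces to (b^2 + 1/R^2) psi_etaeta with
    # psi_etaeta ~= 2 (psi_{wall-1} - psi_wall) / he^2.
    chi_b = np.zeros(n, dtype=bool)
    chi_b[np.concatenate([axis, inlet, outlet])] = True
    wall_only = wall[1:-1]  # corners belong to the inlet/outlet Dirichlet rows
    chi_b_wall = np.zeros(n, dtype=bool)
    chi_b_wall[wall_only] = True
    a22 = keep_rows(e2, intr) + keep_rows(ident, chi_b | chi_b_wall)
    thom_c = (b_c[wall_only] ** 2 + 1.0 / rw2[wall_only] ** 2) * 2.0 / he**2
    a21 = sp.lil_matrix((n, n))
    for node, c in zip(wall_only, thom_c):
        a21[node, node] = c
        a21[node, node - 1] = -c
    a21 = a21.tocsr()
    rhs_chi = np.zeros(n)
    for rows, r_end in ((inlet, rw[0]), (outlet, rw[-1])):
        vbar = q / (np.pi * r_end**2)
        rhs_chi[rows] = -4.0 * vbar * eta**2
    rhs_chi[axis] = 0.0

    a = sp.bmat([[a11, a12], [a21, a22]], format="csr")
    rhs = np.concatenate([rhs_psi, rhs_chi])
    # column-scale by the natural magnitudes of psi and chi, then row-
    # equilibrate: the raw SI system mixes scales over ~15 orders of
    # magnitude, which destroys direct-solve accuracy
    vbar0 = q / (np.pi * rw[0] ** 2)
    col = np.concatenate([np.full(n, q / (2.0 * np.pi)), np.full(n, 4.0 * vbar0)])
    a = a @ sp.diags(col)
    row = 1.0 / np.maximum(np.abs(a).max(axis=1).toarray().ravel(), 1e-300)
    a = (sp.diags(row) @ a).tocsc()
    sol = col * spla.spsolve(a, row * rhs)
    psi = sol[:n]

    # velocities u_z = (1/r) dpsi/dr, u_r = -(1/r) dpsi/dz
    inv_r = 1.0 / r_safe
    psi_r = d_r @ psi
    psi_z = d_z @ psi
    uz = inv_r * psi_r
    ur = -inv_r * psi_z
    ur[axis] = 0.0
    # on-axis u_z via L'Hopital: psi_rr
    uz[axis] = (d_r @ psi_r)[axis]

    # strain rates
    e_zz = d_z @ uz
    e_rr = d_r @ ur
    e_tt = ur * inv_r
    e_tt[axis] = e_rr[axis]  # limit on axis
    e_rz = 0.5 * ((d_r @ uz) + (d_z @ ur))
    phi_density = 2.0 * problem.fluid.viscosity * (e_zz**2 + e_rr**2 + e_tt**2 + 2.0 * e_rz**2)

    # Phi = int phi 2 pi r dV; integrate over eta (dr = R deta) then z
    integrand = (phi_density * rv).reshape(nz, nr) * rw[:, None]
    per_z = simpson(integrand, x=eta, axis=1) * 2.0 * np.pi
    phi_total = simpson(per_z, x=z)
    dp_pa = phi_total / q

    # cumulative profile at the reduced mesh's cell centers
    cum_z = np.concatenate([[0.0], np.cumsum(0.5 * (per_z[1:] + per_z[:-1]) * np.diff(z))])
    cum_at_cells = np.interp(s_m, z, cum_z) / q / MMHG_PA
    total = float(dp_pa / MMHG_PA)
    # the oracle does not decompose loss mechanisms; all dissipation is viscous
    return PressureDrop(
        cumulative_dp=cum_at_cells,
        total_dp=total,
        viscous_component=total,
        loss_component=0.0,
    )
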