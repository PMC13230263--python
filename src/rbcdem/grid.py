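"""Volume-fraction incompressible flow solver on a staggered structured grid.

The carrier fluid (blood plasma) obeys the volume-fraction form of the
incompressible Navier-Stokes equations,

    d(phi)/dt + div(phi u) = 0
    rho ( d(phi u)/dt + div(phi u u) ) = -phi grad p + phi mu lap u - R_pf

where ``phi`` is the fluid volume fraction left free by the sub-grid particles
and ``R_pf = K u - K <u_p>`` the fluid-particle momentum exchange.  The solver
is a PISO-style predictor/double-corrector: momentum is advanced with implicit
diffusion and an implicit exchange diagonal (the ``K u`` half of ``R_pf``),
then two pressure-correction passes restore the discrete phi-continuity.

Two topologies share the code path: ``axisymmetric`` (r, z) for cylindrical
channels (symmetry axis at r = 0, no-slip wall at r = R) and ``planar`` (y, z)
with no-slip walls on both sides.  Solid masks blank cells for stenosed or
branched geometries.  Streamwise (z) boundaries are periodic; a constant axial
body force stands in for the mean pressure gradient.

Wall shear is discretized with a quadratic (three-point) wall flux, which makes
the scheme nodally exact for parabolic profiles — the Hagen-Poiseuille test is
reproduced to machine precision rather than to truncation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Grid",
    "FluidState",
    "TimeControls",
    "build_grid",
    "advance_fluid",
    "interpolate_velocity",
    "sample_fields",
]

PHI_MIN = 0.3  # conditioning clamp on the fluid volume fraction
PRESSURE_TOL = 1e-8  # relative residual for the pressure CG solve
#: cap on the implicit exchange coefficient, in units of rho phi / dt.  The
#: assembled K diverges as the cell slip velocity vanishes (its denominator is
#: |u - <u_p>|); beyond ~rho phi/dt it only expresses "relax fully to the
#: particle velocity within one step", so larger values add stiffness without
#: physics while destroying the pressure-correction face mobility.
K_CAP = 2.0


@dataclass
class TimeControls:
    """Time-step bookkeeping: ``dt_cfd = n_coupling * dt_dem``."""

    dt_cfd: float
    dt_dem: float
    n_coupling: int
    courant_target: float = 0.15

    def __post_init__(self):
        if self.n_coupling < 1:
            raise ValueError("n_coupling must be >= 1")
        if abs(self.dt_cfd - self.n_coupling * self.dt_dem) > 1e-12 * self.dt_cfd:
            raise ValueError("dt_cfd must equal n_coupling * dt_dem")


class Grid:
    """Staggered structured grid.

    ``u_z`` lives on streamwise faces (nr, nz), ``u_r`` on radial faces
    (nr+1, nz), pressure/phi on cell centres (nr, nz).  In axisymmetric mode
    cell volumes are annular rings.
    """

    def __init__(self, topology: str, nr: int, nz: int, dr: float, dz: float,
                 solid_mask: np.ndarray | None = None, depth: float = 1.0):
        if topology not in ("axisymmetric", "planar"):
            raise ValueError(f"unknown topology {topology!r}")
        if dr <= 0 or dz <= 0:
            raise ValueError("cell sizes must be positive")
        self.topology = topology
        self.nr, self.nz = nr, nz
        self.dr, self.dz = dr, dz
        self.depth = depth
        self.r_f = np.arange(nr + 1) * dr
        self.r_c = (np.arange(nr) + 0.5) * dr
        self.z_f = np.arange(nz) * dz
        self.z_c = (np.arange(nz) + 0.5) * dz
        if topology == "axisymmetric":
            self.w_f = self.r_f.copy()
            self.w_c = self.r_c.copy()
            ring = np.pi * (self.r_f[1:] ** 2 - self.r_f[:-1] ** 2) * dz
            self.V_cell = np.repeat(ring[:, None], nz, axis=1)
            self.face_area_z = np.pi * (self.r_f[1:] ** 2 - self.r_f[:-1] ** 2)
        else:
            self.w_f = np.ones(nr + 1)
            self.w_c = np.ones(nr)
            self.V_cell = np.full((nr, nz), dr * dz * depth)
            self.face_area_z = np.full(nr, dr * depth)
        self.solid_mask = (
            np.zeros((nr, nz), dtype=bool) if solid_mask is None else np.asarray(solid_mask, dtype=bool)
        )
        if self.solid_mask.shape != (nr, nz):
            raise ValueError("solid_mask shape mismatch")
        fluid = ~self.solid_mask
        self.fluid = fluid
        # face openness: a face carries an unknown only if both neighbours are fluid
        self.uz_open = fluid & np.roll(fluid, 1, axis=1)
        ur_open = np.zeros((nr + 1, nz), dtype=bool)
        ur_open[1:nr] = fluid[1:] & fluid[:-1]
        self.ur_open = ur_open

    @property
    def R(self) -> float:
        """Radius (axisymmetric) or channel height (planar)."""
        return self.nr * self.dr

    @property
    def L(self) -> float:
        return self.nz * self.dz

    def total_fluid_volume(self) -> float:
        return float(self.V_cell[self.fluid].sum())


@dataclass
class FluidState:
    u_z: np.ndarray  # (nr, nz) streamwise velocity at z-faces
    u_r: np.ndarray  # (nr+1, nz) wall-normal velocity at r-faces
    p: np.ndarray    # (nr, nz) cell pressure
    phi: np.ndarray  # (nr, nz) fluid volume fraction
    body_force: float = 0.0  # axial driving force density [N/m^3]

    @classmethod
    def quiescent(cls, grid: Grid, body_force: float = 0.0) -> "FluidState":
        return cls(
            u_z=np.zeros((grid.nr, grid.nz)),
            u_r=np.zeros((grid.nr + 1, grid.nz)),
            p=np.zeros((grid.nr, grid.nz)),
            phi=np.ones((grid.nr, grid.nz)),
            body_force=body_force,
        )

    def copy(self) -> "FluidState":
        return FluidState(self.u_z.copy(), self.u_r.copy(), self.p.copy(),
                          self.phi.copy(), self.body_force)


def build_grid(spec, resolution) -> Grid:
    """Build a grid tessellating a :class:`~rbcdem.scenarios.ChannelSpec`.

    ``resolution``: (cells across the radius/half-height, cells along the
    channel).  A stenosis mask on the spec blanks cells outside the local wall
    radius.
    """
    nr, nz = resolution
    if nr < 8:
        raise ValueError("resolution too coarse: need >= 8 cells across the radius")
    dr = spec.R_c / nr
    dz = spec.L / nz
    topology = "axisymmetric" if spec.topology == "cylinder" else "planar"
    grid = Grid(topology, nr, nz, dr, dz)
    wall = spec.wall_radius(grid.z_c)
    if np.any(wall < spec.R_c):
        mask = grid.r_c[:, None] > wall[None, :]
        grid = Grid(topology, nr, nz, dr, dz, solid_mask=mask)
    return grid


# --------------------------------------------------------------------------
# momentum + pressure machinery


def _face_avg_z(cell_field):
    """Average a cell field onto streamwise faces (face j between cells j-1, j)."""
    return 0.5 * (cell_field + np.roll(cell_field, 1, axis=1))


def _face_avg_r(cell_field):
    nr = cell_field.shape[0]
    out = np.zeros((nr + 1, cell_field.shape[1]))
    out[1:nr] = 0.5 * (cell_field[1:] + cell_field[:-1])
    out[0] = cell_field[0]
    out[nr] = cell_field[-1]
    return out


def _upwind_grad(field, axis, delta, vel):
    """First-order upwind gradient along ``axis`` (periodic along axis=1)."""
    fwd = (np.roll(field, -1, axis=axis) - field) / delta
    bwd = (field - np.roll(field, 1, axis=axis)) / delta
    if axis == 0:  # non-periodic radial direction: one-sided at the ends
        fwd[-1] = bwd[-1]
        bwd[0] = fwd[0]
    return np.where(vel > 0, bwd, fwd)


def _assemble_momentum_z(grid, phi_f, K_f, adv, u_old, p, G, up_z, dt, mu, rho):
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    open_ = grid.uz_open
    ids = -np.ones((nr, nz), dtype=np.int64)
    ids[open_] = np.arange(open_.sum())
    n = open_.sum()

    rows, cols, vals = [], [], []

    def add(mask, coeff, nb_ids):
        m = mask & open_ & (nb_ids >= 0)
        rows.append(ids[m]); cols.append(nb_ids[m]); vals.append(np.broadcast_to(coeff, mask.shape)[m])

    # radial fluxes of the scalar Laplacian: (1/w_c)(w_f+ q+ - w_f- q-)/dr,
    # scaled by the face volume fraction (the momentum equation carries the
    # viscous term as phi mu lap u)
    c_up = mu * phi_f * grid.w_f[1:][:, None] / (dr * dr * grid.w_c[:, None])
    c_dn = mu * phi_f * grid.w_f[:-1][:, None] / (dr * dr * grid.w_c[:, None])
    id_up = np.vstack([ids[1:], -np.ones((1, nz), dtype=np.int64)])
    id_dn = np.vstack([-np.ones((1, nz), dtype=np.int64), ids[:-1]])
    up_is_wall = np.zeros((nr, nz), dtype=bool)
    up_is_wall[-1] = True      # domain wall: quadratic flux handled below
    dn_is_wall = np.zeros((nr, nz), dtype=bool)
    if grid.topology == "planar":
        dn_is_wall[0] = True
    # masked radial neighbours act as Dirichlet-0 at distance dr: the diagonal
    # keeps the flux coefficient, the off-diagonal entry is simply dropped
    diag = np.where(up_is_wall, 0.0, c_up) + np.where(dn_is_wall, 0.0, c_dn)
    add(~up_is_wall, -c_up, id_up)
    add(~dn_is_wall, -c_dn, id_dn)
    # quadratic wall flux at the outer wall: q_wall = (u[nr-2] - 9 u[nr-1])/(3 dr)
    w_wall = mu * phi_f[-1] * grid.w_f[-1] / (dr * grid.w_c[-1])
    diag[-1] += 9.0 * w_wall / (3.0 * dr)
    m = open_[-1] & (ids[-2] >= 0)
    rows.append(ids[-1][m]); cols.append(ids[-2][m])
    vals.append((-w_wall / (3.0 * dr))[m])
    if grid.topology == "planar":
        w0 = mu * phi_f[0] * grid.w_f[0] / (dr * grid.w_c[0])
        diag[0] += 9.0 * w0 / (3.0 * dr)
        m = open_[0] & (ids[1] >= 0)
        rows.append(ids[0][m]); cols.append(ids[1][m])
        vals.append((-w0 / (3.0 * dr))[m])

    # axial second difference (periodic); closed neighbour -> Dirichlet 0
    c_z = mu * phi_f / (dz * dz)
    id_e = np.roll(ids, -1, axis=1)
    id_w = np.roll(ids, 1, axis=1)
    diag += 2.0 * c_z
    add(np.ones_like(open_), -c_z, id_e)
    add(np.ones_like(open_), -c_z, id_w)

    aP = rho * phi_f / dt + K_f + diag
    rows.append(ids[open_]); cols.append(ids[open_]); vals.append(aP[open_])

    dpdz = (p - np.roll(p, 1, axis=1)) / dz
    b = (rho * phi_f * u_old / dt - rho * phi_f * adv - phi_f * dpdz
         + phi_f * G + K_f * up_z)

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return A, b[open_], ids


def _assemble_momentum_r(grid, phi_f, K_f, adv, u_old, p, up_r, dt, mu, rho):
    """Momentum for the wall-normal velocity on radial faces (i = 1..nr-1)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    open_ = grid.ur_open
    ids = -np.ones((nr + 1, nz), dtype=np.int64)
    ids[open_] = np.arange(open_.sum())
    n = open_.sum()
    if n == 0:
        return None, None, ids

    rows, cols, vals = [], [], []

    def add(coeff, nb_ids, mask=None):
        m = open_ & (nb_ids >= 0)
        if mask is not None:
            m &= mask
        rows.append(ids[m]); cols.append(nb_ids[m]); vals.append(np.broadcast_to(coeff, ids.shape)[m])

    # radial part of the vector Laplacian at r_f[i]:
    # (1/r_f) d/dr (r du/dr) - u/r^2  -> fluxes weighted by w_c, plus -u/r_f^2
    w_at = np.where(grid.w_f > 0, grid.w_f, 1.0)
    c_up = mu * phi_f * np.concatenate([grid.w_c, [grid.w_c[-1]]])[:, None] / (dr * dr * w_at[:, None])
    c_dn = mu * phi_f * np.concatenate([[grid.w_c[0]], grid.w_c])[:, None] / (dr * dr * w_at[:, None])
    id_up = np.vstack([ids[1:], -np.ones((1, nz), dtype=np.int64)])
    id_dn = np.vstack([-np.ones((1, nz), dtype=np.int64), ids[:-1]])
    diag = c_up + c_dn  # closed/boundary neighbours are exact Dirichlet-0 nodes
    add(-c_up, id_up)
    add(-c_dn, id_dn)
    if grid.topology == "axisymmetric":
        diag += mu * phi_f / np.where(grid.r_f[:, None] > 0, grid.r_f[:, None] ** 2, np.inf)

    c_z = mu * phi_f / (dz * dz)
    diag += 2.0 * c_z
    add(-c_z, np.roll(ids, -1, axis=1))
    add(-c_z, np.roll(ids, 1, axis=1))

    aP = rho * phi_f / dt + K_f + diag
    rows.append(ids[open_]); cols.append(ids[open_]); vals.append(aP[open_])

    dpdr = np.zeros((nr + 1, nz))
    dpdr[1:nr] = (p[1:] - p[:-1]) / dr
    b = rho * phi_f * u_old / dt - rho * phi_f * adv - phi_f * dpdr + K_f * up_r

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return A, b[open_], ids


def _divergence(grid, phi, u_z, u_r):
    """Discrete div(phi u) at cell centres."""
    phi_zf = _face_avg_z(phi)
    phi_rf = _face_avg_r(phi)
    qz = phi_zf * u_z
    qr = phi_rf * u_r * grid.w_f[:, None]
    div = (np.roll(qz, -1, axis=1) - qz) / grid.dz
    div += (qr[1:] - qr[:-1]) / (grid.dr * grid.w_c[:, None])
    return div


def effective_K(Kpf: np.ndarray, phi: np.ndarray, rho: float, dt: float) -> np.ndarray:
    """The conditioned exchange coefficient actually applied by the solver."""
    return np.minimum(Kpf, K_CAP * rho * np.clip(phi, PHI_MIN, 1.0) / dt)


def _cached_solve(context, key, A, b, tol=1e-9):
    """Solve A x = b, reusing a cached LU as long as residual-verified
    iterative refinement still reaches ``tol``; refactorizes otherwise."""
    nb = float(np.linalg.norm(b)) + 1e-300
    if context is not None and key in context:
        lu = context[key]
        x = lu.solve(b)
        for _ in range(3):
            r = b - A @ x
            if float(np.linalg.norm(r)) <= tol * nb:
                return x
            x = x + lu.solve(r)
        if float(np.linalg.norm(b - A @ x)) <= tol * nb:
            return x
    lu = spla.splu(A.tocsc())
    if context is not None:
        context[key] = lu
    return lu.solve(b)


def advance_fluid(state: FluidState, grid: Grid, dt: float, mu: float, rho: float,
                  Kpf: np.ndarray | None = None, up_mean: np.ndarray | None = None,
                  dphi_dt: np.ndarray | None = None,
                  context: dict | None = None) -> FluidState:
    """Advance the fluid one time step: implicit predictor + two pressure passes.

    ``Kpf`` is the per-cell momentum-exchange coefficient (kg m^-3 s^-1),
    ``up_mean`` the per-cell mean particle velocity, shape (nr, nz, 2) ordered
    (z-component, r-component); its implicit half enters the momentum diagonal
    and its explicit half the right-hand side.  ``dphi_dt`` is the continuity
    source from a changing particle loading.

    Raises if the Courant number exceeds 1 or the pressure solve stalls.
    """
    nr, nz = grid.nr, grid.nz
    co = dt * max(
        float(np.abs(state.u_z).max(initial=0.0)) / grid.dz,
        float(np.abs(state.u_r).max(initial=0.0)) / grid.dr,
    )
    if co >= 1.0:
        raise RuntimeError(f"Courant violation: Co={co:.3f} >= 1 for dt={dt:.3e}")

    phi = np.clip(state.phi, PHI_MIN, 1.0)
    K = np.zeros((nr, nz)) if Kpf is None else np.minimum(Kpf, K_CAP * rho * phi / dt)  # see effective_K
    upm = np.zeros((nr, nz, 2)) if up_mean is None else up_mean

    phi_zf = _face_avg_z(phi)
    phi_rf = _face_avg_r(phi)
    K_zf = _face_avg_z(K)
    K_rf = _face_avg_r(K)
    K_rf[0] = 0.0
    K_rf[nr] = 0.0
    upz_f = _face_avg_z(upm[:, :, 0])
    upr_f = _face_avg_r(upm[:, :, 1])

    # explicit upwind advection (non-conservative), evaluated on the old field
    uz, ur = state.u_z, state.u_r
    ur_at_zface = 0.25 * (ur[:-1] + ur[1:] + np.roll(ur[:-1], 1, axis=1) + np.roll(ur[1:], 1, axis=1))
    adv_z = uz * _upwind_grad(uz, 1, grid.dz, uz) + ur_at_zface * _upwind_grad(uz, 0, grid.dr, ur_at_zface)
    uz_at_rface = np.zeros((nr + 1, nz))
    uz_c = 0.5 * (uz + np.roll(uz, -1, axis=1))
    uz_at_rface[1:nr] = 0.5 * (uz_c[1:] + uz_c[:-1])
    adv_r = (uz_at_rface * _upwind_grad(ur, 1, grid.dz, uz_at_rface)
             + ur * _upwind_grad(ur, 0, grid.dr, ur))

    A_z, b_z, ids_z = _assemble_momentum_z(
        grid, phi_zf, K_zf, adv_z, uz, state.p, state.body_force, upz_f, dt, mu, rho)
    u_z = np.zeros((nr, nz))
    u_z[grid.uz_open] = _cached_solve(context, "lu_z", A_z, b_z)

    A_r, b_r, ids_r = _assemble_momentum_r(
        grid, phi_rf, K_rf, adv_r, ur, state.p, upr_f, dt, mu, rho)
    u_r = np.zeros((nr + 1, nz))
    if A_r is not None:
        u_r[grid.ur_open] = _cached_solve(context, "lu_r", A_r, b_r)

    p = state.p.copy()
    src = np.zeros((nr, nz)) if dphi_dt is None else dphi_dt

    # face correction mobilities D_f = phi_f / (rho phi_f / dt + K_f)
    D_zf = np.where(grid.uz_open, phi_zf / (rho * phi_zf / dt + K_zf), 0.0)
    D_rf = np.where(grid.ur_open, phi_rf / (rho * phi_rf / dt + K_rf), 0.0)

    cell_ids = -np.ones((nr, nz), dtype=np.int64)
    cell_ids[grid.fluid] = np.arange(grid.fluid.sum())
    A_p = _pressure_matrix(grid, phi_zf, phi_rf, D_zf, D_rf, cell_ids)
    # pin the pressure gauge in cell 0 to lift the constant nullspace, then
    # factorize once and reuse for both correction passes
    A_pinned = A_p.copy()
    s0, e0 = A_pinned.indptr[0], A_pinned.indptr[1]
    A_pinned.data[s0:e0] = np.where(A_pinned.indices[s0:e0] == 0, 1.0, 0.0)
    lu_p = context.get("lu_p") if context is not None else None
    if lu_p is None:
        lu_p = spla.splu(A_pinned.tocsc())
        if context is not None:
            context["lu_p"] = lu_p

    for _ in range(2):  # two PISO correction passes
        div = _divergence(grid, phi, u_z, u_r)
        # enforce div(phi u) = -dphi/dt:  A p' = w_c (target - div), A = -w_c div(phi D grad .)
        rhs = (grid.w_c[:, None] * (-src - div))[grid.fluid]
        rhs = rhs - rhs.mean()
        rhs_solve = rhs.copy()
        rhs_solve[0] = 0.0
        pc, res = _refined_pressure_solve(lu_p, A_pinned, rhs_solve)
        if res > PRESSURE_TOL * float(np.linalg.norm(rhs_solve)) + 1e-250:
            # cached factorization too stale: refactorize and retry once
            lu_p = spla.splu(A_pinned.tocsc())
            if context is not None:
                context["lu_p"] = lu_p
            pc, res = _refined_pressure_solve(lu_p, A_pinned, rhs_solve)
        if not np.isfinite(res) or res > PRESSURE_TOL * float(np.linalg.norm(rhs_solve)) + 1e-250:
            raise RuntimeError(f"pressure correction failed to converge (abs.res={res:.2e})")
        p_corr = np.zeros((nr, nz))
        p_corr[grid.fluid] = pc - pc.mean()
        dpdz = (p_corr - np.roll(p_corr, 1, axis=1)) / grid.dz
        u_z = np.where(grid.uz_open, u_z - D_zf * dpdz, 0.0)
        dpdr = np.zeros((nr + 1, nz))
        dpdr[1:nr] = (p_corr[1:] - p_corr[:-1]) / grid.dr
        u_r = np.where(grid.ur_open, u_r - D_rf * dpdr, 0.0)
        p = p + p_corr

    return FluidState(u_z=u_z, u_r=u_r, p=p, phi=state.phi.copy(), body_force=state.body_force)


def _refined_pressure_solve(lu_p, A_pinned, rhs_solve):
    """LU solve plus residual-verified iterative refinement on the pinned
    pressure system (the row-0 entry is the gauge condition)."""
    pc = lu_p.solve(rhs_solve)
    res = np.inf
    for _ in range(4):
        r = rhs_solve - A_pinned @ pc
        res = float(np.linalg.norm(r))
        if res <= PRESSURE_TOL * float(np.linalg.norm(rhs_solve)) + 1e-250:
            break
        pc = pc + lu_p.solve(r)
    return pc, res


def _pressure_matrix(grid, phi_zf, phi_rf, D_zf, D_rf, cell_ids):
    nr, nz = grid.nr, grid.nz
    rows, cols, vals = [], [], []
    fluid = grid.fluid

    # z faces: face j couples cell j-1 and cell j
    coef_z = grid.w_c[:, None] * phi_zf * D_zf / grid.dz**2
    idW = np.roll(cell_ids, 1, axis=1)
    m = grid.uz_open
    cP, cW = cell_ids[m], idW[m]
    cz = coef_z[m]
    rows += [cP, cW, cP, cW]
    cols += [cP, cW, cW, cP]
    vals += [cz, cz, -cz, -cz]

    # r faces: face i couples cell i-1 and cell i
    coef_r = grid.w_f[:, None] * phi_rf * D_rf / grid.dr**2
    m = grid.ur_open
    ii, jj = np.nonzero(m)
    cN = cell_ids[ii, jj]        # outer cell i
    cS = cell_ids[ii - 1, jj]    # inner cell i-1
    cr = coef_r[m]
    rows += [cN, cS, cN, cS]
    cols += [cN, cS, cS, cN]
    vals += [cr, cr, -cr, -cr]

    n = fluid.sum()
    A = sp.csr_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    return A


def _diag_precond(A):
    d = A.diagonal()
    d = np.where(np.abs(d) > 0, 1.0 / np.where(d != 0, d, 1.0), 1.0)
    return spla.LinearOperator(A.shape, matvec=lambda x: d * x)


# --------------------------------------------------------------------------
# sampling the staggered fields at particle positions


def _interp1_weights(q, x0, dx, n, periodic=False):
    """Index pairs + weights for linear interpolation on a uniform node set."""
    t = (np.asarray(q, dtype=float) - x0) / dx
    i0 = np.floor(t).astype(np.int64)
    frac = t - i0
    if periodic:
        ia = np.mod(i0, n)
        ib = np.mod(i0 + 1, n)
    else:
        i0 = np.clip(i0, 0, n - 2)
        frac = np.clip(t - i0, 0.0, 1.0)
        ia, ib = i0, i0 + 1
    return ia, ib, frac


def _sample_center_field(grid, field, rq, zq, z_nodes, wall_value=None):
    """Bilinear sample of a field stored at radial cell centres.

    Radially the profile is treated as symmetric about the axis (flat below the
    first node); beyond the last node it either stays flat (``wall_value``
    None) or ramps linearly to ``wall_value`` at the wall over the last half
    cell (used for no-slip velocity).
    """
    nr = grid.nr
    z0 = 0.0 if z_nodes == "face" else 0.5 * grid.dz
    ja, jb, fz = _interp1_weights(zq, z0, grid.dz, grid.nz, periodic=True)
    ia, ib, fr = _interp1_weights(rq, grid.r_c[0], grid.dr, nr)
    f_a = field[ia, ja] * (1 - fz) + field[ia, jb] * fz
    f_b = field[ib, ja] * (1 - fz) + field[ib, jb] * fz
    out = f_a * (1 - fr) + f_b * fr
    below = rq < grid.r_c[0]
    if np.any(below):
        out = np.where(below, field[0, ja] * (1 - fz) + field[0, jb] * fz, out)
    above = rq > grid.r_c[-1]
    if np.any(above):
        edge = field[nr - 1, ja] * (1 - fz) + field[nr - 1, jb] * fz
        if wall_value is None:
            out = np.where(above, edge, out)
        else:
            s = np.clip((rq - grid.r_c[-1]) / (0.5 * grid.dr), 0.0, 1.0)
            out = np.where(above, edge * (1 - s) + wall_value * s, out)
    if grid.topology == "planar" and wall_value is not None and np.any(below):
        # the lower edge is a wall in planar mode, not a symmetry axis
        edge0 = field[0, ja] * (1 - fz) + field[0, jb] * fz
        s = np.clip((grid.r_c[0] - rq) / (0.5 * grid.dr), 0.0, 1.0)
        out = np.where(below, edge0 * (1 - s) + wall_value * s, out)
    return out


def _sample_rface_field(grid, field, rq, zq):
    """Bilinear sample of a field stored at radial faces, z centres."""
    ja, jb, fz = _interp1_weights(zq, 0.5 * grid.dz, grid.dz, grid.nz, periodic=True)
    ia, ib, fr = _interp1_weights(np.clip(rq, 0.0, grid.R), 0.0, grid.dr, grid.nr + 1)
    f_a = field[ia, ja] * (1 - fz) + field[ia, jb] * fz
    f_b = field[ib, ja] * (1 - fz) + field[ib, jb] * fz
    return f_a * (1 - fr) + f_b * fr


def _laplacian_uz(grid, u_z, mu_unit=1.0):
    """Discrete scalar Laplacian of u_z on its own (z-face) nodes."""
    nr = grid.nr
    dr, dz = grid.dr, grid.dz
    q = np.zeros((nr + 1, grid.nz))
    q[1:nr] = (u_z[1:] - u_z[:-1]) / dr
    q[nr] = (u_z[nr - 2] - 9.0 * u_z[nr - 1]) / (3.0 * dr)
    if grid.topology == "planar":
        q[0] = -(u_z[1] - 9.0 * u_z[0]) / (3.0 * dr)
    lap = (grid.w_f[1:, None] * q[1:] - grid.w_f[:-1, None] * q[:-1]) / (dr * grid.w_c[:, None])
    lap += (np.roll(u_z, -1, axis=1) - 2 * u_z + np.roll(u_z, 1, axis=1)) / dz**2
    return mu_unit * lap


def sample_fields(state: FluidState, grid: Grid, positions: np.ndarray):
    """Sample velocity, shear rate, pressure gradient and velocity Laplacian
    at particle centres (vectorised).

    ``positions`` is (N, 3) Cartesian; for the axisymmetric topology the axis
    is z = index 2 and r = hypot(x, y); for the planar topology the wall-normal
    coordinate is y (index 1) and the spanwise x is ignored.

    Returns a dict with keys ``u`` (N,3), ``shear`` (N,), ``grad_p`` (N,3),
    ``lap_u`` (N,3), ``radial_unit`` (N,3) (pointing toward the axis/centre),
    ``r`` (N,) the wall-normal coordinate.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    zq = pos[:, 2]
    if grid.topology == "axisymmetric":
        rq = np.hypot(pos[:, 0], pos[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat_out = np.where(rq[:, None] > 0, pos[:, :2] / np.where(rq[:, None] > 0, rq[:, None], 1.0), 0.0)
        e_out3 = np.zeros((pos.shape[0], 3))
        e_out3[:, :2] = rhat_out
    else:
        rq = pos[:, 1]
        e_out3 = np.zeros((pos.shape[0], 3))
        e_out3[:, 1] = np.where(rq >= 0.5 * grid.R, 1.0, -1.0)  # outward = away from centreline
    if np.any(rq > grid.R + 1e-12) or np.any(rq < -1e-12):
        raise ValueError("position outside grid")

    uz_p = _sample_center_field(grid, state.u_z, rq, zq, "face", wall_value=0.0)
    ur_p = _sample_rface_field(grid, state.u_r, rq, zq)

    # shear rate: centred difference of the streamwise velocity across +-dr/2;
    # below the axis the profile is mirrored (axisymmetric) or clamped (planar)
    delta = 0.5 * grid.dr
    up_hi = _sample_center_field(grid, state.u_z, np.minimum(rq + delta, grid.R), zq, "face", wall_value=0.0)
    r_lo = rq - delta
    if grid.topology == "axisymmetric":
        r_lo = np.abs(r_lo)
    else:
        r_lo = np.maximum(r_lo, 0.0)
    up_lo = _sample_center_field(grid, state.u_z, r_lo, zq, "face", wall_value=0.0)
    shear = np.abs(up_hi - up_lo) / (2 * delta)

    # pressure gradient at cell centres
    p = state.p
    dpdz_c = (np.roll(p, -1, axis=1) - np.roll(p, 1, axis=1)) / (2 * grid.dz)
    dpdr_c = np.zeros_like(p)
    dpdr_c[1:-1] = (p[2:] - p[:-2]) / (2 * grid.dr)
    dpdr_c[0] = (p[1] - p[0]) / grid.dr
    dpdr_c[-1] = (p[-1] - p[-2]) / grid.dr
    dpdz_p = _sample_center_field(grid, dpdz_c, rq, zq, "center")
    dpdr_p = _sample_center_field(grid, dpdr_c, rq, zq, "center")

    lap = _laplacian_uz(grid, state.u_z)
    lap_p = _sample_center_field(grid, lap, rq, zq, "face")

    n = pos.shape[0]
    u = np.zeros((n, 3))
    grad_p = np.zeros((n, 3))
    lap_u = np.zeros((n, 3))
    u[:, 2] = uz_p
    grad_p[:, 2] = dpdz_p
    lap_u[:, 2] = lap_p
    if grid.topology == "axisymmetric":
        u[:, :2] = ur_p[:, None] * e_out3[:, :2]
        grad_p[:, :2] = dpdr_p[:, None] * e_out3[:, :2]
    else:
        u[:, 1] = ur_p
        grad_p[:, 1] = dpdr_p
    return {
        "u": u,
        "shear": shear,
        "grad_p": grad_p,
        "lap_u": lap_u,
        "radial_unit": -e_out3,
        "r": rq,
    }


def interpolate_velocity(state: FluidState, grid: Grid, position):
    """Velocity vector and shear rate at one point (thin wrapper over
    :func:`sample_fields`)."""
    out = sample_fields(state, grid, np.asarray(position, dtype=float)[None, :])
    return out["u"][0], float(out["shear"][0])
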