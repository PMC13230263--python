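"""Soft-sphere discrete element dynamics for the sub-grid RBC surrogates.

Particles integrate linear and angular momentum,

    m_p du_p/dt = m_p g + F_fluid + sum F_pp + sum F_pw + F_ext
    I_p domega_p/dt = sum r x F

with Hertz-Mindlin particle-particle and particle-wall contacts (normal Hertz
stiffness with restitution-derived damping, tangential spring capped by
Coulomb friction).  Fluid forces act at the particle centre and contribute no
torque; contact tangential forces do.

The stable time step is bounded by the elastic-wave (Rayleigh) and contact
(Hertz) time scales, ``dt_DEM < 0.1 min(t_Ray, t_Her)``.  Because the RBC drag
closure is stiff (the cell relaxes to the local fluid velocity much faster
than a contact resolves), the drag is integrated semi-implicitly inside the
velocity-Verlet step while contacts stay explicit.

Contact parameters default to a soft-cell surrogate (Young's modulus in the
kPa range); real RBC membranes are far softer than typical DEM materials and
the macroscopic observables at dilute hematocrit are insensitive to the exact
stiffness, which mainly sets the admissible time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ContactParams",
    "ParticleSet",
    "CylinderWalls",
    "PlanarWalls",
    "contact_forces",
    "rayleigh_time",
    "hertz_time",
    "dem_substep",
]


@dataclass
class ContactParams:
    """Material parameters of the soft-sphere contact model."""

    young: float = 1000.0       # Young's modulus [Pa]
    poisson: float = 0.3
    restitution: float = 0.5
    friction: float = 0.1

    def __post_init__(self):
        if self.young <= 0 or not (0 < self.restitution <= 1) or self.friction < 0:
            raise ValueError("invalid contact parameters")

    @property
    def e_star(self) -> float:
        """Effective modulus of an identical pair: 1/E* = 2 (1 - nu^2)/E."""
        return self.young / (2.0 * (1.0 - self.poisson**2))

    @property
    def g_star(self) -> float:
        g = self.young / (2.0 * (1.0 + self.poisson))
        return g / (2.0 * (2.0 - self.poisson))

    @property
    def damping_ratio(self) -> float:
        ln_e = np.log(self.restitution)
        return -ln_e / np.sqrt(ln_e**2 + np.pi**2)


class ParticleSet:
    """Struct-of-arrays container for N spherical particles.

    Mass and moment of inertia follow the solid sphere:
    ``m_p = rho_p pi d^3 / 6``, ``I_p = m_p d^2 / 10``.
    Closure state (DI, C_d, C_l and the fluid forces) is cached per particle by
    the coupling loop.
    """

    def __init__(self, pos, vel=None, d_p=5.6e-6, rho_p=1100.0, omega=None):
        self.pos = np.atleast_2d(np.asarray(pos, dtype=float)).copy()
        n = self.pos.shape[0]
        self.vel = np.zeros((n, 3)) if vel is None else np.asarray(vel, dtype=float).copy()
        self.omega = np.zeros((n, 3)) if omega is None else np.asarray(omega, dtype=float).copy()
        self.d_p = np.broadcast_to(np.asarray(d_p, dtype=float), (n,)).copy()
        self.rho_p = np.broadcast_to(np.asarray(rho_p, dtype=float), (n,)).copy()
        if np.any(self.d_p <= 0) or np.any(self.rho_p <= 0):
            raise ValueError("d_p and rho_p must be positive")
        # cached closure state
        self.DI = np.zeros(n)
        self.C_d = np.zeros(n)
        self.C_l = np.zeros(n)
        self.F_drag = np.zeros((n, 3))
        self.F_lift = np.zeros((n, 3))
        # geometric/inertial arrays (d_p and rho_p are immutable per set)
        self.volume = np.pi * self.d_p**3 / 6.0
        self.mass = self.rho_p * self.volume
        self.inertia = self.mass * self.d_p**2 / 10.0

    def __len__(self):
        return self.pos.shape[0]

    def copy(self):
        out = ParticleSet(self.pos, self.vel, self.d_p, self.rho_p, self.omega)
        out.DI, out.C_d, out.C_l = self.DI.copy(), self.C_d.copy(), self.C_l.copy()
        out.F_drag, out.F_lift = self.F_drag.copy(), self.F_lift.copy()
        return out


class CylinderWalls:
    """No-slip cylindrical wall, optionally constricted: R_wall = R_wall(z)."""

    def __init__(self, R_c: float, wall_radius=None):
        self.R_c = R_c
        self.wall_radius = wall_radius

    def contact_list(self, pos, radius):
        s = np.hypot(pos[:, 0], pos[:, 1])
        rw = self.R_c if self.wall_radius is None else np.asarray(self.wall_radius(pos[:, 2]))
        delta = s + radius - rw
        with np.errstate(invalid="ignore"):
            e_out = np.where(s[:, None] > 0, pos[:, :2] / np.where(s[:, None] > 0, s[:, None], 1.0), 0.0)
        normal = np.zeros_like(pos)
        normal[:, :2] = -e_out  # pushes the particle back toward the axis
        return [(delta, normal)]


class PlanarWalls:
    """Two parallel no-slip walls at y = 0 and y = H."""

    def __init__(self, H: float):
        self.H = H

    def contact_list(self, pos, radius):
        lo = radius - pos[:, 1]
        hi = pos[:, 1] + radius - self.H
        n_lo = np.zeros_like(pos); n_lo[:, 1] = 1.0
        n_hi = np.zeros_like(pos); n_hi[:, 1] = -1.0
        return [(lo, n_lo), (hi, n_hi)]


def rayleigh_time(d_p: float, rho_p: float, params: ContactParams) -> float:
    """Rayleigh surface-wave time scale of a particle,
    ``t_Ray = pi R sqrt(rho_p/G) / (0.1631 nu_P + 0.8766)``."""
    G = params.young / (2.0 * (1.0 + params.poisson))
    return np.pi * (d_p / 2.0) * np.sqrt(rho_p / G) / (0.1631 * params.poisson + 0.8766)


def hertz_time(d_p: float, rho_p: float, params: ContactParams, impact_speed: float,
               v_floor: float | None = None) -> float:
    """Hertz contact duration for an identical binary impact,
    ``t_Her = 2.87 (m_eff^2 / (R_eff E*^2 v))^0.2``.

    Zero impact speed is replaced by ``v_floor`` (typically the bulk velocity
    of the case) to keep the estimate defined.
    """
    v = impact_speed if impact_speed > 0 else v_floor
    if v is None or v <= 0:
        raise ValueError("impact_speed (or v_floor) must be positive")
    m = rho_p * np.pi * d_p**3 / 6.0
    m_eff = m / 2.0
    r_eff = d_p / 4.0
    return 2.87 * (m_eff**2 / (r_eff * params.e_star**2 * v)) ** 0.2


def _cross(a, b):
    """Row-wise cross product of (N, 3) arrays (faster than np.cross)."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _hertz_normal(delta, r_eff, m_eff, v_n, params):
    """Hertz elastic + restitution damping normal force magnitudes.

    ``v_n`` is the normal approach rate (positive when closing)."""
    sq = np.sqrt(r_eff * delta)
    f_el = (4.0 / 3.0) * params.e_star * sq * delta
    s_n = 2.0 * params.e_star * sq
    f_damp = 2.0 * np.sqrt(5.0 / 6.0) * params.damping_ratio * np.sqrt(s_n * m_eff) * v_n
    return f_el, f_damp


#: neighbour-list skin as a fraction of the largest diameter; candidate pairs
#: stay valid while relative displacements remain below the skin
NEIGHBOR_SKIN = 0.3


def contact_forces(particles: ParticleSet, walls=None, params: ContactParams | None = None,
                   history: dict | None = None, pair_cache: dict | None = None,
                   dt: float = 0.0):
    """Particle-particle and particle-wall contact forces and torques.

    Returns ``(F (N,3), torque (N,3), F_pp (N,3), F_pw (N,3))``.  ``history``
    is a mutable dict of tangential spring displacements keyed by contact pair;
    pass the same dict across substeps to accumulate tangential sticking.
    Pair forces are equal and opposite by construction.  Overlaps beyond
    10% of the diameter emit a warning (time step too large).

    ``pair_cache`` (mutable dict) holds a skin-padded candidate pair list so
    successive substeps can skip the neighbour search; the caller must drop
    its ``"pairs"`` entry whenever accumulated motion may exceed the skin.
    """
    params = params or ContactParams()
    n = len(particles)
    F = np.zeros((n, 3))
    T = np.zeros((n, 3))
    F_pp = np.zeros((n, 3))
    F_pw = np.zeros((n, 3))
    if n == 0:
        return F, T, F_pp, F_pw
    pos, vel, omg = particles.pos, particles.vel, particles.omega
    rad = particles.d_p / 2.0
    mass = particles.mass
    new_codes, new_xi = [], []

    if n > 1:
        if pair_cache is not None and "pairs" in pair_cache:
            pairs = pair_cache["pairs"]
        else:
            tree = cKDTree(pos)
            pairs = tree.query_pairs(r=(1.0 + NEIGHBOR_SKIN) * float(particles.d_p.max()),
                                     output_type="ndarray")
            if pair_cache is not None:
                pair_cache["pairs"] = pairs
    else:
        pairs = np.empty((0, 2), dtype=int)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dx = pos[j] - pos[i]
        dist = np.linalg.norm(dx, axis=1)
        delta = rad[i] + rad[j] - dist
        touch = delta > 0
        if np.any(touch):
            i, j, dx, dist, delta = i[touch], j[touch], dx[touch], dist[touch], delta[touch]
            nrm = dx / dist[:, None]  # from i toward j
            r_eff = rad[i] * rad[j] / (rad[i] + rad[j])
            m_eff = mass[i] * mass[j] / (mass[i] + mass[j])
            if np.any(delta > 0.1 * np.minimum(particles.d_p[i], particles.d_p[j])):
                import warnings
                warnings.warn("contact overlap exceeds 10% of the diameter: DEM time step too large",
                              RuntimeWarning, stacklevel=2)
            ci = pos[i] + (rad[i] - 0.5 * delta)[:, None] * nrm
            v_rel = (vel[i] + _cross(omg[i], ci - pos[i])
                     - vel[j] - _cross(omg[j], ci - pos[j]))
            v_n = np.einsum("ij,ij->i", v_rel, nrm)  # positive when closing
            f_el, f_damp = _hertz_normal(delta, r_eff, m_eff, v_n, params)
            fn_mag = f_el + f_damp
            Fn = -fn_mag[:, None] * nrm  # on particle i (pushes i away from j)
            v_t = v_rel - v_n[:, None] * nrm
            codes = (i.astype(np.int64) + 1) * _CODE_BASE + (j.astype(np.int64) + 16)
            Ft, xi = _tangential(history, codes, v_t, delta, r_eff, f_el, params, dt)
            new_codes.append(codes); new_xi.append(xi)
            Fi = Fn + Ft
            np.add.at(F, i, Fi)
            np.add.at(F, j, -Fi)
            np.add.at(F_pp, i, Fi)
            np.add.at(F_pp, j, -Fi)
            np.add.at(T, i, _cross(ci - pos[i], Ft))
            np.add.at(T, j, _cross(ci - pos[j], -Ft))

    if walls is not None:
        for w_idx, (delta, normal) in enumerate(walls.contact_list(pos, rad)):
            touch = delta > 0
            if not np.any(touch):
                continue
            k = np.nonzero(touch)[0]
            d, nw = delta[k], normal[k]
            ck = pos[k] - (rad[k] - 0.5 * d)[:, None] * nw  # contact point on the wall side
            v_rel = vel[k] + _cross(omg[k], ck - pos[k])
            v_n = -np.einsum("ij,ij->i", v_rel, nw)  # closing when moving against the wall normal
            f_el, f_damp = _hertz_normal(d, rad[k], mass[k], v_n, params)
            Fn = (f_el + f_damp)[:, None] * nw
            v_t = v_rel + v_n[:, None] * nw
            codes = (k.astype(np.int64) + 1) * _CODE_BASE + (14 - w_idx)
            Ft, xi = _tangential(history, codes, v_t, d, rad[k], f_el, params, dt)
            new_codes.append(codes); new_xi.append(xi)
            np.add.at(F, k, Fn + Ft)
            np.add.at(F_pw, k, Fn + Ft)
            np.add.at(T, k, _cross(ck - pos[k], Ft))

    if history is not None:
        # persist the tangential springs of the currently touching contacts
        if new_codes:
            codes = np.concatenate(new_codes)
            xi = np.vstack(new_xi)
            order = np.argsort(codes)
            history["codes"], history["xi"] = codes[order], xi[order]
        else:
            history["codes"] = np.empty(0, dtype=np.int64)
            history["xi"] = np.empty((0, 3))
    return F, T, F_pp, F_pw


_CODE_BASE = np.int64(1) << 24  # contact key encoding: (i+1)*BASE + (j+16)


def _tangential(history, codes, v_t, delta, r_eff, f_el, params, dt):
    """Tangential spring force capped by Coulomb friction (vectorised).

    The spring displacement accumulates the tangential slip ``v_t dt`` over
    the life of each contact (looked up by encoded pair key); when the spring
    force exceeds the Coulomb cap mu |F_n| the displacement is rescaled onto
    the cap (sliding).  Returns ``(F_t, xi_new)``.
    """
    if params.friction == 0:
        z = np.zeros_like(v_t)
        return z, z
    k_t = 8.0 * params.g_star * np.sqrt(r_eff * delta)
    xi = np.zeros_like(v_t)
    if history is not None and len(history.get("codes", ())):
        stored = history["codes"]
        idx = np.searchsorted(stored, codes)
        idx_c = np.clip(idx, 0, len(stored) - 1)
        hit = stored[idx_c] == codes
        xi[hit] = history["xi"][idx_c[hit]]
    xi = xi + v_t * dt
    Ft = -k_t[:, None] * xi
    mag = np.sqrt(np.einsum("ij,ij->i", Ft, Ft))
    cap = params.friction * f_el
    over = mag > cap
    scale = np.where(over & (mag > 0), cap / np.where(mag > 0, mag, 1.0), 1.0)
    Ft = Ft * scale[:, None]
    xi = xi * scale[:, None]
    return Ft, xi


@dataclass
class FluidForcing:
    """Per-particle fluid forces frozen over one coupling interval.

    ``u_f`` is the undisturbed fluid velocity at the particle, ``c_drag`` the
    coefficient such that the drag force is ``c_drag |u_f - u_p| (u_f - u_p)``
    (i.e. 0.125 C_d rho pi d_p^2 with C_d frozen), and ``f_other`` the sum of
    lift, pressure and viscous forces.  ``slip_cap`` saturates the slip
    magnitude entering the drag linearization (the closure envelope covers
    |u_p - u| <= u_av).  Drag and ``f_other`` are integrated together with the
    exact constant-coefficient relaxation, so the particle velocity approaches
    ``u_f + f_other/beta`` monotonically and can never overshoot it.
    """

    u_f: np.ndarray
    c_drag: np.ndarray
    f_other: np.ndarray
    slip_cap: float = np.inf


def dem_substep(particles: ParticleSet, dt: float, walls=None,
                params: ContactParams | None = None, fluid: FluidForcing | None = None,
                gravity=(0.0, 0.0, 0.0), ext_force: np.ndarray | None = None,
                history: dict | None = None, dt_limit: float | None = None,
                cache: dict | None = None) -> ParticleSet:
    """One velocity-Verlet DEM substep (in place; returns ``particles``).

    Contact forces are evaluated at the old and new positions (kick-drift-kick);
    the stiff drag relaxation toward the local fluid velocity is folded in with
    a semi-implicit update between the half-kicks, so a cell never overshoots
    the fluid velocity regardless of the drag coefficient magnitude.

    ``cache`` (a mutable dict) carries the end-of-step contact evaluation over
    to the next substep, halving the number of neighbour searches; it must be
    invalidated (cleared) whenever positions change outside this function.
    """
    if dt_limit is not None and dt >= dt_limit:
        raise ValueError(f"dt_dem={dt:.3e} violates the stability bound {dt_limit:.3e} "
                         "(0.1 min(t_Ray, t_Her))")
    m = particles.mass[:, None]
    g = np.asarray(gravity, dtype=float)

    def nondrag_accel(Fc):
        a = Fc / m + g
        if ext_force is not None:
            a = a + ext_force / m
        return a

    if cache is not None and "F" in cache:
        Fc, Tq = cache["F"], cache["T"]
    else:
        # re-evaluation at the current state: no tangential slip accumulation
        Fc, Tq, _, _ = contact_forces(particles, walls, params, history,
                                      pair_cache=cache, dt=0.0)
    particles.vel += 0.5 * dt * nondrag_accel(Fc)
    if fluid is not None:
        rel = particles.vel - fluid.u_f
        slip = np.minimum(np.sqrt(np.einsum("ij,ij->i", rel, rel)), fluid.slip_cap)
        beta = fluid.c_drag * slip
        fac = beta * dt / particles.mass
        small = fac < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            u_eq = fluid.u_f + np.where(small[:, None], 0.0,
                                        fluid.f_other / np.where(beta > 0, beta, 1.0)[:, None])
        decay = np.exp(-fac)[:, None]
        relaxed = u_eq + (particles.vel - u_eq) * decay
        kicked = particles.vel + dt * (fluid.f_other / m)  # free-drag limit
        particles.vel = np.where(small[:, None], kicked, relaxed)
    particles.omega += dt * Tq / particles.inertia[:, None]
    particles.pos += dt * particles.vel
    Fc2, Tq2, _, _ = contact_forces(particles, walls, params, history,
                                    pair_cache=cache, dt=dt)
    particles.vel += 0.5 * dt * nondrag_accel(Fc2)
    if cache is not None:
        cache["F"], cache["T"] = Fc2, Tq2
    return particles


# --------------------------------------------------------------------------
# jitted fast path for the inner substep loop

try:
    from numba import njit as _njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True)
def _eval_forces_nb(pos, vel, omg, rad, mass, pi, pj, xi_p, xi_w, wall_rw, use_wall,
                    e_star, g_star, beta_ratio, mu_f, dt_acc, F, T):
    """Accumulate pair + wall Hertz-Mindlin forces/torques into F, T.

    Tangential springs xi_p (per candidate pair) and xi_w (per particle, wall)
    integrate the slip when dt_acc > 0 and reset when the contact opens.
    Returns the maximum overlap ratio encountered.
    """
    n = pos.shape[0]
    for a in range(n):
        F[a, 0] = 0.0; F[a, 1] = 0.0; F[a, 2] = 0.0
        T[a, 0] = 0.0; T[a, 1] = 0.0; T[a, 2] = 0.0
    max_ov = 0.0
    two_sqrt56 = 2.0 * np.sqrt(5.0 / 6.0)

    for k in range(pi.shape[0]):
        i = pi[k]; j = pj[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dist2 = dx * dx + dy * dy + dz * dz
        sr = rad[i] + rad[j]
        if dist2 >= sr * sr or dist2 == 0.0:
            xi_p[k, 0] = 0.0; xi_p[k, 1] = 0.0; xi_p[k, 2] = 0.0
            continue
        dist = np.sqrt(dist2)
        delta = sr - dist
        ov = delta / min(2.0 * rad[i], 2.0 * rad[j])
        if ov > max_ov:
            max_ov = ov
        nx = dx / dist; ny = dy / dist; nz = dz / dist
        r_eff = rad[i] * rad[j] / sr
        m_eff = mass[i] * mass[j] / (mass[i] + mass[j])
        # contact point and lever arms
        li = rad[i] - 0.5 * delta
        cix = li * nx; ciy = li * ny; ciz = li * nz            # c - pos_i
        cjx = cix - dx; cjy = ciy - dy; cjz = ciz - dz          # c - pos_j
        vrx = (vel[i, 0] + omg[i, 1] * ciz - omg[i, 2] * ciy
               - vel[j, 0] - (omg[j, 1] * cjz - omg[j, 2] * cjy))
        vry = (vel[i, 1] + omg[i, 2] * cix - omg[i, 0] * ciz
               - vel[j, 1] - (omg[j, 2] * cjx - omg[j, 0] * cjz))
        vrz = (vel[i, 2] + omg[i, 0] * ciy - omg[i, 1] * cix
               - vel[j, 2] - (omg[j, 0] * cjy - omg[j, 1] * cjx))
        v_n = vrx * nx + vry * ny + vrz * nz
        sq = np.sqrt(r_eff * delta)
        f_el = (4.0 / 3.0) * e_star * sq * delta
        s_n = 2.0 * e_star * sq
        f_damp = two_sqrt56 * beta_ratio * np.sqrt(s_n * m_eff) * v_n
        fn = f_el + f_damp
        # tangential spring
        ftx = 0.0; fty = 0.0; ftz = 0.0
        if mu_f > 0.0:
            vtx = vrx - v_n * nx; vty = vry - v_n * ny; vtz = vrz - v_n * nz
            xi_p[k, 0] += vtx * dt_acc
            xi_p[k, 1] += vty * dt_acc
            xi_p[k, 2] += vtz * dt_acc
            k_t = 8.0 * g_star * sq
            ftx = -k_t * xi_p[k, 0]; fty = -k_t * xi_p[k, 1]; ftz = -k_t * xi_p[k, 2]
            mag = np.sqrt(ftx * ftx + fty * fty + ftz * ftz)
            cap = mu_f * f_el
            if mag > cap and mag > 0.0:
                s = cap / mag
                ftx *= s; fty *= s; ftz *= s
                xi_p[k, 0] *= s; xi_p[k, 1] *= s; xi_p[k, 2] *= s
        fx = -fn * nx + ftx; fy = -fn * ny + fty; fz = -fn * nz + ftz
        F[i, 0] += fx; F[i, 1] += fy; F[i, 2] += fz
        F[j, 0] -= fx; F[j, 1] -= fy; F[j, 2] -= fz
        T[i, 0] += ciy * ftz - ciz * fty
        T[i, 1] += ciz * ftx - cix * ftz
        T[i, 2] += cix * fty - ciy * ftx
        T[j, 0] -= cjy * ftz - cjz * fty
        T[j, 1] -= cjz * ftx - cjx * ftz
        T[j, 2] -= cjx * fty - cjy * ftx

    if use_wall:
        for i in range(n):
            s = np.sqrt(pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1])
            delta = s + rad[i] - wall_rw[i]
            if delta <= 0.0 or s == 0.0:
                xi_w[i, 0] = 0.0; xi_w[i, 1] = 0.0; xi_w[i, 2] = 0.0
                continue
            ov = delta / (2.0 * rad[i])
            if ov > max_ov:
                max_ov = ov
            nx = -pos[i, 0] / s; ny = -pos[i, 1] / s; nz = 0.0  # inward normal
            lw = rad[i] - 0.5 * delta
            cx = -lw * nx; cy = -lw * ny; cz = 0.0              # c - pos_i
            vrx = vel[i, 0] + omg[i, 1] * cz - omg[i, 2] * cy
            vry = vel[i, 1] + omg[i, 2] * cx - omg[i, 0] * cz
            vrz = vel[i, 2] + omg[i, 0] * cy - omg[i, 1] * cx
            v_n = -(vrx * nx + vry * ny)
            sq = np.sqrt(rad[i] * delta)
            f_el = (4.0 / 3.0) * e_star * sq * delta
            s_n = 2.0 * e_star * sq
            f_damp = two_sqrt56 * beta_ratio * np.sqrt(s_n * mass[i]) * v_n
            fn = f_el + f_damp
            ftx = 0.0; fty = 0.0; ftz = 0.0
            if mu_f > 0.0:
                vtx = vrx + v_n * nx; vty = vry + v_n * ny; vtz = vrz
                xi_w[i, 0] += vtx * dt_acc
                xi_w[i, 1] += vty * dt_acc
                xi_w[i, 2] += vtz * dt_acc
                k_t = 8.0 * g_star * sq
                ftx = -k_t * xi_w[i, 0]; fty = -k_t * xi_w[i, 1]; ftz = -k_t * xi_w[i, 2]
                mag = np.sqrt(ftx * ftx + fty * fty + ftz * ftz)
                cap = mu_f * f_el
                if mag > cap and mag > 0.0:
                    sc = cap / mag
                    ftx *= sc; fty *= sc; ftz *= sc
                    xi_w[i, 0] *= sc; xi_w[i, 1] *= sc; xi_w[i, 2] *= sc
            F[i, 0] += fn * nx + ftx
            F[i, 1] += fn * ny + fty
            F[i, 2] += ftz
            T[i, 0] += cy * ftz - cz * fty
            T[i, 1] += cz * ftx - cx * ftz
            T[i, 2] += cx * fty - cy * ftx
    return max_ov


@_njit(cache=True)
def _substeps_nb(pos, vel, omg, mass, inertia, rad, vol, pi, pj, xi_p, xi_w,
                 wall_rw, use_wall, e_star, g_star, beta_ratio, mu_f,
                 u_f, c_drag, f_other, slip_cap, use_fluid,
                 gx, gy, gz, dt, n_sub, z_plane, L_per):
    """Run ``n_sub`` velocity-Verlet substeps with frozen fluid forcing.

    Mirrors :func:`dem_substep` (kick - drag relaxation - drift - kick) with
    signed flux-plane crossing counting and periodic z-wrapping.  Returns
    ``(crossed_volume, max_overlap_ratio)``.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    T = np.zeros((n, 3))
    max_ov = _eval_forces_nb(pos, vel, omg, rad, mass, pi, pj, xi_p, xi_w, wall_rw,
                             use_wall, e_star, g_star, beta_ratio, mu_f, 0.0, F, T)
    crossed = 0.0
    for s in range(n_sub):
        for i in range(n):
            m = mass[i]
            vel[i, 0] += 0.5 * dt * (F[i, 0] / m + gx)
            vel[i, 1] += 0.5 * dt * (F[i, 1] / m + gy)
            vel[i, 2] += 0.5 * dt * (F[i, 2] / m + gz)
            if use_fluid:
                rx = vel[i, 0] - u_f[i, 0]
                ry = vel[i, 1] - u_f[i, 1]
                rz = vel[i, 2] - u_f[i, 2]
                slip = np.sqrt(rx * rx + ry * ry + rz * rz)
                if slip > slip_cap:
                    slip = slip_cap
                beta = c_drag[i] * slip
                fac = beta * dt / m
                if fac < 1e-12:
                    vel[i, 0] += dt * f_other[i, 0] / m
                    vel[i, 1] += dt * f_other[i, 1] / m
                    vel[i, 2] += dt * f_other[i, 2] / m
                else:
                    ex = np.exp(-fac)
                    ueqx = u_f[i, 0] + f_other[i, 0] / beta
                    ueqy = u_f[i, 1] + f_other[i, 1] / beta
                    ueqz = u_f[i, 2] + f_other[i, 2] / beta
                    vel[i, 0] = ueqx + (vel[i, 0] - ueqx) * ex
                    vel[i, 1] = ueqy + (vel[i, 1] - ueqy) * ex
                    vel[i, 2] = ueqz + (vel[i, 2] - ueqz) * ex
            om = inertia[i]
            omg[i, 0] += dt * T[i, 0] / om
            omg[i, 1] += dt * T[i, 1] / om
            omg[i, 2] += dt * T[i, 2] / om
            z_old = pos[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            z_new = z_old + dt * vel[i, 2]
            if z_old < z_plane and z_new >= z_plane:
                crossed += vol[i]
            elif z_old >= z_plane and z_new < z_plane:
                crossed -= vol[i]
            if z_new >= L_per:
                z_new -= L_per
            elif z_new < 0.0:
                z_new += L_per
            pos[i, 2] = z_new
        ov = _eval_forces_nb(pos, vel, omg, rad, mass, pi, pj, xi_p, xi_w, wall_rw,
                             use_wall, e_star, g_star, beta_ratio, mu_f, dt, F, T)
        if ov > max_ov:
            max_ov = ov
        for i in range(n):
            m = mass[i]
            vel[i, 0] += 0.5 * dt * (F[i, 0] / m + gx)
            vel[i, 1] += 0.5 * dt * (F[i, 1] / m + gy)
            vel[i, 2] += 0.5 * dt * (F[i, 2] / m + gz)
    return crossed, max_ov
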