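"""Case and fixture generation: channel specifications, particle seedings,
stenosis/bifurcation geometries and the resolved-campaign grid.

The closures were fitted on a single-cell campaign in a cylindrical channel
(radius 25 um) spanning six dimensionless radial positions
``r* = r/R_c in {0.2 .. 0.7}`` and five channel Reynolds numbers
``Re = rho D U_max / mu in {0.1 .. 0.5}``; for pipe Poiseuille flow the
dimensionless shear rate reduces to ``gamma+ = Re r*``, giving the data range
gamma+ in [0.02, 0.35].  :func:`campaign_grid` reproduces that grid and is the
anchor for the validity envelope of every closure evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .closures import LocalFlow, dimensionless_state
from .dem import ContactParams

__all__ = [
    "ChannelSpec",
    "CampaignPoint",
    "CaseConfig",
    "campaign_grid",
    "seed_particles",
    "stenosis_case",
    "bifurcation_case",
    "BifurcationCase",
]

#: reference fluid (blood plasma) used when a case does not override it
PLASMA_RHO = 1000.0   # kg/m^3
PLASMA_MU = 1.2e-3    # Pa s
#: volume-equivalent sphere diameter of an undeformed RBC (~90 fL)
RBC_EQUIV_DIAMETER = 5.6e-6
RBC_DENSITY = 1100.0


@dataclass
class StenosisSpec:
    """Axisymmetric cosine constriction centred at z = L/2."""

    throat: float          # minimum channel *diameter* [m]
    length: float          # axial extent of the constriction [m]


@dataclass
class ChannelSpec:
    """Geometry and driving conditions of a channel case.

    ``Re = rho D U_max / mu`` is the channel Reynolds number; the channel
    hematocrit ``Ht_c`` is the seeded RBC volume fraction.  The closures are
    single-cell based: hematocrits above 5% trigger a warning and above 15%
    (the demonstrated validity bound) an error.
    """

    R_c: float
    L: float
    Re: float
    Ht_c: float = 0.0
    rho: float = PLASMA_RHO
    mu: float = PLASMA_MU
    topology: str = "cylinder"
    stenosis: StenosisSpec | None = None

    def __post_init__(self):
        if self.R_c <= 0 or self.L <= 0 or self.Re < 0:
            raise ValueError("R_c, L must be positive and Re >= 0")
        if self.Ht_c < 0 or self.Ht_c > 0.15:
            raise ValueError("Ht_c must lie in [0, 0.15] (closures are single-cell based)")
        if self.Ht_c > 0.05:
            warnings.warn("Ht_c above 5%: outside the dilute regime the closures were "
                          "exercised in", RuntimeWarning, stacklevel=2)

    @property
    def D(self) -> float:
        return 2.0 * self.R_c

    @property
    def nu(self) -> float:
        return self.mu / self.rho

    @property
    def u_max(self) -> float:
        """Centreline velocity of the unladen Poiseuille base flow."""
        return self.Re * self.mu / (self.rho * self.D)

    @property
    def u_av(self) -> float:
        return 0.5 * self.u_max if self.topology == "cylinder" else (2.0 / 3.0) * self.u_max

    @property
    def body_force(self) -> float:
        """Axial driving force density reproducing u_max in pure plasma."""
        if self.topology == "cylinder":
            return 4.0 * self.mu * self.u_max / self.R_c**2
        return 8.0 * self.mu * self.u_max / self.R_c**2  # parabola across height R_c

    @property
    def plasma_flux(self) -> float:
        """Hagen-Poiseuille volumetric flux of pure plasma at the same driving."""
        if self.topology != "cylinder":
            raise NotImplementedError("analytic plasma flux implemented for cylinders")
        return np.pi * self.body_force * self.R_c**4 / (8.0 * self.mu)

    def wall_radius(self, z):
        """Local wall radius (half-height) as a function of z."""
        z = np.asarray(z, dtype=float)
        base = np.full(z.shape, self.R_c)
        if self.stenosis is None:
            return base
        r_throat = 0.5 * self.stenosis.throat
        half = 0.5 * self.stenosis.length
        dzc = z - 0.5 * self.L
        inside = np.abs(dzc) < half
        depth = (self.R_c - r_throat) * 0.5 * (1.0 + np.cos(np.pi * dzc / half))
        return np.where(inside, self.R_c - depth, base)

    def fluid_volume(self) -> float:
        if self.topology != "cylinder":
            raise NotImplementedError
        if self.stenosis is None:
            return np.pi * self.R_c**2 * self.L
        z = np.linspace(0, self.L, 4097)
        return float(np.trapezoid(np.pi * self.wall_radius(z) ** 2, z))


@dataclass(frozen=True)
class CampaignPoint:
    Re: float
    r_star: float
    gamma_plus: float


CAMPAIGN_R_STAR = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
CAMPAIGN_RE = (0.1, 0.2, 0.3, 0.4, 0.5)


def campaign_grid(R_c: float = 25e-6, rho: float = PLASMA_RHO, mu: float = PLASMA_MU):
    """The 6 x 5 (r*, Re) grid of the resolved closure-fitting campaign.

    gamma+ is evaluated through the closure pipeline on the analytic Poiseuille
    profile (shear 2 U_max r / R_c^2), not through the algebraic shortcut
    gamma+ = Re r*, so the reduction itself is exercised.
    """
    nu = mu / rho
    points = []
    for re_ in CAMPAIGN_RE:
        u_max = re_ * mu / (rho * 2.0 * R_c)
        for r_star in CAMPAIGN_R_STAR:
            shear = 2.0 * u_max * (r_star * R_c) / R_c**2
            flow = LocalFlow(
                u_fluid=np.zeros(3), u_particle=np.zeros(3), shear_rate=shear,
                radial_unit=np.array([-1.0, 0.0, 0.0]), u_av=0.5 * u_max,
                nu=nu, rho=rho, d_p=RBC_EQUIV_DIAMETER, R_c=R_c,
            )
            s = dimensionless_state(flow, np.array([0.0, 0.0, 1.0]))
            points.append(CampaignPoint(Re=re_, r_star=r_star, gamma_plus=s.gamma_plus))
    return points


def seed_particles(spec: ChannelSpec, d_p: float = RBC_EQUIV_DIAMETER, seed: int = 0,
                   max_tries: int = 20000) -> np.ndarray:
    """Uniform random non-overlapping particle positions at the target hematocrit.

    Particle count ``N = round(Ht_c V_channel / V_p)``; placements keep a wall
    clearance of d_p/2 and are deterministic for a given seed.  Raises if the
    rejection budget is exhausted (hematocrit too high for the geometry).
    """
    if spec.topology != "cylinder":
        raise NotImplementedError("seeding implemented for cylindrical channels")
    v_p = np.pi * d_p**3 / 6.0
    n_target = int(round(spec.Ht_c * spec.fluid_volume() / v_p))
    if n_target == 0:
        return np.zeros((0, 3))
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_target, 3))
    count = 0
    tries = 0
    while count < n_target:
        if tries >= max_tries:
            raise RuntimeError(
                f"seeding rejection budget exhausted after {tries} tries at Ht_c={spec.Ht_c}; "
                "lower the hematocrit or enlarge the channel")
        tries += 1
        z = rng.uniform(0.0, spec.L)
        r_max = float(spec.wall_radius(z)) - 0.5 * d_p
        if r_max <= 0:
            continue
        r = r_max * np.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * np.pi)
        cand = np.array([r * np.cos(th), r * np.sin(th), z])
        if count:
            d = pos[:count] - cand
            d[:, 2] -= spec.L * np.round(d[:, 2] / spec.L)  # periodic axial images
            if np.min(np.einsum("ij,ij->i", d, d)) < d_p**2:
                continue
        pos[count] = cand
        count += 1
    return pos


def stenosis_case(D: float, throat: float, L: float | None = None, Re: float = 0.5,
                  Ht_c: float = 0.05, stenosis_length: float | None = None) -> ChannelSpec:
    """Axisymmetric stenosed channel (vein-occlusion style constriction)."""
    if throat > D:
        raise ValueError("throat must not exceed the channel diameter")
    L = 4.0 * D if L is None else L
    sten = None
    if throat < D:
        sten = StenosisSpec(throat=throat, length=stenosis_length or 1.5 * D)
    return ChannelSpec(R_c=0.5 * D, L=L, Re=Re, Ht_c=Ht_c, stenosis=sten)


@dataclass
class CutSpec:
    """Measurement cut for hematocrit profiles: centre, in-plane direction, half-width."""

    center: tuple
    direction: tuple
    half_width: float


@dataclass
class BifurcationCase:
    """Planar approximation of a bifurcated microfluidic channel.

    The parent/outlet channel runs straight along z; the daughter branch
    leaves the junction at angle ``alpha`` (degrees).  Hematocrit-profile cuts
    sit 200 um downstream of the bifurcation in each branch, where the
    skewness index S_H is measured.  This is a planar stand-in for the 3D
    device geometry; S_H comparisons on it are qualitative only.
    """

    alpha_deg: float
    width: float = 100e-6
    daughter_width: float = 50e-6
    parent_length: float = 400e-6
    branch_length: float = 400e-6
    cut_distance: float = 200e-6

    def __post_init__(self):
        if not (0.0 < self.alpha_deg <= 90.0):
            raise ValueError("alpha must lie in (0, 90] degrees")

    @property
    def daughter_direction(self):
        """Unit vector of the daughter centreline in the (z, y) plane."""
        a = np.deg2rad(self.alpha_deg)
        return np.array([np.cos(a), np.sin(a)])

    @property
    def domain_size(self):
        """(height H, length L) of the planar domain."""
        dy = self.branch_length * self.daughter_direction[1] + self.daughter_width
        H = self.width + dy + self.width  # parent strip + head room for the daughter
        L = self.parent_length + self.branch_length + self.daughter_width
        return H, L

    @property
    def junction(self):
        """(z, y) of the bifurcation point on the parent centreline."""
        return np.array([self.parent_length, 0.5 * self.width])

    def solid_mask(self, y_centers, z_centers):
        """Boolean solid mask on a planar grid (True = blocked)."""
        zz, yy = np.meshgrid(z_centers, y_centers)
        in_parent = np.abs(yy - 0.5 * self.width) < 0.5 * self.width
        o = self.junction
        d = self.daughter_direction
        pz, py = zz - o[0], yy - o[1]
        t = pz * d[0] + py * d[1]
        perp = np.abs(-pz * d[1] + py * d[0])
        in_daughter = (t >= 0) & (t <= self.branch_length) & (perp < 0.5 * self.daughter_width)
        return ~(in_parent | in_daughter)

    @property
    def cuts(self):
        """Hematocrit-profile cuts 200 um past the junction in each branch."""
        o = self.junction
        d = self.daughter_direction
        outlet = CutSpec(center=(o[0] + self.cut_distance, o[1]),
                         direction=(0.0, 1.0), half_width=0.5 * self.width)
        c = o + self.cut_distance * d
        daughter = CutSpec(center=tuple(c), direction=(-d[1], d[0]),
                           half_width=0.5 * self.daughter_width)
        return {"outlet": outlet, "daughter": daughter}


def bifurcation_case(alpha_deg: float, **kwargs) -> BifurcationCase:
    return BifurcationCase(alpha_deg=alpha_deg, **kwargs)


# --------------------------------------------------------------------------
# case configuration


@dataclass
class CaseConfig:
    """Complete configuration of a coupled run (YAML-serializable)."""

    channel: ChannelSpec
    d_p: float = RBC_EQUIV_DIAMETER
    rho_p: float = RBC_DENSITY
    contacts: ContactParams = field(default_factory=ContactParams)
    resolution: tuple = (16, 32)
    n_coupling: int = 10
    courant_target: float = 0.15
    seed: int = 0
    t_end: float | None = None
    gravity: tuple = (0.0, 0.0, 0.0)
    lift_enabled: bool = True
    steady_window_flowthroughs: float = 20.0
    steady_tol: float = 0.01
    recycle_inlet: bool = False   # stenosis-style inlet injection with recycling
    output_every: int = 0         # coupling steps between field snapshots (0 = none)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resolution"] = list(self.resolution)
        d["gravity"] = list(self.gravity)
        return d

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        d = dict(d)
        ch = dict(d.pop("channel"))
        sten = ch.pop("stenosis", None)
        if sten:
            ch["stenosis"] = StenosisSpec(**sten)
        contacts = d.pop("contacts", None)
        kwargs = {}
        if contacts:
            kwargs["contacts"] = ContactParams(**contacts)
        if "resolution" in d:
            d["resolution"] = tuple(d["resolution"])
        if "gravity" in d:
            d["gravity"] = tuple(d["gravity"])
        return cls(channel=ChannelSpec(**ch), **kwargs, **d)

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def straight_channel_case(D: float = 50e-6, L: float = 200e-6, Re: float = 0.5,
                          Ht_c: float = 0.05, seed: int = 0, **overrides) -> CaseConfig:
    """The straight-channel validation case (Fahraeus-Lindqvist benchmark).

    Defaults: one diameter (50 um), channel hematocrit 5%, the largest
    campaign Reynolds number, a coarse 16 x 32 axisymmetric grid, and a
    contact stiffness of E = 5 kPa.  The stiffness matters: the sheared,
    lift-compressed cell core carries drag-driven contact-chain loads of
    order 1e-9 N, and softer spheres (1 kPa and below) collapse into deep
    overlaps that break volume exclusion entirely; at 5 kPa overlaps stay at
    a few percent.  The DEM step follows the Rayleigh criterion and the
    coupling interval (134) brings the CFD step to the Courant target (0.2,
    the upper end of common practice).
    """
    cfg = CaseConfig(
        channel=ChannelSpec(R_c=0.5 * D, L=L, Re=Re, Ht_c=Ht_c),
        contacts=ContactParams(young=5000.0),
        n_coupling=134,
        courant_target=0.2,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
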