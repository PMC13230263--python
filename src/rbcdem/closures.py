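"""Sub-grid red-blood-cell closure models.

An unresolved CFD-DEM simulation represents each RBC as a volume-equivalent
sphere; the physics lost by not resolving the membrane is reintroduced through
closure correlations fitted on resolved single-cell simulations.  Three
quantities are modelled from the local, dimensionless flow state:

* the deformation index ``DI = (L - B)/(L + B)`` of the cell,
* the drag coefficient ``C_d(DI, Re_p)``,
* the deformability-induced lift coefficient ``C_l(DI, Re_p)``.

The correlations are rational fits valid on the envelope sampled by the
resolved campaign (dimensionless shear rate ``gamma+ in [0.02, 0.35]``,
particle Reynolds number ``Re_p in [0.01, 0.12]``).  Outside that envelope the
raw expressions are singular (both coefficients diverge as ``Re_p -> 0``, the
lift as ``DI -> 0``), so coefficient evaluation clamps its arguments to the
envelope edge while the force formulas keep the true relative velocity; forces
therefore remain finite and vanish smoothly with vanishing slip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LocalFlow",
    "DimensionlessState",
    "ClosureOutputs",
    "ClosureModel",
    "dimensionless_state",
    "deformation_index",
    "drag_coefficient",
    "lift_coefficient",
    "drag_force",
    "lift_force",
]

#: lower clamp on the deformation index before evaluating the lift
#: coefficient (the 0.0008 Re_p / DI^3 term is singular at DI = 0).
DI_FLOOR = 1e-3
#: upper clamp on the deformation index (DI < 1 by definition).
DI_CEIL = 0.999
#: particle Reynolds number range used for *coefficient* evaluation: the
#: fitted envelope of the resolved campaign.  The drag fit behaves as
#: 0.00146/Re_p^3 for Re_p -> 0, which would lock particles rigidly to the
#: fluid; evaluating the coefficients at the envelope edge keeps the model
#: inside its fitted range and the forces finite.
RE_P_FLOOR = 0.01
RE_P_CEIL = 0.12
#: deformation-index range for coefficient evaluation.  The campaign sampled
#: gamma+ in [0.02, 0.35] and slip ratios |u_r+| <= 1, which maps to
#: DI in ~[0.003, 0.12]; below that range the 0.0008 Re_p / DI^3 lift term is
#: an unphysical extrapolation that grows faster than the drag can damp
#: (a lift ~ slip^3 runaway), so it too is clamped to the envelope edge.
DI_EVAL_MIN = 0.003
DI_EVAL_MAX = 0.12


@dataclass(frozen=True)
class LocalFlow:
    """Undisturbed flow state interpolated at a particle centre.

    Velocities in m/s, lengths in m, ``shear_rate`` is the magnitude of the
    wall-normal gradient of the streamwise velocity in 1/s.  ``radial_unit``
    points from the particle toward the channel axis (zero exactly on the
    axis), so a positive lift coefficient drives centerward migration.
    """

    u_fluid: np.ndarray
    u_particle: np.ndarray
    shear_rate: float
    radial_unit: np.ndarray
    u_av: float
    nu: float
    rho: float
    d_p: float
    R_c: float

    def __post_init__(self):
        object.__setattr__(self, "u_fluid", np.asarray(self.u_fluid, dtype=float))
        object.__setattr__(self, "u_particle", np.asarray(self.u_particle, dtype=float))
        object.__setattr__(self, "radial_unit", np.asarray(self.radial_unit, dtype=float))
        if self.shear_rate < 0:
            raise ValueError("shear_rate must be >= 0")
        if self.nu <= 0 or self.d_p <= 0 or self.R_c <= 0:
            raise ValueError("nu, d_p and R_c must be positive")
        n = np.linalg.norm(self.radial_unit)
        if n > 0 and abs(n - 1.0) > 1e-9:
            raise ValueError("radial_unit must be a unit vector or exactly zero")


@dataclass(frozen=True)
class DimensionlessState:
    """(gamma+, u_r+, Re_p) evaluated at a particle."""

    gamma_plus: float
    u_r_plus: float
    re_p: float


@dataclass(frozen=True)
class ClosureOutputs:
    DI: float
    C_d: float
    C_l: float
    F_drag: np.ndarray = field(default_factory=lambda: np.zeros(3))
    F_lift: np.ndarray = field(default_factory=lambda: np.zeros(3))


def dimensionless_state(flow: LocalFlow, flow_direction: np.ndarray) -> DimensionlessState:
    """Map a local flow state to the dimensionless groups of the closures.

    gamma+ = shear_rate * R_c^2 / nu, u_r+ = ((u_p - u) . e_flow)/u_av
    (signed), Re_p = d_p |u_p - u| / nu.
    """
    if flow.u_av == 0:
        raise ValueError("u_av must be nonzero to form u_r+")
    e = np.asarray(flow_direction, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > 1e-9:
        raise ValueError("flow_direction must be a unit vector")
    rel = flow.u_particle - flow.u_fluid
    return DimensionlessState(
        gamma_plus=flow.shear_rate * flow.R_c**2 / flow.nu,
        u_r_plus=float(np.dot(rel, e)) / flow.u_av,
        re_p=flow.d_p * float(np.linalg.norm(rel)) / flow.nu,
    )


def _di_raw(gamma_plus, u_r_plus):
    g3 = np.asarray(gamma_plus, dtype=float) ** 3
    u = np.asarray(u_r_plus, dtype=float)
    denom = g3 * (10.0 + u**3) + 0.117 * np.asarray(gamma_plus, dtype=float) ** 2 * (u - u**4) + 0.0026
    return g3, denom


def deformation_index(s: DimensionlessState, di_floor: float = DI_FLOOR, di_ceil: float = DI_CEIL) -> float:
    """Deformation index of the cell from the rational fit, clamped to [di_floor, di_ceil].

    A non-positive denominator marks an input outside the fitted envelope; the
    floor value is returned and a warning is emitted rather than extrapolating.
    """
    num, denom = _di_raw(s.gamma_plus, s.u_r_plus)
    if denom <= 0:
        warnings.warn(
            f"deformation-index denominator <= 0 for gamma+={s.gamma_plus}, "
            f"u_r+={s.u_r_plus}: input outside the fitted envelope, returning floor",
            RuntimeWarning,
            stacklevel=2,
        )
        return di_floor
    return float(np.clip(num / denom, di_floor, di_ceil))


def drag_coefficient(DI: float, re_p: float) -> float:
    """Drag coefficient ``(169 Re_p^2 (DI+1) + 0.00146) / Re_p^3``."""
    re_p = np.asarray(re_p, dtype=float)
    if np.any(re_p <= 0):
        raise ValueError("drag_coefficient requires Re_p > 0 (caller must floor)")
    out = (169.0 * re_p**2 * (np.asarray(DI) + 1.0) + 0.00146) / re_p**3
    return float(out) if out.ndim == 0 else out


def lift_coefficient(DI: float, re_p: float) -> float:
    """Lift coefficient ``-3.19 DI^4/Re_p + 2.48 DI/Re_p + 0.0008 Re_p/DI^3`` (signed)."""
    DI = np.asarray(DI, dtype=float)
    re_p = np.asarray(re_p, dtype=float)
    if np.any(re_p <= 0) or np.any(DI <= 0):
        raise ValueError("lift_coefficient requires Re_p > 0 and DI > 0 (caller must floor)")
    out = -3.19 * DI**4 / re_p + 2.48 * DI / re_p + 0.0008 * re_p / DI**3
    return float(out) if out.ndim == 0 else out


def drag_force(flow: LocalFlow, C_d: float) -> np.ndarray:
    """Drag force ``0.125 C_d rho pi d_p^2 |u - u_p| (u - u_p)`` [N]."""
    rel = flow.u_fluid - flow.u_particle
    return 0.125 * C_d * flow.rho * np.pi * flow.d_p**2 * np.linalg.norm(rel) * rel


def lift_force(flow: LocalFlow, C_l: float) -> np.ndarray:
    """Lift force ``C_l rho d_p^4 (shear^2 + |u_p - u|^2/d_p^2) r_hat`` [N].

    ``r_hat`` points toward the channel axis; on the axis it is the zero
    vector and the lift vanishes.
    """
    rel = flow.u_particle - flow.u_fluid
    mag = C_l * flow.rho * flow.d_p**4 * (
        flow.shear_rate**2 + float(np.dot(rel, rel)) / flow.d_p**2
    )
    return mag * flow.radial_unit


@dataclass
class ClosureModel:
    """Bundled closure evaluation with the envelope-clamping policy.

    ``re_p_floor``/``di_floor`` are the envelope clamps applied before
    coefficient evaluation; both are configuration values, defaulting to the
    edge of the fitted data range (Re_p) and to a small positive floor that
    regularizes the DI -> 0 lift singularity.
    """

    di_floor: float = DI_FLOOR
    di_ceil: float = DI_CEIL
    re_p_floor: float = RE_P_FLOOR
    re_p_ceil: float = RE_P_CEIL
    di_eval_min: float = DI_EVAL_MIN
    di_eval_max: float = DI_EVAL_MAX
    #: slip magnitude used in closure evaluation is capped at this multiple of
    #: u_av — the fit covers |u_r+| = |u_p - u|/u_av <= 1, and letting the
    #: quadratic force formulas run on out-of-envelope slips makes the lift
    #: grow faster than the drag can damp it.
    slip_cap_u_av: float = 1.0
    lift_enabled: bool = True

    def _capped_flow(self, flow: LocalFlow) -> LocalFlow:
        rel = flow.u_particle - flow.u_fluid
        mag = float(np.linalg.norm(rel))
        cap = self.slip_cap_u_av * flow.u_av
        if mag <= cap or mag == 0.0:
            return flow
        return LocalFlow(flow.u_fluid, flow.u_fluid + rel * (cap / mag), flow.shear_rate,
                         flow.radial_unit, flow.u_av, flow.nu, flow.rho, flow.d_p, flow.R_c)

    def evaluate(self, flow: LocalFlow, flow_direction: np.ndarray) -> ClosureOutputs:
        flow = self._capped_flow(flow)
        s = dimensionless_state(flow, flow_direction)
        DI = deformation_index(s, self.di_floor, self.di_ceil)
        re_eval = float(np.clip(s.re_p, self.re_p_floor, self.re_p_ceil))
        di_eval = float(np.clip(DI, self.di_eval_min, self.di_eval_max))
        C_d = drag_coefficient(di_eval, re_eval)
        C_l = lift_coefficient(di_eval, re_eval) if self.lift_enabled else 0.0
        return ClosureOutputs(
            DI=DI,
            C_d=C_d,
            C_l=C_l,
            F_drag=drag_force(flow, C_d),
            F_lift=lift_force(flow, C_l),
        )

    # vectorised path used by the coupled solver -------------------------------

    def evaluate_batch(
        self,
        u_fluid: np.ndarray,
        u_particle: np.ndarray,
        shear_rate: np.ndarray,
        radial_unit: np.ndarray,
        flow_direction: np.ndarray,
        u_av: float,
        nu: float,
        rho: float,
        d_p: np.ndarray,
        R_c: float,
    ):
        """Evaluate DI, C_d, C_l and the drag/lift forces for N particles at once.

        Shapes: velocities and unit vectors are (N, 3); ``shear_rate`` and
        ``d_p`` broadcast to (N,).  Returns ``(DI, C_d, C_l, F_drag, F_lift)``.
        """
        rel = u_particle - u_fluid  # u_p - u
        rel_mag = np.linalg.norm(rel, axis=1)
        cap = self.slip_cap_u_av * u_av
        scale = np.where(rel_mag > cap, cap / np.where(rel_mag > 0, rel_mag, 1.0), 1.0)
        rel = rel * scale[:, None]
        rel_mag = rel_mag * scale
        d_p = np.broadcast_to(np.asarray(d_p, dtype=float), rel_mag.shape)
        shear_rate = np.broadcast_to(np.asarray(shear_rate, dtype=float), rel_mag.shape)

        gamma_plus = shear_rate * R_c**2 / nu
        u_r_plus = np.einsum("ij,ij->i", rel, np.broadcast_to(flow_direction, rel.shape)) / u_av
        re_p = d_p * rel_mag / nu

        num, denom = _di_raw(gamma_plus, u_r_plus)
        with np.errstate(divide="ignore", invalid="ignore"):
            di = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), self.di_floor)
        di = np.clip(di, self.di_floor, self.di_ceil)

        re_eval = np.clip(re_p, self.re_p_floor, self.re_p_ceil)
        di_eval = np.clip(di, self.di_eval_min, self.di_eval_max)
        c_d = (169.0 * re_eval**2 * (di_eval + 1.0) + 0.00146) / re_eval**3
        if self.lift_enabled:
            c_l = (-3.19 * di_eval**4 / re_eval + 2.48 * di_eval / re_eval
                   + 0.0008 * re_eval / di_eval**3)
        else:
            c_l = np.zeros_like(c_d)

        f_drag = (0.125 * c_d * rho * np.pi * d_p**2 * rel_mag)[:, None] * (-rel)
        lift_mag = c_l * rho * d_p**4 * (shear_rate**2 + (rel_mag / d_p) ** 2)
        f_lift = lift_mag[:, None] * radial_unit
        return di, c_d, c_l, f_drag, f_lift
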